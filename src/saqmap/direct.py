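"""Direct mapping estimators: regressions of utility on SAQ subscales.

Direct mapping regresses the EQ-5D-5L utility on the five SAQ subscale
scores.  Five non-mixture estimators are provided, chosen for how they
handle the utility distribution's quirks (ceiling at 1, left skew,
outliers):

* OLS — the conventional baseline;
* Tobit — normal MLE with right-censoring at 1, for the ceiling pile-up;
* log-link Gaussian GLM — multiplicative mean structure for skewness;
* CLAD — censored least absolute deviations (Powell), a median regression
  robust to the censoring mechanism and error distribution;
* RMM — the MM robust regression estimator (high-breakdown S scale
  followed by an efficient bisquare M step), for outliers and
  heteroskedasticity.

The design matrix is an intercept plus the five subscales divided by 100,
so coefficients refer to the 0–1 subscale scale (column order PL, AS, AF,
TS, DP).  Predictions are reported on the latent (uncensored) scale unless
explicitly clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm
from statsmodels.regression.quantile_regression import QuantReg

from .valuesets import SUBSCALES

DESIGN_COLUMNS = ("const", "pl", "as", "af", "ts", "dp")


def build_design(scores: pd.DataFrame) -> pd.DataFrame:
    """Intercept + five SAQ subscales on the 0–1 scale (score / 100).

    ``scores`` must contain columns pl, as, af, ts, dp on 0–100 with no
    missing cells.
    """
    missing = [c for c in SUBSCALES if c not in scores.columns]
    if missing:
        raise ValueError(f"design needs subscale columns {missing}")
    block = scores[list(SUBSCALES)].astype(float)
    if block.isna().any().any():
        bad = block.columns[block.isna().any()].tolist()
        raise ValueError(f"design has missing cells in {bad}")
    X = block / 100.0
    X.insert(0, "const", 1.0)
    X.columns = list(DESIGN_COLUMNS)
    return X


def _check_design(X: pd.DataFrame) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("design must be 2-D")
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name columns involved in collinearity via QR pivoting
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        bad = [str(c) for c, d in zip(X.columns, diag) if d < 1e-8 * diag.max()]
        raise ValueError(f"rank-deficient design; collinear columns: {bad or 'unknown'}")
    return arr


@dataclass
class FittedDirectModel:
    """A fitted direct-mapping regression."""

    method: str
    beta: np.ndarray                     # intercept + 5 subscale coefficients
    columns: tuple[str, ...] = DESIGN_COLUMNS
    sigma: float | None = None           # residual scale (Tobit, RMM)
    vcov: np.ndarray | None = None
    converged: bool = True
    n_iter: int = 0
    objective: float = float("nan")

    def predict(self, X: pd.DataFrame, *, truncate: bool = False,
                floor: float = -0.391, ceiling: float = 1.0) -> np.ndarray:
        return predict_direct(self, X, truncate=truncate, floor=floor, ceiling=ceiling)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "columns": list(self.columns),
            "beta": [float(b) for b in self.beta],
            "sigma": None if self.sigma is None else float(self.sigma),
            "vcov": None if self.vcov is None else np.asarray(self.vcov).tolist(),
            "convergence": {
                "converged": bool(self.converged),
                "n_iter": int(self.n_iter),
                "objective": float(self.objective),
            },
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FittedDirectModel":
        conv = doc.get("convergence", {})
        return cls(
            method=doc["method"],
            beta=np.asarray(doc["beta"], dtype=float),
            columns=tuple(doc.get("columns", DESIGN_COLUMNS)),
            sigma=doc.get("sigma"),
            vcov=None if doc.get("vcov") is None else np.asarray(doc["vcov"], dtype=float),
            converged=conv.get("converged", True),
            n_iter=conv.get("n_iter", 0),
            objective=conv.get("objective", float("nan")),
        )


def predict_direct(model: FittedDirectModel, X: pd.DataFrame, *,
                   truncate: bool = False, floor: float = -0.391,
                   ceiling: float = 1.0) -> np.ndarray:
    """Method-appropriate prediction: x'β, or exp(x'β) for the log GLM."""
    if tuple(X.columns) != tuple(model.columns):
        raise ValueError(
            f"design columns {tuple(X.columns)} do not match training columns "
            f"{tuple(model.columns)}"
        )
    index = np.asarray(X, dtype=float) @ model.beta
    pred = np.exp(index) if model.method == "glm" else index
    if truncate:
        pred = np.clip(pred, floor, ceiling)
    return pred


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def fit_ols(X: pd.DataFrame, y: Sequence[float]) -> FittedDirectModel:
    """Ordinary least squares."""
    arr = _check_design(X)
    res = sm.OLS(np.asarray(y, dtype=float), arr).fit()
    return FittedDirectModel(
        method="ols",
        beta=np.asarray(res.params),
        columns=tuple(X.columns),
        sigma=float(np.sqrt(res.scale)),
        vcov=np.asarray(res.cov_params()),
        converged=True,
        objective=float(res.ssr),
    )


def fit_glm_log(X: pd.DataFrame, y: Sequence[float]) -> FittedDirectModel:
    """Gaussian GLM with log link, fitted by IRLS; prediction is exp(x'β)."""
    arr = _check_design(X)
    yv = np.asarray(y, dtype=float)
    # IRLS needs strictly positive fitted means throughout; start from an
    # OLS fit on log responses (floored away from zero), which also covers
    # the occasional non-positive observed utility
    start = sm.OLS(np.log(np.clip(yv, 0.05, None)), arr).fit().params
    model = sm.GLM(yv, arr, family=sm.families.Gaussian(sm.families.links.Log()))
    res = model.fit(start_params=start)
    return FittedDirectModel(
        method="glm",
        beta=np.asarray(res.params),
        columns=tuple(X.columns),
        vcov=np.asarray(res.cov_params()),
        converged=bool(res.converged),
        n_iter=int(res.fit_history.get("iteration", 0)) if res.fit_history else 0,
        objective=float(res.deviance),
    )


def _tobit_negll(params: np.ndarray, X: np.ndarray, y: np.ndarray,
                 upper: float) -> float:
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    mu = X @ beta
    cens = y >= upper
    z = (y[~cens] - mu[~cens]) / sigma
    ll = np.sum(scipy.stats.norm.logpdf(z) - log_sigma)
    zc = (upper - mu[cens]) / sigma
    ll += np.sum(scipy.stats.norm.logsf(zc))
    return -ll


def fit_tobit(X: pd.DataFrame, y: Sequence[float], upper: float = 1.0) -> FittedDirectModel:
    """Normal MLE with right-censoring at ``upper`` (default 1).

    Observations at the censoring point contribute the mass
    1 − Φ((upper − x'β)/σ); the rest contribute the normal density.
    Prediction is the latent index x'β.
    """
    arr = _check_design(X)
    yv = np.asarray(y, dtype=float)
    if np.all(yv >= upper):
        raise ValueError("all observations censored: Tobit is not identified")
    ols = sm.OLS(yv, arr).fit()
    x0 = np.append(ols.params, np.log(max(np.sqrt(ols.scale), 1e-3)))
    res = scipy.optimize.minimize(
        _tobit_negll, x0, args=(arr, yv, upper), method="BFGS",
        options={"maxiter": 500, "gtol": 1e-5},
    )
    if not res.success:
        polish = scipy.optimize.minimize(
            _tobit_negll, res.x, args=(arr, yv, upper), method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        if polish.fun <= res.fun:
            polish.hess_inv = res.hess_inv
            polish.nit += res.nit
            res = polish
    beta = res.x[:-1]
    sigma = float(np.exp(res.x[-1]))
    # delta-method vcov for (beta, sigma) from the inverse Hessian in
    # (beta, log sigma) space; report the beta block
    vcov = np.asarray(res.hess_inv)[: len(beta), : len(beta)]
    return FittedDirectModel(
        method="tobit",
        beta=beta,
        columns=tuple(X.columns),
        sigma=sigma,
        vcov=vcov,
        converged=bool(res.success),
        n_iter=int(res.nit),
        objective=float(res.fun),
    )


def _lad(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    res = QuantReg(y, X).fit(q=0.5, max_iter=2000, p_tol=1e-8)
    return np.asarray(res.params)


def fit_clad(X: pd.DataFrame, y: Sequence[float], upper: float = 1.0,
             *, max_iter: int = 50, n_boot: int = 199,
             compute_se: bool = True, seed: int = 0) -> FittedDirectModel:
    """Censored least absolute deviations (Powell's estimator).

    Minimises Σ|y − min(x'β, upper)| by alternating a median regression on
    the currently uncensored subsample {i : x'β < upper} with recomputation
    of that active set, until the set is stable.  Standard errors come from
    a nonparametric bootstrap (``n_boot`` resamples).
    """
    arr = _check_design(X)
    yv = np.asarray(y, dtype=float)

    def solve(Xa: np.ndarray, ya: np.ndarray) -> tuple[np.ndarray, bool, int, float]:
        beta = _lad(Xa, ya)
        best_beta, best_obj = beta, _clad_objective(beta, Xa, ya, upper)
        seen: set[bytes] = set()
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            active = Xa @ beta < upper
            key = np.packbits(active).tobytes()
            if active.sum() <= Xa.shape[1]:
                break
            if key in seen:
                converged = True
                break
            seen.add(key)
            new_beta = _lad(Xa[active], ya[active])
            obj = _clad_objective(new_beta, Xa, ya, upper)
            if obj <= best_obj:
                best_beta, best_obj = new_beta, obj
            if np.allclose(new_beta, beta, atol=1e-10):
                converged = True
                beta = new_beta
                break
            beta = new_beta
        return best_beta, converged, it, best_obj

    beta, converged, n_iter, obj = solve(arr, yv)

    vcov = None
    if compute_se and n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(yv)
        draws = np.empty((n_boot, len(beta)))
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                draws[b], *_ = solve(arr[idx], yv[idx])
            except Exception:
                draws[b] = np.nan
        good = ~np.isnan(draws).any(axis=1)
        if good.sum() > 1:
            vcov = np.cov(draws[good].T)

    return FittedDirectModel(
        method="clad",
        beta=beta,
        columns=tuple(X.columns),
        vcov=vcov,
        converged=converged,
        n_iter=n_iter,
        objective=obj,
    )


def _clad_objective(beta: np.ndarray, X: np.ndarray, y: np.ndarray,
                    upper: float) -> float:
    return float(np.sum(np.abs(y - np.minimum(X @ beta, upper))))


# --- MM robust regression ---------------------------------------------------

_BISQ_C_S = 1.54764   # 50% breakdown
_BISQ_C_M = 4.685     # 95% Gaussian efficiency
_BISQ_B = 0.5         # E[rho_c(Z)] for the S scale at the normal


def _bisquare_rho(u: np.ndarray, c: float) -> np.ndarray:
    t = np.clip(u / c, -1.0, 1.0)
    return (c * c / 6.0) * (1.0 - (1.0 - t * t) ** 3)


def _bisquare_w(u: np.ndarray, c: float) -> np.ndarray:
    t = u / c
    w = (1.0 - t * t) ** 2
    w[np.abs(t) >= 1.0] = 0.0
    return w


def _m_scale(resid: np.ndarray, c: float = _BISQ_C_S, b: float = _BISQ_B * _BISQ_C_S**2 / 6,
             tol: float = 1e-9, max_iter: int = 200) -> float:
    """Solve mean(rho_c(r/s)) = b for s (the bisquare M-scale)."""
    s = np.median(np.abs(resid)) / 0.6745
    if s <= 0:
        return 0.0
    for _ in range(max_iter):
        m = np.mean(_bisquare_rho(resid / s, c))
        s_new = s * np.sqrt(m / b)
        if abs(s_new - s) <= tol * s:
            return float(s_new)
        s = s_new
    return float(s)


def fit_rmm(X: pd.DataFrame, y: Sequence[float], *, n_subsets: int = 200,
            seed: int = 0, max_iter: int = 200) -> FittedDirectModel:
    """MM robust regression (Tukey bisquare).

    Stage 1 (S): elemental p-subsets seed candidate fits; each candidate's
    bisquare M-scale (50% breakdown, c=1.5476) is refined by a few IRLS
    steps and the smallest scale wins.  Stage 2 (M): IRLS with the
    efficiency constant c=4.685 holding the S scale fixed.
    """
    arr = _check_design(X)
    yv = np.asarray(y, dtype=float)
    n, p = arr.shape
    rng = np.random.default_rng(seed)

    best_scale = np.inf
    best_beta: np.ndarray | None = None
    for _ in range(n_subsets):
        idx = rng.choice(n, size=p, replace=False)
        try:
            cand = np.linalg.solve(arr[idx], yv[idx])
        except np.linalg.LinAlgError:
            continue
        resid = yv - arr @ cand
        # a couple of S-refinement IRLS steps
        for _ in range(3):
            s = _m_scale(resid)
            if s <= 0:
                break
            w = _bisquare_w(resid / s, _BISQ_C_S)
            if w.sum() < p:
                break
            wa = arr * w[:, None]
            try:
                cand = np.linalg.solve(wa.T @ arr, wa.T @ yv)
            except np.linalg.LinAlgError:
                break
            resid = yv - arr @ cand
        s = _m_scale(resid)
        if 0 < s < best_scale:
            best_scale, best_beta = s, cand

    if best_beta is None:
        raise ValueError("S-estimation failed on every subsample")
    if best_scale < 1e-10:
        raise ValueError("exact fit: degenerate robust scale")

    # M step at fixed scale
    beta = best_beta
    sigma = best_scale
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = yv - arr @ beta
        w = _bisquare_w(resid / sigma, _BISQ_C_M)
        wa = arr * w[:, None]
        new_beta = np.linalg.solve(wa.T @ arr, wa.T @ yv)
        if np.max(np.abs(new_beta - beta)) < 1e-10:
            beta = new_beta
            converged = True
            break
        beta = new_beta

    resid = yv - arr @ beta
    u = resid / sigma
    psi = u * _bisquare_w(u, _BISQ_C_M)
    psi_prime_mean = np.mean(_bisquare_dpsi(u, _BISQ_C_M))
    xtx_inv = np.linalg.inv(arr.T @ arr)
    kappa = np.mean(psi**2) / max(psi_prime_mean**2, 1e-12)
    vcov = sigma**2 * kappa * xtx_inv * n / max(n - p, 1)

    return FittedDirectModel(
        method="rmm",
        beta=beta,
        columns=tuple(X.columns),
        sigma=float(sigma),
        vcov=vcov,
        converged=converged,
        n_iter=it,
        objective=float(np.mean(_bisquare_rho(u, _BISQ_C_M))),
    )


def _bisquare_dpsi(u: np.ndarray, c: float) -> np.ndarray:
    t = u / c
    out = (1.0 - t * t) * (1.0 - 5.0 * t * t)
    out[np.abs(t) >= 1.0] = 0.0
    return out


FITTERS = {
    "ols": fit_ols,
    "tobit": fit_tobit,
    "glm": fit_glm_log,
    "clad": fit_clad,
    "rmm": fit_rmm,
}
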