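"""Boundary-aware mixture estimators for EQ-5D-5L utilities.

Utility distributions from EQ-5D-5L data are awkward for plain regression:
a probability mass sits exactly at 1 (full health), no value can fall in
the gap between 1 and the largest tariff value below 1, and the continuous
part is left-skewed and possibly multimodal.  Two bespoke estimators
handle this directly:

* **ALDVMM** — adjusted limited dependent variable mixture model: a
  K-component normal mixture where each component places mass at 1 (latent
  index beyond the gap boundary Ψ), mass at the tariff floor, and a normal
  density on (floor, Ψ].
* **Beta mixture (BM)** — a two-part model: a logit for the mass at 1,
  and, conditional on y < 1, a C-component beta regression (logit-linked
  means, per-component precision) on the response rescaled from the
  tariff range [L, 1) to (0, 1).

Both are fitted by direct maximum likelihood with multiple random starts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats

from .direct import DESIGN_COLUMNS, _check_design

_NORM = scipy.stats.norm


# ---------------------------------------------------------------------------
# ALDVMM
# ---------------------------------------------------------------------------


@dataclass
class FittedALDVMM:
    """Fitted adjusted limited dependent variable mixture model."""

    beta: np.ndarray          # (K, p) component coefficient vectors
    sigma: np.ndarray         # (K,) component scales
    delta: np.ndarray         # (K-1,) membership logits (intercept-only)
    psi: float                # upper gap boundary: largest feasible utility < 1
    floor: float
    columns: tuple[str, ...] = DESIGN_COLUMNS
    converged: bool = True
    loglik: float = float("nan")
    n_starts: int = 1

    @property
    def K(self) -> int:
        return self.beta.shape[0]

    @property
    def weights(self) -> np.ndarray:
        return _softmax_weights(self.delta)

    def to_dict(self) -> dict:
        return {
            "method": "aldvmm",
            "columns": list(self.columns),
            "components": [
                {"beta": self.beta[k].tolist(), "sigma": float(self.sigma[k])}
                for k in range(self.K)
            ],
            "delta": self.delta.tolist(),
            "psi": float(self.psi),
            "floor": float(self.floor),
            "convergence": {"converged": bool(self.converged),
                            "loglik": float(self.loglik),
                            "n_starts": int(self.n_starts)},
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FittedALDVMM":
        comps = doc["components"]
        conv = doc.get("convergence", {})
        return cls(
            beta=np.asarray([c["beta"] for c in comps], dtype=float),
            sigma=np.asarray([c["sigma"] for c in comps], dtype=float),
            delta=np.asarray(doc["delta"], dtype=float),
            psi=float(doc["psi"]),
            floor=float(doc["floor"]),
            columns=tuple(doc.get("columns", DESIGN_COLUMNS)),
            converged=conv.get("converged", True),
            loglik=conv.get("loglik", float("nan")),
        )


def _softmax_weights(delta: np.ndarray) -> np.ndarray:
    z = np.append(delta, 0.0)
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def _aldvmm_pack(beta: np.ndarray, log_sigma: np.ndarray, delta: np.ndarray) -> np.ndarray:
    return np.concatenate([beta.ravel(), log_sigma, delta])


def _aldvmm_unpack(params: np.ndarray, K: int, p: int):
    beta = params[: K * p].reshape(K, p)
    log_sigma = params[K * p: K * p + K]
    delta = params[K * p + K:]
    return beta, log_sigma, delta


def _aldvmm_comp_logdens(y: np.ndarray, mu: np.ndarray, sigma: float,
                         psi: float, floor: float) -> np.ndarray:
    """Per-observation log density of one component.

    Mass at 1 for the index beyond Ψ, mass at the floor, normal density on
    (floor, Ψ]; the density part is not renormalised — the three pieces
    integrate to one by construction.
    """
    out = np.empty_like(y)
    at_one = y >= 1.0
    at_floor = np.isclose(y, floor)
    mid = ~(at_one | at_floor)
    z_hi = (psi - mu) / sigma
    z_lo = (floor - mu) / sigma
    out[at_one] = _NORM.logsf(z_hi[at_one])
    out[at_floor] = _NORM.logcdf(z_lo[at_floor])
    out[mid] = _NORM.logpdf((y[mid] - mu[mid]) / sigma) - np.log(sigma)
    return out


def _aldvmm_negll(params: np.ndarray, X: np.ndarray, y: np.ndarray,
                  K: int, psi: float, floor: float) -> float:
    p = X.shape[1]
    beta, log_sigma, delta = _aldvmm_unpack(params, K, p)
    if np.any(np.abs(log_sigma) > 12):
        return 1e12
    log_pi = np.log(_softmax_weights(delta) + 1e-300)
    parts = np.empty((K, len(y)))
    for k in range(K):
        mu = X @ beta[k]
        parts[k] = log_pi[k] + _aldvmm_comp_logdens(y, mu, np.exp(log_sigma[k]), psi, floor)
    ll = scipy.special.logsumexp(parts, axis=0)
    if not np.all(np.isfinite(ll)):
        return 1e12
    return -float(ll.sum())


def fit_aldvmm(X: pd.DataFrame, y: Sequence[float], K: int = 2,
               psi: float = 0.957, floor: float = -0.391, *,
               n_starts: int = 20, seed: int = 0,
               maxiter: int = 500) -> FittedALDVMM:
    """Fit the ALDVMM by maximum likelihood with multiple random starts.

    ``psi`` is the largest feasible utility strictly below 1 (for the
    bundled Chinese tariff, 1 minus the smallest single-level decrement);
    observed responses must lie in [floor, Ψ] ∪ {1}.  Components are
    relabelled in increasing order of intercept for identifiability.
    """
    arr = _check_design(X)
    yv = np.asarray(y, dtype=float)
    if np.any((yv > psi) & (yv < 1.0)):
        raise ValueError(f"responses inside the infeasible gap ({psi}, 1)")
    if np.any((yv < floor) | (yv > 1.0)):
        raise ValueError(f"responses outside [{floor}, 1]")
    if K < 1:
        raise ValueError("K must be >= 1")
    n, p = arr.shape

    # common start: least squares on the uncensored part
    mid = yv < 1.0
    base_beta = np.linalg.lstsq(arr[mid] if mid.sum() > p else arr,
                                yv[mid] if mid.sum() > p else yv, rcond=None)[0]
    base_sigma = max(float(np.std(yv - arr @ base_beta)), 0.02)

    rng = np.random.default_rng(seed)
    best: scipy.optimize.OptimizeResult | None = None
    for s in range(n_starts):
        beta0 = np.tile(base_beta, (K, 1))
        if s > 0:
            beta0 = beta0 + rng.normal(scale=0.25 * max(base_sigma, 0.05),
                                       size=beta0.shape)
            beta0[:, 0] += rng.normal(scale=0.15, size=K)
        log_sigma0 = np.log(base_sigma) + rng.normal(scale=0.3, size=K) * (s > 0)
        delta0 = rng.normal(scale=0.5, size=K - 1) * (s > 0)
        x0 = _aldvmm_pack(beta0, np.atleast_1d(log_sigma0), np.atleast_1d(delta0))
        res = scipy.optimize.minimize(
            _aldvmm_negll, x0, args=(arr, yv, K, psi, floor),
            method="BFGS", options={"maxiter": maxiter, "gtol": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res

    if not best.success:
        polish = scipy.optimize.minimize(
            _aldvmm_negll, best.x, args=(arr, yv, K, psi, floor),
            method="Nelder-Mead",
            options={"maxiter": 20000, "xatol": 1e-7, "fatol": 1e-9})
        if polish.fun <= best.fun:
            best = polish

    beta, log_sigma, delta = _aldvmm_unpack(best.x, K, p)
    # order components by intercept; remap membership logits accordingly
    order = np.argsort(beta[:, 0])
    pi = _softmax_weights(delta)[order]
    beta, log_sigma = beta[order], log_sigma[order]
    new_delta = np.log(pi[:-1] + 1e-300) - np.log(pi[-1] + 1e-300)
    return FittedALDVMM(
        beta=beta,
        sigma=np.exp(log_sigma),
        delta=np.atleast_1d(new_delta),
        psi=psi,
        floor=floor,
        columns=tuple(X.columns),
        converged=bool(best.success),
        loglik=-float(best.fun),
        n_starts=n_starts,
    )


def _trunc_normal_mean(mu: np.ndarray, sigma: float, lo: float, hi: float) -> np.ndarray:
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma
    denom = _NORM.cdf(b) - _NORM.cdf(a)
    denom = np.where(denom < 1e-300, 1e-300, denom)
    return mu + sigma * (_NORM.pdf(a) - _NORM.pdf(b)) / denom


def _aldvmm_predict(model: FittedALDVMM, X: np.ndarray) -> np.ndarray:
    pi = model.weights
    out = np.zeros(X.shape[0])
    for k in range(model.K):
        mu = X @ model.beta[k]
        s = model.sigma[k]
        p_one = _NORM.sf((model.psi - mu) / s)
        p_floor = _NORM.cdf((model.floor - mu) / s)
        p_mid = np.clip(1.0 - p_one - p_floor, 0.0, 1.0)
        e_mid = _trunc_normal_mean(mu, s, model.floor, model.psi)
        out += pi[k] * (p_one * 1.0 + p_floor * model.floor + p_mid * e_mid)
    return out


# ---------------------------------------------------------------------------
# beta mixture with inflation at 1
# ---------------------------------------------------------------------------


@dataclass
class FittedBetaMix:
    """Fitted two-part beta mixture with probability mass at full health."""

    gamma: np.ndarray          # logit coefficients for P(y = 1)
    delta: np.ndarray          # (C, p) logit-link coefficients for component means
    phi: np.ndarray            # (C,) precisions
    omega: np.ndarray          # (C-1,) component-weight logits
    lower: float               # rescaling lower bound L (tariff floor)
    upper: float = 1.0
    columns: tuple[str, ...] = DESIGN_COLUMNS
    converged: bool = True
    loglik: float = float("nan")
    n_starts: int = 1

    @property
    def C(self) -> int:
        return self.delta.shape[0]

    @property
    def weights(self) -> np.ndarray:
        return _softmax_weights(self.omega)

    def to_dict(self) -> dict:
        return {
            "method": "betamix",
            "columns": list(self.columns),
            "gamma": self.gamma.tolist(),
            "components": [
                {"delta": self.delta[c].tolist(), "phi": float(self.phi[c])}
                for c in range(self.C)
            ],
            "omega": self.omega.tolist(),
            "bounds": [float(self.lower), float(self.upper)],
            "convergence": {"converged": bool(self.converged),
                            "loglik": float(self.loglik),
                            "n_starts": int(self.n_starts)},
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FittedBetaMix":
        comps = doc["components"]
        conv = doc.get("convergence", {})
        return cls(
            gamma=np.asarray(doc["gamma"], dtype=float),
            delta=np.asarray([c["delta"] for c in comps], dtype=float),
            phi=np.asarray([c["phi"] for c in comps], dtype=float),
            omega=np.asarray(doc["omega"], dtype=float),
            lower=float(doc["bounds"][0]),
            upper=float(doc["bounds"][1]),
            columns=tuple(doc.get("columns", DESIGN_COLUMNS)),
            converged=conv.get("converged", True),
            loglik=conv.get("loglik", float("nan")),
        )


def _beta_logpdf(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    a = mu * phi
    b = (1.0 - mu) * phi
    return (scipy.special.gammaln(phi) - scipy.special.gammaln(a)
            - scipy.special.gammaln(b)
            + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y))


def _betamix_negll(params: np.ndarray, X: np.ndarray, ystar: np.ndarray,
                   C: int) -> float:
    p = X.shape[1]
    delta = params[: C * p].reshape(C, p)
    log_phi = params[C * p: C * p + C]
    omega = params[C * p + C:]
    if np.any(log_phi > 14) or np.any(log_phi < -6):
        return 1e12
    log_w = np.log(_softmax_weights(omega) + 1e-300)
    parts = np.empty((C, len(ystar)))
    for c in range(C):
        mu = scipy.special.expit(X @ delta[c])
        mu = np.clip(mu, 1e-10, 1.0 - 1e-10)
        parts[c] = log_w[c] + _beta_logpdf(ystar, mu, np.exp(log_phi[c]))
    ll = scipy.special.logsumexp(parts, axis=0)
    if not np.all(np.isfinite(ll)):
        return 1e12
    return -float(ll.sum())


def fit_betamix(X: pd.DataFrame, y: Sequence[float], C: int = 1,
                bounds: tuple[float, float] = (-0.391, 1.0), *,
                n_starts: int = 20, seed: int = 0,
                maxiter: int = 500) -> FittedBetaMix:
    """Fit the inflated beta mixture by two-part maximum likelihood.

    Part 1 is a logistic regression for the indicator 1{y = 1}.  Part 2
    rescales y < 1 to y* = (y − L)/(U − L); values landing exactly at 0
    are nudged to ε = 0.5/n (standard beta-regression practice) and a
    C-component beta mixture with logit-linked means is fitted.
    """
    arr = _check_design(X)
    yv = np.asarray(y, dtype=float)
    L, U = bounds
    if np.any((yv < L) | (yv > U)):
        raise ValueError(f"responses outside [{L}, {U}]")
    if C < 1:
        raise ValueError("C must be >= 1")
    n, p = arr.shape
    at_one = yv >= U

    # part 1: logit for the ceiling mass (Newton; falls back to zero slope
    # on separation)
    import statsmodels.api as sm
    try:
        logit_res = sm.Logit(at_one.astype(float), arr).fit(disp=0, maxiter=200)
        gamma = np.asarray(logit_res.params)
        ll_gamma = float(logit_res.llf)
        gamma_ok = bool(logit_res.mle_retvals.get("converged", True))
    except Exception:
        share = np.clip(at_one.mean(), 1e-6, 1 - 1e-6)
        gamma = np.zeros(p)
        gamma[0] = scipy.special.logit(share)
        ll_gamma = float(len(yv) * (share * np.log(share)
                                    + (1 - share) * np.log(1 - share)))
        gamma_ok = False

    # part 2: beta mixture on the rescaled continuous part
    Xc = arr[~at_one]
    yc = yv[~at_one]
    if len(yc) <= p:
        raise ValueError("too few uncensored observations for the beta part")
    ystar = (yc - L) / (U - L)
    eps = 0.5 / len(yc)
    ystar = np.clip(ystar, eps, 1.0 - eps)

    mu0 = np.clip(ystar.mean(), 0.05, 0.95)
    var0 = max(ystar.var(), 1e-4)
    phi0 = max(mu0 * (1 - mu0) / var0 - 1.0, 1.5)
    rng = np.random.default_rng(seed)
    best: scipy.optimize.OptimizeResult | None = None
    for s in range(n_starts):
        delta0 = np.zeros((C, p))
        delta0[:, 0] = scipy.special.logit(mu0)
        if s > 0:
            delta0 += rng.normal(scale=0.4, size=delta0.shape)
        log_phi0 = np.full(C, np.log(phi0)) + rng.normal(scale=0.3, size=C) * (s > 0)
        omega0 = rng.normal(scale=0.5, size=C - 1) * (s > 0)
        x0 = np.concatenate([delta0.ravel(), log_phi0, omega0])
        res = scipy.optimize.minimize(
            _betamix_negll, x0, args=(Xc, ystar, C),
            method="BFGS", options={"maxiter": maxiter, "gtol": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res

    if not best.success:
        polish = scipy.optimize.minimize(
            _betamix_negll, best.x, args=(Xc, ystar, C), method="Nelder-Mead",
            options={"maxiter": 20000, "xatol": 1e-7, "fatol": 1e-9})
        if polish.fun <= best.fun:
            best = polish

    delta = best.x[: C * p].reshape(C, p)
    log_phi = best.x[C * p: C * p + C]
    omega = best.x[C * p + C:]
    order = np.argsort(delta[:, 0])
    w = _softmax_weights(omega)[order]
    delta, log_phi = delta[order], log_phi[order]
    new_omega = np.log(w[:-1] + 1e-300) - np.log(w[-1] + 1e-300)
    # total two-part log-likelihood on the original utility scale includes
    # the Jacobian of the rescaling for the continuous part
    ll = ll_gamma - float(best.fun) - len(yc) * np.log(U - L)
    return FittedBetaMix(
        gamma=gamma,
        delta=delta,
        phi=np.exp(log_phi),
        omega=np.atleast_1d(new_omega),
        lower=L,
        upper=U,
        columns=tuple(X.columns),
        converged=bool(best.success) and gamma_ok,
        loglik=ll,
        n_starts=n_starts,
    )


def _betamix_predict(model: FittedBetaMix, X: np.ndarray) -> np.ndarray:
    p1 = scipy.special.expit(X @ model.gamma)
    w = model.weights
    mu = np.zeros(X.shape[0])
    for c in range(model.C):
        mu += w[c] * scipy.special.expit(X @ model.delta[c])
    cont = model.lower + (model.upper - model.lower) * mu
    return p1 * model.upper + (1.0 - p1) * cont


# ---------------------------------------------------------------------------
# shared surface
# ---------------------------------------------------------------------------


def predict_mixture(model: FittedALDVMM | FittedBetaMix, X: pd.DataFrame) -> np.ndarray:
    """Expected-value prediction E[Y | x] under the fitted mixture."""
    if tuple(X.columns) != tuple(model.columns):
        raise ValueError("design columns do not match the fitted model")
    arr = np.asarray(X, dtype=float)
    if isinstance(model, FittedALDVMM):
        return _aldvmm_predict(model, arr)
    if isinstance(model, FittedBetaMix):
        return _betamix_predict(model, arr)
    raise TypeError(f"not a mixture model: {type(model).__name__}")


def loglik(model: FittedALDVMM | FittedBetaMix, X: pd.DataFrame,
           y: Sequence[float]) -> float:
    """Exact log-likelihood of ``(X, y)`` under the fitted model."""
    arr = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    if isinstance(model, FittedALDVMM):
        if np.any((yv > model.psi) & (yv < 1.0)):
            raise ValueError("responses inside the infeasible gap")
        params = _aldvmm_pack(model.beta, np.log(model.sigma), model.delta)
        return -_aldvmm_negll(params, arr, yv, model.K, model.psi, model.floor)
    if isinstance(model, FittedBetaMix):
        L, U = model.lower, model.upper
        if np.any((yv < L) | (yv > U)):
            raise ValueError(f"responses outside [{L}, {U}]")
        at_one = yv >= U
        p1 = np.clip(scipy.special.expit(arr @ model.gamma), 1e-300, 1 - 1e-300)
        ll = float(np.sum(np.log(p1[at_one]))) + float(np.sum(np.log1p(-p1[~at_one])))
        yc = yv[~at_one]
        if len(yc):
            ystar = (yc - L) / (U - L)
            eps = 0.5 / len(yc)
            ystar = np.clip(ystar, eps, 1.0 - eps)
            params = np.concatenate([model.delta.ravel(), np.log(model.phi), model.omega])
            ll -= _betamix_negll(params, arr[~at_one], ystar, model.C)
            ll -= len(yc) * np.log(U - L)
        return ll
    raise TypeError(f"not a mixture model: {type(model).__name__}")


def simulate_aldvmm(model: FittedALDVMM, X: pd.DataFrame, n_draws: int,
                    seed: int = 0) -> np.ndarray:
    """Monte-Carlo draws from the fitted ALDVMM at each design row.

    Returns an array of shape (n_draws, n_rows); used as a brute-force
    oracle for :func:`predict_mixture`.
    """
    arr = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    n = arr.shape[0]
    comp = rng.choice(model.K, size=(n_draws, n), p=model.weights)
    mu = arr @ model.beta.T            # (n, K)
    latent = rng.normal(mu.T[comp, np.arange(n)], model.sigma[comp])
    out = np.where(latent > model.psi, 1.0,
                   np.where(latent < model.floor, model.floor, latent))
    return out


def simulate_betamix(model: FittedBetaMix, X: pd.DataFrame, n_draws: int,
                     seed: int = 0) -> np.ndarray:
    """Monte-Carlo draws from the fitted beta mixture (oracle helper)."""
    arr = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    n = arr.shape[0]
    p1 = scipy.special.expit(arr @ model.gamma)
    ceil = rng.random((n_draws, n)) < p1
    comp = rng.choice(model.C, size=(n_draws, n), p=model.weights)
    mu = scipy.special.expit(arr @ model.delta.T)      # (n, C)
    m = mu.T[comp, np.arange(n)]
    phi = model.phi[comp]
    draws = rng.beta(m * phi, (1.0 - m) * phi)
    cont = model.lower + (model.upper - model.lower) * draws
    return np.where(ceil, model.upper, cont)
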