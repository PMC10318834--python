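"""Indirect (response) mapping: ordered logits per EQ-5D dimension.

Instead of regressing the utility itself on the SAQ subscales, response
mapping models each EQ-5D-5L dimension's level as an ordinal outcome of
the subscales, predicts the level probabilities, and converts them to an
expected utility under the tariff.  The per-dimension model is the
proportional-odds (ordered logit) model

    P(level ≤ j | x) = logistic(cut_j − x'β),

with x the five subscales on the 0–1 scale and no separate intercept (the
cut points absorb it).  Levels never observed in the training data are
collapsed out: the fitted categories are the observed distinct levels and
unobserved levels carry probability zero.

Because the tariff is additive across dimensions, the expected utility
under independent dimension predictions has the closed form

    EU = 1 − Σ_d Σ_level p_d(level) · decrement_d(level),

which is exact (the default "expected-decrement" method); Monte-Carlo and
modal-state alternatives are provided for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.special
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .direct import DESIGN_COLUMNS, _check_design
from .valuesets import DIMENSIONS, EQ5DState, ValueSet, utility

#: design columns for response models: subscales only, no intercept
RESPONSE_COLUMNS = tuple(c for c in DESIGN_COLUMNS if c != "const")


class SeparationError(RuntimeError):
    """Perfect separation in an ordered logit fit."""


@dataclass
class OrderedLogitModel:
    """Proportional-odds model for one EQ-5D dimension."""

    dimension: str
    beta: np.ndarray                 # coefficients over PL, AS, AF, TS, DP
    cuts: np.ndarray                 # strictly increasing cut points
    category_levels: tuple[int, ...] # fitted category index -> EQ-5D level
    columns: tuple[str, ...] = RESPONSE_COLUMNS
    converged: bool = True
    loglik: float = float("nan")
    vcov: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.category_levels) != len(self.cuts) + 1:
            raise ValueError("need one more category than cut points")
        if np.any(np.diff(self.cuts) <= 0):
            raise ValueError("cut points must be strictly increasing")

    def to_dict(self) -> dict:
        return {
            "dimension": self.dimension,
            "columns": list(self.columns),
            "beta": self.beta.tolist(),
            "cuts": self.cuts.tolist(),
            "category_levels": list(self.category_levels),
            "convergence": {"converged": bool(self.converged),
                            "loglik": float(self.loglik)},
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "OrderedLogitModel":
        conv = doc.get("convergence", {})
        return cls(
            dimension=doc["dimension"],
            beta=np.asarray(doc["beta"], dtype=float),
            cuts=np.asarray(doc["cuts"], dtype=float),
            category_levels=tuple(doc["category_levels"]),
            columns=tuple(doc.get("columns", RESPONSE_COLUMNS)),
            converged=conv.get("converged", True),
            loglik=conv.get("loglik", float("nan")),
        )


def response_design(scores: pd.DataFrame) -> pd.DataFrame:
    """Subscales / 100 without an intercept (absorbed by the cut points)."""
    from .direct import build_design

    return build_design(scores).drop(columns="const")


def fit_response_models(X: pd.DataFrame, states: pd.DataFrame,
                        ) -> dict[str, OrderedLogitModel]:
    """Fit one proportional-odds model per EQ-5D dimension.

    ``states`` holds integer level columns mo, sc, ua, pd, ad.  Levels not
    observed for a dimension are collapsed out of its model.
    """
    if tuple(X.columns) != RESPONSE_COLUMNS:
        raise ValueError(f"response design must have columns {RESPONSE_COLUMNS}")
    arr = np.asarray(X, dtype=float)
    models: dict[str, OrderedLogitModel] = {}
    for dim in DIMENSIONS:
        levels = np.asarray(states[dim], dtype=int)
        observed = tuple(int(v) for v in np.unique(levels))
        if len(observed) < 2:
            raise ValueError(f"dimension {dim}: a single observed category")
        codes = np.searchsorted(observed, levels)
        model = OrderedModel(codes, arr, distr="logit")
        try:
            res = model.fit(method="bfgs", maxiter=500, disp=0)
        except Exception as exc:  # noqa: BLE001
            raise SeparationError(f"ordered logit failed for {dim}: {exc}") from exc
        params = np.asarray(res.params)
        beta = params[: arr.shape[1]]
        cuts = model.transform_threshold_params(params)[1:-1]
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e3:
            raise SeparationError(f"perfect separation suspected in dimension {dim}")
        try:
            vcov = np.asarray(res.cov_params())
        except Exception:  # singular Hessian (e.g. no covariate signal)
            vcov = None
        models[dim] = OrderedLogitModel(
            dimension=dim,
            beta=beta,
            cuts=np.asarray(cuts, dtype=float),
            category_levels=observed,
            columns=tuple(X.columns),
            converged=bool(res.mle_retvals.get("converged", True)),
            loglik=float(res.llf),
            vcov=vcov,
        )
    return models


def _level_probabilities(model: OrderedLogitModel, arr: np.ndarray) -> np.ndarray:
    """(n, 5) probabilities over EQ-5D levels 1–5 (zeros where collapsed)."""
    index = arr @ model.beta
    cum = scipy.special.expit(model.cuts[None, :] - index[:, None])
    cum = np.hstack([np.zeros((len(index), 1)), cum, np.ones((len(index), 1))])
    cat_probs = np.diff(cum, axis=1)
    out = np.zeros((len(index), 5))
    for j, level in enumerate(model.category_levels):
        out[:, level - 1] = cat_probs[:, j]
    return out


def predict_probabilities(models: Mapping[str, OrderedLogitModel],
                          X: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-dimension (n, 5) level-probability arrays for each design row."""
    out: dict[str, np.ndarray] = {}
    for dim in DIMENSIONS:
        model = models[dim]
        if tuple(X.columns) != tuple(model.columns):
            raise ValueError("design columns do not match the fitted model")
        out[dim] = _level_probabilities(model, np.asarray(X, dtype=float))
    return out


def expected_utility(probs: Mapping[str, np.ndarray], vs: ValueSet,
                     method: str = "expected-decrement", *,
                     n_draws: int = 10_000, seed: int = 0) -> np.ndarray:
    """Utility implied by per-dimension level probabilities.

    ``expected-decrement`` is exact for additive tariffs with independent
    dimensions; ``monte-carlo`` samples states; ``modal`` scores the
    per-dimension argmax state.
    """
    mats = {d: np.atleast_2d(np.asarray(probs[d], dtype=float)) for d in DIMENSIONS}
    n = next(iter(mats.values())).shape[0]
    for d, m in mats.items():
        if m.shape != (n, 5):
            raise ValueError(f"probabilities for {d} must be (n, 5)")
        if np.any(m < -1e-12):
            raise ValueError(f"negative probability in dimension {d}")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-8):
            raise ValueError(f"probabilities for {d} do not sum to 1")

    dec = {d: np.array([vs.decrements[d][lvl] for lvl in range(1, 6)])
           for d in DIMENSIONS}

    if method == "expected-decrement":
        eu = np.ones(n)
        for d in DIMENSIONS:
            eu -= mats[d] @ dec[d]
        return eu
    if method == "monte-carlo":
        rng = np.random.default_rng(seed)
        eu = np.ones(n)
        for d in DIMENSIONS:
            cum = np.cumsum(mats[d], axis=1)
            u = rng.random((n, n_draws))
            lvl_idx = (u[:, :, None] > cum[:, None, :]).sum(axis=2)
            eu -= dec[d][lvl_idx].mean(axis=1)
        return eu
    if method == "modal":
        eu = np.empty(n)
        for i in range(n):
            levels = {d: int(np.argmax(mats[d][i])) + 1 for d in DIMENSIONS}
            eu[i] = utility(EQ5DState(**levels), vs)
        return eu
    raise ValueError(f"unknown method {method!r}")


def predict_indirect(models: Mapping[str, OrderedLogitModel], X: pd.DataFrame,
                     vs: ValueSet, method: str = "expected-decrement",
                     **kwargs) -> np.ndarray:
    """Convenience: probabilities then expected utility in one call."""
    return expected_utility(predict_probabilities(models, X), vs, method, **kwargs)


def probabilities_frame(probs: Mapping[str, np.ndarray],
                        pids: Sequence | None = None) -> pd.DataFrame:
    """Long-format table `pid, dimension, level, probability`."""
    rows = []
    n = next(iter(probs.values())).shape[0]
    ids = list(pids) if pids is not None else list(range(n))
    for d in DIMENSIONS:
        mat = probs[d]
        for i in range(n):
            for lvl in range(1, 6):
                rows.append((ids[i], d, lvl, mat[i, lvl - 1]))
    return pd.DataFrame(rows, columns=["pid", "dimension", "level", "probability"])
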