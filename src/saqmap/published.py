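"""Turnkey crosswalk: apply the published mapping coefficients to new data.

The published mapping study reports coefficient tables for the direct
estimators (OLS, Tobit, log-link GLM, CLAD, RMM; plus the beta-mixture
and ALDVMM component columns) and for the indirect per-dimension ordered
logits.  This module evaluates those printed coefficients on new SAQ
subscale scores, so users can convert SAQ data to utilities without any
fitting data of their own.

Conventions: subscale scores enter on the 0–1 scale (score / 100),
covariate order PL, AS, AF, TS, DP; predictions are unclamped by default,
mirroring how the study reported maxima above 1 for the linear models.

The mixture columns omit the component scales, weights, precision and gap
boundary; expected-value predictions from them therefore require explicit
assumption inputs — there are no silent defaults for those quantities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import scipy.special

from .response import OrderedLogitModel, _level_probabilities
from .valuesets import DIMENSIONS, SUBSCALES, SAQScores, ValueSet, load_value_set

DIRECT_METHODS = ("ols", "tobit", "glm", "clad", "rmm")
_ORDER = ("const", "pl", "as", "af", "ts", "dp")


@dataclass(frozen=True)
class CoefficientSet:
    """The published coefficient tables, values exactly as printed (4 dp)."""

    provenance: str
    direct: Mapping[str, Mapping[str, Mapping[str, float]]]
    betamix: Mapping[str, Mapping[str, Mapping[str, float]]]
    aldvmm: Mapping[str, Mapping[str, Mapping[str, float]]]
    indirect: Mapping[str, Mapping]

    @classmethod
    def load(cls) -> "CoefficientSet":
        doc = json.loads(
            resources.files("saqmap.data")
            .joinpath("published_coefficients.json").read_text()
        )
        return cls(
            provenance=doc["provenance"],
            direct=doc["direct"],
            betamix=doc["betamix"],
            aldvmm=doc["aldvmm"],
            indirect=doc["indirect"],
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "provenance": self.provenance,
                "covariate_order": list(SUBSCALES),
                "direct": self.direct,
                "betamix": self.betamix,
                "aldvmm": self.aldvmm,
                "indirect": self.indirect,
            },
            indent=2,
        )


def _score_vector(scores: SAQScores) -> np.ndarray:
    vals = scores.as_dict()
    arr = np.array([vals[s] for s in SUBSCALES], dtype=float)
    if np.any(np.isnan(arr)):
        missing = [s for s in SUBSCALES if np.isnan(vals[s])]
        raise ValueError(f"missing subscale scores: {missing}")
    return arr / 100.0


def _index(coef: Mapping[str, float], x: np.ndarray) -> float:
    return float(coef["const"] + sum(coef[s] * xi for s, xi in zip(SUBSCALES, x)))


def map_direct(scores: SAQScores, method: str, *, clamp: bool = False,
               coefficients: CoefficientSet | None = None,
               floor: float = -0.391) -> float:
    """Utility from a printed direct-approach coefficient column.

    ``utility = const + β·(scores/100)``, exponentiated for the log-link
    GLM.  ``clamp`` restricts the output to [floor, 1].
    """
    cs = coefficients or CoefficientSet.load()
    if method not in DIRECT_METHODS:
        raise ValueError(f"unknown direct method {method!r}; pick from {DIRECT_METHODS}")
    x = _score_vector(scores)
    value = _index(cs.direct[method]["coef"], x)
    if method == "glm":
        value = float(np.exp(value))
    if clamp:
        value = min(max(value, floor), 1.0)
    return value


def map_direct_mixture(scores: SAQScores, method: str,
                       assumptions: Mapping | None = None, *,
                       coefficients: CoefficientSet | None = None) -> float:
    """Expected utility from the printed mixture-model columns.

    BM needs rescaling ``bounds`` (defaulting to the tariff range
    (−0.391, 1)): EU = p1 + (1 − p1)·(L + (U − L)·logistic(C1_mu index))
    with p1 = logistic(PM_ub index).  ALDVMM additionally needs the
    unprinted component scales ``sigma``, weights ``pi`` and gap boundary
    ``psi`` — they must be supplied explicitly.
    """
    cs = coefficients or CoefficientSet.load()
    assumptions = dict(assumptions or {})
    x = _score_vector(scores)
    if method == "bm":
        L, U = assumptions.get("bounds", (-0.391, 1.0))
        p1 = scipy.special.expit(_index(cs.betamix["pm_ub"]["coef"], x))
        mu = scipy.special.expit(_index(cs.betamix["c1_mu"]["coef"], x))
        return float(p1 * 1.0 + (1.0 - p1) * (L + (U - L) * mu))
    if method == "aldvmm":
        required = [k for k in ("sigma", "pi", "psi") if k not in assumptions]
        if required:
            raise ValueError(
                "the published ALDVMM column omits the component scales, "
                f"weights and gap boundary; supply assumptions {required} "
                "explicitly (there are no defaults)")
        from scipy.stats import norm
        sigma = np.asarray(assumptions["sigma"], dtype=float)
        pi = np.asarray(assumptions["pi"], dtype=float)
        psi = float(assumptions["psi"])
        floor = float(assumptions.get("floor", -0.391))
        mus = np.array([_index(cs.aldvmm[c]["coef"], x) for c in ("com1", "com2")])
        value = 0.0
        for k in range(2):
            a, b = (floor - mus[k]) / sigma[k], (psi - mus[k]) / sigma[k]
            p1 = norm.sf(b)
            pf = norm.cdf(a)
            pmid = max(norm.cdf(b) - norm.cdf(a), 1e-300)
            emid = mus[k] + sigma[k] * (norm.pdf(a) - norm.pdf(b)) / pmid
            value += pi[k] * (p1 + pf * floor + (1 - p1 - pf) * emid)
        return float(min(value, 1.0))
    raise ValueError(f"unknown mixture method {method!r}; pick 'bm' or 'aldvmm'")


def published_response_models(
        level_map: Sequence[int] = (1, 2, 3, 4), *,
        coefficients: CoefficientSet | None = None) -> dict[str, OrderedLogitModel]:
    """The printed indirect-approach ordered logits as model objects.

    Three cut points imply four fitted categories per dimension; which
    EQ-5D levels they correspond to is an assumption (``level_map``,
    default levels 1–4) because the collapsed levels were not reported.
    """
    cs = coefficients or CoefficientSet.load()
    lm = tuple(int(v) for v in level_map)
    if len(set(lm)) != len(lm) or not set(lm).issubset({1, 2, 3, 4, 5}):
        raise ValueError(f"level map {lm} must be distinct levels in 1..5")
    models = {}
    for dim in DIMENSIONS:
        block = cs.indirect[dim]
        if len(lm) != len(block["cuts"]) + 1:
            raise ValueError(
                f"level map {lm} incompatible with {len(block['cuts'])} cut points")
        models[dim] = OrderedLogitModel(
            dimension=dim,
            beta=np.array([block["beta"][s] for s in SUBSCALES], dtype=float),
            cuts=np.asarray(block["cuts"], dtype=float),
            category_levels=lm,
        )
    return models


def map_indirect(scores: SAQScores, level_map: Sequence[int] = (1, 2, 3, 4), *,
                 vs: ValueSet | None = None,
                 coefficients: CoefficientSet | None = None,
                 ) -> tuple[dict[str, np.ndarray], float]:
    """Per-dimension level probabilities and expected utility.

    Probabilities come from the printed cut points and coefficients under
    P(level ≤ j | x) = logistic(cut_j − x'β) with x = scores / 100; the
    expected utility uses the exact expected-decrement formula under the
    bundled tariff.
    """
    vs = vs or load_value_set()
    models = published_response_models(level_map, coefficients=coefficients)
    x = _score_vector(scores)[None, :]
    probs = {d: _level_probabilities(models[d], x)[0] for d in DIMENSIONS}
    eu = 1.0
    for d in DIMENSIONS:
        dec = np.array([vs.decrements[d][lvl] for lvl in range(1, 6)])
        eu -= float(probs[d] @ dec)
    return probs, eu
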