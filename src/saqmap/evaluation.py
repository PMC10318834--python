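"""Goodness-of-fit metrics and the k-fold cross-validation harness.

Model accuracy is summarised by four indicators computed between observed
and predicted utilities: mean absolute error (MAE), root mean squared
error (RMSE), Pearson correlation ρ, and Lin's concordance correlation
coefficient

    CCC = 2·cov(o, p) / (var(o) + var(p) + (mean o − mean p)²),

which penalises location/scale shift as well as imprecision.  Moments in
the CCC use the population (1/n) convention of Lin's original estimator;
a sample (1/(n−1)) variant is available behind a flag.

Internal validation uses k-fold cross-validation: rows are randomly
partitioned into k near-equal folds; each fold in turn is predicted by
models trained on the other k−1; metrics are reported pooled over all
held-out predictions and also per fold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold


@dataclass
class MetricsEntry:
    model: str
    n: int
    mae: float
    rmse: float
    rho: float | None
    ccc: float | None
    pred_mean: float = float("nan")
    pred_min: float = float("nan")
    pred_max: float = float("nan")
    mean_change: float | None = None
    fold: int | None = None

    def as_row(self) -> dict:
        return {
            "model": self.model, "fold": self.fold, "n": self.n,
            "mean": self.pred_mean, "min": self.pred_min, "max": self.pred_max,
            "mean_change": self.mean_change,
            "mae": self.mae, "rmse": self.rmse, "rho": self.rho, "ccc": self.ccc,
        }


@dataclass
class MetricsReport:
    entries: list[MetricsEntry] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.as_row() for e in self.entries])

    def pooled(self) -> pd.DataFrame:
        df = self.to_frame()
        return df[df["fold"].isna()].drop(columns="fold")

    def per_fold(self) -> pd.DataFrame:
        df = self.to_frame()
        return df[df["fold"].notna()]

    def to_text(self, decimals: int = 4) -> str:
        df = self.pooled().set_index("model")
        cols = ["mean", "min", "max", "mean_change", "mae", "rmse", "rho", "ccc"]
        header = "Model      " + "".join(f"{c:>12}" for c in cols)
        lines = [header]
        for model, row in df.iterrows():
            cells = []
            for c in cols:
                v = row[c]
                cells.append(f"{'':>12}" if v is None or (isinstance(v, float) and math.isnan(v))
                             else f"{v:>12.{decimals}f}")
            lines.append(f"{model:<11}" + "".join(cells))
        if self.failures:
            lines.append("")
            for model, msg in self.failures.items():
                lines.append(f"# {model}: {msg}")
        return "\n".join(lines)


def compute_metrics(observed: Sequence[float], predicted: Sequence[float], *,
                    model: str = "", sample_moments: bool = False,
                    fold: int | None = None) -> MetricsEntry:
    """MAE, RMSE, Pearson ρ and Lin's CCC between observed and predicted."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be equal-length vectors")
    if len(o) < 2:
        raise ValueError("need at least two observations")
    err = o - p
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ddof = 1 if sample_moments else 0
    vo, vp = float(np.var(o, ddof=ddof)), float(np.var(p, ddof=ddof))
    if vo == 0.0 or vp == 0.0:
        warnings.warn("zero variance: correlation metrics undefined", stacklevel=2)
        rho = ccc = None
    else:
        cov = float(np.mean((o - o.mean()) * (p - p.mean())))
        if sample_moments:
            cov *= len(o) / (len(o) - 1)
        rho = cov / math.sqrt(vo * vp)
        ccc = 2.0 * cov / (vo + vp + (o.mean() - p.mean()) ** 2)
    return MetricsEntry(
        model=model, n=len(o), mae=mae, rmse=rmse, rho=rho, ccc=ccc,
        pred_mean=float(p.mean()), pred_min=float(p.min()),
        pred_max=float(p.max()), fold=fold,
    )


def assign_folds(n: int, k: int = 5, seed: int = 0,
                 groups: Sequence | None = None) -> np.ndarray:
    """Random fold indices 1..k partitioning ``n`` rows, sizes within 1.

    With ``groups`` (e.g. patient ids), whole groups are kept in one fold.
    """
    if n < k:
        raise ValueError(f"cannot split {n} rows into {k} folds")
    if groups is not None:
        uniq = pd.unique(pd.Series(groups))
        gfold = dict(zip(uniq, assign_folds(len(uniq), k, seed)))
        return np.asarray([gfold[g] for g in groups])
    out = np.empty(n, dtype=int)
    for fold, (_, test) in enumerate(
            KFold(n_splits=k, shuffle=True, random_state=seed).split(np.arange(n)), 1):
        out[test] = fold
    return out


#: a method registry entry: fit(X_frame, y) -> model; predict(model, X_frame) -> yhat
MethodSpec = tuple[Callable, Callable]


def crossvalidate(X: pd.DataFrame, y: Sequence[float],
                  methods: Mapping[str, MethodSpec], k: int = 5, seed: int = 0,
                  *, groups: Sequence | None = None) -> MetricsReport:
    """k-fold cross-validation of registered methods on a common split.

    Each method is trained on k−1 folds and predicts the held-out fold;
    pooled metrics over all held-out predictions are reported alongside
    per-fold metrics.  A method failing on a fold is recorded in
    ``failures`` and the others are unaffected.
    """
    yv = np.asarray(y, dtype=float)
    folds = assign_folds(len(yv), k, seed, groups)
    report = MetricsReport()
    for name, (fit, predict) in methods.items():
        pooled_pred = np.full(len(yv), np.nan)
        ok = True
        for fold in range(1, k + 1):
            test = folds == fold
            try:
                model = fit(X[~test], yv[~test])
                pooled_pred[test] = np.asarray(predict(model, X[test]), dtype=float)
            except Exception as exc:  # noqa: BLE001
                report.failures[name] = f"fold {fold}: {exc}"
                ok = False
                break
            report.entries.append(
                compute_metrics(yv[test], pooled_pred[test], model=name, fold=fold))
        if ok:
            report.entries.append(compute_metrics(yv, pooled_pred, model=name))
    return report


def summarize_predictions(predictions: Sequence[float],
                          pids: Sequence | None = None,
                          waves: Sequence | None = None, *,
                          model: str = "") -> dict:
    """Mean/min/max of predictions plus the mean paired follow-up change.

    The change is the mean of (follow-up − baseline) predictions over
    patients present in both waves; None (with a warning) when no pairs
    exist or wave information is missing.
    """
    p = np.asarray(predictions, dtype=float)
    out = {
        "model": model,
        "mean": float(p.mean()), "min": float(p.min()), "max": float(p.max()),
        "mean_change": None,
    }
    if pids is not None and waves is not None:
        df = pd.DataFrame({"pid": pids, "wave": waves, "pred": p})
        wide = df.pivot_table(index="pid", columns="wave", values="pred")
        if {0, 1}.issubset(wide.columns):
            paired = wide.dropna(subset=[0, 1])
            if len(paired):
                out["mean_change"] = float((paired[1] - paired[0]).mean())
    if out["mean_change"] is None and waves is not None:
        warnings.warn("no paired baseline/follow-up records; mean change missing",
                      stacklevel=2)
    return out
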