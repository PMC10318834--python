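"""Scoring of SAQ items and EQ-5D-5L health states.

The Seattle Angina Questionnaire (SAQ) is a 19-item disease-specific
instrument for coronary heart disease.  Its items are grouped into five
subscales — physical limitation (PL), anginal stability (AS), anginal
frequency (AF), treatment satisfaction (TS) and disease perception (DP) —
each linearly rescaled to 0–100 (higher = better function/satisfaction).

EQ-5D-5L describes health by five ordinal dimensions — mobility (MO),
self-care (SC), usual activities (UA), pain/discomfort (PD) and
anxiety/depression (AD) — each at levels 1 (no problems) to 5 (extreme
problems).  A country-specific value set (tariff) converts each of the
3,125 states to a utility on a scale where 1 is full health and 0 is dead.
The bundled Chinese tariff is additive in per-dimension level decrements
and spans −0.391 (state 55555) to 1 (state 11111).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

DIMENSIONS = ("mo", "sc", "ua", "pd", "ad")
SUBSCALES = ("pl", "as", "af", "ts", "dp")

#: sentinel for a subscale that cannot be scored (too many missing items)
MISSING = float("nan")


class ValidationError(ValueError):
    """Raised when an input value violates an instrument's range."""


class IntegrityError(ValueError):
    """Raised when value-set constants violate a tariff invariant."""


# ---------------------------------------------------------------------------
# EQ-5D-5L states and value sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EQ5DState:
    """An EQ-5D-5L health state: one level (1–5) per dimension."""

    mo: int
    sc: int
    ua: int
    pd: int
    ad: int

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            level = getattr(self, dim)
            if level not in (1, 2, 3, 4, 5):
                raise ValidationError(
                    f"EQ-5D-5L level for {dim.upper()} must be in 1..5, got {level!r}"
                )

    def levels(self) -> tuple[int, int, int, int, int]:
        return (self.mo, self.sc, self.ua, self.pd, self.ad)

    def __str__(self) -> str:
        return "".join(str(v) for v in self.levels())


@dataclass(frozen=True)
class ValueSet:
    """An additive EQ-5D-5L tariff.

    ``decrements[dim][level]`` is the utility lost when ``dim`` is at
    ``level`` (level 1 loses nothing).  Utility of a state is
    ``1 - sum of its decrements``; the floor is the utility of 55555.
    """

    name: str
    decrements: Mapping[str, Mapping[int, float]]
    floor: float = field(init=False)
    ceiling: float = 1.0

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            if dim not in self.decrements:
                raise IntegrityError(f"value set {self.name!r} missing dimension {dim!r}")
            col = self.decrements[dim]
            prev = 0.0
            for level in range(1, 6):
                if level not in col:
                    raise IntegrityError(
                        f"value set {self.name!r}: no decrement for {dim} level {level}"
                    )
                dec = col[level]
                if dec < 0:
                    raise IntegrityError(
                        f"value set {self.name!r}: negative decrement at {dim} level {level}"
                    )
                if dec < prev:
                    raise IntegrityError(
                        f"value set {self.name!r}: decrement decreases at {dim} level {level}"
                    )
                prev = dec
            if abs(col[1]) > 1e-12:
                raise IntegrityError(
                    f"value set {self.name!r}: level-1 decrement for {dim} must be 0"
                )
        worst = 1.0 - sum(self.decrements[d][5] for d in DIMENSIONS)
        object.__setattr__(self, "floor", worst)

    def utility(self, state: EQ5DState) -> float:
        return utility(state, self)

    def gap_boundary(self) -> float:
        """Largest attainable utility strictly below 1.

        Equals 1 minus the smallest nonzero single-level decrement; used as
        the default upper gap boundary of the boundary-inflated mixture model.
        """
        smallest = min(
            self.decrements[d][lvl]
            for d in DIMENSIONS
            for lvl in range(2, 6)
            if self.decrements[d][lvl] > 0
        )
        return 1.0 - smallest


def utility(state: EQ5DState, vs: ValueSet) -> float:
    """Utility of ``state`` under the additive tariff ``vs``."""
    total = sum(vs.decrements[d][getattr(state, d)] for d in DIMENSIONS)
    return 1.0 - total


def load_value_set(source: str | Path = "china-5L") -> ValueSet:
    """Load a value set by bundled name or from a constants CSV.

    The constants file is tabular with columns ``dimension, level,
    decrement``.  The bundled ``"china-5L"`` tariff spans −0.391 to 1.
    """
    name = str(source)
    if name == "china-5L":
        with resources.files("saqmap.data").joinpath("china_5l.csv").open("rb") as fh:
            table = pd.read_csv(fh)
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"no bundled value set or file named {source!r}")
        table = pd.read_csv(path)
        name = path.stem
    required = {"dimension", "level", "decrement"}
    if not required.issubset(table.columns):
        raise ValueError(
            f"value-set constants need columns {sorted(required)}, got {list(table.columns)}"
        )
    decs: dict[str, dict[int, float]] = {}
    for _, row in table.iterrows():
        dim = str(row["dimension"]).strip().lower()
        decs.setdefault(dim, {})[int(row["level"])] = float(row["decrement"])
    vs = ValueSet(name=name, decrements=decs)
    if name == "china-5L" and not (
        math.isclose(vs.utility(EQ5DState(1, 1, 1, 1, 1)), 1.0)
        and math.isclose(vs.floor, -0.391, abs_tol=1e-9)
    ):
        raise IntegrityError("bundled china-5L tariff fails its endpoint checks")
    return vs


def utility_table(vs: ValueSet) -> dict[str, float]:
    """Brute-force utilities of all 3,125 states, keyed by e.g. '21345'."""
    out: dict[str, float] = {}
    for mo in range(1, 6):
        for sc in range(1, 6):
            for ua in range(1, 6):
                for pd_ in range(1, 6):
                    for ad in range(1, 6):
                        st = EQ5DState(mo, sc, ua, pd_, ad)
                        out[str(st)] = utility(st, vs)
    return out


# ---------------------------------------------------------------------------
# SAQ scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SAQItem:
    id: str
    min: int
    max: int


@dataclass(frozen=True)
class SAQItemMap:
    """Assignment of the 19 SAQ items to the five subscales.

    The default follows the standard instrument: PL has 9 items scored 1–6,
    AS one item 1–5, AF two items 1–6, TS four items 1–5 and DP three items
    1–5.  The assignment is overridable for nonstandard administrations.
    """

    subscales: Mapping[str, Sequence[SAQItem]]

    def __post_init__(self) -> None:
        if set(self.subscales) != set(SUBSCALES):
            raise ValidationError(f"item map must define subscales {SUBSCALES}")
        n = sum(len(items) for items in self.subscales.values())
        if n != 19:
            raise ValidationError(f"SAQ has 19 items, map defines {n}")
        for items in self.subscales.values():
            for item in items:
                if item.min != 1 or item.max not in (5, 6):
                    raise ValidationError(
                        f"item {item.id}: range must be 1–5 or 1–6, got {item.min}–{item.max}"
                    )

    @classmethod
    def default(cls) -> "SAQItemMap":
        def items(ids: range, top: int) -> list[SAQItem]:
            return [SAQItem(f"saq_q{i}", 1, top) for i in ids]

        return cls(
            subscales={
                "pl": items(range(1, 10), 6),
                "as": items(range(10, 11), 5),
                "af": items(range(11, 13), 6),
                "ts": items(range(13, 17), 5),
                "dp": items(range(17, 20), 5),
            }
        )


@dataclass(frozen=True)
class SAQScores:
    """The five SAQ subscale scores on the 0–100 scale (NaN = unscorable)."""

    pl: float
    as_: float
    af: float
    ts: float
    dp: float

    def __post_init__(self) -> None:
        for sub in SUBSCALES:
            v = getattr(self, _attr(sub))
            if not math.isnan(v) and not 0.0 <= v <= 100.0:
                raise ValidationError(f"subscale {sub} score {v} outside [0, 100]")

    def as_dict(self) -> dict[str, float]:
        return {sub: getattr(self, _attr(sub)) for sub in SUBSCALES}


def _attr(sub: str) -> str:
    return "as_" if sub == "as" else sub


def score_saq(
    item_responses: Mapping[str, float | None],
    item_map: SAQItemMap | None = None,
    *,
    allow_imputation: bool = True,
) -> SAQScores:
    """Score raw SAQ item responses to the five 0–100 subscales.

    Each subscale score is ``(sum − min_sum) / (max_sum − min_sum) × 100``.
    Missing items (absent or None/NaN) are mean-imputed within the subscale
    when at least half its items are answered and ``allow_imputation`` is
    on; otherwise the subscale is returned as NaN.  Out-of-range responses
    raise :class:`ValidationError` naming the item.
    """
    item_map = item_map or SAQItemMap.default()
    scores: dict[str, float] = {}
    for sub, items in item_map.subscales.items():
        answered: list[float] = []
        n_missing = 0
        for item in items:
            raw = item_responses.get(item.id)
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                n_missing += 1
                continue
            val = float(raw)
            if not item.min <= val <= item.max:
                raise ValidationError(
                    f"response {val} for item {item.id} outside its range "
                    f"{item.min}–{item.max}"
                )
            answered.append(val)
        if n_missing:
            scorable = allow_imputation and len(answered) >= len(items) / 2
            if not scorable:
                scores[sub] = MISSING
                continue
            mean = sum(answered) / len(answered)
            total = sum(answered) + n_missing * mean
        else:
            total = sum(answered)
        lo = sum(it.min for it in items)
        hi = sum(it.max for it in items)
        scores[sub] = (total - lo) / (hi - lo) * 100.0
    return SAQScores(
        pl=scores["pl"], as_=scores["as"], af=scores["af"], ts=scores["ts"], dp=scores["dp"]
    )
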