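"""Scenario parameterisation: LULC demand and transition rules.

The demand side extracts per-class prevalences (cell counts over the dynamic
area) from observed maps, extrapolates them linearly along the slope of the
last two observed steps, clamps negatives, applies policy overrides (frozen
or replacement-only classes), and rebalances so every step sums exactly to
the number of dynamic cells.

The transition side holds one binary matrix per simulation period: rows are
current classes, columns future classes, 1 = allowed.  The shipped default
matrices encode a baseline Swiss scenario: urban land is never taken over,
urban expansion stops after the first forecast step, agricultural classes
interconvert, vegetation succession runs forest-ward only, and glacier
retreat follows the glacier -> bare land -> unproductive vegetation sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .raster_io import ClassCodebook, LULCMap, swiss_codebook

__all__ = [
    "DemandSchedule",
    "PolicyOverride",
    "TransitionMatrix",
    "observed_prevalence",
    "observed_counts",
    "extrapolate_demand",
    "apply_policy_overrides",
    "demand_to_fractions",
    "fractions_to_counts",
    "load_transition_matrix",
    "save_transition_matrix",
    "allowed",
    "all_permissive_matrix",
    "swiss_transition_matrices",
]


@dataclass
class DemandSchedule:
    """Per-step, per-class target cell counts over the dynamic area.

    ``counts`` is indexed by modelled class id with one column per time-step
    label (observed steps first, then future steps); every column sums to
    ``dynamic_total``.
    """

    counts: pd.DataFrame
    dynamic_total: int
    n_observed: int

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < -1e-9).any():
            raise ValueError("demand counts must be non-negative")
        sums = self.counts.sum(axis=0).to_numpy()
        if not np.allclose(sums, self.dynamic_total, atol=1e-6):
            raise ValueError("each step's demand must sum to dynamic_total")

    @property
    def future_labels(self) -> list[str]:
        return list(self.counts.columns[self.n_observed:])

    def step(self, label: str) -> pd.Series:
        return self.counts[label]


@dataclass(frozen=True)
class PolicyOverride:
    """A policy constraint on future demand for a set of classes.

    ``freeze`` pins each class to its value at ``start_step`` for all later
    steps; ``replacement-only`` caps it at that value (the class may shrink
    but only regain up to its losses).
    """

    class_ids: tuple[int, ...]
    action: str  # "freeze" | "replacement-only"
    start_step: int  # index into the future steps (0 = first future step)

    def __post_init__(self) -> None:
        if self.action not in ("freeze", "replacement-only"):
            raise ValueError(f"unknown action {self.action!r}")


def observed_prevalence(lulc: LULCMap) -> pd.Series:
    """Cell counts per modelled class over valid dynamic cells."""
    ids = lulc.codebook.modelled_ids
    counts = lulc.counts(ids)
    return pd.Series(counts, dtype=float)


def observed_counts(maps: Sequence[LULCMap], labels: Sequence[str]) -> pd.DataFrame:
    """Prevalence table (classes x steps) from a series of observed maps."""
    cols = {lab: observed_prevalence(m) for lab, m in zip(labels, maps)}
    return pd.DataFrame(cols)


def _rebalance(values: pd.Series, total: float, locked: Iterable[int]) -> pd.Series:
    """Scale unlocked classes proportionally so the step sums to ``total``.

    Locked classes (frozen/capped by policy, or clamped at zero) keep their
    values; the residual is spread over the rest proportionally to size.
    """
    locked = set(locked)
    out = values.astype(float).copy()
    free = [c for c in out.index if c not in locked]
    residual = total - out[list(locked)].sum() if locked else total
    if not free:
        if abs(out.sum() - total) > 1e-6:
            raise ValueError("infeasible demand: all classes constrained but "
                             "counts do not sum to the dynamic total")
        return out
    if residual < -1e-9:
        raise ValueError("infeasible demand: constrained classes exceed the dynamic total")
    free_sum = out[free].sum()
    if free_sum <= 0:
        out[free] = residual / len(free)
    else:
        out[free] = out[free] * (residual / free_sum)
    return out


def extrapolate_demand(
    observed: pd.DataFrame,
    n_future: int,
    future_labels: Sequence[str] | None = None,
) -> DemandSchedule:
    """Linear demand extrapolation along the last two observed steps.

    Each future step continues the straight line through the last two
    observed anchors; negative projections are clamped to zero and each step
    is rescaled proportionally over the unclamped classes so it sums to the
    dynamic total.
    """
    if observed.shape[1] < 2:
        raise ValueError("need at least two observed steps")
    total = float(observed.iloc[:, 0].sum())
    if not np.allclose(observed.sum(axis=0), total):
        raise ValueError("observed steps do not share a dynamic total")
    a, b = observed.iloc[:, -2], observed.iloc[:, -1]
    slope = b - a
    if future_labels is None:
        future_labels = [f"f{i+1}" for i in range(n_future)]
    counts = observed.astype(float).copy()
    for i, lab in enumerate(future_labels, start=1):
        raw = b + slope * i
        clamped = raw.clip(lower=0.0)
        at_zero = clamped.index[clamped <= 0]
        counts[lab] = _rebalance(clamped, total, locked=at_zero)
    return DemandSchedule(counts, int(round(total)), observed.shape[1])


def apply_policy_overrides(
    schedule: DemandSchedule, overrides: Sequence[PolicyOverride]
) -> DemandSchedule:
    """Apply freeze / replacement-only overrides to the future steps.

    Frozen classes keep their ``start_step`` value in all later steps;
    replacement-only classes never exceed it.  Each affected step is
    rebalanced over unconstrained classes; overrides are idempotent.
    """
    if not overrides:
        return schedule
    counts = schedule.counts.copy()
    future = schedule.future_labels
    for i, lab in enumerate(future):
        locked: dict[int, float] = {}
        for ov in overrides:
            if i < ov.start_step:
                continue
            ref_lab = (future[ov.start_step - 1] if ov.start_step > 0
                       else schedule.counts.columns[schedule.n_observed - 1])
            for cid in ov.class_ids:
                if cid not in counts.index:
                    raise KeyError(f"override names unknown class {cid}")
                ref = float(schedule.counts.loc[cid, ref_lab])
                cur = float(counts.loc[cid, lab])
                if ov.action == "freeze":
                    locked[cid] = ref
                else:  # replacement-only: cap at the reference value
                    locked[cid] = min(cur, ref)
        col = counts[lab].copy()
        for cid, v in locked.items():
            col[cid] = v
        counts[lab] = _rebalance(col, schedule.dynamic_total, locked=locked)
    return DemandSchedule(counts, schedule.dynamic_total, schedule.n_observed)


def demand_to_fractions(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts -> fractions of the dynamic area (interface representation)."""
    return counts / counts.sum(axis=0)


def fractions_to_counts(fractions: pd.DataFrame, dynamic_total: int) -> pd.DataFrame:
    """Fractions -> integer-consistent counts summing to ``dynamic_total``."""
    return fractions * float(dynamic_total)


# ---------------------------------------------------------------------------
# Transition matrices
# ---------------------------------------------------------------------------

@dataclass
class TransitionMatrix:
    """Binary allowed/forbidden matrix over modelled classes for one period."""

    matrix: pd.DataFrame  # rows = current class id, columns = future class id
    period: str

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy()
        if m.shape[0] != m.shape[1]:
            raise ValueError("transition matrix must be square")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("transition matrix entries must be 0 or 1")
        if list(self.matrix.index) != list(self.matrix.columns):
            raise ValueError("row and column labels must match")
        if not np.all(np.diag(m) == 1):
            raise ValueError("diagonal must be 1: a class may always persist")

    @property
    def class_ids(self) -> list[int]:
        return list(self.matrix.index)

    def as_array(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=bool)


def allowed(matrix: TransitionMatrix, from_class: int, to_class: int) -> bool:
    """Is the current -> future conversion permitted in this period?"""
    return bool(matrix.matrix.loc[from_class, to_class])


def save_transition_matrix(matrix: TransitionMatrix, path: str | Path) -> None:
    matrix.matrix.to_csv(path)


def load_transition_matrix(
    path: str | Path, period: str, codebook: ClassCodebook | None = None
) -> TransitionMatrix:
    df = pd.read_csv(path, index_col=0)
    df.columns = [int(c) for c in df.columns]
    df.index = [int(i) for i in df.index]
    tm = TransitionMatrix(df.astype(int), period)
    if codebook is not None:
        expected = list(codebook.modelled_ids)
        if sorted(tm.class_ids) != sorted(expected):
            raise ValueError("transition matrix labels do not match the codebook's "
                             f"modelled classes: {tm.class_ids} vs {expected}")
    return tm


def all_permissive_matrix(codebook: ClassCodebook, period: str = "all") -> TransitionMatrix:
    ids = list(codebook.modelled_ids)
    df = pd.DataFrame(1, index=ids, columns=ids, dtype=int)
    return TransitionMatrix(df, period)


def _swiss_rule_entries(first_period: bool) -> dict[tuple[int, int], int]:
    """Off-diagonal allowed transitions of the baseline Swiss scenario.

    Class ids follow the 17-class codebook: 1 Industry, 2 Building,
    3 Special urban, 4 Urban green, 5 Horticulture, 6 Arable, 7 Grassland,
    8 Alpine grassland, 9 Forest, 10 Brush, 11 Trees, 12 Unproductive
    vegetation, 13 Bare land, 14 Glacier.
    """
    urban = (1, 2, 3, 4)
    e: dict[tuple[int, int], int] = {}

    def allow(frm, to):
        for f in np.atleast_1d(frm):
            for t in np.atleast_1d(to):
                if f != t:
                    e[(int(f), int(t))] = 1

    # Arable and Grassland may be urbanised, first forecast step only.
    if first_period:
        allow([6, 7], urban)
    # Crop rotation / permanent conversion between Arable and Grassland.
    allow(6, 7); allow(7, 6)
    # Arable/Grassland may take over Forest, Brush, Unproductive vegetation.
    allow([9, 10, 12], [6, 7])
    # Alpine grassland may clear Forest, Brush, Trees, Unproductive vegetation.
    allow([9, 10, 11, 12], 8)
    # Pasture abandonment: Alpine grassland -> Brush/Trees/Forest (forest-ward only).
    allow(8, [9, 10, 11])
    # Forest expands over Brush, Trees, Unproductive vegetation (never the
    # reverse) — but not onto built or cultivated land.
    allow([10, 11, 12], 9)
    # Trees / Brush / Unproductive vegetation interconvert freely.
    allow(10, [11, 12]); allow(11, [10, 12]); allow(12, [10, 11])
    # Trees are the only forested class allowed onto Grassland (new hedges).
    allow(7, 11)
    # Horticulture may take over Arable, Grassland, Trees, Unproductive
    # vegetation (demand caps it at replacing losses), and may be lost to
    # agriculture.
    allow([6, 7, 11, 12], 5)
    allow(5, [6, 7])
    # Glacier retreat sequence: Glacier -> Bare land -> Unproductive
    # vegetation, one-way; Unproductive vegetation is the only class that can
    # take over Bare land.
    allow(14, 13)
    allow(13, 12)
    return e


def swiss_transition_matrices() -> tuple[TransitionMatrix, TransitionMatrix]:
    """Default period-1 and period-2 matrices of the baseline scenario.

    Period 1 covers the first forecast step (urban expansion still allowed);
    period 2 covers all later steps (urban columns closed off-diagonal).
    Urban rows are diagonal-only in both periods: no class takes over urban
    land.
    """
    cb = swiss_codebook()
    ids = list(cb.modelled_ids)
    out = []
    for first, period in ((True, "period-1"), (False, "period-2")):
        df = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
        np.fill_diagonal(df.values, 1)
        for (f, t), v in _swiss_rule_entries(first).items():
            df.loc[f, t] = v
        out.append(TransitionMatrix(df, period))
    return out[0], out[1]
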