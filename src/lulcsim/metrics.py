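"""Map-comparison and demand-audit statistics.

Implements the validation toolkit used for categorical map agreement:
overall accuracy with a confidence interval, the quantity/allocation
decomposition of disagreement (Pontius–Millones), one-vs-rest per-class
sensitivity, specificity and balanced accuracy, and the audit of how closely
an allocated map series honours its demand schedule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .raster_io import LULCMap
from .scenario import DemandSchedule, observed_prevalence

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "overall_accuracy_ci",
    "quantity_allocation_disagreement",
    "per_class_stats",
    "balanced_accuracy",
    "demand_audit",
]


@dataclass
class ConfusionMatrix:
    """Reference (rows) x predicted (columns) cell counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if list(self.counts.index) != list(self.counts.columns):
            raise ValueError("row and column labels must match")

    @property
    def total(self) -> float:
        return float(self.counts.to_numpy().sum())

    @property
    def proportions(self) -> pd.DataFrame:
        return self.counts / self.total

    def permuted(self, order: Sequence) -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts.loc[order, order])


def confusion(
    reference: np.ndarray, predicted: np.ndarray, ids: Sequence[int] | None = None
) -> ConfusionMatrix:
    """Cross-tabulate reference vs predicted class vectors."""
    reference = np.asarray(reference).ravel()
    predicted = np.asarray(predicted).ravel()
    if reference.shape != predicted.shape:
        raise ValueError("reference and predicted must have equal length")
    if ids is None:
        ids = sorted(set(reference) | set(predicted))
    ids = [int(i) for i in ids]
    pos = {c: k for k, c in enumerate(ids)}
    counts = np.zeros((len(ids), len(ids)), dtype=np.int64)
    ri = np.array([pos[int(v)] for v in reference])
    pi = np.array([pos[int(v)] for v in predicted])
    np.add.at(counts, (ri, pi), 1)
    return ConfusionMatrix(pd.DataFrame(counts, index=ids, columns=ids))


def overall_accuracy_ci(
    cm: ConfusionMatrix, level: float = 0.95, method: str = "normal"
) -> tuple[float, float, float]:
    """Overall accuracy with a binomial confidence interval, clipped to [0, 1].

    ``method='normal'`` uses the symmetric normal approximation
    oa +/- z*sqrt(oa(1-oa)/n); ``'wilson'`` the Wilson score interval.
    """
    n = cm.total
    if n <= 0:
        raise ValueError("empty confusion matrix")
    oa = float(np.trace(cm.counts.to_numpy())) / n
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    if method == "normal":
        half = z * np.sqrt(oa * (1 - oa) / n)
        lo, hi = oa - half, oa + half
    elif method == "wilson":
        denom = 1 + z * z / n
        centre = (oa + z * z / (2 * n)) / denom
        half = z * np.sqrt(oa * (1 - oa) / n + z * z / (4 * n * n)) / denom
        lo, hi = centre - half, centre + half
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return oa, max(0.0, lo), min(1.0, hi)


def quantity_allocation_disagreement(cm: ConfusionMatrix) -> tuple[float, float]:
    """Quantity (Q) and allocation (A) disagreement of a confusion matrix.

    For each class g with proportion matrix p: q_g = |p_{+g} - p_{g+}| and
    a_g = 2 min(p_{g+} - p_{gg}, p_{+g} - p_{gg}); Q and A are the halved
    sums.  Q + A = 1 - overall agreement, exactly.
    """
    p = cm.proportions.to_numpy()
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    diag = np.diag(p)
    q = np.abs(col - row)
    a = 2.0 * np.minimum(row - diag, col - diag)
    return float(q.sum() / 2.0), float(a.sum() / 2.0)


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Mean of sensitivity (TPR) and specificity (TNR)."""
    return (sensitivity + specificity) / 2.0


def per_class_stats(cm: ConfusionMatrix) -> pd.DataFrame:
    """One-vs-rest sensitivity, specificity, balanced accuracy per class.

    A class absent from the reference has undefined sensitivity: it is
    reported as NaN with a warning, never as 0.
    """
    c = cm.counts.to_numpy(dtype=float)
    if c.shape[0] < 2:
        raise ValueError("need at least two classes")
    n = c.sum()
    ids = list(cm.counts.index)
    rows = []
    for k, cid in enumerate(ids):
        tp = c[k, k]
        fn = c[k, :].sum() - tp
        fp = c[:, k].sum() - tp
        tn = n - tp - fn - fp
        if tp + fn == 0:
            warnings.warn(f"class {cid} absent from reference; sensitivity undefined")
            sens = np.nan
        else:
            sens = tp / (tp + fn)
        spec = tn / (tn + fp) if (tn + fp) > 0 else np.nan
        rows.append({
            "class": cid,
            "sensitivity": sens,
            "specificity": spec,
            "balanced_accuracy": balanced_accuracy(sens, spec),
        })
    return pd.DataFrame(rows).set_index("class")


def demand_audit(
    baseline: LULCMap,
    schedule: DemandSchedule,
    allocated: Sequence[LULCMap],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Requested-vs-obtained prevalence change per class and forecast step.

    Entry = (obtained prevalence - baseline prevalence) - (demanded
    prevalence - baseline prevalence), as a fraction of the dynamic area:
    e.g. a class asked to grow by 0.3 that grew by 0.4 scores 0.1.
    """
    if labels is None:
        labels = schedule.future_labels[: len(allocated)]
    if len(labels) != len(allocated):
        raise ValueError("one label per allocated map required")
    total = float(schedule.dynamic_total)
    base = observed_prevalence(baseline) / total
    out = {}
    for lab, m in zip(labels, allocated):
        obtained = observed_prevalence(m) / total
        demanded = schedule.step(lab) / total
        out[lab] = (obtained - base) - (demanded - base)
    return pd.DataFrame(out)
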