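"""Balanced change sampling and SMOTE-NC minority oversampling.

Cells that change class between time-steps are rare, so an unweighted sample
would teach the classifier to predict persistence only.  The training sample
therefore contains *all* changing cells plus an equal-size random sample of
non-changing cells, and the changing subset is then oversampled per class
with SMOTE-NC (Synthetic Minority Over-sampling TEchnique for Nominal and
Continuous features) until every class matches the most prevalent one.

SMOTE-NC distance between two rows: Euclidean on the continuous features,
plus ``med**2`` for every categorical mismatch, where ``med`` is the median
of the continuous features' standard deviations.  A synthetic row
interpolates continuous values between a seed row and one of its k nearest
same-class neighbours (u ~ Uniform(0,1)) and takes the mode of each
categorical feature among the k neighbours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import assemble_features
from .raster_io import LULCMap, PredictorStack

__all__ = ["TrainingTable", "balanced_change_sample", "smote_nc", "augment_changing"]


@dataclass
class TrainingTable:
    """Sampled cells with raw (pre-encoding) features and sampling flags."""

    features: pd.DataFrame
    response: pd.Series
    change_flag: pd.Series
    synthetic_flag: pd.Series
    continuous_cols: list[str]
    categorical_cols: list[str]

    def __post_init__(self) -> None:
        n = len(self.features)
        for s in (self.response, self.change_flag, self.synthetic_flag):
            if len(s) != n:
                raise ValueError("column length mismatch")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def changing(self) -> "TrainingTable":
        m = self.change_flag.to_numpy(bool)
        return self._subset(m)

    def _subset(self, mask: np.ndarray) -> "TrainingTable":
        return TrainingTable(
            self.features.loc[mask].reset_index(drop=True),
            self.response.loc[mask].reset_index(drop=True),
            self.change_flag.loc[mask].reset_index(drop=True),
            self.synthetic_flag.loc[mask].reset_index(drop=True),
            list(self.continuous_cols),
            list(self.categorical_cols),
        )

    def class_counts(self) -> pd.Series:
        return self.response.value_counts().sort_index()

    def to_frame(self) -> pd.DataFrame:
        df = self.features.copy()
        df["response"] = self.response.to_numpy()
        df["change_flag"] = self.change_flag.to_numpy()
        df["synthetic_flag"] = self.synthetic_flag.to_numpy()
        return df


def balanced_change_sample(
    history: Sequence[LULCMap],
    response_map: LULCMap,
    predictors: PredictorStack,
    *,
    window_cells: int = 5,
    seed: int | np.random.Generator = 0,
) -> TrainingTable:
    """All changing cells plus an equal random sample of non-changing cells.

    A cell "changes" when its class at the response step differs from its
    class at t0.  Only dynamic cells (valid, modelled class at both steps)
    enter the universe.  If fewer non-changing cells exist than changing
    ones, all of them are taken with a warning.
    """
    rng = np.random.default_rng(seed)
    t0 = history[-1]
    t0.grid.require_aligned(response_map.grid)
    table, meta = assemble_features(history, predictors, window_cells)
    rows, cols = meta["rows"], meta["cols"]
    resp = response_map.codes[rows, cols]
    usable = np.isin(resp, response_map.codebook.modelled_ids)
    changed = (resp != t0.codes[rows, cols]) & usable
    unchanged = (~changed) & usable

    n_change = int(changed.sum())
    if n_change == 0:
        raise ValueError("no change signal: no cell changes class")
    idx_change = np.nonzero(changed)[0]
    idx_keep = np.nonzero(unchanged)[0]
    if len(idx_keep) < n_change:
        warnings.warn(
            f"only {len(idx_keep)} non-changing cells for {n_change} changing; taking all"
        )
        idx_same = idx_keep
    else:
        idx_same = rng.choice(idx_keep, size=n_change, replace=False)
    take = np.concatenate([idx_change, np.sort(idx_same)])
    return TrainingTable(
        features=table.iloc[take].reset_index(drop=True),
        response=pd.Series(resp[take]),
        change_flag=pd.Series(np.concatenate(
            [np.ones(len(idx_change), bool), np.zeros(len(idx_same), bool)])),
        synthetic_flag=pd.Series(np.zeros(len(take), bool)),
        continuous_cols=list(meta["continuous"]),
        categorical_cols=list(meta["categorical"]),
    )


def _mixed_distances(
    cont: np.ndarray, cat: np.ndarray, i: int, med_sq: float
) -> np.ndarray:
    """Squared SMOTE-NC distance from row i to every row."""
    d = np.sum((cont - cont[i]) ** 2, axis=1)
    if cat.shape[1]:
        d = d + med_sq * np.sum(cat != cat[i], axis=1)
    return d


def _mode(values: np.ndarray):
    """Most frequent value; ties broken by smallest value."""
    vals, counts = np.unique(values, return_counts=True)
    return vals[np.argmax(counts)]  # np.unique sorts, argmax takes first max


def smote_nc(
    table: TrainingTable,
    targets: Mapping[int, int],
    *,
    k: int = 5,
    seed: int | np.random.Generator = 0,
) -> TrainingTable:
    """Oversample each class of ``table`` up to its target row count.

    Non-synthetic rows are never altered; synthetic rows carry
    ``synthetic_flag``.  A class with a single row cannot be interpolated and
    is duplicated with a warning.  Classes already at (or above) target are
    returned unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    cont_cols = table.continuous_cols
    cat_cols = table.categorical_cols
    cont = table.features[cont_cols].to_numpy(dtype=float)
    cat = table.features[cat_cols].to_numpy() if cat_cols else \
        np.empty((len(table), 0))
    sds = cont.std(axis=0, ddof=1) if len(cont) > 1 else np.zeros(cont.shape[1])
    med = float(np.median(sds)) if cont.shape[1] else 1.0
    med_sq = med * med

    resp = table.response.to_numpy()
    new_rows: list[dict] = []
    new_resp: list[int] = []
    for cls in sorted(targets):
        members = np.nonzero(resp == cls)[0]
        need = int(targets[cls]) - len(members)
        if need <= 0:
            continue
        if len(members) == 0:
            raise ValueError(f"class {cls} has no rows to oversample from")
        if len(members) == 1:
            warnings.warn(f"class {cls} has a single row; duplicating it")
            base = table.features.iloc[members[0]]
            for _ in range(need):
                new_rows.append(base.to_dict())
                new_resp.append(cls)
            continue
        kk = min(k, len(members) - 1)
        # pairwise neighbour lists within the class under the mixed metric
        ccont, ccat = cont[members], cat[members]
        neigh: list[np.ndarray] = []
        for ii in range(len(members)):
            d = _mixed_distances(ccont, ccat, ii, med_sq)
            d[ii] = np.inf
            order = np.argsort(d, kind="stable")  # ties by row order
            neigh.append(order[:kk])
        for _ in range(need):
            si = rng.integers(len(members))
            nb = neigh[si]
            ni = nb[rng.integers(len(nb))]
            u = rng.uniform()
            cvals = ccont[si] + u * (ccont[ni] - ccont[si])
            row = {c: v for c, v in zip(cont_cols, cvals)}
            for j, c in enumerate(cat_cols):
                row[c] = _mode(ccat[nb, j])
            new_rows.append(row)
            new_resp.append(cls)

    if not new_rows:
        return table
    synth = pd.DataFrame(new_rows)[table.features.columns]
    feats = pd.concat([table.features, synth], ignore_index=True)
    resp_out = pd.concat([table.response, pd.Series(new_resp)], ignore_index=True)
    n_new = len(new_rows)
    return TrainingTable(
        features=feats,
        response=resp_out,
        change_flag=pd.concat(
            [table.change_flag, pd.Series(np.ones(n_new, bool))], ignore_index=True),
        synthetic_flag=pd.concat(
            [table.synthetic_flag, pd.Series(np.ones(n_new, bool))], ignore_index=True),
        continuous_cols=list(cont_cols),
        categorical_cols=list(cat_cols),
    )


def augment_changing(
    table: TrainingTable,
    *,
    k: int = 5,
    target: int | None = None,
    seed: int | np.random.Generator = 0,
) -> TrainingTable:
    """Oversample the changing subset so every class matches the largest one.

    Non-changing rows pass through untouched; only changing cells are
    augmented (their most prevalent class is still rarer than the rarest
    non-changing class, so balancing within the changing subset suffices).
    """
    changing = table.changing
    counts = changing.class_counts()
    tgt = int(target if target is not None else counts.max())
    targets = {int(c): tgt for c in counts.index}
    augmented = smote_nc(changing, targets, k=k, seed=seed)
    keep = ~table.change_flag.to_numpy(bool)
    rest = table._subset(keep)
    return TrainingTable(
        features=pd.concat([rest.features, augmented.features], ignore_index=True),
        response=pd.concat([rest.response, augmented.response], ignore_index=True),
        change_flag=pd.concat([rest.change_flag, augmented.change_flag],
                              ignore_index=True),
        synthetic_flag=pd.concat([rest.synthetic_flag, augmented.synthetic_flag],
                                 ignore_index=True),
        continuous_cols=list(table.continuous_cols),
        categorical_cols=list(table.categorical_cols),
    )
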