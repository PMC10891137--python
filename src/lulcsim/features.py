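"""Feature engineering for the suitability classifier.

Builds the model's feature table from a three-step LULC history and a
predictor stack: focal-window class proportions and dominant class, lagged
class codes, distance-to-class layers, one-hot encoding of categoricals with
a schema frozen at fit time, greedy correlation-based selection among
continuous columns, and standardisation with stored parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster_io import NODATA, LULCMap, PredictorStack

__all__ = [
    "neighbourhood_proportion",
    "class_proportions",
    "dominant_class",
    "distance_to_class",
    "OneHotSchema",
    "select_uncorrelated",
    "window_cells_for",
    "Standardizer",
    "change_association",
    "assemble_features",
    "FeaturePipeline",
    "DISTANCE_SENTINEL",
]

#: Distance reported for classes absent from the map, metres.
DISTANCE_SENTINEL = 1e7


def window_cells_for(extent_m: float, cell_size: float) -> int:
    """Cells spanned by a window of ``extent_m`` metres, rounded up to odd.

    Centred focal windows need an odd cell count, so a 5 km window on 100 m
    cells (50 cells) becomes 51.
    """
    n = max(1, round(extent_m / cell_size))
    return n if n % 2 == 1 else n + 1


def _window_sum(arr: np.ndarray, window_cells: int) -> np.ndarray:
    """Sum of ``arr`` over a centred window, truncated at the array edge."""
    k = np.ones((window_cells, window_cells))
    return ndimage.correlate(arr.astype(float), k, mode="constant", cval=0.0)


def _check_window(window_cells: int) -> None:
    if window_cells < 1 or window_cells % 2 == 0:
        raise ValueError("window_cells must be an odd positive integer")


def neighbourhood_proportion(
    lulc: LULCMap, class_id: int, window_cells: int
) -> np.ndarray:
    """Fraction of valid in-window cells of ``class_id`` around each cell.

    The window is truncated at map edges: the denominator is the number of
    valid cells actually inside the window.  Cells whose window contains no
    valid cell get NaN.
    """
    _check_window(window_cells)
    if class_id not in lulc.codebook:
        raise KeyError(f"unknown class id {class_id}")
    valid = lulc.valid_mask.astype(float)
    hits = ((lulc.codes == class_id) & lulc.valid_mask).astype(float)
    denom = _window_sum(valid, window_cells)
    num = _window_sum(hits, window_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, num / np.maximum(denom, 1e-300), np.nan)
    return out


def class_proportions(
    lulc: LULCMap, window_cells: int, ids: Sequence[int] | None = None
) -> dict[int, np.ndarray]:
    """``neighbourhood_proportion`` for every class; cellwise sums equal 1."""
    ids = list(ids if ids is not None else lulc.codebook.ids)
    return {i: neighbourhood_proportion(lulc, i, window_cells) for i in ids}


def dominant_class(lulc: LULCMap, window_cells: int) -> np.ndarray:
    """Modal class in the centred window; ties broken by smallest class id.

    All-nodata windows yield the nodata code.
    """
    _check_window(window_cells)
    ids = sorted(lulc.codebook.ids)
    best_count = np.full(lulc.grid.shape, -1.0)
    best_id = np.full(lulc.grid.shape, NODATA, dtype=np.int32)
    for cid in ids:  # ascending id, strict > keeps the smallest id on ties
        cnt = _window_sum(((lulc.codes == cid) & lulc.valid_mask).astype(float),
                          window_cells)
        better = cnt > best_count + 0.5
        best_id = np.where(better, cid, best_id)
        best_count = np.maximum(best_count, cnt)
    best_id[best_count < 0.5] = NODATA
    return best_id


def distance_to_class(lulc: LULCMap, class_id: int,
                      sentinel: float = DISTANCE_SENTINEL) -> np.ndarray:
    """Euclidean metres from each cell centre to the nearest ``class_id`` cell.

    Zero on the class itself; ``sentinel`` everywhere if the class is absent.
    """
    if class_id not in lulc.codebook:
        raise KeyError(f"unknown class id {class_id}")
    target = (lulc.codes == class_id) & lulc.valid_mask
    if not target.any():
        return np.full(lulc.grid.shape, sentinel)
    return ndimage.distance_transform_edt(
        ~target, sampling=lulc.grid.cell_size
    )


# ---------------------------------------------------------------------------
# Encoding, selection, standardisation
# ---------------------------------------------------------------------------

@dataclass
class OneHotSchema:
    """One-hot encoding with levels frozen at fit time.

    Transforming data containing a level unseen at fit time is an error:
    the classifier's input schema must stay constant across projection steps.
    """

    levels: dict[str, tuple] = field(default_factory=dict)

    def fit(self, df: pd.DataFrame, columns: Sequence[str]) -> "OneHotSchema":
        for c in columns:
            self.levels[c] = tuple(sorted(pd.unique(df[c].dropna())))
        return self

    @property
    def columns(self) -> list[str]:
        return list(self.levels)

    def encoded_names(self) -> list[str]:
        return [f"{c}={lv}" for c in self.levels for lv in self.levels[c]]

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for c, levels in self.levels.items():
            seen = set(pd.unique(df[c].dropna()))
            unseen = seen - set(levels)
            if unseen:
                raise ValueError(
                    f"column {c!r} has levels unseen at fit time: {sorted(unseen)}"
                )
            for lv in levels:
                out[f"{c}={lv}"] = (df[c] == lv).astype(float)
        return pd.DataFrame(out, index=df.index)


def change_association(features: pd.DataFrame, changed: pd.Series | np.ndarray) -> pd.Series:
    """Rank continuous features by |point-biserial correlation| with change.

    Used to order columns for the greedy correlation filter: features most
    associated with the cell-changed-class indicator are visited first.
    """
    y = np.asarray(changed, dtype=float)
    scores = {}
    for c in features.columns:
        x = np.asarray(features[c], dtype=float)
        sx = x.std()
        if sx == 0 or y.std() == 0:
            scores[c] = 0.0
        else:
            scores[c] = abs(float(np.corrcoef(x, y)[0, 1]))
    return pd.Series(scores).sort_values(ascending=False)


def select_uncorrelated(
    features: pd.DataFrame,
    ranking: pd.Series,
    threshold: float = 0.7,
) -> list[str]:
    """Greedy correlation filter over continuous columns.

    Visits columns in descending ``ranking`` order and drops any column whose
    absolute Pearson correlation with an already-retained column reaches
    ``threshold``.  Zero-variance columns are dropped with a warning before
    ranking.  Selection is computed once on training data and then frozen.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if features.shape[1] == 0:
        raise ValueError("no columns to select from")
    cols = [c for c in ranking.index if c in features.columns]
    usable = []
    for c in cols:
        if features[c].std() == 0:
            warnings.warn(f"dropping zero-variance column {c!r}")
        else:
            usable.append(c)
    retained: list[str] = []
    for c in usable:
        x = features[c].to_numpy(dtype=float)
        ok = True
        for r in retained:
            rxy = abs(float(np.corrcoef(x, features[r].to_numpy(dtype=float))[0, 1]))
            if rxy >= threshold:
                ok = False
                break
        if ok:
            retained.append(c)
    return retained


@dataclass
class Standardizer:
    """Centre and scale by training mean and sample standard deviation."""

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def fit(self, df: pd.DataFrame, columns: Sequence[str]) -> "Standardizer":
        for c in columns:
            m = float(df[c].mean())
            s = float(df[c].std(ddof=1))
            if s == 0 or not np.isfinite(s):
                warnings.warn(f"dropping zero-variance column {c!r} from standardisation")
                continue
            self.means[c] = m
            self.sds[c] = s
        return self

    @property
    def columns(self) -> list[str]:
        return list(self.means)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if not self.means:
            raise RuntimeError("Standardizer must be fit before transform")
        out = df[self.columns].copy()
        for c in self.columns:
            out[c] = (df[c] - self.means[c]) / self.sds[c]
        return out


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

def assemble_features(
    history: Sequence[LULCMap],
    predictors: PredictorStack,
    window_cells: int = 5,
) -> tuple[pd.DataFrame, dict]:
    """Build the raw (pre-encoding) feature table from three lagged maps.

    One row per dynamic cell of the most recent map (t0).  LULC-derived
    features: class code at t-2/t-1/t0 (nominal), per-modelled-class
    neighbourhood proportion at t0 (continuous), dominant class at t0
    (nominal).  Stack layers are appended with their declared kinds.

    Returns ``(table, meta)`` where meta lists continuous/categorical column
    names and the (row, col) index arrays of the included cells.
    """
    if len(history) != 3:
        raise ValueError("history must contain exactly 3 maps (t-2, t-1, t0)")
    t0 = history[-1]
    for m in history:
        t0.grid.require_aligned(m.grid)
    t0.grid.require_aligned(predictors.grid, what="predictor stack")
    dyn = t0.dynamic_mask()
    rows, cols = np.nonzero(dyn)
    data: dict[str, np.ndarray] = {}
    categorical: list[str] = []
    continuous: list[str] = []

    for lag, m in zip(("tm2", "tm1", "t0"), history):
        name = f"lulc_{lag}"
        data[name] = m.codes[rows, cols]
        categorical.append(name)

    props = class_proportions(t0, window_cells, ids=t0.codebook.modelled_ids)
    for cid, layer in props.items():
        name = f"prop_c{cid}_t0"
        data[name] = layer[rows, cols]
        continuous.append(name)

    dom = dominant_class(t0, window_cells)
    data["dominant_t0"] = dom[rows, cols]
    categorical.append("dominant_t0")

    for lname, layer in predictors.layers.items():
        data[lname] = layer.data[rows, cols]
        (continuous if layer.kind == "continuous" else categorical).append(lname)

    table = pd.DataFrame(data)
    meta = {
        "continuous": continuous,
        "categorical": categorical,
        "rows": rows,
        "cols": cols,
    }
    return table, meta


@dataclass
class FeaturePipeline:
    """Frozen encoding pipeline: selection -> standardisation -> one-hot.

    Continuous columns pass the greedy correlation filter and are
    standardised; categorical columns are one-hot encoded and bypass both
    (the filter handles continuous variables only, and indicator columns
    gain nothing from scaling).  The whole schema is frozen at fit time.
    """

    threshold: float = 0.7
    retained: list[str] = field(default_factory=list)
    standardizer: Standardizer = field(default_factory=Standardizer)
    onehot: OneHotSchema = field(default_factory=OneHotSchema)
    continuous_cols: list[str] = field(default_factory=list)
    categorical_cols: list[str] = field(default_factory=list)

    def fit(
        self,
        table: pd.DataFrame,
        continuous: Sequence[str],
        categorical: Sequence[str],
        changed: pd.Series | np.ndarray,
    ) -> "FeaturePipeline":
        self.continuous_cols = list(continuous)
        self.categorical_cols = list(categorical)
        cont = table[self.continuous_cols]
        ranking = change_association(cont, changed)
        self.retained = select_uncorrelated(cont, ranking, self.threshold)
        self.standardizer = Standardizer().fit(table, self.retained)
        self.onehot = OneHotSchema().fit(table, self.categorical_cols)
        return self

    @property
    def output_columns(self) -> list[str]:
        return self.standardizer.columns + self.onehot.encoded_names()

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        cont = self.standardizer.transform(table)
        cat = self.onehot.transform(table)
        return pd.concat([cont, cat], axis=1)

    def schema_frame(self) -> pd.DataFrame:
        """Sidecar schema: column, type, mean, sd, retained flag."""
        rows = []
        for c in self.continuous_cols:
            rows.append({
                "column": c, "type": "continuous",
                "mean": self.standardizer.means.get(c, np.nan),
                "sd": self.standardizer.sds.get(c, np.nan),
                "retained": c in self.retained,
            })
        for c in self.categorical_cols:
            rows.append({"column": c, "type": "categorical",
                         "mean": np.nan, "sd": np.nan, "retained": True})
        return pd.DataFrame(rows)

    def save_schema(self, path: str | Path) -> None:
        self.schema_frame().to_csv(path, index=False)
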