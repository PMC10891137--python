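"""Synthetic multi-temporal landscape generator with known dynamics.

Emulates the statistical structure of national land-statistics LULC series:
a K-class categorical raster observed at several time-steps, where only a
small fraction of cells changes class at each step, class prevalences are
strongly imbalanced and drift slowly, transitions depend on continuous
environmental gradients and on neighbourhood composition, and one class
(e.g. water) is static.

Generative model: at each step a cell is drawn as "changing" with
probability ``change_rate``; a changing cell draws its new class from a
multinomial logit over the modelled classes (excluding its current class)
with linear predictor

    intercept_c(t) + predictor_effects[c] . x + neighbourhood_effect * f_c

where x are the standardised continuous predictors at the cell and f_c the
focal same-class proportion in a small window.  Static-class cells never
change.  All randomness flows through one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .features import class_proportions
from .raster_io import (
    Grid,
    LULCMap,
    PredictorLayer,
    PredictorStack,
    synthetic_codebook,
    write_layer,
    write_map,
    write_point_grid_csv,
)

__all__ = ["LandscapeConfig", "SyntheticTruth", "generate_landscape", "write_fixture"]


@dataclass(frozen=True)
class LandscapeConfig:
    """Configuration of the synthetic landscape generator.

    Defaults describe the reference study conditions used throughout the
    test suite: a 100x100 grid of 100 m cells, 6 classes (class 6 static,
    occupying high ground), 4 observed time-steps, 5% of dynamic cells
    changing per step, and mild opposing prevalence drifts.
    """

    grid_rows: int = 100
    grid_cols: int = 100
    cell_size: float = 100.0
    n_classes: int = 6
    n_steps: int = 4
    change_rate: float = 0.05
    class_drift: tuple[float, ...] = (0.004, 0.002, 0.0, -0.002, -0.004, 0.0)
    predictor_effects: tuple[tuple[float, ...], ...] = (
        (1.5, 0.0, 0.0),
        (0.0, 1.5, 0.0),
        (0.0, 0.0, 1.5),
        (-1.5, 0.0, 0.0),
        (0.0, -1.5, 0.0),
        (0.0, 0.0, 0.0),
    )
    neighbourhood_effect: float = 2.0
    static_class_ids: tuple[int, ...] = (6,)
    focal_window: int = 5
    drift_strength: float = 200.0
    seed: int = 7
    origin_easting: float = 2600000.0
    origin_northing: float = 1200000.0
    crs_id: str = "EPSG:2056"

    def __post_init__(self) -> None:
        if self.n_classes < 3:
            raise ValueError("n_classes must be >= 3")
        if self.n_steps < 4:
            raise ValueError("n_steps must be >= 4")
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValueError("grid must have positive area")
        if not 0 <= self.change_rate < 1:
            raise ValueError("change_rate must be in [0, 1)")
        if len(self.class_drift) != self.n_classes:
            raise ValueError("class_drift needs one entry per class")
        if abs(sum(self.class_drift)) > 1e-9:
            raise ValueError("class_drift must sum to 0 (prevalences stay a partition)")
        if len(self.predictor_effects) != self.n_classes:
            raise ValueError("predictor_effects needs one row per class")
        if self.change_rate > 0 and self.change_rate * self.grid_rows * self.grid_cols < 1:
            raise ValueError("change_rate * cells must be >= 1")
        for sid in self.static_class_ids:
            if not 1 <= sid <= self.n_classes:
                raise ValueError(f"static class id {sid} out of range")

    @property
    def grid(self) -> Grid:
        return Grid(self.grid_rows, self.grid_cols, self.cell_size,
                    self.origin_easting, self.origin_northing, self.crs_id)


@dataclass
class SyntheticTruth:
    """Ground truth of one generated landscape series."""

    config: LandscapeConfig
    effects: np.ndarray                       # (n_classes, n_predictors)
    neighbourhood_effect: float
    prevalences: list[dict[int, int]] = field(default_factory=list)
    changed_indices: list[np.ndarray] = field(default_factory=list)

    def changed_fraction(self, step: int) -> float:
        n_dyn = self._n_dynamic
        return len(self.changed_indices[step]) / n_dyn

    @property
    def _n_dynamic(self) -> int:
        total = self.config.grid_rows * self.config.grid_cols
        static = sum(self.prevalences[0].get(s, 0)
                     for s in self.config.static_class_ids)
        return total - static


def _gaussian_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    return (f - f.mean()) / f.std()


def _make_predictors(cfg: LandscapeConfig, rng: np.random.Generator) -> PredictorStack:
    shape = (cfg.grid_rows, cfg.grid_cols)
    stack = PredictorStack(cfg.grid)
    # elevation-like smooth gradient plus gentle relief
    rowgrad = np.linspace(1.0, -1.0, cfg.grid_rows)[:, None] * np.ones(shape)
    elev = rowgrad + 0.6 * _gaussian_field(rng, shape, sigma=8.0)
    elev = (elev - elev.mean()) / elev.std()
    stack.add(PredictorLayer("elevation", "continuous", elev))
    stack.add(PredictorLayer("moisture", "continuous",
                             _gaussian_field(rng, shape, sigma=5.0)))
    stack.add(PredictorLayer("access", "continuous",
                             _gaussian_field(rng, shape, sigma=5.0)))
    # categorical predictor: contiguous regions (nearest of a few seed points)
    n_regions = 5
    pr = rng.uniform(0, cfg.grid_rows, n_regions)
    pc = rng.uniform(0, cfg.grid_cols, n_regions)
    rr, cc = np.mgrid[0:cfg.grid_rows, 0:cfg.grid_cols]
    d = (rr[..., None] - pr) ** 2 + (cc[..., None] - pc) ** 2
    region = np.argmin(d, axis=-1).astype(np.int32) + 1
    stack.add(PredictorLayer("region", "categorical", region))
    return stack


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def generate_landscape(
    config: LandscapeConfig,
) -> tuple[list[LULCMap], PredictorStack, SyntheticTruth]:
    """Generate ``n_steps`` LULC maps, the predictor stack and ground truth.

    Deterministic given ``config.seed``; ``change_rate=0`` freezes every step
    at the initial map.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    stack = _make_predictors(cfg, rng)
    codebook = synthetic_codebook(cfg.n_classes, cfg.static_class_ids)
    modelled = np.array(codebook.modelled_ids)
    effects = np.asarray(cfg.predictor_effects, dtype=float)
    drift = np.asarray(cfg.class_drift, dtype=float)
    shape = (cfg.grid_rows, cfg.grid_cols)

    x = np.stack([stack[n].data for n in ("elevation", "moisture", "access")],
                 axis=-1)  # (r, c, 3)

    # static mask: the static classes occupy the highest-elevation cells
    elev = stack["elevation"].data
    static_mask = np.zeros(shape, bool)
    codes0 = np.zeros(shape, np.int32)
    n_static = len(cfg.static_class_ids)
    if n_static:
        frac = 0.08  # static land share of the landscape
        thr = np.quantile(elev, 1 - frac)
        static_mask = elev >= thr
        # split static area among static classes by row bands
        sids = sorted(cfg.static_class_ids)
        srows, scols = np.nonzero(static_mask)
        bands = np.array_split(np.argsort(srows, kind="stable"), n_static)
        for sid, band in zip(sids, bands):
            codes0[srows[band], scols[band]] = sid

    # initial dynamic cells: multinomial logit on predictors (no neighbourhood)
    logits = x @ effects[modelled - 1].T  # (r, c, n_modelled)
    # imbalanced prevalences via staggered intercepts
    base_intercepts = np.linspace(0.8, -0.8, len(modelled))
    logits = logits + base_intercepts
    p = _softmax(logits)
    u = rng.uniform(size=shape)
    cum = np.cumsum(p, axis=-1)
    pick = (u[..., None] > cum).sum(axis=-1)
    codes0 = np.where(static_mask, codes0, modelled[pick])

    grid = cfg.grid
    maps = [LULCMap(grid, codes0, codebook)]
    truth = SyntheticTruth(cfg, effects, cfg.neighbourhood_effect)
    truth.prevalences.append(maps[0].counts())
    truth.changed_indices.append(np.empty(0, dtype=np.int64))

    dyn_idx = np.nonzero(~static_mask.ravel())[0]
    n_dyn = len(dyn_idx)
    # initial shares of the dynamic area; the configured drift moves the
    # per-step target shares, and a proportional feedback on the intercepts
    # steers realized prevalences onto that trend
    share0 = np.array([truth.prevalences[0][m] / n_dyn for m in modelled])
    for t in range(1, cfg.n_steps):
        cur = maps[-1]
        new_codes = cur.codes.copy()
        if cfg.change_rate > 0:
            changing = rng.uniform(size=len(dyn_idx)) < cfg.change_rate
            chg = dyn_idx[changing]
            if len(chg):
                props = class_proportions(cur, cfg.focal_window, ids=list(modelled))
                rr, cc = np.unravel_index(chg, shape)
                share_now = np.array(
                    [truth.prevalences[-1][m] / n_dyn for m in modelled])
                share_target = share0 + drift[modelled - 1] * t
                z = x[rr, cc] @ effects[modelled - 1].T
                z = z + base_intercepts
                z = z + cfg.drift_strength * (share_target - share_now)
                z = z + cfg.neighbourhood_effect * np.stack(
                    [props[m][rr, cc] for m in modelled], axis=-1)
                # a changing cell must change: exclude the current class
                cur_cls = cur.codes[rr, cc]
                forbid = cur_cls[:, None] == modelled[None, :]
                z = np.where(forbid, -np.inf, z)
                pz = _softmax(z)
                uu = rng.uniform(size=len(chg))
                pick = (uu[:, None] > np.cumsum(pz, axis=1)).sum(axis=1)
                new_codes[rr, cc] = modelled[pick]
                chg = chg[new_codes.ravel()[chg] != cur.codes.ravel()[chg]]
        else:
            chg = np.empty(0, dtype=np.int64)
        nxt = LULCMap(grid, new_codes, codebook)
        maps.append(nxt)
        truth.prevalences.append(nxt.counts())
        truth.changed_indices.append(chg)
    return maps, stack, truth


def write_fixture(config: LandscapeConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete runnable pipeline input set to ``out_dir``.

    Produces one GeoTIFF per time-step, one per predictor layer, the
    point-grid CSV with one class column per step, a demand CSV (observed
    prevalence fractions per step) and an all-permissive transition CSV.
    Returns the paths written, keyed by role.
    """
    from .scenario import (  # local import: scenario depends on raster_io only
        all_permissive_matrix,
        demand_to_fractions,
        observed_counts,
        save_transition_matrix,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    maps, stack, truth = generate_landscape(config)
    paths: dict[str, Path] = {}
    labels = [f"t{i}" for i in range(len(maps))]
    for lab, m in zip(labels, maps):
        p = out / f"lulc_{lab}.tif"
        write_map(m, p)
        paths[f"lulc_{lab}"] = p
    for name, layer in stack.layers.items():
        p = out / f"predictor_{name}.tif"
        write_layer(layer, stack.grid, p)
        paths[f"predictor_{name}"] = p
    p = out / "lulc_points.csv"
    write_point_grid_csv(maps, labels, p)
    paths["points"] = p

    counts = observed_counts(maps, labels)
    frac = demand_to_fractions(counts)
    p = out / "demand.csv"
    frac.to_csv(p)
    paths["demand"] = p

    codebook = maps[0].codebook
    tm = all_permissive_matrix(codebook, period="all")
    p = out / "transitions.csv"
    save_transition_matrix(tm, p)
    paths["transitions"] = p
    return paths
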