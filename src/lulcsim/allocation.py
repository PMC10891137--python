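"""CLUE-S demand-constrained allocation of suitability maps.

The allocator turns per-class suitability layers into a single categorical
map whose class prevalences match a demand vector, subject to binary
transition rules.  It maintains one additive iteration parameter per class
(a demand "price" lambda_c, all zero initially): every pass assigns each
dynamic cell to the allowed class maximising ``suitability + lambda_c``,
compares the per-class allocated counts with demand, and nudges each
lambda_c up when its class is under-allocated and down when over-allocated,
with multiplicative step damping when deviations start oscillating.  At the
(near-)fixed point, cells are filled from the highest suitability downwards
for every class while classes compete through their lambdas — suitability is
balanced against demand.

Forbidden destinations enter the argmax as minus infinity, so no lambda can
resurrect an illegal transition; cells whose rules allow only persistence
are pre-assigned and removed from competition.  Ties break deterministically
(lowest class id, then row-major cell order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .raster_io import LULCMap
from .scenario import DemandSchedule, TransitionMatrix
from .suitability import SuitabilityModel, SuitabilityStack, project_step

__all__ = ["AllocationResult", "InfeasibleDemandError", "clues_allocate", "run_forecast"]


class InfeasibleDemandError(ValueError):
    """Demand cannot be met under the transition rules."""


@dataclass
class AllocationResult:
    """Outcome of one allocation step."""

    map: LULCMap
    iterations_used: int
    deviations: pd.Series  # allocated - demanded, cells, per class
    converged: bool
    lambdas: pd.Series
    tolerance: float

    @property
    def max_abs_deviation(self) -> float:
        return float(self.deviations.abs().max())


def _integerise_demand(demand: pd.Series, total: int) -> np.ndarray:
    """Round demand to integers that sum exactly to ``total`` (largest remainder)."""
    vals = demand.to_numpy(dtype=float)
    if (vals < -1e-9).any():
        raise ValueError("demand must be non-negative")
    if abs(vals.sum() - total) > 0.5 + 1e-6:
        raise ValueError(
            f"demand sums to {vals.sum():.1f} but there are {total} dynamic cells")
    base = np.floor(vals).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(vals - base), kind="stable")
        base[order[:short]] += 1
    elif short < 0:
        order = np.argsort(vals - base, kind="stable")
        base[order[:(-short)]] -= 1
    return base


def clues_allocate(
    suitability: SuitabilityStack,
    current: LULCMap,
    demand: Mapping[int, float] | pd.Series,
    rules: TransitionMatrix,
    *,
    tolerance: float | None = None,
    max_iter: int = 1000,
    step: float = 0.5,
    damping: float = 0.9,
) -> AllocationResult:
    """Allocate every dynamic cell to one class, meeting demand under rules.

    ``demand`` gives target cell counts per modelled class and must sum to
    the number of dynamic cells.  Default tolerance is
    ``max(1, 0.05% of dynamic cells)``.  Returns the assignment with the
    smallest maximum deviation seen, flagged converged when that deviation is
    within tolerance.  Static cells are returned unchanged.
    """
    ids = list(suitability.class_ids)
    suitability.check_simplex()
    current.grid.require_aligned(suitability.grid, what="suitability stack")
    dyn = current.dynamic_mask() & suitability.valid_mask
    rows, cols = np.nonzero(dyn)
    n_dyn = len(rows)
    if n_dyn == 0:
        raise ValueError("no dynamic cells to allocate")
    if tolerance is None:
        tolerance = max(1.0, 0.0005 * n_dyn)

    demand = pd.Series(demand, dtype=float).reindex(ids)
    if demand.isna().any():
        raise ValueError("demand must cover every modelled class")
    target = _integerise_demand(demand, n_dyn)

    S = suitability.probs[:, rows, cols].T.copy()  # (n_dyn, K)
    cur_cls = current.codes[rows, cols]
    rule = rules.matrix.reindex(index=ids, columns=ids)
    if rule.isna().to_numpy().any():
        raise ValueError("transition matrix does not cover the modelled classes")
    rule_arr = rule.to_numpy(dtype=bool)
    id_pos = {cid: k for k, cid in enumerate(ids)}
    cur_pos = np.array([id_pos[c] for c in cur_cls])
    A = rule_arr[cur_pos]  # (n_dyn, K) allowed destinations
    if not A.any(axis=1).all():
        raise InfeasibleDemandError("some cells have no allowed destination class")

    # Pre-assign cells whose rules allow persistence only.
    single = A.sum(axis=1) == 1
    pre_counts = np.zeros(len(ids), dtype=int)
    if single.any():
        dest = np.argmax(A[single], axis=1)
        pre_counts = np.bincount(dest, minlength=len(ids))
    free = ~single
    residual = target - pre_counts
    deficit = [ids[k] for k in range(len(ids)) if residual[k] < 0]
    if deficit:
        raise InfeasibleDemandError(
            f"demand below the count of rule-locked cells for classes {deficit}")
    # Per-class capacity: cells allowed to become the class.
    capacity = A[free].sum(axis=0) if free.any() else np.zeros(len(ids), int)
    short = [ids[k] for k in range(len(ids)) if residual[k] > capacity[k]]
    if short:
        raise InfeasibleDemandError(
            f"demanded count exceeds cells allowed to convert for classes {short}")

    Sf = S[free]
    Sf[~A[free]] = -np.inf
    lam = np.zeros(len(ids))
    best: tuple[float, np.ndarray, np.ndarray, int] | None = None
    prev_dev = None
    st = step
    assign = np.empty(free.sum(), dtype=int)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        assign = np.argmax(Sf + lam, axis=1)  # ties: lowest class id
        counts = np.bincount(assign, minlength=len(ids)) + pre_counts
        dev = counts - target
        maxdev = float(np.max(np.abs(dev)))
        if best is None or maxdev < best[0]:
            best = (maxdev, assign.copy(), dev.copy(), it)
        if maxdev <= tolerance:
            converged = True
            break
        if prev_dev is not None and np.any((dev * prev_dev) < 0) and \
                np.max(np.abs(dev)) >= np.max(np.abs(prev_dev)):
            st *= damping
        lam = lam + st * (target - counts) / n_dyn
        prev_dev = dev
    maxdev, assign, dev, best_it = best
    converged = converged or maxdev <= tolerance

    codes = current.codes.copy()
    flat_free = np.nonzero(free)[0]
    ids_arr = np.array(ids)
    codes[rows[flat_free], cols[flat_free]] = ids_arr[assign]
    if single.any():
        flat_single = np.nonzero(single)[0]
        codes[rows[flat_single], cols[flat_single]] = ids_arr[
            np.argmax(A[single], axis=1)]
    out = LULCMap(current.grid, codes, current.codebook, current.valid_mask.copy())
    return AllocationResult(
        map=out,
        iterations_used=it,
        deviations=pd.Series(dev, index=ids, dtype=float),
        converged=bool(converged),
        lambdas=pd.Series(lam, index=ids),
        tolerance=float(tolerance),
    )


def run_forecast(
    model: SuitabilityModel,
    initial_maps: Sequence[LULCMap],
    predictors,
    schedule: DemandSchedule,
    rules_per_step: Sequence[TransitionMatrix],
    n_steps: int | None = None,
    *,
    postprocess: Callable[[LULCMap], LULCMap] | None = None,
    tolerance: float | None = None,
    max_iter: int = 1000,
) -> list[AllocationResult]:
    """Iterate project -> allocate -> post-process over the forecast horizon.

    Each step's allocated (and optionally post-processed) map joins the
    history window used to project the next step.
    """
    future = schedule.future_labels
    if n_steps is None:
        n_steps = len(future)
    if n_steps > len(future):
        raise ValueError("schedule does not cover the requested horizon")
    if len(rules_per_step) < n_steps:
        raise ValueError("need one transition matrix per forecast step")
    if len(initial_maps) < 3:
        raise ValueError("need at least three initial maps")
    history = list(initial_maps[-3:])
    results: list[AllocationResult] = []
    for i in range(n_steps):
        stack = project_step(model, history, predictors)
        res = clues_allocate(
            stack, history[-1], schedule.step(future[i]), rules_per_step[i],
            tolerance=tolerance, max_iter=max_iter,
        )
        out_map = postprocess(res.map) if postprocess else res.map
        res.map = out_map
        results.append(res)
        history = history[1:] + [out_map]
    return results
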