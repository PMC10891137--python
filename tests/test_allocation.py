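"""CLUE-S allocation: fixed points, oracles, legality and conservation."""

import itertools

import numpy as np
import pandas as pd
import pytest

import lulcsim as L


def _stack_from(S, grid, ids):
    """SuitabilityStack from an (n_cells, K) matrix on a filled grid."""
    K = len(ids)
    probs = S.T.reshape(K, *grid.shape).astype(float)
    return L.SuitabilityStack(grid, tuple(ids), probs)


def _tiny_instance(map_factory, S, cur, ids=(1, 2)):
    cb = L.synthetic_codebook(max(ids))
    n = len(cur)
    m = map_factory(np.asarray(cur).reshape(1, n), cb)
    stack = _stack_from(np.asarray(S, float), m.grid, ids)
    return m, stack, cb


def _brute_force(S, demand, allowed_fn=None):
    """Best total suitability over all assignments meeting demand exactly."""
    n, K = S.shape
    best_val, best = -np.inf, None
    for assign in itertools.product(range(K), repeat=n):
        if list(np.bincount(assign, minlength=K)) != list(demand):
            continue
        if allowed_fn and not all(allowed_fn(i, k) for i, k in enumerate(assign)):
            continue
        v = S[np.arange(n), assign].sum()
        if v > best_val:
            best_val, best = v, assign
    return best_val, best


class TestCluesAllocate:
    def test_fixed_point_when_demand_matches_argmax(self, map_factory):
        S = np.array([[0.9, 0.1], [0.8, 0.2], [0.4, 0.6], [0.3, 0.7]])
        m, stack, cb = _tiny_instance(map_factory, S, [1, 1, 2, 2])
        demand = pd.Series({1: 2, 2: 2})
        res = L.clues_allocate(stack, m, demand, L.all_permissive_matrix(cb),
                               tolerance=0.0)
        assert res.converged
        assert res.iterations_used == 1
        assert (res.lambdas == 0).all()
        assert res.max_abs_deviation == 0

    def test_four_cell_worked_example(self, map_factory):
        # highest-suitability cells are filled first for each class
        S = np.array([[0.9, 0.1], [0.8, 0.2], [0.4, 0.6], [0.3, 0.7]])
        m, stack, cb = _tiny_instance(map_factory, S, [2, 2, 1, 1])
        res = L.clues_allocate(stack, m, pd.Series({1: 2, 2: 2}),
                               L.all_permissive_matrix(cb), tolerance=0.0)
        assert list(res.map.codes.ravel()) == [1, 1, 2, 2]

    def test_persistence_locked_cell_respected(self, map_factory):
        # cell 3's current class (1) may only persist: diagonal-only row;
        # the remaining demand is reallocated among cells 1, 2, 4
        S = np.array([[0.9, 0.1], [0.8, 0.2], [0.4, 0.6], [0.3, 0.7]])
        m, stack, cb = _tiny_instance(map_factory, S, [2, 2, 1, 2])
        rules = pd.DataFrame([[1, 0], [1, 1]], index=[1, 2], columns=[1, 2])
        tm = L.TransitionMatrix(rules, "p")
        res = L.clues_allocate(stack, m, pd.Series({1: 2, 2: 2}), tm,
                               tolerance=0.0)
        assert res.converged
        got = list(res.map.codes.ravel())
        assert got[2] == 1  # rule-locked cell keeps its class
        assert got.count(1) == 2 and got.count(2) == 2
        # matches constrained enumeration (cell index 2 can only be class 1)
        best_val, _ = _brute_force(S, [2, 2],
                                   lambda i, k: k == 0 if i == 2 else True)
        got_val = S[np.arange(4), np.array(got) - 1].sum()
        assert got_val == pytest.approx(best_val)

    def test_matches_exhaustive_oracle_on_random_instances(self, map_factory):
        rng = np.random.default_rng(0)
        grid = None
        for _ in range(12):
            n, K = 8, 3
            S = rng.dirichlet(np.ones(K), size=n)
            cur = rng.integers(1, K + 1, size=n)
            demand = rng.multinomial(n, np.ones(K) / K)
            cb = L.synthetic_codebook(K)
            m = L.LULCMap(L.Grid(2, 4, 100.0, 0.0, 1000.0, "EPSG:2056"),
                          cur.reshape(2, 4), cb)
            stack = _stack_from(S, m.grid, (1, 2, 3))
            res = L.clues_allocate(stack, m, pd.Series(demand, index=[1, 2, 3]),
                                   L.all_permissive_matrix(cb),
                                   tolerance=0.0, max_iter=5000)
            assert res.converged
            got = res.map.codes.ravel()
            counts = [int((got == c).sum()) for c in (1, 2, 3)]
            assert counts == list(demand)
            best_val, _ = _brute_force(S, demand)
            got_val = S[np.arange(n), got - 1].sum()
            assert got_val == pytest.approx(best_val, abs=1e-9)

    def test_infeasible_demand_names_class(self, map_factory):
        # both cells are rule-locked to class 1, yet class 1's demand is 0:
        # the error must name the offending class
        S = np.array([[0.5, 0.5], [0.5, 0.5]])
        m, stack, cb = _tiny_instance(map_factory, S, [1, 1])
        rules = pd.DataFrame([[1, 0], [0, 1]], index=[1, 2], columns=[1, 2])
        tm = L.TransitionMatrix(rules, "p")
        with pytest.raises(L.InfeasibleDemandError, match=r"\[1\]"):
            L.clues_allocate(stack, m, pd.Series({1: 0, 2: 2}), tm)

    def test_demand_exceeding_convertible_cells_names_class(self, map_factory):
        # no cell is allowed to become class 3, yet one is demanded
        S = np.full((3, 3), 1 / 3)
        cb = L.synthetic_codebook(3)
        m = L.LULCMap(L.Grid(1, 3, 100.0, 0.0, 1000.0, "EPSG:2056"),
                      np.array([[1, 1, 1]]), cb)
        stack = _stack_from(S, m.grid, (1, 2, 3))
        rules = pd.DataFrame([[1, 1, 0], [0, 1, 1], [1, 0, 1]],
                             index=[1, 2, 3], columns=[1, 2, 3])
        tm = L.TransitionMatrix(rules, "p")
        with pytest.raises(L.InfeasibleDemandError, match=r"\[3\]"):
            L.clues_allocate(stack, m, pd.Series({1: 0, 2: 2, 3: 1}), tm)

    def test_non_simplex_suitability_rejected(self, map_factory):
        S = np.array([[0.9, 0.9], [0.1, 0.1]])
        m, stack, cb = _tiny_instance(map_factory, S, [1, 2])
        with pytest.raises(ValueError, match="sum to 1"):
            L.clues_allocate(stack, m, pd.Series({1: 1, 2: 1}),
                             L.all_permissive_matrix(cb))

    def test_demand_must_cover_dynamic_cells(self, map_factory):
        S = np.array([[0.9, 0.1], [0.2, 0.8]])
        m, stack, cb = _tiny_instance(map_factory, S, [1, 2])
        with pytest.raises(ValueError, match="dynamic cells"):
            L.clues_allocate(stack, m, pd.Series({1: 5, 2: 5}),
                             L.all_permissive_matrix(cb))


@pytest.fixture(scope="module")
def forecast(landscape, trained_pipeline):
    maps, stack, _ = landscape
    _, model, _ = trained_pipeline
    labels = [f"t{i}" for i in range(4)]
    schedule = L.extrapolate_demand(L.observed_counts(maps, labels), 3)
    rules = [L.all_permissive_matrix(maps[0].codebook)] * 3
    results = L.run_forecast(model, maps, stack, schedule, rules, 3)
    return maps, schedule, results


class TestRunForecast:

    def test_three_steps_produced_and_converged(self, forecast):
        _, _, results = forecast
        assert len(results) == 3
        assert all(r.converged for r in results)

    def test_conservation_and_static_cells(self, forecast):
        maps, _, results = forecast
        n_dyn = maps[-1].dynamic_mask().sum()
        static = np.isin(maps[0].codes, maps[0].codebook.static_ids)
        for r in results:
            assert r.map.dynamic_mask().sum() == n_dyn
            assert np.array_equal(r.map.codes[static], maps[0].codes[static])

    def test_every_transition_legal(self, landscape, trained_pipeline):
        """With restrictive rules, no realised transition violates them."""
        maps, stack, _ = landscape
        _, model, _ = trained_pipeline
        cb = maps[0].codebook
        ids = list(cb.modelled_ids)
        # near-diagonal rules: each class may persist or move to the next id
        df = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
        np.fill_diagonal(df.values, 1)
        for i in range(len(ids) - 1):
            df.iloc[i, i + 1] = 1
        df.iloc[-1, 0] = 1
        tm = L.TransitionMatrix(df, "ring")
        labels = [f"t{i}" for i in range(4)]
        schedule = L.extrapolate_demand(L.observed_counts(maps, labels), 2)
        results = L.run_forecast(model, maps, stack, schedule, [tm, tm], 2)
        prev = maps[-1]
        for r in results:
            dyn = prev.dynamic_mask()
            src = prev.codes[dyn]
            dst = r.map.codes[dyn]
            for s, d in zip(*np.unique(np.stack([src, dst]), axis=1)):
                assert L.allowed(tm, int(s), int(d))
            prev = r.map

    def test_self_consistency_with_current_demand(self, landscape, trained_pipeline):
        """Demand fixed at current prevalences is met within tolerance."""
        maps, stack, _ = landscape
        _, model, _ = trained_pipeline
        cur = L.observed_prevalence(maps[-1])
        obs = pd.DataFrame({"t2": cur, "t3": cur})
        schedule = L.extrapolate_demand(obs, 2)
        rules = [L.all_permissive_matrix(maps[0].codebook)] * 2
        results = L.run_forecast(model, maps, stack, schedule, rules, 2)
        for r in results:
            assert r.max_abs_deviation <= r.tolerance

    def test_rerun_identical(self, landscape, trained_pipeline):
        maps, stack, _ = landscape
        _, model, _ = trained_pipeline
        labels = [f"t{i}" for i in range(4)]
        schedule = L.extrapolate_demand(L.observed_counts(maps, labels), 2)
        rules = [L.all_permissive_matrix(maps[0].codebook)] * 2
        r1 = L.run_forecast(model, maps, stack, schedule, rules, 2)
        r2 = L.run_forecast(model, maps, stack, schedule, rules, 2)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.map.codes, b.map.codes)
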