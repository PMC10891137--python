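"""Demand extrapolation, policy overrides and transition rules."""

import numpy as np
import pandas as pd
import pytest

import lulcsim as L


class TestObservedPrevalence:
    def test_uniform_map(self, map_factory):
        cb = L.synthetic_codebook(7)
        m = map_factory(np.full((10, 10), 6), cb)
        counts = L.observed_prevalence(m)
        assert counts[6] == 100
        assert counts.drop(6).sum() == 0

    def test_counts_sum_to_dynamic_total(self, landscape):
        maps, _, _ = landscape
        for m in maps:
            counts = L.observed_prevalence(m)
            assert counts.sum() == m.dynamic_mask().sum()

    def test_planted_counts_recovered(self, map_factory, tiny_codebook):
        codes = np.array([[1, 1, 2], [3, 3, 3]])
        m = map_factory(codes, tiny_codebook)
        counts = L.observed_prevalence(m)
        assert dict(counts) == {1: 2, 2: 1, 3: 3}


class TestExtrapolateDemand:
    def test_constant_history_stays_constant(self):
        obs = pd.DataFrame({f"t{i}": {1: 100.0, 2: 200.0} for i in range(4)})
        sched = L.extrapolate_demand(obs, 3)
        for lab in sched.future_labels:
            assert sched.step(lab)[1] == pytest.approx(100.0)
            assert sched.step(lab)[2] == pytest.approx(200.0)

    def test_slope_through_last_two_anchors(self):
        obs = pd.DataFrame({
            "t0": {1: 90.0, 2: 210.0}, "t1": {1: 95.0, 2: 205.0},
            "t2": {1: 100.0, 2: 200.0}, "t3": {1: 120.0, 2: 180.0},
        })
        sched = L.extrapolate_demand(obs, 3)
        assert [sched.step(l)[1] for l in sched.future_labels] == [140.0, 160.0, 180.0]
        assert [sched.step(l)[2] for l in sched.future_labels] == [160.0, 140.0, 120.0]

    def test_negative_projection_clamped_and_redistributed(self):
        obs = pd.DataFrame({"t0": {1: 30.0, 2: 70.0}, "t1": {1: 10.0, 2: 90.0}})
        sched = L.extrapolate_demand(obs, 2)
        second = sched.step(sched.future_labels[1])
        assert second[1] == 0.0  # raw -30 clamped
        assert second.sum() == pytest.approx(100.0)

    def test_single_observed_step_rejected(self):
        obs = pd.DataFrame({"t0": {1: 50.0, 2: 50.0}})
        with pytest.raises(ValueError, match="two observed"):
            L.extrapolate_demand(obs, 1)


class TestPolicyOverrides:
    def _schedule(self):
        obs = pd.DataFrame({"t0": {1: 100.0, 2: 400.0, 3: 500.0},
                            "t1": {1: 120.0, 2: 420.0, 3: 460.0}})
        return L.extrapolate_demand(obs, 3)

    def test_freeze_pins_later_steps(self):
        sched = self._schedule()
        out = L.apply_policy_overrides(
            sched, [L.PolicyOverride((1,), "freeze", start_step=1)])
        f1_value = sched.step("f1")[1]
        for lab in ("f2", "f3"):
            assert out.step(lab)[1] == pytest.approx(f1_value)
            assert out.step(lab).sum() == pytest.approx(sched.dynamic_total)

    def test_no_overrides_identity(self):
        sched = self._schedule()
        out = L.apply_policy_overrides(sched, [])
        pd.testing.assert_frame_equal(out.counts, sched.counts)

    def test_freeze_surplus_redistributed_proportionally(self):
        sched = self._schedule()
        out = L.apply_policy_overrides(
            sched, [L.PolicyOverride((1,), "freeze", start_step=0)])
        base = sched.counts[sched.counts.columns[sched.n_observed - 1]]
        for lab in out.future_labels:
            col = out.step(lab)
            assert col[1] == pytest.approx(base[1])
            assert col.sum() == pytest.approx(sched.dynamic_total)
            # unfrozen classes keep their relative proportions
            raw = sched.step(lab)
            assert col[2] / col[3] == pytest.approx(raw[2] / raw[3])

    def test_replacement_only_caps_growth(self):
        sched = self._schedule()
        out = L.apply_policy_overrides(
            sched, [L.PolicyOverride((1,), "replacement-only", start_step=0)])
        cap = sched.step("f1")[1]
        for lab in out.future_labels:
            assert out.step(lab)[1] <= cap + 1e-9

    def test_overrides_idempotent(self):
        sched = self._schedule()
        ov = [L.PolicyOverride((1,), "freeze", start_step=1)]
        once = L.apply_policy_overrides(sched, ov)
        twice = L.apply_policy_overrides(once, ov)
        pd.testing.assert_frame_equal(once.counts, twice.counts)


class TestTransitionMatrixIO:
    def test_csv_round_trip(self, tmp_path, tiny_codebook):
        tm = L.all_permissive_matrix(tiny_codebook, period="p1")
        p = tmp_path / "tm.csv"
        L.save_transition_matrix(tm, p)
        back = L.load_transition_matrix(p, "p1", tiny_codebook)
        pd.testing.assert_frame_equal(back.matrix, tm.matrix)

    def test_non_binary_entries_rejected(self):
        df = pd.DataFrame([[1, 2], [0, 1]], index=[1, 2], columns=[1, 2])
        with pytest.raises(ValueError, match="0 or 1"):
            L.TransitionMatrix(df, "p1")

    def test_zero_diagonal_rejected(self):
        df = pd.DataFrame([[0, 1], [1, 1]], index=[1, 2], columns=[1, 2])
        with pytest.raises(ValueError, match="diagonal"):
            L.TransitionMatrix(df, "p1")

    def test_label_mismatch_with_codebook_rejected(self, tmp_path):
        cb5 = L.synthetic_codebook(5)
        tm = L.all_permissive_matrix(cb5)
        p = tmp_path / "tm.csv"
        L.save_transition_matrix(tm, p)
        with pytest.raises(ValueError, match="codebook"):
            L.load_transition_matrix(p, "p1", L.synthetic_codebook(3))


class TestBaselineScenarioRules:
    """Every narrative rule of the baseline scenario, as matrix assertions.

    Class ids: 1 Industry, 2 Building, 3 Special urban, 4 Urban green,
    5 Horticulture, 6 Arable, 7 Grassland, 8 Alpine grassland, 9 Forest,
    10 Brush, 11 Trees, 12 Unproductive vegetation, 13 Bare land, 14 Glacier.
    """

    @pytest.fixture()
    def matrices(self):
        return L.swiss_transition_matrices()

    URBAN = (1, 2, 3, 4)

    def test_urban_land_never_taken_over(self, matrices):
        for tm in matrices:
            for u in self.URBAN:
                row = tm.matrix.loc[u]
                assert row[u] == 1
                assert row.drop(u).sum() == 0

    def test_urban_expansion_prevented_in_second_period(self, matrices):
        _, p2 = matrices
        for u in self.URBAN:
            col = p2.matrix[u]
            assert col.drop(u).sum() == 0

    def test_arable_grassland_urbanisable_first_step_only(self, matrices):
        p1, p2 = matrices
        for src in (6, 7):
            for u in self.URBAN:
                assert L.allowed(p1, src, u)
                assert not L.allowed(p2, src, u)

    def test_arable_grassland_interconvert_and_clear_vegetation(self, matrices):
        for tm in matrices:
            assert L.allowed(tm, 6, 7) and L.allowed(tm, 7, 6)
            for src in (9, 10, 12):
                assert L.allowed(tm, src, 6) and L.allowed(tm, src, 7)

    def test_alpine_grassland_clears_forested_classes(self, matrices):
        for tm in matrices:
            for src in (9, 10, 11, 12):
                assert L.allowed(tm, src, 8)

    def test_succession_is_forestward_only(self, matrices):
        for tm in matrices:
            assert L.allowed(tm, 8, 10) and L.allowed(tm, 8, 11)
            assert L.allowed(tm, 10, 9) and L.allowed(tm, 11, 9)
            assert not L.allowed(tm, 9, 10) and not L.allowed(tm, 9, 11)

    def test_forest_expansion_targets(self, matrices):
        for tm in matrices:
            assert L.allowed(tm, 8, 9)  # pasture abandonment
            for src in (10, 11, 12):
                assert L.allowed(tm, src, 9)
            for src in (*self.URBAN, 5, 6, 7):  # built and cultivated land
                assert not L.allowed(tm, src, 9)

    def test_ambiguous_vegetation_classes_interconvert(self, matrices):
        for tm in matrices:
            for a in (10, 11, 12):
                for b in (10, 11, 12):
                    assert L.allowed(tm, a, b)

    def test_trees_only_forested_class_onto_grassland(self, matrices):
        for tm in matrices:
            assert L.allowed(tm, 7, 11)
            assert not L.allowed(tm, 7, 9) and not L.allowed(tm, 7, 10)

    def test_horticulture_sources(self, matrices):
        for tm in matrices:
            for src in (6, 7, 11, 12):
                assert L.allowed(tm, src, 5)

    def test_glacier_retreat_sequence_one_way(self, matrices):
        for tm in matrices:
            assert L.allowed(tm, 14, 13) and L.allowed(tm, 13, 12)
            assert not L.allowed(tm, 13, 14) and not L.allowed(tm, 12, 13)
            # only Unproductive vegetation's own succession targets follow
            assert tm.matrix[13].drop([13, 14]).sum() == 0  # only Glacier -> Bare land
            assert tm.matrix[14].drop(14).sum() == 0        # nothing becomes Glacier
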