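import numpy as np
import pytest

import thermsol as ts
from thermsol import tpp2d as t2
from thermsol.tpp2d import FoldChangeData, WindowResults


@pytest.fixture(scope="module")
def fcd(small_2d_sim_module):
    cfg, sim = small_2d_sim_module
    return t2.preprocess_2dtpp(sim.quant, sim.samples)


@pytest.fixture(scope="module")
def small_2d_sim_module():
    cfg = ts.SimConfig.tpp2d(
        n_proteins=40, noise_cv=0.05, seed=42,
        fractions={"null": 0.7, "stabilized": 0.2, "destabilized": 0.1},
    )
    return cfg, ts.simulate_2dtpp(cfg)


class TestPreprocessing:
    def test_equal_treated_and_vehicle_intensities_give_unit_fold_changes(self):
        cfg = ts.SimConfig.tpp2d(n_proteins=8, noise_cv=0.0, seed=0,
                                 fractions={"null": 1.0})
        sim = ts.simulate_2dtpp(cfg)
        out = t2.preprocess_2dtpp(sim.quant, sim.samples)
        np.testing.assert_allclose(out.fc, 1.0, atol=1e-9)

    def test_channel_scaling_invariance(self, small_2d_sim_module):
        """Multiplying one TMT channel's intensities by 10 leaves the
        normalized fold changes unchanged."""
        _, sim = small_2d_sim_module
        ref = t2.preprocess_2dtpp(sim.quant, sim.samples)
        df = sim.quant.df.copy()
        victim = next(s.sample_id for s in sim.samples if s.concentration_mM > 0)
        df.loc[df["sample_id"] == victim, "value"] *= 10
        scaled = t2.preprocess_2dtpp(ts.QuantTable(df, "intensity"), sim.samples)
        np.testing.assert_allclose(scaled.fc, ref.fc, rtol=1e-9)

    def test_channel_log2_median_is_zero_after_normalization(self, fcd):
        treated = fcd.fc[:, :, :, 1:]
        for r in range(fcd.replicates.size):
            for t in range(fcd.temperatures.size):
                for c in range(treated.shape[3]):
                    med = np.median(np.log2(treated[:, r, t, c]))
                    assert med == pytest.approx(0.0, abs=1e-9)

    def test_vehicle_pinned_to_one(self, fcd):
        np.testing.assert_allclose(fcd.fc[:, :, :, 0], 1.0)


class TestWindowScores:
    def test_adjacent_pairs_give_n_minus_one_windows(self, fcd):
        wr = t2.window_scores(fcd)
        assert len(wr.window_temps) == fcd.temperatures.size - 1
        assert wr.F.shape == (len(fcd.proteins), fcd.temperatures.size - 1)

    def test_flat_data_scores_near_zero(self):
        cfg = ts.SimConfig.tpp2d(n_proteins=8, noise_cv=0.0, seed=0,
                                 fractions={"null": 1.0})
        sim = ts.simulate_2dtpp(cfg)
        out = t2.preprocess_2dtpp(sim.quant, sim.samples)
        wr = t2.window_scores(out)
        np.testing.assert_allclose(wr.F, 0.0, atol=1e-6)

    def test_window_statistic_is_median_over_replicates(self):
        comps = np.array([[[1.0], [3.0], [2.0]]])  # protein x rep x window
        F = np.nanmedian(comps, axis=1)
        assert F[0, 0] == 2.0


class TestCombinedScore:
    def _wr(self, F, phi):
        n_win = F.shape[1]
        shape = (F.shape[0], 1, n_win)
        return WindowResults(
            window_temps=[(40 + i, 41 + i) for i in range(n_win)],
            F=F, components=F[:, None, :], phi_extreme=phi,
            e=np.zeros(shape), converged=np.ones(shape, dtype=bool),
        )

    def test_sums_log_evidence_over_gated_windows(self):
        F = np.array([[np.e, np.e**2]])
        phi = np.array([[2.0, 2.0]])
        scores, direction = t2.combined_scores(self._wr(F, phi))
        assert scores[0] == pytest.approx(3.0)
        assert direction[0] == "stabilized"

    def test_fold_change_inside_gate_band_is_excluded(self):
        F = np.array([[np.e, np.e]])
        phi = np.array([[1.2, 2.0]])  # 1.2 lies inside (1/1.5, 1.5)
        scores, _ = t2.combined_scores(self._wr(F, phi))
        assert scores[0] == pytest.approx(1.0)

    def test_no_gated_windows_scores_zero_with_no_direction(self):
        F = np.array([[5.0, 5.0]])
        phi = np.array([[1.1, 0.9]])
        scores, direction = t2.combined_scores(self._wr(F, phi))
        assert scores[0] == 0.0 and direction[0] == "none"

    def test_windows_with_sub_unit_evidence_do_not_cancel_signal(self):
        F = np.array([[0.1, np.e**2]])  # ln(0.1) < 0 would cancel otherwise
        phi = np.array([[2.0, 2.0]])
        scores, _ = t2.combined_scores(self._wr(F, phi))
        assert scores[0] == pytest.approx(2.0)

    def test_dominant_extreme_decides_mixed_directions(self):
        F = np.array([[np.e, np.e]])
        phi = np.array([[0.4, 2.0]])  # |log2 0.4| > |log2 2|
        _, direction = t2.combined_scores(self._wr(F, phi))
        assert direction[0] == "destabilized"


class TestPermutation:
    def test_vehicle_values_bit_identical(self, fcd):
        perm = t2.permute_dataset(fcd, seed=3)
        assert np.array_equal(perm.fc[:, :, :, 0], fcd.fc[:, :, :, 0])

    def test_stratum_multisets_preserved(self, fcd):
        perm = t2.permute_dataset(fcd, seed=3)
        for t in range(fcd.temperatures.size):
            for q in np.unique(fcd.qupm):
                sel = fcd.qupm == q
                before = np.sort(fcd.fc[sel, :, t, 1:].ravel())
                after = np.sort(perm.fc[sel, :, t, 1:].ravel())
                np.testing.assert_array_equal(before, after)

    def test_same_seed_reproduces_permutation(self, fcd):
        a = t2.permute_dataset(fcd, seed=11)
        b = t2.permute_dataset(fcd, seed=11)
        np.testing.assert_array_equal(a.fc, b.fc)

    def test_values_actually_move(self, fcd):
        perm = t2.permute_dataset(fcd, seed=3)
        assert not np.allclose(perm.fc[:, :, :, 1:], fcd.fc[:, :, :, 1:])


@pytest.fixture(scope="module")
def result(small_2d_sim_module):
    _, sim = small_2d_sim_module
    return sim, ts.run_tpp2d(sim.quant, sim.samples,
                             ts.AnalysisConfig(n_permutations=20, seed=5))


class TestHitCallingAndAffinity:

    def test_spiked_effects_dominate_hit_list(self, result):
        sim, res = result
        truth = sim.truth.set_index("protein_id")
        assert len(res.hits) > 0
        called = truth.loc[res.hits["protein_id"], "effect_class"]
        assert (called != "null").mean() >= 0.9

    def test_directions_match_ground_truth(self, result):
        sim, res = result
        truth = sim.truth.set_index("protein_id")
        for _, row in res.hits.iterrows():
            assert row["direction"] == truth.loc[row["protein_id"], "effect_class"]

    def test_score_invariant_under_protein_reordering(self, small_2d_sim_module):
        _, sim = small_2d_sim_module
        fcd = t2.preprocess_2dtpp(sim.quant, sim.samples)
        wr = t2.window_scores(fcd)
        scores, _ = t2.combined_scores(wr)
        order = np.random.default_rng(1).permutation(len(fcd.proteins))
        shuffled = FoldChangeData(
            [fcd.proteins[i] for i in order], fcd.replicates, fcd.temperatures,
            fcd.concentrations_mM, fcd.fc[order], fcd.qupm[order],
        )
        scores2, _ = t2.combined_scores(t2.window_scores(shuffled))
        np.testing.assert_allclose(scores2, scores[order], rtol=1e-9)

    def test_effect_in_single_replicate_gets_no_affinity(self):
        """The gate fold change must appear in at least two replicates."""
        cfg = ts.SimConfig.tpp2d(n_proteins=6, noise_cv=0.0, seed=1,
                                 fractions={"null": 0.5, "stabilized": 0.5})
        sim = ts.simulate_2dtpp(cfg)
        fcd = t2.preprocess_2dtpp(sim.quant, sim.samples)
        # erase the effect in all but replicate 0
        fcd.fc[:, 1:, :, :] = 1.0
        wr = t2.window_scores(fcd)
        directions = np.array(["stabilized"] * 6, dtype=object)
        pec50 = t2.assign_pec50(fcd, wr, directions, np.ones(6, dtype=bool))
        assert np.isnan(pec50).all()

    def test_empty_input_yields_empty_hits(self):
        import pandas as pd
        scores = pd.DataFrame(columns=["protein_id", "F_comb", "direction", "fdr"])
        assert len(t2.call_hits(scores)) == 0
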