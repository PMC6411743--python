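import numpy as np
import pytest

import thermsol as ts
from thermsol import spp as sp
from thermsol.spp import SppData, glog2, glog2_inverse, lts_affine


class TestNormalization:
    def test_samples_identical_up_to_scale_are_calibrated_together(self, rng):
        ref = rng.lognormal(13, 1.5, size=200)
        matrix = np.column_stack([ref, 2.0 * ref, 0.5 * ref])
        out = sp.vsn_like_normalize(matrix)
        np.testing.assert_allclose(out[:, 1], out[:, 0], rtol=1e-6)
        np.testing.assert_allclose(out[:, 2], out[:, 0], rtol=1e-6)

    def test_glog_matches_log2_at_high_intensity(self):
        v = np.array([1e5, 1e6, 1e7])
        c = 50.0
        np.testing.assert_allclose(glog2(v, c), np.log2(v), rtol=0.01)
        np.testing.assert_allclose(glog2_inverse(glog2(v, c), c), v, rtol=1e-9)

    def test_lts_ignores_a_minority_of_changing_proteins(self, rng):
        ref = rng.lognormal(13, 1, size=300)
        y = 3.0 * ref + 100.0
        outliers = rng.choice(300, size=45, replace=False)
        y[outliers] *= rng.uniform(2, 5, size=45)
        a, b = lts_affine(y, ref)
        assert b == pytest.approx(3.0, rel=0.02)

    def test_vehicle_fold_change_is_one(self, small_spp_sim):
        _, sim = small_spp_sim
        spd = ts.normalize_spp(sim.quant, sim.samples)
        np.testing.assert_allclose(spd.fc[:, :, 0], 1.0)


class TestInsolubleClassification:
    def _spd(self, sds, np40_vehicle):
        n = len(sds)
        np40 = np.zeros((n, 1, 2))
        np40[:, 0, 0] = np40_vehicle
        np40[:, 0, 1] = np40_vehicle
        return SppData(
            proteins=[f"P{i}" for i in range(n)],
            replicates=np.array([1]),
            concentrations_mM=np.array([0.0, 1.0]),
            np40=np40,
            sds=np.array(sds, dtype=float)[:, None],
            fc=np.ones((n, 1, 2)),
            qupm=np.full(n, 2),
        )

    def test_fifty_percent_boundary_is_insoluble_inclusive(self):
        spd = self._spd([1.5, 1.49, 3.0], [1.0, 1.0, 1.2])
        flags = ts.classify_insoluble(spd)
        assert list(flags) == [True, False, True]  # 1.5, 1.49, 2.5

    def test_scale_invariance_of_the_flag(self, small_spp_sim):
        """Rescaling one replicate wholesale leaves the within-plex
        SDS/NP40 ratios, and hence every flag, exactly unchanged."""
        _, sim = small_spp_sim
        spd = ts.normalize_spp(sim.quant, sim.samples)
        ref_ratio = ts.sds_np40_ratio(spd)
        ref = ts.classify_insoluble(spd)
        df = sim.quant.df.copy()
        rep1 = {s.sample_id for s in sim.samples if s.replicate == 1}
        df.loc[df["sample_id"].isin(rep1), "value"] *= 37.0
        scaled = ts.normalize_spp(ts.QuantTable(df, "intensity"), sim.samples)
        np.testing.assert_allclose(ts.sds_np40_ratio(scaled), ref_ratio, rtol=1e-12)
        np.testing.assert_array_equal(ts.classify_insoluble(scaled), ref)

    def test_zero_np40_vehicle_flags_infinite_ratio(self):
        spd = self._spd([2.0], [0.0])
        ratio = ts.sds_np40_ratio(spd)
        assert np.isposinf(ratio[0])
        assert ts.classify_insoluble(spd)[0]


class TestSolubilityScores:
    def test_flat_profile_scores_zero(self):
        cfg = ts.SimConfig.spp(n_proteins=10, noise_cv=0.0, seed=2,
                               fractions={"null": 1.0})
        sim = ts.simulate_spp(cfg)
        spd = ts.normalize_spp(sim.quant, sim.samples)
        F, _, _, trigger = sp.spp_scores(spd)
        assert not trigger.any()
        np.testing.assert_allclose(F, 0.0)

    def test_noise_free_release_recovers_affinity(self):
        """With a majority-unchanged proteome (the calibration assumption)
        noise-free release profiles refit EC50 essentially exactly."""
        cfg = ts.SimConfig.spp(n_proteins=40, noise_cv=0.0, seed=3,
                               fractions={"null": 0.6, "solubilized": 0.4},
                               insoluble_fraction_range=(0.6, 0.6),
                               release_range=(1.0, 1.0),
                               pec50_range=(3.0, 3.0))
        sim = ts.simulate_spp(cfg)
        spd = ts.normalize_spp(sim.quant, sim.samples)
        F, e, _, trigger = sp.spp_scores(spd)
        truth = sim.truth.set_index("protein_id")
        sol = np.array([truth.loc[p, "effect_class"] == "solubilized"
                        for p in spd.proteins])
        assert trigger[sol].all()
        assert (F[sol] > 1e3).all()
        np.testing.assert_allclose(-e[sol], 3.0, atol=0.05)

    def test_sub_gate_profile_is_not_a_candidate(self):
        """A clear dose trend below the 1.5-fold gate never enters fitting."""
        cfg = ts.SimConfig.spp(n_proteins=10, noise_cv=0.0, seed=4,
                               fractions={"solubilized": 1.0},
                               insoluble_fraction_range=(0.2, 0.2),
                               release_range=(1.0, 1.0))  # max fc = 1.25
        sim = ts.simulate_spp(cfg)
        spd = ts.normalize_spp(sim.quant, sim.samples)
        _, _, extreme, trigger = sp.spp_scores(spd)
        assert (extreme < 1.5).all()
        assert not trigger.any()


class TestSppPermutation:
    def test_qupm_stratum_multisets_preserved(self, small_spp_sim):
        _, sim = small_spp_sim
        spd = ts.normalize_spp(sim.quant, sim.samples)
        perm = ts.permute_spp(spd, seed=9)
        for q in np.unique(spd.qupm):
            sel = spd.qupm == q
            np.testing.assert_array_equal(
                np.sort(spd.fc[sel, :, 1:].ravel()),
                np.sort(perm.fc[sel, :, 1:].ravel()),
            )
        np.testing.assert_array_equal(perm.fc[:, :, 0], spd.fc[:, :, 0])


class TestHitCalling:
    def test_spiked_proteins_recovered_with_direction(self, small_spp_sim):
        _, sim = small_spp_sim
        res = ts.run_spp(sim.quant, sim.samples,
                         ts.AnalysisConfig(n_permutations=20, seed=1))
        m = res.profiles.set_index("protein_id").join(sim.truth.set_index("protein_id"))
        hits = m[m.hit]
        assert len(hits) > 0
        assert (hits.effect_class != "null").mean() >= 0.9
        sol = hits[hits.effect_class == "solubilized"]
        assert (sol.direction == "solubilized").all()

    def test_strong_fit_below_gate_is_not_a_hit(self):
        """Hit calling requires the median fold-change gate, not just a
        good model fit."""
        cfg = ts.SimConfig.spp(n_proteins=40, noise_cv=0.02, seed=6,
                               fractions={"null": 0.75, "solubilized": 0.25},
                               insoluble_fraction_range=(0.25, 0.25),
                               release_range=(1.0, 1.0))  # max fc = 1.33 < 1.5
        sim = ts.simulate_spp(cfg)
        res = ts.run_spp(sim.quant, sim.samples,
                         ts.AnalysisConfig(n_permutations=10, seed=2))
        assert len(res.hits) == 0

    def test_monotone_in_release_fraction(self):
        """Increasing the released share never removes a protein from the
        hit list (nested simulations, fixed seed)."""
        hits_by_release = []
        for release in (0.7, 0.85, 1.0):
            cfg = ts.SimConfig.spp(n_proteins=60, noise_cv=0.05, seed=13,
                                   fractions={"null": 0.8, "solubilized": 0.2},
                                   insoluble_fraction_range=(0.6, 0.6),
                                   release_range=(release, release))
            sim = ts.simulate_spp(cfg)
            res = ts.run_spp(sim.quant, sim.samples,
                             ts.AnalysisConfig(n_permutations=20, seed=3))
            hits_by_release.append(set(res.hits["protein_id"]))
        assert hits_by_release[0] <= hits_by_release[1] <= hits_by_release[2]
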