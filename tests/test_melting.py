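import numpy as np
import pytest

import thermsol as ts
from thermsol.melting import (
    MeltingProfile,
    comelt_distance,
    complex_comelt_test,
    delta_tm,
    fit_melting_curve,
    group_shift_test,
    max_fold_change_on_heating,
    melting_params_for_tm,
    plateau_sigmoid,
    solubility_corrected_curve,
    tm_from_params,
)

TEMPS = np.array(ts.TR_TEMPERATURES)


def _profile(tm, p=0.05, a=550.0, temps=TEMPS, pid="P1", cond="vehicle"):
    aa, bb, pp = melting_params_for_tm(tm, p, a)
    return MeltingProfile(pid, cond, temps, plateau_sigmoid(temps, aa, bb, pp))


class TestMeltingCurveFit:
    def test_noise_free_melting_point_recovered(self):
        fit = fit_melting_curve(_profile(50.0, p=0.05))
        assert fit.valid
        assert fit.tm == pytest.approx(50.0, abs=0.1)

    def test_flat_profile_has_no_melting_point(self):
        fit = fit_melting_curve(MeltingProfile("P1", "vehicle", TEMPS, np.ones(10)))
        assert fit.tm is None or fit.r2 < 0.8
        assert not fit.valid

    def test_standard_ten_temperature_gradient_accepted(self):
        fit = fit_melting_curve(_profile(52.0))
        assert fit.valid and fit.rss < 1e-10

    def test_tm_solves_half_denaturation(self):
        a, b, p = melting_params_for_tm(51.3, 0.2, 600.0)
        tm = tm_from_params(a, b, p)
        assert plateau_sigmoid(tm, a, b, p) == pytest.approx(0.5, abs=1e-9)

    def test_temperature_shift_equivariance(self):
        """Shifting the gradient by +c degC shifts the fitted Tm by +c
        (up to the curvature of the 1/T parameterization)."""
        base = fit_melting_curve(_profile(50.0)).tm
        for shift in (-2.0, 2.0):
            prof = _profile(50.0)
            shifted = MeltingProfile("P1", "vehicle", TEMPS + shift, prof.fraction)
            fit = fit_melting_curve(shifted)
            assert fit.tm == pytest.approx(base + shift, abs=0.15)

    def test_high_plateau_is_flagged_invalid(self):
        fit = fit_melting_curve(_profile(50.0, p=0.45))
        assert not fit.valid


class TestDeltaTm:
    def test_identical_curves_shift_zero(self):
        f = fit_melting_curve(_profile(50.0))
        assert delta_tm(f, f) == pytest.approx(0.0, abs=1e-9)

    def test_three_degree_stabilization(self):
        treated = fit_melting_curve(_profile(53.0))
        vehicle = fit_melting_curve(_profile(50.0))
        assert delta_tm(treated, vehicle) == pytest.approx(3.0, abs=0.2)

    def test_invalid_fit_gives_absent_shift(self):
        good = fit_melting_curve(_profile(50.0))
        bad = fit_melting_curve(MeltingProfile("P", "vehicle", TEMPS, np.ones(10)))
        assert delta_tm(good, bad) is None


class TestCoMeltDistance:
    def test_identical_profiles_at_zero(self):
        p = _profile(50.0)
        assert comelt_distance(p, p) == 0.0

    def test_uniform_offset_of_point_one_gives_one_hundredth(self):
        a = _profile(50.0)
        b = MeltingProfile("P2", "vehicle", TEMPS, a.fraction + 0.1)
        assert comelt_distance(a, b) == pytest.approx(0.01)

    def test_semimetric_properties(self, rng):
        profs = [
            MeltingProfile(f"P{i}", "vehicle", TEMPS, rng.uniform(0, 1, 10))
            for i in range(4)
        ]
        for a in profs:
            for b in profs:
                d_ab = comelt_distance(a, b)
                assert d_ab >= 0
                assert d_ab == comelt_distance(b, a)
                if a is b:
                    assert d_ab == 0

    def test_distinct_melting_points_exceed_proximity_cutoff(self):
        """Clearly separated melting points (5 degC) are not co-melting at
        the 0.02 cutoff, while identical-template pairs are."""
        a, b = _profile(50.0), _profile(55.0, pid="P2")
        assert comelt_distance(a, b) >= 0.02
        assert comelt_distance(a, _profile(50.0, pid="P3")) < 0.02

    def test_fewer_than_five_shared_temperatures_absent(self):
        a = _profile(50.0, temps=TEMPS[:4])
        b = _profile(50.0, temps=TEMPS[:4])
        assert comelt_distance(a, b) is None


@pytest.fixture(scope="module")
def background():
    gen = np.random.default_rng(5)
    return [
        _profile(gen.uniform(44, 62), p=gen.uniform(0, 0.2), pid=f"B{i}")
        for i in range(60)
    ]


class TestComplexComeltTest:

    def test_identical_subunits_reach_minimal_p(self, background):
        subunits = [_profile(50.0, pid=f"S{i}") for i in range(4)]
        res = complex_comelt_test(subunits, background, n_rand=999, seed=0)
        assert res.p_value <= 0.001
        assert res.proximity_pairs == res.n_pairs

    def test_background_complex_is_unremarkable(self, background):
        res = complex_comelt_test(background[:4], background, n_rand=999, seed=0)
        assert res.p_value > 0.05

    def test_same_seed_same_p(self, background):
        subunits = background[10:14]
        a = complex_comelt_test(subunits, background, n_rand=99, seed=3)
        b = complex_comelt_test(subunits, background, n_rand=99, seed=3)
        assert a.p_value == b.p_value

    def test_requires_three_subunits_and_large_background(self, background):
        with pytest.raises(ValueError, match="three"):
            complex_comelt_test(background[:2], background, n_rand=9, seed=0)
        with pytest.raises(ValueError, match="background"):
            complex_comelt_test(background[:5], background[:3], n_rand=9, seed=0)


class TestHeatingResponse:
    def test_maximum_fold_change_vs_reference(self):
        resp = max_fold_change_on_heating(
            [37.0, 42.0, 58.0, 66.0], [1.0, 1.3, 2.0, 0.4]
        )
        assert resp.max_fold_change == pytest.approx(2.0)
        assert resp.log2_max_fold_change == pytest.approx(1.0)
        assert resp.argmax_temperature == 58.0

    def test_monotone_decreasing_curve_has_negative_log2_response(self):
        resp = max_fold_change_on_heating(TEMPS, np.linspace(1.0, 0.2, 10))
        assert resp.max_fold_change < 1
        assert resp.log2_max_fold_change < 0

    def test_two_phase_protein_peaks_at_transition_temperature(self):
        """A protein leaving an insoluble assembly on heating peaks in
        soluble abundance at its transition temperature before melting."""
        T = TEMPS
        gain = 1 + 1.5 * np.exp(-((T - 58.0) ** 2) / 8.0)
        melt = plateau_sigmoid(T, *melting_params_for_tm(62.0, 0.0))
        values = gain * melt / (gain[0] * melt[0])
        resp = max_fold_change_on_heating(T, values)
        assert resp.argmax_temperature == pytest.approx(58.6)

    def test_missing_reference_is_an_error(self):
        with pytest.raises(ValueError, match="reference"):
            max_fold_change_on_heating([42.0, 50.0], [1.0, 1.0])


class TestSolubilityCorrection:
    def test_unit_fold_change_is_identity(self):
        prof, corrected = solubility_corrected_curve(
            "P1", "treated", TEMPS, np.linspace(2, 0.5, 10), 1.0
        )
        assert corrected
        np.testing.assert_allclose(prof.fraction[0], 1.0)

    def test_doubled_solubility_restores_vehicle_curve(self):
        vehicle = np.linspace(2, 0.5, 10)
        treated = 2.0 * vehicle
        prof, _ = solubility_corrected_curve("P1", "treated", TEMPS, treated, 2.0)
        np.testing.assert_allclose(prof.fraction, vehicle / vehicle[0], rtol=1e-12)

    def test_missing_value_returns_uncorrected_flagged(self):
        prof, corrected = solubility_corrected_curve(
            "P1", "treated", TEMPS, np.linspace(2, 0.5, 10), None
        )
        assert not corrected

    def test_zero_fold_change_is_an_error(self):
        with pytest.raises(ValueError):
            solubility_corrected_curve("P1", "treated", TEMPS, np.ones(10), 0.0)


class TestGroupShiftTest:
    def test_identical_paired_groups_have_no_signal(self):
        stat, p = group_shift_test([1, 2, 3], [1, 2, 3], paired=True)
        assert np.isnan(p)

    def test_clear_shift_is_detected(self, rng):
        a = rng.normal(0, 1, 50)
        b = a + 3.0
        _, p = group_shift_test(a, b, paired=True)
        assert p < 1e-3
        _, p2 = group_shift_test(a, b, paired=False)
        assert p2 < 1e-3

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            group_shift_test([], [1.0])


class TestTrPipeline:
    def test_treated_vehicle_shift_recovered(self, tr_sim_with_complexes):
        _, sim = tr_sim_with_complexes
        curves = ts.run_tpp_tr(sim.quant, sim.samples)
        m = curves.set_index("protein_id").join(sim.truth.set_index("protein_id"))
        got = m.dropna(subset=["delta_tm"])
        assert len(got) >= 0.8 * len(m)
        # renormalization at 37 degC allows a sub-degree systematic shift
        stab = got[got.effect_class == "stabilized"]
        assert (stab.delta_tm - stab.true_tm_shift).abs().median() < 1.0
        null = got[got.effect_class == "null"]
        assert null.delta_tm.abs().median() < 0.5
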