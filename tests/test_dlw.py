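"""Doubly labeled water kinetics chain."""

import numpy as np
import pytest

from paee.constants import DEFAULTS
from paee.dlw import (BaselineViolationError, DLWQualityWarning, DosingRecord,
                      InsufficientDataError, IsotopeSample,
                      NegativeProductionError, atom_fraction_to_delta,
                      delta_to_atom_fraction, dilution_spaces, dlw_week,
                      fit_elimination, labeled_water_molar_mass, rco2,
                      tee_from_rco2, tracer_moles)
from paee.simulate import NoiseConfig, render_isotopes


def make_samples(e0_d, e0_o, k_d, k_o, days=(1.0, 8.0, 15.0),
                 base_d=-55.0, base_o=-7.0):
    """Exact mono-exponential enrichment curves as delta-permil samples."""
    c = DEFAULTS
    bx_d = delta_to_atom_fraction(base_d, c.vsmow_2h_ratio)
    bx_o = delta_to_atom_fraction(base_o, c.vsmow_18o_ratio)
    out = [IsotopeSample(0.0, base_d, base_o)]
    for t in days:
        x_d = bx_d + e0_d * np.exp(-k_d * t)
        x_o = bx_o + e0_o * np.exp(-k_o * t)
        out.append(IsotopeSample(
            t, atom_fraction_to_delta(x_d, c.vsmow_2h_ratio),
            atom_fraction_to_delta(x_o, c.vsmow_18o_ratio)))
    return out


class TestTracerMoles:
    def test_pure_tracer_limit(self):
        # 100 atom% with natural abundance zeroed: moles = mass / molar mass
        c = DEFAULTS.override(vsmow_2h_ratio=0.0, vsmow_18o_ratio=0.0)
        dose = DosingRecord("p", mass_2h2o_g=20.0276, mass_h218o_g=20.0,
                            atom_pct_2h=100.0, atom_pct_18o=100.0)
        mol_2h, mol_18o = tracer_moles(dose, c)
        assert mol_2h == pytest.approx(
            20.0276 / labeled_water_molar_mass("2H", 1.0))
        assert mol_18o == pytest.approx(
            20.0 / labeled_water_molar_mass("18O", 1.0))

    def test_matches_mass_balance_oracle(self):
        # protocol dose for 40 kg predicted TBW: 4.8 g 2H2O at 99.8 atom%
        dose = DosingRecord("p", mass_2h2o_g=4.8, mass_h218o_g=100.0)
        mol_2h, mol_18o = tracer_moles(dose)
        a = 0.998
        m = 2 * (a * 2.0141017779 + (1 - a) * 1.0078250319) + 15.9994
        nat = DEFAULTS.natural_2h_fraction
        assert mol_2h == pytest.approx(4.8 / m * (a - nat), rel=1e-12)
        a18 = 0.10
        m18 = 2 * 1.00794 + a18 * 17.9991604 + (1 - a18) * 15.9949146221
        assert mol_18o == pytest.approx(
            100.0 / m18 * (a18 - DEFAULTS.natural_18o_fraction), rel=1e-12)

    def test_halving_mass_halves_moles(self):
        full = DosingRecord("p", mass_2h2o_g=4.8, mass_h218o_g=100.0)
        half = DosingRecord("p", mass_2h2o_g=2.4, mass_h218o_g=50.0)
        f = tracer_moles(full)
        h = tracer_moles(half)
        assert h[0] == pytest.approx(f[0] / 2)
        assert h[1] == pytest.approx(f[1] / 2)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            DosingRecord("p", mass_2h2o_g=0.0, mass_h218o_g=1.0)


class TestFitElimination:
    def test_noiseless_exponential_recovered_exactly(self):
        samples = make_samples(1.1e-4, 2.4e-4, k_d=0.10, k_o=0.12)
        k, e0 = fit_elimination(samples, "2H")
        assert k == pytest.approx(0.10, rel=1e-9)
        assert e0 == pytest.approx(1.1e-4, rel=1e-9)
        k, e0 = fit_elimination(samples, "18O")
        assert k == pytest.approx(0.12, rel=1e-9)
        assert e0 == pytest.approx(2.4e-4, rel=1e-9)

    def test_two_points_reduce_to_slope_formula(self):
        samples = make_samples(1.1e-4, 2.4e-4, 0.10, 0.12, days=(1.0, 15.0))
        k, _ = fit_elimination(samples, "2H")
        from paee.dlw import excess_series
        t, e = excess_series(samples, "2H")
        assert k == pytest.approx((np.log(e[0]) - np.log(e[1])) / (t[1] - t[0]))

    def test_window_restricts_the_fit(self):
        # different k before/after day 8; window isolates the early segment
        early = make_samples(1.1e-4, 2.4e-4, 0.10, 0.12, days=(1.0, 4.0, 8.0))
        k, _ = fit_elimination(early, "18O", window=(0.0, 8.0))
        assert k == pytest.approx(0.12, rel=1e-9)

    def test_noisy_fit_matches_grid_search_oracle(self, rng):
        true_k, true_e0 = 0.11, 1.05e-4
        times = np.array([1.0, 4.0, 8.0, 11.0, 15.0])
        log_e = np.log(true_e0) - true_k * times + rng.normal(0, 0.01, 5)
        c = DEFAULTS
        bx = delta_to_atom_fraction(-55.0, c.vsmow_2h_ratio)
        samples = [IsotopeSample(0.0, -55.0, -7.0)] + [
            IsotopeSample(t, atom_fraction_to_delta(bx + np.exp(le),
                                                    c.vsmow_2h_ratio), 100.0)
            for t, le in zip(times, log_e)]
        k_fit, e0_fit = fit_elimination(samples, "2H")
        # brute-force least squares over a (k, ln e0) grid
        ks = np.linspace(0.08, 0.14, 601)
        e0s = np.linspace(np.log(true_e0) - 0.1, np.log(true_e0) + 0.1, 601)
        K, E = np.meshgrid(ks, e0s)
        sse = ((log_e[None, None, :] - (E[..., None] - K[..., None]
                                        * times[None, None, :])) ** 2).sum(-1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert k_fit == pytest.approx(K[i, j], abs=1e-4)
        assert np.log(e0_fit) == pytest.approx(E[i, j], abs=1e-3)

    def test_enrichment_below_baseline_raises(self):
        samples = [IsotopeSample(0.0, -55.0, -7.0),
                   IsotopeSample(1.0, -60.0, 100.0),
                   IsotopeSample(8.0, -58.0, 50.0)]
        with pytest.raises(BaselineViolationError):
            fit_elimination(samples, "2H")

    def test_single_post_dose_point_insufficient(self):
        samples = make_samples(1e-4, 2e-4, 0.1, 0.12, days=(1.0,))
        with pytest.raises(InsufficientDataError):
            fit_elimination(samples, "2H")


class TestDilutionSpaces:
    def test_hand_arithmetic(self):
        # target N_d = 2082, N_o = 2014 -> TBW = mean(2000, 2000) = 2000
        dose = DosingRecord("p", mass_2h2o_g=4.8, mass_h218o_g=100.0)
        mol_2h, mol_18o = tracer_moles(dose)
        res = dilution_spaces(dose, mol_2h / 2082.0, mol_18o / 2014.0)
        assert res.n_d_mol == pytest.approx(2082.0)
        assert res.n_o_mol == pytest.approx(2014.0)
        assert res.tbw_mol == pytest.approx(2000.0, abs=0.01)
        assert res.nd_no_ratio == pytest.approx(1.0338, abs=1e-4)
        assert res.qc_ok

    def test_consistent_spaces_recover_tbw_exactly(self):
        dose = DosingRecord("p", mass_2h2o_g=4.8, mass_h218o_g=100.0)
        mol_2h, mol_18o = tracer_moles(dose)
        X = 2000.0
        res = dilution_spaces(dose, mol_2h / (1.041 * X), mol_18o / (1.007 * X))
        assert res.tbw_mol == pytest.approx(X, rel=1e-12)

    def test_ratio_outside_band_warns_but_returns(self):
        dose = DosingRecord("p", mass_2h2o_g=4.8, mass_h218o_g=100.0)
        mol_2h, mol_18o = tracer_moles(dose)
        with pytest.warns(DLWQualityWarning):
            res = dilution_spaces(dose, mol_2h / 2180.0, mol_18o / 2000.0)
        assert not res.qc_ok
        assert res.nd_no_ratio == pytest.approx(1.09)


class TestRco2AndTee:
    def test_hand_arithmetic(self):
        # 0.4554 * 2000 * (1.007*0.12 - 1.041*0.10) = 15.246... mol/day
        assert rco2(2000.0, 0.12, 0.10) == pytest.approx(15.2468, abs=1e-3)

    def test_null_production_boundary(self):
        k_d = 0.10
        k_o = 1.041 * k_d / 1.007
        assert rco2(2000.0, k_o, k_d) == pytest.approx(0.0, abs=1e-12)

    def test_swapped_rates_raise(self):
        with pytest.raises(NegativeProductionError):
            rco2(2000.0, 0.10, 0.12)

    def test_linear_in_tbw(self):
        assert rco2(4000.0, 0.12, 0.10) == pytest.approx(
            2 * rco2(2000.0, 0.12, 0.10))

    def test_tee_chained_hand_arithmetic(self):
        # rCO2 15.246 mol/d at RQ .85: VCO2 341.7 L/d, VO2 402.0 L/d
        tee = tee_from_rco2(15.246, rq=0.85)
        vco2 = 15.246 * 22.414
        vo2 = vco2 / 0.85
        assert vco2 == pytest.approx(341.72, abs=0.05)
        assert vo2 == pytest.approx(402.0, abs=0.1)
        assert tee == pytest.approx(
            (3.941 * vo2 + 1.106 * vco2) * 4.184e-3, rel=1e-12)

    def test_zero_production_zero_tee(self):
        assert tee_from_rco2(0.0) == 0.0

    def test_tee_decreasing_in_rq(self):
        tees = [tee_from_rco2(15.0, rq=q) for q in (0.7, 0.85, 1.0)]
        assert tees == sorted(tees, reverse=True)

    def test_rq_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="quotient"):
            tee_from_rco2(15.0, rq=1.2)


class TestDlwWeek:
    def test_zero_noise_round_trip_within_0p1pct(self, participant):
        p = participant
        tee = p.true_pal * p.bmr_mj_day
        samples, dose = render_isotopes(p, tee, tee, NoiseConfig.zero(), 3)
        for week in (1, 2):
            res = dlw_week(samples, dose, p.bmr_mj_day, week)
            assert res.tee_mj_day == pytest.approx(tee, rel=1e-3)
            assert res.tbw_mol == pytest.approx(p.tbw_mol, rel=1e-3)
            assert res.nd_no_ratio == pytest.approx(p.nd_no_ratio, rel=1e-6)
            assert res.k_o_perday > res.k_d_perday

    def test_identical_kinetics_identical_weeks(self):
        dose = DosingRecord("p", mass_2h2o_g=4.8, mass_h218o_g=100.0)
        samples = make_samples(1.1e-4, 2.5e-4, 0.10, 0.12)
        # duplicate each sampling day to mimic the protocol
        samples += make_samples(1.1e-4, 2.5e-4, 0.10, 0.12)[1:]
        r1 = dlw_week(samples, dose, 6.0, 1)
        r2 = dlw_week(samples, dose, 6.0, 2)
        assert r1.tee_mj_day == pytest.approx(r2.tee_mj_day, rel=1e-9)

    def test_pal_is_tee_over_bmr(self):
        dose = DosingRecord("p", mass_2h2o_g=4.8, mass_h218o_g=100.0)
        samples = make_samples(1.1e-4, 2.5e-4, 0.10, 0.12)
        res = dlw_week(samples, dose, 6.0, 1)
        assert res.pal == pytest.approx(res.tee_mj_day / 6.0)
        res_unity = dlw_week(samples, dose, res.tee_mj_day, 1)
        assert res_unity.pal == pytest.approx(1.0)

    def test_missing_endpoint_day_raises(self):
        dose = DosingRecord("p", mass_2h2o_g=4.8, mass_h218o_g=100.0)
        samples = make_samples(1.1e-4, 2.5e-4, 0.10, 0.12, days=(1.0, 8.0))
        with pytest.raises(InsufficientDataError, match="day 15"):
            dlw_week(samples, dose, 6.0, 2)

    def test_noisy_estimates_unbiased_over_200_participants(self):
        from paee.simulate import generate_cohort
        participants, _ = generate_cohort(200, seed=21)
        rel_err = []
        for i, p in enumerate(participants):
            tee = p.true_pal * p.bmr_mj_day
            samples, dose = render_isotopes(p, tee, tee, NoiseConfig(), 1000 + i)
            res = dlw_week(samples, dose, p.bmr_mj_day, 1)
            rel_err.append((res.tee_mj_day - tee) / tee)
        rel_err = np.asarray(rel_err)
        ci_half = 1.96 * rel_err.std(ddof=1) / np.sqrt(rel_err.size)
        assert abs(rel_err.mean()) < ci_half + 1e-3
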