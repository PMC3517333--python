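"""Truth-first cohort simulator."""

import numpy as np
import pytest
from scipy.stats import truncnorm

from paee.compendium import default_compendium
from paee.par24 import average_mets, score_week
from paee.recall7 import average_mets_recall, score_recall_week
from paee.simulate import (ND_NO, PHYSIOLOGY, NoiseConfig, generate_cohort,
                           generate_true_schedule, implied_pal,
                           render_isotopes, render_reports, simulate_study)
from paee.stats import flag_outliers


class TestGenerateCohort:
    def test_same_seed_identical_cohort(self):
        a = generate_cohort(20, seed=7)
        b = generate_cohort(20, seed=7)
        assert a == b

    def test_n20_composition(self, cohort20):
        participants, assignment = cohort20
        assert len(participants) == 20
        assert sum(p.sex == "male" for p in participants) == 10
        orders = list(assignment.values())
        assert orders.count(("par24", "recall7")) == 10
        assert orders.count(("recall7", "par24")) == 10
        # crossover: everyone uses both instruments
        assert all(set(o) == {"par24", "recall7"} for o in orders)

    def test_large_cohort_male_bmr_matches_truncated_normal_mean(self):
        participants, _ = generate_cohort(2000, seed=3)
        bmr = np.array([p.bmr_mj_day for p in participants
                        if p.sex == "male"])
        mean, sd, lo, hi = PHYSIOLOGY["male"]["bmr_mj_day"]
        dist = truncnorm((lo - mean) / sd, (hi - mean) / sd, mean, sd)
        assert bmr.size == 1000
        assert bmr.mean() == pytest.approx(
            dist.mean(), abs=2 * dist.std() / np.sqrt(bmr.size))
        assert bmr.min() >= lo and bmr.max() <= hi

    def test_nd_no_ratios_within_configured_range(self, cohort20):
        participants, _ = cohort20
        _, _, lo, hi = ND_NO
        for p in participants:
            assert lo <= p.nd_no_ratio <= hi

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(1, seed=0)


class TestTrueSchedule:
    def test_implied_pal_within_1pct(self, cohort20, comp):
        participants, _ = cohort20
        for p in participants[:6]:
            for grid in generate_true_schedule(p, 3, seed=5, compendium=comp):
                assert len(grid) == 96
                assert implied_pal(grid, comp) == pytest.approx(
                    p.true_pal, rel=0.01)

    def test_two_seeds_differ_but_preserve_pal(self, participant, comp):
        g1 = generate_true_schedule(participant, 1, seed=1, compendium=comp)[0]
        g2 = generate_true_schedule(participant, 1, seed=2, compendium=comp)[0]
        assert g1 != g2
        assert implied_pal(g1, comp) == pytest.approx(
            implied_pal(g2, comp), rel=0.01)

    def test_sedentary_floor_dominated_by_low_met_slots(self, participant,
                                                        comp):
        from dataclasses import replace
        p = replace(participant, true_pal=1.42)
        grid = generate_true_schedule(p, 1, seed=5, compendium=comp)[0]
        from paee.compendium import lookup_mets
        low = sum(1 for c in grid if lookup_mets(comp, c) <= 1.5)
        assert low > 48  # more than half the day at <= 1.5 METs


class TestRenderReports:
    def test_noiseless_diary_is_exact_copy_of_truth(self, participant, comp,
                                                    no_noise):
        sched = generate_true_schedule(participant, 7, seed=9, compendium=comp)
        diary, _ = render_reports(sched, participant, no_noise, seed=4,
                                  compendium=comp)
        assert [list(d.slots) for d in diary] == [list(g) for g in sched]

    def test_noiseless_recall_matches_aggregation_oracle(self, participant,
                                                         comp, no_noise):
        from paee.compendium import SELECTABLE_CLASSES, class_for_mets, lookup_mets
        sched = generate_true_schedule(participant, 7, seed=9, compendium=comp)
        _, recall = render_reports(sched, participant, no_noise, seed=4,
                                   compendium=comp)
        for grid, day in zip(sched, recall):
            met_hours = 0.0
            for code in grid:
                met = lookup_mets(comp, code)
                if code in ("sleep", "napping"):
                    met_hours += 0.9 * 0.25
                else:
                    cls = class_for_mets(met)
                    met_hours += (cls.mets if cls.name in SELECTABLE_CLASSES
                                  else 1.3) * 0.25
            assert average_mets_recall(day) == pytest.approx(met_hours / 24,
                                                             rel=1e-9)

    def test_misclassification_prob_one_changes_every_slot(self, participant,
                                                           comp):
        noise = NoiseConfig.zero()
        from dataclasses import replace
        noise = replace(noise, diary_misclass_prob=1.0)
        sched = generate_true_schedule(participant, 2, seed=9, compendium=comp)
        diary, _ = render_reports(sched, participant, noise, seed=4,
                                  compendium=comp)
        for grid, day in zip(sched, diary):
            assert all(a != b for a, b in zip(grid, day.slots))

    def test_gross_overestimator_inflates_recall_tee(self, comp):
        from dataclasses import replace
        participants, _ = generate_cohort(10, seed=13)
        gross = replace(NoiseConfig.zero(), gross_overestimator_prob=1.0)
        bmr_kcal = 1500.0
        for p in participants[:4]:
            sched = generate_true_schedule(p, 7, seed=2, compendium=comp)
            _, corrupted = render_reports(sched, p, gross, seed=6,
                                          compendium=comp)
            _, faithful = render_reports(sched, p, NoiseConfig.zero(), seed=6,
                                         compendium=comp)
            # every waking hour reported as moderate: well above faithful
            assert (score_recall_week(corrupted, bmr_kcal).tee_mj
                    > 1.2 * score_recall_week(faithful, bmr_kcal).tee_mj)

    def test_single_corrupted_participant_is_flagged(self, comp):
        from dataclasses import replace
        participants, _ = generate_cohort(20, seed=31)
        diffs = []
        for i, p in enumerate(participants):
            gross = replace(NoiseConfig.zero(),
                            gross_overestimator_prob=1.0 if i == 0 else 0.0)
            sched = generate_true_schedule(p, 7, seed=40 + i, compendium=comp)
            _, recall = render_reports(sched, p, gross, seed=50 + i,
                                       compendium=comp)
            bmr_kcal = p.bmr_mj_day / 4.184e-3
            reported = score_recall_week(recall, bmr_kcal).tee_mj
            diffs.append(reported - p.true_pal * p.bmr_mj_day)
        assert flag_outliers(diffs, k_sd=3.0) == [0]


class TestRenderIsotopes:
    def test_doubling_tee_increases_ko(self, participant, no_noise):
        from paee.dlw import fit_elimination
        p = participant
        base_tee = p.true_pal * p.bmr_mj_day
        rates = []
        for tee in (base_tee, 2 * base_tee):
            samples, _ = render_isotopes(p, tee, tee, no_noise, 8)
            k, _ = fit_elimination(samples, "18O")
            rates.append(k)
        assert rates[1] > rates[0]

    def test_sampling_design(self, participant, no_noise):
        samples, dose = render_isotopes(participant, 12.0, 12.0, no_noise, 8)
        times = sorted(s.time_days for s in samples)
        assert times == [0.0, 1.0, 1.0, 8.0, 8.0, 15.0, 15.0]
        # protocol dose sizes per kg predicted TBW
        tbw_kg = participant.tbw_mol * 18.01528 / 1000
        assert dose.mass_2h2o_g == pytest.approx(0.12 * tbw_kg)
        assert dose.mass_h218o_g == pytest.approx(2.5 * tbw_kg)

    def test_nonpositive_tee_rejected(self, participant, no_noise):
        with pytest.raises(ValueError, match="positive"):
            render_isotopes(participant, 0.0, 12.0, no_noise, 8)


class TestSimulateStudy:
    def test_bit_reproducible_under_fixed_seed(self):
        a = simulate_study(6, seed=17)
        b = simulate_study(6, seed=17)
        assert a.truth == b.truth
        assert a.diary_days == b.diary_days
        assert a.recall_days == b.recall_days
        assert a.isotope_samples == b.isotope_samples

    def test_every_channel_present_for_every_participant(self):
        data = simulate_study(4, seed=17)
        for p in data.participants:
            assert len(data.diary_days[p.id]) == 14
            assert len(data.recall_days[p.id]) == 14
            assert len(data.isotope_samples[p.id]) == 7
            assert p.id in data.doses and p.id in data.gas_series

    def test_noiseless_diary_scores_back_to_weekly_truth(self, comp):
        data = simulate_study(4, seed=23, noise=NoiseConfig.zero())
        for p in data.participants:
            bmr_kcal = p.bmr_mj_day / 4.184e-3
            week1 = data.diary_days[p.id][:7]
            out = score_week(week1, bmr_kcal, comp)
            assert out.tee_mj == pytest.approx(
                data.truth[p.id]["tee_mj_week1"], rel=1e-9)
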