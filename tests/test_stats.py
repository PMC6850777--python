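"""Aging statistics: curves, trend test, survival, bootstrap, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glmaging.presets import get_preset
from glmaging.stats import (
    BootstrapConfig,
    align_to_event,
    bootstrap_ci,
    cochran_q_trend,
    counterfactual_lifespan_gain,
    duration_vs_age_test,
    filter_first_hours,
    glm_probability_by_age,
    history_dependence,
    km_survival,
    logrank,
    mean_rls,
    spearman_event_vs_remaining,
    terminal_fraction_stats,
)
from glmaging.synthetic.cohort import simulate_cohort
from glmaging.synthetic.traces import synthesize_traces
from glmaging.types import CellRecord, GLMEvent


def _cell(cid, rls, fate="died", first=0.0):
    return CellRecord(
        cell_id=cid,
        strain="toy",
        first_detection_min=first,
        division_times_min=[100.0 * (i + 1) for i in range(rls)],
        fate=fate,
        fate_time_min=100.0 * rls + 50.0,
    )


def _event(cid, age, outcome="corrected"):
    onset = 100.0 * age - 10.0
    res = onset + 60.0 if outcome == "corrected" else None
    return GLMEvent(cid, age, onset, res, outcome)


class TestInclusionFilter:
    def test_boundary_is_inclusive(self):
        cells = [_cell("a", 3, first=180.0), _cell("b", 3, first=200.0),
                 _cell("c", 3, first=0.0)]
        kept = filter_first_hours(cells)
        assert [c.cell_id for c in kept] == ["a", "c"]

    def test_all_early_cohort_unchanged(self):
        cells = [_cell(f"c{i}", 2, first=0.0) for i in range(5)]
        assert filter_first_hours(cells) == cells


class TestAgeAlignedCurve:
    def test_birth_alignment_toy_with_censoring(self):
        # A: rls 3, event at 2, died. B: rls 2, died. C: censored after 2,
        # event at 1. Hand count: p = (1/3, 1/3, 0/1) at ages 1..3.
        cells = [_cell("A", 3), _cell("B", 2),
                 _cell("C", 2, fate="censored_lost")]
        events = [_event("A", 2), _event("C", 1)]
        curve = glm_probability_by_age(cells, events, "birth")
        assert curve.ages.tolist() == [1, 2, 3]
        assert curve.p.tolist() == pytest.approx([1 / 3, 1 / 3, 0.0])
        assert curve.n_at_risk.tolist() == [3, 3, 1]
        assert curve.sem.tolist() == pytest.approx(
            list(np.sqrt(curve.p * (1 - curve.p) / curve.n_at_risk))
        )

    def test_no_events_gives_zero_curve(self):
        cells = [_cell("A", 4), _cell("B", 2)]
        curve = glm_probability_by_age(cells, [], "birth")
        assert np.all(curve.p == 0)

    def test_risk_set_nonincreasing_for_birth_alignment(self):
        records, events = simulate_cohort(get_preset("wild_type"), 300, seed=61)
        curve = glm_probability_by_age(records, events, "birth")
        assert np.all(np.diff(curve.n_at_risk) <= 0)

    def test_death_alignment_excludes_censored(self):
        cells = [_cell("A", 3), _cell("C", 5, fate="censored_lost")]
        curve = glm_probability_by_age(cells, [], "death")
        assert curve.n_at_risk.max() == 1  # only the dead cell

    def test_death_aligned_probability_rises_toward_death(self):
        records, events = simulate_cohort(get_preset("wild_type"), 1500, seed=62)
        curve = glm_probability_by_age(records, events, "death")
        p = dict(zip(curve.ages.tolist(), curve.p.tolist()))
        assert p[1] > p[10]
        assert p[1] > 4 * p[10]  # dramatic rise near death

    def test_birth_curve_recovers_generator_hazard(self):
        # Flat-hazard generator: each age's p sits in its binomial band.
        p0 = 0.08
        preset = get_preset("wild_type").with_(
            h_young=p0, late_ramp=(p0,) * 5, lambda_cytokinesis_per_h=0.0,
            terminal_death_hazard_per_h=0.0, censor_hazard=0.0, multi_event_prob=0.0,
        )
        records, events = simulate_cohort(preset, 5000, seed=63, run_end_min=1e9)
        curve = glm_probability_by_age(records, events, "birth")
        sel = curve.n_at_risk >= 200
        z = (curve.p[sel] - p0) / np.sqrt(p0 * (1 - p0) / curve.n_at_risk[sel])
        assert np.mean(np.abs(z) < 1.96) >= 0.90
        assert np.abs(z).max() < 4.5

    def test_unknown_alignment_rejected(self):
        with pytest.raises(ValueError, match="alignment"):
            glm_probability_by_age([], [], "sideways")


class TestCochranQ:
    def test_hand_derived_toy(self):
        # Rows (1,1,0),(1,0,0),(1,1,1),(0,0,0) over 3 bins: Q=3, p=0.2231.
        cells = [_cell(c, 3) for c in "abcd"]
        events = [_event("a", 1), _event("a", 2), _event("b", 1),
                  _event("c", 1), _event("c", 2), _event("c", 3)]
        q, p = cochran_q_trend(cells, events, [(1, 1), (2, 2), (3, 3)])
        assert q == pytest.approx(3.0, abs=1e-12)
        assert p == pytest.approx(0.2231, abs=1e-4)

    def test_identical_columns_give_zero(self):
        cells = [_cell(c, 4) for c in "ab"]
        events = [_event("a", 1), _event("a", 3)]
        q, p = cochran_q_trend(cells, events, [(1, 2), (3, 4)])
        assert q == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_too_few_complete_cases_rejected(self):
        cells = [_cell("a", 5)]
        with pytest.raises(ValueError, match="complete-case"):
            cochran_q_trend(cells, [], [(1, 10), (11, 20)])

    @given(st.randoms(use_true_random=False))
    def test_row_permutation_invariance(self, rnd):
        cells = [_cell(f"c{i}", 12) for i in range(8)]
        events = [_event(f"c{i}", a) for i in range(8) for a in range(1, i + 2)]
        q1, _ = cochran_q_trend(cells, events, [(1, 4), (5, 8), (9, 12)])
        shuffled = list(cells)
        rnd.shuffle(shuffled)
        q2, _ = cochran_q_trend(shuffled, events, [(1, 4), (5, 8), (9, 12)])
        assert q1 == pytest.approx(q2, abs=1e-12)

    def test_wild_type_age_trend_detected(self):
        records, events = simulate_cohort(get_preset("wild_type"), 400, seed=64)
        q, p = cochran_q_trend(records, events)
        assert p < 0.05


class TestSurvival:
    def test_km_without_censoring_is_empirical_survival(self):
        cells = [_cell("a", 3), _cell("b", 5), _cell("c", 5), _cell("d", 9)]
        curve = km_survival(cells)
        emp = {3: 0.75, 5: 0.25, 9: 0.0}
        got = dict(zip(curve.times.tolist(), curve.survival.tolist()))
        for t, s in emp.items():
            assert got[t] == pytest.approx(s)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert curve.survival[0] == pytest.approx(1.0)

    def test_logrank_hand_derived_toy(self):
        # A dies at {1,2}, B at {3,4}: chi-square = 1.1667^2/0.4722 = 2.882.
        a = km_survival([_cell("a1", 1), _cell("a2", 2)])
        b = km_survival([_cell("b1", 3), _cell("b2", 4)])
        chi2, p = logrank(a, b)
        assert chi2 == pytest.approx(2.8824, abs=1e-3)

    def test_identical_groups_give_zero_statistic(self):
        g = [_cell("a", 3), _cell("b", 7)]
        chi2, _ = logrank(km_survival(g), km_survival(g))
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_deaths_rejected(self):
        g = [_cell("a", 3)]
        h = [_cell("b", 3, fate="censored_lost")]
        with pytest.raises(ValueError, match="deaths"):
            logrank(km_survival(g), km_survival(h, include_censored=True))

    def test_excluding_late_biased_censoring_lowers_mean(self):
        # Cells censored late carry information about long lifespans; the
        # KM mean with them included exceeds the uncensored-only mean.
        rng = np.random.default_rng(65)
        cells = []
        for i in range(400):
            rls = int(rng.integers(5, 40))
            fate = "censored_lost" if (rls > 22 and rng.random() < 0.6) else "died"
            cells.append(_cell(f"c{i}", rls, fate=fate))
        assert mean_rls(cells, include_censored=True) > mean_rls(cells) + 1.0


class TestBootstrap:
    def test_degenerate_sample_gives_zero_width(self):
        vals = [1.0] * 30
        lo, hi = bootstrap_ci(np.mean, vals, BootstrapConfig(200, "percentile95", 0))
        assert lo == hi == 1.0

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(66)
        vals = rng.standard_normal(50)
        cfg = BootstrapConfig(300, "nonoverlap_p05", 7)
        assert bootstrap_ci(np.mean, vals, cfg) == bootstrap_ci(np.mean, vals, cfg)

    def test_proportion_interval_width_matches_binomial(self):
        # n=400, p=0.25: analytic 95% width = 2 * 1.96 * sqrt(pq/n).
        vals = np.r_[np.ones(100), np.zeros(300)]
        lo, hi = bootstrap_ci(np.mean, vals, BootstrapConfig(3000, "percentile95", 1))
        width = hi - lo
        analytic = 2 * 1.96 * np.sqrt(0.25 * 0.75 / 400)
        assert abs(width - analytic) / analytic < 0.2

    def test_width_shrinks_as_root_n(self):
        rng = np.random.default_rng(67)
        widths = []
        for n in [100, 400, 1600]:
            vals = rng.standard_normal(n)
            lo, hi = bootstrap_ci(np.mean, vals, BootstrapConfig(800, "percentile95", n))
            widths.append(hi - lo)
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.25)
        assert widths[1] / widths[2] == pytest.approx(2.0, rel=0.25)

    def test_fragile_statistic_rejected(self):
        def bad(sample):
            raise RuntimeError("undefined")
        with pytest.raises(ValueError, match="resamples"):
            bootstrap_ci(bad, [1.0, 2.0], BootstrapConfig(100, "percentile95", 0))

    def test_small_n_boot_rejected(self):
        with pytest.raises(ValueError, match="n_boot"):
            BootstrapConfig(50, "percentile95", 0).validate()


class TestSpearman:
    def test_hand_derived_toy(self):
        cells = [_cell(c, 5 + r) for c, r in zip("abcd", (1, 2, 3, 4))]
        events = [_event("a", 5), _event("b", 5)]
        rho = spearman_event_vs_remaining(cells, events, age=5)
        assert rho == pytest.approx(-0.8944, abs=1e-4)

    def test_independent_indicator_gives_near_zero(self):
        rng = np.random.default_rng(68)
        cells, events = [], []
        for i in range(4000):
            rls = 10 + int(rng.integers(0, 20))
            cells.append(_cell(f"c{i}", rls))
            if rng.random() < 0.3:
                events.append(_event(f"c{i}", 5))
        rho = spearman_event_vs_remaining(cells, events, age=5)
        assert abs(rho) < 0.05

    def test_constant_indicator_rejected(self):
        cells = [_cell("a", 6), _cell("b", 8)]
        with pytest.raises(ValueError, match="indicator"):
            spearman_event_vs_remaining(cells, [], age=3)

    def test_late_events_predict_shorter_remaining_life(self):
        records, events = simulate_cohort(get_preset("wild_type"), 2000, seed=69)
        rho = spearman_event_vs_remaining(records, events, age=20)
        assert rho < -0.1


class TestHistoryDependence:
    def test_events_only_after_prior_events(self):
        cells = [_cell("a", 6), _cell("b", 6)]
        events = [_event("a", 2), _event("a", 4)]
        out = history_dependence(cells, events)
        assert out["p_given_prior"] > 0
        assert out["p_given_none"] == 0

    def test_frailty_induces_history_dependence(self):
        records, events = simulate_cohort(get_preset("wild_type"), 3000, seed=70)
        out = history_dependence(records, events)
        assert out["p_given_prior"] > 1.3 * out["p_given_none"]

    def test_history_free_generator_shows_no_dependence(self):
        p0 = 0.08
        preset = get_preset("wild_type").with_(
            h_young=p0, late_ramp=(p0,) * 5, lambda_cytokinesis_per_h=0.0,
            terminal_death_hazard_per_h=0.0, censor_hazard=0.0, multi_event_prob=0.0,
        )
        records, events = simulate_cohort(preset, 4000, seed=71, run_end_min=1e9)
        out = history_dependence(records, events)
        assert out["p_given_prior"] == pytest.approx(out["p_given_none"], abs=0.015)


class TestCounterfactualGain:
    def test_no_events_means_no_gain(self):
        assert counterfactual_lifespan_gain([_cell("a", 5)], []) == 0.0

    def test_two_cell_worked_example(self):
        # rls 10 each; one corrected event at age 5 -> cf mean 7.5, gain 33.3%.
        cells = [_cell("a", 10), _cell("b", 10)]
        gain = counterfactual_lifespan_gain(cells, [_event("a", 5)])
        assert gain == pytest.approx(100 * (10 / 7.5 - 1), abs=1e-9)

    def test_censored_cells_excluded(self):
        cells = [_cell("a", 10), _cell("z", 2, fate="censored_end")]
        gain = counterfactual_lifespan_gain(cells, [_event("a", 5)])
        assert gain == pytest.approx(100.0, abs=1e-9)  # 10 / 5 - 1


class TestDurationVsAge:
    def test_hand_derived_toy(self):
        df = pd.DataFrame(
            {"duration_min": [1, 2, 3, 2, 3, 4], "cycle_index": [1, 1, 1, 9, 9, 9]}
        )
        t, p = duration_vs_age_test(df)
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert p == pytest.approx(0.287, abs=2e-3)

    def test_identical_groups_give_t_zero(self):
        df = pd.DataFrame(
            {"duration_min": [5, 6, 7, 5, 6, 7], "cycle_index": [1, 1, 1, 9, 9, 9]}
        )
        t, p = duration_vs_age_test(df)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_degenerate_variance_rejected(self):
        df = pd.DataFrame(
            {"duration_min": [5, 5, 5, 5], "cycle_index": [1, 1, 9, 9]}
        )
        with pytest.raises(ValueError, match="variance"):
            duration_vs_age_test(df)


@pytest.fixture(scope="module")
def aligned():
    preset = get_preset("wild_type").with_(trace_noise_cv=0.0, bleach_per_frame=0.0)
    records, events = simulate_cohort(preset, 80, seed=72)
    traces = synthesize_traces(records, events, preset, seed=73)
    return align_to_event(traces, events, min_duration_min=30.0)


class TestAlignToEvent:
    def test_mother_rises_from_leak_to_1n_at_correction(self, aligned):
        before = aligned.loc[aligned.t_min == -30, "mean"].iloc[0]
        after = aligned.loc[aligned.t_min == 25, "mean"].iloc[0]
        assert before < 0.55  # arrested: leak fraction of 2N, in 1N units
        assert after == pytest.approx(1.0, abs=0.05)

    def test_no_qualifying_events_rejected(self):
        with pytest.raises(ValueError, match="no corrected events"):
            align_to_event([], [], min_duration_min=30.0)


class TestTerminalFractions:
    def test_worked_toy_counts(self):
        cells = [_cell(f"d{i}", 5) for i in range(10)]
        events = []
        for i in range(3):  # 3 terminal deaths among 10 cells
            events.append(_event(f"d{i}", 5, outcome="terminal_cytokinesis"))
        for i in range(10):  # 17 more events, all corrected
            for a in (1, 2):
                if len(events) < 20:
                    events.append(_event(f"d{i}", a))
        out = terminal_fraction_stats(cells, events)
        assert out["death_fraction"] == pytest.approx(0.30)
        assert out["uncorrected_fraction"] == pytest.approx(0.15)

    def test_all_corrected_gives_zero_fractions(self):
        cells = [_cell("a", 4)]
        out = terminal_fraction_stats(cells, [_event("a", 2)])
        assert out == {"death_fraction": 0.0, "uncorrected_fraction": 0.0}

    def test_bfa1_exceeds_wild_type_with_separated_intervals(self):
        boot = BootstrapConfig(300, "nonoverlap_p05", 74)
        out = {}
        for name, seed in [("wild_type", 75), ("bfa1", 76)]:
            records, events = simulate_cohort(get_preset(name), 200, seed=seed)
            out[name] = terminal_fraction_stats(records, events, boot)
        for key in ("death_fraction", "uncorrected_fraction"):
            lo_bfa1 = out["bfa1"][f"{key}_ci"][0]
            hi_wt = out["wild_type"][f"{key}_ci"][1]
            assert lo_bfa1 > hi_wt  # non-overlap at the p=0.05 calibration
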