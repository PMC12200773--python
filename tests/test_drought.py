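"""Drought engine: run extraction, the two drought criteria, the
standardized dryness intensity, and the exposure categories."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from droughtlink.config import PipelineConfig
from droughtlink.drought import (
    CategoryThresholds,
    SpeiSeries,
    assign_categories,
    combine_methods,
    compute_thresholds,
    count_method,
    extract_runs,
    flag_dry_months,
    recent_max_run,
    standardized_intensity,
    sum_method,
    summarize_window,
)


def brute_force_runs(flags):
    """Independent maximal-stretch scanner: enumerate (start, length)."""
    runs, i = [], 0
    while i < len(flags):
        if flags[i]:
            j = i
            while j + 1 < len(flags) and flags[j + 1]:
                j += 1
            runs.append((i, j - i + 1))
            i = j + 1
        else:
            i += 1
    return runs


def series(values, unit="u", start=0):
    return SpeiSeries(unit_id=unit, start_month=start, values=np.array(values, float))


class TestDryFlags:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([-1.0], [True]),  # threshold is inclusive
            ([-0.99, 0.3], [False, False]),
            ([0.5, -2.0, -2.0, -2.0, -1.0], [False, True, True, True, True]),
        ],
    )
    def test_threshold_boundary(self, values, expected):
        assert flag_dry_months(np.array(values)).tolist() == expected

    def test_missing_months_never_dry(self):
        flags = flag_dry_months(np.array([np.nan, -2.0, np.nan]))
        assert flags.tolist() == [False, True, False]


class TestRunExtraction:
    def test_no_dry_months(self):
        assert extract_runs(np.zeros(10, bool), np.zeros(10)) == []

    def test_two_runs_with_sums(self):
        flags = np.array([1] * 5 + [0] + [1] * 2, bool)
        vals = np.array([-2.0] * 5 + [0.5] + [-1.5] * 2)
        runs = extract_runs(flags, vals, start_month=100)
        assert [(r.start_month, r.length, r.sum_spei) for r in runs] == [
            (100, 5, -10.0),
            (106, 2, -3.0),
        ]

    def test_exhaustive_against_scanner(self):
        """All 2^10 dry/wet patterns agree with the brute-force scanner."""
        for bits in itertools.product([False, True], repeat=10):
            flags = np.array(bits)
            vals = np.where(flags, -2.0, 1.0)
            runs = extract_runs(flags, vals)
            assert [(r.start_month, r.length) for r in runs] == brute_force_runs(bits)


class TestCountMethod:
    @pytest.mark.parametrize(
        "lengths,n_flagged,n_cycles",
        [((5,), 5, 1), ((4,), 0, 0), ((6, 3, 7), 13, 2)],
    )
    def test_run_length_rule(self, lengths, n_flagged, n_cycles):
        vals, flags = [], []
        for L in lengths:
            vals += [-2.0] * L + [1.0]
            flags += [True] * L + [False]
        runs = extract_runs(np.array(flags), np.array(vals))
        cflags, cycles = count_method(runs, len(vals), min_run_length=5)
        assert int(cflags.sum()) == n_flagged
        assert len(cycles) == n_cycles


class TestSumMethod:
    def test_intense_six_month_run_qualifies(self):
        # 6 x -3.0 sums to -18.0 <= -17.5
        runs = extract_runs(np.ones(6, bool), np.full(6, -3.0))
        flags, cycles = sum_method(runs, 6)
        assert int(flags.sum()) == 6 and len(cycles) == 1

    def test_mild_five_month_run_fails_sum_but_passes_count(self):
        runs = extract_runs(np.ones(5, bool), np.full(5, -1.0))
        sflags, scycles = sum_method(runs, 5)
        cflags, ccycles = count_method(runs, 5, min_run_length=5)
        assert int(sflags.sum()) == 0 and len(scycles) == 0
        assert int(cflags.sum()) == 5 and len(ccycles) == 1

    def test_short_severe_run_passes_sum_but_not_count(self):
        # the intensity criterion applies to runs of any length
        runs = extract_runs(np.ones(4, bool), np.full(4, -4.5))
        sflags, scycles = sum_method(runs, 4)
        cflags, _ = count_method(runs, 4, min_run_length=5)
        assert int(sflags.sum()) == 4 and len(scycles) == 1
        assert int(cflags.sum()) == 0


class TestCombineMethods:
    def test_six_month_intense_run_meets_both(self):
        vals = np.full(6, -3.0)
        runs = extract_runs(np.ones(6, bool), vals)
        cflags, _ = count_method(runs, 6, min_run_length=5)
        sflags, _ = sum_method(runs, 6)
        both, cycles = combine_methods(cflags, sflags, vals)
        assert int(both.sum()) == 6 and len(cycles) == 1

    @given(st.lists(st.floats(-4, 4), min_size=10, max_size=60))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_both_bounded_by_each_method(self, values):
        vals = np.array(values)
        flags = flag_dry_months(vals)
        runs = extract_runs(flags, vals)
        cflags, _ = count_method(runs, len(vals), min_run_length=5)
        sflags, _ = sum_method(runs, len(vals))
        both, _ = combine_methods(cflags, sflags, vals)
        assert np.all(both <= cflags) and np.all(both <= sflags)
        assert np.all(cflags <= flags) and np.all(sflags <= flags)


class TestStandardizedIntensity:
    def test_single_cycle(self):
        # one cycle: 7 months summing -21 -> -21 / (7/1) = -3.0
        assert standardized_intensity(-21.0, 7, 1) == pytest.approx(-3.0)

    def test_two_cycles(self):
        # sums -20 and -24 over 8 and 12 months -> -44 / (20/2) = -4.4
        assert standardized_intensity(-44.0, 20, 2) == pytest.approx(-4.4)

    def test_undefined_without_cycles(self):
        assert np.isnan(standardized_intensity(0.0, 0, 0))


class TestRecentMaxRun:
    def _run_series(self, dry_tail):
        vals = np.concatenate([np.ones(48 - dry_tail), np.full(dry_tail, -2.0)])
        return extract_runs(flag_dry_months(vals), vals)

    @pytest.mark.parametrize("tail,expected", [(13, 13), (12, 12)])
    def test_trailing_run_length(self, tail, expected):
        runs = self._run_series(tail)
        assert recent_max_run(runs, (0, 47), 24) == expected

    def test_run_truncated_to_subwindow_overlap(self):
        # 20-month run ending 15 months before the window end: months
        # 13..32; trailing 24-month sub-window is months 24..47 -> overlap 9
        vals = np.ones(48)
        vals[13:33] = -2.0
        runs = extract_runs(flag_dry_months(vals), vals)
        overlap = min(32, 47) - max(13, 24) + 1
        assert recent_max_run(runs, (0, 47), 24) == overlap == 9


class TestSummarizeWindow:
    def test_all_positive_series(self, default_config):
        s = series(np.ones(48) * 0.5)
        summ = summarize_window(s, (0, 47), default_config)
        assert summ.n_dry == summ.n_count == summ.n_sum == summ.n_both == 0
        assert np.isnan(summ.sdi)
        assert summ.n_slight_moderate == 0

    def test_injected_drought_recovered(self, default_config):
        vals = np.ones(48) * 0.5
        vals[10:20] = -2.0  # 10-month run summing -20: both methods
        summ = summarize_window(series(vals), (0, 47), default_config)
        assert summ.n_dry == 10
        assert summ.n_count == summ.n_sum == summ.n_both == 10
        assert summ.cycles_count == summ.cycles_sum == summ.cycles_both == 1
        assert summ.sdi == pytest.approx(-20.0 / 10.0)

    def test_mild_band_is_strictly_between_minus_one_and_zero(self, default_config):
        vals = np.array([-1.0, -0.5, 0.0, -0.99, 0.5] + [1.0] * 43)
        summ = summarize_window(series(vals), (0, 47), default_config)
        assert summ.n_slight_moderate == 2  # -0.5 and -0.99 only

    def test_partial_coverage_errors(self, default_config):
        with pytest.raises(ValueError, match="not covered"):
            summarize_window(series(np.ones(40)), (0, 47), default_config)

    def test_deepening_a_month_cannot_increase_sdi(self, default_config):
        rng = np.random.default_rng(3)
        vals = rng.standard_normal(48)
        vals[5:13] = -2.5
        base = summarize_window(series(vals), (0, 47), default_config).sdi
        vals2 = vals.copy()
        vals2[7] -= 1.5
        deeper = summarize_window(series(vals2), (0, 47), default_config).sdi
        assert deeper <= base

    def test_lengthening_a_run_cannot_decrease_count_months(self, default_config):
        vals = np.ones(48)
        vals[10:16] = -2.0
        base = summarize_window(series(vals), (0, 47), default_config).n_count
        vals[16] = -2.0
        longer = summarize_window(series(vals), (0, 47), default_config).n_count
        assert longer >= base


def _summary_with(unit, sdi, n_both):
    from droughtlink.drought import DroughtWindowSummary

    return DroughtWindowSummary(
        unit_id=unit, window=(0, 47), n_dry=0, n_count=0, n_sum=0,
        n_both=n_both, cycles_count=0, cycles_sum=0 if np.isnan(sdi) else 1,
        cycles_both=0, sdi=sdi, recent_max_run=0, n_slight_moderate=0,
    )


class TestThresholds:
    def test_most_negative_decile_selected(self):
        summaries = [_summary_with(f"u{i}", -float(i), 0) for i in range(1, 11)]
        th = compute_thresholds(summaries, 0.10)
        qualifying = [s.unit_id for s in summaries if s.sdi <= th.sdi_cutoff]
        assert qualifying == ["u10"]  # sorted-order oracle: only the extreme

    def test_replication_invariance(self):
        summaries = [_summary_with(f"u{i}", -float(i), i) for i in range(1, 21)]
        th1 = compute_thresholds(summaries)
        th2 = compute_thresholds(summaries + summaries)
        assert th1.sdi_cutoff == pytest.approx(th2.sdi_cutoff)
        assert th1.both_cutoff == pytest.approx(th2.both_cutoff)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        summaries = [
            _summary_with(f"u{i}", -rng.uniform(1, 9), rng.integers(0, 30))
            for i in range(25)
        ]
        th1 = compute_thresholds(summaries)
        rng.shuffle(summaries)
        th2 = compute_thresholds(summaries)
        assert (th1.sdi_cutoff, th1.both_cutoff) == (th2.sdi_cutoff, th2.both_cutoff)

    def test_no_defined_sdi_warns_and_disables_very_dry(self):
        summaries = [_summary_with(f"u{i}", float("nan"), 0) for i in range(5)]
        with pytest.warns(UserWarning, match="very_dry"):
            th = compute_thresholds(summaries)
        assert np.isnan(th.sdi_cutoff)
        prof = assign_categories(summaries[0], th)
        assert not prof.very_dry

    def test_all_zero_both_counts(self):
        summaries = [_summary_with(f"u{i}", -2.0, 0) for i in range(12)]
        th = compute_thresholds(summaries)
        assert th.both_cutoff == 0
        # prolonged_extreme still requires at least one both-month
        assert not assign_categories(summaries[0], th).prolonged_extreme


class TestAssignCategories:
    def test_recent_and_long_strict_boundary(self):
        th = CategoryThresholds(sdi_cutoff=-5.0, both_cutoff=10.0)
        s13 = _summary_with("a", -1.0, 0)
        s13.recent_max_run = 13
        s12 = _summary_with("b", -1.0, 0)
        s12.recent_max_run = 12
        assert assign_categories(s13, th).recent_and_long
        assert not assign_categories(s12, th).recent_and_long

    def test_flags_may_overlap(self):
        th = CategoryThresholds(sdi_cutoff=-3.0, both_cutoff=5.0)
        s = _summary_with("a", -4.0, 8)
        s.recent_max_run = 20
        prof = assign_categories(s, th)
        assert prof.very_dry and prof.recent_and_long and prof.prolonged_extreme

    def test_tie_at_cutoff_included(self):
        th = CategoryThresholds(sdi_cutoff=-3.0, both_cutoff=5.0)
        s = _summary_with("a", -3.0, 5)
        prof = assign_categories(s, th)
        assert prof.very_dry and prof.prolonged_extreme
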