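import numpy as np
import pandas as pd
import pytest

from restwatch import rest_activity as ra
from restwatch.errors import AllMissing, NoInBedEpochs, NoWakeSpan, SeriesTooShort
from restwatch.io_formats import BedSchedule, EpochSeries

from conftest import NOON, make_schedule, make_series


def brute_force_dichotomy(in_counts, out_counts, strict=True):
    """Literal counting oracle: strict inequalities against the exact median."""
    out_counts = [c for c in out_counts if not np.isnan(c)]
    in_counts = [c for c in in_counts if not np.isnan(c)]
    med = np.median(out_counts)
    if strict:
        hits = sum(1 for c in in_counts if c < med)
    else:
        hits = sum(1 for c in in_counts if c <= med)
    return 100.0 * hits / len(in_counts)


def series_with_nights(in_blocks, out_blocks):
    """Interleave out/in count blocks into one series + schedule.

    Layout: out0, in0, out1, in1, ... each block contiguous.
    """
    counts = []
    intervals = []
    t = 0
    for out_c, in_c in zip(out_blocks, in_blocks):
        counts.extend(out_c)
        t += len(out_c)
        start = NOON + pd.Timedelta(minutes=t)
        counts.extend(in_c)
        t += len(in_c)
        intervals.append((start, NOON + pd.Timedelta(minutes=t)))
    s = make_series(np.array(counts, dtype=float))
    return s, make_schedule(intervals)


class TestDichotomyIndex:
    def test_all_in_bed_below_median(self):
        s, sch = series_with_nights([[0, 0, 0]], [[5, 10, 15]])
        assert ra.dichotomy_index(s, sch) == 100.0

    def test_strict_inequality_against_exact_median(self):
        # out-of-bed [0,10,20,10,40] -> median 10; in-bed [5,10,15]: only 5 < 10
        s, sch = series_with_nights([[5, 10, 15]], [[0, 10, 20, 10, 40]])
        got = ra.dichotomy_index(s, sch)
        assert got == pytest.approx(100.0 / 3.0)
        assert got == pytest.approx(brute_force_dichotomy([5, 10, 15], [0, 10, 20, 10, 40]))

    def test_nonstrict_convention_flag(self):
        s, sch = series_with_nights([[5, 10, 15]], [[0, 10, 20, 10, 40]])
        assert ra.dichotomy_index(s, sch, strict=False) == pytest.approx(200.0 / 3.0)

    def test_disrupted_classification_boundary(self):
        from restwatch.rest_activity import DISRUPTED_CUTOFF_PCT, RestActivityMetrics

        m = RestActivityMetrics("P", 97.5, 0.1, 100, 200, 8, "per_protocol")
        assert m.disrupted  # <= 97.5 flags disruption
        m2 = RestActivityMetrics("P", 97.51, 0.1, 100, 200, 8, "per_protocol")
        assert not m2.disrupted
        assert DISRUPTED_CUTOFF_PCT == 97.5

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            n_nights = rng.integers(1, 6)
            in_blocks = [rng.integers(0, 50, rng.integers(1, 40)).astype(float)
                         for _ in range(n_nights)]
            out_blocks = [rng.integers(0, 200, rng.integers(1, 40)).astype(float)
                          for _ in range(n_nights)]
            s, sch = series_with_nights(in_blocks, out_blocks)
            expect = brute_force_dichotomy(np.concatenate(in_blocks), np.concatenate(out_blocks))
            assert ra.dichotomy_index(s, sch) == pytest.approx(expect)

    def test_invariant_under_monotone_transform(self, rng):
        # odd out-of-bed pool so the median is an order statistic (an even pool
        # interpolates two order statistics, which a monotone map need not preserve)
        for _ in range(30):
            in_blocks = [rng.integers(0, 60, 30).astype(float)]
            out_blocks = [rng.integers(0, 60, 51).astype(float)]
            s, sch = series_with_nights(in_blocks, out_blocks)
            base = ra.dichotomy_index(s, sch)
            a, b, c = rng.uniform(0.5, 3), rng.uniform(0, 100), rng.uniform(0.01, 0.1)
            transformed = a * s.counts + b + c * s.counts**2  # strictly increasing on >=0
            s2 = make_series(transformed)
            assert ra.dichotomy_index(s2, sch) == pytest.approx(base)

    def test_pooled_median_not_per_night(self):
        # two nights; pooling changes the answer vs per-night medians
        s, sch = series_with_nights(
            [[5, 5], [5, 5]], [[0, 0, 0], [100, 100, 100]]
        )
        # pooled out-of-bed median of [0,0,0,100,100,100] = 50 -> all 4 in-bed < 50
        assert ra.dichotomy_index(s, sch) == 100.0

    def test_missing_epochs_excluded(self):
        in_c = [5.0, np.nan, 15.0]
        out_c = [0.0, 10.0, 20.0, np.nan, 40.0]
        s, sch = series_with_nights([in_c], [out_c])
        assert ra.dichotomy_index(s, sch) == pytest.approx(
            brute_force_dichotomy(in_c, out_c)
        )

    def test_error_contracts(self):
        s = make_series(np.ones(100))
        with pytest.raises(NoInBedEpochs):
            ra.dichotomy_index(s, make_schedule([]))
        in_c = [np.nan, np.nan]
        s2, sch2 = series_with_nights([in_c], [[1.0, 2.0]])
        with pytest.raises(AllMissing):
            ra.dichotomy_index(s2, sch2)


class TestRestriction20h:
    def test_agrees_when_boundary_hours_empty(self):
        # in-bed interval starts 120 min into the series and the hour around
        # each boundary holds only missing epochs -> identical pools
        counts = np.full(400, np.nan)
        counts[:60] = [50] * 60  # out-of-bed, clear of both boundary windows
        counts[180:240] = [1] * 60  # in-bed, >60 min past the boundary
        s = make_series(counts)
        sch = make_schedule([(NOON + pd.Timedelta(minutes=120), NOON + pd.Timedelta(minutes=310))])
        full = ra.dichotomy_index(s, sch)
        restricted = ra.dichotomy_index(s, sch, restriction="20h")
        assert full == restricted == 100.0

    def test_excludes_boundary_epochs_from_both_pools(self):
        # high counts only in the hour after bed start: excluded under 20h
        counts = np.concatenate([np.full(240, 100.0), np.full(60, 500.0), np.full(180, 0.0)])
        s = make_series(counts)
        sch = make_schedule([(NOON + pd.Timedelta(minutes=240), NOON + pd.Timedelta(minutes=480))])
        assert ra.dichotomy_index(s, sch) < 100.0
        assert ra.dichotomy_index(s, sch, restriction="20h") == 100.0

    def test_rank_agreement_on_synthetic_cohort(self, small_cohort):
        from scipy.stats import spearmanr

        full, restr = [], []
        for pid, s in small_cohort.series.items():
            sch = small_cohort.schedules[pid]
            full.append(ra.dichotomy_index(s, sch))
            restr.append(ra.dichotomy_index(s, sch, restriction="20h"))
        r, _ = spearmanr(full, restr)
        assert r > 0.7  # qualitative: the two variants rank participants alike


class TestR24:
    def test_pure_sinusoid_gives_one(self):
        t = np.arange(8 * 1440)
        counts = 100 + 50 * np.sin(2 * np.pi * t / 1440)
        assert ra.r24_autocorrelation(make_series(counts)) >= 0.999

    def test_iid_noise_near_zero(self, rng):
        counts = rng.integers(0, 100, 8 * 1440).astype(float)
        assert abs(ra.r24_autocorrelation(make_series(counts))) < 0.05

    def test_matches_two_pass_oracle(self, rng):
        # 4-day toy series with a planted partial repeat of day one
        base = rng.integers(0, 100, 1440).astype(float)
        noise = rng.integers(0, 100, 4 * 1440).astype(float)
        counts = noise.copy()
        counts[:1440] = base
        counts[1440:2160] = base[:720]  # half of day two repeats day one
        got = ra.r24_autocorrelation(make_series(counts))
        a, b = counts[:-1440], counts[1440:]
        ma, mb = a.mean(), b.mean()
        num = float(np.sum((a - ma) * (b - mb)))
        den = float(np.sqrt(np.sum((a - ma) ** 2) * np.sum((b - mb) ** 2)))
        assert got == pytest.approx(num / den, abs=1e-12)

    def test_concatenated_copy_of_first_day(self, rng):
        base = rng.integers(0, 100, 2 * 1440).astype(float)
        counts = np.concatenate([base, base[:1440]])
        got = ra.r24_autocorrelation(make_series(counts))
        a, b = counts[:-1440], counts[1440:]
        expect = np.corrcoef(a, b)[0, 1]
        assert got == pytest.approx(expect, abs=1e-12)
        assert -1.0 <= got <= 1.0

    def test_too_short_raises(self):
        with pytest.raises(SeriesTooShort):
            ra.r24_autocorrelation(make_series(np.ones(2000)))


class TestMeans:
    def test_mda_examples(self):
        assert ra.mean_daily_activity(make_series([0, 10, 20])) == 10.0
        assert ra.mean_daily_activity(make_series([7.0] * 50)) == 7.0

    def test_mda_ignores_missing(self, rng):
        counts = rng.integers(0, 100, 500).astype(float)
        counts[rng.choice(500, 100, replace=False)] = np.nan
        expect = np.mean([c for c in counts if not np.isnan(c)])
        assert ra.mean_daily_activity(make_series(counts)) == pytest.approx(expect)

    def test_wake_activity_single_span(self):
        s, sch = series_with_nights([[0, 0], [0, 0]], [[10, 10], [30, 30]])
        # span between the two nights holds the counts 30,30
        assert ra.mean_wake_activity(s, sch) == 30.0

    def test_wake_activity_pooled_spans(self, rng):
        in_blocks = [rng.integers(0, 5, 20).astype(float) for _ in range(3)]
        out_blocks = [rng.integers(0, 100, 30).astype(float) for _ in range(3)]
        s, sch = series_with_nights(in_blocks, out_blocks)
        # spans strictly between nights = out blocks 1 and 2 (not the first)
        expect = np.concatenate([out_blocks[1], out_blocks[2]]).mean()
        assert ra.mean_wake_activity(s, sch) == pytest.approx(expect)

    def test_wake_activity_needs_two_nights(self):
        s, sch = series_with_nights([[0, 0]], [[1, 2]])
        with pytest.raises(NoWakeSpan):
            ra.mean_wake_activity(s, sch)


class TestAnalysisSets:
    def _series_valid_days(self, day_flags):
        counts = []
        for ok in day_flags:
            block = np.ones(1440)
            if not ok:
                block[: int(1440 * 0.2)] = np.nan  # 80% non-missing < 90% threshold
            counts.append(block)
        return make_series(np.concatenate(counts))

    def diary(self, n):
        from restwatch.io_formats import DiaryNight

        return [DiaryNight("P01", i, 1380.0, 1390.0, 10.0, 20.0, 1.0, 400.0, 420.0)
                for i in range(n)]

    def test_per_protocol(self):
        s = self._series_valid_days([True] * 8)
        assert ra.qualify_analysis_set(s, None, self.diary(8)) == "per_protocol"

    def test_full_analysis(self):
        s = self._series_valid_days([True] * 4)
        assert ra.qualify_analysis_set(s, None, self.diary(4)) == "full_analysis"

    def test_excluded_below_threshold(self):
        s = self._series_valid_days([True, True])
        assert ra.qualify_analysis_set(s, None, self.diary(8)) == "excluded"

    def test_consecutive_requirement(self):
        # 2 valid, 1 invalid, 2 valid: longest run = 2 -> excluded
        s = self._series_valid_days([True, True, False, True, True])
        assert ra.qualify_analysis_set(s, None, self.diary(5)) == "excluded"

    def test_diary_needed_for_full_analysis(self):
        s = self._series_valid_days([True] * 4)
        assert ra.qualify_analysis_set(s, None, self.diary(2)) == "excluded"
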