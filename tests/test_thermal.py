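"""Running baseline, SIH metrics, cosinor fits and period summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from ovitherm import (
    BaselineTrace,
    cosinor_fit_day,
    cosinor_series,
    running_baseline,
    sih_metrics,
    summarise_periods,
)
from ovitherm.thermal import CosinorFit

from conftest import (
    cosine_trace,
    grid_search_cosinor,
    make_trace,
    naive_running_mean,
    naive_sih,
)

HW = pd.Timedelta(hours=6)
K = 72  # 6 h at 5-min spacing


class TestRunningBaseline:
    def test_constant_trace_gives_constant_baseline(self):
        tr = make_trace(np.full(600, 39.0))
        b = running_baseline(tr, HW)
        assert np.allclose(b.ts, 39.0)

    def test_symmetric_window_cancels_on_linear_ramp(self):
        tr = make_trace(39.0 + 0.001 * np.arange(500))
        b = running_baseline(tr, HW)
        interior = slice(K, 500 - K)
        assert np.allclose(b.ts[interior], tr.tc[interior], atol=1e-12)
        assert b.complete[interior].all()
        assert not b.complete[0] and not b.complete[-1]

    def test_matches_bruteforce_mean_including_edges(self, rng):
        tc = 39.0 + rng.normal(0, 0.2, size=3 * 288)
        tr = make_trace(tc)
        b = running_baseline(tr, HW)
        idx = np.concatenate([[0, 1, K - 1, K, len(tc) - 1],
                              rng.integers(0, len(tc), 20)])
        for i in idx:
            assert b.ts[i] == pytest.approx(naive_running_mean(tc, K, int(i)),
                                            abs=1e-9)

    def test_half_window_must_align_with_grid(self):
        tr = make_trace(np.full(300, 39.0))
        with pytest.raises(ValueError, match="multiple of the sampling interval"):
            running_baseline(tr, pd.Timedelta(minutes=7))


class TestSIHMetrics:
    def _flat_baseline(self, tr, offset=0.0):
        return BaselineTrace(timestamps=tr.timestamps, ts=tr.tc - offset,
                             complete=np.ones(len(tr), dtype=bool))

    def test_zero_deviation_gives_zero_auc_and_amplitude(self):
        tr = make_trace(np.full(600, 39.0))
        m = sih_metrics(tr, self._flat_baseline(tr), tr.timestamps[300])
        assert m.auc == 0.0 and m.amplitude == 0.0
        assert m.duration_minutes == 0.0  # deviation never turns positive

    def test_constant_half_degree_deviation(self):
        # d_k = +0.5 for each of the 10 window samples -> 25 degC.min
        tr = make_trace(np.full(600, 39.0))
        m = sih_metrics(tr, self._flat_baseline(tr, offset=0.5), tr.timestamps[300])
        assert m.auc == pytest.approx(25.0)
        assert m.amplitude == pytest.approx(0.5)
        assert m.n_samples == 10
        assert m.duration_minutes == 50.0  # never returns: censored

    def test_auc_keeps_sign_below_baseline(self):
        tr = make_trace(np.full(600, 39.0))
        m = sih_metrics(tr, self._flat_baseline(tr, offset=-0.2), tr.timestamps[300])
        assert m.auc == pytest.approx(-10.0)
        assert m.amplitude == pytest.approx(-0.2)

    def test_matches_bruteforce_on_noisy_trace(self, rng):
        tc = 39.0 + rng.normal(0, 0.15, size=3 * 288)
        tr = make_trace(tc)
        b = running_baseline(tr, HW)
        start = tr.timestamps[400]
        m = sih_metrics(tr, b, start, event_label="e")
        auc, amp = naive_sih(tc, tr.timestamps, K, start, 50, 5)
        assert m.auc == pytest.approx(auc, abs=1e-9)
        assert m.amplitude == pytest.approx(amp, abs=1e-9)

    def test_window_beyond_trace_names_event(self):
        tr = make_trace(np.full(600, 39.0))
        with pytest.raises(ValueError, match="arena"):
            sih_metrics(tr, self._flat_baseline(tr), tr.timestamps[-3],
                        event_label="arena")

    def test_incomplete_baseline_in_window_rejected(self):
        tr = make_trace(np.full(600, 39.0))
        b = running_baseline(tr, HW)  # first K samples are edge-truncated
        with pytest.raises(ValueError, match="edge-truncated"):
            sih_metrics(tr, b, tr.timestamps[10], event_label="early")

    def test_shift_invariance(self, rng):
        tc = 39.0 + rng.normal(0, 0.1, size=3 * 288)
        tr1, tr2 = make_trace(tc), make_trace(tc + 1.7)
        s = tr1.timestamps[500]
        m1 = sih_metrics(tr1, running_baseline(tr1, HW), s)
        m2 = sih_metrics(tr2, running_baseline(tr2, HW), s)
        assert m1.auc == pytest.approx(m2.auc, abs=1e-9)
        assert m1.amplitude == pytest.approx(m2.amplitude, abs=1e-9)


class TestCosinorFit:
    def test_noise_free_cosine_recovered_exactly(self):
        tr = cosine_trace(39.0, 0.4, 18.0, days=1)
        f = cosinor_fit_day(tr, tr.timestamps[0])
        assert f.mesor == pytest.approx(39.0, abs=1e-6)
        assert f.amplitude == pytest.approx(0.4, abs=1e-6)
        assert f.acrophase_hours == pytest.approx(18.0, abs=1e-6)
        assert f.rss == pytest.approx(0.0, abs=1e-9)
        assert f.cosinor_min == pytest.approx(38.6, abs=1e-6)
        assert f.cosinor_max == pytest.approx(39.4, abs=1e-6)

    def test_constant_trace_degenerate(self):
        tr = make_trace(np.full(288, 38.5))
        f = cosinor_fit_day(tr, tr.timestamps[0])
        assert f.mesor == pytest.approx(38.5, abs=1e-9)
        assert f.amplitude == pytest.approx(0.0, abs=1e-9)
        assert math.isnan(f.acrophase_hours)
        assert f.rss == pytest.approx(0.0, abs=1e-12)

    def test_matches_grid_search_oracle_on_noisy_day(self, rng):
        noise = rng.normal(0, 0.08, size=288)
        tr = cosine_trace(39.1, 0.35, 20.5, days=1, noise=noise)
        f = cosinor_fit_day(tr, tr.timestamps[0])
        t_h = np.arange(288) * 5 / 60.0
        oracle = grid_search_cosinor(t_h, tr.tc, phase_step_h=0.002)
        assert f.mesor == pytest.approx(oracle["mesor"], abs=1e-4)
        assert f.amplitude == pytest.approx(oracle["amplitude"], abs=1e-4)
        assert f.acrophase_hours == pytest.approx(oracle["acrophase"], abs=0.002)
        assert f.rss <= oracle["rss"] + 1e-9

    def test_shift_in_trace_level_shifts_mesor_only(self, rng):
        noise = rng.normal(0, 0.05, size=288)
        tr1 = cosine_trace(39.0, 0.3, 15.0, days=1, noise=noise)
        tr2 = make_trace(tr1.tc + 2.0)
        f1 = cosinor_fit_day(tr1, tr1.timestamps[0])
        f2 = cosinor_fit_day(tr2, tr2.timestamps[0])
        assert f2.mesor - f1.mesor == pytest.approx(2.0, abs=1e-9)
        assert f2.amplitude == pytest.approx(f1.amplitude, abs=1e-9)
        assert f2.acrophase_hours == pytest.approx(f1.acrophase_hours, abs=1e-9)

    def test_too_few_samples_flagged(self):
        tr = make_trace(np.full(288, 39.0))
        f = cosinor_fit_day(tr, tr.timestamps[0] + pd.Timedelta(days=5))
        assert f.flagged and "fewer than 3" in f.flag_reason


class TestCosinorSeries:
    def test_ten_complete_days_give_ten_fits(self):
        tr = cosine_trace(days=10)
        assert len(cosinor_series(tr)) == 10

    def test_partial_boundary_days_skipped(self):
        # starts 06:00, spans 48 h -> only one complete civil day
        tr = cosine_trace(days=2, start="2024-01-01 06:00")
        fits = cosinor_series(tr)
        assert len(fits) == 1
        assert fits[0].day_start == pd.Timestamp("2024-01-02")

    def test_identical_days_give_identical_fits(self):
        tr = cosine_trace(days=4)
        fits = cosinor_series(tr)
        for f in fits[1:]:
            assert f.mesor == pytest.approx(fits[0].mesor, abs=1e-9)
            assert f.amplitude == pytest.approx(fits[0].amplitude, abs=1e-9)
            assert f.acrophase_hours == pytest.approx(
                fits[0].acrophase_hours, abs=1e-9)


def _fit(day, mesor=39.0, amp=0.3, animal="X-01", flagged=False):
    return CosinorFit(animal_id=animal, day_start=pd.Timestamp(day),
                      mesor=mesor, amplitude=amp, acrophase_hours=18.0,
                      cosinor_min=mesor - amp, cosinor_max=mesor + amp,
                      rss=0.0, n_samples=288, flagged=flagged)


class TestPeriodSummaries:
    DAYS = [pd.Timestamp("2024-01-01") + pd.Timedelta(days=d) for d in range(3)]

    def test_mean_of_identical_fits_equals_each(self):
        fits = [_fit(d) for d in self.DAYS]
        (s,) = summarise_periods(fits, {"P1": self.DAYS})
        assert s.mesor == pytest.approx(39.0)
        assert s.amplitude == pytest.approx(0.3)
        assert s.n_days == 3 and not s.flagged

    def test_amplitude_mean_is_arithmetic(self):
        fits = [_fit(d, amp=a) for d, a in zip(self.DAYS, (0.2, 0.3, 0.4))]
        (s,) = summarise_periods(fits, {"P1": self.DAYS})
        assert s.amplitude == pytest.approx(0.3)

    def test_missing_day_flags_summary(self):
        fits = [_fit(d) for d in self.DAYS[:2]]
        (s,) = summarise_periods(fits, {"P1": self.DAYS})
        assert s.flagged and "missing" in s.flag_reason and s.n_days == 2

    def test_flagged_day_flags_summary(self):
        fits = [_fit(d) for d in self.DAYS[:2]] + [_fit(self.DAYS[2], flagged=True)]
        (s,) = summarise_periods(fits, {"P1": self.DAYS})
        assert s.flagged and "flagged" in s.flag_reason
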