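"""Burst segmentation at the 40 % trough-to-peak level and cycle metrics."""

import numpy as np
import pytest
from scipy.optimize import brentq

from locorhythm import bursts as br
from locorhythm.core import epoch_of

from conftest import envelope_from

FS = 1000.0   # dense sampling for analytic waveform checks


def triangle_burst(base=2.0, fs=FS, pad=3.0):
    """Symmetric triangle: trough 0, peak 1, total width ``base``."""
    t = np.arange(int((base + 2 * pad) * fs)) / fs
    x = np.maximum(0.0, 1.0 - np.abs(t - (pad + base / 2)) / (base / 2))
    return t, x


class TestBounds:
    def test_triangle_duration_is_0p6_base_exactly(self):
        base = 2.0
        t, x = triangle_burst(base)
        onset, offset = br.burst_bounds(x, 3.0, 3.0 + base / 2, fs=FS)
        assert offset - onset == pytest.approx(0.6 * base, abs=2e-3)

    def test_square_pulse_duration_is_width_for_any_threshold(self):
        fs, w = FS, 1.5
        t = np.arange(int(8 * fs)) / fs
        x = ((t >= 3.0) & (t < 3.0 + w)).astype(float)
        for thr in (0.1, 0.4, 0.9):
            onset, offset = br.burst_bounds(x, 2.0, 3.0 + w / 2, fs=fs,
                                            threshold_fraction=thr)
            assert offset - onset == pytest.approx(w, abs=2 / fs)

    def test_half_sine_duration_matches_root_finding_oracle(self):
        base = 2.0
        fs = FS
        t = np.arange(int(8 * fs)) / fs
        x = np.where((t >= 3.0) & (t <= 3.0 + base),
                     np.sin(np.pi * (t - 3.0) / base), 0.0)
        onset, offset = br.burst_bounds(x, 2.0, 3.0 + base / 2, fs=fs)
        # oracle: numerical root-finding on the dense waveform
        t_on = brentq(lambda u: np.sin(np.pi * u / base) - 0.4, 0, base / 2)
        dur_oracle = base - 2 * t_on
        assert abs((offset - onset) - dur_oracle) < 1e-3
        # closed form: B * (1 - 2 asin(0.4)/pi) ~ 0.738 B
        assert dur_oracle == pytest.approx(base * (1 - 2 * np.arcsin(0.4) / np.pi),
                                           abs=1e-9)

    def test_flat_top_degenerate_cycle_is_skipped(self):
        x = np.ones(1000)
        with pytest.raises(br.CycleSkipped):
            br.burst_bounds(x, 0.1, 0.5, fs=FS)

    def test_bad_threshold_and_order_rejected(self):
        t, x = triangle_burst()
        with pytest.raises(ValueError, match="threshold"):
            br.burst_bounds(x, 3.0, 4.0, fs=FS, threshold_fraction=1.2)
        with pytest.raises(ValueError, match="precede"):
            br.burst_bounds(x, 4.0, 3.0, fs=FS)


class TestDetect:
    def test_constant_envelope_gives_empty_list(self):
        assert br.detect_cycles(np.full(2000, 2.5), fs=19.0) == []

    def test_raised_cosine_train_count_and_peak_times(self):
        fs, f = 19.0, 0.3
        t = np.arange(int(80 * fs)) / fs
        x = 0.5 * (1 - np.cos(2 * np.pi * f * t))
        pairs = br.detect_cycles(x, fs=fs, min_period=0.5 / f)
        interior = [p for p in pairs if 10 < p[1] < 70]
        assert 17 <= len(pairs) <= 18 or 16 <= len(interior) <= 18
        # peak times sit at the cosine maxima within one sample
        for _, pk in pairs:
            k = round(pk * f - 0.5)
            assert abs(pk - (k + 0.5) / f) <= 1.5 / fs

    def test_programmed_burst_count_recovered_from_noisy_envelope(self):
        rng = np.random.default_rng(2)
        fs, f, duty = 19.0, 0.25, 0.5
        t = np.arange(int(50 * fs)) / fs   # 12 full cycles + margin
        phase = (f * t) % 1.0
        x = ((phase < duty).astype(float)
             * (1 + 0.1 * rng.standard_normal(t.size)))
        x += 0.03 * rng.standard_normal(t.size)
        pairs = br.detect_cycles(x, fs=fs, min_period=0.5 / f,
                                 smooth_seconds=0.3)
        assert len(pairs) == 11   # 12 bursts; edge-partial peaks dropped


class TestMetrics:
    @staticmethod
    def _square_env(period=10.0, high=6.0, fs=19.0, dur=120.0, amp=1.0,
                    epochs=None):
        t = np.arange(int(dur * fs)) / fs
        phase = (t % period) / period
        x = amp * 0.5 * (1 - np.cos(2 * np.pi * np.clip(phase / (high / period),
                                                        0, 1)))
        # smooth-edged pulse of duty high/period (raised-cosine body)
        x = amp * ((phase < high / period).astype(float))
        return envelope_from(x, fs, epochs=epochs)

    def test_square_envelope_duty_0p6(self):
        env = self._square_env()
        tab = br.analyze_channel(env, 0, min_period=5.0, smooth_seconds=0.0,
                                 extremum_halfwidth=0)
        duties = tab["duty_cycle"].dropna()
        assert len(duties) >= 8
        assert np.allclose(duties, 0.600, atol=0.01)

    def test_duration_plus_interval_equals_period(self, wholecord_trial):
        env = wholecord_trial["env19"]
        tab = br.analyze_channel(env, 0, min_period=1.5)
        ok = tab.dropna(subset=["period"])
        assert len(ok) > 10
        assert np.allclose(ok.burst_duration + ok.interburst_interval,
                           ok.period, atol=1e-9)
        assert ((ok.duty_cycle > 0) & (ok.duty_cycle < 1)).all()
        assert (ok.onset_time < ok.peak_time).all()
        assert (ok.peak_time < ok.offset_time).all()

    def test_amplitude_invariant_under_additive_offset(self):
        env1 = self._square_env()
        env2 = self._square_env()
        env2.env = env2.env + 5.0
        t1 = br.analyze_channel(env1, 0, min_period=5.0, smooth_seconds=0.0,
                                extremum_halfwidth=0)
        t2 = br.analyze_channel(env2, 0, min_period=5.0, smooth_seconds=0.0,
                                extremum_halfwidth=0)
        assert np.allclose(t1.amplitude, t2.amplitude, atol=1e-9)

    def test_duty_invariant_under_time_rescaling(self):
        a = br.analyze_channel(self._square_env(period=10.0, high=6.0), 0,
                               min_period=5.0, smooth_seconds=0.0,
                               extremum_halfwidth=0)
        b = br.analyze_channel(self._square_env(period=5.0, high=3.0,
                                                dur=60.0), 0,
                               min_period=2.5, smooth_seconds=0.0,
                               extremum_halfwidth=0)
        assert abs(a.duty_cycle.dropna().mean()
                   - b.duty_cycle.dropna().mean()) < 0.01

    def test_single_cycle_has_duration_but_no_interval(self):
        bounds = [(1.0, 2.0)]
        cycles = [(0.5, 1.5)]
        tab = br.burst_metrics(bounds, cycles, peak_values=np.array([1.0]),
                               trough_values=np.array([0.0]))
        row = tab.iloc[0]
        assert row.burst_duration == 1.0 and row.amplitude == 1.0
        assert np.isnan(row.interburst_interval) and np.isnan(row.duty_cycle)


class TestRandomizedRecovery:
    def test_duty_bias_and_count_on_random_envelopes(self):
        # randomized duty 0.2-0.8, frequency 0.1-0.9 Hz, SNR = 5, random
        # phase; counted inside the interior window (edge partials excluded)
        rng = np.random.default_rng(12345)
        biases, count_errors = [], 0
        n_draws = 1000
        for _ in range(n_draws):
            f = rng.uniform(0.1, 0.9)
            duty = rng.uniform(0.2, 0.8)
            fs, dur = 50.0, 60.0
            t = np.arange(int(dur * fs)) / fs
            u = rng.uniform()
            x = (((f * t + u) % 1.0) < duty).astype(float)
            y = np.abs(x * (1 + rng.standard_normal(t.size) / 5.0)) \
                + 0.02 * np.abs(rng.standard_normal(t.size))
            tab = br.analyze_channel(envelope_from(y, fs), 0,
                                     min_period=0.5 / f,
                                     smooth_seconds=min(0.3, 0.15 / f),
                                     extremum_halfwidth=1)
            ks = np.arange(np.ceil(u - duty / 2),
                           np.floor(f * dur + u - duty / 2))
            tpk = (ks - u + duty / 2) / f
            tpk = tpk[(tpk > 0) & (tpk < dur)]
            w0, w1 = tpk[1] - 0.4 / f, tpk[-2] + 0.4 / f
            n_true = int(((tpk >= w0) & (tpk <= w1)).sum())
            n_det = int(((tab.peak_time >= w0) & (tab.peak_time <= w1)).sum())
            count_errors += int(n_det != n_true)
            duties = tab["duty_cycle"].dropna()
            if len(duties):
                biases.append(duties.mean() - duty)
        assert count_errors == 0
        assert abs(np.mean(biases)) < 0.02

    def test_crossings_agree_with_dense_exhaustive_scan(self):
        # brute-force oracle: first/last sample-level crossing on a dense
        # noiseless waveform must match the interpolated crossing to < 1 ms
        fs = 10_000.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(np.pi * np.clip((t - 3) / 4, 0, 1)) ** 1.3
        onset, offset = br.burst_bounds(x, 2.0, 5.0, fs=fs)
        level = 0.4 * x[int(5 * fs)]
        above = x >= level
        onset_scan = t[np.flatnonzero(~above[:-1] & above[1:])[0] + 1]
        offset_scan = t[np.flatnonzero(above[:-1] & ~above[1:])[-1]]
        assert abs(onset - onset_scan) < 1e-3
        assert abs(offset - offset_scan) < 1e-3


class TestEpochSummary:
    @staticmethod
    def _tab(dur_pre, dur_light, channel="ch"):
        rows = []
        t = 0.0
        for epoch, dur, n in (("pre", dur_pre, 10), ("light", dur_light, 10)):
            for _ in range(n):
                rows.append({"channel": channel, "epoch": epoch,
                             "trough_time": t, "peak_time": t + dur / 2,
                             "onset_time": t, "offset_time": t + dur,
                             "burst_duration": dur,
                             "interburst_interval": dur,
                             "amplitude": 1.0, "period": 2 * dur,
                             "duty_cycle": 0.5})
                t += 2 * dur
        import pandas as pd
        return pd.DataFrame(rows)

    def test_identical_epochs_give_zero_change(self):
        summ = br.epoch_summary([self._tab(1.0, 1.0)], epochs=("pre", "light"))
        assert np.allclose(summ["burst_duration_pct_change"], 0.0, atol=1e-9)

    def test_forty_percent_longer_bursts_report_plus_forty(self):
        summ = br.epoch_summary([self._tab(1.0, 1.4)], epochs=("pre", "light"))
        light = summ[summ.epoch == "light"].iloc[0]
        assert light["burst_duration_pct_change"] == pytest.approx(40.0, abs=1e-9)

    def test_trial_without_baseline_cycles_is_excluded(self, caplog):
        good = self._tab(1.0, 1.2)
        bad = good[good.epoch == "light"].reset_index(drop=True)
        summ = br.epoch_summary([good, bad], epochs=("pre", "light"))
        light = summ[summ.epoch == "light"].iloc[0]
        assert light["burst_duration_pct_change"] == pytest.approx(20.0, abs=1e-9)

    def test_all_trials_without_baseline_is_error(self):
        bad = self._tab(1.0, 1.2)
        bad = bad[bad.epoch == "light"].reset_index(drop=True)
        with pytest.raises(ValueError, match="pre"):
            br.epoch_summary([bad], epochs=("pre", "light"))
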