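"""ROI geometry, trace conditioning chain, and calcium cycle averages."""

import numpy as np
import pytest

from locorhythm import calcium as ca
from locorhythm import synthetic as syn
from locorhythm.synthetic import Protocol


def trace(values, frame_rate=6.0, **kw):
    v = np.asarray(values, dtype=float)
    return ca.CalciumTrace(values=v, frame_times=np.arange(v.size) / frame_rate,
                           **kw)


class TestRois:
    def test_600_field_gives_six_100_tall_bands(self):
        rs = ca.make_grid_rois((600, 600))
        assert len(rs.masks) == 6
        for m in rs.masks.values():
            assert m.sum() == 600 * 100

    def test_indivisible_height_goes_to_last_roi(self):
        rs = ca.make_grid_rois((601, 600))
        sizes = [int(m.sum(axis=0).max()) for m in rs.masks.values()]
        assert sizes[:5] == [100] * 5 and sizes[5] == 101

    def test_grid_tiles_field_without_overlap(self):
        rs = ca.make_grid_rois((64, 48))
        total = np.zeros((64, 48), dtype=int)
        for m in rs.masks.values():
            total += m
        assert (total == 1).all()

    def test_doughnut_excludes_cell_and_neighbors(self):
        other = np.zeros((64, 64), dtype=bool)
        other[30:40, 38:48] = True
        rs = ca.make_cell_roi((64, 64), (32, 32), 5, others=[other])
        assert not (rs.masks["cell"] & rs.masks["doughnut"]).any()
        assert not (rs.masks["doughnut"] & other).any()
        assert rs.masks["doughnut"].any()

    def test_field_too_short_is_error(self):
        with pytest.raises(ValueError):
            ca.make_grid_rois((4, 100))


class TestExtract:
    def test_uniform_frames_give_constant_trace(self):
        stack = np.full((10, 8, 8), 7.0)
        roi = np.ones((8, 8), dtype=bool)
        tr = ca.extract_trace(stack, roi, 4.0)
        assert np.allclose(tr.values, 7.0)

    def test_single_bright_pixel_contributes_v_over_n(self):
        stack = np.zeros((3, 8, 8))
        stack[:, 2, 2] = 64.0
        roi = np.zeros((8, 8), dtype=bool)
        roi[:4, :4] = True          # 16 pixels
        tr = ca.extract_trace(stack, roi, 4.0)
        assert np.allclose(tr.values, 64.0 / 16)

    def test_empty_roi_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            ca.extract_trace(np.zeros((3, 8, 8)), np.zeros((8, 8), bool), 4.0)

    def test_extracted_trace_tracks_clean_cell_trace(self):
        proto = Protocol(total_duration=60.0)
        stack, truth = syn.simulate_calcium(
            proto, [((20, 20), 4, 0.8, 0.0)], neuropil_amplitude=0.0,
            bleach=(0.0, 10.0), frame_rate=6.0, seed=2, field_shape=(48, 48),
            noise_scale=1.0)
        rs = ca.make_cell_roi((48, 48), (20, 20), 4)
        tr = ca.extract_trace(stack, rs.masks["cell"], 6.0)
        r = np.corrcoef(tr.values, truth.cell_traces[0])[0, 1]
        assert r > 0.95


class TestDoughnut:
    def test_identical_traces_cancel(self):
        a = trace(np.array([5.0, 6.0, 7.0]))
        out = ca.doughnut_subtract(a, trace(np.array([5.0, 6.0, 7.0])))
        assert np.allclose(out.values, 0.0)
        assert out.state["neuropil_subtracted"]

    def test_linearity_recovers_residual_exactly(self):
        rng = np.random.default_rng(0)
        d = rng.random(50)
        r = rng.random(50)
        out = ca.doughnut_subtract(trace(d + r), trace(d))
        assert np.allclose(out.values, r, atol=1e-12)

    def test_subtraction_improves_correlation_with_true_signal(self):
        proto = Protocol(total_duration=90.0)
        stack, truth = syn.simulate_calcium(
            proto, [((24, 24), 4, 0.4, 180.0)], neuropil_amplitude=0.6,
            bleach=(0.0, 10.0), frame_rate=6.0, seed=4, field_shape=(48, 48),
            noise_scale=0.5)
        rs = ca.make_cell_roi((48, 48), (24, 24), 5)
        cell = ca.extract_trace(stack, rs.masks["cell"], 6.0)
        ring = ca.extract_trace(stack, rs.masks["doughnut"], 6.0)
        sub = ca.doughnut_subtract(cell, ring)
        r_raw = np.corrcoef(cell.values, truth.cell_traces[0])[0, 1]
        r_sub = np.corrcoef(sub.values, truth.cell_traces[0])[0, 1]
        assert r_sub > r_raw

    def test_frame_grid_mismatch_is_error(self):
        with pytest.raises(ValueError, match="frame grid"):
            ca.doughnut_subtract(trace(np.ones(5)), trace(np.ones(6)))


class TestBleach:
    def test_pure_exponential_fully_removed(self):
        t = np.arange(0, 120, 1 / 6)
        a = 30.0
        y = 100 + a * np.exp(-t / 40.0)
        out = ca.bleach_correct(trace(y))
        assert np.ptp(out.values) < 0.01 * a

    def test_tau_recovered_and_sinusoid_preserved(self):
        t = np.arange(0, 120, 1 / 6)
        y = 100 + 30 * np.exp(-t / 40.0) + 5 * np.sin(2 * np.pi * 0.3 * t)
        out = ca.bleach_correct(trace(y))
        assert abs(out.bleach_fit["tau"] / 40.0 - 1) < 0.10
        X = np.column_stack([np.sin(2 * np.pi * 0.3 * t),
                             np.cos(2 * np.pi * 0.3 * t), np.ones_like(t)])
        coef, *_ = np.linalg.lstsq(X, out.values, rcond=None)
        assert abs(np.hypot(coef[0], coef[1]) / 5.0 - 1) < 0.05

    def test_constant_input_passes_through(self):
        out = ca.bleach_correct(trace(np.full(30, 42.0)))
        assert np.allclose(out.values, 42.0)

    def test_too_few_frames_is_error(self):
        with pytest.raises(ValueError, match="frames"):
            ca.bleach_correct(trace(np.ones(10)))


class TestDff:
    def test_printed_formula_example(self):
        out = ca.dff(trace(np.array([2.0, 1.0, 3.0])))
        assert np.allclose(out.values, [100.0, 0.0, 200.0])
        assert out.f0 == 1.0

    def test_constant_trace_gives_zeros(self):
        out = ca.dff(trace(np.full(10, 3.3)))
        assert np.allclose(out.values, 0.0)

    def test_scale_invariance(self):
        v = np.array([2.0, 1.0, 3.0, 1.5])
        a = ca.dff(trace(v)).values
        b = ca.dff(trace(7.0 * v)).values
        assert np.allclose(a, b)

    def test_nonpositive_minimum_is_error(self):
        with pytest.raises(ValueError, match="f0"):
            ca.dff(trace(np.array([1.0, 0.0, 2.0])))


class TestBandpass:
    def test_inband_tone_passes_and_out_of_band_attenuated(self):
        fr = 16.0
        t = np.arange(0, 200, 1 / fr)
        for f, check in ((0.3, lambda g: g >= 0.95), (2.0, lambda g: g <= 0.1)):
            y = np.sin(2 * np.pi * f * t)
            out = ca.bandpass_ca(trace(10 + y, frame_rate=fr))
            sel = slice(int(20 * fr), int(180 * fr))
            gain = np.ptp(out.values[sel]) / 2.0
            assert check(gain), (f, gain)

    def test_out_of_band_attenuation_matches_designed_response(self):
        # oracle: the designed transfer function, squared for zero-phase use;
        # the tone amplitude is measured by projection so slow edge
        # transients of the 0.05 Hz pole do not contaminate it
        from scipy import signal as sg
        fr = 16.0
        sos = sg.butter(4, (0.05, 0.8), btype="bandpass", fs=fr, output="sos")
        _, h = sg.sosfreqz(sos, worN=[2.0 / (fr / 2) * np.pi])
        expected_gain = np.abs(h[0]) ** 2
        t = np.arange(0, 400, 1 / fr)
        out = ca.bandpass_ca(trace(10 + np.sin(2 * np.pi * 2.0 * t),
                                   frame_rate=fr))
        sel = slice(int(100 * fr), int(300 * fr))
        X = np.column_stack([np.sin(2 * np.pi * 2.0 * t[sel]),
                             np.cos(2 * np.pi * 2.0 * t[sel])])
        coef, *_ = np.linalg.lstsq(X, out.values[sel], rcond=None)
        gain = float(np.hypot(*coef))
        assert gain <= 0.1           # attenuated far beyond 10x
        assert gain == pytest.approx(expected_gain, rel=0.5, abs=1e-3)

    def test_dc_removed(self):
        out = ca.bandpass_ca(trace(np.full(600, 50.0) +
                                   np.sin(np.arange(600) * 0.3)))
        assert abs(out.values.mean()) < 0.5

    def test_low_frame_rate_rejected(self):
        with pytest.raises(ValueError, match="frame rate"):
            ca.bandpass_ca(trace(np.ones(100), frame_rate=1.0))


class TestOrderContract:
    def test_neuropil_after_bleach_rejected(self):
        a = ca.bleach_correct(trace(100 + np.exp(-np.arange(60) / 10.0)))
        with pytest.raises(ValueError, match="order"):
            ca.doughnut_subtract(a, trace(np.zeros(60)))

    def test_double_dff_rejected(self):
        out = ca.dff(trace(np.array([2.0, 1.0, 3.0])))
        out.values = out.values + 1.0
        with pytest.raises(ValueError, match="already"):
            ca.dff(out)

    def test_bandpass_then_dff_rejected(self):
        fr = 16.0
        t = np.arange(0, 100, 1 / fr)
        bp = ca.bandpass_ca(trace(10 + np.sin(2 * np.pi * 0.3 * t),
                                  frame_rate=fr))
        bp.values = bp.values + 10.0
        with pytest.raises(ValueError, match="order"):
            ca.dff(bp)


class TestCTA:
    @staticmethod
    def _movie(phases, seed=0, noise=1.0, duration=80.0):
        proto = Protocol(total_duration=duration)
        cells = [((16 + 20 * k, 16 + 20 * k), 3, 0.8, ph)
                 for k, ph in enumerate(phases)]
        return syn.simulate_calcium(proto, cells, neuropil_amplitude=0.1,
                                    bleach=(0.2, 40.0), frame_rate=6.0,
                                    seed=seed, field_shape=(56, 56),
                                    noise_scale=noise)

    @staticmethod
    def _process(stack, center):
        rs = ca.make_cell_roi(stack.shape[1:], center, 4)
        cell = ca.extract_trace(stack, rs.masks["cell"], 6.0)
        ring = ca.extract_trace(stack, rs.masks["doughnut"], 6.0)
        return ca.bandpass_ca(ca.dff(ca.bleach_correct(
            ca.doughnut_subtract(cell, ring))))

    def test_in_and_antiphase_cells_classified_by_cta(self):
        stack, truth = self._movie([0.0, 180.0], seed=1)
        f = truth.base_frequency
        # reference rhythm (phase 0) has its troughs at integer cycles
        onsets = np.arange(1 / f, 78.0, 1 / f)
        peak_phases = []
        for center in ((16, 16), (36, 36)):
            tr = self._process(stack, center)
            cta = ca.ca_cycle_triggered_average(tr, onsets)
            half = cta.mean[:len(cta.mean) // 2]
            peak_phases.append(cta.phase[int(np.argmax(half))])
        # in-phase cell peaks mid-cycle; anti-phase cell peaks at the edges
        assert abs(peak_phases[0] - 0.5) < 0.15
        assert min(peak_phases[1], 1 - peak_phases[1]) < 0.15

    def test_antiphase_cell_trough_at_reference_peak(self):
        stack, truth = self._movie([180.0], seed=2, noise=0.0)
        f = truth.base_frequency
        onsets = np.arange(1 / f, 78.0, 1 / f)
        tr = self._process(stack, (16, 16))
        cta = ca.ca_cycle_triggered_average(tr, onsets)
        half = cta.mean[:len(cta.mean) // 2]
        trough_phase = cta.phase[int(np.argmin(half))]
        assert abs(trough_phase - 0.5) < 0.1   # reference peaks mid-cycle

    def test_nonrhythmic_cell_below_shuffle_floor(self):
        rng = np.random.default_rng(9)
        stack, truth = self._movie([0.0], seed=3)
        f = truth.base_frequency
        tr = self._process(stack, (16, 16))
        # zero out the rhythm by shuffling frames in time for the "cell"
        flat = trace(rng.permutation(tr.values))
        onsets = np.arange(1.0, 78.0, 1 / f)
        cta_locked = ca.ca_cycle_triggered_average(tr, onsets)
        # cycle-shuffled surrogate oracle: CTA amplitude on shuffled onsets
        amps = []
        for _ in range(20):
            jitter = rng.uniform(0, 1 / f, onsets.size)
            amps.append(ca.ca_cycle_triggered_average(
                flat, np.sort(onsets + jitter)).amplitude)
        floor = np.percentile(amps, 95)
        assert cta_locked.amplitude > floor
        assert ca.ca_cycle_triggered_average(flat, onsets).amplitude < 3 * floor

    def test_too_few_cycles_is_error(self):
        tr = trace(np.sin(np.arange(100) * 0.1))
        with pytest.raises(ValueError, match="cycles"):
            ca.ca_cycle_triggered_average(tr, np.array([1.0, 5.0]))
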