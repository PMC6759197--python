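"""Wavelet spectrograms and frequency / phase time series of the rhythm.

The integrated envelopes are transformed with a complex Morlet continuous
wavelet transform on a log-spaced frequency grid; the time axis is binned to
3,200 points over the analysis window.  The rhythm frequency is the ridge
(per-bin magnitude argmax over the band, median-smoothed), inter-channel
phase is the argument of the cross-wavelet coefficient at the reference
channel's ridge, 10 s of edge-effect bins are trimmed, and series are
normalized as percent change from the pre-light baseline.  A tonic-segment
detector flags elevated, non-oscillating stretches so frequency statistics
can be restricted to the rhythmically active part of the signal.

Mother-wavelet choice: complex Morlet with center-frequency parameter 6
(``cmor2.0-0.9549`` in PyWavelets' bandwidth-center parameterization), the
standard compromise between time and frequency resolution for rhythm
tracking in this band.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

from .core import IntegratedNeurogram, RhythmSeries, Spectrogram, TonicMask, wrap_deg

__all__ = [
    "wavelet_spectrogram",
    "extract_frequency",
    "extract_phase",
    "trim_edges",
    "normalize_percent_change",
    "envelope_series",
    "flag_tonic",
    "RHYTHM_BANDS",
    "MORLET",
    "N_TIME_BINS",
]

#: analysis band (Hz) per episode mode: brackets all expected rhythm
#: frequencies (~0.1-0.9 Hz) with margin
RHYTHM_BANDS = {"drug": (0.05, 2.0), "evoked": (0.2, 4.0)}

#: complex Morlet, bandwidth 2.0, center 0.9549 cycles (= omega0 of 6)
MORLET = "cmor2.0-0.9549"

#: time bins of every spectrogram before edge trimming
N_TIME_BINS = 3200


def wavelet_spectrogram(
    env: IntegratedNeurogram,
    channel: str | int = 0,
    band: tuple[float, float] | None = None,
    n_freqs: int = 300,
    n_times: int = N_TIME_BINS,
    wavelet: str = MORLET,
) -> Spectrogram:
    """Complex CWT of one envelope channel, binned to ``n_times`` time points."""
    band = band or RHYTHM_BANDS[env.mode]
    if env.duration < 3.0 / band[0]:
        raise ValueError(
            f"duration {env.duration:.1f} s too short for the lowest analyzed "
            f"frequency {band[0]} Hz (need >= 3 periods)")
    idx = env.channel_index(channel) if isinstance(channel, str) else channel
    x = env.env[idx]
    freqs = np.geomspace(band[0], band[1], n_freqs)
    # scale = C * fs / f with the wavelet's exact center frequency; pywt's
    # numeric central_frequency() is FFT-bin quantized (~2 % off), which
    # would bias every ridge frequency by the same factor
    if wavelet.startswith("cmor"):
        center = float(wavelet[4:].split("-")[1])
    else:
        center = pywt.central_frequency(wavelet, precision=14)
    scales = center / (freqs / env.fs)
    W, _ = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / env.fs,
                    method="fft")
    # L1 renormalization: equal-amplitude tones get equal ridge magnitude
    # across scales, so the band argmax is not biased toward low frequencies
    W /= np.sqrt(scales)[:, None]
    t_in = np.arange(x.size) / env.fs
    t_out = np.linspace(t_in[0], t_in[-1], n_times)
    Wi = np.empty((n_freqs, n_times), dtype=complex)
    for i in range(n_freqs):
        Wi[i] = np.interp(t_out, t_in, W[i].real) \
            + 1j * np.interp(t_out, t_in, W[i].imag)
    return Spectrogram(
        W=Wi, freqs=freqs, times=t_out,
        channel=env.channels[idx].name, epochs=dict(env.epochs),
        params={"wavelet": wavelet, "band": tuple(band), "n_freqs": n_freqs,
                "envelope_fs": env.fs, "mode": env.mode},
    )


def _ridge(spec: Spectrogram) -> tuple[np.ndarray, np.ndarray]:
    """(row indices, missing mask) of the per-bin magnitude ridge."""
    mag = np.abs(spec.W)
    missing = mag.max(axis=0) <= 0
    return mag.argmax(axis=0), missing


def extract_frequency(spec: Spectrogram, smooth_bins: int = 5) -> RhythmSeries:
    """Ridge frequency time series (Hz); all-zero columns become missing."""
    idx, missing = _ridge(spec)
    f = spec.freqs[idx].astype(float)
    if smooth_bins > 1:
        f = ndimage.median_filter(f, size=smooth_bins, mode="nearest")
    f[missing] = np.nan
    return RhythmSeries(values=f, times=spec.times.copy(), kind="frequency",
                        units="Hz", channel=spec.channel,
                        epochs=dict(spec.epochs),
                        meta={"smooth_bins": smooth_bins})


def extract_phase(spec_a: Spectrogram, spec_b: Spectrogram) -> RhythmSeries:
    """Phase of channel A relative to B (degrees, [0, 360)).

    Evaluated as the argument of the cross-wavelet coefficient
    ``W_a * conj(W_b)`` at the reference (first-named) channel's ridge
    frequency; a positive lag means A leads.
    """
    if spec_a.W.shape != spec_b.W.shape or not np.allclose(spec_a.freqs,
                                                           spec_b.freqs):
        raise ValueError("spectrograms must share the time-frequency grid")
    idx, missing_a = _ridge(spec_a)
    cols = np.arange(spec_a.W.shape[1])
    cross = spec_a.W[idx, cols] * np.conj(spec_b.W[idx, cols])
    missing = missing_a | (np.abs(spec_b.W).max(axis=0) <= 0)
    phase = wrap_deg(np.degrees(np.angle(cross))).astype(float)
    phase[missing] = np.nan
    return RhythmSeries(values=phase, times=spec_a.times.copy(), kind="phase",
                        units="deg", channel=f"{spec_a.channel}-{spec_b.channel}",
                        epochs=dict(spec_a.epochs))


def trim_edges(series: RhythmSeries, trim: float = 10.0) -> RhythmSeries:
    """Drop ``trim`` seconds of wavelet edge effects at each end."""
    if trim < 0:
        raise ValueError("trim must be >= 0")
    if trim == 0:
        return series
    t0, t1 = series.times[0], series.times[-1]
    if t1 - t0 <= 2 * trim:
        raise ValueError(f"series of {t1 - t0:.1f} s too short to trim "
                         f"{trim} s from each end")
    sel = (series.times >= t0 + trim) & (series.times <= t1 - trim)
    return RhythmSeries(values=series.values[sel], times=series.times[sel],
                        kind=series.kind, units=series.units,
                        channel=series.channel, epochs=dict(series.epochs),
                        trim=series.trim + trim, meta=dict(series.meta))


def normalize_percent_change(series: RhythmSeries,
                             baseline: str = "pre") -> RhythmSeries:
    """Percent change from the baseline-epoch mean.

    ``out(t) = 100 * (x(t) / mean_baseline - 1)``; the baseline mean of the
    output is 0.  Missing bins propagate.
    """
    m = series.epoch_mean(baseline)
    if not np.isfinite(m) or m <= 0:
        raise ValueError(
            f"baseline epoch {baseline!r} mean must be positive (got {m})")
    vals = 100.0 * (series.values / m - 1.0)
    return RhythmSeries(values=vals, times=series.times.copy(),
                        kind="percent-change", units="%",
                        channel=series.channel, epochs=dict(series.epochs),
                        trim=series.trim,
                        meta={**series.meta, "baseline_epoch": baseline,
                              "baseline_mean": m, "source_kind": series.kind})


def envelope_series(env: IntegratedNeurogram, channel: str | int = 0,
                    times: np.ndarray | None = None) -> RhythmSeries:
    """Envelope level as a RhythmSeries (optionally on a spectrogram grid)."""
    idx = env.channel_index(channel) if isinstance(channel, str) else channel
    t_in = env.times
    if times is None:
        t, v = t_in, env.env[idx].astype(float)
    else:
        t = np.asarray(times)
        v = np.interp(t, t_in, env.env[idx])
    return RhythmSeries(values=v, times=t.copy(), kind="envelope", units="a.u.",
                        channel=env.channels[idx].name, epochs=dict(env.epochs))


def _runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of True runs (stop exclusive)."""
    idx = np.flatnonzero(np.diff(np.r_[0, mask.astype(int), 0]))
    for a, b in zip(idx[::2], idx[1::2]):
        yield int(a), int(b)


def flag_tonic(
    env: IntegratedNeurogram,
    spec: Spectrogram,
    baseline_epoch: str = "pre",
    elevation_frac: float = 1.10,
    run_length_frac: float = 1.4,
    level_frac: float = 0.7,
    min_duration: float = 3.0,
    smooth_seconds: float = 1.0,
) -> TonicMask:
    """Flag tonic bins: elevated, sustained envelope with no oscillation dips.

    The envelope (smoothed by a ``smooth_seconds`` median filter) is
    thresholded at its baseline-epoch median; a contiguous elevated run is a
    tonic candidate when its level exceeds the baseline burst-peak level
    (``elevation_frac`` times the baseline 90th percentile) or when it lasts
    longer than ``run_length_frac`` times the longest plausible burst (the
    median baseline high-run), i.e. the envelope fails to dip where the
    rhythm's duty cycle says it must.  Candidate runs shorter than
    ``min_duration`` are ignored; surviving runs are refined to the maximal
    contiguous interval on which the envelope stays above ``level_frac``
    times the run's plateau level (its 90th percentile), which places the
    boundaries at the tonic plateau's own edges.  A quiescent (near-zero)
    envelope is never tonic.

    A purely spectral criterion (rhythm-band wavelet power) is not used to
    delimit the boundaries: a tonic plateau of ~10 s has genuine in-band
    energy near 0.1 Hz and Morlet support at these frequencies smears any
    power measure over several seconds.
    """
    e = envelope_series(env, spec.channel, times=spec.times).values
    dt = float(np.median(np.diff(spec.times)))
    k = max(1, int(round(smooth_seconds / dt)) | 1)
    e_s = ndimage.median_filter(e, size=k, mode="nearest")

    if baseline_epoch in spec.epochs:
        a, b = spec.epochs[baseline_epoch]
        base = (spec.times >= a) & (spec.times < b)
    else:
        base = np.ones(spec.times.size, dtype=bool)
    m0 = float(np.median(e_s[base]))
    p10, p90 = (float(v) for v in np.percentile(e_s[base], [10, 90]))
    if p90 <= 0:
        return TonicMask(mask=np.zeros(spec.times.size, dtype=bool),
                         times=spec.times.copy(),
                         params={"baseline_median": m0})

    # mid-level threshold: the baseline median itself sits on the burst edge
    # when the duty cycle is near 0.5, fragmenting runs in envelope noise
    thr = 0.5 * (p10 + p90)
    high = e_s > thr
    base_runs = [(i, j) for i, j in _runs(high & base)]
    b_med = (float(np.median([(j - i) * dt for i, j in base_runs]))
             if base_runs else min_duration)

    mask = np.zeros(spec.times.size, dtype=bool)
    for a_i, b_i in _runs(high):
        length = (b_i - a_i) * dt
        level_top = float(np.percentile(e_s[a_i:b_i], 90))
        elevated = float(np.median(e_s[a_i:b_i])) > elevation_frac * p90
        overlong = length > run_length_frac * b_med
        if length < min_duration or not (elevated or overlong):
            continue
        level = level_frac * level_top
        c = (a_i + b_i) // 2
        lo = c
        while lo > 0 and e_s[lo - 1] > level:
            lo -= 1
        hi = c
        while hi < e_s.size - 1 and e_s[hi + 1] > level:
            hi += 1
        mask[lo:hi + 1] = True

    return TonicMask(mask=mask, times=spec.times.copy(),
                     params={"elevation_frac": elevation_frac,
                             "run_length_frac": run_length_frac,
                             "level_frac": level_frac,
                             "min_duration": min_duration,
                             "baseline_epoch": baseline_epoch,
                             "baseline_median": m0,
                             "baseline_p90": p90,
                             "baseline_high_run": b_med})
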