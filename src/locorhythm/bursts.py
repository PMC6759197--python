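"""Burst segmentation and per-cycle pattern metrics.

Bursts are delimited on the integrated envelope at 40 % of the
trough-to-peak height: the onset is the last upward crossing of
``trough + 0.4 * (peak - trough)`` before the peak (preceding trough), the
offset the first downward crossing after the peak (following trough's
level — symmetric treatment, robust to slow baseline drift).  Crossings are
refined by sub-sample linear interpolation, since whole-sample times at
19 Hz (~53 ms) are too coarse for sub-second bursts.  Per cycle the table
records duration, interburst interval, amplitude (peak - trough), period
(onset to next onset) and duty cycle (duration / period); cycles are
labeled by the epoch containing their peak.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import IntegratedNeurogram, epoch_of

__all__ = [
    "detect_cycles",
    "burst_bounds",
    "burst_metrics",
    "analyze_channel",
    "epoch_summary",
    "CycleSkipped",
]

log = logging.getLogger(__name__)

#: burst boundary level as a fraction of the trough-to-peak distance
DEFAULT_THRESHOLD = 0.40

BURST_COLUMNS = ["channel", "epoch", "trough_time", "peak_time", "onset_time",
                 "offset_time", "burst_duration", "interburst_interval",
                 "amplitude", "period", "duty_cycle"]


class CycleSkipped(ValueError):
    """Raised when a cycle's 40 % level is never crossed (flat-top degenerate)."""


def _smooth(x: np.ndarray, fs: float, seconds: float) -> np.ndarray:
    """Zero-lag moving average over ``seconds`` (odd window)."""
    if seconds <= 0:
        return x
    k = max(1, int(round(seconds * fs)) | 1)
    return np.convolve(x, np.ones(k) / k, mode="same")


def detect_cycles(
    env: IntegratedNeurogram | np.ndarray,
    channel: str | int = 0,
    fs: float | None = None,
    min_period: float | None = None,
    hysteresis: tuple[float, float] = (0.30, 0.55),
    smooth_seconds: float = 0.0,
    normalize: bool = True,
) -> list[tuple[float, float]]:
    """Alternating trough/peak sequence as ``(trough_time, peak_time)`` pairs.

    Bursts are segmented by hysteresis on the envelope's robust range
    (P5-P95): a burst is a run above the low level that reaches the high
    level, so splitting a burst requires a dip through most of its
    amplitude (not just carrier ripple) and bridging an interburst gap
    requires noise to fill most of the gap's depth.  With ``normalize`` the
    envelope is first divided by its rolling 90th percentile (~2.5 expected
    periods), so that epochs whose burst amplitude is strongly modulated
    (e.g. by the illumination) are segmented on equal footing.  Gaps and
    runs shorter than a fraction of ``min_period`` are merged/dropped, and
    burst midpoints closer than ``min_period`` (default: half a period of
    the fastest band frequency) are merged.  Each returned trough is the
    minimum between the previous peak and the paired peak; partial cycles
    at the record edges are dropped.  A constant envelope yields an empty
    list.  ``smooth_seconds`` applies a moving average before segmentation.
    """
    if isinstance(env, IntegratedNeurogram):
        idx = env.channel_index(channel) if isinstance(channel, str) else channel
        x, fs = env.env[idx], env.fs
    else:
        x = np.asarray(env, dtype=float)
        if fs is None:
            raise ValueError("fs is required for array input")
    x = _smooth(x, fs, smooth_seconds)
    if min_period is None:
        min_period = 0.5 / 2.0    # half a period at the 2 Hz band edge
    if np.ptp(x) <= 0:
        return []
    if normalize:
        win = max(5, int(round(5 * min_period * fs)) | 1)
        ref = ndimage.percentile_filter(x, 90, size=min(win, x.size),
                                        mode="nearest")
        # floor keeps quiescent stretches from being blown up to burst size
        floor = 0.25 * np.percentile(x, 95)
        x = x / np.maximum(ref, max(floor, 1e-12))
    p5, p95 = np.percentile(x, [5, 95])
    span = p95 - p5
    if span <= 0:
        return []
    lo = p5 + hysteresis[0] * span
    hi = p5 + hysteresis[1] * span
    min_gap = max(2, int(round(0.15 * min_period * fs)))
    min_seg = max(2, int(round(0.15 * min_period * fs)))

    above = x > lo
    idx_edges = np.flatnonzero(np.diff(np.r_[0, above.astype(int), 0]))
    segs = [[int(a), int(b)] for a, b in zip(idx_edges[::2], idx_edges[1::2])]
    # close noise-sized gaps, then drop noise-sized or sub-threshold runs
    merged: list[list[int]] = []
    for seg in segs:
        if merged and seg[0] - merged[-1][1] < min_gap:
            merged[-1][1] = seg[1]
        else:
            merged.append(seg)
    segs = [s for s in merged
            if s[1] - s[0] >= min_seg and x[s[0]:s[1]].max() > hi]
    # enforce the minimum period on segment midpoints (peak positions on
    # noisy plateaus jitter across the whole burst; midpoints do not)
    def peak_of(s):
        return s[0] + int(np.argmax(x[s[0]:s[1]]))
    i = 0
    while i + 1 < len(segs):
        mid_gap = (sum(segs[i + 1]) - sum(segs[i])) / 2 / fs
        if mid_gap < min_period:
            segs[i] = [segs[i][0], segs[i + 1][1]]
            del segs[i + 1]
        else:
            i += 1
    if len(segs) < 3:
        return []
    t = np.arange(x.size) / fs
    peaks = [peak_of(s) for s in segs]
    pairs = []
    for j in range(1, len(segs) - 1):
        a, b = peaks[j - 1], peaks[j]
        trough = a + int(np.argmin(x[a:b]))
        pairs.append((t[trough], t[peaks[j]]))
    return pairs


def _cross_time(t: np.ndarray, x: np.ndarray, i0: int, i1: int, level: float,
                rising: bool, last: bool) -> float:
    """Sub-sample time of a level crossing of ``x`` within [i0, i1]."""
    seg = x[i0:i1 + 1]
    if rising:
        below = seg < level
        cross = np.flatnonzero(below[:-1] & ~below[1:])
    else:
        above = seg >= level
        cross = np.flatnonzero(above[:-1] & ~above[1:])
    if cross.size == 0:
        raise CycleSkipped(
            f"level {level:.4g} never crossed in [{t[i0]:.2f}, {t[i1]:.2f}] s")
    j = i0 + (cross[-1] if last else cross[0])
    x0, x1 = x[j], x[j + 1]
    frac = 0.5 if x1 == x0 else (level - x0) / (x1 - x0)
    return float(t[j] + frac * (t[j + 1] - t[j]))


def burst_bounds(
    env: IntegratedNeurogram | np.ndarray,
    trough_time: float,
    peak_time: float,
    next_trough_time: float | None = None,
    threshold_fraction: float = DEFAULT_THRESHOLD,
    channel: str | int = 0,
    fs: float | None = None,
    extremum_halfwidth: int = 0,
) -> tuple[float, float]:
    """(onset, offset) of one burst by the fractional trough-to-peak rule.

    The rising edge uses the preceding trough's level, the falling edge the
    following trough's (``next_trough_time``; defaults to the preceding
    trough's level when absent).  ``extremum_halfwidth`` averages the
    envelope over that many samples on each side of an extremum when setting
    the crossing levels, a robust estimate for noisy envelopes (0 = the
    exact extremum sample, appropriate for clean waveforms).
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    if trough_time >= peak_time:
        raise ValueError("trough must precede peak")
    if isinstance(env, IntegratedNeurogram):
        idx = env.channel_index(channel) if isinstance(channel, str) else channel
        x, fs = env.env[idx], env.fs
    else:
        x = np.asarray(env, dtype=float)
        if fs is None:
            raise ValueError("fs is required for array input")
    t = np.arange(x.size) / fs
    i_tr = int(round(trough_time * fs))
    i_pk = int(round(peak_time * fs))

    def val(i):
        h = extremum_halfwidth
        return float(x[max(0, i - h):i + h + 1].mean())

    peak_v, trough_v = val(i_pk), val(i_tr)
    lvl_rise = trough_v + threshold_fraction * (peak_v - trough_v)
    onset = _cross_time(t, x, i_tr, i_pk, lvl_rise, rising=True, last=True)

    if next_trough_time is not None:
        i_nt = int(round(next_trough_time * fs))
        lvl_fall = val(i_nt) + threshold_fraction * (peak_v - val(i_nt))
    else:
        i_nt = x.size - 1
        lvl_fall = lvl_rise
    offset = _cross_time(t, x, i_pk, i_nt, lvl_fall, rising=False, last=False)
    return onset, offset


def burst_metrics(
    bounds: list[tuple[float, float]],
    cycles: list[tuple[float, float]],
    env: IntegratedNeurogram | np.ndarray | None = None,
    epochs: dict[str, tuple[float, float]] | None = None,
    channel: str = "",
    peak_values: np.ndarray | None = None,
    trough_values: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tabulate per-cycle burst metrics from boundaries and extrema.

    ``bounds`` and ``cycles`` must be index-aligned.  Amplitude is
    peak minus preceding trough; interburst interval runs offset to next
    onset; period onset to next onset; duty = duration / period.  The last
    cycle has no following onset, so its interval/period/duty are missing.
    """
    if len(bounds) != len(cycles):
        raise ValueError("bounds and cycles must align")
    n = len(bounds)
    rows = []
    for i, ((onset, offset), (tr_t, pk_t)) in enumerate(zip(bounds, cycles)):
        if peak_values is not None:
            amp = float(peak_values[i] - trough_values[i])
        elif env is not None:
            x = env.env[env.channel_index(channel)] if isinstance(
                env, IntegratedNeurogram) else np.asarray(env)
            fs = env.fs if isinstance(env, IntegratedNeurogram) else None
            if fs is None:
                raise ValueError("need peak/trough values or an envelope with fs")
            amp = float(x[int(round(pk_t * fs))] - x[int(round(tr_t * fs))])
        else:
            amp = np.nan
        dur = offset - onset
        if i + 1 < n:
            nxt = bounds[i + 1][0]
            ibi, period = nxt - offset, nxt - onset
            duty = dur / period
        else:
            ibi = period = duty = np.nan
        rows.append({
            "channel": channel,
            "epoch": epoch_of(pk_t, epochs) if epochs else "",
            "trough_time": tr_t, "peak_time": pk_t,
            "onset_time": onset, "offset_time": offset,
            "burst_duration": dur, "interburst_interval": ibi,
            "amplitude": amp, "period": period, "duty_cycle": duty,
        })
    return pd.DataFrame(rows, columns=BURST_COLUMNS)


def analyze_channel(
    env: IntegratedNeurogram,
    channel: str | int = 0,
    threshold_fraction: float = DEFAULT_THRESHOLD,
    min_period: float | None = None,
    exclude: list[tuple[float, float]] | None = None,
    smooth_seconds: float = 0.3,
    extremum_halfwidth: int = 2,
) -> pd.DataFrame:
    """detect_cycles + burst_bounds + burst_metrics for one channel.

    The envelope is lightly smoothed (default 0.3 s moving average — well
    below the shortest expected burst, well above the 19 Hz sample spacing)
    so residual carrier ripple neither splits burst tops into extra peaks
    nor jitters the 40 % crossings; extremum levels additionally average
    ``extremum_halfwidth`` samples per side.  ``exclude`` intervals
    (e.g. detected tonic stretches): bursts overlapping an interval are
    dropped, and cycles whose onset-to-next-onset period spans one lose
    their period/interval/duty (the burst itself may be clean but the cycle
    is not).
    """
    idx = env.channel_index(channel) if isinstance(channel, str) else channel
    name = env.channels[idx].name
    fs = env.fs
    x = _smooth(env.env[idx], fs, smooth_seconds)
    cycles = detect_cycles(x, fs=fs, min_period=min_period)
    if not cycles:
        return pd.DataFrame(columns=BURST_COLUMNS)
    bounds, kept, pk_v, tr_v = [], [], [], []
    for i, (tr_t, pk_t) in enumerate(cycles):
        nxt = cycles[i + 1][0] if i + 1 < len(cycles) else None
        try:
            bounds.append(burst_bounds(x, tr_t, pk_t, nxt, threshold_fraction,
                                       fs=fs,
                                       extremum_halfwidth=extremum_halfwidth))
        except CycleSkipped as e:
            log.info("channel %s: cycle at %.2f s skipped (%s)", name, pk_t, e)
            continue
        kept.append((tr_t, pk_t))
        pk_v.append(x[int(round(pk_t * fs))])
        tr_v.append(x[int(round(tr_t * fs))])
    tab = burst_metrics(bounds, kept, epochs=env.epochs, channel=name,
                        peak_values=np.asarray(pk_v),
                        trough_values=np.asarray(tr_v))
    if env.epochs and len(tab):
        # cycles straddling an epoch boundary reflect neither condition:
        # drop bursts that span one; void period metrics that span one
        ep = env.epochs
        burst_mixed = tab.apply(
            lambda r: epoch_of(r.onset_time, ep) != epoch_of(r.offset_time, ep),
            axis=1)
        tab = tab[~burst_mixed].reset_index(drop=True)
        cyc_mixed = tab.apply(
            lambda r: (np.isfinite(r.period)
                       and epoch_of(r.onset_time, ep)
                       != epoch_of(r.onset_time + r.period, ep)),
            axis=1)
        if cyc_mixed.any():
            tab.loc[cyc_mixed,
                    ["period", "interburst_interval", "duty_cycle"]] = np.nan
    for a, b in exclude or []:
        burst_hit = (tab["onset_time"] <= b) & (tab["offset_time"] >= a)
        tab = tab[~burst_hit].reset_index(drop=True)
        cyc_end = tab["onset_time"] + tab["period"]
        cycle_hit = (tab["onset_time"] <= b) & (cyc_end >= a)
        tab.loc[cycle_hit, ["period", "interburst_interval", "duty_cycle"]] = np.nan
    return tab


_METRICS = ["burst_duration", "interburst_interval", "amplitude", "period",
            "duty_cycle"]


def _trial_epoch_means(table: pd.DataFrame) -> pd.DataFrame:
    return (table.dropna(subset=["epoch"])
                 .groupby(["channel", "epoch"], sort=False)[_METRICS]
                 .agg(["mean", "count"]))


def epoch_summary(
    tables: list[pd.DataFrame],
    epochs: tuple[str, ...] = ("pre", "light", "post"),
    baseline: str = "pre",
) -> pd.DataFrame:
    """Per-channel, per-epoch means with percent change vs the baseline epoch.

    Averaging order matches the study design: cycle values are averaged per
    trial first, trial means are averaged into one value per experiment
    (this function), and experiment values are averaged across experiments
    by the caller.  Percent change is ``100 * (epoch mean / baseline mean -
    1)``, so the baseline row is 0 by construction.  Trials with an empty
    baseline epoch are excluded with a warning.
    """
    usable = []
    for i, tab in enumerate(tables):
        if tab.empty or not (tab["epoch"] == baseline).any():
            log.warning("trial %d has no %s-epoch cycles; excluded", i, baseline)
            continue
        usable.append(_trial_epoch_means(tab))
    if not usable:
        raise ValueError(f"no trial has cycles in the {baseline!r} epoch")
    stacked = pd.concat(usable)
    means = (stacked.xs("mean", axis=1, level=1)
                    .groupby(["channel", "epoch"], sort=False).mean())
    counts = (stacked.xs("count", axis=1, level=1)
                     .groupby(["channel", "epoch"], sort=False).sum())

    rows = []
    for ch in means.index.get_level_values(0).unique():
        sub = means.loc[ch]
        for ep in epochs:
            if ep not in sub.index:
                continue
            row = {"channel": ch, "epoch": ep}
            for m in _METRICS:
                v = sub.loc[ep, m]
                b = sub.loc[baseline, m] if baseline in sub.index else np.nan
                row[f"{m}_mean"] = v
                row[f"{m}_pct_change"] = (100.0 * (v / b - 1.0)
                                          if np.isfinite(b) and b != 0 else np.nan)
            row["n_cycles"] = int(counts.loc[(ch, ep), "burst_duration"])
            rows.append(row)
    return pd.DataFrame(rows)
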