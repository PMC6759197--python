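"""Intracellular membrane-potential analysis.

Spike detection (threshold crossing with a dV/dt confirmation and a
refractory period), cycle-triggered averaging of the locomotor synaptic
drive on a normalized two-cycle phase grid (spikes are removed with a
median filter before averaging), per-cycle spike counts, and input
resistance from the slope of the current/voltage relation restricted to its
linear range.  The liquid junction potential is not corrected.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal

from .core import CycleTriggeredAverage
from .synthetic import IntracellularTrace

__all__ = [
    "detect_spikes",
    "remove_spikes",
    "cycle_triggered_average",
    "spikes_per_cycle",
    "input_resistance",
]


def detect_spikes(
    trace: IntracellularTrace | np.ndarray,
    fs: float | None = None,
    threshold_mv: float = -20.0,
    dvdt_min: float = 10.0,          # V/s
    refractory: float = 0.003,       # s
) -> np.ndarray:
    """Spike times (s) at upward threshold crossings.

    A crossing counts as a spike when the membrane potential rises through
    ``threshold_mv`` with a slope of at least ``dvdt_min`` V/s; subsequent
    crossings within the refractory period are ignored.  Zero spikes is a
    valid result.
    """
    if isinstance(trace, IntracellularTrace):
        vm, fs = trace.vm, trace.fs
    else:
        vm = np.asarray(trace, dtype=float)
        if fs is None:
            raise ValueError("fs is required for array input")
    if fs < 5000:
        raise ValueError("spike detection needs sampling >= 5 kHz")
    below = vm[:-1] < threshold_mv
    above = vm[1:] >= threshold_mv
    idx = np.flatnonzero(below & above) + 1
    # dV/dt in V/s: vm is mV, so mV/sample * fs / 1000
    dvdt = np.diff(vm) * fs / 1000.0
    idx = idx[dvdt[idx - 1] >= dvdt_min]
    times, last = [], -np.inf
    for i in idx:
        t = i / fs
        if t - last >= refractory:
            times.append(t)
            last = t
    return np.asarray(times)


def remove_spikes(vm: np.ndarray, fs: float, width: float = 0.015) -> np.ndarray:
    """Median-filter the trace (default 15 ms) to suppress spikes for drive
    estimation."""
    k = max(1, int(round(width * fs)) | 1)
    return ndimage.median_filter(vm, size=k, mode="nearest")


def cycle_triggered_average(
    trace: IntracellularTrace | np.ndarray,
    cycle_onsets: np.ndarray,
    fs: float | None = None,
    n_phase_bins: int = 200,
    despike: bool = True,
    drive_rate: float = 1000.0,
) -> CycleTriggeredAverage:
    """Cycle-triggered average of the synaptic drive over two cycles.

    Each onset-to-onset cycle is resampled to ``n_phase_bins`` normalized
    phase bins; the mean and SD over cycles are duplicated to display two
    cycles.  Drive amplitude is max - min of the mean waveform, trough
    potential its minimum.  The trace is median-filtered (spike removal)
    and decimated to ``drive_rate`` before averaging, since the drive lives
    far below the spike band.  SD is reported only with >= 3 cycles.
    """
    if isinstance(trace, IntracellularTrace):
        vm, fs = trace.vm, trace.fs
    else:
        vm = np.asarray(trace, dtype=float)
        if fs is None:
            raise ValueError("fs is required for array input")
    onsets = np.sort(np.asarray(cycle_onsets, dtype=float))
    if onsets.size < 2:
        raise ValueError("need at least 2 cycle onsets")

    if fs > drive_rate:
        q = int(fs // drive_rate)
        x = signal.decimate(vm, q, ftype="fir", zero_phase=True)
        fs_d = fs / q
    else:
        x, fs_d = vm.astype(float), fs
    if despike:
        x = remove_spikes(x, fs_d)

    t = np.arange(x.size) / fs_d
    grid = (np.arange(n_phase_bins) + 0.5) / n_phase_bins
    cycles = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        if a < t[0] or b > t[-1]:
            continue
        cycles.append(np.interp(a + grid * (b - a), t, x))
    if not cycles:
        raise ValueError("no complete cycles inside the trace")
    arr = np.vstack(cycles)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] >= 3 else None
    mean2 = np.tile(mean, 2)
    return CycleTriggeredAverage(
        phase=np.concatenate([grid, grid + 1.0]),
        mean=mean2,
        sd=np.tile(sd, 2) if sd is not None else None,
        n_cycles=arr.shape[0],
        amplitude=float(mean.max() - mean.min()),
        trough=float(mean.min()),
        meta={"n_phase_bins": n_phase_bins, "despike": despike},
    )


def spikes_per_cycle(spike_times: np.ndarray,
                     cycle_onsets: np.ndarray) -> np.ndarray:
    """Spike count in each [onset, next onset) interval."""
    onsets = np.sort(np.asarray(cycle_onsets, dtype=float))
    if onsets.size < 2:
        raise ValueError("need at least 2 cycle onsets")
    return np.histogram(np.asarray(spike_times), bins=onsets)[0]


def input_resistance(
    steps: list[tuple[float, float]] | np.ndarray,
    max_rel_residual: float = 0.02,
) -> tuple[float, np.ndarray]:
    """Input resistance (MOhm) from the current/voltage slope in the linear range.

    ``steps`` are (current nA, steady-state voltage mV) pairs from 200 ms
    current steps.  The slope is an ordinary least-squares fit over the
    largest contiguous subset (>= 3 points, ordered by current) whose fit
    residuals all stay below ``max_rel_residual`` times the subset's voltage
    range — this excludes saturating distortion at extreme steps.  Returns
    ``(resistance_mohm, used_mask)``.
    """
    arr = np.asarray(steps, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (current, voltage) steps")
    order = np.argsort(arr[:, 0])
    I, V = arr[order, 0], arr[order, 1]
    n = I.size
    for width in range(n, 2, -1):
        for start in range(0, n - width + 1):
            Ii, Vi = I[start:start + width], V[start:start + width]
            A = np.column_stack([Ii, np.ones(width)])
            coef, *_ = np.linalg.lstsq(A, Vi, rcond=None)
            resid = Vi - A @ coef
            vrange = Vi.max() - Vi.min()
            scale = vrange if vrange > 0 else max(abs(Vi).max(), 1.0)
            if np.abs(resid).max() <= max_rel_residual * scale:
                used = np.zeros(n, dtype=bool)
                used[start:start + width] = True
                mask = np.zeros(n, dtype=bool)
                mask[order] = used
                return float(coef[0]), mask
    raise ValueError("no contiguous linear range of >= 3 points found")
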