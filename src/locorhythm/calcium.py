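"""Calcium-imaging ROI trace extraction and conditioning.

The processing chain, enforced in this order by per-trace state flags:
neuropil (doughnut) subtraction -> monoexponential bleach correction ->
dF/F (``100 * (f - f0) / f0`` with f0 the trace minimum) -> zero-phase
band-pass at [0.05, 0.8] Hz.  ROIs are either six equal rectangles tiling
the field dorsoventrally or per-cell masks, each paired with a
doughnut-shaped annulus (outer radius twice the cell radius, other cells'
pixels excluded) whose mean trace estimates the background signal from
cells and processes under the cell of interest.

Input stacks are registered multi-page TIFFs (or arrays); registration
itself is out of scope, but a frame-to-frame correlation check warns when
residual motion is suspected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize, signal

from .core import CycleTriggeredAverage

__all__ = [
    "RoiSet",
    "CalciumTrace",
    "make_grid_rois",
    "make_cell_roi",
    "extract_trace",
    "doughnut_subtract",
    "bleach_correct",
    "dff",
    "bandpass_ca",
    "ca_cycle_triggered_average",
    "read_stack",
    "write_stack",
    "check_registration",
    "CA_BAND",
]

log = logging.getLogger(__name__)

CA_BAND = (0.05, 0.8)   # Hz

_ORDER = ["neuropil_subtracted", "bleach_corrected", "dff", "bandpassed"]


@dataclass
class RoiSet:
    """Named boolean pixel masks over the imaging field."""

    masks: dict[str, np.ndarray]
    field_shape: tuple[int, int]

    def __post_init__(self):
        for name, m in self.masks.items():
            if m.shape != tuple(self.field_shape):
                raise ValueError(f"ROI {name!r} does not match the field shape")
            if not m.any():
                raise ValueError(f"ROI {name!r} is empty")


@dataclass
class CalciumTrace:
    """Mean-pixel time series of one ROI with processing-state flags."""

    values: np.ndarray
    frame_times: np.ndarray
    roi: str = ""
    state: dict = field(default_factory=lambda: {k: False for k in _ORDER})
    f0: float | None = None
    bleach_fit: dict | None = None

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.frame_times)))

    def _advance(self, step: str) -> dict:
        """Check the processing-order contract and return the new state."""
        i = _ORDER.index(step)
        if self.state.get(step):
            raise ValueError(f"{step} already applied (state flags are monotone)")
        later = [s for s in _ORDER[i + 1:] if self.state.get(s)]
        if later:
            raise ValueError(
                f"cannot apply {step} after {later[0]}: required order is "
                + " -> ".join(_ORDER))
        new = dict(self.state)
        new[step] = True
        return new


def make_grid_rois(field_shape: tuple[int, int], n: int = 6) -> RoiSet:
    """``n`` identical rectangles tiling the field in the dorsoventral
    (vertical) direction; an indivisible height goes to the last ROI."""
    ny, nx = field_shape
    if ny < n:
        raise ValueError(f"field must be at least {n} pixels tall")
    h = ny // n
    masks = {}
    for i in range(n):
        m = np.zeros(field_shape, dtype=bool)
        top = i * h
        bottom = (i + 1) * h if i < n - 1 else ny
        m[top:bottom, :] = True
        masks[f"grid{i}"] = m
    return RoiSet(masks=masks, field_shape=tuple(field_shape))


def make_cell_roi(
    field_shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    others: list[np.ndarray] | None = None,
    outer_factor: float = 2.0,
) -> RoiSet:
    """Disk cell ROI plus its doughnut (annulus to ``outer_factor * radius``,
    excluding the cell's own pixels and any ``others`` cell masks)."""
    ny, nx = field_shape
    cy, cx = center
    yy, xx = np.mgrid[0:ny, 0:nx]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    cell = r2 <= radius**2
    ring = (r2 <= (outer_factor * radius) ** 2) & ~cell
    for other in others or []:
        ring &= ~other
    if not cell.any() or not ring.any():
        raise ValueError("cell or doughnut ROI is empty for this geometry")
    return RoiSet(masks={"cell": cell, "doughnut": ring},
                  field_shape=tuple(field_shape))


def extract_trace(stack: np.ndarray, roi: np.ndarray, frame_rate: float,
                  name: str = "") -> CalciumTrace:
    """Per-frame mean pixel value over the ROI."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != stack.shape[1:]:
        raise ValueError("ROI does not match the stack field")
    if not roi.any():
        raise ValueError("empty ROI")
    vals = stack[:, roi].mean(axis=1)
    times = np.arange(stack.shape[0]) / frame_rate
    return CalciumTrace(values=vals.astype(float), frame_times=times, roi=name)


def doughnut_subtract(cell: CalciumTrace, doughnut: CalciumTrace) -> CalciumTrace:
    """Subtract the doughnut (neuropil) trace from the cell trace."""
    if cell.values.shape != doughnut.values.shape or not np.allclose(
            cell.frame_times, doughnut.frame_times):
        raise ValueError("cell and doughnut traces must share the frame grid")
    state = cell._advance("neuropil_subtracted")
    return CalciumTrace(values=cell.values - doughnut.values,
                        frame_times=cell.frame_times.copy(), roi=cell.roi,
                        state=state, f0=cell.f0)


def _monoexp(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def bleach_correct(trace: CalciumTrace) -> CalciumTrace:
    """Fit ``a * exp(-t/tau) + c`` and subtract the exponential component.

    The constant offset stays in the trace (camera baseline does not decay
    to zero).  A non-convergent fit falls back to linear detrending with a
    warning.
    """
    if trace.values.size < 20:
        raise ValueError("bleach correction needs >= 20 frames")
    state = trace._advance("bleach_corrected")
    t, y = trace.frame_times, trace.values
    span = y.max() - y.min()
    fit: dict
    if span <= 0:   # constant input: a -> 0 branch
        out = y.copy()
        fit = {"a": 0.0, "tau": np.inf, "c": float(y[0]), "method": "constant"}
    else:
        try:
            p0 = (max(y[0] - y[-1], 0.1 * span), max(t[-1] / 3, 1e-3),
                  float(y[-1]))
            popt, _ = optimize.curve_fit(
                _monoexp, t, y, p0=p0,
                bounds=([-2 * span, 1e-6, -np.inf], [2 * span, np.inf, np.inf]),
                maxfev=20000)
            a, tau, c = popt
            out = y - _monoexp(t, a, tau, 0.0)
            fit = {"a": float(a), "tau": float(tau), "c": float(c),
                   "method": "monoexponential"}
        except (RuntimeError, ValueError):
            warnings.warn("monoexponential bleach fit did not converge; "
                          "falling back to linear detrend", stacklevel=2)
            coef = np.polyfit(t, y, 1)
            out = y - coef[0] * t
            fit = {"slope": float(coef[0]), "method": "linear"}
    return CalciumTrace(values=out, frame_times=t.copy(), roi=trace.roi,
                        state=state, f0=trace.f0, bleach_fit=fit)


def dff(trace: CalciumTrace) -> CalciumTrace:
    """Percent fluorescence change: ``100 * (f - f0) / f0`` with ``f0 = min f``.

    Requires a positive minimum; the output minimum is exactly 0.
    """
    f0 = float(trace.values.min())
    if f0 <= 0:
        raise ValueError(
            "trace minimum (f0) must be positive for dF/F; restore the "
            "baseline offset before calling dff")
    state = trace._advance("dff")
    vals = 100.0 * (trace.values - f0) / f0
    return CalciumTrace(values=vals, frame_times=trace.frame_times.copy(),
                        roi=trace.roi, state=state, f0=f0,
                        bleach_fit=trace.bleach_fit)


def bandpass_ca(trace: CalciumTrace,
                band: tuple[float, float] = CA_BAND) -> CalciumTrace:
    """Zero-phase 4th-order Butterworth band-pass in the rhythm band."""
    fr = trace.frame_rate
    if fr <= 2 * band[1]:
        raise ValueError(
            f"frame rate {fr:.2f} Hz too low for the {band[1]} Hz band edge")
    state = trace._advance("bandpassed")
    sos = signal.butter(4, band, btype="bandpass", fs=fr, output="sos")
    padlen = min(int(3 * fr / band[0]), trace.values.size - 2)
    out = signal.sosfiltfilt(sos, trace.values, padlen=padlen, padtype="odd")
    return CalciumTrace(values=out, frame_times=trace.frame_times.copy(),
                        roi=trace.roi, state=state, f0=trace.f0,
                        bleach_fit=trace.bleach_fit)


def ca_cycle_triggered_average(
    trace: CalciumTrace,
    cycle_onsets: np.ndarray,
    n_phase_bins: int = 200,
) -> CycleTriggeredAverage:
    """Cycle-triggered average of a calcium trace on ventral-root cycle onsets.

    Same contract as the intracellular CTA, evaluated on the calcium frame
    grid; needs at least 3 complete cycles overlapping the trace.
    """
    onsets = np.sort(np.asarray(cycle_onsets, dtype=float))
    t0, t1 = trace.frame_times[0], trace.frame_times[-1]
    inside = onsets[(onsets >= t0) & (onsets <= t1)]
    if inside.size < 4:   # 4 onsets bound 3 complete cycles
        raise ValueError("need >= 3 complete cycles overlapping the trace")
    grid = (np.arange(n_phase_bins) + 0.5) / n_phase_bins
    cycles = []
    for a, b in zip(inside[:-1], inside[1:]):
        cycles.append(np.interp(a + grid * (b - a), trace.frame_times,
                                trace.values))
    arr = np.vstack(cycles)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] >= 3 else None
    return CycleTriggeredAverage(
        phase=np.concatenate([grid, grid + 1.0]),
        mean=np.tile(mean, 2),
        sd=np.tile(sd, 2) if sd is not None else None,
        n_cycles=arr.shape[0],
        amplitude=float(mean.max() - mean.min()),
        trough=float(mean.min()),
        meta={"source": "calcium", "roi": trace.roi},
    )


def check_registration(stack: np.ndarray, warn_below: float = 0.8) -> float:
    """Median frame-to-frame correlation; warns when residual motion is likely."""
    flat = stack.reshape(stack.shape[0], -1).astype(float)
    a, b = flat[:-1], flat[1:]
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, (a * b).sum(axis=1) / denom, 1.0)
    med = float(np.median(corr))
    if med < warn_below:
        warnings.warn(f"median frame-to-frame correlation {med:.2f} suggests "
                      "residual motion (stacks must be pre-registered)",
                      stacklevel=2)
    return med


def read_stack(path: str | Path) -> np.ndarray:
    import tifffile
    return tifffile.imread(str(path))


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    import tifffile
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))
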