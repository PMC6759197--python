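"""Shared containers and small utilities used across the analysis stages.

Conventions
-----------
* Times are seconds, relative to the start of the aligned analysis window.
* Angles are degrees in [0, 360) at module boundaries.
* Epochs are half-open intervals ``{name: (start, end)}`` in window time;
  the canonical drug-mode epochs are ``pre``, ``light``, ``post``.
* Randomness always flows from an integer root seed through
  :func:`child_rng`, so adding channels/trials never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChannelInfo",
    "Events",
    "RawRecording",
    "AlignedTrial",
    "IntegratedNeurogram",
    "Spectrogram",
    "RhythmSeries",
    "TonicMask",
    "CycleTriggeredAverage",
    "child_rng",
    "child_seed",
    "wrap_deg",
    "epoch_of",
]


def child_rng(root_seed: int, *context) -> np.random.Generator:
    """Generator derived from ``root_seed`` and a context tuple.

    Contexts are hashed into a :class:`numpy.random.SeedSequence` spawn key,
    so streams for (seed, "carrier", channel=2) are independent of — and do
    not reorder — streams for any other context.
    """
    return np.random.default_rng(child_seed(root_seed, *context))


def child_seed(root_seed: int, *context) -> np.random.SeedSequence:
    entropy = [int(root_seed)]
    for c in context:
        if isinstance(c, str):
            entropy.extend(c.encode("utf8"))
        else:
            entropy.append(int(c))
    return np.random.SeedSequence(entropy)


def wrap_deg(angle) -> np.ndarray | float:
    """Wrap angle(s) in degrees to [0, 360)."""
    return np.asarray(angle) % 360.0


def epoch_of(t: float, epochs: dict[str, tuple[float, float]]) -> str | None:
    """Name of the half-open epoch containing time ``t`` (last epoch closed)."""
    names = list(epochs)
    for i, name in enumerate(names):
        a, b = epochs[name]
        if a <= t < b or (i == len(names) - 1 and t == b):
            return name
    return None


@dataclass
class ChannelInfo:
    """Role metadata for one recorded channel."""

    name: str
    side: str = ""          # "left" | "right" | ""
    segment: str = ""       # e.g. "L2", "L5"
    role: str = ""          # "flexor" | "extensor" | ""


@dataclass
class Events:
    light_on: float | None = None
    light_off: float | None = None
    stim_times: np.ndarray | None = None   # seconds
    stim_rate: float | None = None         # Hz, for train bookkeeping


@dataclass
class RawRecording:
    """Multi-channel sampled traces with channel roles and event times."""

    data: np.ndarray            # (n_channels, n_samples), volts (a.u. for synthetic)
    fs: float                   # Hz
    channels: list[ChannelInfo]
    events: Events = field(default_factory=Events)
    group: str = ""             # genotype / condition label
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel metadata does not match data shape")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    def channel_index(self, name: str) -> int:
        for i, ch in enumerate(self.channels):
            if ch.name == name:
                return i
        raise KeyError(f"no channel named {name!r}")


@dataclass
class AlignedTrial:
    """Event-aligned analysis window cut from a :class:`RawRecording`."""

    data: np.ndarray
    fs: float
    channels: list[ChannelInfo]
    window: tuple[float, float]                  # in original recording time
    epochs: dict[str, tuple[float, float]]       # in window time
    mode: str                                    # "drug" | "evoked"
    events: Events = field(default_factory=Events)
    group: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    def channel_index(self, name: str) -> int:
        for i, ch in enumerate(self.channels):
            if ch.name == name:
                return i
        raise KeyError(f"no channel named {name!r}")


@dataclass
class IntegratedNeurogram:
    """Rectified, low-pass-filtered envelope of the aligned neurogram."""

    env: np.ndarray                              # (n_channels, n_samples), >= 0
    fs: float
    channels: list[ChannelInfo]
    epochs: dict[str, tuple[float, float]]
    corners: tuple[float, float, float]          # (low, high, final low) Hz
    mode: str = "drug"
    group: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.env.shape[1]) / self.fs

    @property
    def duration(self) -> float:
        return self.env.shape[1] / self.fs

    def channel_index(self, name: str) -> int:
        for i, ch in enumerate(self.channels):
            if ch.name == name:
                return i
        raise KeyError(f"no channel named {name!r}")


@dataclass
class Spectrogram:
    """Complex continuous-wavelet transform of one envelope channel."""

    W: np.ndarray               # complex, (n_freqs, n_times)
    freqs: np.ndarray           # Hz, strictly increasing (log-spaced)
    times: np.ndarray           # seconds, window time, length n_times
    channel: str
    epochs: dict[str, tuple[float, float]]
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


@dataclass
class RhythmSeries:
    """Frequency / phase / envelope-level / percent-change time series."""

    values: np.ndarray
    times: np.ndarray
    kind: str                   # "frequency" | "phase" | "envelope" | "percent-change"
    units: str
    channel: str
    epochs: dict[str, tuple[float, float]]
    trim: float = 0.0           # seconds removed at each edge
    meta: dict = field(default_factory=dict)

    def epoch_values(self, name: str) -> np.ndarray:
        a, b = self.epochs[name]
        sel = (self.times >= a) & (self.times < b)
        return self.values[sel]

    def epoch_mean(self, name: str) -> float:
        v = self.epoch_values(name)
        return float(np.nanmean(v)) if v.size else float("nan")


@dataclass
class TonicMask:
    """Per-bin tonic (non-rhythmic, elevated) flags on a series time grid."""

    mask: np.ndarray            # bool, True = tonic
    times: np.ndarray
    params: dict = field(default_factory=dict)

    def extent(self) -> float:
        """Total flagged duration in seconds."""
        if not self.mask.any():
            return 0.0
        dt = float(np.median(np.diff(self.times)))
        return float(self.mask.sum() * dt)

    def dilated(self, guard_seconds: float) -> np.ndarray:
        """Mask with each tonic run widened by ``guard_seconds`` per side."""
        if guard_seconds <= 0 or not self.mask.any():
            return self.mask.copy()
        dt = float(np.median(np.diff(self.times)))
        k = int(round(guard_seconds / dt))
        out = self.mask.copy()
        idx = np.flatnonzero(self.mask)
        for i in idx[np.flatnonzero(np.diff(idx, prepend=-10) > 1)]:   # run starts
            out[max(0, i - k):i] = True
        for i in idx[np.flatnonzero(np.diff(idx, append=idx[-1] + 10) > 1)]:  # run ends
            out[i:i + k + 1] = True
        return out


@dataclass
class CycleTriggeredAverage:
    """Mean (and SD) waveform over a two-cycle normalized-phase window."""

    phase: np.ndarray           # cycles, [0, 2)
    mean: np.ndarray
    sd: np.ndarray | None       # None when fewer than 3 cycles
    n_cycles: int
    amplitude: float            # max - min of the mean waveform
    trough: float               # min of the mean waveform
    meta: dict = field(default_factory=dict)
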