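"""Seeded synthetic recordings with exported ground truth.

The generator emulates the study conditions of an isolated neonatal-mouse
spinal cord preparation: multi-channel ventral-root neurograms with
flexor/extensor and left/right phase structure, a 60 s illumination window
that modulates frequency, amplitude and duty cycle, a hemicord scenario with
a tonic (non-oscillatory) onset, stimulus-train-evoked episodes,
intracellular motoneuron traces with locomotor drive and spikes, and calcium
movies with shared neuropil signal and monoexponential bleaching.

Every random draw flows from one root seed through named
``SeedSequence`` children, so adding channels or trials never perturbs
earlier draws, and identical ``(spec, seed)`` give bit-identical output.

Cohort presets (:data:`PRESETS`) program the group-level scenario values
(frequencies, modulation factors, duty cycles) reported for the whole-cord,
hemicord and dorsal-root-evoked experiments.  Per-experiment heterogeneity
uses stratified (moment-matched) draws from the stated normal distributions:
each cohort receives the inverse-CDF values at equal-probability stratum
midpoints in a random order, so the cohort mean and SD match the programmed
population values instead of wandering with sampling noise, while each
experiment's marginal distribution is unchanged.  Midpoint draws for n <= 20
lie within +/-2 SD automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import ChannelInfo, Events, RawRecording, child_rng, wrap_deg

__all__ = [
    "Protocol",
    "ChannelSpec",
    "RhythmSpec",
    "GroundTruth",
    "simulate_neurograms",
    "simulate_intracellular",
    "simulate_calcium",
    "IntracellularTrace",
    "design_cohort",
    "simulate_experiment",
    "stratified_normal",
    "PRESETS",
]


# ------------------------------------------------------------------- types

@dataclass
class Protocol:
    """Recording protocol: duration, illumination or stimulus train, rate."""

    total_duration: float                 # s
    sampling_rate: float = 10_000.0       # Hz
    light_on: float | None = None         # s
    light_off: float | None = None        # s
    stim_start: float | None = None       # s (first pulse)
    stim_rate: float | None = None        # Hz
    train_duration: float | None = None   # s
    pulse_width: float = 250e-6           # s

    def __post_init__(self):
        if self.total_duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be positive")
        if self.light_on is not None:
            if self.light_off is None or not (0 < self.light_on < self.light_off
                                              < self.total_duration):
                raise ValueError("light window must lie strictly inside the recording")
        if self.stim_start is not None:
            if self.stim_rate is None or self.train_duration is None:
                raise ValueError("stimulus train needs stim_rate and train_duration")
            if not (0 <= self.stim_start and
                    self.stim_start + self.train_duration < self.total_duration):
                raise ValueError("train pulses must all lie inside the recording")

    @property
    def stim_times(self) -> np.ndarray | None:
        if self.stim_start is None:
            return None
        n = int(round(self.stim_rate * self.train_duration))
        return self.stim_start + np.arange(n) / self.stim_rate


@dataclass
class ChannelSpec:
    """Per-channel rhythm parameters."""

    name: str
    role: str = ""                 # "flexor" | "extensor"
    side: str = ""
    segment: str = ""
    phase_offset_deg: float = 0.0  # normalized to [0, 360)
    duty: float = 0.5              # fraction of the cycle the burst is on
    amplitude: float = 1.0         # a.u.
    light_amp_factor: float = 1.0
    light_duty_factor: float = 1.0

    def __post_init__(self):
        self.phase_offset_deg = float(wrap_deg(self.phase_offset_deg))
        if not 0.0 < self.duty < 1.0:
            raise ValueError("duty_cycle must be in (0, 1)")
        if self.light_amp_factor <= 0 or self.light_duty_factor <= 0:
            raise ValueError("modulation factors must be positive")


@dataclass
class RhythmSpec:
    """Common-oscillator rhythm specification for a multi-channel neurogram."""

    base_frequency: float                       # Hz
    channels: list[ChannelSpec]
    light_freq_factor: float = 1.0
    tonic_onset_duration: float = 0.0           # s, 0 = none
    tonic_amplitude_factor: float = 1.5         # x channel amplitude during tonic
    tonic_ramp: float = 0.5                     # s, clamp edge ramp
    edge_smooth: float | None = None            # s; None -> 10% of period
    baseline_noise: float = 0.05                # fraction of channel amplitude
    carrier: str = "noise"                      # "noise" | "spikes"
    active_window: tuple[float, float] | None = None  # gate rhythm (evoked episodes)

    def __post_init__(self):
        if self.base_frequency <= 0:
            raise ValueError("base_frequency must be positive")
        if self.tonic_onset_duration < 0:
            raise ValueError("tonic_onset_duration must be >= 0")
        if self.light_freq_factor <= 0:
            raise ValueError("modulation factors must be positive")


@dataclass
class GroundTruth:
    """Programmed values underlying one synthetic recording."""

    seed: int
    f_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    f_hz: np.ndarray = field(default_factory=lambda: np.empty(0))   # NaN where tonic
    tonic_interval: tuple[float, float] | None = None
    channels: dict = field(default_factory=dict)
    # {name: {onsets, offsets, duty: {epoch: v}, amplitude: {epoch: v},
    #         phase_offset_deg}}
    base_frequency: float = float("nan")
    light_freq_factor: float = 1.0
    spike_times: np.ndarray | None = None
    drive_amplitude: dict | None = None          # {epoch: mV}
    bleach: tuple[float, float] | None = None    # (amplitude, tau s)
    cell_traces: np.ndarray | None = None        # (n_cells, n_frames) clean
    params: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x
        return {k: conv(v) for k, v in vars(self).items()}


# --------------------------------------------------------------- envelope

def _pulse(theta: np.ndarray, duty: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Rectangular pulse with raised-cosine edges in cycle-phase coordinates.

    ``theta`` in [0, 1); rising edge centered at 0, falling edge at ``duty``;
    ``w`` is the full transition width in cycles.
    """
    h = np.maximum(w / 2.0, 1e-9)
    th = np.where(theta >= 0.5, theta - 1.0, theta)      # (-0.5, 0.5)
    d = theta - duty
    d -= np.round(d)                                     # (-0.5, 0.5)
    rise = 0.5 * (1.0 - np.cos(np.pi * (th + h) / (2 * h)))
    fall = 0.5 * (1.0 + np.cos(np.pi * (d + h) / (2 * h)))
    return np.select(
        [np.abs(th) < h, np.abs(d) < h, (theta >= h) & (theta <= duty - h)],
        [rise, fall, 1.0],
        default=0.0,
    )


def _smooth_gate(t: np.ndarray, window: tuple[float, float], ramp: float) -> np.ndarray:
    """Trapezoid gate on [a, b] with raised-cosine ramps of length ``ramp``."""
    a, b = window
    g = np.zeros_like(t)
    g[(t >= a + ramp) & (t <= b - ramp)] = 1.0
    up = (t >= a) & (t < a + ramp)
    g[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - a) / ramp))
    dn = (t > b - ramp) & (t <= b)
    g[dn] = 0.5 * (1 - np.cos(np.pi * (b - t[dn]) / ramp))
    return g


def simulate_neurograms(
    protocol: Protocol,
    spec: RhythmSpec,
    n_channels: int | None = None,
    seed: int = 0,
) -> tuple[RawRecording, GroundTruth]:
    """Generate a multi-channel rhythmic neurogram and its ground truth.

    All channels share one phase oscillator whose instantaneous frequency is
    ``base_frequency``, scaled by ``light_freq_factor`` inside the light
    window, and frozen during the tonic onset (when the envelope is instead
    clamped elevated and non-oscillatory).  Each channel's envelope is a
    smoothed periodic pulse of the programmed duty and phase; the output
    trace is baseline noise plus envelope times a zero-mean broadband
    carrier.
    """
    if n_channels is not None and n_channels != len(spec.channels):
        raise ValueError("n_channels must match the number of channel specs")
    if not spec.channels:
        raise ValueError("need at least one channel")
    fs = protocol.sampling_rate
    n = int(round(protocol.total_duration * fs))
    t = np.arange(n) / fs

    light_on, light_off = protocol.light_on, protocol.light_off
    has_light = light_on is not None
    tonic = None
    if spec.tonic_onset_duration > 0:
        if not has_light:
            raise ValueError("tonic onset requires a light window")
        tonic = (light_on, light_on + spec.tonic_onset_duration)
        if tonic[1] >= light_off:
            raise ValueError("tonic onset must end before the light goes off")

    # instantaneous frequency profile (frozen oscillator during tonic)
    f_inst = np.full(n, spec.base_frequency)
    if has_light:
        in_light = (t >= light_on) & (t < light_off)
        f_inst[in_light] = spec.base_frequency * spec.light_freq_factor
    if tonic is not None:
        f_inst[(t >= tonic[0]) & (t < tonic[1])] = 0.0

    for ch in spec.channels:
        period = 1.0 / (spec.base_frequency * max(spec.light_freq_factor, 1.0))
        if min(ch.duty, ch.duty * ch.light_duty_factor) * period * fs < 2:
            raise ValueError(
                f"channel {ch.name}: duty x period shorter than 2 samples")

    phase0 = child_rng(seed, "phase0").uniform()
    phi = phase0 + np.cumsum(f_inst) / fs          # cycles

    # edge width in cycles: fixed seconds if given, else 10% of the cycle
    if spec.edge_smooth is not None:
        w_cycles = spec.edge_smooth * np.where(f_inst > 0, f_inst,
                                               spec.base_frequency)
    else:
        w_cycles = np.full(n, 0.10)

    truth = GroundTruth(
        seed=int(seed),
        base_frequency=spec.base_frequency,
        light_freq_factor=spec.light_freq_factor,
        tonic_interval=tonic,
        params={"phase0": phase0, "edge_smooth": spec.edge_smooth,
                "carrier": spec.carrier},
    )
    # decimated truth frequency profile (NaN where non-rhythmic)
    step = max(1, int(fs / 19.0))
    f_truth = f_inst[::step].astype(float)
    f_truth[f_truth == 0.0] = np.nan
    truth.f_times, truth.f_hz = t[::step], f_truth

    if tonic is not None:
        clamp = (spec.tonic_amplitude_factor
                 * _smooth_gate(t, tonic, min(spec.tonic_ramp,
                                              spec.tonic_onset_duration / 2)))
    data = np.empty((len(spec.channels), n))
    infos = []
    for i, ch in enumerate(spec.channels):
        c = phi - ch.phase_offset_deg / 360.0
        duty = np.full(n, ch.duty)
        amp_mod = np.ones(n)
        if has_light:
            duty[in_light] = min(ch.duty * ch.light_duty_factor, 0.98)
            amp_mod[in_light] = ch.light_amp_factor
        env = _pulse(c % 1.0, duty, w_cycles) * amp_mod
        if tonic is not None:
            env = np.maximum(env, clamp)
        if spec.active_window is not None:
            env *= _smooth_gate(t, spec.active_window, 0.3)

        if spec.carrier == "spikes":
            rng = child_rng(seed, "carrier", i)
            rate = 400.0  # Hz, population firing within bursts
            train = (rng.random(n) < rate / fs).astype(float)
            kernel = np.array([0.0, 1.0, -0.6, -0.2, 0.1])
            carrier = np.convolve(train, kernel, mode="same")
            carrier -= carrier.mean()
        else:
            carrier = child_rng(seed, "carrier", i).standard_normal(n)
        noise = child_rng(seed, "baseline", i).standard_normal(n)
        data[i] = ch.amplitude * (spec.baseline_noise * noise + env * carrier)
        infos.append(ChannelInfo(name=ch.name, side=ch.side,
                                 segment=ch.segment, role=ch.role))

        # true square-edge burst boundaries from the phase trajectory
        ks = np.arange(np.ceil(c[0] + 1e-9), np.floor(c[-1] - 1e-9) + 1)
        onsets = np.interp(ks, c, t)
        duty_at_onset = duty[np.minimum(np.searchsorted(t, onsets),
                                        n - 1)]
        offsets = np.interp(ks + duty_at_onset, c, t)
        if tonic is not None:  # boundaries swallowed by the clamp are not bursts
            keep = ~((onsets >= tonic[0]) & (onsets < tonic[1]))
            onsets, offsets = onsets[keep], offsets[keep]
        duty_light = (min(ch.duty * ch.light_duty_factor, 0.98)
                      if has_light else ch.duty)
        truth.channels[ch.name] = {
            "onsets": onsets,
            "offsets": offsets,
            "phase_offset_deg": ch.phase_offset_deg,
            "duty": {"pre": ch.duty, "light": duty_light, "post": ch.duty},
            "amplitude": {"pre": ch.amplitude,
                          "light": ch.amplitude * ch.light_amp_factor,
                          "post": ch.amplitude},
        }

    events = Events(light_on=light_on, light_off=light_off,
                    stim_times=protocol.stim_times, stim_rate=protocol.stim_rate)
    rec = RawRecording(data=data, fs=fs, channels=infos, events=events,
                       meta={"seed": int(seed)})
    return rec, truth


# ---------------------------------------------------------- intracellular

@dataclass
class IntracellularTrace:
    """Membrane-potential trace (mV) with optional current-step protocol."""

    vm: np.ndarray            # mV
    fs: float
    cell: str = ""
    epochs: dict = field(default_factory=dict)
    current_steps: list[tuple[float, float]] | None = None  # (nA, steady mV)
    meta: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.vm.size) / self.fs


def _spike_template(fs: float, amplitude: float) -> np.ndarray:
    """Stereotyped action-potential waveform: 0.5 ms rise, 1.2 ms decay, AHP."""
    t = np.arange(int(0.004 * fs)) / fs
    wf = amplitude * (np.exp(-t / 0.0012) - np.exp(-t / 0.0003))
    wf /= wf.max()
    wf *= amplitude
    ahp = -0.12 * amplitude * np.exp(-t / 0.0015) * (t > 0.0015)
    return wf + ahp


def simulate_intracellular(
    protocol: Protocol,
    drive_amplitude: float | dict,
    baseline_vm: float = -60.0,
    spike_rate_gain: float = 0.0,
    seed: int = 0,
    rhythm_frequency: float = 0.33,
    noise_mv: float = 0.3,
    spike_amplitude: float = 75.0,
    refractory: float = 0.008,
) -> tuple[IntracellularTrace, GroundTruth]:
    """Membrane trace with rhythm-locked synaptic drive and spikes.

    ``drive_amplitude`` (peak-to-trough, mV) may be a scalar or an
    ``{"pre", "light", "post"}`` mapping for light-modulated drive.  Spikes
    are emitted by an inhomogeneous point process with rate
    ``spike_rate_gain * drive(t)`` (spikes/s per mV above the drive trough)
    and an absolute refractory period.
    """
    if spike_rate_gain < 0:
        raise ValueError("spike_rate_gain must be >= 0")
    if isinstance(drive_amplitude, dict):
        amp = dict(drive_amplitude)
    else:
        amp = {"pre": float(drive_amplitude), "light": float(drive_amplitude),
               "post": float(drive_amplitude)}
    if min(amp.values()) < 0:
        raise ValueError("drive_amplitude must be >= 0")

    fs = protocol.sampling_rate
    n = int(round(protocol.total_duration * fs))
    t = np.arange(n) / fs
    a = np.full(n, amp["pre"])
    epochs = {"pre": (0.0, protocol.total_duration)}
    if protocol.light_on is not None:
        in_light = (t >= protocol.light_on) & (t < protocol.light_off)
        a[in_light] = amp["light"]
        a[t >= protocol.light_off] = amp["post"]
        epochs = {"pre": (0.0, protocol.light_on),
                  "light": (protocol.light_on, protocol.light_off),
                  "post": (protocol.light_off, protocol.total_duration)}

    phase0 = child_rng(seed, "ic-phase0").uniform()
    drive = a * 0.5 * (1.0 - np.cos(2 * np.pi * (rhythm_frequency * t + phase0)))
    vm = baseline_vm + drive
    vm += noise_mv * child_rng(seed, "ic-noise").standard_normal(n)

    # inhomogeneous Poisson spikes with absolute refractory period
    rng = child_rng(seed, "ic-spikes")
    p = np.clip(spike_rate_gain * drive / fs, 0.0, 1.0)
    cand = np.flatnonzero(rng.random(n) < p)
    spikes = []
    last = -np.inf
    for i in cand:
        if t[i] - last >= refractory:
            spikes.append(i)
            last = t[i]
    spikes = np.asarray(spikes, dtype=int)
    if spikes.size:
        tpl = _spike_template(fs, spike_amplitude)
        for i in spikes:
            j = min(i + tpl.size, n)
            vm[i:j] += tpl[: j - i]

    truth = GroundTruth(
        seed=int(seed), base_frequency=rhythm_frequency,
        spike_times=t[spikes], drive_amplitude=amp,
        params={"baseline_vm": baseline_vm, "spike_rate_gain": spike_rate_gain,
                "phase0": phase0},
    )
    trace = IntracellularTrace(vm=vm, fs=fs, epochs=epochs,
                               meta={"seed": int(seed)})
    return trace, truth


# --------------------------------------------------------------- calcium

def simulate_calcium(
    protocol: Protocol,
    cells: list[tuple],
    neuropil_amplitude: float = 0.2,
    bleach: tuple[float, float] = (0.3, 60.0),
    frame_rate: float = 6.0,
    seed: int = 0,
    field_shape: tuple[int, int] = (64, 64),
    rhythm_frequency: float = 0.3,
    base_intensity: float = 100.0,
    cell_brightness: float = 80.0,
    noise_scale: float = 1.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Synthetic calcium movie: cell blobs + shared neuropil + bleaching.

    ``cells`` is a list of ``(center_yx, radius_px, rhythmic_amplitude,
    phase_deg)``.  Each frame is static anatomy plus rhythmically modulated
    cell blobs plus a spatially smooth neuropil component sharing the rhythm,
    all multiplied by a monoexponential bleaching factor, plus shot-like
    noise.  Returns ``(stack, truth)`` with ``stack`` of shape
    ``(n_frames, ny, nx)``.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    b_amp, b_tau = bleach
    if b_tau <= 0:
        raise ValueError("bleach tau must be positive")
    ny, nx = field_shape
    n_frames = int(round(protocol.total_duration * frame_rate))
    tf = np.arange(n_frames) / frame_rate

    yy, xx = np.mgrid[0:ny, 0:nx]
    anatomy = base_intensity * (1.0 + 0.1 * np.sin(2 * np.pi * yy / ny))

    rhythm = lambda ph_deg: 0.5 * (1.0 - np.cos(          # noqa: E731
        2 * np.pi * rhythm_frequency * tf - np.deg2rad(ph_deg)))

    frames = np.tile(anatomy[None], (n_frames, 1, 1))
    clean = np.zeros((len(cells), n_frames))
    cell_meta = []
    for k, (center, radius, amp, phase) in enumerate(cells):
        cy, cx = center
        if not (radius <= cy <= ny - 1 - radius and radius <= cx <= nx - 1 - radius):
            raise ValueError(f"cell {k} lies outside the field of view")
        blob = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * (radius / 1.5) ** 2))
        trace = cell_brightness * (1.0 + amp * rhythm(phase))
        frames += blob[None] * trace[:, None, None]
        clean[k] = trace
        cell_meta.append({"center": [cy, cx], "radius": radius,
                          "amplitude": amp, "phase_deg": float(wrap_deg(phase))})

    if neuropil_amplitude > 0:
        smooth = 0.5 + 0.5 * np.cos(np.pi * (xx - nx / 2) / nx) \
                           * np.cos(np.pi * (yy - ny / 2) / ny)
        np_trace = base_intensity * neuropil_amplitude * rhythm(0.0)
        frames += smooth[None] * np_trace[:, None, None]

    bleach_t = 1.0 - b_amp * (1.0 - np.exp(-tf / b_tau))
    frames *= bleach_t[:, None, None]

    if noise_scale > 0:
        rng = child_rng(seed, "ca-noise")
        frames += noise_scale * np.sqrt(np.maximum(frames, 0)) \
            * rng.standard_normal(frames.shape)

    truth = GroundTruth(
        seed=int(seed), base_frequency=rhythm_frequency,
        bleach=(b_amp, b_tau), cell_traces=clean,
        params={"cells": cell_meta, "neuropil_amplitude": neuropil_amplitude,
                "frame_rate": frame_rate},
    )
    return frames, truth


# ------------------------------------------------------- cohort presets

def stratified_normal(mean: float, sd: float, n: int,
                      rng: np.random.Generator, clip_sd: float = 2.0) -> np.ndarray:
    """Moment-matched sample: inverse-CDF at equal-probability stratum midpoints,
    truncated at ``clip_sd`` standard deviations, in random order."""
    z = stats.norm.ppf((np.arange(n) + 0.5) / n)
    z = np.clip(z, -clip_sd, clip_sd)
    return mean + sd * rng.permutation(z)


def _anti_assign(values: np.ndarray, keys: np.ndarray) -> np.ndarray:
    """Assign sorted ``values`` (ascending) against sorted ``keys`` (descending):
    the largest key receives the smallest value.  Marginals are unchanged."""
    out = np.empty_like(values)
    out[np.argsort(-keys)] = np.sort(values)
    return out


def _wholecord_designs(n: int, seed: int, n_trials: int) -> list[dict]:
    # Drug-evoked whole-cord scenario: light slows the rhythm ~15 %
    # (0.33 -> 0.29 Hz), flexor burst duration x1.402, extensor x1.1963,
    # pre-light duties extensor 0.59 / flexor 0.53.
    rng = child_rng(seed, "cohort", "wholecord-arch")
    f0 = stratified_normal(0.33, 0.06, n, rng)
    ffac = stratified_normal(0.29 / 0.33, 0.05, n, rng)
    duty_fl = stratified_normal(0.53, 0.07, n, rng)
    duty_ex = stratified_normal(0.59, 0.04, n, rng)
    durf_fl = _anti_assign(stratified_normal(1.402, 0.1525, n, rng), duty_fl)
    durf_ex = _anti_assign(stratified_normal(1.1963, 0.2237, n, rng), duty_ex)
    designs = []
    for i in range(n):
        chans = [
            dict(name="lL2", role="flexor", side="left", segment="L2",
                 phase_offset_deg=0.0, duty=duty_fl[i],
                 light_amp_factor=1.30, light_duty_factor=durf_fl[i] * ffac[i]),
            dict(name="rL2", role="flexor", side="right", segment="L2",
                 phase_offset_deg=180.0, duty=duty_fl[i],
                 light_amp_factor=1.30, light_duty_factor=durf_fl[i] * ffac[i]),
            dict(name="lL5", role="extensor", side="left", segment="L5",
                 phase_offset_deg=180.0, duty=duty_ex[i],
                 light_amp_factor=1.20, light_duty_factor=durf_ex[i] * ffac[i]),
        ]
        designs.append(dict(
            preset="wholecord-arch", mode="drug", index=i,
            base_frequency=f0[i], light_freq_factor=ffac[i],
            duration_factors={"flexor": durf_fl[i], "extensor": durf_ex[i]},
            channels=chans, tonic_onset_duration=0.0,
            n_trials=n_trials, trial_jitter=0.05,
            protocol=dict(total_duration=180.0, light_on=60.0, light_off=120.0),
        ))
    return designs


def _hemicord_designs(n: int, seed: int, n_trials: int) -> list[dict]:
    # Hemicord scenario: tonic onset (10 s) at the light, then rhythmic
    # activity accelerated from 0.10 to 0.17 Hz; extensor burst duration
    # x0.6061 (-39.39 %), flexor x1.1268; pre duties flexor 0.35 / ext 0.61.
    rng = child_rng(seed, "cohort", "hemicord-arch")
    # Pre-light and light-epoch rhythmic frequencies are rank-coupled
    # (experiments with faster baselines stay faster under light), which
    # keeps the implied per-experiment speed-up within the observed range.
    f0 = np.sort(stratified_normal(0.10, 0.02, n, rng))
    f1 = np.sort(stratified_normal(0.17, 0.06, n, rng))
    ratio = f1 / f0
    durf_ex = _anti_assign(stratified_normal(0.6061, 0.2236, n, rng), ratio)
    durf_fl = _anti_assign(stratified_normal(1.1268, 0.2385, n, rng), ratio)
    duty_fl = _anti_assign(stratified_normal(0.35, 0.06, n, rng), durf_fl * ratio)
    duty_ex = _anti_assign(stratified_normal(0.61, 0.09, n, rng), durf_ex * ratio)
    ampf_fl = stratified_normal(1 - 0.3525, 0.1711, n, rng)
    ampf_ex = stratified_normal(1 + 0.6114, 0.4554, n, rng)
    perm = rng.permutation(n)
    designs = []
    for j in range(n):
        i = perm[j]
        chans = [
            dict(name="L2", role="flexor", side="left", segment="L2",
                 phase_offset_deg=0.0, duty=duty_fl[i],
                 light_amp_factor=max(ampf_fl[i], 0.2),
                 light_duty_factor=min(durf_fl[i] * ratio[i],
                                       0.88 / duty_fl[i])),
            dict(name="L5", role="extensor", side="left", segment="L5",
                 phase_offset_deg=180.0, duty=duty_ex[i],
                 light_amp_factor=max(ampf_ex[i], 0.3),
                 light_duty_factor=min(durf_ex[i] * ratio[i],
                                       0.88 / duty_ex[i])),
        ]
        designs.append(dict(
            preset="hemicord-arch", mode="drug", index=j,
            base_frequency=f0[i], light_freq_factor=ratio[i],
            light_frequency=f1[i],
            duration_factors={"flexor": durf_fl[i], "extensor": durf_ex[i]},
            channels=chans, tonic_onset_duration=10.0, tonic_amplitude_factor=1.5,
            n_trials=n_trials, trial_jitter=0.05,
            protocol=dict(total_duration=180.0, light_on=60.0, light_off=120.0),
        ))
    return designs


def _dr_evoked_designs(n: int, seed: int, n_trials: int) -> list[dict]:
    # Sacral dorsal-root-evoked scenario: 4 Hz train for 10 s; light reduces
    # the evoked rhythm frequency by 21.6 % +/- 10.23 % (0.89 -> 0.69 Hz).
    rng = child_rng(seed, "cohort", "dr-evoked-arch")
    f0 = stratified_normal(0.89, 0.08, n, rng)
    red = stratified_normal(21.6, 10.23, n, rng)      # percent reduction
    designs = []
    for i in range(n):
        chans = [
            dict(name="lL2", role="flexor", side="left", segment="L2",
                 phase_offset_deg=0.0, duty=0.53, light_amp_factor=1.3003),
            dict(name="rL2", role="flexor", side="right", segment="L2",
                 phase_offset_deg=180.0, duty=0.53, light_amp_factor=1.3003),
            dict(name="lL5", role="extensor", side="left", segment="L5",
                 phase_offset_deg=180.0, duty=0.59, light_amp_factor=1.6777),
        ]
        designs.append(dict(
            preset="dr-evoked-arch", mode="evoked", index=i,
            base_frequency=f0[i], light_freq_factor=1.0 - red[i] / 100.0,
            reduction_pct=red[i],
            channels=chans, n_trials=n_trials, trial_jitter=0.05,
            protocol=dict(total_duration=20.0, stim_start=3.0, stim_rate=4.0,
                          train_duration=10.0),
        ))
    return designs


PRESETS = {
    "wholecord-arch": dict(builder=_wholecord_designs, n_default=16),
    "hemicord-arch": dict(builder=_hemicord_designs, n_default=13),
    "dr-evoked-arch": dict(builder=_dr_evoked_designs, n_default=12),
}


def design_cohort(preset: str, n_experiments: int | None = None,
                  seed: int = 0, n_trials: int = 3) -> list[dict]:
    """Draw per-experiment parameters for a scenario preset."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    entry = PRESETS[preset]
    n = n_experiments if n_experiments is not None else entry["n_default"]
    return entry["builder"](n, seed, n_trials)


def _trial_spec(design: dict, trial: int, seed: int) -> tuple[Protocol, RhythmSpec]:
    jit = design.get("trial_jitter", 0.0)
    z = float(np.clip(child_rng(seed, "trial-jitter", design["index"], trial)
                      .standard_normal(), -2, 2))
    f_trial = design["base_frequency"] * (1.0 + jit * z)
    channels = [ChannelSpec(**c) for c in design["channels"]]
    proto = Protocol(**design["protocol"])
    spec = RhythmSpec(
        base_frequency=f_trial,
        channels=channels,
        light_freq_factor=design.get("light_freq_factor", 1.0),
        tonic_onset_duration=design.get("tonic_onset_duration", 0.0),
        tonic_amplitude_factor=design.get("tonic_amplitude_factor", 1.5),
    )
    return proto, spec


def simulate_experiment(design: dict, seed: int = 0) -> list[dict]:
    """Simulate all trials of one designed experiment.

    Drug mode returns ``[{"recording", "truth"}, ...]`` (one per trial).
    Evoked mode returns ``[{"condition": "control"|"light", "recording",
    "truth"}, ...]`` with ``n_trials`` per condition, since control and
    illuminated stimulus trains are separate episodes.
    """
    out = []
    if design["mode"] == "drug":
        for k in range(design["n_trials"]):
            proto, spec = _trial_spec(design, k, seed)
            rec, truth = simulate_neurograms(
                proto, spec, seed=child_seed(seed, design["index"], k))
            rec.meta.update(preset=design["preset"], experiment=design["index"],
                            trial=k)
            out.append({"recording": rec, "truth": truth})
        return out
    # evoked: separate control and light episodes
    for cond in ("control", "light"):
        for k in range(design["n_trials"]):
            proto, spec = _trial_spec(design, k, seed)
            if cond == "light":
                spec.base_frequency *= design["light_freq_factor"]
            else:
                for ch in spec.channels:
                    ch.light_amp_factor = 1.0
            spec.light_freq_factor = 1.0
            spec.active_window = (proto.stim_start,
                                  proto.stim_start + proto.train_duration + 1.0)
            # light factors gate on the episode itself in light trials
            lit = cond == "light"
            for ch in spec.channels:
                if lit:
                    ch.amplitude *= ch.light_amp_factor
                ch.light_amp_factor = 1.0
            rec, truth = simulate_neurograms(
                proto, spec, seed=child_seed(seed, design["index"], cond, k))
            rec.meta.update(preset=design["preset"], experiment=design["index"],
                            trial=k, condition=cond)
            out.append({"condition": cond, "recording": rec, "truth": truth})
    return out


def child_seed(root_seed, *context) -> int:
    """Small deterministic integer seed derived from a root seed and context."""
    from .core import child_seed as _cs
    return int(_cs(root_seed, *context).generate_state(1)[0] % (2**31))
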