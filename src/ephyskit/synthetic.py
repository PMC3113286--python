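"""Simulated recordings with known ground truth.

The generator writes continuous multichannel recordings with an event list
and injected components, so every analysis stage can be tested against known
truth without any external dataset. The physics it emulates is deliberately
minimal: additive Gaussian sensor noise (white or 1/f "pink"), plus
stereotyped event-locked components:

``evoked_wave``
    Gaussian-windowed cosine burst with the *same* phase on every trial —
    survives trial averaging (phase-locked, "evoked" activity).
``induced_burst``
    The same burst with an independent uniform random phase per trial —
    cancels in the average but not in averaged single-trial power
    ("induced" activity).
``coupled_pair``
    An induced burst placed on two channels with a fixed phase lag, for
    phase-synchrony tests.
``artifact_step``
    A DC step of given amplitude (drives artifact-rejection tests).
``dc_topography``
    A constant offset on the affected channels for the component duration.

Determinism: the integer ``seed`` fully determines the output. Noise, event
jitter, and each component draw from separate, stably derived substreams, so
adding a component never changes another component's randomness or the
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ContinuousRecord, EventList, Montage
from .errors import ParameterError

__all__ = ["SimComponent", "SimSpec", "simulate", "harmonic_topography",
           "fibonacci_montage"]

_NOISE_STREAM = 0x501ABEEF
_EVENT_STREAM = 0x0E7E97


@dataclass
class SimComponent:
    """One injected signal component, time-locked to events of one code."""

    kind: str  # evoked_wave | induced_burst | coupled_pair | artifact_step | dc_topography
    channels: list[int]
    latency: float  # s relative to event
    duration: float  # s
    amplitude: float
    frequency: float | None = None  # Hz, oscillatory kinds
    phase: float = 0.0  # rad, fixed-phase kinds
    phase_policy: str = "fixed"  # fixed | uniform_random_per_trial
    phase_lag: float = 0.0  # rad, coupled_pair
    partner: int | None = None  # coupled_pair partner channel
    event_code: int | None = None  # None: lock to every event

    KINDS = ("evoked_wave", "induced_burst", "coupled_pair",
             "artifact_step", "dc_topography")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ParameterError(f"unknown component kind {self.kind!r}")
        if self.duration <= 0:
            raise ParameterError("component duration must be > 0")
        if self.amplitude < 0:
            raise ParameterError("component amplitude must be >= 0")
        if self.kind in ("evoked_wave", "induced_burst", "coupled_pair"):
            if self.frequency is None or self.frequency <= 0:
                raise ParameterError(f"{self.kind} needs a positive frequency")
        if self.kind in ("induced_burst", "coupled_pair"):
            # induced oscillations: phase varies trial to trial (the pair
            # keeps its lag, not its stimulus phase)
            self.phase_policy = "uniform_random_per_trial"
        if self.kind == "coupled_pair" and self.partner is None:
            raise ParameterError("coupled_pair needs a partner channel")


@dataclass
class SimSpec:
    """Full description of a simulated recording."""

    fs: float = 512.0
    n_channels: int = 4
    duration: float | None = None  # s; None: sized to fit the events
    noise: str = "white"  # white | pink
    noise_sd: float = 1.0
    #: (code, n_trials, inter-trial interval s, uniform jitter half-width s)
    events: list[tuple[int, int, float, float]] = field(
        default_factory=lambda: [(1, 20, 1.0, 0.0)])
    components: list[SimComponent] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.noise not in ("white", "pink"):
            raise ParameterError("noise must be 'white' or 'pink'")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        for comp in self.components:
            if comp.frequency is not None and comp.frequency >= self.fs / 2:
                raise ParameterError(
                    f"component frequency {comp.frequency} Hz is at or above "
                    f"Nyquist ({self.fs / 2} Hz)")


def _pink_noise(rng: np.random.Generator, n_ch: int, n_samp: int,
                sd: float, fs: float) -> np.ndarray:
    """1/f-amplitude noise by spectral shaping of white noise."""
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    shaping[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * shaping, n=n_samp, axis=1)
    std = shaped.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return sd * shaped / std


def _burst(t: np.ndarray, comp: SimComponent, phase: float) -> np.ndarray:
    """Gaussian-windowed cosine centred in the component window."""
    tc = comp.latency + comp.duration / 2.0
    sigma = comp.duration / 6.0  # +-3 sigma spans the stated duration
    env = np.exp(-((t - tc) ** 2) / (2.0 * sigma ** 2))
    return comp.amplitude * env * np.cos(
        2.0 * np.pi * comp.frequency * (t - tc) + phase)


def simulate(spec: SimSpec) -> ContinuousRecord:
    """Render a SimSpec into a ContinuousRecord with its EventList."""
    fs = spec.fs
    rng_ev = np.random.default_rng([spec.seed, _EVENT_STREAM])

    lead = 2.0  # s of padding before the first and after the last event
    samples, codes = [], []
    cursor = lead
    for code, n_trials, iti, jitter in spec.events:
        for _ in range(int(n_trials)):
            t = cursor
            if jitter > 0:
                t += rng_ev.uniform(-jitter, jitter)
            samples.append(int(round(t * fs)))
            codes.append(int(code))
            cursor += iti
    duration = spec.duration
    if duration is None:
        duration = (max(samples) / fs if samples else 0.0) + lead
    n_samp = int(round(duration * fs))
    if samples and max(samples) >= n_samp:
        raise ParameterError("declared duration too short for the event train")

    rng_noise = np.random.default_rng([spec.seed, _NOISE_STREAM])
    if spec.noise_sd == 0:
        data = np.zeros((spec.n_channels, n_samp))
    elif spec.noise == "white":
        data = spec.noise_sd * rng_noise.standard_normal((spec.n_channels, n_samp))
    else:
        data = _pink_noise(rng_noise, spec.n_channels, n_samp, spec.noise_sd, fs)

    events = EventList(samples, codes)
    for ci, comp in enumerate(spec.components):
        rng_c = np.random.default_rng([spec.seed, 1000 + ci])
        locked = [
            int(s) for s, c in zip(events.samples, events.codes)
            if comp.event_code is None or c == comp.event_code
        ]
        n0 = int(np.floor(comp.latency * fs)) - 1
        n1 = int(np.ceil((comp.latency + comp.duration) * fs)) + 1
        offsets = np.arange(n0, n1 + 1)
        t_rel = offsets / fs
        for s0 in locked:
            if comp.kind == "artifact_step":
                wave = np.full(t_rel.size, comp.amplitude)
            elif comp.kind == "dc_topography":
                wave = np.full(t_rel.size, comp.amplitude)
            else:
                if comp.phase_policy == "uniform_random_per_trial":
                    phase = rng_c.uniform(0.0, 2.0 * np.pi)
                else:
                    phase = comp.phase
                wave = _burst(t_rel, comp, phase)
            idx = s0 + offsets
            valid = (idx >= 0) & (idx < n_samp)
            targets = list(comp.channels)
            waves = [wave]
            if comp.kind == "coupled_pair":
                waves = [wave] * len(targets)
                targets = targets + [comp.partner]
                waves.append(_burst(t_rel, comp, phase + comp.phase_lag))
            for ch, w in zip(targets, waves):
                data[ch, idx[valid]] += w[valid]

    names = [f"ch{i + 1}" for i in range(spec.n_channels)]
    units = ["uV"] * spec.n_channels
    return ContinuousRecord(data, fs, names, units, events)


# ------------------------------------------------------------- topographies

def fibonacci_montage(n_channels: int = 64, z_min: float = -0.25) -> Montage:
    """Quasi-uniform synthetic electrode cap on the unit sphere.

    Points follow a spherical Fibonacci lattice restricted to ``z > z_min``
    (a cap covering somewhat more than the upper hemisphere, like a dense
    EEG montage extending below the equator).
    """
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    pts: list[tuple[float, float, float]] = []
    # oversample the full sphere until enough points land inside the cap
    n_total = n_channels
    while len(pts) < n_channels:
        pts = []
        for k in range(n_total):
            z = 1.0 - 2.0 * (k + 0.5) / n_total
            if z <= z_min:
                continue
            r = np.sqrt(max(0.0, 1.0 - z * z))
            phi = 2.0 * np.pi * k / golden
            pts.append((r * np.cos(phi), r * np.sin(phi), z))
        n_total += 1
    labels = [f"E{i + 1}" for i in range(n_channels)]
    return Montage(labels, np.asarray(pts[:n_channels]))


def harmonic_topography(montage: Montage, degree: int, order: int = 0,
                        scale: float = 1.0) -> np.ndarray:
    """Real spherical harmonic Y_n^m sampled at the electrode positions.

    Serves as an analytic oracle for spherical-spline interpolation and the
    surface Laplacian: on the unit sphere the Laplace-Beltrami operator has
    eigenvalue -n(n+1) on Y_n^m, so the scalp current density of this
    topography on a sphere of radius r is n(n+1)/r^2 times the potential.
    """
    if order < -degree or order > degree:
        raise ParameterError("need -degree <= order <= degree")
    from scipy.special import sph_harm_y

    x, y, z = montage.positions.T
    theta = np.arccos(np.clip(z, -1.0, 1.0))  # polar angle
    phi = np.arctan2(y, x)  # azimuth
    m = abs(order)
    ylm = sph_harm_y(degree, m, theta, phi)
    if order == 0:
        vals = ylm.real
    elif order > 0:
        vals = np.sqrt(2.0) * (-1.0) ** m * ylm.real
    else:
        vals = np.sqrt(2.0) * (-1.0) ** m * ylm.imag
    return scale * vals
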