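"""Morlet/Gabor time-frequency transforms, power maps, and phase locking.

The workhorse is the complex Morlet wavelet

    w(t, f) = A exp(-t^2 / (2 sigma_t^2)) exp(i 2 pi f t),
    sigma_t = m / (2 pi f),

with ``m`` cycles (default 7) and A chosen for unit energy
(``integral |w|^2 dt = 1``) so power is comparable across frequencies. The
Gabor variant is the same machinery with a *fixed* Gaussian window SD in
seconds, i.e. a sliding-window Fourier analysis with one-sample hop.

Single-trial convolution is computed per frequency by FFT convolution after
reflection padding; samples closer than two wavelet SDs to an epoch edge
are flagged as unreliable (stored in the output record's ``extra``
metadata), not deleted.

Evoked versus induced activity: power averaged over single-trial transforms
retains activity regardless of its phase relation to the event; the
transform of the trial-averaged signal (or the phase-locking factor) keeps
only phase-locked activity; subtracting the evoked average from each trial
before transforming isolates the induced part.

The phase-locking factor (intertrial coherence) at each (t, f) point is the
resultant length of the unit phase vectors across trials,
``PLF = |mean_k exp(i phi_k)|``: 0 for random phase, 1 for perfect locking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .containers import EvokedRecord, TFRecord
from .epochs import EpochSet
from .errors import ParameterError

__all__ = ["WaveletSpec", "tf_transform", "tf_power_avg", "tf_evoked_power",
           "tf_subtract_evoked", "plf", "tf_baseline", "band_course",
           "morlet_kernel"]


@dataclass
class WaveletSpec:
    """Frequency grid and wavelet family for a TF analysis."""

    freqs: np.ndarray
    n_cycles: float | np.ndarray = 7.0
    family: str = "morlet"  # morlet | gabor
    window_sd: float = 0.05  # s, gabor only

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=np.float64).reshape(-1)
        if self.freqs.size == 0 or np.any(self.freqs <= 0):
            raise ParameterError("frequencies must be positive")
        if np.any(np.diff(self.freqs) <= 0):
            raise ParameterError("frequencies must be strictly increasing")
        if self.family not in ("morlet", "gabor"):
            raise ParameterError("family must be 'morlet' or 'gabor'")
        cyc = np.broadcast_to(np.asarray(self.n_cycles, dtype=np.float64),
                              self.freqs.shape).copy()
        if np.any(cyc < 1):
            raise ParameterError("n_cycles must be >= 1")
        self.n_cycles = cyc
        if self.window_sd <= 0:
            raise ParameterError("window_sd must be > 0")

    def sigma_t(self) -> np.ndarray:
        """Temporal SD of each wavelet, in seconds."""
        if self.family == "gabor":
            return np.full(self.freqs.shape, self.window_sd)
        return self.n_cycles / (2.0 * np.pi * self.freqs)


def morlet_kernel(freq: float, sigma_t: float, fs: float) -> np.ndarray:
    """Unit-energy complex wavelet sampled out to +-5 sigma_t."""
    half = int(np.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(-t ** 2 / (2.0 * sigma_t ** 2)) * np.exp(2j * np.pi * freq * t)
    energy = np.sum(np.abs(w) ** 2) / fs
    return w / np.sqrt(energy)


def _check_freqs(spec: WaveletSpec, fs: float, n_samples: int) -> None:
    if np.any(spec.freqs >= fs / 2.0):
        raise ParameterError(
            f"frequencies must be below Nyquist ({fs / 2.0} Hz)")
    sigma = spec.sigma_t()
    if n_samples / fs < 2.0 * sigma.max():
        warnings.warn(
            "epoch shorter than two wavelet SDs at the lowest frequency; "
            "edge effects dominate", stacklevel=3)


def tf_transform(e: EpochSet, spec: WaveletSpec) -> np.ndarray:
    """Complex wavelet coefficients, trials x channels x freqs x samples."""
    _check_freqs(spec, e.fs, e.n_samples)
    n_tr, n_ch, n_s = e.data.shape
    sigmas = spec.sigma_t()
    out = np.empty((n_tr, n_ch, spec.freqs.size, n_s), dtype=np.complex128)
    flat = e.data.reshape(n_tr * n_ch, n_s)
    for fi, (f, st) in enumerate(zip(spec.freqs, sigmas)):
        w = morlet_kernel(float(f), float(st), e.fs)
        half = (w.size - 1) // 2
        pad = min(half, n_s - 1)
        padded = np.pad(flat, [(0, 0), (pad, pad)], mode="reflect")
        conv = _sig.fftconvolve(padded, np.conj(w[::-1])[None, :], mode="same",
                                axes=1)
        out[:, :, fi, :] = conv[:, pad:pad + n_s].reshape(n_tr, n_ch, n_s)
    return out


def _edge_invalid(spec: WaveletSpec, fs: float, n_samples: int) -> list[int]:
    """Per-frequency count of unreliable samples at each epoch edge."""
    return [int(min(np.ceil(2.0 * st * fs), n_samples)) for st in spec.sigma_t()]


def _make_tfr(e: EpochSet, spec: WaveletSpec, data: np.ndarray, quantity: str,
              channel_names=None, channel_units=None) -> TFRecord:
    extra = {"edge_invalid_samples": _edge_invalid(spec, e.fs, e.n_samples),
             "family": spec.family,
             "n_cycles": np.asarray(spec.n_cycles).tolist()}
    return TFRecord(data, spec.freqs, e.fs, e.t0, e.event_code, e.n_trials,
                    quantity,
                    channel_names if channel_names is not None else list(e.channel_names),
                    channel_units if channel_units is not None else list(e.channel_units),
                    extra)


def tf_power_avg(e: EpochSet, spec: WaveletSpec) -> TFRecord:
    """Mean over trials of single-trial power (evoked + induced activity)."""
    coefs = tf_transform(e, spec)
    power = np.mean(np.abs(coefs) ** 2, axis=0)
    return _make_tfr(e, spec, power, "power")


def _as_single_trial(data: np.ndarray, e: EpochSet) -> EpochSet:
    return EpochSet(data[None, :, :], e.fs, e.t0, e.event_code,
                    np.array([0]), np.array([0]),
                    list(e.channel_names), list(e.channel_units))


def tf_evoked_power(e: EpochSet, spec: WaveletSpec) -> TFRecord:
    """Power of the trial-averaged signal (phase-locked activity only)."""
    avg = _as_single_trial(e.data.mean(axis=0), e)
    coefs = tf_transform(avg, spec)
    power = np.abs(coefs[0]) ** 2
    tfr = _make_tfr(e, spec, power, "evoked_power")
    tfr.n_trials = e.n_trials
    return tfr


def tf_subtract_evoked(e: EpochSet, ev: EvokedRecord, spec: WaveletSpec
                       ) -> TFRecord:
    """Average power after removing the evoked response from every trial.

    Subtracting the evoked average waveform from each single trial before
    the transform cancels phase-locked activity, leaving induced power.
    """
    if (ev.n_samples != e.n_samples or list(ev.channel_names) != list(e.channel_names)
            or abs(ev.t0 - e.t0) > 1e-12 or ev.fs != e.fs):
        raise ParameterError("evoked record does not match the epoch axes")
    resid = e.copy()
    resid.data = e.data - ev.data[None, :, :]
    tfr = tf_power_avg(resid, spec)
    return tfr


def plf(e: EpochSet, spec: WaveletSpec) -> TFRecord:
    """Phase-locking factor (intertrial coherence) across trials."""
    if e.n_trials < 2:
        raise ParameterError("phase-locking factor needs at least 2 trials")
    coefs = tf_transform(e, spec)
    mag = np.abs(coefs)
    with np.errstate(invalid="ignore", divide="ignore"):
        phases = np.where(mag > 0, coefs / np.where(mag == 0, 1.0, mag), 0.0)
    plv = np.abs(phases.mean(axis=0))
    plv = np.clip(plv, 0.0, 1.0)
    return _make_tfr(e, spec, plv, "plf",
                     channel_units=[""] * e.n_channels)


def tf_baseline(tfr: TFRecord, bwin: tuple[float, float], mode: str = "db"
                ) -> TFRecord:
    """Baseline-normalise a TF map per channel and frequency.

    Modes: ``subtract`` (P - B), ``ratio`` (P / B), ``db``
    (10 log10(P / B)), ``zscore`` ((P - B) / SD_baseline), with B the mean
    over the baseline samples of each (channel, frequency) row.
    """
    if mode not in ("subtract", "ratio", "db", "zscore"):
        raise ParameterError("mode must be subtract, ratio, db or zscore")
    b0, b1 = bwin
    times = tfr.times
    mask = (times >= b0) & (times < b1)
    if not mask.any():
        raise ParameterError("baseline window outside the TF epoch")
    base = tfr.data[:, :, mask].mean(axis=2, keepdims=True)
    if mode == "subtract":
        data = tfr.data - base
    elif mode in ("ratio", "db"):
        if np.any(base == 0):
            raise ParameterError("zero baseline mean; ratio/db undefined")
        data = tfr.data / base
        if mode == "db":
            if np.any(data <= 0):
                raise ParameterError("non-positive power ratio; db undefined")
            data = 10.0 * np.log10(data)
    else:
        sd = tfr.data[:, :, mask].std(axis=2, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ParameterError("zero baseline SD; zscore undefined")
        data = (tfr.data - base) / sd
    return TFRecord(data, tfr.freqs, tfr.fs, tfr.t0, tfr.event_code,
                    tfr.n_trials, "power", list(tfr.channel_names),
                    list(tfr.channel_units), dict(tfr.extra))


def band_course(tfr: TFRecord, f_lo: float, f_hi: float) -> EvokedRecord:
    """Mean time course of the frequency bins inside ``[f_lo, f_hi]``.

    Returns a standard event-locked record, so band power (or phase
    locking) re-enters the averaging/statistics pipeline like any ERP.
    """
    mask = (tfr.freqs >= f_lo) & (tfr.freqs <= f_hi)
    if not mask.any():
        raise ParameterError(
            f"band [{f_lo}, {f_hi}] Hz contains no frequency bin")
    course = tfr.data[:, mask, :].mean(axis=1)
    return EvokedRecord(course, tfr.fs, tfr.t0, tfr.event_code, tfr.n_trials,
                        list(tfr.channel_names), list(tfr.channel_units))
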