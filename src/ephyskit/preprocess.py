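"""Artifact rejection, filtering, and bad-channel reconstruction.

Rejection operations never touch the signal: they return an event list with
updated reject flags, mirroring the convention that trial bookkeeping lives
in the event file. Comparison against a threshold is strict (a trial whose
extreme value equals the threshold exactly is kept): a limit that "should
not be exceeded" rejects only values strictly beyond it.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .containers import ContinuousRecord, EventList, EvokedRecord, Montage
from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = ["reject_fixed_threshold", "reject_range", "butterworth_filter",
           "apply_fir", "interpolate_bad_channels"]


def _per_channel(values, rec: ContinuousRecord, name: str) -> np.ndarray:
    """Expand a scalar or {channel: value} mapping to a per-channel vector."""
    if np.isscalar(values):
        v = float(values)
        if v <= 0:
            raise ParameterError(f"{name} must be > 0")
        return np.full(rec.n_channels, v)
    out = np.full(rec.n_channels, np.inf)
    for ch, v in values.items():
        if float(v) <= 0:
            raise ParameterError(f"{name} must be > 0")
        out[rec.channel_index(ch)] = float(v)
    return out


def _iter_epochs(rec: ContinuousRecord, codes: Sequence[int],
                 window: tuple[float, float]):
    """Yield (event index, epoch slice or None-if-edge) for matching events."""
    t0, t1 = window
    if not t0 < t1:
        raise ParameterError("window must satisfy t0 < t1")
    n = int(round((t1 - t0) * rec.fs))
    if n < 1:
        raise ParameterError("window shorter than one sample")
    off = int(round(t0 * rec.fs))
    code_set = set(int(c) for c in codes)
    for i, ev in enumerate(rec.events):
        if ev.code not in code_set:
            continue
        start = ev.sample + off
        if start < 0 or start + n > rec.n_samples:
            yield i, None
        else:
            yield i, rec.data[:, start:start + n]


def reject_fixed_threshold(rec: ContinuousRecord, codes: Sequence[int],
                           window: tuple[float, float],
                           thresholds: float | Mapping[str, float]
                           ) -> EventList:
    """Flag trials whose absolute amplitude exceeds a fixed threshold.

    A trial is rejected as soon as any sample of any thresholded channel
    satisfies ``|x| > threshold`` inside the epoch window (e.g. +-75 uV for
    scalp EEG). Thresholds may be one number or a per-channel mapping;
    channels without a threshold are not checked. Epochs crossing a
    recording edge are rejected outright (reason logged).
    """
    thr = _per_channel(thresholds, rec, "threshold")
    rejects = rec.events.rejects.copy()
    for i, ep in _iter_epochs(rec, codes, window):
        if ep is None:
            logger.info("event %d rejected: epoch crosses recording edge", i)
            rejects[i] = True
            continue
        exceeded = np.abs(ep) > thr[:, None]
        if exceeded.any():
            rejects[i] = True
    return rec.events.with_rejects(rejects)


def reject_range(rec: ContinuousRecord, codes: Sequence[int],
                 window: tuple[float, float], win_len: float,
                 max_range: float | Mapping[str, float]) -> EventList:
    """Flag trials with too much variation inside any sliding sub-window.

    A trial is rejected when some channel shows ``max - min > max_range``
    within any window of ``round(win_len * fs)`` samples sliding one sample
    at a time through the epoch (e.g. 2000 fT within 500 ms for MEG).
    """
    w = int(round(win_len * rec.fs))
    if w < 2:
        raise ParameterError("win_len must span at least 2 samples")
    limit = _per_channel(max_range, rec, "max_range")
    rejects = rec.events.rejects.copy()
    for i, ep in _iter_epochs(rec, codes, window):
        if ep is None:
            logger.info("event %d rejected: epoch crosses recording edge", i)
            rejects[i] = True
            continue
        if ep.shape[1] < w:
            raise ParameterError("win_len longer than the epoch window")
        sw = np.lib.stride_tricks.sliding_window_view(ep, w, axis=1)
        ranges = sw.max(axis=2) - sw.min(axis=2)
        if (ranges > limit[:, None]).any():
            rejects[i] = True
    return rec.events.with_rejects(rejects)


def butterworth_filter(x: ContinuousRecord | EvokedRecord, kind: str,
                       cutoffs: float | Sequence[float], order: int = 4,
                       mode: str = "zero_phase"):
    """Butterworth filtering of every channel.

    ``kind`` is one of ``low``, ``high``, ``band``, ``stop``; band kinds
    take two cutoffs. ``zero_phase`` runs the filter forward and backward
    (no net phase shift, squared magnitude response, -6 dB at the cutoff);
    ``causal`` is a single forward pass (-3 dB at the cutoff). Edges are
    handled by odd-reflection padding.
    """
    btype = {"low": "lowpass", "high": "highpass", "band": "bandpass",
             "stop": "bandstop"}.get(kind)
    if btype is None:
        raise ParameterError("kind must be low, high, band or stop")
    if mode not in ("causal", "zero_phase"):
        raise ParameterError("mode must be 'causal' or 'zero_phase'")
    wn = np.atleast_1d(np.asarray(cutoffs, dtype=np.float64))
    if kind in ("band", "stop"):
        if wn.size != 2 or not wn[0] < wn[1]:
            raise ParameterError(f"{kind} filter needs two increasing cutoffs")
    elif wn.size != 1:
        raise ParameterError(f"{kind} filter takes a single cutoff")
    nyq = x.fs / 2.0
    if np.any(wn <= 0) or np.any(wn >= nyq):
        raise ParameterError(
            f"cutoffs must lie strictly inside (0, {nyq}) Hz")
    sos = signal.butter(order, wn if wn.size > 1 else float(wn[0]),
                        btype=btype, fs=x.fs, output="sos")
    out = x.copy()
    if mode == "zero_phase":
        out.data = signal.sosfiltfilt(sos, x.data, axis=-1)
    else:
        pad = min(3 * max(order, 1) * 2, x.data.shape[-1] - 1)
        padded = np.pad(x.data, [(0, 0)] * (x.data.ndim - 1) + [(pad, 0)],
                        mode="reflect")
        out.data = signal.sosfilt(sos, padded, axis=-1)[..., pad:]
    return out


def apply_fir(x: ContinuousRecord | EvokedRecord, coefficients):
    """Apply user-supplied FIR taps causally, same-length output.

    ``y[n] = sum_k b[k] x[n-k]`` with reflection padding at the left edge.
    """
    b = np.asarray(coefficients, dtype=np.float64).reshape(-1)
    if b.size == 0:
        raise ParameterError("need at least one coefficient")
    out = x.copy()
    if b.size == 1:
        out.data = b[0] * x.data
        return out
    pad = b.size - 1
    padded = np.pad(x.data, [(0, 0)] * (x.data.ndim - 1) + [(pad, 0)],
                    mode="reflect")
    filt = signal.lfilter(b, [1.0], padded, axis=-1)
    out.data = filt[..., pad:]
    return out


def interpolate_bad_channels(rec: ContinuousRecord | EvokedRecord,
                             montage: Montage, bad: Sequence[str]):
    """Reconstruct bad channels by spherical-spline interpolation.

    Fits the spline on the good channels at every time sample (one shared
    linear operator, so this is a single matrix product) and replaces the
    bad channels in a copy; good channels are untouched.
    """
    from .topomap import interpolation_matrix

    bad = list(bad)
    if not bad:
        return rec.copy()
    bad_idx = [rec.channel_index(ch) for ch in bad]
    good_idx = [i for i in range(rec.n_channels) if i not in bad_idx]
    if len(good_idx) < 4:
        raise ParameterError("need at least 4 good channels for interpolation")
    good_names = [rec.channel_names[i] for i in good_idx]
    good_m = montage.subset(good_names)
    targets = montage.positions[[montage.index(ch) for ch in bad]]
    M = interpolation_matrix(good_m, targets)
    out = rec.copy()
    out.data[bad_idx, :] = M @ rec.data[good_idx, :]
    return out
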