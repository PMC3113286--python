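"""Epoch extraction, baseline correction, averaging, and ERP measures."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .containers import ContinuousRecord, EvokedRecord
from .errors import ConsistencyError, ParameterError

logger = logging.getLogger(__name__)

__all__ = ["EpochSet", "epoch", "baseline_correct", "average",
           "grand_average", "subtract", "measure", "MEASURES"]

MEASURES = ("peak_amp", "peak_lat", "mean_amp", "trough_amp", "trough_lat")


@dataclass
class EpochSet:
    """Single-trial epochs: trials x channels x samples.

    Only kept (non-rejected) events contribute. ``event_samples`` retains
    each trial's event position in the source recording so baselines can be
    re-anchored to other events.
    """

    data: np.ndarray
    fs: float
    t0: float
    event_code: int
    trial_indices: np.ndarray  # indices into the source EventList
    event_samples: np.ndarray  # event sample of each trial in the source
    channel_names: list[str]
    channel_units: list[str]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ConsistencyError("epoch data must be trials x channels x samples")
        if self.data.shape[0] < 1:
            raise ConsistencyError("EpochSet needs at least one trial")
        self.trial_indices = np.asarray(self.trial_indices, dtype=np.int64)
        self.event_samples = np.asarray(self.event_samples, dtype=np.int64)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(),
                       trial_indices=self.trial_indices.copy(),
                       event_samples=self.event_samples.copy())


def _window_samples(t0: float, t1: float, fs: float) -> int:
    if not t0 < t1:
        raise ParameterError("epoch window must satisfy t0 < t1")
    return int(round((t1 - t0) * fs))


def epoch(rec: ContinuousRecord, code: int, window: tuple[float, float]
          ) -> EpochSet:
    """Extract single-trial epochs around kept events of one code.

    ``window = (t0, t1)`` in seconds relative to the event, half-open:
    the epoch holds ``round((t1 - t0) * fs)`` samples and sample ``k`` is at
    time ``t0 + k / fs``. Rejected events and events whose epoch would cross
    a recording edge are skipped.
    """
    t0, t1 = window
    n = _window_samples(t0, t1, rec.fs)
    start_off = int(round(t0 * rec.fs))
    trials, idx_used, ev_samples = [], [], []
    for i, ev in enumerate(rec.events):
        if ev.code != code or ev.reject:
            continue
        start = ev.sample + start_off
        if start < 0 or start + n > rec.n_samples:
            logger.warning("event %d at sample %d: epoch outside recording, skipped",
                           i, ev.sample)
            continue
        trials.append(rec.data[:, start:start + n])
        idx_used.append(i)
        ev_samples.append(ev.sample)
    if not trials:
        raise ParameterError(
            f"no usable (kept, fully inside) events of code {code}")
    return EpochSet(np.stack(trials), rec.fs, t0, code,
                    np.asarray(idx_used), np.asarray(ev_samples),
                    list(rec.channel_names), list(rec.channel_units))


def baseline_correct(x: EpochSet | EvokedRecord, bwin: tuple[float, float],
                     ref: str = "same_event", ref_code: int | None = None,
                     rec: ContinuousRecord | None = None):
    """Subtract a per-channel baseline mean from each trial (or the average).

    ``ref='same_event'``: the baseline window ``bwin`` (seconds) is relative
    to each trial's own event and must lie inside the epoch.

    ``ref='other_event'``: ``bwin`` is positioned relative to the nearest
    *preceding* event of ``ref_code`` in the source recording ``rec``
    (e.g. a pre-stimulus baseline for response-locked epochs). Trials with
    no pairable reference event, or whose baseline crosses a recording
    edge, are dropped with a warning. Only available for EpochSet.
    """
    b0, b1 = bwin
    if not b0 < b1:
        raise ParameterError("baseline window must satisfy b0 < b1")
    if ref not in ("same_event", "other_event"):
        raise ParameterError("ref must be 'same_event' or 'other_event'")

    if ref == "same_event":
        if isinstance(x, EvokedRecord):
            times = x.times
            mask = (times >= b0) & (times < b1)
            if not mask.any():
                raise ParameterError("baseline window outside epoch")
            out = x.copy()
            out.data = out.data - out.data[:, mask].mean(axis=1, keepdims=True)
            return out
        times = x.times
        mask = (times >= b0) & (times < b1)
        if not mask.any():
            raise ParameterError("baseline window outside epoch")
        out = x.copy()
        out.data = out.data - out.data[:, :, mask].mean(axis=2, keepdims=True)
        return out

    # other_event baseline
    if not isinstance(x, EpochSet):
        raise ParameterError("other_event baseline needs single-trial epochs")
    if ref_code is None or rec is None:
        raise ParameterError("other_event baseline needs ref_code and rec")
    ref_samples = rec.events.samples[(rec.events.codes == ref_code)
                                     & ~rec.events.rejects]
    s0 = int(round(b0 * rec.fs))
    nb = _window_samples(b0, b1, rec.fs)
    keep, corrected = [], []
    for k in range(x.n_trials):
        anchor_candidates = ref_samples[ref_samples <= x.event_samples[k]]
        if anchor_candidates.size == 0:
            logger.warning("trial %d: no preceding event of code %d, dropped",
                           k, ref_code)
            continue
        anchor = int(anchor_candidates[-1])
        start = anchor + s0
        if start < 0 or start + nb > rec.n_samples:
            logger.warning("trial %d: baseline outside recording, dropped", k)
            continue
        base = rec.data[:, start:start + nb].mean(axis=1, keepdims=True)
        corrected.append(x.data[k] - base)
        keep.append(k)
    if not corrected:
        raise ParameterError("no trial had a usable reference baseline")
    keep = np.asarray(keep)
    return EpochSet(np.stack(corrected), x.fs, x.t0, x.event_code,
                    x.trial_indices[keep], x.event_samples[keep],
                    list(x.channel_names), list(x.channel_units))


def average(e: EpochSet) -> EvokedRecord:
    """Trial average; ``n_trials`` records the count that contributed."""
    return EvokedRecord(e.data.mean(axis=0), e.fs, e.t0, e.event_code,
                        e.n_trials, list(e.channel_names),
                        list(e.channel_units))


def _check_axes_match(records: Sequence[EvokedRecord]) -> None:
    ref = records[0]
    for r in records[1:]:
        if (r.channel_names != ref.channel_names or r.fs != ref.fs
                or abs(r.t0 - ref.t0) > 1e-12
                or r.n_samples != ref.n_samples):
            raise ConsistencyError(
                "records differ in channels, sampling rate, window or length")


def grand_average(records: Sequence[EvokedRecord],
                  weights: str = "equal") -> EvokedRecord:
    """Average several evoked records (e.g. across subjects).

    ``weights='equal'`` (default) averages the inputs as-is;
    ``'by_n_trials'`` weights each record by its trial count. The order of
    the inputs never matters.
    """
    records = list(records)
    if not records:
        raise ParameterError("grand_average needs at least one record")
    _check_axes_match(records)
    if weights == "equal":
        w = np.ones(len(records))
    elif weights == "by_n_trials":
        w = np.asarray([r.n_trials for r in records], dtype=np.float64)
    else:
        raise ParameterError("weights must be 'equal' or 'by_n_trials'")
    w = w / w.sum()
    data = sum(wi * r.data for wi, r in zip(w, records))
    ref = records[0]
    return EvokedRecord(data, ref.fs, ref.t0, ref.event_code,
                        int(sum(r.n_trials for r in records)),
                        list(ref.channel_names), list(ref.channel_units))


def subtract(a: EvokedRecord, b: EvokedRecord) -> EvokedRecord:
    """Difference wave ``a - b``; axes must match exactly (no resampling)."""
    _check_axes_match([a, b])
    return EvokedRecord(a.data - b.data, a.fs, a.t0, a.event_code,
                        min(a.n_trials, b.n_trials),
                        list(a.channel_names), list(a.channel_units))


def measure(ev: EvokedRecord, channel: str | int,
            window: tuple[float, float], what: str) -> float:
    """Amplitude/latency measure of one channel inside a time window.

    ``peak_amp``/``peak_lat`` use the maximum, ``trough_*`` the minimum,
    ``mean_amp`` the mean; latencies are in seconds relative to the event
    and ties resolve to the earliest sample.
    """
    if what not in MEASURES:
        raise ParameterError(f"measure must be one of {MEASURES}")
    ci = ev.channel_index(channel) if isinstance(channel, str) else int(channel)
    t0, t1 = window
    times = ev.times
    mask = (times >= t0) & (times <= t1)
    if not mask.any():
        raise ParameterError("measurement window outside epoch")
    seg = ev.data[ci, mask]
    seg_t = times[mask]
    if what == "mean_amp":
        return float(seg.mean())
    if what in ("peak_amp", "peak_lat"):
        i = int(np.argmax(seg))
        return float(seg[i]) if what == "peak_amp" else float(seg_t[i])
    i = int(np.argmin(seg))
    return float(seg[i]) if what == "trough_amp" else float(seg_t[i])


def measure_row(ev: EvokedRecord, channel: str | int,
                window: tuple[float, float], what: str,
                subject: str = "", condition: str = "") -> dict:
    """One measurement as a row dict for a delimited results table."""
    value = measure(ev, channel, window, what)
    name = ev.channel_names[channel] if isinstance(channel, int) else channel
    return {"subject": subject, "condition": condition, "channel": name,
            "measure": what, "t_start": window[0], "t_stop": window[1],
            "value": value}
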