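"""Core data containers for event-coded neural time series.

Four containers cover every analysis product in the toolkit:

* :class:`ContinuousRecord` — a multichannel continuous recording with an
  attached :class:`EventList` (the ``.eeg`` role).
* :class:`EvokedRecord` — channels x samples event-locked data such as an
  average (the ``.p`` role).
* :class:`TFRecord` — channels x frequencies x samples time-frequency maps
  of power, phase locking, or p-values (the ``.tf`` role).
* :class:`EventList` — ordered (sample, code, reject) records (the ``.pos``
  role).

Every constructor validates its invariants and refuses to build an invalid
object; the result of any analysis function in the package is expressible in
one of these containers, which keeps pipelines closed under composition.

Conventions: sample indices are 0-based; the time of sample ``k`` of a
continuous record is ``k / fs`` seconds; epoch windows are half-open
``[start, stop)``; units are opaque strings and are never converted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import ConsistencyError, ParameterError

__all__ = [
    "Event",
    "EventList",
    "ContinuousRecord",
    "EvokedRecord",
    "TFRecord",
    "Montage",
    "ParamSet",
    "TF_QUANTITIES",
]

TF_QUANTITIES = ("power", "evoked_power", "plf", "plv", "pvalue")


@dataclass(frozen=True)
class Event:
    sample: int
    code: int
    reject: bool = False


class EventList:
    """Ordered list of events, sorted by sample (stable for ties).

    Internally stored as three parallel numpy arrays so vectorised selection
    is cheap; iteration yields :class:`Event` records.
    """

    def __init__(
        self,
        samples: Sequence[int] = (),
        codes: Sequence[int] = (),
        rejects: Sequence[bool] | None = None,
    ):
        samples = np.asarray(samples, dtype=np.int64).reshape(-1)
        codes = np.asarray(codes, dtype=np.int64).reshape(-1)
        if rejects is None:
            rejects = np.zeros(samples.size, dtype=bool)
        rejects = np.asarray(rejects, dtype=bool).reshape(-1)
        if not (samples.size == codes.size == rejects.size):
            raise ConsistencyError(
                "samples, codes and rejects must have equal length"
            )
        if samples.size and samples.min() < 0:
            raise ConsistencyError("event samples must be >= 0")
        order = np.argsort(samples, kind="stable")
        self.samples = samples[order]
        self.codes = codes[order]
        self.rejects = rejects[order]

    @classmethod
    def from_records(cls, records: Sequence[tuple | Event]) -> "EventList":
        rows = [
            (r.sample, r.code, r.reject) if isinstance(r, Event) else tuple(r)
            for r in records
        ]
        if not rows:
            return cls()
        samples, codes, rejects = zip(
            *((r[0], r[1], bool(r[2]) if len(r) > 2 else False) for r in rows)
        )
        return cls(samples, codes, rejects)

    def __len__(self) -> int:
        return int(self.samples.size)

    def __iter__(self) -> Iterator[Event]:
        for s, c, r in zip(self.samples, self.codes, self.rejects):
            yield Event(int(s), int(c), bool(r))

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventList):
            return NotImplemented
        return (
            np.array_equal(self.samples, other.samples)
            and np.array_equal(self.codes, other.codes)
            and np.array_equal(self.rejects, other.rejects)
        )

    def __repr__(self) -> str:
        return f"EventList({len(self)} events, codes={sorted(set(self.codes.tolist()))})"

    def copy(self) -> "EventList":
        return EventList(self.samples.copy(), self.codes.copy(), self.rejects.copy())

    def with_rejects(self, rejects: np.ndarray) -> "EventList":
        return EventList(self.samples, self.codes, rejects)


def _check_channels(data, channel_names, channel_units):
    if data.ndim < 2:
        raise ConsistencyError("data must have at least 2 dimensions")
    n_ch = data.shape[0]
    if len(channel_names) != n_ch or len(channel_units) != n_ch:
        raise ConsistencyError(
            f"{n_ch} data channels but {len(channel_names)} names / "
            f"{len(channel_units)} units"
        )
    if len(set(channel_names)) != n_ch:
        raise ConsistencyError("channel names must be unique")


@dataclass
class ContinuousRecord:
    """Continuous multichannel recording with event codes.

    ``data`` is channels x samples in physical units per channel.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    channel_units: list[str]
    events: EventList = field(default_factory=EventList)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channel_names = list(self.channel_names)
        self.channel_units = list(self.channel_units)
        if self.fs <= 0:
            raise ConsistencyError("sampling rate must be > 0")
        _check_channels(self.data, self.channel_names, self.channel_units)
        if len(self.events) and self.events.samples.max() >= self.n_samples:
            raise ConsistencyError(
                f"event at sample {int(self.events.samples.max())} outside "
                f"recording of {self.n_samples} samples"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ParameterError(f"unknown channel {name!r}") from None

    def copy(self) -> "ContinuousRecord":
        return ContinuousRecord(
            self.data.copy(), self.fs, list(self.channel_names),
            list(self.channel_units), self.events.copy(),
        )


@dataclass
class EvokedRecord:
    """Event-locked channels x samples data (typically a trial average).

    ``t0`` is the time of the first sample relative to the event, in seconds
    (negative for a pre-stimulus baseline); sample ``k`` is at ``t0 + k/fs``.
    """

    data: np.ndarray
    fs: float
    t0: float
    event_code: int
    n_trials: int
    channel_names: list[str]
    channel_units: list[str]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channel_names = list(self.channel_names)
        self.channel_units = list(self.channel_units)
        if self.fs <= 0:
            raise ConsistencyError("sampling rate must be > 0")
        if self.n_trials < 1:
            raise ConsistencyError("n_trials must be >= 1")
        _check_channels(self.data, self.channel_names, self.channel_units)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ParameterError(f"unknown channel {name!r}") from None

    def copy(self) -> "EvokedRecord":
        return replace(self, data=self.data.copy(),
                       channel_names=list(self.channel_names),
                       channel_units=list(self.channel_units))


@dataclass
class TFRecord:
    """Time-frequency maps: channels x frequencies x samples.

    ``quantity`` declares what the values are; bounded quantities are
    validated (``plf``/``plv`` in [0, 1], ``pvalue`` in (0, 1]).
    """

    data: np.ndarray
    freqs: np.ndarray
    fs: float
    t0: float
    event_code: int
    n_trials: int
    quantity: str
    channel_names: list[str]
    channel_units: list[str]
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.freqs = np.asarray(self.freqs, dtype=np.float64).reshape(-1)
        self.channel_names = list(self.channel_names)
        self.channel_units = list(self.channel_units)
        if self.fs <= 0:
            raise ConsistencyError("sampling rate must be > 0")
        if self.data.ndim != 3:
            raise ConsistencyError("TF data must be channels x freqs x samples")
        if self.data.shape[1] != self.freqs.size:
            raise ConsistencyError(
                f"data has {self.data.shape[1]} frequency bins but freqs has "
                f"{self.freqs.size}"
            )
        if self.freqs.size and (np.any(np.diff(self.freqs) <= 0) or self.freqs[0] <= 0):
            raise ConsistencyError("freqs must be strictly increasing and > 0")
        if self.quantity not in TF_QUANTITIES:
            raise ConsistencyError(
                f"quantity must be one of {TF_QUANTITIES}, got {self.quantity!r}"
            )
        vals = self.data[np.isfinite(self.data)]
        if self.quantity in ("plf", "plv") and vals.size:
            if vals.min() < 0 or vals.max() > 1:
                raise ConsistencyError(f"{self.quantity} values must lie in [0, 1]")
        if self.quantity == "pvalue" and vals.size:
            if vals.min() <= 0 or vals.max() > 1:
                raise ConsistencyError("p-values must lie in (0, 1]")
        _check_channels(self.data, self.channel_names, self.channel_units)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ParameterError(f"unknown channel {name!r}") from None


class Montage:
    """Labelled sensor positions on the unit sphere.

    Frame: right-handed, +x through the nose, +y through the left ear,
    +z through the vertex. Spherical input uses azimuth measured from +x
    towards +y and elevation from the horizontal plane, both in degrees, so
    the vertex (Cz) is elevation 90.
    """

    def __init__(self, labels: Sequence[str], positions: np.ndarray):
        positions = np.asarray(positions, dtype=np.float64)
        labels = list(labels)
        if positions.ndim != 2 or positions.shape[1] != 3:
            raise ConsistencyError("positions must be n x 3")
        if len(labels) != positions.shape[0]:
            raise ConsistencyError("labels and positions length mismatch")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ConsistencyError(f"duplicate montage label(s): {dup}")
        norms = np.linalg.norm(positions, axis=1)
        if np.any(norms == 0):
            bad = labels[int(np.argmin(norms))]
            raise ConsistencyError(f"zero-norm position for channel {bad!r}")
        if np.any(np.abs(norms - 1.0) > 1e-9):
            positions = positions / norms[:, None]
        self.labels = labels
        self.positions = positions

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ParameterError(f"unknown montage channel {label!r}") from None

    def subset(self, labels: Sequence[str]) -> "Montage":
        idx = [self.index(l) for l in labels]
        return Montage([self.labels[i] for i in idx], self.positions[idx])

    @classmethod
    def from_spherical(cls, labels: Sequence[str], azimuth_deg, elevation_deg):
        az = np.deg2rad(np.asarray(azimuth_deg, dtype=np.float64))
        el = np.deg2rad(np.asarray(elevation_deg, dtype=np.float64))
        pos = np.column_stack(
            [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
        )
        return cls(labels, pos)


class ParamSet(Mapping):
    """Key-value parameters parsed from a ``.par``-style text file.

    Behaves as a read-only mapping of strings. Operations consuming a
    ParamSet declare their accepted keys; unknown keys are an error (caught
    via :meth:`check_keys`), so typos in batch files fail loudly.
    """

    def __init__(self, values: Mapping[str, str] | None = None):
        self._values = dict(values or {})

    def __getitem__(self, key: str) -> str:
        return self._values[key]

    def __iter__(self):
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def check_keys(self, allowed: Sequence[str]) -> None:
        unknown = sorted(set(self._values) - set(allowed))
        if unknown:
            raise ParameterError(
                f"unknown parameter key(s) {unknown}; accepted keys: "
                f"{sorted(allowed)}"
            )

    def get_float(self, key: str, default: float | None = None) -> float | None:
        if key not in self._values:
            return default
        return float(self._values[key])

    def get_int(self, key: str, default: int | None = None) -> int | None:
        if key not in self._values:
            return default
        return int(self._values[key])

    def get_str(self, key: str, default: str | None = None) -> str | None:
        return self._values.get(key, default)

    def get_list(self, key: str, default=None, conv=str):
        if key not in self._values:
            return default
        raw = self._values[key]
        return [conv(part.strip()) for part in raw.split(",") if part.strip()]
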