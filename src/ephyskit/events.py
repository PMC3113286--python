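"""Event-list preprocessing: recoding, selection, reaction times.

All operations are pure (the input list is never modified) and stable
(the relative order of events is preserved).
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np

from .containers import EventList
from .errors import ParameterError

__all__ = ["recode_events", "select_events", "reaction_times"]


def recode_events(ev: EventList, mapping: Mapping[int, int]) -> EventList:
    """Replace event codes according to ``mapping``.

    Substitution is simultaneous: with ``{10: 20, 20: 10}`` the two codes
    are swapped, never chained. Codes outside the mapping pass through.
    """
    codes = ev.codes.copy()
    out = codes.copy()
    for src, dst in mapping.items():
        out[codes == src] = dst
    return EventList(ev.samples.copy(), out, ev.rejects.copy())


def select_events(ev: EventList, codes: Iterable[int] | None = None,
                  keep_rejected: bool = False) -> EventList:
    """Subset an event list by code, excluding rejected events by default.

    ``codes=None`` keeps all codes; an empty set selects nothing.
    """
    if codes is None:
        mask = np.ones(len(ev), dtype=bool)
    else:
        code_set = np.asarray(sorted(set(int(c) for c in codes)), dtype=np.int64)
        mask = np.isin(ev.codes, code_set)
    if not keep_rejected:
        mask &= ~ev.rejects
    return EventList(ev.samples[mask], ev.codes[mask], ev.rejects[mask])


def reaction_times(ev: EventList, stim_code: int, resp_code: int, fs: float,
                   max_rt: float) -> list[tuple[int, float | None]]:
    """Pair stimulus events with their responses and return reaction times.

    For each stimulus, the first following response of ``resp_code`` within
    ``max_rt`` seconds is paired, provided no other stimulus intervenes (a
    response always belongs to its nearest preceding stimulus). Stimuli
    without a response in the window get ``None``. Rejected events are
    ignored.

    Returns a list of ``(stimulus_sample, rt_seconds_or_None)``.
    """
    if max_rt <= 0:
        raise ParameterError("max_rt must be > 0")
    if stim_code == resp_code:
        raise ParameterError("stimulus and response codes must differ")
    kept = select_events(ev, codes=[stim_code, resp_code])
    stims = kept.samples[kept.codes == stim_code]
    resps = kept.samples[kept.codes == resp_code]
    max_samples = max_rt * fs
    out: list[tuple[int, float | None]] = []
    for i, s in enumerate(stims):
        upper = s + max_samples
        # responses may not be claimed across an intervening stimulus
        if i + 1 < stims.size:
            upper = min(upper, float(stims[i + 1]))
        cand = resps[(resps > s) & (resps <= upper)]
        if cand.size:
            rt = (int(cand[0]) - int(s)) / fs
            out.append((int(s), rt))
        else:
            out.append((int(s), None))
    return out
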