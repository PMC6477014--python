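"""Ordinal bladder filling states.

The monitoring pipeline classifies the bladder into four ordinal states —
empty, half (1/2), three-quarters (3/4) and full — the four reference points
at which data are acquired during a filling session.  The urge to void
typically begins around the 3/4 state, which is why it is the default alarm
triggering point.
"""
from __future__ import annotations

from enum import IntEnum


class BladderState(IntEnum):
    """Four-level ordinal bladder state, ordered by fill."""

    EMPTY = 0
    HALF = 1
    THREE_QUARTERS = 2
    FULL = 3

    @property
    def label(self) -> str:
        return _LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "BladderState":
        try:
            return _FROM_LABEL[label.strip().lower()]
        except KeyError:
            raise ValueError(f"unknown bladder state label: {label!r}") from None


_LABELS = {
    BladderState.EMPTY: "empty",
    BladderState.HALF: "1/2",
    BladderState.THREE_QUARTERS: "3/4",
    BladderState.FULL: "full",
}

_FROM_LABEL = {
    "empty": BladderState.EMPTY,
    "1/2": BladderState.HALF,
    "half": BladderState.HALF,
    "3/4": BladderState.THREE_QUARTERS,
    "full": BladderState.FULL,
}

#: canonical label order used in tables and confusion matrices
STATE_LABELS = [s.label for s in BladderState]
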