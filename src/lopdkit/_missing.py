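"""Typed missing values.

Clinical tables mark absent measurements with short tokens whose meaning
matters downstream: a test the patient could not perform is graded differently
from a value that simply was not recorded.  ``Missing`` keeps that reason
attached to the hole it fills.
"""

from __future__ import annotations

from dataclasses import dataclass

NOT_PERFORMED = "not_performed"
UNAVAILABLE = "unavailable"

#: tokens recognized in input tables, lower-cased
MISSING_MARKERS = {
    "np": NOT_PERFORMED,
    "n.p.": NOT_PERFORMED,
    "n.p": NOT_PERFORMED,
    "nr": UNAVAILABLE,
    "n.r.": UNAVAILABLE,
    "na": UNAVAILABLE,
    "n.a.": UNAVAILABLE,
}

#: how a missing value is written back out, per reason
_MARKER_FOR_REASON = {NOT_PERFORMED: "n.p.", UNAVAILABLE: "na"}


@dataclass(frozen=True)
class Missing:
    """A measurement that is absent for a stated reason."""

    reason: str

    def __post_init__(self) -> None:
        if self.reason not in (NOT_PERFORMED, UNAVAILABLE):
            raise ValueError(f"unknown missing reason: {self.reason!r}")

    def marker(self) -> str:
        return _MARKER_FOR_REASON[self.reason]

    def __bool__(self) -> bool:  # a missing value is never truthy
        return False


MISSING_NOT_PERFORMED = Missing(NOT_PERFORMED)
MISSING_UNAVAILABLE = Missing(UNAVAILABLE)


def is_missing(value: object) -> bool:
    return isinstance(value, Missing)


def parse_missing(token: str) -> Missing | None:
    """Return a ``Missing`` if *token* is a recognized missing marker."""
    return (
        Missing(MISSING_MARKERS[token.strip().lower()])
        if token.strip().lower() in MISSING_MARKERS
        else None
    )
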