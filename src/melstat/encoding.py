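"""Transposition-invariant interval encoding of pitch windows.

A window of n+1 pitches is re-expressed as signed semitone offsets from the
window's first pitch, which becomes 0.  A rising semitone is +1, a falling
semitone -1.  The encoding removes the absolute key from every window, so
n-gram statistics computed over it describe interval patterns rather than
pitch patterns.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "IntervalPattern",
    "window_to_pattern",
    "extract_ngrams",
    "pattern_to_pitches",
    "format_pattern",
    "parse_pattern",
]

MIN_PITCH = 0
MAX_PITCH = 127


@dataclass(frozen=True, order=True)
class IntervalPattern:
    """An order-n window encoded as n+1 semitone offsets, first element 0.

    ``offsets[:-1]`` is the conditioning context (the paper-style events
    e_1 ... e_n) and ``offsets[-1]`` the predicted target e_{n+1}.
    """

    offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.offsets) < 2:
            raise ValueError("a pattern needs at least two elements (order >= 1)")
        if self.offsets[0] != 0:
            raise ValueError(f"first offset must be 0, got {self.offsets[0]}")

    @property
    def order(self) -> int:
        return len(self.offsets) - 1

    @property
    def context(self) -> tuple[int, ...]:
        return self.offsets[:-1]

    @property
    def target(self) -> int:
        return self.offsets[-1]

    def __str__(self) -> str:
        return format_pattern(self)


def window_to_pattern(pitches: Sequence[int]) -> IntervalPattern:
    """Encode a pitch window as offsets relative to its first pitch.

    ``[60, 58] -> (0, -2)``: a descending whole tone, wherever it occurs.
    """
    if len(pitches) < 2:
        raise ValueError(f"window needs >= 2 pitches, got {len(pitches)}")
    first = pitches[0]
    return IntervalPattern(tuple(int(p) - int(first) for p in pitches))


def extract_ngrams(pitches: Sequence[int], order: int) -> Counter[IntervalPattern]:
    """All order-n interval patterns of a pitch sequence, as a multiset.

    One pattern per sliding window of length ``order + 1`` with step 1;
    windows never cross the end of the sequence, so a sequence of length L
    yields ``max(0, L - order)`` patterns.  A sequence shorter than
    ``order + 1`` yields an empty multiset.
    """
    if not 1 <= order <= 6:
        raise ValueError(f"order must be in 1..6, got {order}")
    counts: Counter[IntervalPattern] = Counter()
    n = len(pitches)
    for i in range(n - order):
        counts[window_to_pattern(pitches[i : i + order + 1])] += 1
    return counts


def pattern_to_pitches(pattern: IntervalPattern, anchor: int) -> list[int]:
    """Decode a pattern to concrete pitches starting at ``anchor``.

    Exact inverse of :func:`window_to_pattern` anchored at the window's
    first pitch.  Raises if any decoded pitch leaves the MIDI range 0-127.
    """
    pitches = []
    for i, off in enumerate(pattern.offsets):
        p = anchor + off
        if not MIN_PITCH <= p <= MAX_PITCH:
            raise ValueError(
                f"offset index {i} ({off:+d}) anchored at {anchor} gives pitch {p}, "
                f"outside {MIN_PITCH}-{MAX_PITCH}"
            )
        pitches.append(p)
    return pitches


def format_pattern(pattern: IntervalPattern) -> str:
    """Serialize as a bracketed integer list, e.g. ``"[0, -2, -4]"``."""
    return "[" + ", ".join(str(o) for o in pattern.offsets) + "]"


def parse_pattern(text: str) -> IntervalPattern:
    """Inverse of :func:`format_pattern`."""
    inner = text.strip().lstrip("[").rstrip("]")
    return IntervalPattern(tuple(int(tok) for tok in inner.split(",")))
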