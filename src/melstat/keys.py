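"""Key names, pitch classes and canonical spellings.

Keys are (root pitch class, mode) pairs.  Enharmonic spellings (F# vs Gb)
are collapsed to the pitch class for all computation; a canonical display
spelling per (pitch class, mode) follows common key-signature practice
(e.g. Eb major but D# pitch class spelled as Eb, F# minor rather than Gb
minor).
"""

from __future__ import annotations

__all__ = ["name_to_pc", "pc_to_name", "key_label", "MAJOR_ROOTS", "MINOR_ROOTS"]

_BASE = {"C": 0, "D": 2, "E": 4, "F": 5, "G": 7, "A": 9, "B": 11}

# canonical spelling of each pitch class as a key root, by mode
MAJOR_ROOTS = ["C", "Db", "D", "Eb", "E", "F", "Gb", "G", "Ab", "A", "Bb", "B"]
MINOR_ROOTS = ["C", "C#", "D", "Eb", "E", "F", "F#", "G", "G#", "A", "Bb", "B"]


def name_to_pc(name: str) -> int:
    """Pitch class 0-11 of a note name like 'C', 'F#', 'Gb', 'B♭', 'Cb'."""
    s = name.strip()
    if not s or s[0].upper() not in _BASE:
        raise ValueError(f"unknown key root {name!r}")
    pc = _BASE[s[0].upper()]
    for ch in s[1:]:
        if ch in ("#", "♯"):
            pc += 1
        elif ch in ("b", "♭"):
            pc -= 1
        else:
            raise ValueError(f"unknown accidental {ch!r} in key root {name!r}")
    return pc % 12


def pc_to_name(pc: int, mode: str = "major") -> str:
    """Canonical key-root spelling for a pitch class in the given mode."""
    roots = MAJOR_ROOTS if mode == "major" else MINOR_ROOTS
    return roots[pc % 12]


def key_label(pc: int, mode: str) -> str:
    """Short key label in the usual style: 'C' for C major, 'Am' for A minor."""
    name = pc_to_name(pc, mode)
    return name if mode == "major" else name + "m"
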