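"""MusicXML reading, highest-line melody extraction and corpus management.

Scores arrive as plain (.xml/.musicxml) or compressed (.mxl) MusicXML.  The
reader resolves every sounded note to an absolute onset in quarter-note
units (exact fractions — onset grouping uses equality, not a tolerance) and
a MIDI semitone index, flags grace notes and annotates ties.  The melody of
a piece is the sequence of highest pitches playable at each onset: grace
notes are excluded, tied same-pitch notes count once, and at every onset the
maximum pitch among notes starting there is taken across all voices.
"""

from __future__ import annotations

import logging
import zipfile
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from lxml import etree

from melstat.keys import name_to_pc

__all__ = [
    "NoteEvent",
    "PieceMeta",
    "MelodicSequence",
    "Score",
    "ExtractionRules",
    "read_musicxml",
    "extract_highest_line",
    "load_corpus",
    "corpus_to_melody_csv",
    "corpus_from_melody_csv",
    "melody_to_musicxml",
]

logger = logging.getLogger(__name__)

_STEP_SEMITONE = {"C": 0, "D": 2, "E": 4, "F": 5, "G": 7, "A": 9, "B": 11}

TieRole = Literal["none", "start", "continue", "stop"]


@dataclass(frozen=True)
class NoteEvent:
    """One sounded note: absolute quarter-note onset/duration, MIDI pitch."""

    onset: Fraction
    duration: Fraction
    pitch: int
    is_grace: bool = False
    tie_role: TieRole = "none"
    voice_id: str = "1"

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")
        if not self.is_grace and self.duration <= 0:
            raise ValueError(f"non-grace note needs duration > 0, got {self.duration}")
        if not 0 <= self.pitch <= 127:
            raise ValueError(f"pitch {self.pitch} outside MIDI range 0-127")


@dataclass(frozen=True)
class PieceMeta:
    """Corpus metadata of one piece: key root, mode, series number, type."""

    key_root: str
    mode: Literal["major", "minor"]
    series: int
    type: Literal["prelude", "fugue"]
    piece_id: str = ""

    def __post_init__(self) -> None:
        name_to_pc(self.key_root)  # raises on an invalid root
        if self.mode not in ("major", "minor"):
            raise ValueError(f"mode must be major|minor, got {self.mode!r}")
        if int(self.series) not in (1, 2):
            raise ValueError(f"series must be 1 or 2, got {self.series!r}")
        if self.type not in ("prelude", "fugue"):
            raise ValueError(f"type must be prelude|fugue, got {self.type!r}")
        if not self.piece_id:
            object.__setattr__(self, "piece_id", self.default_id())

    @property
    def key_pc(self) -> int:
        return name_to_pc(self.key_root)

    def condition(self) -> tuple[str, str, int, str]:
        return (self.key_root, self.mode, int(self.series), self.type)

    def default_id(self) -> str:
        m = "" if self.mode == "major" else "m"
        return f"{self.key_root}{m}_no{self.series}_{self.type}"


@dataclass
class MelodicSequence:
    """The ordered highest-pitch line of one piece, plus its metadata."""

    pitches: list[int]
    meta: PieceMeta | None = None

    def __len__(self) -> int:
        return len(self.pitches)


@dataclass
class Score:
    """Raw parse result: all note events of all parts plus declared metadata."""

    events: list[NoteEvent]
    key_fifths: int | None = None
    key_mode: str | None = None
    title: str | None = None


@dataclass(frozen=True)
class ExtractionRules:
    """Melody-extraction configuration (defaults reproduce the study rules)."""

    exclude_grace: bool = True
    merge_ties: bool = True


# ---------------------------------------------------------------------------
# MusicXML reading


def _midi_pitch(pitch_el: etree._Element) -> int:
    step = pitch_el.findtext("step")
    octave = int(pitch_el.findtext("octave"))
    alter = pitch_el.findtext("alter")
    semis = _STEP_SEMITONE[step] + (int(float(alter)) if alter else 0)
    return (octave + 1) * 12 + semis


def _parse_part(part: etree._Element, events: list[NoteEvent]) -> None:
    divisions = Fraction(1)
    cursor = Fraction(0)
    prev_onset = Fraction(0)
    for measure in part.iter("measure"):
        for el in measure:
            if el.tag == "attributes":
                div = el.findtext("divisions")
                if div is not None:
                    divisions = Fraction(int(div))
            elif el.tag == "backup":
                cursor -= Fraction(int(el.findtext("duration"))) / divisions
            elif el.tag == "forward":
                cursor += Fraction(int(el.findtext("duration"))) / divisions
            elif el.tag == "note":
                is_grace = el.find("grace") is not None
                is_chord = el.find("chord") is not None
                dur_text = el.findtext("duration")
                dur = Fraction(0) if dur_text is None else Fraction(int(dur_text)) / divisions
                if el.find("rest") is not None:
                    if not is_chord:
                        cursor += dur
                    continue
                pitch_el = el.find("pitch")
                if pitch_el is None:
                    logger.warning("skipping unpitched element at quarter-note %s", cursor)
                    if not is_chord and not is_grace:
                        cursor += dur
                    continue
                onset = prev_onset if is_chord else cursor
                ties = {t.get("type") for t in el.findall("tie")}
                if {"start", "stop"} <= ties:
                    tie_role: TieRole = "continue"
                elif "start" in ties:
                    tie_role = "start"
                elif "stop" in ties:
                    tie_role = "stop"
                else:
                    tie_role = "none"
                events.append(
                    NoteEvent(
                        onset=onset,
                        duration=dur,
                        pitch=_midi_pitch(pitch_el),
                        is_grace=is_grace,
                        tie_role=tie_role,
                        voice_id=el.findtext("voice") or "1",
                    )
                )
                if not is_chord:
                    prev_onset = onset
                    if not is_grace:
                        cursor += dur


def read_musicxml(path: str | Path) -> Score:
    """Parse a plain or compressed MusicXML file into a flat event list.

    Raises ``FileNotFoundError`` for a missing file and
    ``lxml.etree.XMLSyntaxError`` (which carries the offending line) for
    malformed XML.  Unpitched elements are skipped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"score file not found: {path}")
    if path.suffix.lower() == ".mxl":
        with zipfile.ZipFile(path) as zf:
            root_name = _mxl_rootfile(zf)
            data = zf.read(root_name)
        root = etree.fromstring(data)
    else:
        root = etree.parse(str(path)).getroot()

    if root.tag == "score-timewise":
        raise ValueError(f"{path}: timewise MusicXML is not supported; export partwise")

    events: list[NoteEvent] = []
    for part in root.findall("part"):
        _parse_part(part, events)
    events.sort(key=lambda e: (e.onset, -e.pitch))

    key_el = root.find(".//attributes/key")
    fifths = mode = None
    if key_el is not None:
        f = key_el.findtext("fifths")
        fifths = int(f) if f is not None else None
        mode = key_el.findtext("mode")
    title = root.findtext(".//work/work-title") or root.findtext("movement-title")
    return Score(events=events, key_fifths=fifths, key_mode=mode, title=title)


def _mxl_rootfile(zf: zipfile.ZipFile) -> str:
    try:
        container = etree.fromstring(zf.read("META-INF/container.xml"))
        rootfile = container.find(".//rootfile")
        if rootfile is not None and rootfile.get("full-path"):
            return rootfile.get("full-path")
    except KeyError:
        pass
    for name in zf.namelist():
        if name.lower().endswith(".xml") and not name.startswith("META-INF"):
            return name
    raise ValueError("no MusicXML root file found in .mxl archive")


# ---------------------------------------------------------------------------
# Melody extraction


def _merge_ties_linear(events: list[NoteEvent]) -> list[NoteEvent]:
    """Collapse tied same-pitch chains within each voice (linear scan)."""
    by_voice: dict[str, list[NoteEvent]] = {}
    for ev in sorted(events, key=lambda e: e.onset):
        by_voice.setdefault(ev.voice_id, []).append(ev)
    out: list[NoteEvent] = []
    for voice_events in by_voice.values():
        chains: list[tuple[NoteEvent, TieRole]] = []  # (accumulated event, last written role)
        for ev in voice_events:
            if ev.tie_role in ("continue", "stop"):
                idx = next(
                    (
                        i
                        for i, (acc, last) in enumerate(chains)
                        if acc.pitch == ev.pitch
                        and last in ("start", "continue")
                        and acc.onset + acc.duration == ev.onset
                    ),
                    None,
                )
                if idx is not None:
                    acc, _ = chains.pop(idx)
                    acc = replace(acc, duration=acc.duration + ev.duration)
                    if ev.tie_role == "continue":
                        chains.append((acc, "continue"))
                    else:
                        out.append(acc)
                    continue
            if ev.tie_role in ("start",):
                chains.append((ev, "start"))
            else:
                out.append(ev)
        out.extend(acc for acc, _ in chains)  # unterminated ties
    out.sort(key=lambda e: (e.onset, -e.pitch))
    return out


def extract_highest_line(
    score: Score,
    rules: ExtractionRules = ExtractionRules(),
    meta: PieceMeta | None = None,
) -> MelodicSequence:
    """Extract the highest-pitch melodic line of a score.

    Grace notes are dropped, tied same-pitch chains are merged into single
    events, events are grouped by exact onset, and at each onset the maximum
    pitch among notes starting there (across all voices) is emitted.  An
    empty score yields an empty sequence with a warning rather than an
    error.
    """
    events = score.events
    if rules.exclude_grace:
        events = [e for e in events if not e.is_grace]
    if rules.merge_ties:
        events = _merge_ties_linear(events)
    if not events:
        logger.warning("score has no sounded notes after filtering; empty melody")
        return MelodicSequence(pitches=[], meta=meta)
    by_onset: dict[Fraction, int] = {}
    for ev in events:
        if ev.onset not in by_onset or ev.pitch > by_onset[ev.onset]:
            by_onset[ev.onset] = ev.pitch
    pitches = [by_onset[t] for t in sorted(by_onset)]
    return MelodicSequence(pitches=pitches, meta=meta)


# ---------------------------------------------------------------------------
# Corpus loading and melody serialization


def load_corpus(
    directory: str | Path,
    manifest: str | Path | pd.DataFrame,
    rules: ExtractionRules = ExtractionRules(),
) -> list[MelodicSequence]:
    """Read every score listed in a manifest and extract its melody.

    The manifest is a CSV (or DataFrame) with columns
    ``file,key_root,mode,series,type`` and optionally ``piece_id``.  The
    (key_root, mode, series, type) combination must be unique across rows;
    all missing files are reported together.
    """
    directory = Path(directory)
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    if manifest.empty:
        logger.warning("empty manifest: returning empty corpus")
        return []
    metas = [
        PieceMeta(
            key_root=str(row.key_root),
            mode=str(row.mode),
            series=int(row.series),
            type=str(row.type),
            piece_id=str(getattr(row, "piece_id", "") or ""),
        )
        for row in manifest.itertuples(index=False)
    ]
    seen: dict[tuple, str] = {}
    for meta in metas:
        cond = (meta.key_pc, meta.mode, int(meta.series), meta.type)
        if cond in seen:
            raise ValueError(
                f"duplicate corpus condition {meta.condition()} "
                f"(pieces {seen[cond]!r} and {meta.piece_id!r})"
            )
        seen[cond] = meta.piece_id
    paths = [directory / str(f) for f in manifest["file"]]
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise FileNotFoundError("missing score files: " + ", ".join(missing))
    corpus = []
    for path, meta in zip(paths, metas):
        score = read_musicxml(path)
        corpus.append(extract_highest_line(score, rules=rules, meta=meta))
    return corpus


def corpus_to_melody_csv(
    corpus: Sequence[MelodicSequence], melodies_path: str | Path, manifest_path: str | Path
) -> None:
    """Write a corpus as a long melody CSV plus a metadata manifest CSV."""
    rows = [
        {"piece_id": seq.meta.piece_id, "position": i, "pitch": p}
        for seq in corpus
        for i, p in enumerate(seq.pitches)
    ]
    pd.DataFrame(rows, columns=["piece_id", "position", "pitch"]).to_csv(
        melodies_path, index=False
    )
    meta_rows = [
        {
            "piece_id": seq.meta.piece_id,
            "key_root": seq.meta.key_root,
            "mode": seq.meta.mode,
            "series": seq.meta.series,
            "type": seq.meta.type,
        }
        for seq in corpus
    ]
    pd.DataFrame(meta_rows).to_csv(manifest_path, index=False)


def corpus_from_melody_csv(
    melodies_path: str | Path, manifest_path: str | Path
) -> list[MelodicSequence]:
    """Inverse of :func:`corpus_to_melody_csv`; preserves manifest order."""
    mel = pd.read_csv(melodies_path)
    man = pd.read_csv(manifest_path)
    corpus = []
    for row in man.itertuples(index=False):
        meta = PieceMeta(
            key_root=str(row.key_root),
            mode=str(row.mode),
            series=int(row.series),
            type=str(row.type),
            piece_id=str(row.piece_id),
        )
        sub = mel[mel["piece_id"] == meta.piece_id].sort_values("position")
        corpus.append(MelodicSequence(pitches=[int(p) for p in sub["pitch"]], meta=meta))
    return corpus


_PC_TO_STEP_ALTER = {
    0: ("C", 0), 1: ("C", 1), 2: ("D", 0), 3: ("E", -1), 4: ("E", 0), 5: ("F", 0),
    6: ("F", 1), 7: ("G", 0), 8: ("A", -1), 9: ("A", 0), 10: ("B", -1), 11: ("B", 0),
}


def melody_to_musicxml(seq: MelodicSequence) -> str:
    """Render a melody as minimal single-part MusicXML (quarter notes)."""
    root = etree.Element("score-partwise", version="3.1")
    part_list = etree.SubElement(root, "part-list")
    sp = etree.SubElement(part_list, "score-part", id="P1")
    etree.SubElement(sp, "part-name").text = (
        seq.meta.piece_id if seq.meta else "melody"
    )
    part = etree.SubElement(root, "part", id="P1")
    measure = etree.SubElement(part, "measure", number="1")
    attrs = etree.SubElement(measure, "attributes")
    etree.SubElement(attrs, "divisions").text = "1"
    for p in seq.pitches:
        note = etree.SubElement(measure, "note")
        pitch = etree.SubElement(note, "pitch")
        step, alter = _PC_TO_STEP_ALTER[p % 12]
        etree.SubElement(pitch, "step").text = step
        if alter:
            etree.SubElement(pitch, "alter").text = str(alter)
        etree.SubElement(pitch, "octave").text = str(p // 12 - 1)
        etree.SubElement(note, "duration").text = "1"
        etree.SubElement(note, "voice").text = "1"
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode()
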