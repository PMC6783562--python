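"""Shared fixtures: programmatic MusicXML builders and small corpora."""

from __future__ import annotations

import zipfile
from pathlib import Path

import pytest

NOTE_TEMPLATE = """      <note>
{chord}{grace}        <pitch>
          <step>{step}</step>
{alter}          <octave>{octave}</octave>
        </pitch>
{duration}        <voice>{voice}</voice>
{ties}      </note>
"""

_STEP_OF = {0: ("C", 0), 1: ("C", 1), 2: ("D", 0), 3: ("E", -1), 4: ("E", 0), 5: ("F", 0),
            6: ("F", 1), 7: ("G", 0), 8: ("A", -1), 9: ("A", 0), 10: ("B", -1), 11: ("B", 0)}


def note_xml(
    midi: int,
    duration: int = 1,
    voice: int = 1,
    chord: bool = False,
    grace: bool = False,
    tie: tuple[str, ...] = (),
) -> str:
    step, alter = _STEP_OF[midi % 12]
    return NOTE_TEMPLATE.format(
        chord="        <chord/>\n" if chord else "",
        grace="        <grace/>\n" if grace else "",
        step=step,
        alter=f"          <alter>{alter}</alter>\n" if alter else "",
        octave=midi // 12 - 1,
        duration="" if grace else f"        <duration>{duration}</duration>\n",
        voice=voice,
        ties="".join(f'        <tie type="{t}"/>\n' for t in tie),
    )


def rest_xml(duration: int = 1, voice: int = 1) -> str:
    return (
        "      <note>\n        <rest/>\n"
        f"        <duration>{duration}</duration>\n"
        f"        <voice>{voice}</voice>\n      </note>\n"
    )


def backup_xml(duration: int) -> str:
    return f"      <backup>\n        <duration>{duration}</duration>\n      </backup>\n"


def score_xml(body: str, divisions: int = 1) -> str:
    """Wrap measure content in a minimal one-part partwise score."""
    return f"""<?xml version="1.0" encoding="UTF-8"?>
<score-partwise version="3.1">
  <part-list>
    <score-part id="P1"><part-name>test</part-name></score-part>
  </part-list>
  <part id="P1">
    <measure number="1">
      <attributes>
        <divisions>{divisions}</divisions>
        <key><fifths>0</fifths><mode>major</mode></key>
      </attributes>
{body}    </measure>
  </part>
</score-partwise>
"""


@pytest.fixture
def write_score(tmp_path: Path):
    """Write a MusicXML string (or .mxl archive) into tmp_path."""

    def _write(name: str, content: str) -> Path:
        path = tmp_path / name
        if name.endswith(".mxl"):
            with zipfile.ZipFile(path, "w") as zf:
                zf.writestr(
                    "META-INF/container.xml",
                    '<?xml version="1.0"?><container><rootfiles>'
                    '<rootfile full-path="score.xml"/></rootfiles></container>',
                )
                zf.writestr("score.xml", content)
        else:
            path.write_text(content)
        return path

    return _write
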