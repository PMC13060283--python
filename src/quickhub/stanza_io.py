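"""Parser and serializer for the UCSC RA-style stanza dialect.

hub.txt, genomes.txt and trackDb.txt all share the same plain-text shape: a
file is a sequence of *stanzas*, each a maximal run of ``key value`` lines,
separated by one or more blank lines.  Comment lines start with ``#``.
Indentation on key-value lines is cosmetic (track hierarchy is expressed via
``parent``/``superTrack`` keys, not whitespace) and is stripped.  A trailing
backslash joins the following line before the key/value split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "Stanza",
    "StanzaParseError",
    "parse_stanzas",
    "serialize_stanzas",
    "decode_text",
]

#: keys that identify a stanza; at most one occurrence per stanza
IDENTITY_KEYS = frozenset({"track", "genome", "hub"})


class StanzaParseError(ValueError):
    """Raised for malformed stanza text; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class Stanza:
    """One blank-line-delimited block of ordered ``(key, value)`` entries."""

    entries: list[tuple[str, str]] = field(default_factory=list)
    source_line: int = field(default=0, compare=False)

    def get(self, key: str, default: str | None = None) -> str | None:
        """Return the value for *key*; the last occurrence wins."""
        found = default
        for k, v in self.entries:
            if k == key:
                found = v
        return found

    def keys(self) -> list[str]:
        return [k for k, _ in self.entries]

    @property
    def identity(self) -> tuple[str, str] | None:
        """The ``(key, value)`` of the stanza's identity entry, if any."""
        for k, v in self.entries:
            if k in IDENTITY_KEYS:
                return k, v
        return None


def decode_text(data: bytes, warnings: list[str] | None = None) -> str:
    """Decode *data* as UTF-8, replacing undecodable bytes with a warning."""
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        if warnings is not None:
            warnings.append("input is not valid UTF-8; undecodable bytes replaced")
        return data.decode("utf-8", errors="replace")


def _logical_lines(text: str) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, line) after joining backslash continuations."""
    raw = text.split("\n")
    if raw and raw[-1] == "":
        raw.pop()
    i = 0
    while i < len(raw):
        lineno = i + 1
        line = raw[i].rstrip("\r")
        while line.endswith("\\"):
            i += 1
            cont = raw[i].rstrip("\r") if i < len(raw) else ""
            line = line[:-1] + cont.lstrip()
        yield lineno, line
        i += 1


def parse_stanzas(text: str, warnings: list[str] | None = None) -> list[Stanza]:
    """Parse RA-style *text* into a list of :class:`Stanza`.

    Blank lines separate stanzas; ``#`` comment lines are skipped; leading
    indentation is discarded; the first whitespace run on a line splits the
    key from the value; values keep internal whitespace but lose trailing
    whitespace.  Entry order within a stanza is preserved exactly.
    """
    stanzas: list[Stanza] = []
    current: Stanza | None = None
    for lineno, line in _logical_lines(text):
        stripped = line.strip()
        if not stripped:
            current = None
            continue
        if stripped.startswith("#"):
            continue
        parts = stripped.split(None, 1)
        key = parts[0]
        if not key:  # pragma: no cover - split(None) never yields empty tokens
            raise StanzaParseError("no key token on line", lineno)
        value = parts[1].rstrip() if len(parts) > 1 else ""
        if current is None:
            current = Stanza(source_line=lineno)
            stanzas.append(current)
        if key in IDENTITY_KEYS and any(k == key for k, _ in current.entries):
            raise StanzaParseError(
                f"duplicate identity key {key!r} within one stanza", lineno
            )
        if key not in IDENTITY_KEYS and any(k == key for k, _ in current.entries):
            if warnings is not None:
                warnings.append(
                    f"line {lineno}: duplicate key {key!r} in stanza; last wins"
                )
        current.entries.append((key, value))
    return stanzas


def serialize_stanzas(stanzas: Sequence[Stanza]) -> str:
    """Serialize stanzas back to canonical text (LF, one blank line between).

    ``parse_stanzas(serialize_stanzas(s))`` equals ``s`` up to line numbers.
    """
    blocks = []
    for stanza in stanzas:
        lines = []
        for key, value in stanza.entries:
            if not key or any(c.isspace() for c in key):
                raise ValueError(f"invalid stanza key {key!r}")
            lines.append(f"{key} {value}".rstrip())
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")
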