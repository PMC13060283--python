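"""Typed model of an IGB Quickload repository.

A Quickload site is a directory tree: ``contents.txt`` at the root lists one
genome directory per line (tab-separated directory name and description);
each genome directory holds ``annots.xml`` (one ``<file>`` element per data
track, with display attributes) and ``genome.txt`` (tab-separated sequence
name and length, in display order).

Parsing is permissive (any XML root element is accepted, unknown attributes
are preserved); serialization is canonical (``<files>`` root, canonical
attributes first, insertion order preserved).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

from lxml import etree

__all__ = [
    "ContentsEntry",
    "AnnotEntry",
    "QuickloadGenome",
    "QuickloadRepo",
    "QuickloadParseError",
    "parse_contents",
    "serialize_contents",
    "parse_annots",
    "serialize_annots",
    "parse_genome_table",
    "serialize_genome_table",
]

_HEX6 = re.compile(r"^[0-9A-Fa-f]{6}$")
_HEX3 = re.compile(r"^[0-9A-Fa-f]{3}$")

#: attribute name on the XML element -> AnnotEntry field
CANONICAL_ATTRS = (
    ("name", "file_name"),
    ("title", "title"),
    ("description", "description"),
    ("foreground", "foreground_hex"),
    ("background", "background_hex"),
    ("load_hint", "load_hint"),
    ("label_field", "label_field"),
    ("url", "info_url"),
)


class QuickloadParseError(ValueError):
    """Malformed contents.txt, annots.xml or genome.txt input."""


@dataclass
class ContentsEntry:
    genome_dir: str
    description: str = ""


@dataclass
class AnnotEntry:
    """One ``<file>`` element of annots.xml.

    ``title`` uses ``/``-separated segments to encode the folder hierarchy
    shown in IGB's Available Data tab; colors are 6-digit uppercase hex.
    """

    file_name: str
    title: str = ""
    description: str = ""
    foreground_hex: str = ""
    background_hex: str = ""
    load_hint: str = ""
    label_field: str = ""
    info_url: str = ""
    extras: list[tuple[str, str]] = field(default_factory=list)

    def title_segments(self) -> list[str]:
        return [s for s in self.title.split("/") if s] if self.title else []


@dataclass
class QuickloadGenome:
    genome_dir: str
    annots: list[AnnotEntry] = field(default_factory=list)
    chromosomes: list[tuple[str, int]] = field(default_factory=list)
    two_bit_name: str = ""


@dataclass
class QuickloadRepo:
    contents: list[ContentsEntry] = field(default_factory=list)
    genomes: dict[str, QuickloadGenome] = field(default_factory=dict)
    base_url: str = field(default="", compare=False)
    warnings: list[str] = field(default_factory=list, compare=False)


def parse_contents(text: str) -> list[ContentsEntry]:
    """Parse contents.txt: ``genome_dir<TAB>description`` per line."""
    entries: list[ContentsEntry] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        genome_dir, _, description = line.partition("\t")
        genome_dir = genome_dir.strip()
        if not genome_dir:
            raise QuickloadParseError(
                f"contents.txt line {lineno}: empty genome directory field"
            )
        if "/" in genome_dir:
            raise QuickloadParseError(
                f"contents.txt line {lineno}: genome directory {genome_dir!r} "
                f"contains '/'"
            )
        entries.append(ContentsEntry(genome_dir=genome_dir, description=description))
    return entries


def serialize_contents(entries: Sequence[ContentsEntry]) -> str:
    lines = []
    for e in entries:
        if not e.genome_dir or "\t" in e.genome_dir or "/" in e.genome_dir:
            raise ValueError(f"invalid genome directory name {e.genome_dir!r}")
        lines.append(f"{e.genome_dir}\t{e.description}" if e.description else e.genome_dir)
    return "".join(line + "\n" for line in lines)


def _normalize_hex(value: str, what: str, warnings: list[str]) -> str:
    if _HEX6.match(value):
        return value.upper()
    if _HEX3.match(value):
        warnings.append(f"{what}: 3-digit hex color {value!r} rejected; color unset")
    else:
        warnings.append(f"{what}: malformed hex color {value!r}; color unset")
    return ""


def parse_annots(xml_text: str | bytes, warnings: list[str] | None = None) -> list[AnnotEntry]:
    """Parse annots.xml into :class:`AnnotEntry` records in document order.

    Any root element is accepted; only children named ``file`` are read.
    A ``file`` element without a ``name`` attribute is skipped with a warning.
    Malformed XML raises :class:`QuickloadParseError`.
    """
    if warnings is None:
        warnings = []
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        # resolve_entities=False: annots.xml never needs entity expansion
        parser = etree.XMLParser(resolve_entities=False, no_network=True)
        root = etree.fromstring(xml_text, parser=parser)
    except etree.XMLSyntaxError as exc:
        raise QuickloadParseError(f"malformed annots.xml: {exc}") from exc

    entries: list[AnnotEntry] = []
    for elem in root:
        if not isinstance(elem.tag, str) or elem.tag != "file":
            continue
        attrs = dict(elem.attrib)
        if "name" not in attrs or not attrs["name"]:
            warnings.append("annots.xml: <file> element without name attribute skipped")
            continue
        entry = AnnotEntry(file_name=attrs.pop("name"))
        entry.title = attrs.pop("title", "")
        entry.description = attrs.pop("description", "")
        fg = attrs.pop("foreground", "")
        if fg:
            entry.foreground_hex = _normalize_hex(fg, f"file {entry.file_name}", warnings)
        bg = attrs.pop("background", "")
        if bg:
            entry.background_hex = _normalize_hex(bg, f"file {entry.file_name}", warnings)
        entry.load_hint = attrs.pop("load_hint", "")
        entry.label_field = attrs.pop("label_field", "")
        entry.info_url = attrs.pop("url", "")
        entry.extras = [(k, v) for k, v in attrs.items()]
        entries.append(entry)
    return entries


def serialize_annots(entries: Sequence[AnnotEntry]) -> str:
    """Serialize entries to canonical annots.xml text.

    Root element is ``<files>``; canonical attributes first (insertion
    order), extras after; attribute values are XML-escaped by the writer.
    """
    root = etree.Element("files")
    for entry in entries:
        if not entry.file_name:
            raise ValueError("AnnotEntry.file_name must be non-empty")
        for hexval in (entry.foreground_hex, entry.background_hex):
            if hexval and not re.match(r"^[0-9A-F]{6}$", hexval):
                raise ValueError(f"invalid hex color {hexval!r}")
        elem = etree.SubElement(root, "file")
        for attr, fieldname in CANONICAL_ATTRS:
            value = getattr(entry, fieldname)
            if value:
                elem.set(attr, value)
        for key, value in entry.extras:
            elem.set(key, value)
    body = etree.tostring(root, encoding="unicode", pretty_print=True)
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + body


def parse_genome_table(text: str) -> list[tuple[str, int]]:
    """Parse genome.txt: ``seq_name<TAB>length`` per line, order preserved."""
    rows: list[tuple[str, int]] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        name, _, length_str = line.partition("\t")
        name = name.strip()
        if not name or not length_str.strip():
            raise QuickloadParseError(
                f"genome.txt line {lineno}: expected 'name<TAB>length'"
            )
        try:
            length = int(length_str.strip())
        except ValueError:
            raise QuickloadParseError(
                f"genome.txt line {lineno}: non-integer length {length_str!r}"
            ) from None
        if length < 1:
            raise QuickloadParseError(
                f"genome.txt line {lineno}: non-positive length {length}"
            )
        if name in seen:
            raise QuickloadParseError(
                f"genome.txt line {lineno}: duplicate sequence name {name!r}"
            )
        seen.add(name)
        rows.append((name, length))
    return rows


def serialize_genome_table(rows: Sequence[tuple[str, int]]) -> str:
    seen: set[str] = set()
    out = []
    for name, length in rows:
        if not name:
            raise ValueError("sequence name must be non-empty")
        if name in seen:
            raise ValueError(f"duplicate sequence name {name!r}")
        if length < 1:
            raise ValueError(f"non-positive length {length} for {name!r}")
        seen.add(name)
        out.append(f"{name}\t{length}\n")
    return "".join(out)
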