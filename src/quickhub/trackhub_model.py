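"""Typed model of a UCSC track hub.

A track hub is three layers of stanza files: ``hub.txt`` (the manifest),
``genomes.txt`` (one stanza per genome assembly) and a ``trackDb.txt`` per
genome (one stanza per track).  The ``useOneFile on`` dialect collapses all
three into ``hub.txt``.  This module builds a :class:`TrackHub` from raw
stanza text, reconstructs the track hierarchy from ``parent``/``superTrack``
keys, and serializes the model back to the same file set.

Recognized trackDb keys are mapped to typed fields; every other key is kept
verbatim in ``extras`` so serialization is lossless.
"""

from __future__ import annotations

import posixpath
from dataclasses import dataclass, field
from typing import Sequence
from urllib.parse import urljoin, urlparse

from .stanza_io import Stanza, parse_stanzas, serialize_stanzas

__all__ = [
    "HubManifest",
    "GenomeEntry",
    "TrackDef",
    "TrackHub",
    "TrackNode",
    "StructuralError",
    "build_trackhub",
    "track_hierarchy",
    "serialize_trackhub",
    "resolve_url",
]

VISIBILITIES = ("hide", "dense", "squish", "pack", "full")
TRACK_TYPE_KINDS = ("bigWig", "bigBed", "bam", "cram", "vcfTabix", "bigGenePred")

#: trackDb keys that populate typed TrackDef fields; the rest go to extras
RECOGNIZED_TRACK_KEYS = (
    "track", "type", "bigDataUrl", "bigDataIndex", "shortLabel", "longLabel",
    "visibility", "color", "altColor", "parent", "superTrack", "container",
    "compositeTrack", "priority", "html", "group",
)


class StructuralError(ValueError):
    """A hub file set is missing a required stanza or key, or has a cycle."""


@dataclass
class HubManifest:
    hub_name: str
    short_label: str = ""
    long_label: str = ""
    genomes_file: str = ""
    email: str = ""
    description_url: str = ""
    use_one_file: bool = False
    extras: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class GenomeEntry:
    genome_id: str
    trackdb_path: str
    two_bit_path: str = ""
    organism: str = ""
    scientific_name: str = ""
    default_pos: str = ""
    extras: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class TrackDef:
    track_name: str
    type_kind: str = "other"          # bigWig|bigBed|bam|cram|vcfTabix|bigGenePred|other
    raw_type: str = ""                # full "type" value, e.g. "bigBed 12 +"
    big_data_url: str = ""
    big_data_index: str = ""
    short_label: str = ""
    long_label: str = ""
    visibility: str = "hide"
    color_rgb: tuple[int, int, int] | None = None
    alt_color_rgb: tuple[int, int, int] | None = None
    parent_name: str = ""
    parent_default_on: bool = True
    container_kind: str = "none"      # none|composite|multiWig|superTrack
    priority: float | None = None
    html_path: str = ""
    group: str = ""
    extras: list[tuple[str, str]] = field(default_factory=list)

    @property
    def is_container(self) -> bool:
        return self.container_kind != "none"

    def display_label(self) -> str:
        return self.long_label or self.short_label or self.track_name


@dataclass
class TrackHub:
    manifest: HubManifest
    genomes: list[GenomeEntry] = field(default_factory=list)
    tracks_by_genome: dict[str, list[TrackDef]] = field(default_factory=dict)
    base_url: str = field(default="", compare=False)
    warnings: list[str] = field(default_factory=list, compare=False)


@dataclass
class TrackNode:
    """One node of the track forest: a track and its ordered children."""

    track: TrackDef
    children: list["TrackNode"] = field(default_factory=list)


def resolve_url(base: str, relative: str) -> str:
    """Resolve *relative* against *base* (URL or POSIX path directory).

    Absolute URLs and absolute paths pass through unchanged; an empty base
    leaves relative references untouched.
    """
    if not relative:
        return relative
    if urlparse(relative).scheme or relative.startswith("/"):
        return relative
    if not base:
        return relative
    if urlparse(base).scheme:
        if not base.endswith("/"):
            base += "/"
        return urljoin(base, relative)
    return posixpath.normpath(posixpath.join(base, relative))


def _parse_color(value: str, warnings: list[str], what: str) -> tuple[int, int, int] | None:
    parts = value.split(",")
    try:
        r, g, b = (int(p.strip()) for p in parts)
    except (TypeError, ValueError):
        warnings.append(f"unparseable {what} value {value!r}; ignored")
        return None
    if not all(0 <= c <= 255 for c in (r, g, b)):
        warnings.append(f"{what} component out of range in {value!r}; ignored")
        return None
    return (r, g, b)


def _track_from_stanza(stanza: Stanza, warnings: list[str]) -> TrackDef:
    name = stanza.get("track") or ""
    track = TrackDef(track_name=name)
    seen: set[str] = set()
    for key, value in stanza.entries:
        if key in seen and key in RECOGNIZED_TRACK_KEYS:
            warnings.append(f"track {name}: duplicate key {key!r}; last wins")
        seen.add(key)
        _apply_track_key(track, key, value, warnings)
    if not track.is_container and not track.big_data_url:
        warnings.append(f"track {name}: leaf track without bigDataUrl")
    return track


def _apply_track_key(track: TrackDef, key: str, value: str, warnings: list[str]) -> None:
    name = track.track_name
    if key == "track":
        track.track_name = value
    elif key == "type":
        track.raw_type = value
        kind = value.split()[0] if value.split() else ""
        track.type_kind = kind if kind in TRACK_TYPE_KINDS else "other"
    elif key == "bigDataUrl":
        track.big_data_url = value
    elif key == "bigDataIndex":
        track.big_data_index = value
    elif key == "shortLabel":
        track.short_label = value
    elif key == "longLabel":
        track.long_label = value
    elif key == "visibility":
        if value in VISIBILITIES:
            track.visibility = value
        else:
            warnings.append(
                f"track {name}: unknown visibility {value!r}; treated as pack"
            )
            track.visibility = "pack"
    elif key == "color":
        track.color_rgb = _parse_color(value, warnings, f"track {name} color")
    elif key == "altColor":
        track.alt_color_rgb = _parse_color(value, warnings, f"track {name} altColor")
    elif key == "parent":
        tokens = value.split()
        track.parent_name = tokens[0] if tokens else ""
        if len(tokens) > 1:
            track.parent_default_on = tokens[1].lower() != "off"
    elif key == "superTrack":
        tokens = value.split()
        if tokens and tokens[0] == "on":
            track.container_kind = "superTrack"
        elif tokens:
            # child membership form: "superTrack <parent> [show|hide]"
            track.parent_name = tokens[0]
            if len(tokens) > 1:
                track.parent_default_on = tokens[1].lower() != "hide"
        else:
            track.container_kind = "superTrack"
    elif key == "compositeTrack":
        if value.split() and value.split()[0] == "on":
            track.container_kind = "composite"
        else:
            track.extras.append((key, value))
    elif key == "container":
        if value.strip() == "multiWig":
            track.container_kind = "multiWig"
        else:
            track.extras.append((key, value))
    elif key == "priority":
        try:
            track.priority = float(value)
        except ValueError:
            warnings.append(f"track {name}: unparseable priority {value!r}; ignored")
    elif key == "html":
        track.html_path = value
    elif key == "group":
        track.group = value
    else:
        track.extras.append((key, value))


def _genome_from_stanza(stanza: Stanza) -> GenomeEntry:
    genome_id = stanza.get("genome") or ""
    trackdb = stanza.get("trackDb") or ""
    if not genome_id or not trackdb:
        raise StructuralError(
            f"genome stanza at line {stanza.source_line} needs both "
            f"'genome' and 'trackDb' keys"
        )
    entry = GenomeEntry(genome_id=genome_id, trackdb_path=trackdb)
    for key, value in stanza.entries:
        if key == "twoBitPath":
            entry.two_bit_path = value
        elif key == "organism":
            entry.organism = value
        elif key == "scientificName":
            entry.scientific_name = value
        elif key == "defaultPos":
            entry.default_pos = value
        elif key not in ("genome", "trackDb"):
            entry.extras.append((key, value))
    return entry


def _genome_one_file_stanza(stanza: Stanza) -> GenomeEntry:
    genome_id = stanza.get("genome") or ""
    if not genome_id:
        raise StructuralError(
            f"genome stanza at line {stanza.source_line} has empty 'genome' value"
        )
    entry = GenomeEntry(genome_id=genome_id, trackdb_path="hub.txt")
    for key, value in stanza.entries:
        if key == "twoBitPath":
            entry.two_bit_path = value
        elif key == "organism":
            entry.organism = value
        elif key == "scientificName":
            entry.scientific_name = value
        elif key == "defaultPos":
            entry.default_pos = value
        elif key != "genome":
            entry.extras.append((key, value))
    return entry


def _manifest_from_stanza(stanza: Stanza) -> HubManifest:
    manifest = HubManifest(hub_name=stanza.get("hub") or "")
    if not manifest.hub_name:
        raise StructuralError("hub stanza has empty 'hub' value")
    for key, value in stanza.entries:
        if key == "shortLabel":
            manifest.short_label = value
        elif key == "longLabel":
            manifest.long_label = value
        elif key == "genomesFile":
            manifest.genomes_file = value
        elif key == "email":
            manifest.email = value
        elif key == "descriptionUrl":
            manifest.description_url = value
        elif key == "useOneFile":
            manifest.use_one_file = value.strip().lower() == "on"
        elif key != "hub":
            manifest.extras.append((key, value))
    return manifest


def build_trackhub(
    hub_text: str,
    genomes_text: str = "",
    trackdb_texts: dict[str, str] | None = None,
    base_url: str = "",
) -> TrackHub:
    """Build a :class:`TrackHub` from raw file text.

    *trackdb_texts* maps genome_id to that genome's trackDb.txt text; it is
    ignored when the hub uses the ``useOneFile`` dialect.

    Raises :class:`StructuralError` if the ``hub`` stanza is missing or a
    genome stanza lacks its required keys.
    """
    warnings: list[str] = []
    hub_stanzas = parse_stanzas(hub_text, warnings)
    if not hub_stanzas or hub_stanzas[0].get("hub") is None:
        raise StructuralError("hub.txt must start with a 'hub' stanza")
    manifest = _manifest_from_stanza(hub_stanzas[0])

    genomes: list[GenomeEntry] = []
    tracks_by_genome: dict[str, list[TrackDef]] = {}

    if manifest.use_one_file:
        current: GenomeEntry | None = None
        for stanza in hub_stanzas[1:]:
            ident = stanza.identity
            if ident is None:
                raise StructuralError(
                    f"stanza at line {stanza.source_line} has no "
                    f"hub/genome/track identity key"
                )
            if ident[0] == "genome":
                current = _genome_one_file_stanza(stanza)
                genomes.append(current)
                tracks_by_genome[current.genome_id] = []
            elif ident[0] == "track":
                if current is None:
                    raise StructuralError(
                        f"track stanza at line {stanza.source_line} "
                        f"precedes any genome stanza"
                    )
                tracks_by_genome[current.genome_id].append(
                    _track_from_stanza(stanza, warnings)
                )
            else:
                raise StructuralError(
                    f"unexpected second 'hub' stanza at line {stanza.source_line}"
                )
    else:
        for stanza in parse_stanzas(genomes_text, warnings):
            entry = _genome_from_stanza(stanza)
            genomes.append(entry)
            tracks_by_genome[entry.genome_id] = []
        for genome_id, text in (trackdb_texts or {}).items():
            if genome_id not in tracks_by_genome:
                warnings.append(f"trackDb supplied for unknown genome {genome_id!r}")
                continue
            tracks_by_genome[genome_id] = parse_trackdb(text, warnings)

    _check_track_refs(tracks_by_genome, warnings)
    return TrackHub(
        manifest=manifest,
        genomes=genomes,
        tracks_by_genome=tracks_by_genome,
        base_url=base_url,
        warnings=warnings,
    )


def parse_trackdb(text: str, warnings: list[str]) -> list[TrackDef]:
    """Parse one trackDb.txt into TrackDefs.

    Stanzas without a ``track`` key are skipped with a warning; in
    particular unresolved ``include`` directives (the fetch layer splices
    resolvable includes before parsing, keeping this parser pure).
    """
    tracks: list[TrackDef] = []
    for stanza in parse_stanzas(text, warnings):
        if stanza.get("track") is None:
            if stanza.entries and stanza.entries[0][0] == "include":
                warnings.append(
                    f"include directive {stanza.entries[0][1]!r} not resolved; skipped"
                )
            else:
                warnings.append(
                    f"trackDb stanza at line {stanza.source_line} has no "
                    f"'track' key; skipped"
                )
            continue
        tracks.append(_track_from_stanza(stanza, warnings))
    return tracks


def _check_track_refs(
    tracks_by_genome: dict[str, list[TrackDef]], warnings: list[str]
) -> None:
    for genome_id, tracks in tracks_by_genome.items():
        names = {t.track_name for t in tracks}
        seen: set[str] = set()
        for t in tracks:
            if t.track_name in seen:
                warnings.append(
                    f"genome {genome_id}: duplicate track name {t.track_name!r}"
                )
            seen.add(t.track_name)
            if t.parent_name and t.parent_name not in names:
                warnings.append(
                    f"genome {genome_id}: track {t.track_name} has dangling "
                    f"parent {t.parent_name!r}"
                )


def track_hierarchy(tracks: Sequence[TrackDef]) -> list[TrackNode]:
    """Arrange one trackDb's tracks into a forest.

    Parent/child edges come from ``parent_name``; roots are parentless tracks
    (and tracks whose parent is missing — dangling parents become roots).
    Sibling order follows source order.  A parent cycle raises
    :class:`StructuralError` naming the tracks involved.
    """
    by_name = {t.track_name: t for t in tracks}
    nodes = {t.track_name: TrackNode(t) for t in tracks}
    roots: list[TrackNode] = []
    for t in tracks:
        if t.parent_name and t.parent_name in by_name:
            nodes[t.parent_name].children.append(nodes[t.track_name])
        else:
            roots.append(nodes[t.track_name])

    # cycle detection: every node must be reachable from a root
    reached: set[str] = set()
    stack = [n for n in roots]
    while stack:
        node = stack.pop()
        if node.track.track_name in reached:
            continue
        reached.add(node.track.track_name)
        stack.extend(node.children)
    unreached = [t.track_name for t in tracks if t.track_name not in reached]
    if unreached:
        raise StructuralError(
            "parent cycle among tracks: {" + ", ".join(sorted(unreached)) + "}"
        )
    return roots


def _track_stanza(track: TrackDef) -> Stanza:
    entries: list[tuple[str, str]] = [("track", track.track_name)]
    if track.container_kind == "superTrack":
        entries.append(("superTrack", "on"))
    elif track.container_kind == "composite":
        entries.append(("compositeTrack", "on"))
    elif track.container_kind == "multiWig":
        entries.append(("container", "multiWig"))
    if track.parent_name:
        entries.append(
            ("parent", f"{track.parent_name} "
                       f"{'on' if track.parent_default_on else 'off'}")
        )
    if track.raw_type:
        entries.append(("type", track.raw_type))
    if track.big_data_url:
        entries.append(("bigDataUrl", track.big_data_url))
    if track.big_data_index:
        entries.append(("bigDataIndex", track.big_data_index))
    if track.short_label:
        entries.append(("shortLabel", track.short_label))
    if track.long_label:
        entries.append(("longLabel", track.long_label))
    entries.append(("visibility", track.visibility))
    if track.color_rgb is not None:
        entries.append(("color", ",".join(str(c) for c in track.color_rgb)))
    if track.alt_color_rgb is not None:
        entries.append(("altColor", ",".join(str(c) for c in track.alt_color_rgb)))
    if track.priority is not None:
        p = track.priority
        entries.append(("priority", str(int(p)) if p == int(p) else repr(p)))
    if track.html_path:
        entries.append(("html", track.html_path))
    if track.group:
        entries.append(("group", track.group))
    entries.extend(track.extras)
    return Stanza(entries=entries)


def _genome_stanza(entry: GenomeEntry, include_trackdb: bool) -> Stanza:
    entries: list[tuple[str, str]] = [("genome", entry.genome_id)]
    if include_trackdb:
        entries.append(("trackDb", entry.trackdb_path))
    if entry.two_bit_path:
        entries.append(("twoBitPath", entry.two_bit_path))
    if entry.organism:
        entries.append(("organism", entry.organism))
    if entry.scientific_name:
        entries.append(("scientificName", entry.scientific_name))
    if entry.default_pos:
        entries.append(("defaultPos", entry.default_pos))
    entries.extend(entry.extras)
    return Stanza(entries=entries)


def _manifest_stanza(manifest: HubManifest, one_file: bool, genomes_file: str) -> Stanza:
    entries: list[tuple[str, str]] = [("hub", manifest.hub_name)]
    if manifest.short_label:
        entries.append(("shortLabel", manifest.short_label))
    if manifest.long_label:
        entries.append(("longLabel", manifest.long_label))
    if one_file:
        entries.append(("useOneFile", "on"))
    else:
        entries.append(("genomesFile", genomes_file))
    if manifest.email:
        entries.append(("email", manifest.email))
    if manifest.description_url:
        entries.append(("descriptionUrl", manifest.description_url))
    entries.extend(manifest.extras)
    return Stanza(entries=entries)


def serialize_trackhub(hub: TrackHub, one_file: bool | None = None) -> dict[str, str]:
    """Serialize *hub* to a ``{relative path: text}`` map.

    With ``one_file`` true the whole hub is a single ``hub.txt``; otherwise
    the map holds ``hub.txt``, the genomes file, and one trackDb.txt per
    genome at each genome's ``trackdb_path``.
    ``build_trackhub`` on the output reproduces *hub* modulo ``base_url``.
    """
    if one_file is None:
        one_file = hub.manifest.use_one_file
    files: dict[str, str] = {}
    if one_file:
        stanzas = [_manifest_stanza(hub.manifest, True, "")]
        for genome in hub.genomes:
            stanzas.append(_genome_stanza(genome, include_trackdb=False))
            for track in hub.tracks_by_genome.get(genome.genome_id, []):
                stanzas.append(_track_stanza(track))
        files["hub.txt"] = serialize_stanzas(stanzas)
        return files

    genomes_file = hub.manifest.genomes_file or "genomes.txt"
    files["hub.txt"] = serialize_stanzas(
        [_manifest_stanza(hub.manifest, False, genomes_file)]
    )
    files[genomes_file] = serialize_stanzas(
        [_genome_stanza(g, include_trackdb=True) for g in hub.genomes]
    )
    for genome in hub.genomes:
        tracks = hub.tracks_by_genome.get(genome.genome_id, [])
        files[genome.trackdb_path] = serialize_stanzas(
            [_track_stanza(t) for t in tracks]
        )
    return files
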