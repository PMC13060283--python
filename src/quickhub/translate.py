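"""Bidirectional mapping between track hubs and Quickload repositories.

The two formats describe the same thing — where data files live and how to
display them — with different vocabularies: trackDb stanzas with RGB colors,
``visibility`` modes and parent/superTrack hierarchy on the UCSC side;
``annots.xml`` ``<file>`` elements with hex colors and ``/``-separated title
paths on the IGB side.  Only indexed binary data formats travel between the
browsers (bigWig, bigBed, BAM, CRAM, tabix VCF); everything else is dropped
and accounted for in a :class:`ConversionReport`.

Settings with no counterpart in the target dialect are not discarded: they
are stashed in reserved ``x_hub_`` (trackDb settings carried inside
annots.xml) and ``x_ql_`` (annots.xml attributes carried inside trackDb)
attributes, so a round trip restores them.  The ``canonical core`` — data
URL, type kind, color, visibility, display label and folder path — survives
a round trip even without the stash.
"""

from __future__ import annotations

import posixpath
import re
from dataclasses import dataclass, field
from urllib.parse import urlparse

from .quickload_model import (
    AnnotEntry,
    ContentsEntry,
    QuickloadGenome,
    QuickloadRepo,
)
from .trackhub_model import (
    GenomeEntry,
    HubManifest,
    TrackDef,
    TrackHub,
    TrackNode,
    _apply_track_key,
    resolve_url,
    track_hierarchy,
)

__all__ = [
    "ConversionReport",
    "SynonymTable",
    "DEFAULT_SYNONYMS",
    "rgb_to_hex",
    "hex_to_rgb",
    "map_track_type_to_quickload",
    "map_file_to_hub_type",
    "hub_to_quickload",
    "quickload_to_hub",
    "canonical_core",
    "sanitize_track_name",
]

#: track type kinds that IGB can open from a translated Quickload
SUPPORTED_KINDS = frozenset({"bigWig", "bigBed", "bam", "cram", "vcfTabix", "bigGenePred"})

#: data-file extensions (lowercased) -> trackDb type kind
EXTENSION_KINDS = (
    (".vcf.gz", "vcfTabix"),
    (".bigwig", "bigWig"),
    (".bw", "bigWig"),
    (".bigbed", "bigBed"),
    (".bb", "bigBed"),
    (".bam", "bam"),
    (".cram", "cram"),
)

_HUB_STASH = "x_hub_"
_QL_STASH = "x_ql_"


class SynonymError(ValueError):
    """A synonym table is not a one-to-one mapping."""


@dataclass
class SynonymTable:
    """One-to-one map between UCSC genome ids and Quickload directory names."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        hub_ids = [h for h, _ in self.pairs]
        ql_dirs = [q for _, q in self.pairs]
        if len(set(hub_ids)) != len(hub_ids) or len(set(ql_dirs)) != len(ql_dirs):
            raise SynonymError("synonym table must be one-to-one")
        self._to_ql = dict(self.pairs)
        self._to_hub = {q: h for h, q in self.pairs}

    def to_quickload(self, genome_id: str) -> str:
        """Quickload directory for a UCSC id; identity when unmapped."""
        return self._to_ql.get(genome_id, genome_id)

    def to_hub(self, genome_dir: str) -> str:
        """UCSC id for a Quickload directory; identity when unmapped."""
        return self._to_hub.get(genome_dir, genome_dir)

    @classmethod
    def from_tsv(cls, text: str) -> "SynonymTable":
        """Load ``hub_id<TAB>quickload_dir`` lines (# comments allowed)."""
        pairs = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            hub_id, _, ql_dir = line.partition("\t")
            if not hub_id or not ql_dir.strip():
                raise SynonymError(f"bad synonym line {line!r}")
            pairs.append((hub_id.strip(), ql_dir.strip()))
        return cls(pairs)


#: common UCSC db <-> IGB Quickload directory names; accession-style GenArk
#: ids (GCA_/GCF_...) deliberately pass through unchanged
DEFAULT_SYNONYMS = SynonymTable(
    [
        ("hg38", "H_sapiens_Dec_2013"),
        ("hg19", "H_sapiens_Feb_2009"),
        ("mm39", "M_musculus_Jun_2020"),
        ("mm10", "M_musculus_Dec_2011"),
        ("danRer11", "D_rerio_May_2017"),
        ("dm6", "D_melanogaster_Aug_2014"),
        ("ce11", "C_elegans_Feb_2013"),
        ("sacCer3", "S_cerevisiae_Apr_2011"),
        ("araTha1", "A_thaliana_Jun_2009"),
    ]
)


@dataclass
class ConversionReport:
    """Per-conversion lossiness ledger.

    ``tracks_in`` counts the data (leaf) tracks considered; containers are
    folder structure, not data tracks.  The invariant
    ``tracks_out + len(dropped) == tracks_in`` always holds.
    """

    tracks_in: int = 0
    tracks_out: int = 0
    dropped: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    genome_name_map: dict[str, str] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"tracks in: {self.tracks_in}, translated: {self.tracks_out}, "
            f"dropped: {len(self.dropped)}"
        ]
        for ident, reason in self.dropped:
            lines.append(f"  dropped {ident}: {reason}")
        for warning in self.warnings:
            lines.append(f"  warning: {warning}")
        return "\n".join(lines)


def rgb_to_hex(r: int, g: int, b: int) -> str:
    """``(0, 0, 255) -> "0000FF"`` — uppercase two hex digits per channel."""
    for c in (r, g, b):
        if not isinstance(c, int) or isinstance(c, bool) or not 0 <= c <= 255:
            raise ValueError(f"RGB component {c!r} out of range 0-255")
    return f"{r:02X}{g:02X}{b:02X}"


def hex_to_rgb(hex6: str) -> tuple[int, int, int]:
    """Exact inverse of :func:`rgb_to_hex`; accepts either letter case."""
    if not isinstance(hex6, str) or not re.fullmatch(r"[0-9A-Fa-f]{6}", hex6):
        raise ValueError(f"malformed hex color {hex6!r}")
    return (int(hex6[0:2], 16), int(hex6[2:4], 16), int(hex6[4:6], 16))


def map_track_type_to_quickload(type_kind: str) -> tuple[bool, str]:
    """Whether a trackDb type kind survives translation to Quickload.

    bigGenePred is treated as a bigBed-family annotation file, which IGB
    opens like any other bigBed.
    """
    if type_kind in SUPPORTED_KINDS:
        return True, ""
    return False, f"track type {type_kind!r} has no Quickload counterpart"


def map_file_to_hub_type(file_name: str) -> tuple[str, str]:
    """trackDb type kind for a Quickload data file, by extension.

    Returns ``(kind, "")`` or ``("", reason)``.  Track hubs require indexed
    binary formats, so plain-text formats (.bed, .gff3, un-bgzipped .vcf...)
    are unsupported.
    """
    path = urlparse(file_name).path if "://" in file_name else file_name
    lowered = path.lower()
    for ext, kind in EXTENSION_KINDS:
        if lowered.endswith(ext):
            return kind, ""
    ext = posixpath.splitext(lowered)[1] or "(no extension)"
    return "", f"file extension {ext} is not an indexed binary hub format"


def sanitize_track_name(label: str, taken: set[str]) -> str:
    """Word-like unique trackDb name from a display label."""
    name = re.sub(r"[^A-Za-z0-9_]", "_", label) or "track"
    if name[0].isdigit():
        name = "t_" + name
    candidate = name
    suffix = 2
    while candidate in taken:
        candidate = f"{name}_{suffix}"
        suffix += 1
    taken.add(candidate)
    return candidate


def _ordered_children(nodes: list[TrackNode]) -> list[TrackNode]:
    """Priority ascending, unset priorities after set ones, then source order."""

    def sort_key(pair: tuple[int, TrackNode]):
        index, node = pair
        priority = node.track.priority
        return (priority is None, priority if priority is not None else 0.0, index)

    return [node for _, node in sorted(enumerate(nodes), key=sort_key)]


def _trackdb_dir(hub: TrackHub, genome: GenomeEntry) -> str:
    trackdb_url = resolve_url(hub.base_url, genome.trackdb_path)
    return posixpath.dirname(trackdb_url)


def _stash_hub_settings(track: TrackDef, entry: AnnotEntry) -> None:
    """Carry trackDb-only settings inside annots.xml attributes."""
    if track.raw_type:
        entry.extras.append((_HUB_STASH + "type", track.raw_type))
    entry.extras.append((_HUB_STASH + "visibility", track.visibility))
    if track.short_label:
        entry.extras.append((_HUB_STASH + "shortLabel", track.short_label))
    if track.alt_color_rgb is not None:
        entry.extras.append(
            (_HUB_STASH + "altColor", ",".join(str(c) for c in track.alt_color_rgb))
        )
    if track.priority is not None:
        p = track.priority
        entry.extras.append(
            (_HUB_STASH + "priority", str(int(p)) if p == int(p) else repr(p))
        )
    if track.group:
        entry.extras.append((_HUB_STASH + "group", track.group))
    if track.big_data_index:
        entry.extras.append((_HUB_STASH + "bigDataIndex", track.big_data_index))
    for key, value in track.extras:
        if key.startswith(_QL_STASH):
            continue  # restored to typed annot fields by the caller
        entry.extras.append((_HUB_STASH + key, value))


def _restore_ql_settings(track: TrackDef, entry: AnnotEntry) -> None:
    """Restore annots.xml-only attributes stashed in trackDb extras."""
    for key, value in track.extras:
        if key == _QL_STASH + "background":
            entry.background_hex = value
        elif key == _QL_STASH + "load_hint":
            entry.load_hint = value
        elif key == _QL_STASH + "label_field":
            entry.label_field = value
        elif key.startswith(_QL_STASH):
            entry.extras.append((key[len(_QL_STASH):], value))


def hub_to_quickload(
    hub: TrackHub, synonyms: SynonymTable = DEFAULT_SYNONYMS
) -> tuple[QuickloadRepo, ConversionReport]:
    """Translate a track hub into a Quickload repository model.

    One contents.txt line per genome; per genome, one annots.xml ``<file>``
    entry per leaf track with a supported type.  Container tracks become
    folder segments of the annot title.  Unsupported leaf tracks land in
    ``report.dropped``.  All emitted file URLs are resolved against the
    hub's base URL, so they are absolute whenever the base is.
    """
    report = ConversionReport()
    repo = QuickloadRepo(base_url="")
    for genome in hub.genomes:
        genome_dir = synonyms.to_quickload(genome.genome_id)
        report.genome_name_map[genome.genome_id] = genome_dir
        repo.contents.append(
            ContentsEntry(genome_dir=genome_dir, description=hub.manifest.long_label)
        )
        ql_genome = QuickloadGenome(genome_dir=genome_dir)
        if genome.two_bit_path:
            ql_genome.two_bit_name = posixpath.basename(genome.two_bit_path)
        tracks = hub.tracks_by_genome.get(genome.genome_id, [])
        forest = track_hierarchy(tracks)
        data_dir = _trackdb_dir(hub, genome)

        def walk(nodes: list[TrackNode], path: tuple[str, ...]) -> None:
            for node in _ordered_children(nodes):
                track = node.track
                label = track.display_label()
                if track.is_container or node.children:
                    if not track.is_container:
                        report.warnings.append(
                            f"track {track.track_name} has children but no "
                            f"container setting; treated as a folder"
                        )
                    walk(node.children, path + (label,))
                    continue
                report.tracks_in += 1
                supported, _ = map_track_type_to_quickload(track.type_kind)
                if not supported:
                    raw = track.raw_type or track.type_kind
                    report.dropped.append(
                        (
                            track.track_name,
                            f"track type {raw!r} has no Quickload counterpart",
                        )
                    )
                    continue
                entry = AnnotEntry(
                    file_name=resolve_url(data_dir, track.big_data_url),
                    title="/".join(path + (label,)),
                    description=track.long_label,
                )
                if track.color_rgb is not None:
                    entry.foreground_hex = rgb_to_hex(*track.color_rgb)
                if track.html_path:
                    entry.info_url = resolve_url(data_dir, track.html_path)
                _restore_ql_settings(track, entry)
                _stash_hub_settings(track, entry)
                ql_genome.annots.append(entry)
                report.tracks_out += 1

        walk(forest, ())
        repo.genomes[genome_dir] = ql_genome
    return repo, report


def _restore_hub_settings(track: TrackDef, entry: AnnotEntry, warnings: list[str]) -> None:
    """Apply stashed ``x_hub_*`` attributes back onto their trackDb keys."""
    for key, value in entry.extras:
        if key.startswith(_HUB_STASH):
            _apply_track_key(track, key[len(_HUB_STASH):], value, warnings)


def _carry_ql_settings(track: TrackDef, entry: AnnotEntry) -> None:
    """Keep annots.xml-only attributes inside trackDb extras."""
    if entry.background_hex:
        track.extras.append((_QL_STASH + "background", entry.background_hex))
    if entry.load_hint:
        track.extras.append((_QL_STASH + "load_hint", entry.load_hint))
    if entry.label_field:
        track.extras.append((_QL_STASH + "label_field", entry.label_field))
    for key, value in entry.extras:
        if not key.startswith(_HUB_STASH):
            track.extras.append((_QL_STASH + key, value))


def quickload_to_hub(
    repo: QuickloadRepo, synonyms: SynonymTable = DEFAULT_SYNONYMS
) -> tuple[TrackHub, ConversionReport]:
    """Translate a Quickload repository into a track hub model.

    One genome per contents.txt line; per annot entry with a supported file
    extension, one leaf track.  Multi-segment annot titles synthesize one
    superTrack container per distinct folder path.  Hub-level manifest
    fields do not exist in Quickload, so they are synthesized
    deterministically from the repository contents.
    """
    report = ConversionReport()
    first_description = next(
        (c.description for c in repo.contents if c.description), ""
    )
    long_label = first_description or "Converted Quickload repository"
    manifest = HubManifest(
        hub_name="converted_quickload",
        short_label=long_label[:17],
        long_label=long_label,
        genomes_file="genomes.txt",
    )
    hub = TrackHub(manifest=manifest, base_url="")

    for contents_entry in repo.contents:
        genome_dir = contents_entry.genome_dir
        genome_id = synonyms.to_hub(genome_dir)
        report.genome_name_map[genome_dir] = genome_id
        genome_base = resolve_url(repo.base_url, genome_dir + "/") if repo.base_url else genome_dir
        ql_genome = repo.genomes.get(genome_dir)
        entry = GenomeEntry(
            genome_id=genome_id, trackdb_path=f"{genome_id}/trackDb.txt"
        )
        if ql_genome is not None and ql_genome.two_bit_name:
            entry.two_bit_path = resolve_url(genome_base, ql_genome.two_bit_name)
        hub.genomes.append(entry)

        tracks: list[TrackDef] = []
        taken: set[str] = set()
        containers: dict[tuple[str, ...], str] = {}

        def folder_track(path: tuple[str, ...]) -> str:
            """Track name of the container for *path*, creating the chain."""
            if path in containers:
                return containers[path]
            parent = folder_track(path[:-1]) if len(path) > 1 else ""
            name = sanitize_track_name(path[-1], taken)
            container = TrackDef(
                track_name=name,
                container_kind="superTrack",
                short_label=path[-1][:17],
                long_label=path[-1],
                parent_name=parent,
            )
            tracks.append(container)
            containers[path] = name
            return name

        for annot in ql_genome.annots if ql_genome is not None else []:
            report.tracks_in += 1
            kind, reason = map_file_to_hub_type(annot.file_name)
            stashed_type = next(
                (v for k, v in annot.extras if k == _HUB_STASH + "type"), ""
            )
            if not kind and not stashed_type:
                report.dropped.append((annot.file_name, reason))
                continue
            segments = annot.title_segments()
            leaf = segments[-1] if segments else posixpath.basename(
                urlparse(annot.file_name).path or annot.file_name
            )
            folders = tuple(segments[:-1])
            parent = folder_track(folders) if folders else ""
            track = TrackDef(
                track_name=sanitize_track_name(leaf, taken),
                type_kind=kind or "other",
                raw_type=kind,
                big_data_url=resolve_url(genome_base, annot.file_name),
                short_label=leaf[:17],
                long_label=annot.description or leaf,
                visibility="pack",
                parent_name=parent,
            )
            if annot.foreground_hex:
                track.color_rgb = hex_to_rgb(annot.foreground_hex)
            if annot.info_url:
                track.html_path = annot.info_url
            _restore_hub_settings(track, annot, report.warnings)
            _carry_ql_settings(track, annot)
            tracks.append(track)
            report.tracks_out += 1

        hub.tracks_by_genome[genome_id] = tracks
    return hub, report


def canonical_core(hub: TrackHub) -> dict[tuple[str, str], tuple]:
    """Round-trip comparison key for a hub.

    Maps ``(genome_id, resolved data URL)`` to the settings that must
    survive hub -> quickload -> hub translation: type kind, color,
    visibility, display label and folder path.  Only leaf tracks with
    supported types participate; order does not.
    """
    core: dict[tuple[str, str], tuple] = {}
    for genome in hub.genomes:
        data_dir = _trackdb_dir(hub, genome)
        tracks = hub.tracks_by_genome.get(genome.genome_id, [])
        forest = track_hierarchy(tracks)

        def walk(nodes: list[TrackNode], path: tuple[str, ...]) -> None:
            for node in nodes:
                track = node.track
                if track.is_container or node.children:
                    walk(node.children, path + (track.display_label(),))
                    continue
                if track.type_kind not in SUPPORTED_KINDS:
                    continue
                url = resolve_url(data_dir, track.big_data_url)
                core[(genome.genome_id, url)] = (
                    track.type_kind,
                    track.color_rgb,
                    track.visibility,
                    track.display_label(),
                    path,
                )

        walk(forest, ())
    return core
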