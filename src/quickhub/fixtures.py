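"""Deterministic synthetic repositories for offline testing.

Real track hubs and Quickload sites live on the web; tests cannot depend on
them.  This module generates miniature but structurally faithful hubs,
Quickload repositories, 2bit files and assembly catalogs — together with
the ground-truth in-memory model each file set encodes — as a pure function
of a :class:`FixtureSpec`.  Data files referenced by the metadata are
zero-byte placeholders: the translator's contract is that it never opens
them, and tests assert exactly that.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .quickload_model import (
    AnnotEntry,
    ContentsEntry,
    QuickloadGenome,
    QuickloadRepo,
    serialize_annots,
    serialize_contents,
    serialize_genome_table,
)
from .trackhub_model import (
    GenomeEntry,
    HubManifest,
    TrackDef,
    TrackHub,
    serialize_trackhub,
)
from .translate import rgb_to_hex
from .twobit import write_twobit

__all__ = [
    "FixtureSpec",
    "generate_hub",
    "generate_quickload",
    "generate_catalog",
    "generate_sequences",
]

#: leaf track type -> (trackDb "type" value, data file extension)
_KIND_FILES = {
    "bigWig": ("bigWig 0 1000", ".bw"),
    "bigBed": ("bigBed 9 +", ".bb"),
    "bam": ("bam", ".bam"),
    "cram": ("cram", ".cram"),
    "vcfTabix": ("vcfTabix", ".vcf.gz"),
    "unsupported": ("bedGraph 4", ".bedGraph"),
}

_TISSUES = (
    "heart", "lung", "prostate", "kidney", "liver", "brain", "spleen",
    "thyroid", "testis", "ovary", "colon", "stomach", "muscle", "skin",
)

_SPECIES = (
    ("Homo sapiens", "human", 9606),
    ("Mus musculus", "house mouse", 10090),
    ("Danio rerio", "zebrafish", 7955),
    ("Arabidopsis thaliana", "thale cress", 3702),
    ("Drosophila melanogaster", "fruit fly", 7227),
    ("Caenorhabditis elegans", "roundworm", 6239),
    ("Saccharomyces cerevisiae", "baker's yeast", 559292),
    ("Gallus gallus", "chicken", 9031),
)


def _default_type_mix() -> dict[str, float]:
    return {
        "bigWig": 3.0,
        "bigBed": 2.0,
        "bam": 2.0,
        "cram": 1.0,
        "vcfTabix": 1.0,
        "unsupported": 1.0,
    }


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic repository; generation is pure in this."""

    seed: int = 0
    n_genomes: int = 1
    tracks_per_genome: tuple[int, int] = (2, 5)
    type_mix: dict[str, float] = field(default_factory=_default_type_mix)
    hierarchy_depth: int = 1
    with_two_bit: bool = False
    with_colors: float = 0.5

    def __post_init__(self) -> None:
        weights = list(self.type_mix.values())
        if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
            raise ValueError("type_mix weights must be non-negative, not all zero")
        if not 0 <= self.hierarchy_depth <= 2:
            raise ValueError("hierarchy_depth must be 0, 1 or 2")

    def supported_only(self) -> "FixtureSpec":
        mix = {k: w for k, w in self.type_mix.items() if k != "unsupported"}
        return replace(self, type_mix=mix or {"bigWig": 1.0})


def generate_sequences(rng: random.Random, n_seqs: int | None = None) -> dict[str, str]:
    """Small random chromosome set, with occasional N runs."""
    n = n_seqs if n_seqs is not None else rng.randint(1, 3)
    sequences: dict[str, str] = {}
    for i in range(n):
        length = rng.randint(12, 60)
        bases = []
        j = 0
        while j < length:
            if rng.random() < 0.1:
                run = min(rng.randint(1, 5), length - j)
                bases.append("N" * run)
                j += run
            else:
                bases.append(rng.choice("ACGT"))
                j += 1
        sequences[f"chr{i + 1}"] = "".join(bases)[:length]
    return sequences


def _pick_kind(rng: random.Random, mix: dict[str, float]) -> str:
    kinds = sorted(mix)  # sorted for seed-stable iteration order
    weights = [mix[k] for k in kinds]
    return rng.choices(kinds, weights=weights, k=1)[0]


def _genome_ids(rng: random.Random, n: int) -> list[str]:
    ids: list[str] = []
    pool = ["hg38", "mm39", "danRer11", "dm6", "ce11", "sacCer3"]
    rng.shuffle(pool)
    for i in range(n):
        if i < len(pool) and rng.random() < 0.5:
            ids.append(pool[i])
        else:
            ids.append(f"GCF_{rng.randrange(10**9):09d}.{rng.randint(1, 9)}")
    return ids


def _make_tracks(
    rng: random.Random, spec: FixtureSpec, genome_index: int
) -> list[TrackDef]:
    n_leaves = rng.randint(*spec.tracks_per_genome)
    tracks: list[TrackDef] = []

    containers: list[str] = []
    if spec.hierarchy_depth >= 1 and n_leaves >= 2:
        top = TrackDef(
            track_name=f"g{genome_index}_folder",
            container_kind="superTrack",
            short_label="RNA-Seq",
            long_label="RNA-Seq coverage",
            visibility="full",
        )
        tracks.append(top)
        containers.append(top.track_name)
        if spec.hierarchy_depth == 2:
            nested = TrackDef(
                track_name=f"g{genome_index}_folder_reps",
                container_kind="composite",
                parent_name=top.track_name,
                short_label="Replicates",
                long_label="Biological replicates",
                visibility="dense",
            )
            tracks.append(nested)
            containers.append(nested.track_name)

    for leaf in range(n_leaves):
        kind = _pick_kind(rng, spec.type_mix)
        raw_type, ext = _KIND_FILES[kind]
        tissue = _TISSUES[(genome_index * 7 + leaf) % len(_TISSUES)]
        track = TrackDef(
            track_name=f"g{genome_index}_t{leaf}",
            type_kind=kind if kind != "unsupported" else "other",
            raw_type=raw_type,
            big_data_url=f"data/g{genome_index}_t{leaf}{ext}",
            short_label=f"{tissue[:12]} {leaf}",
            long_label=f"{tissue.capitalize()} sample {leaf} ({kind})",
            visibility=rng.choice(("hide", "dense", "squish", "pack", "full")),
        )
        if rng.random() < spec.with_colors:
            track.color_rgb = (
                rng.randint(0, 255), rng.randint(0, 255), rng.randint(0, 255)
            )
        if rng.random() < 0.3:
            track.priority = float(rng.randint(1, 50))
        if rng.random() < 0.3:
            track.extras.append(("maxHeightPixels", "100:32:8"))
        if containers and rng.random() < 0.7:
            track.parent_name = rng.choice(containers)
        tracks.append(track)
    return tracks


def generate_hub(spec: FixtureSpec) -> tuple[dict[str, bytes], TrackHub]:
    """Synthesize a three-file track hub and its ground-truth model.

    The returned file map holds hub.txt/genomes.txt/trackDb.txt text, a
    zero-byte placeholder per referenced data file, and (with
    ``with_two_bit``) a real miniature 2bit per genome.
    """
    rng = random.Random(spec.seed)
    manifest = HubManifest(
        hub_name=f"fixture_hub_{spec.seed}",
        short_label=f"Fixture {spec.seed}",
        long_label=f"Synthetic fixture hub (seed {spec.seed})",
        genomes_file="genomes.txt",
        email="nobody@example.org",
    )
    hub = TrackHub(manifest=manifest)
    two_bit_files: dict[str, bytes] = {}
    for i, genome_id in enumerate(_genome_ids(rng, spec.n_genomes)):
        entry = GenomeEntry(
            genome_id=genome_id,
            trackdb_path=f"{genome_id}/trackDb.txt",
        )
        if spec.with_two_bit:
            entry.two_bit_path = f"{genome_id}/{genome_id}.2bit"
            two_bit_files[entry.two_bit_path] = write_twobit(generate_sequences(rng))
        hub.genomes.append(entry)
        hub.tracks_by_genome[genome_id] = _make_tracks(rng, spec, i)

    files = {
        path: text.encode() for path, text in serialize_trackhub(hub, False).items()
    }
    for genome in hub.genomes:
        for track in hub.tracks_by_genome[genome.genome_id]:
            if track.big_data_url:
                files[f"{genome.genome_id}/{track.big_data_url}"] = b""
    files.update(two_bit_files)
    return files, hub


def generate_quickload(spec: FixtureSpec) -> tuple[dict[str, bytes], QuickloadRepo]:
    """Synthesize a Quickload repository and its ground-truth model."""
    rng = random.Random(spec.seed)
    repo = QuickloadRepo()
    files: dict[str, bytes] = {}
    for i in range(spec.n_genomes):
        scientific, common, _taxon = _SPECIES[i % len(_SPECIES)]
        genus, species = scientific.split(" ", 1)
        genome_dir = f"{genus[0]}_{species.replace(' ', '_')}_v{spec.seed % 7}_{i}"
        repo.contents.append(
            ContentsEntry(genome_dir=genome_dir, description=f"{common} fixture genome")
        )
        genome = QuickloadGenome(genome_dir=genome_dir)

        n_annots = rng.randint(*spec.tracks_per_genome)
        for j in range(n_annots):
            kind = _pick_kind(rng, spec.type_mix)
            _, ext = _KIND_FILES[kind]
            ext = ext if kind != "unsupported" else ".gff3"
            tissue = _TISSUES[(i * 5 + j) % len(_TISSUES)]
            folders = []
            if spec.hierarchy_depth >= 1:
                folders.append("RNA-Seq")
            if spec.hierarchy_depth == 2:
                folders.append("Coverage")
            title = "/".join(folders + [f"{tissue.capitalize()} {j}"])
            entry = AnnotEntry(
                file_name=f"data/{tissue}_{j}{ext}",
                title=title,
                description=f"{tissue} sample {j}",
            )
            if rng.random() < spec.with_colors:
                entry.foreground_hex = rgb_to_hex(
                    rng.randint(0, 255), rng.randint(0, 255), rng.randint(0, 255)
                )
            if rng.random() < 0.2:
                entry.load_hint = "Whole Sequence"
            genome.annots.append(entry)
            files[f"{genome_dir}/{entry.file_name}"] = b""

        if spec.with_two_bit:
            sequences = generate_sequences(rng)
            genome.two_bit_name = "genome.2bit"
            genome.chromosomes = [(name, len(seq)) for name, seq in sequences.items()]
            files[f"{genome_dir}/genome.2bit"] = write_twobit(sequences)
        else:
            genome.chromosomes = [
                (f"chr{k + 1}", rng.randint(1000, 99999)) for k in range(rng.randint(1, 3))
            ]
        files[f"{genome_dir}/annots.xml"] = serialize_annots(genome.annots).encode()
        files[f"{genome_dir}/genome.txt"] = serialize_genome_table(
            genome.chromosomes
        ).encode()
        repo.genomes[genome_dir] = genome

    files["contents.txt"] = serialize_contents(repo.contents).encode()
    return files, repo


def generate_catalog(seed: int, n: int) -> tuple[str, list]:
    """Synthesize an assembly catalog TSV and its ground-truth records."""
    from .catalog import AssemblyRecord

    rng = random.Random(seed)
    header = "accession\tassembly_name\tscientific_name\tcommon_name\ttaxon_id\thub_url"
    lines = [header]
    records: list[AssemblyRecord] = []
    used: set[str] = set()
    for i in range(n):
        scientific, common, taxon = _SPECIES[i % len(_SPECIES)]
        while True:
            accession = (
                f"{rng.choice(('GCA', 'GCF'))}_{rng.randrange(10**9):09d}."
                f"{rng.randint(1, 9)}"
            )
            if accession not in used:
                used.add(accession)
                break
        record = AssemblyRecord(
            accession=accession,
            assembly_name=f"ASM{rng.randrange(10**6)}v{rng.randint(1, 3)}",
            scientific_name=scientific,
            common_name=common,
            taxon_id=taxon,
            hub_url=f"https://hubs.example.org/{accession}/hub.txt",
        )
        records.append(record)
        lines.append(
            f"{record.accession}\t{record.assembly_name}\t{record.scientific_name}"
            f"\t{record.common_name}\t{record.taxon_id}\t{record.hub_url}"
        )
    return "\n".join(lines) + "\n", records
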