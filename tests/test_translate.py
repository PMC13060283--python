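"""The bidirectional mapping engine and its conservation/round-trip laws."""

import pytest
from hypothesis import given, settings, strategies as st

from conftest import spec_for
from quickhub.fixtures import generate_hub, generate_quickload
from quickhub.quickload_model import AnnotEntry, ContentsEntry, QuickloadGenome, QuickloadRepo
from quickhub.trackhub_model import GenomeEntry, HubManifest, TrackDef, TrackHub
from quickhub.translate import (
    SynonymTable,
    SynonymError,
    canonical_core,
    hex_to_rgb,
    hub_to_quickload,
    map_file_to_hub_type,
    map_track_type_to_quickload,
    quickload_to_hub,
    rgb_to_hex,
    sanitize_track_name,
)


class TestColors:
    def test_blue(self):
        assert rgb_to_hex(0, 0, 255) == "0000FF"

    def test_white(self):
        assert rgb_to_hex(255, 255, 255) == "FFFFFF"

    def test_out_of_range_component(self):
        with pytest.raises(ValueError):
            rgb_to_hex(256, 0, 0)
        with pytest.raises(ValueError):
            rgb_to_hex(0, -1, 0)

    def test_hex_to_rgb(self):
        assert hex_to_rgb("0000FF") == (0, 0, 255)
        assert hex_to_rgb("a0b1c2") == (0xA0, 0xB1, 0xC2)

    @pytest.mark.parametrize("bad", ["GG0000", "00FF0", "00FF000", "", "0000F "])
    def test_malformed_hex_rejected(self, bad):
        with pytest.raises(ValueError):
            hex_to_rgb(bad)

    @given(st.tuples(st.integers(0, 255), st.integers(0, 255), st.integers(0, 255)))
    @settings(max_examples=200, deadline=None)
    def test_bijection(self, rgb):
        assert hex_to_rgb(rgb_to_hex(*rgb)) == rgb


class TestTypeMaps:
    @pytest.mark.parametrize(
        "kind", ["bigWig", "bigBed", "bam", "cram", "vcfTabix", "bigGenePred"]
    )
    def test_supported_kinds(self, kind):
        assert map_track_type_to_quickload(kind) == (True, "")

    def test_unsupported_carries_raw_type(self):
        ok, reason = map_track_type_to_quickload("bedGraph")
        assert not ok and "bedGraph" in reason

    @pytest.mark.parametrize(
        "name,kind",
        [
            ("x.bw", "bigWig"),
            ("x.bigWig", "bigWig"),
            ("x.bb", "bigBed"),
            ("x.bam", "bam"),
            ("x.cram", "cram"),
            ("x.vcf.gz", "vcfTabix"),
            ("x.VCF.GZ", "vcfTabix"),
            ("http://h/p/x.BW?y=1", "bigWig"),
        ],
    )
    def test_extension_mapping(self, name, kind):
        assert map_file_to_hub_type(name) == (kind, "")

    @pytest.mark.parametrize("name", ["x.gff3", "x.bed", "x.vcf", "x.psl", "x"])
    def test_plain_text_formats_unsupported(self, name):
        kind, reason = map_file_to_hub_type(name)
        assert kind == "" and reason


class TestSynonyms:
    def test_round_trip_and_identity_default(self):
        table = SynonymTable([("hg38", "H_sapiens_Dec_2013")])
        assert table.to_quickload("hg38") == "H_sapiens_Dec_2013"
        assert table.to_hub("H_sapiens_Dec_2013") == "hg38"
        assert table.to_quickload("GCF_000001405.40") == "GCF_000001405.40"

    def test_non_bijective_table_rejected(self):
        with pytest.raises(SynonymError):
            SynonymTable([("hg38", "A"), ("hg38", "B")])

    def test_tsv_loading(self):
        table = SynonymTable.from_tsv("# comment\nhg38\tH_sapiens_Dec_2013\n")
        assert table.to_hub("H_sapiens_Dec_2013") == "hg38"


def _three_track_hub():
    tracks = [
        TrackDef(
            track_name="cov", type_kind="bigWig", raw_type="bigWig",
            big_data_url="data/cov.bw", long_label="Heart coverage",
            visibility="full", color_rgb=(0, 0, 255),
        ),
        TrackDef(
            track_name="reads", type_kind="bam", raw_type="bam",
            big_data_url="data/reads.bam", long_label="Heart reads",
        ),
        TrackDef(
            track_name="graph", type_kind="other", raw_type="bedGraph 4",
            big_data_url="data/graph.bedGraph", long_label="Graph",
        ),
    ]
    return TrackHub(
        manifest=HubManifest(hub_name="h", long_label="My hub"),
        genomes=[GenomeEntry(genome_id="hg38", trackdb_path="hg38/trackDb.txt")],
        tracks_by_genome={"hg38": tracks},
        base_url="https://x.org/hub",
    )


class TestHubToQuickload:
    def test_supported_translated_unsupported_dropped(self):
        repo, report = hub_to_quickload(_three_track_hub())
        assert report.tracks_in == 3
        assert report.tracks_out == 2
        assert report.dropped == [("graph", report.dropped[0][1])]
        assert "bedGraph" in report.dropped[0][1]
        genome = repo.genomes["H_sapiens_Dec_2013"]
        cov, reads = genome.annots
        assert cov.file_name == "https://x.org/hub/hg38/data/cov.bw"
        assert cov.title == "Heart coverage"
        assert cov.foreground_hex == "0000FF"
        assert cov.description == "Heart coverage"
        assert reads.foreground_hex == ""

    def test_contents_uses_synonym_and_hub_label(self):
        repo, report = hub_to_quickload(_three_track_hub())
        assert repo.contents == [
            ContentsEntry("H_sapiens_Dec_2013", "My hub")
        ]
        assert report.genome_name_map == {"hg38": "H_sapiens_Dec_2013"}

    def test_empty_trackdb_lists_genome_with_no_annots(self):
        hub = _three_track_hub()
        hub.tracks_by_genome["hg38"] = []
        repo, report = hub_to_quickload(hub)
        assert len(repo.contents) == 1
        assert repo.genomes["H_sapiens_Dec_2013"].annots == []
        assert report.tracks_in == 0

    def test_supertrack_children_get_folder_titles(self):
        tracks = [
            TrackDef(track_name="rna", container_kind="superTrack",
                     long_label="RNA-Seq"),
            TrackDef(track_name="heart", parent_name="rna", type_kind="bigWig",
                     raw_type="bigWig", big_data_url="h.bw",
                     long_label="Heart coverage"),
        ]
        hub = _three_track_hub()
        hub.tracks_by_genome["hg38"] = tracks
        repo, report = hub_to_quickload(hub)
        (entry,) = repo.genomes["H_sapiens_Dec_2013"].annots
        assert entry.title == "RNA-Seq/Heart coverage"
        assert report.tracks_in == 1  # the container is structure, not data

    def test_priority_orders_siblings_ascending_unset_last(self):
        tracks = [
            TrackDef(track_name="c", type_kind="bam", raw_type="bam",
                     big_data_url="c.bam"),
            TrackDef(track_name="b", type_kind="bam", raw_type="bam",
                     big_data_url="b.bam", priority=2.0),
            TrackDef(track_name="a", type_kind="bam", raw_type="bam",
                     big_data_url="a.bam", priority=1.0),
        ]
        hub = _three_track_hub()
        hub.tracks_by_genome["hg38"] = tracks
        repo, _ = hub_to_quickload(hub)
        names = [e.file_name.rsplit("/", 1)[-1]
                 for e in repo.genomes["H_sapiens_Dec_2013"].annots]
        assert names == ["a.bam", "b.bam", "c.bam"]

    def test_two_bit_name_recorded(self):
        hub = _three_track_hub()
        hub.genomes[0].two_bit_path = "hg38/hg38.2bit"
        repo, _ = hub_to_quickload(hub)
        assert repo.genomes["H_sapiens_Dec_2013"].two_bit_name == "hg38.2bit"


class TestQuickloadToHub:
    def _repo(self, annots):
        return QuickloadRepo(
            contents=[ContentsEntry("G_dir", "A repo")],
            genomes={"G_dir": QuickloadGenome(genome_dir="G_dir", annots=annots)},
            base_url="https://q.org/ql",
        )

    def test_basic_annot_becomes_track(self):
        repo = self._repo([
            AnnotEntry(file_name="a.bw", title="Cov", foreground_hex="FF0000")
        ])
        hub, report = quickload_to_hub(repo)
        (track,) = hub.tracks_by_genome["G_dir"]
        assert track.type_kind == "bigWig"
        assert track.color_rgb == (255, 0, 0)
        assert track.visibility == "pack"
        assert track.big_data_url == "https://q.org/ql/G_dir/a.bw"
        assert report.tracks_out == 1

    def test_folder_title_synthesizes_supertrack(self):
        repo = self._repo([AnnotEntry(file_name="h.bam", title="RNA-Seq/Heart")])
        hub, _ = quickload_to_hub(repo)
        folder, child = hub.tracks_by_genome["G_dir"]
        assert folder.container_kind == "superTrack"
        assert folder.long_label == "RNA-Seq"
        assert child.parent_name == folder.track_name

    def test_shared_folder_created_once(self):
        repo = self._repo([
            AnnotEntry(file_name="a.bam", title="RNA-Seq/Heart"),
            AnnotEntry(file_name="b.bam", title="RNA-Seq/Lung"),
        ])
        hub, _ = quickload_to_hub(repo)
        containers = [t for t in hub.tracks_by_genome["G_dir"] if t.is_container]
        assert len(containers) == 1

    def test_unsupported_extension_dropped_with_reason(self):
        repo = self._repo([AnnotEntry(file_name="genes.gff3", title="Genes")])
        hub, report = quickload_to_hub(repo)
        assert hub.tracks_by_genome["G_dir"] == []
        ((ident, reason),) = report.dropped
        assert "gff3" in reason and ident == "genes.gff3"

    def test_short_label_truncated_to_17_chars(self):
        repo = self._repo([
            AnnotEntry(file_name="a.bw", title="A very long display name indeed")
        ])
        hub, _ = quickload_to_hub(repo)
        (track,) = hub.tracks_by_genome["G_dir"]
        assert track.short_label == "A very long displ"
        assert len(track.short_label) == 17


def test_sanitize_track_name_rules():
    taken: set[str] = set()
    assert sanitize_track_name("Heart coverage!", taken) == "Heart_coverage_"
    assert sanitize_track_name("Heart coverage!", taken) == "Heart_coverage__2"
    assert sanitize_track_name("1st track", taken) == "t_1st_track"
    assert sanitize_track_name("", taken) == "track"


@pytest.mark.parametrize("seed", range(10))
def test_conservation_both_directions(seed):
    _, hub = generate_hub(spec_for(seed))
    hub.base_url = "https://x.org/h"
    repo, report = hub_to_quickload(hub)
    assert report.tracks_out + len(report.dropped) == report.tracks_in

    _, ql = generate_quickload(spec_for(seed))
    ql.base_url = "https://x.org/q"
    _, report2 = quickload_to_hub(ql)
    assert report2.tracks_out + len(report2.dropped) == report2.tracks_in
    assert report2.tracks_in == sum(len(g.annots) for g in ql.genomes.values())


@pytest.mark.parametrize("depth", [0, 1, 2])
def test_round_trip_preserves_canonical_core(depth):
    spec = spec_for(40 + depth, hierarchy_depth=depth).supported_only()
    _, hub = generate_hub(spec)
    hub.base_url = "https://x.org/h"
    repo, _ = hub_to_quickload(hub)
    back, _ = quickload_to_hub(repo)
    assert canonical_core(back) == canonical_core(hub)


def test_translation_is_deterministic(hub_fixture):
    _, hub = hub_fixture
    hub.base_url = "https://x.org/h"
    from quickhub.quickload_model import serialize_annots

    repo1, _ = hub_to_quickload(hub)
    repo2, _ = hub_to_quickload(hub)
    for gdir in repo1.genomes:
        assert serialize_annots(repo1.genomes[gdir].annots) == serialize_annots(
            repo2.genomes[gdir].annots
        )
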