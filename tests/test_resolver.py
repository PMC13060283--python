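"""The on-demand façade: URL codec, lazy resolution, WSGI layer."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from conftest import HUB_BASE, QL_BASE, mount
from quickhub.quickload_model import parse_annots, parse_contents, parse_genome_table
from quickhub.resolver_service import (
    TO_QUICKLOAD,
    TO_TRACKHUB,
    ConversionRequest,
    MemoryTransport,
    NotFoundError,
    RecordingTransport,
    SourceParseError,
    UpstreamError,
    convert_repository,
    create_wsgi_app,
    make_converted_url,
    parse_converted_url,
    resolve,
)
from quickhub.stanza_io import parse_stanzas
from quickhub.translate import DEFAULT_SYNONYMS, hub_to_quickload

SVC = "https://svc.example.org/"


class TestConvertedUrls:
    def test_encode_then_parse_recovers_inputs(self):
        url = make_converted_url(TO_QUICKLOAD, "https://x.org/hub.txt", SVC)
        assert parse_converted_url(url, SVC) == (
            TO_QUICKLOAD, "https://x.org/hub.txt", ""
        )

    def test_encoding_twice_equals_encoding_once(self):
        once = make_converted_url(TO_TRACKHUB, "http://x.org/ql", SVC)
        assert make_converted_url(TO_TRACKHUB, once, SVC) == once

    def test_non_http_scheme_rejected(self):
        with pytest.raises(ValueError):
            make_converted_url(TO_QUICKLOAD, "ftp://x.org/hub.txt", SVC)

    def test_relative_source_rejected(self):
        with pytest.raises(ValueError):
            make_converted_url(TO_QUICKLOAD, "hub.txt", SVC)

    def test_rel_path_recovered(self):
        url = make_converted_url(TO_QUICKLOAD, "https://x.org/hub.txt", SVC)
        direction, source, rel = parse_converted_url(url + "hg38/annots.xml", SVC)
        assert rel == "hg38/annots.xml"

    @given(
        scheme=st.sampled_from(["http", "https"]),
        host=st.from_regex(r"[a-z][a-z0-9-]{0,10}\.[a-z]{2,5}", fullmatch=True),
        path=st.lists(
            st.from_regex(r"[A-Za-z0-9._~ %&=+-]{1,12}", fullmatch=True), max_size=4
        ),
    )
    @settings(max_examples=80, deadline=None)
    def test_codec_inverse_for_randomized_urls(self, scheme, host, path):
        source = f"{scheme}://{host}/" + "/".join(path)
        url = make_converted_url(TO_QUICKLOAD, source, SVC)
        assert parse_converted_url(url, SVC)[1] == source


@pytest.fixture
def hub_transport(hub_fixture):
    files, hub = hub_fixture
    return mount(files, HUB_BASE), hub


@pytest.fixture
def ql_transport(quickload_fixture):
    files, repo = quickload_fixture
    return mount(files, QL_BASE), repo


def _req(direction, source, rel):
    return ConversionRequest(direction=direction, source_url=source, rel_path=rel)


class TestToQuickload:
    def test_contents_has_one_line_per_genome(self, hub_transport):
        transport, hub = hub_transport
        media, body = resolve(
            _req(TO_QUICKLOAD, f"{HUB_BASE}/hub.txt", "contents.txt"), transport
        )
        assert media == "text/plain"
        entries = parse_contents(body.decode())
        assert len(entries) == len(hub.genomes)

    def test_contents_never_fetches_trackdbs_or_data_files(self, hub_transport):
        transport, hub = hub_transport
        recording = RecordingTransport(transport)
        resolve(
            _req(TO_QUICKLOAD, f"{HUB_BASE}/hub.txt", "contents.txt"), recording
        )
        fetched = set(recording.urls)
        assert fetched == {f"{HUB_BASE}/hub.txt", f"{HUB_BASE}/genomes.txt"}
        for genome in hub.genomes:
            for track in hub.tracks_by_genome[genome.genome_id]:
                if track.big_data_url:
                    assert not any(track.big_data_url in url for url in fetched)

    def test_annots_matches_in_memory_translation(self, hub_transport):
        transport, hub = hub_transport
        hub.base_url = HUB_BASE
        expected_repo, _ = hub_to_quickload(hub, DEFAULT_SYNONYMS)
        genome_dir = DEFAULT_SYNONYMS.to_quickload(hub.genomes[0].genome_id)
        _, body = resolve(
            _req(TO_QUICKLOAD, f"{HUB_BASE}/hub.txt", f"{genome_dir}/annots.xml"),
            transport,
        )
        assert parse_annots(body) == expected_repo.genomes[genome_dir].annots

    def test_genome_txt_synthesized_from_two_bit_by_ranged_fetches(
        self, hub_transport
    ):
        transport, hub = hub_transport
        recording = RecordingTransport(transport)
        genome = hub.genomes[0]
        genome_dir = DEFAULT_SYNONYMS.to_quickload(genome.genome_id)
        _, body = resolve(
            _req(TO_QUICKLOAD, f"{HUB_BASE}/hub.txt", f"{genome_dir}/genome.txt"),
            recording,
        )
        rows = parse_genome_table(body.decode())
        assert rows  # names/lengths extracted from the 2bit
        two_bit_url = f"{HUB_BASE}/{genome.two_bit_path}"
        ranges = [r for url, r in recording.requests if url == two_bit_url]
        assert ranges and all(r is not None for r in ranges)  # never a full read

    def test_unknown_genome_not_found(self, hub_transport):
        transport, _ = hub_transport
        with pytest.raises(NotFoundError):
            resolve(
                _req(TO_QUICKLOAD, f"{HUB_BASE}/hub.txt", "nosuch/annots.xml"),
                transport,
            )

    def test_unknown_path_not_found(self, hub_transport):
        transport, _ = hub_transport
        with pytest.raises(NotFoundError):
            resolve(_req(TO_QUICKLOAD, f"{HUB_BASE}/hub.txt", "weird.bin"), transport)

    def test_repeated_requests_are_byte_identical(self, hub_transport):
        transport, hub = hub_transport
        genome_dir = DEFAULT_SYNONYMS.to_quickload(hub.genomes[0].genome_id)
        for rel in ("contents.txt", f"{genome_dir}/annots.xml"):
            request = _req(TO_QUICKLOAD, f"{HUB_BASE}/hub.txt", rel)
            assert resolve(request, transport) == resolve(request, transport)


class TestToTrackhub:
    def test_hub_and_genomes_served_from_contents_only(self, ql_transport):
        transport, repo = ql_transport
        recording = RecordingTransport(transport)
        _, hub_body = resolve(_req(TO_TRACKHUB, QL_BASE, "hub.txt"), recording)
        _, genomes_body = resolve(_req(TO_TRACKHUB, QL_BASE, "genomes.txt"), recording)
        assert set(recording.urls) == {f"{QL_BASE}/contents.txt"}
        (hub_stanza,) = parse_stanzas(hub_body.decode())
        assert hub_stanza.get("hub")
        genome_stanzas = parse_stanzas(genomes_body.decode())
        assert len(genome_stanzas) == len(repo.contents)

    def test_trackdb_round_trips_annots(self, ql_transport):
        transport, repo = ql_transport
        genome_dir = repo.contents[0].genome_dir
        _, body = resolve(
            _req(TO_TRACKHUB, QL_BASE, f"{genome_dir}/trackDb.txt"), transport
        )
        stanzas = parse_stanzas(body.decode())
        supported = [
            a for a in repo.genomes[genome_dir].annots
            if not a.file_name.endswith(".gff3")
        ]
        leaves = [s for s in stanzas if s.get("bigDataUrl")]
        assert len(leaves) == len(supported)

    def test_missing_genome_not_found(self, ql_transport):
        transport, _ = ql_transport
        with pytest.raises(NotFoundError):
            resolve(_req(TO_TRACKHUB, QL_BASE, "nope/trackDb.txt"), transport)


def test_unreachable_source_raises_upstream_error():
    with pytest.raises(UpstreamError):
        resolve(
            _req(TO_QUICKLOAD, "https://gone.example.org/hub.txt", "contents.txt"),
            MemoryTransport(),
        )


def test_unparseable_source_raises_parse_error():
    transport = MemoryTransport({"https://x.org/hub.txt": b"genome only\nno hub\n"})
    with pytest.raises(SourceParseError):
        resolve(_req(TO_QUICKLOAD, "https://x.org/hub.txt", "contents.txt"), transport)


def test_dotdot_in_rel_path_rejected():
    with pytest.raises(ValueError):
        ConversionRequest(TO_QUICKLOAD, "https://x.org/hub.txt", "../etc/passwd")


def test_convert_repository_matches_lazy_resolution(hub_fixture):
    files, hub = hub_fixture
    transport = mount(files, HUB_BASE)
    eager, report = convert_repository(
        f"{HUB_BASE}/hub.txt", TO_QUICKLOAD, transport
    )
    assert report.tracks_out + len(report.dropped) == report.tracks_in
    for rel_path, text in eager.items():
        _, lazy = resolve(
            _req(TO_QUICKLOAD, f"{HUB_BASE}/hub.txt", rel_path), transport
        )
        assert lazy.decode() == text


class TestWsgi:
    def _get(self, app, path):
        captured = {}

        def start_response(status, headers):
            captured["status"] = status
            captured["headers"] = dict(headers)

        environ = {
            "REQUEST_METHOD": "GET",
            "PATH_INFO": path,
            "wsgi.input": io.BytesIO(),
        }
        body = b"".join(app(environ, start_response))
        return captured["status"], captured["headers"], body

    def test_serves_translated_contents(self, hub_fixture):
        files, hub = hub_fixture
        transport = mount(files, HUB_BASE)
        app = create_wsgi_app(transport, service_base=SVC)
        url = make_converted_url(TO_QUICKLOAD, f"{HUB_BASE}/hub.txt", SVC)
        path = url[len(SVC) - 1:]
        status, headers, body = self._get(app, path + "contents.txt")
        assert status == "200 OK"
        assert headers["Content-Type"] == "text/plain"
        assert len(parse_contents(body.decode())) == len(hub.genomes)

    def test_unknown_path_is_404(self, hub_fixture):
        files, _ = hub_fixture
        app = create_wsgi_app(mount(files, HUB_BASE), service_base=SVC)
        status, _, _ = self._get(app, "/not/a/converted/url")
        assert status.startswith("404")

    def test_upstream_failure_is_502(self):
        app = create_wsgi_app(MemoryTransport(), service_base=SVC)
        url = make_converted_url(TO_QUICKLOAD, "https://gone.org/hub.txt", SVC)
        status, _, _ = self._get(app, url[len(SVC) - 1:] + "contents.txt")
        assert status.startswith("502")


def test_trackdb_include_directives_spliced_by_fetch_layer():
    hub_files = {
        "hub.txt": b"hub h\nshortLabel H\nlongLabel Hub\ngenomesFile genomes.txt\n",
        "genomes.txt": b"genome hg38\ntrackDb hg38/trackDb.txt\n",
        "hg38/trackDb.txt": b"include extra.txt\n\ntrack a\ntype bam\nbigDataUrl a.bam\n",
        "hg38/extra.txt": b"track b\ntype bigWig\nbigDataUrl b.bw\n",
    }
    transport = mount(hub_files, HUB_BASE)
    genome_dir = DEFAULT_SYNONYMS.to_quickload("hg38")
    _, body = resolve(
        _req(TO_QUICKLOAD, f"{HUB_BASE}/hub.txt", f"{genome_dir}/annots.xml"),
        transport,
    )
    names = [a.file_name for a in parse_annots(body)]
    assert any(n.endswith("b.bw") for n in names)
    assert any(n.endswith("a.bam") for n in names)


def test_unresolvable_include_skipped_with_remaining_tracks_kept():
    hub_files = {
        "hub.txt": b"hub h\nshortLabel H\nlongLabel Hub\ngenomesFile genomes.txt\n",
        "genomes.txt": b"genome hg38\ntrackDb hg38/trackDb.txt\n",
        "hg38/trackDb.txt": b"include missing.txt\n\ntrack a\ntype bam\nbigDataUrl a.bam\n",
    }
    transport = mount(hub_files, HUB_BASE)
    genome_dir = DEFAULT_SYNONYMS.to_quickload("hg38")
    _, body = resolve(
        _req(TO_QUICKLOAD, f"{HUB_BASE}/hub.txt", f"{genome_dir}/annots.xml"),
        transport,
    )
    assert len(parse_annots(body)) == 1
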