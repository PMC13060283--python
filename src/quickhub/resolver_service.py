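"""The façade service: serve a translated repository without materializing it.

A converted URL embeds the conversion direction and the source URL.  Each
request below it (``contents.txt``, ``hg38/annots.xml``, ``genomes.txt``,
``hg38/trackDb.txt``...) is answered by fetching only the source files that
path needs, building partial models, translating, and serializing — the
translated repository never exists on disk and data files (BAM, bigWig...)
are never fetched.  Responses are deterministic: identical requests yield
identical bytes.

All network access goes through a :class:`Transport`; tests inject an
in-memory one.
"""

from __future__ import annotations

import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol
from urllib.parse import quote, unquote, urlparse

from . import translate
from .quickload_model import (
    QuickloadGenome,
    QuickloadRepo,
    parse_annots,
    parse_contents,
    serialize_annots,
    serialize_contents,
    serialize_genome_table,
)
from .stanza_io import decode_text
from .trackhub_model import (
    GenomeEntry,
    TrackHub,
    build_trackhub,
    resolve_url,
    serialize_trackhub,
)
from .translate import SynonymTable, DEFAULT_SYNONYMS
from .twobit import index_byte_span, read_twobit_index

__all__ = [
    "TO_QUICKLOAD",
    "TO_TRACKHUB",
    "ConversionRequest",
    "Transport",
    "MemoryTransport",
    "LocalFileTransport",
    "HttpTransport",
    "RecordingTransport",
    "NotFoundError",
    "UpstreamError",
    "SourceParseError",
    "make_converted_url",
    "parse_converted_url",
    "resolve",
    "convert_repository",
    "create_wsgi_app",
]

TO_QUICKLOAD = "to_quickload"
TO_TRACKHUB = "to_trackhub"
_DIRECTIONS = (TO_QUICKLOAD, TO_TRACKHUB)


class NotFoundError(LookupError):
    """The requested virtual path does not exist in the translated view."""


class UpstreamError(IOError):
    """A source file could not be fetched or parsed; carries the URL."""

    def __init__(self, message: str, url: str):
        super().__init__(message)
        self.url = url


class SourceParseError(UpstreamError):
    """The source was fetched but its content is structurally invalid."""


@dataclass
class ConversionRequest:
    direction: str
    source_url: str
    rel_path: str

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if ".." in self.rel_path.split("/"):
            raise ValueError(f"rel_path {self.rel_path!r} contains '..'")


class Transport(Protocol):
    """Fetch bytes for an absolute URL, optionally a byte range."""

    def fetch(self, url: str, byte_range: tuple[int, int] | None = None) -> bytes:
        """Return the body (or the half-open byte range [start, stop)).

        Raises :class:`UpstreamError` when the URL is unreachable or absent.
        """
        ...


@dataclass
class MemoryTransport:
    """Serves from a ``{url: bytes}`` map; the test double."""

    files: dict[str, bytes] = field(default_factory=dict)

    def fetch(self, url: str, byte_range: tuple[int, int] | None = None) -> bytes:
        if url not in self.files:
            raise UpstreamError(f"not in memory transport: {url}", url)
        data = self.files[url]
        if byte_range is not None:
            start, stop = byte_range
            return data[start:stop]
        return data


@dataclass
class LocalFileTransport:
    """Serves plain filesystem paths and file:// URLs."""

    root: str = ""

    def fetch(self, url: str, byte_range: tuple[int, int] | None = None) -> bytes:
        parsed = urlparse(url)
        if parsed.scheme == "file":
            path = Path(unquote(parsed.path))
        elif parsed.scheme:
            raise UpstreamError(f"LocalFileTransport cannot fetch {url}", url)
        else:
            path = Path(self.root) / url if self.root else Path(url)
        try:
            data = path.read_bytes()
        except OSError as exc:
            raise UpstreamError(f"cannot read {path}: {exc}", url) from exc
        if byte_range is not None:
            start, stop = byte_range
            return data[start:stop]
        return data


class HttpTransport:
    """Fetches http(s) URLs, using Range headers for partial reads."""

    def __init__(self, timeout: float = 30.0, user_agent: str = "quickhub"):
        self.timeout = timeout
        self.user_agent = user_agent

    def fetch(self, url: str, byte_range: tuple[int, int] | None = None) -> bytes:
        headers = {"User-Agent": self.user_agent}
        if byte_range is not None:
            start, stop = byte_range
            headers["Range"] = f"bytes={start}-{stop - 1}"
        request = urllib.request.Request(url, headers=headers)
        try:
            with urllib.request.urlopen(request, timeout=self.timeout) as response:
                data = response.read()
        except (urllib.error.URLError, OSError) as exc:
            raise UpstreamError(f"cannot fetch {url}: {exc}", url) from exc
        if byte_range is not None and len(data) > (byte_range[1] - byte_range[0]):
            # server ignored the Range header; slice locally
            data = data[byte_range[0]:byte_range[1]]
        return data


class RecordingTransport:
    """Wraps a transport and records every (url, byte_range) fetched."""

    def __init__(self, inner: Transport):
        self.inner = inner
        self.requests: list[tuple[str, tuple[int, int] | None]] = []

    def fetch(self, url: str, byte_range: tuple[int, int] | None = None) -> bytes:
        self.requests.append((url, byte_range))
        return self.inner.fetch(url, byte_range)

    @property
    def urls(self) -> list[str]:
        return [url for url, _ in self.requests]


def make_converted_url(direction: str, source_url: str, service_base: str) -> str:
    """Deterministic, reversible converted URL for (direction, source).

    The source URL is percent-encoded into one path segment under the
    service base.  Applying the function to an already-converted URL
    returns it unchanged.  Only http(s) sources are accepted.
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    try:
        parsed_direction, parsed_source, rel = parse_converted_url(
            source_url, service_base
        )
        if parsed_direction == direction and not rel:
            return source_url  # already converted: idempotent
    except ValueError:
        pass
    scheme = urlparse(source_url).scheme
    if scheme not in ("http", "https"):
        raise ValueError(
            f"source URL must be absolute http(s), got {source_url!r}"
        )
    base = service_base if service_base.endswith("/") else service_base + "/"
    return f"{base}{direction}/{quote(source_url, safe='')}/"


def parse_converted_url(url: str, service_base: str) -> tuple[str, str, str]:
    """Invert :func:`make_converted_url`.

    Returns ``(direction, source_url, rel_path)``; rel_path is whatever
    follows the encoded source segment (empty for the conversion root).
    """
    base = service_base if service_base.endswith("/") else service_base + "/"
    if not url.startswith(base):
        raise ValueError(f"{url!r} is not under service base {service_base!r}")
    tail = url[len(base):]
    parts = tail.split("/", 2)
    if len(parts) < 2 or parts[0] not in _DIRECTIONS or not parts[1]:
        raise ValueError(f"{url!r} is not a converted URL")
    direction = parts[0]
    source_url = unquote(parts[1])
    if urlparse(source_url).scheme not in ("http", "https"):
        raise ValueError(f"decoded source {source_url!r} is not http(s)")
    rel_path = parts[2] if len(parts) > 2 else ""
    return direction, source_url, rel_path


# ---------------------------------------------------------------------------
# lazy source loading


def _fetch_text(transport: Transport, url: str) -> str:
    warnings: list[str] = []
    return decode_text(transport.fetch(url), warnings)


def _load_hub_skeleton(
    source_url: str, transport: Transport
) -> tuple[TrackHub, dict[str, GenomeEntry]]:
    """Fetch hub.txt (and genomes.txt unless one-file); no trackDbs yet."""
    base_url = source_url.rsplit("/", 1)[0]
    hub_text = _fetch_text(transport, source_url)
    try:
        hub = build_trackhub(hub_text, "", {}, base_url=base_url)
    except ValueError as exc:
        raise SourceParseError(f"cannot parse hub.txt: {exc}", source_url) from exc
    if not hub.manifest.use_one_file:
        genomes_url = resolve_url(base_url, hub.manifest.genomes_file or "genomes.txt")
        genomes_text = _fetch_text(transport, genomes_url)
        try:
            hub = build_trackhub(hub_text, genomes_text, {}, base_url=base_url)
        except ValueError as exc:
            raise SourceParseError(f"cannot parse genomes.txt: {exc}", genomes_url) from exc
    return hub, {g.genome_id: g for g in hub.genomes}


def _splice_includes(
    text: str, base_dir: str, transport: Transport, warnings: list[str]
) -> str:
    """Replace resolvable trackDb ``include`` directives with their content."""
    if "include" not in text:
        return text
    out: list[str] = []
    for line in text.splitlines():
        parts = line.split(None, 1)
        if parts and parts[0] == "include" and len(parts) > 1:
            included_url = resolve_url(base_dir, parts[1].strip())
            try:
                out.append(_fetch_text(transport, included_url).rstrip("\n"))
            except UpstreamError:
                warnings.append(f"include {included_url!r} unreachable; skipped")
            continue
        out.append(line)
    return "\n".join(out) + "\n"


def _load_hub_genome_tracks(
    hub: TrackHub, genome: GenomeEntry, transport: Transport
) -> None:
    if hub.manifest.use_one_file:
        return  # tracks already embedded in hub.txt
    from .trackhub_model import parse_trackdb

    trackdb_url = resolve_url(hub.base_url, genome.trackdb_path)
    trackdb_dir = trackdb_url.rsplit("/", 1)[0] if "/" in trackdb_url else ""
    text = _fetch_text(transport, trackdb_url)
    warnings: list[str] = []
    text = _splice_includes(text, trackdb_dir, transport, warnings)
    try:
        hub.tracks_by_genome[genome.genome_id] = parse_trackdb(text, warnings)
    except ValueError as exc:
        raise SourceParseError(f"cannot parse trackDb: {exc}", trackdb_url) from exc
    hub.warnings.extend(warnings)


def _load_quickload_contents(source_url: str, transport: Transport) -> QuickloadRepo:
    root = source_url.rstrip("/")
    contents_url = root + "/contents.txt"
    text = _fetch_text(transport, contents_url)
    try:
        contents = parse_contents(text)
    except ValueError as exc:
        raise SourceParseError(f"cannot parse contents.txt: {exc}", contents_url) from exc
    return QuickloadRepo(contents=contents, base_url=root)


def _load_quickload_genome(
    repo: QuickloadRepo, genome_dir: str, transport: Transport
) -> None:
    annots_url = f"{repo.base_url}/{genome_dir}/annots.xml"
    warnings: list[str] = []
    try:
        annots = parse_annots(transport.fetch(annots_url), warnings)
    except ValueError as exc:
        raise SourceParseError(f"cannot parse annots.xml: {exc}", annots_url) from exc
    repo.genomes[genome_dir] = QuickloadGenome(genome_dir=genome_dir, annots=annots)
    repo.warnings.extend(warnings)


def _remote_twobit_table(url: str, transport: Transport) -> list[tuple[str, int]]:
    """Names and lengths from a 2bit file using ranged fetches only.

    Fetches the 16-byte header (validating signature and version), then
    enough leading bytes to cover the index (growing geometrically), then
    4 bytes per record — never the packed bases.
    """
    import struct

    from .twobit import TWOBIT_SIGNATURE, TwoBitFormatError, TwoBitVersionError

    header = transport.fetch(url, (0, 16))
    if len(header) < 16:
        raise TwoBitFormatError(f"truncated 2bit header at {url}")
    if struct.unpack_from(">I", header)[0] == TWOBIT_SIGNATURE:
        order = ">"
    elif struct.unpack_from("<I", header)[0] == TWOBIT_SIGNATURE:
        order = "<"
    else:
        raise TwoBitFormatError(f"bad 2bit signature at {url}")
    version = struct.unpack_from(order + "I", header, 4)[0]
    if version != 0:
        raise TwoBitVersionError(f"unsupported 2bit version {version} at {url}")

    chunk = 4096
    while True:
        head = transport.fetch(url, (0, 16 + chunk))
        try:
            span = index_byte_span(head)
            break
        except TwoBitFormatError:
            if len(head) < 16 + chunk:
                raise  # whole file fetched and index still truncated
            chunk *= 4
    index = read_twobit_index(head[:span], fetch_record_sizes=False)
    rows: list[tuple[str, int]] = []
    for record in index.records:
        size_bytes = transport.fetch(url, (record.offset, record.offset + 4))
        rows.append((record.name, struct.unpack(order + "I", size_bytes)[0]))
    return rows


# ---------------------------------------------------------------------------
# the façade itself


def resolve(
    request: ConversionRequest,
    transport: Transport,
    synonyms: SynonymTable = DEFAULT_SYNONYMS,
) -> tuple[str, bytes]:
    """Serve one virtual path of a converted repository.

    Returns ``(media_type, body)``.  Raises :class:`NotFoundError` for
    paths outside the translated view and :class:`UpstreamError` when a
    needed source file cannot be fetched or parsed.
    """
    if request.direction == TO_QUICKLOAD:
        return _resolve_to_quickload(request, transport, synonyms)
    return _resolve_to_trackhub(request, transport, synonyms)


def _resolve_to_quickload(
    request: ConversionRequest, transport: Transport, synonyms: SynonymTable
) -> tuple[str, bytes]:
    hub, by_id = _load_hub_skeleton(request.source_url, transport)

    if request.rel_path == "contents.txt":
        repo, _ = translate.hub_to_quickload(_without_tracks(hub), synonyms)
        return "text/plain", serialize_contents(repo.contents).encode()

    parts = request.rel_path.split("/")
    if len(parts) == 2:
        genome_dir, leaf = parts
        genome = next(
            (g for g in hub.genomes if synonyms.to_quickload(g.genome_id) == genome_dir),
            None,
        )
        if genome is None:
            raise NotFoundError(f"no genome {genome_dir!r} in this hub")
        if leaf == "annots.xml":
            _load_hub_genome_tracks(hub, genome, transport)
            single = _single_genome_hub(hub, genome)
            repo, _ = translate.hub_to_quickload(single, synonyms)
            annots = repo.genomes[genome_dir].annots
            return "application/xml", serialize_annots(annots).encode()
        if leaf == "genome.txt":
            if not genome.two_bit_path:
                raise NotFoundError(
                    f"hub declares no twoBitPath for {genome.genome_id}; "
                    f"genome.txt cannot be synthesized"
                )
            two_bit_url = resolve_url(
                _genomes_dir(hub), genome.two_bit_path
            )
            rows = _remote_twobit_table(two_bit_url, transport)
            return "text/plain", serialize_genome_table(rows).encode()
    raise NotFoundError(f"unknown Quickload path {request.rel_path!r}")


def _genomes_dir(hub: TrackHub) -> str:
    # twoBitPath is relative to genomes.txt, which sits next to hub.txt here
    return hub.base_url


def _without_tracks(hub: TrackHub) -> TrackHub:
    return TrackHub(
        manifest=hub.manifest,
        genomes=hub.genomes,
        tracks_by_genome={g.genome_id: [] for g in hub.genomes},
        base_url=hub.base_url,
    )


def _single_genome_hub(hub: TrackHub, genome: GenomeEntry) -> TrackHub:
    return TrackHub(
        manifest=hub.manifest,
        genomes=[genome],
        tracks_by_genome={
            genome.genome_id: hub.tracks_by_genome.get(genome.genome_id, [])
        },
        base_url=hub.base_url,
    )


def _resolve_to_trackhub(
    request: ConversionRequest, transport: Transport, synonyms: SynonymTable
) -> tuple[str, bytes]:
    repo = _load_quickload_contents(request.source_url, transport)

    if request.rel_path in ("hub.txt", "genomes.txt"):
        hub, _ = translate.quickload_to_hub(repo, synonyms)
        files = serialize_trackhub(hub, one_file=False)
        return "text/plain", files[request.rel_path].encode()

    parts = request.rel_path.split("/")
    if len(parts) == 2 and parts[1] == "trackDb.txt":
        genome_id = parts[0]
        entry = next(
            (c for c in repo.contents if synonyms.to_hub(c.genome_dir) == genome_id),
            None,
        )
        if entry is None:
            raise NotFoundError(f"no genome {genome_id!r} in this Quickload")
        _load_quickload_genome(repo, entry.genome_dir, transport)
        hub, _ = translate.quickload_to_hub(repo, synonyms)
        files = serialize_trackhub(hub, one_file=False)
        path = f"{genome_id}/trackDb.txt"
        if path not in files:
            raise NotFoundError(f"no trackDb for genome {genome_id!r}")
        return "text/plain", files[path].encode()
    raise NotFoundError(f"unknown track hub path {request.rel_path!r}")


# ---------------------------------------------------------------------------
# whole-repository conversion (the CLI path)


def convert_repository(
    source_url: str,
    direction: str,
    transport: Transport,
    synonyms: SynonymTable = DEFAULT_SYNONYMS,
) -> tuple[dict[str, str], translate.ConversionReport]:
    """Translate a whole repository eagerly into a ``{path: text}`` map."""
    if direction == TO_QUICKLOAD:
        hub, _ = _load_hub_skeleton(source_url, transport)
        for genome in hub.genomes:
            _load_hub_genome_tracks(hub, genome, transport)
        repo, report = translate.hub_to_quickload(hub, synonyms)
        files: dict[str, str] = {"contents.txt": serialize_contents(repo.contents)}
        for genome_dir, ql_genome in repo.genomes.items():
            files[f"{genome_dir}/annots.xml"] = serialize_annots(ql_genome.annots)
            source_genome = next(
                (
                    g
                    for g in hub.genomes
                    if synonyms.to_quickload(g.genome_id) == genome_dir
                ),
                None,
            )
            if source_genome is not None and source_genome.two_bit_path:
                two_bit_url = resolve_url(hub.base_url, source_genome.two_bit_path)
                try:
                    rows = _remote_twobit_table(two_bit_url, transport)
                except (UpstreamError, ValueError) as exc:
                    report.warnings.append(
                        f"genome.txt for {genome_dir} skipped: {exc}"
                    )
                else:
                    files[f"{genome_dir}/genome.txt"] = serialize_genome_table(rows)
        return files, report

    if direction == TO_TRACKHUB:
        repo = _load_quickload_contents(source_url, transport)
        for entry in repo.contents:
            try:
                _load_quickload_genome(repo, entry.genome_dir, transport)
            except UpstreamError as exc:
                repo.warnings.append(str(exc))
        hub, report = translate.quickload_to_hub(repo, synonyms)
        report.warnings.extend(repo.warnings)
        return serialize_trackhub(hub, one_file=False), report

    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# WSGI layer (stdlib; no framework needed for three GET routes)


def create_wsgi_app(
    transport: Transport | None = None,
    synonyms: SynonymTable = DEFAULT_SYNONYMS,
    service_base: str = "http://localhost:8000/",
):
    """WSGI application serving converted repositories.

    Routes: ``/{to_quickload|to_trackhub}/<encoded source>/<rel path>``.
    """
    transport = transport if transport is not None else HttpTransport()

    def app(environ, start_response):
        path = environ.get("PATH_INFO", "/")
        if environ.get("REQUEST_METHOD", "GET") != "GET":
            start_response("405 Method Not Allowed", [("Content-Type", "text/plain")])
            return [b"GET only\n"]
        try:
            direction, source_url, rel_path = parse_converted_url(
                service_base.rstrip("/") + path, service_base
            )
            request = ConversionRequest(
                direction=direction, source_url=source_url, rel_path=rel_path
            )
        except ValueError as exc:
            start_response("404 Not Found", [("Content-Type", "text/plain")])
            return [f"not a converted URL: {exc}\n".encode()]
        try:
            media_type, body = resolve(request, transport, synonyms)
        except NotFoundError as exc:
            start_response("404 Not Found", [("Content-Type", "text/plain")])
            return [f"{exc}\n".encode()]
        except UpstreamError as exc:
            start_response("502 Bad Gateway", [("Content-Type", "text/plain")])
            return [f"upstream failure for {exc.url}: {exc}\n".encode()]
        start_response(
            "200 OK",
            [("Content-Type", media_type), ("Content-Length", str(len(body)))],
        )
        return [body]

    return app
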