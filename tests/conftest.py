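"""Shared helpers: mount synthetic repositories behind in-memory transports."""

from __future__ import annotations

import pytest
from hypothesis import settings

from quickhub.fixtures import FixtureSpec, generate_hub, generate_quickload

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")
from quickhub.resolver_service import MemoryTransport
from quickhub.trackhub_model import TrackHub, build_trackhub

HUB_BASE = "https://data.example.org/myhub"
QL_BASE = "https://data.example.org/myql"


def mount(files: dict[str, bytes], base: str) -> MemoryTransport:
    """In-memory transport serving *files* below *base*."""
    return MemoryTransport({f"{base}/{path}": blob for path, blob in files.items()})


def rebuild_hub(files: dict[str, bytes], hub: TrackHub, base_url: str = "") -> TrackHub:
    """Run the parser over a generated hub's text files."""
    trackdbs = {
        g.genome_id: files[g.trackdb_path].decode() for g in hub.genomes
    }
    return build_trackhub(
        files["hub.txt"].decode(),
        files.get("genomes.txt", b"").decode(),
        trackdbs,
        base_url=base_url,
    )


def spec_for(seed: int, **overrides) -> FixtureSpec:
    """Varied-but-deterministic fixture parameters keyed by seed."""
    defaults = dict(
        seed=seed,
        n_genomes=1 + seed % 3,
        hierarchy_depth=seed % 3,
        with_colors=0.6,
        with_two_bit=(seed % 5 == 0),
    )
    defaults.update(overrides)
    return FixtureSpec(**defaults)


@pytest.fixture
def hub_fixture():
    spec = FixtureSpec(seed=11, n_genomes=2, hierarchy_depth=1, with_two_bit=True)
    files, hub = generate_hub(spec)
    return files, hub


@pytest.fixture
def quickload_fixture():
    spec = FixtureSpec(seed=11, n_genomes=2, hierarchy_depth=1, with_two_bit=True)
    files, repo = generate_quickload(spec)
    return files, repo
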