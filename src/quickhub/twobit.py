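"""Minimal 2bit reader and writer.

The 2bit format stores genome sequences packed two bits per base behind a
small header and index: signature ``0x1A412743`` (either byte order),
version (must be 0), sequence count, then per sequence a name, a file
offset, and at that offset a record starting with the base count
(``dnaSize``), N-run blocks, mask blocks, and the packed bases.

The translator only needs sequence names and lengths — enough to synthesize
a Quickload ``genome.txt`` from an assembly hub's ``twoBitPath`` — so the
reader parses the header, the index, and the leading ``dnaSize`` of each
record, and never touches packed bases or block lists.  The writer emits
complete, valid files so the reader is testable without downloading real
genomes.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

__all__ = [
    "TWOBIT_SIGNATURE",
    "TwoBitIndex",
    "TwoBitFormatError",
    "TwoBitVersionError",
    "read_twobit_index",
    "write_twobit",
    "genome_table_from_twobit",
    "index_byte_span",
]

TWOBIT_SIGNATURE = 0x1A412743
_HEADER = struct.Struct(">IIII")

# base encoding per the format: T=0, C=1, A=2, G=3; N is packed as T bits
# and recorded in an nBlock
_BASE_BITS = {"T": 0, "C": 1, "A": 2, "G": 3, "N": 0}


class TwoBitFormatError(ValueError):
    """Data does not look like a 2bit file (bad signature, truncation...)."""


class TwoBitVersionError(TwoBitFormatError):
    """The 2bit version field is not 0 (the long/64-bit variant)."""


@dataclass
class TwoBitRecord:
    name: str
    offset: int
    dna_size: int | None = None


@dataclass
class TwoBitIndex:
    sequence_count: int
    records: list[TwoBitRecord] = field(default_factory=list)
    byte_order: str = "big"  # "big" | "little"


def _need(data: bytes, end: int, what: str) -> None:
    if len(data) < end:
        raise TwoBitFormatError(
            f"truncated 2bit data: need byte {end} for {what}, have {len(data)}"
        )


def read_twobit_index(data: bytes, fetch_record_sizes: bool = True) -> TwoBitIndex:
    """Parse the header and index of 2bit *data*.

    With ``fetch_record_sizes`` the 4-byte ``dnaSize`` at each record offset
    is read as well; otherwise only names and offsets are returned and no
    byte past the index is touched.
    """
    _need(data, 16, "header")
    sig_be = struct.unpack_from(">I", data, 0)[0]
    if sig_be == TWOBIT_SIGNATURE:
        order = ">"
        byte_order = "big"
    elif struct.unpack_from("<I", data, 0)[0] == TWOBIT_SIGNATURE:
        order = "<"
        byte_order = "little"
    else:
        raise TwoBitFormatError(
            f"bad 2bit signature 0x{sig_be:08X} (expected 0x{TWOBIT_SIGNATURE:08X})"
        )
    version, seq_count, _reserved = struct.unpack_from(order + "III", data, 4)
    if version != 0:
        raise TwoBitVersionError(f"unsupported 2bit version {version} (only 0)")

    records: list[TwoBitRecord] = []
    pos = 16
    for i in range(seq_count):
        _need(data, pos + 1, f"name size of index entry {i}")
        name_size = data[pos]
        pos += 1
        _need(data, pos + name_size + 4, f"index entry {i}")
        name = data[pos:pos + name_size].decode("ascii", errors="replace")
        pos += name_size
        offset = struct.unpack_from(order + "I", data, pos)[0]
        pos += 4
        records.append(TwoBitRecord(name=name, offset=offset))

    names = [r.name for r in records]
    if len(set(names)) != len(names):
        raise TwoBitFormatError("duplicate sequence names in 2bit index")

    if fetch_record_sizes:
        for record in records:
            _need(data, record.offset + 4, f"dnaSize of {record.name!r}")
            record.dna_size = struct.unpack_from(order + "I", data, record.offset)[0]

    return TwoBitIndex(sequence_count=seq_count, records=records, byte_order=byte_order)


def index_byte_span(data_head: bytes) -> int:
    """Byte length of header + index, computed from a prefix of the file.

    Used by the ranged-fetch path to know how many leading bytes cover the
    whole index.  *data_head* must contain at least the full index; raises
    :class:`TwoBitFormatError` when it does not (fetch more and retry).
    """
    index = read_twobit_index(data_head, fetch_record_sizes=False)
    pos = 16
    for record in index.records:
        pos += 1 + len(record.name.encode("ascii", errors="replace")) + 4
    return pos


def _pack_bases(sequence: str) -> bytes:
    packed = bytearray((len(sequence) + 3) // 4)
    for i, base in enumerate(sequence):
        packed[i // 4] |= _BASE_BITS[base] << (6 - 2 * (i % 4))
    return bytes(packed)


def _n_blocks(sequence: str) -> list[tuple[int, int]]:
    blocks: list[tuple[int, int]] = []
    start = None
    for i, base in enumerate(sequence):
        if base == "N":
            if start is None:
                start = i
        elif start is not None:
            blocks.append((start, i - start))
            start = None
    if start is not None:
        blocks.append((start, len(sequence) - start))
    return blocks


def write_twobit(sequences: dict[str, str]) -> bytes:
    """Write a valid version-0, big-endian 2bit file.

    *sequences* maps unique, non-empty names to DNA strings over
    ``{A,C,G,T,N}`` (case-insensitive).  N runs are recorded as nBlocks;
    mask blocks are empty.  ``read_twobit_index(write_twobit(s))`` recovers
    names, order and lengths exactly.
    """
    names = list(sequences)
    if any(not n for n in names):
        raise ValueError("sequence names must be non-empty")

    normalized: dict[str, str] = {}
    for name, seq in sequences.items():
        up = seq.upper()
        bad = set(up) - set("ACGTN")
        if bad:
            raise ValueError(
                f"sequence {name!r} contains non-DNA characters: {sorted(bad)}"
            )
        normalized[name] = up

    header = _HEADER.pack(TWOBIT_SIGNATURE, 0, len(names), 0)
    index_size = sum(1 + len(n.encode("ascii")) + 4 for n in names)

    # lay out records after header + index
    record_blobs: list[bytes] = []
    offsets: list[int] = []
    pos = 16 + index_size
    for name in names:
        seq = normalized[name]
        nblocks = _n_blocks(seq)
        blob = struct.pack(">I", len(seq))
        blob += struct.pack(">I", len(nblocks))
        blob += b"".join(struct.pack(">I", s) for s, _ in nblocks)
        blob += b"".join(struct.pack(">I", sz) for _, sz in nblocks)
        blob += struct.pack(">I", 0)  # maskBlockCount
        blob += struct.pack(">I", 0)  # reserved
        blob += _pack_bases(seq)
        offsets.append(pos)
        record_blobs.append(blob)
        pos += len(blob)

    index = b""
    for name, offset in zip(names, offsets):
        encoded = name.encode("ascii")
        if len(encoded) > 255:
            raise ValueError(f"sequence name {name!r} longer than 255 bytes")
        index += struct.pack(">B", len(encoded)) + encoded + struct.pack(">I", offset)

    return header + index + b"".join(record_blobs)


def genome_table_from_twobit(index: TwoBitIndex) -> list[tuple[str, int]]:
    """``(name, length)`` rows in index order, for genome.txt synthesis."""
    rows: list[tuple[str, int]] = []
    for record in index.records:
        if record.dna_size is None:
            raise ValueError(
                f"record {record.name!r} has no dna_size; "
                f"read the index with fetch_record_sizes=True"
            )
        rows.append((record.name, record.dna_size))
    return rows
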