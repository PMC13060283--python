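"""Assembly catalog search, GenArk style.

UCSC's Genome Archive (GenArk) publishes tens of thousands of assembly
hubs keyed by GCA_/GCF_ accessions.  This module loads a local TSV snapshot
of such a catalog and answers the searches a genome-browser user types:
species common name, scientific name, assembly version, accession, or
taxon id.  Matching is a plain scan — catalogs of ~50k rows need no index.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass

from .resolver_service import TO_QUICKLOAD, make_converted_url
from .translate import SynonymTable, DEFAULT_SYNONYMS

__all__ = [
    "AssemblyRecord",
    "CatalogFormatError",
    "REQUIRED_COLUMNS",
    "load_catalog",
    "search",
    "open_assembly",
]

REQUIRED_COLUMNS = (
    "accession",
    "assembly_name",
    "scientific_name",
    "common_name",
    "taxon_id",
    "hub_url",
)


class CatalogFormatError(ValueError):
    """The catalog TSV is missing a required column."""


@dataclass
class AssemblyRecord:
    accession: str
    assembly_name: str
    scientific_name: str
    common_name: str
    taxon_id: int
    hub_url: str


def load_catalog(
    text: str, dialect: str = "tsv", warnings: list[str] | None = None
) -> list[AssemblyRecord]:
    """Parse a catalog TSV (header row names the columns, any order)."""
    if dialect != "tsv":
        raise ValueError(f"unsupported catalog dialect {dialect!r}")
    lines = [
        line
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not lines:
        return []
    reader = csv.DictReader(io.StringIO("\n".join(lines)), delimiter="\t")
    header = reader.fieldnames or []
    for column in REQUIRED_COLUMNS:
        if column not in header:
            raise CatalogFormatError(f"catalog is missing required column {column!r}")
    records: list[AssemblyRecord] = []
    seen: set[str] = set()
    for row_number, row in enumerate(reader, start=2):
        try:
            taxon_id = int((row["taxon_id"] or "").strip())
        except ValueError:
            if warnings is not None:
                warnings.append(
                    f"catalog row {row_number}: non-integer taxon_id "
                    f"{row['taxon_id']!r}; row skipped"
                )
            continue
        accession = (row["accession"] or "").strip()
        if not accession:
            if warnings is not None:
                warnings.append(f"catalog row {row_number}: empty accession; skipped")
            continue
        if accession in seen:
            if warnings is not None:
                warnings.append(
                    f"catalog row {row_number}: duplicate accession {accession}; skipped"
                )
            continue
        seen.add(accession)
        records.append(
            AssemblyRecord(
                accession=accession,
                assembly_name=(row["assembly_name"] or "").strip(),
                scientific_name=(row["scientific_name"] or "").strip(),
                common_name=(row["common_name"] or "").strip(),
                taxon_id=taxon_id,
                hub_url=(row["hub_url"] or "").strip(),
            )
        )
    return records


def _token_matches(record: AssemblyRecord, token: str) -> bool:
    lowered = token.lower()
    if lowered in record.common_name.lower():
        return True
    if lowered in record.scientific_name.lower():
        return True
    if lowered in record.assembly_name.lower():
        return True
    if lowered in record.accession.lower():
        return True
    return token == str(record.taxon_id)


def search(records: list[AssemblyRecord], query: str) -> list[AssemblyRecord]:
    """Case-insensitive substring search across name fields and accession,
    plus exact-string match on the decimal taxon id.

    Multi-token queries AND their tokens: every token must match some
    field.  An empty query returns all records.  Result order is catalog
    order.
    """
    tokens = query.split()
    if not tokens:
        return list(records)
    return [
        record
        for record in records
        if all(_token_matches(record, token) for token in tokens)
    ]


def open_assembly(
    record: AssemblyRecord,
    synonyms: SynonymTable = DEFAULT_SYNONYMS,
    service_base: str = "http://localhost:8000/",
) -> str:
    """Converted Quickload URL for one assembly's hub (the "load" action)."""
    del synonyms  # genome naming happens inside the conversion, not here
    return make_converted_url(TO_QUICKLOAD, record.hub_url, service_base)
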