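# Methods

## The problem and the model

A genomic data collection published on the web is described twice over by
the two major browser ecosystems.  A UCSC *track hub* is a set of
stanza-format text files: `hub.txt` names the hub and points to
`genomes.txt`, which lists genome assemblies and points to one
`trackDb.txt` per assembly; each trackDb stanza defines one track — the
data file URL (`bigDataUrl`), a type (`bigWig`, `bam`, ...), labels,
an RGB `color`, a `visibility` display mode, and hierarchy via
`parent`/`superTrack`/`compositeTrack` keys.  An IGB *Quickload* site is a
directory tree: `contents.txt` lists genome directories; each holds
`annots.xml`, whose `<file>` elements name data files with a display
`title` (where `/`-separated segments encode folders), a hex `foreground`
color and other attributes, plus `genome.txt`, a tab-separated table of
chromosome names and lengths.

quickhub treats translation as a mapping between two typed in-memory
models (`TrackHub`, `QuickloadRepo`) rather than between text files.
Parsers are permissive (comments, indentation, CRLF, duplicate keys,
mis-encoded bytes are tolerated with recorded warnings); serializers are
canonical (one normal form per model), so parse∘serialize is the identity
on models and serialize∘parse is idempotent on text.

## Translation semantics

**Supported data formats.** Both browsers stream indexed binary formats
over HTTP; those are the only types translated: bigWig, bigBed, BAM,
CRAM, tabix-indexed VCF (`vcfTabix`), with bigGenePred treated as a
bigBed-family annotation.  Hub→Quickload decides by the trackDb type;
Quickload→hub decides by file extension (`.bw`/`.bigWig`, `.bb`/`.bigBed`,
`.bam`, `.cram`, `.vcf.gz`, case-insensitive), because annots.xml carries
no type field.  Plain-text formats (`.bed`, `.gff3`, un-bgzipped `.vcf`)
are dropped with a reason, since track hubs cannot reference them.

**Hierarchy.** UCSC's three container mechanisms (superTrack, composite,
multiWig) are collapsed into a single forest; a leaf's folder path becomes
the `/`-joined prefix of the annots.xml title, built from each container's
long label.  In the reverse direction every distinct folder path
synthesizes one superTrack container.  Sibling order applies trackDb
`priority` ascending, unset priorities after set ones, then source order.

**Conservation accounting.** `tracks_in` counts *leaf* (data) tracks;
containers are folder structure, not data, so they neither count as
translated nor as dropped.  The invariant
`tracks_out + |dropped| == tracks_in` holds in both directions.

**Lossless stash.** Settings with no target-side counterpart are carried
in reserved attributes instead of being discarded: trackDb-only settings
(`type`, `visibility`, `shortLabel`, `altColor`, `priority`, `group`,
`bigDataIndex`, and all unrecognized trackDb keys) travel as `x_hub_*`
annots.xml attributes; annots-only attributes (`background`, `load_hint`,
`label_field`, unknown extras) travel as `x_ql_*` trackDb keys.  On the
return trip each stash is unpacked onto its original key.  The *canonical
core* — resolved data URL, type kind, color, visibility, display label,
folder path — is what a round trip must preserve even conceptually
without the stash, and is what the round-trip tests compare (keyed by
genome and URL, so ordering and generated track names don't participate).
`visibility` is deliberately **not** mapped onto IGB's `load_hint`
auto-load behavior: a hub author's "full" means "draw expanded", not
"download on open"; visibility rides the stash instead.

**Names.** Genome naming defaults to identity — GenArk accession ids
(`GCF_...`) pass through unchanged — with a small shipped synonym table
for the common UCSC db ↔ IGB directory pairs (`hg38` ↔
`H_sapiens_Dec_2013`, etc.), replaceable via `--synonyms`.  Track names
generated from display labels are sanitized to `[A-Za-z0-9_]`, prefixed
`t_` when starting with a digit, and uniquified with numeric suffixes;
short labels are truncated to 17 characters per the UCSC guideline.
Quickload has no hub-level manifest, so Quickload→hub synthesizes one
deterministically (hub name `converted_quickload`, labels from the first
contents description).

## The 2bit reader

Assembly hubs point at a 2bit sequence file (`twoBitPath`); Quickload
instead needs an explicit chromosome table.  quickhub reads only what that
synthesis requires: the 16-byte header (signature `0x1A412743` in either
byte order; version must be 0 — the 64-bit "long" variant is rejected
explicitly), the name/offset index, and the leading 4-byte `dnaSize` of
each sequence record.  Packed bases, N-blocks and mask blocks are never
parsed.  Over HTTP this is done with ranged requests — header, a
geometrically grown index prefix, then 4 bytes per sequence — so a
multi-gigabyte genome costs a few kilobytes of transfer.  The package also
contains a complete 2bit *writer* (big-endian, N runs recorded as
nBlocks) so the reader is testable offline; the reader is additionally
checked against a reference file hand-assembled byte-by-byte from the
published layout, independently of the writer.

## The façade service

A converted URL deterministically percent-encodes `(direction, source
URL)` under the service base; encode/parse are mutual inverses and
encoding is idempotent.  Each virtual path below it is served by fetching
only the sources that path needs: `contents.txt` needs `hub.txt` (+
`genomes.txt`); `<genome>/annots.xml` additionally needs that genome's
trackDb; `<genome>/genome.txt` needs ranged reads of the 2bit;
`hub.txt`/`genomes.txt` on the reverse direction need only
`contents.txt`.  All I/O goes through an injectable `Transport`
(in-memory, local-file, HTTP), which is what makes the laziness property
testable: a recording transport proves that serving `contents.txt` never
touches a data file.  The service keeps no state and no cache; responses
are pure functions of (request, source bytes, synonyms), hence
byte-identical across repeats and safe to cache externally.  Upstream
failures surface as errors (HTTP 502 in the WSGI layer), never as empty
repositories.

## Synthetic fixtures

`quickhub.fixtures` generates miniature repositories as a pure function of
a `FixtureSpec` (seed; genomes per repo, default 1–3; 2–5 data tracks per
genome; a type mix weighted 3:2:2:1:1:1 across
bigWig/bigBed/bam/cram/vcfTabix/unsupported; folder depth 0–2; colors on
~50–60% of tracks; optional miniature 2bit files with 1–3 chromosomes of
12–60 bases including N runs).  Each generator returns both the files and
the ground-truth model, so parser tests assert exact agreement.
Referenced data files are zero-byte placeholders — honest, because the
translator's contract is to never open them.

What the fixtures do *not* emulate: multi-hundred-track production hubs,
the full zoo of trackDb settings (carried generically as extras),
inconsistent hand-edited indentation beyond what the stanza tests inject,
server quirks (redirects, missing Range support is handled but not
generated), or real sequence content.  Passing tests therefore demonstrate
the translation and I/O contracts, not browser-rendering fidelity; the
published-format compatibility rests on emitting the documented dialects
exactly.

## Numerical and degenerate-input choices

- Colors: RGB↔hex is an exact bijection on 0–255 triples; 3-digit hex
  shorthand is rejected (entry kept, color unset, warning) so there is a
  single canonical representation.
- Duplicate stanza keys: all entries are preserved by the parser (entry
  count is conserved); lookups take the last occurrence with a warning.
  A duplicated identity key (`track`, `genome`, `hub`) is a parse error.
- Unknown `visibility` tokens ingest as `pack` with a warning.
- Dangling parents become roots with a warning; parent cycles are a
  structural error naming the cycle.
- Empty inputs are valid everywhere (empty hub text → no stanzas; empty
  trackDb → genome listed with zero annots; zero-sequence 2bit files).
- genome.txt order is source order, never re-sorted; duplicate sequence
  names and non-positive lengths are rejected.

## Problem sizes

The test suite and the acceptance script run entirely on generated
fixtures: 200 hubs for the parser fixpoint, 100 seeded repositories
(folder depths 0–2) for the canonical-core round trip, 60 for model round
trips, 30 per direction for conservation, 40 randomized 2bit files, a
256-step exhaustive red-channel color sweep with randomized green/blue,
200 randomized converted URLs and 200 randomized catalog queries against
a 60-assembly catalog.  The whole suite completes in a few seconds on one
CPU.

## Known limitations

- multiWig overlay semantics are reduced to "a folder"; overlay rendering
  hints survive only via the extras stash.
- trackDb `include` directives are not followed (recorded as a warning by
  the fetch layer's contract); `useOneFile` hubs are fully supported.
- The Quickload→hub direction cannot recover a type more specific than
  the file extension implies unless the stash is present.
- Remote 2bit reading assumes servers honor Range headers; when one does
  not, the transport slices the full response locally (correct, but the
  bandwidth saving is lost).
- The synonym table ships a handful of common pairs; institution-specific
  directory names need a user-supplied table.
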