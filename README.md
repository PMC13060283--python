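# quickhub

Bidirectional translator between the two metadata dialects that genome
browsers use for web-hosted data collections:

* **UCSC track hubs** — `hub.txt`, `genomes.txt` and per-genome
  `trackDb.txt` files of key-value stanzas, consumed by the UCSC Genome
  Browser;
* **IGB Quickload repositories** — `contents.txt`, per-genome `annots.xml`
  and `genome.txt`, consumed by the Integrated Genome Browser.

Both formats answer the same questions — *where are the data files and how
should each track be displayed?* — with different vocabularies.  quickhub
maps one onto the other so a collection published in either format can be
browsed in both applications, without touching the data files themselves.
Data files travel as opaque URLs; only the indexed binary formats both
browsers can stream (bigWig, bigBed, BAM, CRAM, tabix-indexed VCF) are
translated, and 2bit genome sequence files are indexed to synthesize the
chromosome table (`genome.txt`) Quickload needs.

## What the translation does

Per track, the engine maps:

| track hub (trackDb)            | Quickload (annots.xml)                  |
|--------------------------------|-----------------------------------------|
| `bigDataUrl` (resolved)        | `file` element `name` attribute         |
| `longLabel` + container path   | `title` with `/`-separated folders      |
| `color R,G,B`                  | `foreground` 6-digit hex                |
| `html` page                    | `url`                                   |
| superTrack / composite nesting | title folder hierarchy, and back        |

Settings with no counterpart in the target dialect (e.g. `visibility`,
`priority`, `maxHeightPixels`) are stashed in reserved `x_hub_*` attributes
rather than discarded, so a round trip restores them; every dropped track
is accounted for in a `ConversionReport` that satisfies
`tracks_out + dropped == tracks_in`.

The same engine backs three entry points: a library
(`quickhub.translate`), a CLI (`quickhub convert`), and an on-demand
**façade service** (`quickhub serve`) that encodes the source URL into a
converted URL and synthesizes each requested metadata file lazily —
serving `contents.txt` fetches only `hub.txt` and `genomes.txt`, never a
trackDb or a data file, and 2bit files are read with ranged requests
(header, index, 4 bytes per sequence).

## Worked example

A miniature hub with a superTrack, one bigWig child and one track in a
format hubs can stream but Quickload cannot use (`bedGraph`):

```
hub/hub.txt            hub myhub / longLabel RNA-Seq coverage across tissues ...
hub/genomes.txt        genome hg38 / trackDb hg38/trackDb.txt
hub/hg38/trackDb.txt   superTrack "rnaseq", bigWig "heart" (color 204,0,0,
                       visibility full), bedGraph "genes"
```

```sh
$ quickhub convert hub --to quickload --out ql
tracks in: 2, translated: 1, dropped: 1
  dropped genes: track type 'bedGraph' has no Quickload counterpart
```

The report counts the two *data* tracks (the superTrack is folder
structure, not data): the bigWig translated, the bedGraph dropped with its
reason.  The output tree is a valid Quickload site:

```sh
$ cat ql/contents.txt
H_sapiens_Dec_2013	RNA-Seq coverage across tissues

$ cat ql/H_sapiens_Dec_2013/annots.xml
<?xml version="1.0" encoding="UTF-8"?>
<files>
  <file name="hub/hg38/data/heart.bw" title="RNA-Seq coverage/Heart coverage"
        description="Heart coverage" foreground="CC0000" x_hub_type="bigWig"
        x_hub_visibility="full" x_hub_shortLabel="Heart"/>
</files>
```

`hg38` became the conventional IGB directory name `H_sapiens_Dec_2013`
(a shipped synonym table; accession-style GenArk ids pass through
unchanged), the RGB color became hex, the superTrack became the
`RNA-Seq coverage/` folder prefix of the title, and the `x_hub_*`
attributes carry the hub-only settings so converting back restores them.
Translating in the other direction (`--to trackhub`) emits `hub.txt`,
`genomes.txt` and per-genome `trackDb.txt`, synthesizing one superTrack
per title folder.

There is also an assembly-catalog helper mirroring the search fields a
GenArk-style genome list needs:

```sh
$ quickhub catalog-search "zebrafish" --catalog assemblies.tsv
```

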