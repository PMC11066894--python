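# covdepth

Fast, bounded-memory coverage and depth statistics from BAM/CRAM
alignments. For each chromosome, gene (GFF/GTF), BED region or fixed-size
window, `covdepth` reports **Covered site**, **Total depth**,
**Coverage (%)**, **Mean depth** and (optionally) **GC (%)**.

Key design points:

- **Blocked depth arrays** — per-base depth is accumulated in lazily
  materialized 1 MiB integer blocks, so memory is bounded by the covered
  footprint, not chromosome length.
- **Chromosome-parallel workers** — with an index, chromosomes are
  load-balanced across workers (greedy longest-first by length); surplus
  threads become htslib decoder threads for the longest chromosomes.
  Output is byte-identical for every thread count.
- **Minimal CRAM decoding** — only FLAG, RNAME, POS, MAPQ and CIGAR are
  decoded (htslib `required_fields`), so plain coverage runs on CRAM do not
  need the reference FASTA at all.
- **Unsorted input accepted** — files without an index are streamed
  whole-file in a single pass (parallelism is disabled for them).

## CLI

```sh
covdepth -i aln.bam                      # per-chromosome report to stdout
covdepth -i aln.bam -w 100000 -o w.tsv   # fixed 100 kb windows
covdepth -i aln.bam -b targets.bed       # per BED line (kept verbatim)
covdepth -i aln.bam -g genes.gff3        # per gene, merged CDS-else-exon
covdepth -i aln.cram -t 8                # CRAM, 8 workers, no reference needed
covdepth -i aln.bam -r ref.fa -c         # add GC(%) column
covdepth -i aln.bam -q 20 -f 0x704       # MAPQ >= 20, explicit flag mask
```

Flags: `-i` input BAM/CRAM (required); `-o` output TSV (default stdout,
`.gz` for gzip); `-g`/`-b`/`-w` mutually exclusive region modes; `-r`
reference FASTA; `-c` GC column (requires `-r`); `-q` minimum MAPQ
(default 0); `-f` exclusion FLAG mask, decimal or 0x-hex; `-t` worker
threads (default 1).

**Note:** `-f` *replaces* the default mask `0x704`
(unmapped | secondary | QC-fail | duplicate) rather than adding to it.
Supplementary alignments (0x800) are **not** excluded by default.

Report coordinates are 1-based inclusive; internally everything is 0-based
half-open. Percentages and mean depth are printed with two decimals
(half-up); `Covered_site`/`Total_depth` are exact integers. Chromosome
mode appends a whole-genome `Total` row.

### CIGAR semantics

`M`, `=`, `X` add depth at each spanned reference base; `D`, `N` advance
the reference cursor without adding depth (a deletion-spanned base is not
covered); `I`, `S`, `H`, `P` touch neither.

## Python API

```python
from covdepth import (open_alignment, stream_records, FilterConfig,
                      passes_filters, DepthBlocks, accumulate_read,
                      region_stats, TargetRegion)

src = open_alignment("aln.bam")
d = DepthBlocks("chr1", src.chrom_length("chr1"))
cfg = FilterConfig(min_mapq=20)
for rec in stream_records(src, region="chr1"):
    if passes_filters(rec, cfg):
        accumulate_read(d, rec)
print(region_stats(d, TargetRegion("chr1", 0, 1_000_000)))
```

`covdepth.simulate` generates seeded synthetic references, sorted+indexed
BAM/CRAM fixtures and a plain-text truth table, plus `oracle_depth`, a
naive per-base pileup used as the independent oracle throughout the tests.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance suite:
engine-vs-oracle equivalence over 50 randomized datasets and every region
mode, thread- and format-invariance of report bytes, window/chromosome
conservation, default-filter semantics, GFF3/GTF merge semantics against a
set-union oracle, scheduler partition invariants, and GC properties.

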