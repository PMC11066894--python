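"""Build the labeled regions to summarize.

Sources: whole chromosomes, fixed-size windows, BED lines, or per-gene
merged CDS/exon sets from GFF3/GTF.  All coordinates are 0-based half-open
internally; conversion from the 1-based closed GFF/GTF convention happens
here and nowhere else.
"""

from __future__ import annotations

import gzip
import io
import logging
import os
import re
from dataclasses import dataclass

from covdepth.alignment_reader import ChromInfo
from covdepth.errors import FormatError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetRegion:
    """A labeled half-open genomic interval."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene with its merged CDS-or-exon parts, disjoint and sorted."""

    gene_id: str
    chrom: str
    parts: tuple[TargetRegion, ...]

    @property
    def span(self) -> tuple[int, int]:
        return self.parts[0].start, self.parts[-1].end

    @property
    def total_length(self) -> int:
        return sum(len(p) for p in self.parts)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge half-open intervals into a disjoint, sorted, non-touching list.

    Touching intervals ([0,5) and [5,10)) merge: per-gene statistics must
    count each reference base exactly once.
    """
    for iv in intervals:
        if iv[0] >= iv[1]:
            raise ValidationError(f"invalid interval {iv}: start >= end")
    if not intervals:
        return []
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def _open_text(path: str | os.PathLike) -> io.TextIOBase:
    path = os.fspath(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


def parse_bed(path: str | os.PathLike, chroms: list[ChromInfo]) -> list[TargetRegion]:
    """Parse a BED file into target regions, coordinates taken verbatim.

    Label is column 4 when present, else ``chrom:start-end`` in 1-based
    inclusive display.  Lines starting with ``#``, ``track`` or ``browser``
    are skipped.  Lines are NOT merged: the user asked for those exact
    regions, overlaps included.
    """
    lengths = {c.name: c.length for c in chroms}
    regions: list[TargetRegion] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path} line {lineno}: expected >= 3 tab-separated columns")
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: non-integer coordinates") from exc
            if chrom not in lengths:
                raise ValidationError(f"{path} line {lineno}: unknown chromosome {chrom!r}")
            if start >= end or start < 0:
                raise ValidationError(f"{path} line {lineno}: invalid interval {start}-{end}")
            if end > lengths[chrom]:
                raise ValidationError(
                    f"{path} line {lineno}: end {end} exceeds {chrom} length {lengths[chrom]}"
                )
            label = cols[3] if len(cols) >= 4 and cols[3] else f"{chrom}:{start + 1}-{end}"
            regions.append(TargetRegion(chrom, start, end, label))
    return regions


def make_windows(chroms: list[ChromInfo], window_size: int) -> list[TargetRegion]:
    """Tile each chromosome with fixed windows; the last one is truncated."""
    if window_size < 1:
        raise ValidationError(f"window size must be >= 1, got {window_size}")
    out: list[TargetRegion] = []
    for c in chroms:
        for start in range(0, c.length, window_size):
            end = min(start + window_size, c.length)
            out.append(TargetRegion(c.name, start, end, f"{c.name}:{start + 1}-{end}"))
    return out


# --- GFF3 / GTF gene models -------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gff3_attrs(text: str) -> dict[str, str]:
    out = {}
    for chunk in text.strip().rstrip(";").split(";"):
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _parse_gtf_attrs(text: str) -> dict[str, str]:
    return dict(_GTF_ATTR.findall(text))


def _detect_dialect(lines: list[tuple[int, list[str]]]) -> str:
    """GFF3 uses key=value attributes (ID=/Parent=); GTF uses key "value";."""
    for _, cols in lines:
        attrs = cols[8]
        if "ID=" in attrs or "Parent=" in attrs or ("=" in attrs and '"' not in attrs):
            return "gff3"
        if _GTF_ATTR.search(attrs):
            return "gtf"
    raise FormatError("cannot detect annotation dialect (neither GFF3 nor GTF attributes found)")


def parse_annotation(
    path: str | os.PathLike,
    chroms: list[ChromInfo],
    feature_preference: tuple[str, ...] = ("CDS", "exon"),
) -> list[GeneModel]:
    """Parse GFF3/GTF into per-gene merged interval sets.

    For each gene the first preferred feature type with any features wins
    (CDS if the gene has CDS, else exon), pooled across all transcripts and
    merged.  Gene identity comes from the GFF3 ``gene``-type ancestor
    (following ``Parent`` chains) or the GTF ``gene_id`` attribute.
    """
    lengths = {c.name: c.length for c in chroms}
    data: list[tuple[int, list[str]]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError(f"{path} line {lineno}: expected 9 tab-separated columns")
            data.append((lineno, cols))
    if not data:
        raise FormatError(f"{path}: no feature lines found")
    dialect = _detect_dialect(data)

    wanted = set(feature_preference)
    skipped = 0
    # gene_id -> {feature_type -> [(start,end)]}, plus chrom per gene
    per_gene: dict[str, dict[str, list[tuple[int, int]]]] = {}
    gene_chrom: dict[str, str] = {}
    gene_order: dict[str, int] = {}

    if dialect == "gff3":
        id_type: dict[str, str] = {}
        id_parent: dict[str, str] = {}
        for lineno, cols in data:
            attrs = _parse_gff3_attrs(cols[8])
            fid = attrs.get("ID")
            if fid:
                id_type[fid] = cols[2]
                parent = attrs.get("Parent")
                if parent:
                    id_parent[fid] = parent.split(",")[0]

        def gene_ancestor(attrs: dict[str, str]) -> str | None:
            node = attrs.get("Parent", attrs.get("ID"))
            if node:
                node = node.split(",")[0]
            seen = set()
            while node and node not in seen:
                seen.add(node)
                if id_type.get(node) == "gene":
                    return node
                node = id_parent.get(node)
            return None

        rows = ((lineno, cols, gene_ancestor(_parse_gff3_attrs(cols[8]))) for lineno, cols in data)
    else:
        rows = (
            (lineno, cols, _parse_gtf_attrs(cols[8]).get("gene_id"))
            for lineno, cols in data
        )

    for lineno, cols, gid in rows:
        ftype = cols[2]
        if ftype not in wanted:
            continue
        if gid is None:
            logger.warning("%s line %d: %s feature with no resolvable gene; skipped", path, lineno, ftype)
            skipped += 1
            continue
        chrom = cols[0]
        if chrom not in lengths:
            raise ValidationError(f"{path} line {lineno}: unknown chromosome {chrom!r}")
        try:
            start1, end1 = int(cols[3]), int(cols[4])
        except ValueError as exc:
            raise FormatError(f"{path} line {lineno}: non-integer coordinates") from exc
        if start1 < 1 or end1 < start1:
            raise ValidationError(f"{path} line {lineno}: invalid 1-based interval {start1}-{end1}")
        if end1 > lengths[chrom]:
            raise ValidationError(f"{path} line {lineno}: end {end1} exceeds {chrom} length {lengths[chrom]}")
        per_gene.setdefault(gid, {}).setdefault(ftype, []).append((start1 - 1, end1))
        gene_chrom.setdefault(gid, chrom)
        gene_order.setdefault(gid, lineno)
        if gene_chrom[gid] != chrom:
            raise ValidationError(f"{path} line {lineno}: gene {gid!r} spans multiple chromosomes")

    if skipped:
        logger.warning("%s: skipped %d feature(s) with no resolvable gene", path, skipped)
    if not per_gene:
        raise FormatError(f"{path}: no genes recovered (feature types searched: {feature_preference})")

    genes: list[GeneModel] = []
    for gid, by_type in per_gene.items():
        for ftype in feature_preference:
            if ftype in by_type:
                ivals = merge_intervals(by_type[ftype])
                chrom = gene_chrom[gid]
                parts = tuple(TargetRegion(chrom, s, e, gid) for s, e in ivals)
                genes.append(GeneModel(gid, chrom, parts))
                break
    chrom_rank = {c.name: i for i, c in enumerate(chroms)}
    genes.sort(key=lambda g: (chrom_rank[g.chrom], g.span[0], g.gene_id))
    return genes
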