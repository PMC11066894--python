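"""Blocked per-base depth accumulation and region reduction.

Depth for one chromosome lives in fixed-capacity integer blocks (1 MiB of
bases by default) materialized lazily, so memory is bounded by the covered
footprint rather than chromosome length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from covdepth.alignment_reader import ReadAlignment
from covdepth.errors import ValidationError
from covdepth.target_intervals import GeneModel, TargetRegion

logger = logging.getLogger(__name__)

DEFAULT_BLOCK_SIZE = 1 << 20

# CIGAR ops that consume reference AND align a read base (add depth),
# vs ops that only advance the reference cursor.
_DEPTH_OPS = frozenset("M=X")
_SKIP_OPS = frozenset("DN")


@dataclass
class DepthBlocks:
    """Sparse blocked depth array for one chromosome."""

    chrom: str
    chrom_length: int
    block_size: int = DEFAULT_BLOCK_SIZE
    blocks: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.block_size < 1:
            raise ValidationError(f"block_size must be >= 1, got {self.block_size}")
        if self.chrom_length < 1:
            raise ValidationError(f"chrom_length must be >= 1, got {self.chrom_length}")

    def _block(self, idx: int) -> np.ndarray:
        blk = self.blocks.get(idx)
        if blk is None:
            size = min(self.block_size, self.chrom_length - idx * self.block_size)
            blk = self.blocks[idx] = np.zeros(size, dtype=np.int64)
        return blk

    def _add_span(self, start: int, end: int) -> None:
        """Increment depth over [start, end), clipped to the chromosome."""
        end = min(end, self.chrom_length)
        if start >= end:
            return
        bs = self.block_size
        idx = start // bs
        while idx * bs < end:
            lo = max(start, idx * bs) - idx * bs
            hi = min(end, (idx + 1) * bs) - idx * bs
            self._block(idx)[lo:hi] += 1
            idx += 1

    def to_array(self) -> np.ndarray:
        """Dense per-base depth (test/debug helper; O(chrom_length))."""
        out = np.zeros(self.chrom_length, dtype=np.int64)
        for idx, blk in self.blocks.items():
            out[idx * self.block_size : idx * self.block_size + len(blk)] = blk
        return out


def accumulate_read(d: DepthBlocks, rec: ReadAlignment) -> DepthBlocks:
    """Walk the CIGAR from ``rec.pos``, incrementing depth under M/=/X ops.

    D and N advance the reference cursor without adding depth; I, S, H and P
    touch neither.  Spans past the chromosome end are discarded with a
    warning.
    """
    cursor = rec.pos
    overflow = False
    for op, length in rec.cigar:
        if op in _DEPTH_OPS:
            if cursor + length > d.chrom_length:
                overflow = True
            d._add_span(cursor, cursor + length)
            cursor += length
        elif op in _SKIP_OPS:
            cursor += length
    if overflow:
        logger.warning(
            "read at %s:%d extends past chromosome end (%d); excess bases ignored",
            rec.ref_name, rec.pos, d.chrom_length,
        )
    return d


@dataclass(frozen=True)
class RegionStats:
    """Output metric bundle for one region or gene."""

    length: int
    covered_site: int
    total_depth: int
    gc_pct: float | None = None

    @property
    def coverage_pct(self) -> float:
        return 100.0 * self.covered_site / self.length

    @property
    def mean_depth(self) -> float:
        return self.total_depth / self.length


def _span_stats(d: DepthBlocks, start: int, end: int) -> tuple[int, int]:
    covered = 0
    total = 0
    bs = d.block_size
    for idx in range(start // bs, (end - 1) // bs + 1):
        blk = d.blocks.get(idx)
        if blk is None:
            continue
        lo = max(start, idx * bs) - idx * bs
        hi = min(end, (idx + 1) * bs) - idx * bs
        window = blk[lo:hi]
        covered += int(np.count_nonzero(window))
        total += int(window.sum())
    return covered, total


def region_stats(d: DepthBlocks, region: TargetRegion) -> RegionStats:
    """Reduce one region to covered sites, total depth and the derived rates."""
    if region.chrom != d.chrom:
        raise ValidationError(f"region chromosome {region.chrom!r} != depth chromosome {d.chrom!r}")
    if region.end > d.chrom_length:
        raise ValidationError(
            f"region {region.chrom}:{region.start}-{region.end} exceeds chromosome length {d.chrom_length}"
        )
    covered, total = _span_stats(d, region.start, region.end)
    return RegionStats(length=len(region), covered_site=covered, total_depth=total)


def gene_stats(d: DepthBlocks, g: GeneModel) -> RegionStats:
    """As :func:`region_stats`, pooled over the gene's merged parts."""
    covered = 0
    total = 0
    length = 0
    for part in g.parts:
        s = region_stats(d, part)
        covered += s.covered_site
        total += s.total_depth
        length += s.length
    return RegionStats(length=length, covered_site=covered, total_depth=total)
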