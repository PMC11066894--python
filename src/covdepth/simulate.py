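"""Synthetic reference + alignment fixtures with known ground truth.

Generates a reproducible FASTA, a coordinate-sorted indexed BAM, a matching
CRAM, and a plain-text truth table of ``(ref_name, pos, flag, mapq, cigar)``.
Also provides :func:`oracle_depth`, a deliberately naive full-chromosome
pileup that shares no code with the blocked depth engine and serves as the
independent equivalence oracle in tests.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pysam

from covdepth.alignment_reader import ChromInfo

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class TruthRecord(NamedTuple):
    ref_name: str
    pos: int
    flag: int
    mapq: int
    cigar: str  # "*" for unmapped


@dataclass(frozen=True)
class SimConfig:
    """Knobs for one synthetic dataset; same seed => byte-identical files."""

    chrom_lengths: tuple[int, ...] = (1000, 500)
    n_reads: int = 200
    read_length: int | tuple[int, int] = 50
    frac_duplicate: float = 0.0
    frac_secondary: float = 0.0
    frac_unmapped: float = 0.0
    frac_qcfail: float = 0.0
    frac_low_mapq: float = 0.0
    p_indel: float = 0.0
    p_softclip: float = 0.0
    p_splice: float = 0.0
    n_run_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_duplicate", "frac_secondary", "frac_unmapped", "frac_qcfail",
                     "frac_low_mapq", "p_indel", "p_softclip", "p_splice", "n_run_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.frac_duplicate + self.frac_secondary + self.frac_unmapped + self.frac_qcfail > 1.0:
            raise ValueError("flag-category fractions must sum to <= 1")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(len(self.chrom_lengths)))


@dataclass
class SimOutput:
    fasta: str
    bam: str
    cram: str
    truth_path: str
    truth: list[TruthRecord] = field(default_factory=list)
    chroms: list[ChromInfo] = field(default_factory=list)


def generate_reference(cfg: SimConfig, out_dir: str | os.PathLike) -> tuple[str, list[ChromInfo]]:
    """Write a seeded random A/C/G/T FASTA (optional N runs) plus its .fai."""
    rng = np.random.default_rng(cfg.seed)
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    fasta = os.path.join(out_dir, "ref.fa")
    chroms: list[ChromInfo] = []
    with open(fasta, "w", encoding="ascii") as fh:
        for name, length in zip(cfg.chrom_names, cfg.chrom_lengths):
            seq = _BASES[rng.integers(0, 4, size=length)].copy()
            if cfg.n_run_fraction > 0 and length >= 10:
                n_bases = int(length * cfg.n_run_fraction)
                while n_bases > 0:
                    run = int(min(n_bases, rng.integers(1, 11)))
                    start = int(rng.integers(0, length - run + 1))
                    seq[start:start + run] = ord("N")
                    n_bases -= run
            fh.write(f">{name}\n")
            text = seq.tobytes().decode("ascii")
            for i in range(0, length, 60):
                fh.write(text[i:i + 60] + "\n")
            chroms.append(ChromInfo(name, length))
    pysam.faidx(fasta)
    return fasta, chroms


def _draw_cigar(rng: np.random.Generator, qlen: int, cfg: SimConfig) -> list[tuple[str, int]]:
    """Query-consuming ops always sum to qlen; at most one clip pair, one indel, one splice."""
    left_clip = right_clip = 0
    if cfg.p_softclip and rng.random() < cfg.p_softclip and qlen >= 10:
        left_clip = int(rng.integers(1, max(2, qlen // 4)))
        if rng.random() < 0.5:
            right_clip = int(rng.integers(1, max(2, qlen // 4)))
    core = qlen - left_clip - right_clip
    ops: list[tuple[str, int]] = []
    if cfg.p_indel and rng.random() < cfg.p_indel and core >= 5:
        if rng.random() < 0.5:  # insertion
            ilen = int(rng.integers(1, 4))
            m1 = int(rng.integers(1, core - ilen))
            ops = [("M", m1), ("I", ilen), ("M", core - ilen - m1)]
        else:  # deletion
            dlen = int(rng.integers(1, 6))
            m1 = int(rng.integers(1, core))
            ops = [("M", m1), ("D", dlen), ("M", core - m1)]
    else:
        ops = [("M", core)]
    if cfg.p_splice and rng.random() < cfg.p_splice and ops[-1][1] >= 4:
        op, mlen = ops.pop()
        gap = int(rng.integers(10, 101))
        m1 = int(rng.integers(1, mlen))
        ops += [(op, m1), ("N", gap), (op, mlen - m1)]
    ops = [o for o in ops if o[1] > 0]
    if left_clip:
        ops.insert(0, ("S", left_clip))
    if right_clip:
        ops.append(("S", right_clip))
    return ops


def _cigar_str(ops: list[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in ops) if ops else "*"


def generate_alignments(cfg: SimConfig, fasta: str, out_dir: str | os.PathLike) -> SimOutput:
    """Write sorted+indexed BAM, matching CRAM, and the truth-table TSV."""
    rng = np.random.default_rng(cfg.seed + 1)
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    chrom_names = list(cfg.chrom_names)
    lengths = list(cfg.chrom_lengths)
    weights = np.asarray(lengths, dtype=float)
    weights /= weights.sum()

    header = pysam.AlignmentHeader.from_references(chrom_names, lengths)
    segments: list[pysam.AlignedSegment] = []
    for i in range(cfg.n_reads):
        if isinstance(cfg.read_length, tuple):
            qlen = int(rng.integers(cfg.read_length[0], cfg.read_length[1] + 1))
        else:
            qlen = cfg.read_length
        ci = int(rng.choice(len(chrom_names), p=weights))
        clen = lengths[ci]
        # category draw: duplicate / secondary / unmapped / qcfail / normal
        u = rng.random()
        flag = 0
        if u < cfg.frac_duplicate:
            flag |= 0x400
        elif u < cfg.frac_duplicate + cfg.frac_secondary:
            flag |= 0x100
        elif u < cfg.frac_duplicate + cfg.frac_secondary + cfg.frac_unmapped:
            flag |= 0x4
        elif u < cfg.frac_duplicate + cfg.frac_secondary + cfg.frac_unmapped + cfg.frac_qcfail:
            flag |= 0x200
        unmapped = bool(flag & 0x4)
        if not unmapped and rng.random() < 0.5:
            flag |= 0x10
        mapq = 0 if unmapped else (
            int(rng.integers(0, 60)) if rng.random() < cfg.frac_low_mapq else 60)
        pos = int(rng.integers(0, clen))  # reads near the end may overhang; engine clips

        seg = pysam.AlignedSegment(header)
        seg.query_name = f"read{i}"
        seg.flag = flag
        seg.reference_id = ci  # unmapped reads stay placed on a chromosome
        seg.reference_start = pos
        seg.mapping_quality = mapq
        if unmapped:
            ops: list[tuple[str, int]] = []
        else:
            ops = _draw_cigar(rng, qlen, cfg)
            seg.cigartuples = [("MIDNSHP=X".index(op), n) for op, n in ops]
        seg.query_sequence = _BASES[rng.integers(0, 4, size=qlen)].tobytes().decode("ascii")
        segments.append(seg)

    segments.sort(key=lambda s: (s.reference_id, s.reference_start))
    bam = os.path.join(out_dir, "reads.bam")
    cram = os.path.join(out_dir, "reads.cram")
    with pysam.AlignmentFile(bam, "wb", header=header) as fh:
        for seg in segments:
            fh.write(seg)
    pysam.index(bam)
    with pysam.AlignmentFile(cram, "wc", header=header, reference_filename=fasta) as fh:
        for seg in segments:
            fh.write(seg)
    pysam.index(cram)

    truth = [
        TruthRecord(chrom_names[s.reference_id], s.reference_start, s.flag,
                    s.mapping_quality, _cigar_str([( "MIDNSHP=X"[op], n) for op, n in (s.cigartuples or [])]))
        for s in segments
    ]
    truth_path = os.path.join(out_dir, "truth.tsv")
    with open(truth_path, "w", encoding="ascii") as fh:
        fh.write("#ref_name\tpos\tflag\tmapq\tcigar\n")
        for t in truth:
            fh.write(f"{t.ref_name}\t{t.pos}\t{t.flag}\t{t.mapq}\t{t.cigar}\n")

    chroms = [ChromInfo(n, l) for n, l in zip(chrom_names, lengths)]
    return SimOutput(fasta=fasta, bam=bam, cram=cram, truth_path=truth_path,
                     truth=truth, chroms=chroms)


def load_truth(path: str | os.PathLike) -> list[TruthRecord]:
    out = []
    with open(path, encoding="ascii") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            ref, pos, flag, mapq, cigar = line.rstrip("\n").split("\t")
            out.append(TruthRecord(ref, int(pos), int(flag), int(mapq), cigar))
    return out


def oracle_depth(
    truth: list[TruthRecord],
    chrom: str,
    chrom_length: int,
    exclude_flag_mask: int = 0x704,
    min_mapq: int = 0,
) -> np.ndarray:
    """Naive per-base pileup over one full chromosome.

    Independent re-implementation of SAM CIGAR semantics: M/=/X add depth
    and advance, D/N advance only, everything else is ignored.  Shares no
    code with the blocked engine.
    """
    depth = np.zeros(chrom_length, dtype=np.int64)
    for rec in truth:
        if rec.ref_name != chrom or rec.cigar == "*":
            continue
        if (rec.flag & exclude_flag_mask) != 0 or rec.mapq < min_mapq:
            continue
        cursor = rec.pos
        for m in _CIGAR_RE.finditer(rec.cigar):
            n, op = int(m.group(1)), m.group(2)
            if op in "M=X":
                for j in range(cursor, min(cursor + n, chrom_length)):
                    depth[j] += 1
                cursor += n
            elif op in "DN":
                cursor += n
    return depth
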