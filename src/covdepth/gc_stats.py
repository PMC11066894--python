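"""GC percentage of reported regions from the reference FASTA.

Numerator counts G/C (case-insensitive); denominator counts A/C/G/T
(case-insensitive).  N and IUPAC ambiguity codes are excluded from both, so
assembly gaps cannot depress GC.  An empty denominator yields ``None``
(printed as ``-`` in reports).
"""

from __future__ import annotations

import logging
import os

import pysam

from covdepth.errors import ValidationError
from covdepth.target_intervals import GeneModel, TargetRegion

logger = logging.getLogger(__name__)

_GC = frozenset("GCgc")
_ACGT = frozenset("ACGTacgt")


def _counts(seq: str) -> tuple[int, int]:
    gc = sum(1 for b in seq if b in _GC)
    acgt = sum(1 for b in seq if b in _ACGT)
    return gc, acgt


def gc_fraction_counts(seq: str) -> tuple[int, int]:
    """(GC count, unambiguous-base count) for a raw sequence string."""
    return _counts(seq)


def gc_percent_of_seq(seq: str) -> float | None:
    gc, acgt = _counts(seq)
    return 100.0 * gc / acgt if acgt else None


class ReferenceGC:
    """Random-access GC calculator over an indexed FASTA."""

    def __init__(self, fasta_path: str | os.PathLike):
        self.path = os.fspath(fasta_path)
        self._fasta = pysam.FastaFile(self.path)

    def close(self) -> None:
        self._fasta.close()

    def __enter__(self) -> "ReferenceGC":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def _fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fasta.references:
            raise ValidationError(f"chromosome {chrom!r} absent from reference {self.path}")
        seq_len = self._fasta.get_reference_length(chrom)
        if end > seq_len:
            raise ValidationError(
                f"region {chrom}:{start}-{end} exceeds reference sequence length {seq_len}"
            )
        return self._fasta.fetch(chrom, start, end)

    def gc_percent(self, target: TargetRegion | GeneModel) -> float | None:
        """GC % of a region, or pooled across a gene's merged parts."""
        if isinstance(target, GeneModel):
            gc = acgt = 0
            for part in target.parts:
                g, a = _counts(self._fetch(part.chrom, part.start, part.end))
                gc += g
                acgt += a
        else:
            gc, acgt = _counts(self._fetch(target.chrom, target.start, target.end))
        return 100.0 * gc / acgt if acgt else None


def gc_percent(ref: "ReferenceGC | str | os.PathLike", target: TargetRegion | GeneModel) -> float | None:
    """Convenience wrapper accepting a FASTA path or an open :class:`ReferenceGC`."""
    if isinstance(ref, ReferenceGC):
        return ref.gc_percent(target)
    with ReferenceGC(ref) as opened:
        return opened.gc_percent(target)
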