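"""Open BAM/CRAM files and stream minimally-decoded alignment records.

Only five fields are ever decoded from each record: reference name,
position, FLAG, MAPQ and CIGAR.  For CRAM input this is enforced through
htslib's ``required_fields`` option, which skips sequence/quality decoding
entirely (and with it the need for reference bases during plain streaming).
"""

from __future__ import annotations

import os
from collections.abc import Iterator
from dataclasses import dataclass, field

import pysam

from covdepth.errors import FormatError, ValidationError

# htslib SAM_* required-field bits: FLAG|RNAME|POS|MAPQ|CIGAR
_REQUIRED_FIELDS = 0x2 | 0x4 | 0x8 | 0x10 | 0x20

_CIGAR_OPS = "MIDNSHP=X"

#: Default exclusion mask: unmapped | secondary | QC-fail | duplicate.
DEFAULT_EXCLUDE_FLAGS = 0x4 | 0x100 | 0x200 | 0x400


@dataclass(frozen=True)
class ChromInfo:
    """One reference sequence from the alignment header."""

    name: str
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError(f"chromosome {self.name!r} has non-positive length {self.length}")


@dataclass(frozen=True)
class ReadAlignment:
    """Minimal decoded alignment record (no sequence, no qualities)."""

    ref_name: str
    pos: int
    flag: int
    mapq: int
    cigar: tuple[tuple[str, int], ...]


@dataclass(frozen=True)
class FilterConfig:
    """Record-level filtering: FLAG exclusion mask plus MAPQ threshold."""

    exclude_flag_mask: int = DEFAULT_EXCLUDE_FLAGS
    min_mapq: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.exclude_flag_mask <= 0xFFFF:
            raise ValidationError(f"exclude_flag_mask {self.exclude_flag_mask:#x} outside 16-bit range")
        if self.min_mapq < 0:
            raise ValidationError(f"min_mapq must be >= 0, got {self.min_mapq}")


@dataclass
class AlignmentSource:
    """Handle-free description of an opened alignment file.

    Carries everything needed to (re)open the file, so independent workers
    can each create their own htslib handle.
    """

    path: str
    format: str  # "BAM" or "CRAM"
    chromosomes: list[ChromInfo]
    has_index: bool
    reference: str | None = None
    decoder_threads: int = field(default=1, compare=False)

    @property
    def chrom_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chrom_length(self, name: str) -> int:
        for c in self.chromosomes:
            if c.name == name:
                return c.length
        raise ValidationError(f"chromosome {name!r} not in header; valid names: {', '.join(self.chrom_names)}")


def _open_handle(source: AlignmentSource, threads: int = 1) -> pysam.AlignmentFile:
    kwargs: dict = {"threads": max(1, threads)}
    if source.format == "CRAM":
        if source.reference is not None:
            kwargs["reference_filename"] = source.reference
        kwargs["format_options"] = [f"required_fields={_REQUIRED_FIELDS:#x}".encode()]
    return pysam.AlignmentFile(source.path, "r", **kwargs)


def open_alignment(path: str | os.PathLike, reference: str | os.PathLike | None = None) -> AlignmentSource:
    """Open a BAM/CRAM file and return its header chromosomes plus capabilities.

    Parameters
    ----------
    path
        BAM or CRAM file.
    reference
        Reference FASTA, required to decode CRAM files that cannot resolve
        their reference otherwise.

    Raises
    ------
    FormatError
        On unreadable/garbled files, or CRAM whose reference is unresolvable.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"alignment file not found: {path}")
    ref = os.fspath(reference) if reference is not None else None
    try:
        with pysam.AlignmentFile(path, "r", check_sq=False, reference_filename=ref) as handle:
            if handle.is_cram:
                fmt = "CRAM"
            elif handle.is_bam:
                fmt = "BAM"
            else:
                fmt = handle.format or "SAM"
            chroms = [ChromInfo(n, l) for n, l in zip(handle.references, handle.lengths)]
            try:
                has_index = bool(handle.has_index())
            except (AttributeError, ValueError):
                has_index = False
    except (ValueError, OSError) as exc:
        if "reference" in str(exc).lower():
            raise FormatError(f"CRAM file {path} requires a reference FASTA ({exc})") from exc
        raise FormatError(f"cannot read alignment file {path}: {exc}") from exc
    if len({c.name for c in chroms}) != len(chroms):
        raise FormatError(f"duplicate reference names in header of {path}")
    return AlignmentSource(path=path, format=fmt, chromosomes=chroms, has_index=has_index, reference=ref)


def _to_record(seg: pysam.AlignedSegment) -> ReadAlignment:
    ct = seg.cigartuples
    cigar = tuple((_CIGAR_OPS[op], ln) for op, ln in ct) if ct else ()
    return ReadAlignment(
        ref_name=seg.reference_name if seg.reference_id >= 0 else "*",
        pos=seg.reference_start,
        flag=seg.flag,
        mapq=seg.mapping_quality,
        cigar=cigar,
    )


def stream_records(
    source: AlignmentSource,
    region: str | None = None,
    decoder_threads: int | None = None,
) -> Iterator[ReadAlignment]:
    """Yield :class:`ReadAlignment` records, whole-file or for one chromosome.

    ``region`` (a chromosome name) requires an index; every record whose
    reference span overlaps the chromosome is yielded.  Unmapped records are
    yielded with an empty CIGAR and left to the filter.
    """
    if region is not None:
        if region not in source.chrom_names:
            raise ValidationError(
                f"region {region!r} not in header; valid names: {', '.join(source.chrom_names)}"
            )
        if not source.has_index:
            raise ValidationError(f"region fetch for {region!r} requires an index for {source.path}")
    threads = decoder_threads if decoder_threads is not None else source.decoder_threads
    with _open_handle(source, threads=threads) as handle:
        it = handle.fetch(contig=region) if region is not None else handle.fetch(until_eof=True)
        for seg in it:
            yield _to_record(seg)


def passes_filters(rec: ReadAlignment, cfg: FilterConfig) -> bool:
    """True iff the record survives the FLAG mask and MAPQ threshold."""
    return (rec.flag & cfg.exclude_flag_mask) == 0 and rec.mapq >= cfg.min_mapq
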