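import logging

import pysam
import pytest

from covdepth.alignment_reader import ChromInfo

logging.getLogger("covdepth").setLevel(logging.ERROR)
logging.getLogger("covdepth.depth_engine").setLevel(logging.ERROR)


def make_bam(path, chroms, records, sort=True, index=True, cram_reference=None):
    """Write a small alignment file from (chrom, pos, flag, mapq, cigar_str) tuples.

    ``cigar_str`` of "*" means no CIGAR (unmapped).  Returns the path.
    """
    path = str(path)
    names = [c.name for c in chroms]
    header = pysam.AlignmentHeader.from_references(names, [c.length for c in chroms])
    segs = []
    for i, (chrom, pos, flag, mapq, cigar) in enumerate(records):
        seg = pysam.AlignedSegment(header)
        seg.query_name = f"r{i}"
        seg.flag = flag
        seg.reference_id = names.index(chrom)
        seg.reference_start = pos
        seg.mapping_quality = mapq
        if cigar != "*":
            seg.cigarstring = cigar
            qlen = seg.infer_query_length() or 0
        else:
            qlen = 10
        seg.query_sequence = "A" * qlen
        segs.append(seg)
    if sort:
        segs.sort(key=lambda s: (s.reference_id, s.reference_start))
    mode = "wc" if path.endswith(".cram") else "wb"
    kwargs = {"reference_filename": cram_reference} if mode == "wc" else {}
    with pysam.AlignmentFile(path, mode, header=header, **kwargs) as fh:
        for seg in segs:
            fh.write(seg)
    if index:
        pysam.index(path)
    return path


@pytest.fixture
def two_chroms():
    return [ChromInfo("chr1", 1000), ChromInfo("chr2", 500)]


@pytest.fixture
def small_bam(tmp_path, two_chroms):
    """3 reads on chr1, 2 on chr2, all plain 10M."""
    records = [
        ("chr1", 0, 0, 60, "10M"),
        ("chr1", 5, 0, 60, "10M"),
        ("chr1", 100, 0, 60, "10M"),
        ("chr2", 0, 0, 60, "10M"),
        ("chr2", 200, 0, 60, "10M"),
    ]
    return make_bam(tmp_path / "small.bam", two_chroms, records)
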