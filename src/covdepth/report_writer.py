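"""Assemble per-region statistics into the tab-separated report.

Report coordinates are 1-based inclusive for human/GFF congruence (internal
arithmetic is 0-based half-open).  Percentages and mean depth are printed
with two decimals, half-up; the integer columns carry full precision.
"""

from __future__ import annotations

import gzip
import io
import os
import sys
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from covdepth.errors import CovDepthError

MODES = ("chromosome", "window", "bed", "gene")

_SENTINEL = "-"  # GC undefined (no unambiguous bases)


@dataclass(frozen=True)
class ReportRow:
    """One output line: label columns plus the metric bundle."""

    labels: tuple[str, ...]  # (chrom) / (chrom,start,end) / (gene,chrom,start,end), 1-based display
    length: int
    covered_site: int
    total_depth: int
    gc_pct: float | None = None
    gc_counts: tuple[int, int] | None = None  # (gc, unambiguous) for pooled totals


def _fmt2(x: float) -> str:
    return str(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _header(mode: str, gc_enabled: bool) -> str:
    if mode == "chromosome":
        cols = ["#Chr", "Length"]
    elif mode in ("window", "bed"):
        cols = ["#Chr", "Start", "End", "Length"]
    elif mode == "gene":
        cols = ["#GeneID", "Chr", "Start", "End", "Length"]
    else:
        raise CovDepthError(f"unknown report mode {mode!r}")
    if gc_enabled:
        cols.append("GC(%)")
    cols += ["Covered_site", "Total_depth", "Coverage(%)", "Mean_depth"]
    return "\t".join(cols)


def _format_row(labels: tuple[str, ...], length: int, covered: int, total: int,
                gc_pct: float | None, gc_enabled: bool) -> str:
    cols = list(labels) + [str(length)]
    if gc_enabled:
        cols.append(_SENTINEL if gc_pct is None else _fmt2(gc_pct))
    coverage = 100.0 * covered / length if length else 0.0
    mean = total / length if length else 0.0
    cols += [str(covered), str(total), _fmt2(coverage), _fmt2(mean)]
    return "\t".join(cols)


def render_report(rows: list[ReportRow], mode: str, gc_enabled: bool) -> str:
    """Render the full report as a string (header, rows, Total in chromosome mode)."""
    lines = [_header(mode, gc_enabled)]
    for row in rows:
        lines.append(_format_row(row.labels, row.length, row.covered_site,
                                 row.total_depth, row.gc_pct, gc_enabled))
    if mode == "chromosome":
        length = sum(r.length for r in rows)
        covered = sum(r.covered_site for r in rows)
        total = sum(r.total_depth for r in rows)
        gc_pct = None
        if gc_enabled and rows and all(r.gc_counts is not None for r in rows):
            gc = sum(r.gc_counts[0] for r in rows)
            den = sum(r.gc_counts[1] for r in rows)
            gc_pct = 100.0 * gc / den if den else None
        if length:
            lines.append(_format_row(("Total",), length, covered, total, gc_pct, gc_enabled))
    return "\n".join(lines) + "\n"


def write_report(
    rows: list[ReportRow],
    mode: str,
    gc_enabled: bool,
    out: "str | os.PathLike | io.TextIOBase | None" = None,
) -> None:
    """Write the report to a path (gzip when it ends in ``.gz``), a stream, or stdout."""
    text = render_report(rows, mode, gc_enabled)
    if out is None:
        sys.stdout.write(text)
        return
    if hasattr(out, "write"):
        out.write(text)
        return
    path = os.fspath(out)
    try:
        if path.endswith(".gz"):
            with gzip.open(path, "wt", encoding="utf-8") as fh:
                fh.write(text)
        else:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
    except OSError as exc:
        raise CovDepthError(f"cannot write report to {path}: {exc}") from exc
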