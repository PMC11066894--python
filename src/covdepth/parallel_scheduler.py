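"""Partition chromosomes across workers; assign surplus decoder threads.

Multi-worker runs must produce byte-identical output to single-worker
runs: workers share nothing, results are re-ordered to header order at the
end.
"""

from __future__ import annotations

from collections.abc import Callable, Sequence
from concurrent.futures import FIRST_EXCEPTION, ThreadPoolExecutor, wait
from dataclasses import dataclass
from typing import TypeVar

from covdepth.alignment_reader import ChromInfo
from covdepth.errors import ValidationError

T = TypeVar("T")


@dataclass(frozen=True)
class WorkPlan:
    """One chromosome-name list per worker, plus per-chromosome decoder threads."""

    groups: tuple[tuple[str, ...], ...]
    decoder_threads: dict[str, int]


def build_plan(chroms: Sequence[ChromInfo], n_threads: int, indexed: bool) -> WorkPlan:
    """Greedy longest-first load balancing over ``min(n_threads, #chroms)`` groups.

    Unindexed input (or a single thread) forces one serial group in header
    order.  When threads outnumber chromosomes, the surplus is dealt one at
    a time to chromosomes in descending length order, wrapping around, as
    extra decoder threads.
    """
    if n_threads < 1:
        raise ValidationError(f"thread count must be >= 1, got {n_threads}")
    names = [c.name for c in chroms]
    if not indexed or n_threads == 1 or len(chroms) <= 1:
        decoder = {n: 1 for n in names}
        if indexed and chroms and n_threads > len(chroms):
            _deal_surplus(chroms, n_threads - len(chroms), decoder)
        groups = (tuple(names),) if names else ()
        return WorkPlan(groups=groups, decoder_threads=decoder)

    # sort by length descending, ties by header order
    order = sorted(range(len(chroms)), key=lambda i: (-chroms[i].length, i))
    n_groups = min(n_threads, len(chroms))
    group_members: list[list[str]] = [[] for _ in range(n_groups)]
    loads = [0] * n_groups
    for i in order:
        g = loads.index(min(loads))  # least-loaded, ties to lowest index
        group_members[g].append(chroms[i].name)
        loads[g] += chroms[i].length

    decoder = {n: 1 for n in names}
    if n_threads > len(chroms):
        _deal_surplus(chroms, n_threads - len(chroms), decoder)
    return WorkPlan(groups=tuple(tuple(g) for g in group_members), decoder_threads=decoder)


def _deal_surplus(chroms: Sequence[ChromInfo], surplus: int, decoder: dict[str, int]) -> None:
    by_len = sorted(range(len(chroms)), key=lambda i: (-chroms[i].length, i))
    for k in range(surplus):
        decoder[chroms[by_len[k % len(chroms)]].name] += 1


def run_plan(
    plan: WorkPlan,
    job: Callable[[str], T],
    chrom_order: Sequence[str] | None = None,
) -> dict[str, T]:
    """Run ``job(chrom)`` for every scheduled chromosome; collect in header order.

    Each group runs in its own worker; within a group chromosomes run
    sequentially.  The first worker failure aborts the run.
    """
    if not plan.groups:
        return {}
    results: dict[str, T] = {}
    if len(plan.groups) == 1:
        for name in plan.groups[0]:
            results[name] = job(name)
    else:
        def run_group(names: tuple[str, ...]) -> dict[str, T]:
            return {n: job(n) for n in names}

        with ThreadPoolExecutor(max_workers=len(plan.groups)) as pool:
            futures = [pool.submit(run_group, g) for g in plan.groups]
            done, not_done = wait(futures, return_when=FIRST_EXCEPTION)
            failed = next((f for f in done if f.exception() is not None), None)
            if failed is not None:
                for f in not_done:
                    f.cancel()
                raise failed.exception()
            for f in futures:
                results.update(f.result())

    order = list(chrom_order) if chrom_order is not None else [n for g in plan.groups for n in g]
    return {n: results[n] for n in order if n in results}
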