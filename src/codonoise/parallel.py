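"""Block-parallel execution of the abundance-sorted denoising pass.

The merging inequality ``ratio < beta(d)`` caps the abundance ratio of any
daughter at ``beta(min d)``. Consequently, within the abundance interval
between the least abundant confirmed-correct sequence and its maximum
daughter abundance (MDA), no two sequences can merge with each other: their
mutual ratio is at least ``beta(min d)``. Every sequence in that interval can
therefore be evaluated against the committed correct pool independently — in
any order, on any number of workers — and the result is identical to the
sequential pass. This module owns that scheduling contract.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from typing import Callable, Sequence

from .records import SequenceRecord

Evaluator = Callable[[int, tuple[int, ...]], list]


def run_blocks(
    records: Sequence[SequenceRecord],
    beta_min: float,
    evaluator: Evaluator,
    workers: int = 1,
) -> tuple[list[str], list[list]]:
    """Run the one-pass block algorithm over abundance-sorted records.

    Parameters
    ----------
    records
        Records sorted by decreasing abundance (canonical order). Index into
        this sequence is the local rank.
    beta_min
        ``beta(min d, alpha)`` — the loosest merging threshold, defining MDA
        (``reads * beta_min``) and MMA (``reads / beta_min``).
    evaluator
        ``evaluator(member_index, correct_pool)`` returns the member's merge
        candidates against the given pool (local indices, abundance-sorted).
        It must be pure with respect to the pool snapshot.
    workers
        Thread count for within-block evaluation. Results are committed in
        rank order, so the output is identical for any value.

    Returns
    -------
    (status, candidates)
        ``status[i]`` is ``"correct"`` or ``"daughter"``; ``candidates[i]``
        holds the stored merge candidates of daughters (empty for correct
        records).
    """
    n = len(records)
    status: list[str] = [""] * n
    candidates: list[list] = [[] for _ in range(n)]
    if n == 0:
        return status, candidates

    status[0] = "correct"
    correct: list[int] = [0]

    executor = ThreadPoolExecutor(max_workers=workers) if workers > 1 else None
    try:
        i = 1
        while i < n:
            mda_val = records[correct[-1]].total_reads * beta_min
            j = i
            while j < n and records[j].total_reads >= mda_val:
                j += 1
            if j == i:
                # No member reaches the current MDA (e.g. a long run of equal
                # abundances after daughters): advance one sequence at a time.
                j = i + 1
            block = range(i, j)
            pool = tuple(correct)
            if executor is not None and len(block) > 1:
                results = list(executor.map(lambda k: evaluator(k, pool), block))
            else:
                results = [evaluator(k, pool) for k in block]
            for k, cands in zip(block, results):
                if cands:
                    status[k] = "daughter"
                    candidates[k] = cands
                else:
                    status[k] = "correct"
                    correct.append(k)
            i = j
    finally:
        if executor is not None:
            executor.shutdown()
    return status, candidates
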