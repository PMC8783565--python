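"""Independent O(n^2) reference denoiser used as the test oracle.

Implements the merging rules directly from their definition — sort by
abundance, compare every potential daughter against every more abundant
confirmed-correct sequence, keep candidates where ratio < 0.5^(alpha*d+1),
assign per criterion — with no MDA/MMA pruning and no block scheduling.
Deliberately simple and slow; it shares nothing with the package's scheduler.
"""

from __future__ import annotations

from collections import Counter

import edlib
import numpy as np


def ref_beta(d: float, alpha: float) -> float:
    return 0.5 ** (alpha * d + 1)


def ref_weights(ent: tuple[float, float, float]) -> tuple[float, float, float]:
    t = sum(ent)
    return tuple(3.0 * e / t for e in ent)  # type: ignore[return-value]


def _weighted_hamming(a: str, b: str, weights, frame_offset: int) -> float:
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    pos = (np.arange(len(a)) - frame_offset) % 3
    wvec = np.choose(pos, weights)
    return float(wvec[aa != bb].sum())


def ref_denoise(
    records: list[tuple[str, str, int]],
    alpha: float,
    entropy_mode: bool = False,
    ent: tuple[float, float, float] | None = None,
    frame_offset: int = 0,
    modal_length: int | None = None,
):
    """Reference result: (esv_ids, {criterion: {daughter_id: mother_id}}, discarded_ids).

    ``records`` are (id, seq, reads) triples in any order.
    """
    ordered = sorted(records, key=lambda r: (-r[2], r[0]))

    if entropy_mode:
        weights = ref_weights(ent)
        if modal_length is None:
            counts = Counter(len(seq) for _, seq, _ in ordered)
            top = max(counts.values())
            modal_length = min(n for n, c in counts.items() if c == top)
        kept = [r for r in ordered if (len(r[1]) - modal_length) % 3 == 0]
        discarded = [r[0] for r in ordered if (len(r[1]) - modal_length) % 3 != 0]
        groups: dict[int, list] = {}
        for r in kept:
            groups.setdefault(len(r[1]), []).append(r)

        def dist(a: str, b: str) -> float:
            return _weighted_hamming(a, b, weights, frame_offset)

    else:
        groups = {0: ordered}
        discarded = []

        def dist(a: str, b: str) -> float:
            if a == b:
                return 0.0
            return float(edlib.align(a, b, mode="NW", task="distance")["editDistance"])

    esv_ids: list[str] = []
    all_cands: dict[str, list] = {}
    for group in groups.values():
        correct: list[tuple[str, str, int]] = []
        for rid, seq, reads in group:
            cands = []
            for mid, mseq, mreads in correct:
                if mreads == reads:
                    continue
                d = dist(seq, mseq)
                b = ref_beta(d, alpha)
                ratio = reads / mreads
                if ratio < b:
                    cands.append((mid, mreads, d, ratio, ratio / b))
            if cands:
                all_cands[rid] = cands
            else:
                correct.append((rid, seq, reads))
                esv_ids.append(rid)

    keys = {
        "ratio": lambda c: (c[3], -c[1], c[0]),
        "distance": lambda c: (c[2], -c[1], c[0]),
        "ratio_distance": lambda c: (c[4], -c[1], c[0]),
    }
    assignments = {
        crit: {rid: min(cands, key=key)[0] for rid, cands in all_cands.items()}
        for crit, key in keys.items()
    }
    return sorted(esv_ids), assignments, sorted(discarded)
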