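"""Codon-position entropies and entropy-corrected genetic distance.

In coding markers the three codon positions carry very different natural
variability: third positions are the most variable, second positions the
least. The Shannon entropy of alignment columns, averaged per codon position,
quantifies this. The corrected distance re-weights the per-position mismatch
counts of a pair of aligned equal-length sequences by the normalized position
entropies

    d_corr = sum_i d_i * e_i * 3 / (e1 + e2 + e3)

so that a mismatch at a naturally variable (high-entropy) position counts for
more than one at a conserved position, making third-position variants harder
to absorb as sequencing errors. When entropy correction is off, the plain
Levenshtein (unit-cost edit) distance is used instead.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import NamedTuple

import edlib
import numpy as np

from .records import Dataset

_TOL = 1e-9


@dataclass(frozen=True)
class EntropyTriple:
    """Mean Shannon entropies (bits) of codon positions 1-3.

    The normalized weights ``w_i = e_i * 3 / (e1 + e2 + e3)`` always sum to 3
    and are invariant under rescaling all entropies by a common positive
    constant; the corrected distance depends only on the weights, so the log
    base used for the entropies is immaterial.
    """

    e1: float
    e2: float
    e3: float

    def __post_init__(self) -> None:
        if min(self.e1, self.e2, self.e3) < 0:
            raise ValueError("entropies must be non-negative")

    @property
    def total(self) -> float:
        return self.e1 + self.e2 + self.e3

    @property
    def weights(self) -> tuple[float, float, float]:
        t = self.total
        if t <= 0:
            raise ValueError(
                "zero total entropy: data are degenerate, entropy correction impossible"
            )
        return (3.0 * self.e1 / t, 3.0 * self.e2 / t, 3.0 * self.e3 / t)


class PositionDiffs(NamedTuple):
    """Mismatch counts bucketed by within-codon position (1, 2, 3)."""

    d1: int
    d2: int
    d3: int

    @property
    def total(self) -> int:
        return self.d1 + self.d2 + self.d3


_BASES = "ACGT"


def compute_entropy(
    dataset: Dataset, frame_offset: int = 0, weighting: str = "reads"
) -> EntropyTriple:
    """Per-codon-position Shannon entropies from the modal-length sequences.

    Only sequences of the modal length (the most frequent length; ties broken
    toward the shorter) enter the calculation, since only that class is
    guaranteed alignable column-by-column. For each column the entropy
    ``H = -sum_b p_b log2 p_b`` is computed over the four base frequencies;
    ``e_i`` is the mean over columns whose codon position is *i*, where the
    position of column *j* is ``((j - frame_offset) mod 3) + 1``.

    ``weighting="reads"`` (default) weights base frequencies by read counts,
    reflecting the read-level error process; ``"unique"`` counts each
    dereplicated sequence once.
    """
    if weighting not in ("reads", "unique"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if not dataset.records:
        raise ValueError("empty dataset: cannot compute entropy")
    lengths = Counter(len(r.seq) for r in dataset.records)
    top = max(lengths.values())
    modal = min(length for length, n in lengths.items() if n == top)
    recs = [r for r in dataset.records if len(r.seq) == modal]

    mat = np.frombuffer("".join(r.seq for r in recs).encode(), dtype=np.uint8)
    mat = mat.reshape(len(recs), modal)
    if weighting == "reads":
        w = np.array([r.total_reads for r in recs], dtype=np.float64)
    else:
        w = np.ones(len(recs), dtype=np.float64)

    # counts[b, col] = weighted frequency of base b in that column
    counts = np.stack([((mat == ord(b)).T * w).sum(axis=1) for b in _BASES])
    probs = counts / counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(probs > 0, probs * np.log2(probs), 0.0)
    col_entropy = -terms.sum(axis=0)

    pos = (np.arange(modal) - frame_offset) % 3  # 0-based codon position
    means = []
    for i in range(3):
        cols = col_entropy[pos == i]
        means.append(float(cols.mean()) if cols.size else 0.0)
    return EntropyTriple(*means)


def position_diffs(a: str, b: str, frame_offset: int = 0) -> PositionDiffs:
    """Count mismatches of two aligned equal-length sequences per codon position."""
    if len(a) != len(b):
        raise ValueError(
            f"position_diffs requires equal lengths ({len(a)} != {len(b)}); "
            "route sequences to length classes first"
        )
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    mism = aa != bb
    pos = (np.arange(len(a)) - frame_offset) % 3
    return PositionDiffs(
        int(np.count_nonzero(mism & (pos == 0))),
        int(np.count_nonzero(mism & (pos == 1))),
        int(np.count_nonzero(mism & (pos == 2))),
    )


def corrected_distance(diffs: PositionDiffs, ent: EntropyTriple) -> float:
    """Entropy-weighted distance ``sum_i d_i * w_i``.

    Reduces to the plain mismatch (Hamming) count when the three entropies are
    equal.
    """
    w1, w2, w3 = ent.weights
    return diffs.d1 * w1 + diffs.d2 * w2 + diffs.d3 * w3


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitutions, insertions, deletions)."""
    if a == b:
        return 0
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def min_corrected_unit(ent: EntropyTriple | None) -> float:
    """Smallest possible distance of a single change.

    With entropy correction this is the weight of the least-entropic codon
    position, ``min_i w_i``; without correction a single change has distance 1.
    This quantity sets ``beta(min d)``, the loosest merging threshold, from
    which the MDA/MMA pruning bounds derive.
    """
    if ent is None:
        return 1.0
    return min(ent.weights)
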