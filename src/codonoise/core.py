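"""The one-pass abundance-skew denoiser.

Sequences are sorted by decreasing abundance; each potential daughter (PDS)
is compared with the confirmed-correct, more abundant sequences (PMS). A pair
at genetic distance ``d`` merges when the abundance ratio PDS/PMS falls below

    beta(d) = 0.5 ** (alpha * d + 1)

where ``alpha`` is the stringency parameter. With entropy correction on,
``d`` is the entropy-weighted mismatch count within a sequence-length class;
otherwise it is the Levenshtein distance. A daughter stores every mother
satisfying the inequality, and the final assignment is made per criterion:
lowest ratio (most abundant mother — the classical formulation), lowest
distance (closest mother), or lowest ratio/beta(d) skew. Daughters never act
as mothers. The MDA/MMA abundance bounds prune comparisons that cannot
possibly merge and define the blocks evaluated in parallel.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from . import parallel
from .entropy_distance import (
    EntropyTriple,
    compute_entropy,
    levenshtein,
    min_corrected_unit,
)
from .records import Dataset, SequenceRecord

CRITERIA = ("ratio", "distance", "ratio_distance")


@dataclass(frozen=True)
class DenoiseParams:
    """Knobs of a denoising run.

    alpha : stringency; higher alpha shrinks beta(d), demanding a stronger
        abundance skew to merge (5 is the customary value for 313-bp COI).
    criterion : subset of ``{"ratio", "distance", "ratio_distance"}``.
    entropy_mode : weight mismatches by codon-position entropy instead of
        Levenshtein distance (coding markers only).
    entropy : user-supplied entropy triple; ``None`` means compute from data.
    frame_offset : codon position of the first base (0 means the amplicon
        starts at position 1 of a codon).
    modal_length : anchor of the length-class partition; ``None`` = modal
        length of the data.
    min_abund : post-merging minimum ESV abundance (0 disables the filter).
    fast_ratio : first-hit shortcut, valid only for the ratio criterion.
    workers : thread count for block evaluation (never changes the result).
    """

    alpha: float = 5.0
    criterion: tuple[str, ...] = ("ratio_distance",)
    entropy_mode: bool = False
    entropy: EntropyTriple | None = None
    entropy_weighting: str = "reads"
    frame_offset: int = 0
    modal_length: int | None = None
    min_abund: int = 0
    fast_ratio: bool = False
    workers: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        crit = tuple(self.criterion)
        if crit == ("all",):
            crit = CRITERIA
        unknown = set(crit) - set(CRITERIA)
        if unknown:
            raise ValueError(f"unknown criteria: {sorted(unknown)}")
        if not crit:
            raise ValueError("at least one criterion required")
        object.__setattr__(self, "criterion", crit)
        if self.fast_ratio and crit != ("ratio",):
            raise ValueError("fast_ratio requires criterion == ('ratio',)")


@dataclass(frozen=True)
class MergeCandidate:
    """One (PDS, PMS) pair satisfying the merging inequality."""

    pms_rank: int
    pms_id: str
    pms_reads: int
    d: float
    ratio: float
    skew: float  # ratio / beta(d), always < 1 for stored candidates


@dataclass(frozen=True)
class TraceEntry:
    """A committed merge: daughter, chosen mother and the decisive values."""

    daughter_id: str
    mother_id: str
    d: float
    ratio: float
    skew: float


@dataclass
class DenoiseResult:
    criteria: tuple[str, ...]
    esvs: dict[str, list[SequenceRecord]]
    trace: dict[str, list[TraceEntry]]
    discarded: list[SequenceRecord]
    filtered: dict[str, list[SequenceRecord]]
    status: dict[str, str]  # record id -> {"correct", "daughter", "discarded"}
    sample_names: list[str]
    entropy: EntropyTriple | None
    modal_length: int | None
    params: DenoiseParams
    input_reads: int


def beta(d: float, alpha: float) -> float:
    """Threshold daughter/mother abundance ratio at distance ``d``."""
    return 0.5 ** (alpha * d + 1)


def mda(mother_reads: float, beta_min: float) -> float:
    """Maximum daughter abundance of a mother: anything more abundant than
    ``mother_reads * beta(min d)`` cannot be its daughter."""
    return mother_reads * beta_min


def mma(daughter_reads: float, beta_min: float) -> float:
    """Minimum mother abundance of a daughter: anything less abundant than
    ``daughter_reads / beta(min d)`` cannot be its mother."""
    return daughter_reads / beta_min


def canonical_sort(dataset: Dataset) -> Dataset:
    """Sort by decreasing abundance, ties by ascending id; assign ranks.

    This order fixes every downstream tie, making runs bit-reproducible
    across worker counts and input permutations.
    """
    ordered = sorted(dataset.records, key=lambda r: (-r.total_reads, r.id))
    ordered = [replace(r, rank=i) for i, r in enumerate(ordered)]
    return Dataset(
        records=ordered,
        sample_names=list(dataset.sample_names),
        source_dialect=dataset.source_dialect,
    )


def partition_lengths(
    dataset: Dataset, modal_length: int | None = None
) -> tuple[dict[int, list[SequenceRecord]], list[SequenceRecord]]:
    """Split records into codon-compatible length classes.

    Accepted lengths differ from the modal length by whole codons (multiples
    of 3); every other record is considered erroneous and discarded. Used only
    in entropy mode — the Levenshtein path handles indels directly.
    """
    if not dataset.records:
        raise ValueError("empty dataset")
    if modal_length is None:
        counts = Counter(len(r.seq) for r in dataset.records)
        top = max(counts.values())
        modal_length = min(length for length, n in counts.items() if n == top)
    classes: dict[int, list[SequenceRecord]] = {}
    discarded: list[SequenceRecord] = []
    for r in dataset.records:
        if (len(r.seq) - modal_length) % 3 == 0:
            classes.setdefault(len(r.seq), []).append(r)
        else:
            discarded.append(r)
    if modal_length not in classes:
        raise ValueError(f"no sequences at modal length {modal_length}")
    return classes, discarded


def merge_test(
    pds: SequenceRecord,
    pms: SequenceRecord,
    params: DenoiseParams,
    ent: EntropyTriple | None = None,
) -> MergeCandidate | None:
    """Evaluate one (PDS, PMS) pair against the merging inequality.

    Returns a candidate iff ``ratio < beta(d)`` strictly; equal-abundance
    pairs can never merge (ratio 1 >= beta always).
    """
    if pms.total_reads < pds.total_reads:
        raise ValueError("pms must be at least as abundant as pds")
    if params.entropy_mode:
        if ent is None:
            ent = params.entropy
        if ent is None:
            raise ValueError("entropy mode requires an entropy triple")
        from .entropy_distance import corrected_distance, position_diffs

        d: float = corrected_distance(
            position_diffs(pds.seq, pms.seq, params.frame_offset), ent
        )
    else:
        d = float(levenshtein(pds.seq, pms.seq))
    b = beta(d, params.alpha)
    ratio = pds.total_reads / pms.total_reads
    if ratio < b:
        return MergeCandidate(
            pms_rank=pms.rank if pms.rank is not None else -1,
            pms_id=pms.id,
            pms_reads=pms.total_reads,
            d=d,
            ratio=ratio,
            skew=ratio / b,
        )
    return None


_CRIT_KEYS = {
    "ratio": lambda c: (c.ratio, -c.pms_reads, c.pms_rank),
    "distance": lambda c: (c.d, -c.pms_reads, c.pms_rank),
    "ratio_distance": lambda c: (c.skew, -c.pms_reads, c.pms_rank),
}


def choose_mother(candidates: Iterable[MergeCandidate], criterion: str) -> MergeCandidate:
    """Pick the best mother under a criterion.

    Ties are broken by greater mother abundance, then lower mother rank —
    deterministic given the canonical sort.
    """
    cands = list(candidates)
    if not cands:
        raise ValueError("choose_mother requires at least one candidate")
    return min(cands, key=_CRIT_KEYS[criterion])


def _class_evaluator(records, params, ent, beta_min):
    """Build the per-member candidate collector for one length class.

    Entropy mode precomputes the byte matrix and per-column entropy weights so
    a pairwise corrected distance is a single vectorized reduction; the
    Levenshtein mode delegates to edlib. Both reproduce merge_test exactly.
    """
    alpha = params.alpha
    reads = [r.total_reads for r in records]
    if params.entropy_mode:
        length = len(records[0].seq)
        mat = np.frombuffer(
            "".join(r.seq for r in records).encode(), dtype=np.uint8
        ).reshape(len(records), length)
        w = ent.weights
        pos = (np.arange(length) - params.frame_offset) % 3
        wvec = np.choose(pos, w)

        def dist(k: int, m: int) -> float:
            return float(wvec[mat[k] != mat[m]].sum())

    else:

        def dist(k: int, m: int) -> float:
            return float(levenshtein(records[k].seq, records[m].seq))

    def evaluate(k: int, pool: tuple[int, ...]) -> list[MergeCandidate]:
        rk = reads[k]
        mma_val = rk / beta_min
        out: list[MergeCandidate] = []
        for m in pool:
            rm = reads[m]
            if rm < mma_val:
                break  # pool is abundance-sorted; nothing further qualifies
            if rm == rk:
                continue
            d = dist(k, m)
            b = beta(d, alpha)
            ratio = rk / rm
            if ratio < b:
                rec = records[m]
                out.append(
                    MergeCandidate(
                        pms_rank=rec.rank if rec.rank is not None else m,
                        pms_id=rec.id,
                        pms_reads=rm,
                        d=d,
                        ratio=ratio,
                        skew=ratio / b,
                    )
                )
                if params.fast_ratio:
                    break  # first hit is the most abundant valid mother
        return out

    return evaluate


def denoise(dataset: Dataset, params: DenoiseParams) -> DenoiseResult:
    """Run the full one-pass denoiser and merge counts per criterion.

    The result is independent of ``params.workers`` and of the input record
    order. Every input record ends up exactly one of: ESV, merged daughter,
    or discarded by the length rule; read totals are conserved per criterion
    (ESV totals + discarded reads == input reads).
    """
    if not dataset.records:
        raise ValueError("empty dataset")
    ds = canonical_sort(dataset)
    records = ds.records
    input_reads = ds.total_reads

    ent: EntropyTriple | None = None
    modal: int | None = None
    if params.entropy_mode:
        ent = params.entropy or compute_entropy(
            ds, params.frame_offset, params.entropy_weighting
        )
        ent.weights  # raises on zero total entropy (degenerate data)
        classes, discarded = partition_lengths(ds, params.modal_length)
        modal = params.modal_length
        if modal is None:
            counts = Counter(len(r.seq) for r in ds.records)
            top = max(counts.values())
            modal = min(length for length, n in counts.items() if n == top)
    else:
        classes = {0: records}
        discarded = []

    beta_min = beta(min_corrected_unit(ent), params.alpha)

    status: dict[str, str] = {r.id: "discarded" for r in discarded}
    cands_by_rank: dict[int, list[MergeCandidate]] = {}
    rank_to_record = {r.rank: r for r in records}

    for class_records in classes.values():
        evaluator = _class_evaluator(class_records, params, ent, beta_min)
        st, cands = parallel.run_blocks(
            class_records, beta_min, evaluator, workers=params.workers
        )
        for local, rec in enumerate(class_records):
            status[rec.id] = st[local]
            if st[local] == "daughter":
                cands_by_rank[rec.rank] = cands[local]

    esvs: dict[str, list[SequenceRecord]] = {}
    trace: dict[str, list[TraceEntry]] = {}
    correct_ranks = sorted(
        r.rank for r in records if status[r.id] == "correct"
    )
    daughter_ranks = sorted(cands_by_rank)
    for crit in params.criterion:
        totals = {rk: rank_to_record[rk].total_reads for rk in correct_ranks}
        samples = {
            rk: Counter(rank_to_record[rk].sample_reads) for rk in correct_ranks
        }
        rows: list[TraceEntry] = []
        for rk in daughter_ranks:
            rec = rank_to_record[rk]
            best = choose_mother(cands_by_rank[rk], crit)
            totals[best.pms_rank] += rec.total_reads
            samples[best.pms_rank].update(rec.sample_reads)
            rows.append(
                TraceEntry(
                    daughter_id=rec.id,
                    mother_id=best.pms_id,
                    d=best.d,
                    ratio=best.ratio,
                    skew=best.skew,
                )
            )
        merged = [
            replace(
                rank_to_record[rk],
                total_reads=totals[rk],
                sample_reads=dict(samples[rk]),
                rank=None,
            )
            for rk in correct_ranks
        ]
        merged.sort(key=lambda r: (-r.total_reads, r.id))
        esvs[crit] = merged
        trace[crit] = rows

    result = DenoiseResult(
        criteria=params.criterion,
        esvs=esvs,
        trace=trace,
        discarded=discarded,
        filtered={crit: [] for crit in params.criterion},
        status=status,
        sample_names=list(ds.sample_names),
        entropy=ent,
        modal_length=modal,
        params=params,
        input_reads=input_reads,
    )
    if params.min_abund > 0:
        result = filter_min_abund(result, params.min_abund)
    return result


def fast_ratio_denoise(dataset: Dataset, params: DenoiseParams) -> DenoiseResult:
    """First-hit variant of the ratio criterion.

    Each daughter is assigned to the most abundant mother satisfying the
    inequality and drops out of further comparisons. Because the first hit
    when scanning the abundance-sorted correct pool is also the
    ratio-minimizing mother, the ESV set equals ``denoise`` under the ratio
    criterion.
    """
    params = dataclasses.replace(params, criterion=("ratio",), fast_ratio=True)
    return denoise(dataset, params)


def filter_min_abund(result: DenoiseResult, threshold: int) -> DenoiseResult:
    """Drop ESVs whose merged abundance is below ``threshold`` (keep >=)."""
    if threshold <= 0:
        return result
    esvs: dict[str, list[SequenceRecord]] = {}
    filtered: dict[str, list[SequenceRecord]] = {}
    for crit in result.criteria:
        kept = [r for r in result.esvs[crit] if r.total_reads >= threshold]
        removed = [r for r in result.esvs[crit] if r.total_reads < threshold]
        esvs[crit] = kept
        filtered[crit] = result.filtered.get(crit, []) + removed
    return dataclasses.replace(result, esvs=esvs, filtered=filtered)
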