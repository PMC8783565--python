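"""Synthetic mock-community generator and denoising evaluation harness.

The experiment it emulates: start from a set of "good" template haplotypes
with a realistic skewed read-abundance distribution, apply independent
per-base substitution errors to every read (a uniform rate, 0.005 by default,
intermediate among reported Illumina values), dereplicate, remove singleton
amplicons, denoise, and score the outcome. Because each error amplicon's
template of origin is tracked, two quantities can be measured that real data
never yields: how many true templates survive as ESVs, and the match ratio —
the fraction of merged daughters that were joined to their true mother.

Templates are built with codon-structured variability (third positions most
diverse between templates, second positions least) so that computed entropies
order e3 > e1 > e2, as in real coding markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DenoiseParams, DenoiseResult, denoise
from .records import Dataset, SequenceRecord

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Per-codon-position probability that a template deviates from the column's
# major base; ordered to reproduce the natural e3 > e1 > e2 entropy ranking.
_DIVERSITY = {0: 0.10, 1: 0.03, 2: 0.35}


@dataclass
class SimTruth:
    """Ground truth of one simulation."""

    templates: list[tuple[str, str, int]]  # (id, seq, reads)
    provenance: dict[str, str] = field(default_factory=dict)  # error id -> template id
    error_rate: float = 0.0
    seed: int = 0

    @property
    def template_ids(self) -> set[str]:
        return {t[0] for t in self.templates}


@dataclass
class EvalMetrics:
    n_total: int
    n_good_retained: int
    n_error_retained: int
    match_ratio: float | None  # None when no merge occurred
    n_merged: int = 0


def generate_templates(
    n: int,
    length: int,
    abundance_model: str = "lognormal",
    seed: int = 0,
    lognormal_mean: float = np.log(100.0),
    lognormal_sigma: float = 1.3,
    geometric_top: int = 2000,
    geometric_decay: float = 0.9,
    min_reads: int = 2,
) -> list[tuple[str, str, int]]:
    """Draw ``n`` distinct in-frame template haplotypes with abundances.

    Each alignment column has a major base; templates deviate from it with a
    codon-position-dependent probability (highest at third positions).
    Abundances come from a lognormal (default) or geometric model, floored at
    ``min_reads`` so no template is a singleton.
    """
    if length % 3 != 0:
        raise ValueError("template length must be divisible by 3")
    rng = np.random.default_rng(seed)
    major = rng.choice(_BASES, size=length)
    pos = np.arange(length) % 3
    p_div = np.choose(pos, [_DIVERSITY[0], _DIVERSITY[1], _DIVERSITY[2]])

    seqs: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(seqs) < n:
        attempts += 1
        if attempts > 50 * n:
            raise ValueError(
                f"cannot draw {n} distinct templates of length {length}"
            )
        arr = major.copy()
        hit = rng.random(length) < p_div
        shift = rng.integers(1, 4, size=int(hit.sum()))
        idx = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(idx + shift) % 4]
        s = arr.tobytes().decode()
        if s not in seen:
            seen.add(s)
            seqs.append(s)

    if abundance_model == "lognormal":
        reads = rng.lognormal(lognormal_mean, lognormal_sigma, size=n)
        reads = np.maximum(np.round(reads).astype(int), min_reads)
    elif abundance_model == "geometric":
        reads = np.maximum(
            np.round(geometric_top * geometric_decay ** np.arange(n)).astype(int),
            min_reads,
        )
    else:
        raise ValueError(f"unknown abundance model {abundance_model!r}")

    width = len(str(n))
    return [
        (f"tmpl_{i:0{width}d}", seqs[i], int(reads[i])) for i in range(n)
    ]


def simulate_errors(
    templates: list[tuple[str, str, int]], error_rate: float, seed: int = 0
) -> tuple[Dataset, SimTruth]:
    """Mutate every read independently and dereplicate the result.

    Each base of each read is substituted with probability ``error_rate``
    (uniform over the three alternatives). Identical resulting reads are
    aggregated into amplicons. The provenance of each non-template amplicon
    is the template whose reads contributed most of its copies (ties to the
    more abundant template).
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    tmpl_reads = {tid: reads for tid, _, reads in templates}
    tmpl_seqs = {seq: tid for tid, seq, _ in templates}

    # seq -> {template id -> copies}
    agg: dict[str, dict[str, int]] = {}
    for tid, seq, reads in templates:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        length = arr.size
        n_mut = rng.binomial(length, error_rate, size=reads)
        n_clean = int((n_mut == 0).sum())
        if n_clean:
            agg.setdefault(seq, {}).setdefault(tid, 0)
            agg[seq][tid] += n_clean
        for k in n_mut[n_mut > 0]:
            read = arr.copy()
            sites = rng.choice(length, size=int(k), replace=False)
            shift = rng.integers(1, 4, size=int(k))
            idx = np.searchsorted(_BASES, read[sites])
            read[sites] = _BASES[(idx + shift) % 4]
            s = read.tobytes().decode()
            agg.setdefault(s, {}).setdefault(tid, 0)
            agg[s][tid] += 1

    records: list[SequenceRecord] = []
    provenance: dict[str, str] = {}
    # Deterministic error-amplicon naming: by decreasing copies, then sequence.
    err_seqs = sorted(
        (s for s in agg if s not in tmpl_seqs),
        key=lambda s: (-sum(agg[s].values()), s),
    )
    width = max(5, len(str(len(err_seqs))))
    for s, tid in tmpl_seqs.items():
        if s in agg:
            records.append(
                SequenceRecord(id=tid, seq=s, total_reads=sum(agg[s].values()))
            )
    for i, s in enumerate(err_seqs):
        eid = f"err_{i:0{width}d}"
        records.append(SequenceRecord(id=eid, seq=s, total_reads=sum(agg[s].values())))
        # majority template; ties to the more abundant template, then id
        provenance[eid] = max(
            agg[s].items(), key=lambda kv: (kv[1], tmpl_reads[kv[0]], kv[0])
        )[0]

    truth = SimTruth(
        templates=list(templates),
        provenance=provenance,
        error_rate=error_rate,
        seed=seed,
    )
    return Dataset(records=records, source_dialect="fasta"), truth


def remove_singletons(dataset: Dataset) -> Dataset:
    """Drop amplicons carrying a single read."""
    kept = [r for r in dataset.records if r.total_reads >= 2]
    return Dataset(
        records=kept,
        sample_names=list(dataset.sample_names),
        source_dialect=dataset.source_dialect,
    )


def _lineage(esv_id: str, truth: SimTruth) -> str:
    """Map an amplicon id to its template of origin (templates map to themselves)."""
    return truth.provenance.get(esv_id, esv_id)


def evaluate(
    result: DenoiseResult,
    truth: SimTruth,
    min_abund: int = 0,
    criterion: str | None = None,
) -> EvalMetrics:
    """Score a denoising result against the simulation ground truth.

    ``n_good_retained`` counts templates surviving as ESVs (after the optional
    abundance filter); ``n_error_retained`` the remaining ESVs. The match
    ratio is computed over all merged daughters: a merge matches when the
    chosen mother's lineage traces to the daughter's own template.
    """
    if criterion is None:
        if len(result.criteria) != 1:
            raise ValueError("specify criterion for multi-criterion results")
        criterion = result.criteria[0]
    esvs = [r for r in result.esvs[criterion] if r.total_reads >= max(min_abund, 0)]
    tids = truth.template_ids
    n_good = sum(1 for r in esvs if r.id in tids)
    n_error = len(esvs) - n_good

    rows = result.trace[criterion]
    n_merged = len(rows)
    if n_merged == 0:
        ratio = None
    else:
        matches = sum(
            1
            for t in rows
            if _lineage(t.mother_id, truth) == _lineage(t.daughter_id, truth)
        )
        ratio = matches / n_merged
    return EvalMetrics(
        n_total=len(esvs),
        n_good_retained=n_good,
        n_error_retained=n_error,
        match_ratio=ratio,
        n_merged=n_merged,
    )


def alpha_sweep(
    templates: list[tuple[str, str, int]],
    error_rate: float,
    alphas: list[float],
    criteria: list[str],
    entropy: str = "off",
    min_abund: int = 0,
    seed: int = 0,
    drop_singletons: bool = True,
    workers: int = 1,
) -> pd.DataFrame:
    """Full pipeline over a grid of alphas and criteria; one row per cell."""
    dataset, truth = simulate_errors(templates, error_rate, seed=seed)
    if drop_singletons:
        dataset = remove_singletons(dataset)
    rows = []
    for alpha in alphas:
        params = DenoiseParams(
            alpha=alpha,
            criterion=tuple(criteria),
            entropy_mode=(entropy == "on"),
            workers=workers,
        )
        result = denoise(dataset, params)
        for crit in criteria:
            m = evaluate(result, truth, min_abund=min_abund, criterion=crit)
            rows.append(
                {
                    "alpha": alpha,
                    "criterion": crit,
                    "entropy": entropy,
                    "min_abund": min_abund,
                    "n_total": m.n_total,
                    "n_good_retained": m.n_good_retained,
                    "n_error_retained": m.n_error_retained,
                    "n_merged": m.n_merged,
                    "match_ratio": m.match_ratio,
                }
            )
    return pd.DataFrame(rows)
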