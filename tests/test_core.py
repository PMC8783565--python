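"""Merging inequality, mother choice, pruning bounds and the full denoiser."""

import numpy as np
import pytest

from codonoise import (
    Dataset,
    DenoiseParams,
    EntropyTriple,
    SequenceRecord,
    beta,
    canonical_sort,
    choose_mother,
    denoise,
    fast_ratio_denoise,
    filter_min_abund,
    mda,
    merge_test,
    mma,
    partition_lengths,
)
from codonoise.core import MergeCandidate

from conftest import make_fixture


def test_beta_printed_values():
    assert beta(0, 5) == 0.5
    assert beta(1, 5) == 0.015625
    assert beta(2, 5) == 0.00048828125


def test_beta_strictly_decreasing():
    for alpha in (1, 3, 5, 10):
        vals = [beta(d, alpha) for d in (0, 0.5, 1, 2, 5)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
    assert beta(1, 2) > beta(1, 3)


def _ds(records):
    return Dataset(records=records, source_dialect="fasta")


def test_canonical_sort_ties_by_id(rng):
    ds = _ds(
        [
            SequenceRecord("c", "AAA", 5),
            SequenceRecord("b", "CCC", 9),
            SequenceRecord("a", "GGG", 9),
        ]
    )
    out = canonical_sort(ds)
    assert [r.id for r in out.records] == ["a", "b", "c"]
    assert [r.rank for r in out.records] == [0, 1, 2]


def test_canonical_sort_permutation_invariant(rng):
    ds = make_fixture(rng, 40)
    ref = [r.id for r in canonical_sort(ds).records]
    for _ in range(5):
        perm = list(ds.records)
        rng.shuffle(perm)
        assert [r.id for r in canonical_sort(_ds(perm)).records] == ref


def test_partition_lengths_modal_313_example():
    recs = [
        SequenceRecord(f"r{i}", "A" * n, 10 - i)
        for i, n in enumerate([313, 313, 310, 316, 312])
    ]
    classes, discarded = partition_lengths(_ds(recs))
    assert sorted(classes) == [310, 313, 316]
    assert [r.id for r in discarded] == ["r4"]  # 312 breaks the codon rule
    # union of classes + discarded == input
    n_in_classes = sum(len(v) for v in classes.values())
    assert n_in_classes + len(discarded) == len(recs)


def test_partition_lengths_single_class():
    recs = [SequenceRecord(f"r{i}", "ACG" * 4, i + 1) for i in range(4)]
    classes, discarded = partition_lengths(_ds(recs))
    assert list(classes) == [12] and discarded == []


def test_partition_lengths_empty_modal_class_error():
    recs = [SequenceRecord("a", "A" * 10, 1)]
    with pytest.raises(ValueError, match="modal length"):
        partition_lengths(_ds(recs), modal_length=13)


def _rec(id_, seq, reads, rank=None):
    return SequenceRecord(id_, seq, reads, rank=rank)


def test_merge_test_toy_pairs():
    params = DenoiseParams(alpha=5.0, criterion=("ratio",))
    m = _rec("m", "ACGTACGTA", 100, rank=0)
    d1 = _rec("d1", "ACGTACGTC", 1, rank=1)
    d2 = _rec("d2", "ACGTACGTC", 2, rank=1)
    cand = merge_test(d1, m, params)
    assert cand is not None and cand.ratio == pytest.approx(0.01)
    assert cand.d == 1.0 and cand.skew == pytest.approx(0.01 / 0.015625)
    assert merge_test(d2, m, params) is None  # 0.02 > 0.015625


def test_merge_test_entropy_shields_third_position_change():
    # single third-position mismatch, entropy-weighted distance 1.875
    ent = EntropyTriple(0.5, 0.25, 1.25)
    params = DenoiseParams(alpha=5.0, criterion=("ratio",), entropy_mode=True, entropy=ent)
    m = _rec("m", "ACGACGACG", 100, rank=0)
    d = _rec("d", "ACGACGACT", 1, rank=1)
    assert merge_test(d, m, params) is None  # beta(1.875,5) ~ 7.5e-4 < 0.01
    # the same pair merges without correction
    assert merge_test(d, m, DenoiseParams(alpha=5.0, criterion=("ratio",))) is not None


def test_merge_test_boundary_equality_does_not_merge():
    params = DenoiseParams(alpha=5.0, criterion=("ratio",))
    m = _rec("m", "ACGTACGTA", 64, rank=0)
    d = _rec("d", "ACGTACGTC", 1, rank=1)  # ratio exactly beta(1,5) = 1/64
    assert merge_test(d, m, params) is None


def test_merge_test_outcome_flips_monotonically_with_alpha():
    m = _rec("m", "ACGTACGTA", 500, rank=0)
    d = _rec("d", "ACGTACGTC", 3, rank=1)
    merged = [
        merge_test(d, m, DenoiseParams(alpha=a, criterion=("ratio",))) is not None
        for a in (0.5, 1, 2, 3, 4, 5, 6, 8, 10)
    ]
    # once the pair stops merging at some alpha it never merges again
    assert merged == sorted(merged, reverse=True)


def _cand(rank, id_, reads, d, alpha=5.0, pds_reads=1):
    ratio = pds_reads / reads
    return MergeCandidate(rank, id_, reads, d, ratio, ratio / beta(d, alpha))


def test_choose_mother_three_criteria_disagree():
    c1 = _cand(0, "PMS1", 4000, d=2)
    c2 = _cand(1, "PMS2", 200, d=1)
    assert choose_mother([c1, c2], "ratio").pms_id == "PMS1"
    assert choose_mother([c1, c2], "distance").pms_id == "PMS2"
    assert c2.skew == pytest.approx(0.32)
    assert c1.skew == pytest.approx(0.512)
    assert choose_mother([c1, c2], "ratio_distance").pms_id == "PMS2"


def test_choose_mother_single_candidate_and_argmin_oracle(rng):
    c = _cand(0, "only", 100, d=1)
    for crit in ("ratio", "distance", "ratio_distance"):
        assert choose_mother([c], crit) is c
    keys = {
        "ratio": lambda c: (c.ratio, -c.pms_reads, c.pms_rank),
        "distance": lambda c: (c.d, -c.pms_reads, c.pms_rank),
        "ratio_distance": lambda c: (c.skew, -c.pms_reads, c.pms_rank),
    }
    for _ in range(25):
        cands = [
            _cand(i, f"m{i}", int(rng.integers(50, 5000)), d=int(rng.integers(1, 4)))
            for i in range(int(rng.integers(1, 6)))
        ]
        for crit, key in keys.items():
            assert choose_mother(cands, crit) == min(cands, key=key)


def test_mda_mma_values():
    beta_min = beta(1, 5)
    assert mda(1000, beta_min) == pytest.approx(15.625)
    assert mma(1, beta_min) == pytest.approx(64.0)
    assert mda(10, 0.5) == 5.0
    assert mma(10, 0.5) == 20.0


def test_denoise_toy_merge_and_no_merge():
    m = SequenceRecord("m", "ACGTACGTA", 100)
    d = SequenceRecord("d", "ACGTACGTC", 1)
    res = denoise(_ds([m, d]), DenoiseParams(alpha=5.0, criterion=("ratio",)))
    assert [(r.id, r.total_reads) for r in res.esvs["ratio"]] == [("m", 101)]

    d2 = SequenceRecord("d", "ACGTACGTC", 2)
    res2 = denoise(_ds([m, d2]), DenoiseParams(alpha=5.0, criterion=("ratio",)))
    assert len(res2.esvs["ratio"]) == 2


def test_daughters_never_serve_as_mothers():
    m = SequenceRecord("m", "ACGTACGTAACGTACGTA", 100000)
    d = SequenceRecord("d", "ACGTACGTAACGTACGTC", 100)  # 1 change from m
    e = SequenceRecord("e", "ACGTACGTAACGTACGCC", 1)  # 1 from d, 2 from m
    res = denoise(_ds([m, d, e]), DenoiseParams(alpha=5.0, criterion=("distance",)))
    assert res.status == {"m": "correct", "d": "daughter", "e": "daughter"}
    mothers = {t.daughter_id: t.mother_id for t in res.trace["distance"]}
    # e is closer to d, but d was tagged daughter and cannot be a mother
    assert mothers == {"d": "m", "e": "m"}


def test_fast_ratio_equivalent_to_ratio(rng):
    for n in (40, 120):
        ds = make_fixture(rng, n)
        full = denoise(ds, DenoiseParams(alpha=5.0, criterion=("ratio",)))
        fast = fast_ratio_denoise(ds, DenoiseParams(alpha=5.0, criterion=("ratio",)))
        assert [r.id for r in full.esvs["ratio"]] == [r.id for r in fast.esvs["ratio"]]
        assert [(r.id, r.total_reads) for r in full.esvs["ratio"]] == [
            (r.id, r.total_reads) for r in fast.esvs["ratio"]
        ]


def test_fast_ratio_equal_abundance_mothers_tie_to_canonical_order():
    ma = SequenceRecord("ma", "ACGTACGTA", 1000)
    mb = SequenceRecord("mb", "ACGTACGTG", 1000)
    d = SequenceRecord("d", "ACGTACGTC", 1)  # d=1 to both
    res = fast_ratio_denoise(_ds([mb, ma, d]), DenoiseParams(criterion=("ratio",)))
    assert res.trace["ratio"][0].mother_id == "ma"


def test_filter_min_abund_boundary_and_monotonicity(rng):
    recs = [
        SequenceRecord("a", "ACGTACGTA", 11),
        SequenceRecord("b", "TGCATGCAT", 10),
        SequenceRecord("c", "GGGGGCCCC", 9),
    ]
    res = denoise(_ds(recs), DenoiseParams(alpha=5.0, criterion=("ratio",)))
    assert len(res.esvs["ratio"]) == 3
    f0 = filter_min_abund(res, 0)
    assert [r.id for r in f0.esvs["ratio"]] == ["a", "b", "c"]
    f10 = filter_min_abund(res, 10)
    assert [r.id for r in f10.esvs["ratio"]] == ["a", "b"]
    assert [r.id for r in f10.filtered["ratio"]] == ["c"]

    ds = make_fixture(rng, 60)
    res = denoise(ds, DenoiseParams(alpha=5.0, criterion=("ratio",)))
    sizes = [len(filter_min_abund(res, t).esvs["ratio"]) for t in (0, 2, 5, 10, 50)]
    assert sizes == sorted(sizes, reverse=True)


def test_entropy_on_retains_third_position_variants():
    """A true variant differing only at third positions survives correction."""
    # entropy triple with dominant third position
    ent = EntropyTriple(0.4, 0.2, 1.2)
    m = SequenceRecord("m", "ACGACGACGACG", 5000)
    v = SequenceRecord("v", "ACTACGACGACG", 20)  # one third-position change
    ds = _ds([m, v])
    off = denoise(ds, DenoiseParams(alpha=5.0, criterion=("ratio",)))
    on = denoise(
        ds,
        DenoiseParams(alpha=5.0, criterion=("ratio",), entropy_mode=True, entropy=ent),
    )
    assert len(on.esvs["ratio"]) >= len(off.esvs["ratio"])
    assert [r.id for r in on.esvs["ratio"]] == ["m", "v"]
    assert [r.id for r in off.esvs["ratio"]] == ["m"]


def test_denoise_records_partition_exactly(rng):
    ds = make_fixture(rng, 100)
    res = denoise(ds, DenoiseParams(alpha=3.0, criterion=("all",), entropy_mode=True))
    ids = {r.id for r in ds.records}
    tags = {"correct": set(), "daughter": set(), "discarded": set()}
    for rid, tag in res.status.items():
        tags[tag].add(rid)
    assert tags["correct"] | tags["daughter"] | tags["discarded"] == ids
    assert not (tags["correct"] & tags["daughter"])
    esv_ids = {r.id for r in res.esvs["ratio"]} | {
        r.id for r in res.filtered["ratio"]
    }
    assert esv_ids == tags["correct"]
    assert {t.daughter_id for t in res.trace["ratio"]} == tags["daughter"]
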