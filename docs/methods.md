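# Methods

## The denoising model

`codonoise` infers exact sequence variants (ESVs) from dereplicated amplicon
reads under the standard abundance-skew error model: an erroneous amplicon is
expected to be both *similar to* and *much rarer than* the correct sequence
("mother") that produced it. Sequences are sorted by decreasing abundance and
each potential daughter (PDS) is compared against the more abundant
confirmed-correct sequences (PMS). A pair at genetic distance *d* satisfies
the merging inequality when

    ratio = reads(PDS) / reads(PMS) < beta(d) = 0.5^(alpha * d + 1)

with `alpha` the stringency parameter: larger `alpha` shrinks `beta(d)` and
demands a stronger skew. The inequality is strict, so equal-abundance pairs
can never merge (`ratio = 1 >= 0.5 >= beta` always). Every qualifying mother
of a daughter is stored, and the final assignment is made per criterion:

* **ratio** — the mother with the lowest abundance ratio (equivalently the
  most abundant valid mother; the classical formulation);
* **distance** — the closest valid mother;
* **ratio_distance** — the mother minimising the skew `ratio / beta(d)`.

The criteria produce the same ESV *set* (correct/daughter status is
criterion-independent) but different merged abundances. Daughters never act
as mothers: the pass is one-way down the abundance ranking, with no posterior
re-mapping of reads. A `fast_ratio` shortcut stops at the first qualifying
mother when scanning mothers in decreasing-abundance order, which is exactly
the ratio-minimising one, so its ESV set matches the full ratio criterion.

## Entropy correction for coding markers

In coding genes the three codon positions differ sharply in natural
variability (third ≫ first > second). A mismatch at a third position is more
likely a real variant than an error, so treating all mismatches equally
over-merges natural haplotypes. With correction on, the distance becomes

    d_corr = sum_i d_i * w_i,   w_i = 3 * e_i / (e1 + e2 + e3)

where `d_i` is the mismatch count at codon position *i* and `e_i` the mean
Shannon entropy of alignment columns at that position. `d_corr` depends only
on the normalised weights, so it is invariant to rescaling the entropy triple
(and to the log base; we report bits). It reduces to the plain mismatch count
when the three entropies are equal.

Entropies are computed from the data (from modal-length sequences only, the
one class guaranteed alignable as a block) or supplied by the user. The
default weights base frequencies by read counts, since the error process acts
on reads; `unique` weighting is available. The codon position of column *j*
is `((j - frame_offset) mod 3) + 1`; a modal length that is not a multiple of
3 is accepted — real COI fragments (e.g. 313 bp) are not codon-multiples, and
only the per-column position assignment matters.

Because position bookkeeping requires positional homology, correction uses
mismatch counts rather than edit distance, and only equal-length sequences
are compared. The dataset is partitioned into length classes differing from
the modal length by whole codons (indels in coding sequences are usually
whole-codon); any other length is reported as discarded. Each class is
denoised independently, all using the entropy triple of the modal class.
Without correction the Levenshtein distance (via `edlib`) is used and no
partitioning occurs.

## Pruning bounds and the parallel block scheme

The loosest merging threshold is `beta(min d)`, where `min d` is 1 without
correction and the weight of the least-entropic position (`min_i w_i`) with
correction. Two abundance bounds follow:

* **MDA** (maximum daughter abundance) of a mother:
  `reads(PMS) * beta(min d)` — nothing more abundant can be its daughter;
* **MMA** (minimum mother abundance) of a daughter:
  `reads(PDS) / beta(min d)` — nothing less abundant can be its mother.

These prune the comparison space and define the parallel blocks: between the
least abundant confirmed-correct sequence and its MDA, no two sequences can
merge with each other (their mutual ratio is at least `beta(min d)`), so all
of them can be evaluated against the committed correct pool independently and
concurrently. After a block commits, the next MDA is taken from the new last
correct sequence; if no sequence reaches the current MDA the scheduler
advances one sequence at a time, which also handles long runs of equal
abundances. Results are committed in rank order, so output is bit-identical
for any worker count; the test suite checks this and the equivalence of the
whole scheduler with a direct quadratic implementation of the rules.

## Tie-breaking and numerical choices

All ordering is fixed by the canonical sort: reads descending, id ascending
(lexicographic). Mother-choice ties are broken by greater mother abundance,
then lower rank. Corrected distances are compared as IEEE doubles with no
tolerance: candidates for one daughter are computed identically in every run,
so bit-reproducibility holds across runs, worker counts and input
permutations. The boundary of the minimum-abundance filter keeps ESVs with
merged reads `>= threshold`, applied after merging. Degenerate inputs: an
empty dataset, a missing modal class, and zero total entropy in correction
mode are hard errors; an all-identical-abundance dataset denoises to all
ESVs.

## The synthetic mock community

Building a real mock community of many known haplotypes for a coding marker
is impractical, so calibration uses a provenance-tracked simulation:

1. `n` distinct in-frame templates are drawn from a column model in which
   each column has a major base and a codon-position-dependent deviation
   probability (0.10 / 0.03 / 0.35 for positions 1/2/3), reproducing the
   natural entropy ranking `e3 > e1 > e2`. Read abundances come from a
   lognormal (default: median 100 reads, sigma 1.3 in log space, floored at
   2 reads — a heavy-tailed "realistic" community) or a geometric ladder.
2. Every read of every template is mutated independently: each base is
   substituted with probability `error_rate` (default 0.005, intermediate
   among reported Illumina values), uniformly over the three alternatives.
   Identical reads are aggregated into amplicons; each non-template amplicon
   records the template whose reads produced most of its copies (ties to the
   more abundant template — collisions are rare at this error rate).
3. Singleton amplicons (one read) are removed, as is common practice before
   denoising.

Scoring counts the templates surviving as ESVs, the non-template ESVs (before
and after the abundance filter), and the **match ratio**: merged daughters
whose chosen mother's lineage (the mother itself, or the template of origin
of an erroneously retained mother) equals the daughter's own template of
origin, divided by all merged daughters. `alpha_sweep` runs the full pipeline
over a grid of alphas and criteria.

What the simulation does *not* emulate: indel errors (they would interact
with the length-class rule and are left out deliberately; the error model is
substitution-only), chimeras, position- or quality-dependent error rates, and
PCR amplification noise. Passing tests therefore demonstrate correctness of
the algorithm and the expected qualitative behaviour (template recovery near
1 at moderate alpha, match ratios near 1 for alpha >= 5, more retained
third-position variants with correction), not quantitative performance on any
real dataset.

## Default problem sizes

The acceptance script and test suite run the experiment at desk scale: 50
templates of length 150 (about 300-400 amplicons after singleton removal),
10 seeds for the stochastic recovery check, and 50 random instances of
100-300 records for the oracle-equivalence check. These sizes make the full
suite run in a couple of minutes while leaving every code path exercised;
all generators accept larger sizes unchanged.

## Known limitations

* Entropy correction assumes in-frame, alignment-free positional homology of
  equal-length sequences; frameshifted data must be trimmed upstream.
* The entropy triple from very shallow datasets is noisy; user-supplied
  marker-specific values are preferable there.
* Chimera removal is out of scope and should run before or after denoising.
* Thread-based workers help most in the Levenshtein mode (edlib releases the
  GIL); the worker contract is determinism, not linear speedup.
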