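# codonoise

Entropy-aware denoising of dereplicated metabarcoding amplicons.

Erroneous amplicons generated during PCR and sequencing are a major nuisance
in DNA metabarcoding. Most denoisers were designed for non-coding ribosomal
markers and treat every nucleotide position alike; for coding markers such as
COI that assumption over-merges real haplotypes, because third codon
positions are naturally far more variable than first and second positions.
`codonoise` implements the classical abundance-skew (UNOISE-style) merging
model with an optional per-codon-position entropy correction of the genetic
distance, three selectable mother-assignment criteria, and a deterministic
abundance-block scheme that makes the pass parallelizable without changing
the result. It is aimed at metabarcoding practitioners who want to denoise
dereplicated reads (FASTA with `;size=N` annotations, or CSV with per-sample
counts) into exact sequence variants (ESVs) at any point of their pipeline.

## Model

A less abundant sequence (potential daughter, PDS) is merged into a more
abundant one (potential mother, PMS) at genetic distance *d* when

    reads(PDS) / reads(PMS) < beta(d) = 0.5^(alpha * d + 1)

with stringency `alpha` (5 is the customary value for the 313-bp COI
fragment). With entropy correction, *d* is replaced by

    d_corr = sum_{i=1..3} d_i * e_i * 3 / (e1 + e2 + e3)

where `d_i` is the number of mismatches at codon position *i* and `e_i` the
mean Shannon entropy of alignment columns at that position, computed from the
data or supplied by the user; without correction *d* is the Levenshtein
distance. Daughters may satisfy the inequality for several mothers; the
final assignment follows the **ratio** (most abundant mother), **distance**
(closest mother) or **ratio_distance** (lowest `ratio/beta(d)` skew)
criterion. The `beta(min d)` bounds MDA (`reads * beta(min d)`, the maximum
abundance of a mother's daughter) and MMA (`reads / beta(min d)`, the
minimum abundance of a daughter's mother) prune the comparisons and define
blocks of sequences that are provably mutually unmergeable, hence safe to
evaluate in parallel. A provenance-tracked mock-community simulator
(templates → per-base substitution errors → dereplication → singleton
removal) is built in for calibration.

## Worked example

Simulate a small mock community and denoise it with entropy correction:

```
$ codonoise simulate --n-templates 20 --length 90 --error-rate 0.005 --seed 7 -o sim
INFO codonoise: wrote dataset: sim_reads.fasta (188 amplicons)
INFO codonoise: wrote truth: sim_truth.tsv

$ codonoise denoise --fasta sim_reads.fasta --alpha 5 --criterion all \
      --entropy_correction --min_abund 10 -o dn
$ cat dn_report.tsv
parameter	value
input_records	188
input_reads	2723
alpha	5.0
criteria	ratio,distance,ratio_distance
entropy_correction	True
entropy_triple	0.464625,0.087325,1.186623
modal_length	90
beta_min_d	0.2965976691259042
min_abund	10
...
esvs_ratio	20
merged_daughters_ratio	108
filtered_low_abund_ratio	60
```

The 188 dereplicated amplicons (2,723 reads) collapse to exactly the 20
template haplotypes after the 10-read abundance filter; 108 error amplicons
were merged into mothers and 60 rare leftovers filtered. The entropy triple
shows the expected coding-gene ranking (`e3 = 1.19 > e1 = 0.46 > e2 =
0.087`), and `beta_min_d` is the merging threshold at the smallest corrected
distance (a single second-position change). The trace files record, per
merged daughter, the chosen mother with its distance, abundance ratio and
skew.

The same functionality is available as a library:

```python
from codonoise import DenoiseParams, denoise, read_fasta

ds = read_fasta("sim_reads.fasta")
res = denoise(ds, DenoiseParams(alpha=5.0, criterion=("ratio_distance",),
                                entropy_mode=True, min_abund=10))
print(len(res.esvs["ratio_distance"]))   # 20
```

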