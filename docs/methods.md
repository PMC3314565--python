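# Methods

This note records the statistical model behind `exonflow`, the choices
made where the design was genuinely open, and what the simulation-based
tests do and do not establish.

## Data model and assumptions

Input is a probeset × sample matrix of log2 intensities as produced by
RMA-style probe summarization, together with sample metadata (condition
`normal`/`pathological` required; patient pairing, gender, age of onset,
stage and free-form covariates optional), probeset annotation linking
each probeset to one transcript cluster, one gene, a 1-based inclusive
genomic interval, an exon ordinal in transcription order, and the set of
known isoforms containing it, and an optional DABG p-value matrix of the
same shape. Everything downstream assumes log2 scale; the package never
exponentiates except to render a ratio-scale fold change. Strand is
used for display ordering only. Validation is total: every malformed
input produces a diagnostic naming the offending record.

## Transcript-cluster normalization

Exon-level statistics operate on `e = x − g`, the log-space subtraction
of the transcript-cluster summary (equivalent to a ratio of linear
intensities). The summary is computed over **all** probesets of the
cluster by Tukey median polish, taking `overall + column effect` as the
per-sample value. Median polish is the additive-fit engine of RMA, and
its robustness is load-bearing here: with a mean summary, a single
spliced probeset among k drags the cluster estimate by δ/k, attenuating
the splicing index of a planted δ=1 event to δ(1−1/k) ≈ 0.87 at k=8;
with median polish the measured attenuation is 3–6% over k = 5–12. The
residual attenuation is a known, accepted bias of cluster-normalized
splicing indices. A `mean` summarizer is available as a transparent
alternative for oracle-style checks.

Median polish sweeps rows then columns, re-centring effects on their
medians, with a fixed order, at most 10 sweeps, and a 1e-6 convergence
tolerance, so results are deterministic across platforms. One
consequence: the fit is only approximately equivariant to per-sample
location shifts (observed ~6e-4 on 8×10 matrices), because the sweep
path differs; column means are exactly equivariant.

## Exon-level statistics

* Splicing index: `SI = mean(e, normal) − mean(e, pathological)`,
  positive when the normal signal is higher (log2 units).
* Student's t: two-sample pooled-variance t on `e`, two-sided. Paired
  mode (one-sample t on within-pair differences keyed by patient id) is
  opt-in; unpaired is the default even for paired designs, the more
  conservative reading when pairing use is not established.
* ANOVA p-value: one-way fixed-effects ANOVA on `e` across the
  experimental groups, in the spirit of the microarray
  alternative-splicing detection (MiDAS) approach. No
  variance-stabilization constant is applied (the published constant is
  not available); the internal contract is the exact two-group identity
  F = t², which holds to ~1e-15 in the implementation and is asserted
  to 1e-10 in tests.
* Degenerate zero-variance inputs return p = 1 when the group means
  also agree (no evidence), p = 0 when they differ — never NaN.
* Fold change: group difference of the raw log2 intensities, by design
  not gene-normalized, same sign convention as SI.
* DABG detection: fraction of samples per group with DABG p ≤ 0.05
  (threshold tunable). The filter retains probesets detected in at
  least one group (`either`, default) or both (`both`), at ≥ 0.5 of
  samples by default; filtered probesets are flagged, never deleted.
* Multiplicity: Benjamini–Hochberg q-values, off by default so the raw
  per-probeset outputs are primary; thresholds (`flagged` = both
  p-values < 0.05 and |SI| ≥ 0.5) are report-time choices, not baked
  into the statistics.

## Gene-level statistics

Transcript clusters can lump neighbouring genes, so gene expression is
summarized (median polish again) from the probesets with non-empty
isoform membership only. Genes with no isoform-mapped probesets fall
back to all their probesets with a logged warning rather than being
dropped. Fold change and t-test reuse the exon-level machinery on the
per-sample summary.

## Meta statistics and ranking

Per gene: min, max, mean and sample variance (n−1 denominator, defined
as 0 for single-probeset genes) of each of {t p, ANOVA p, SI, FC} over
the gene's unfiltered probesets — 16 components. Components are
standardized across genes (z-score with population SD; zero-variance
components map to zero; min-max scaling available behind a flag), and
genes are ranked by Euclidean distance over the query's *active*
components only, ties broken by gene id. Pathway/GO neighbour ranking
uses the full 16-component vector relative to the focal gene. The
shipped default splicing-event query (min p = 0, mean t p = 1, SI peak
at the observed maximum) is this package's reconstruction of a sensible
default, not a published setting. Note that the "mean p" component of
an event gene concentrates *below* 0.5 in realistic noise — the
unaffected probesets have uniform null p-values — so the minimum-p
components carry most of the signal; see the ranking tests.

## Conditional-inference trees

Per probeset, the response is its cluster-normalized expression and the
candidate covariates are condition (included by default, so
pathology-independent splicing surfaces explicitly; excludable) plus
every clinical covariate. At each node:

1. each testable covariate gets a permutation p-value for association
   with the response — statistic |Pearson r| for numeric covariates,
   maximum absolute standardized group-mean deviation for categorical
   ones; p = (1 + #{permuted ≥ observed}) / (B + 1);
2. p-values are Bonferroni-adjusted by the number of testable
   covariates; if the minimum adjusted p exceeds α the node is a leaf
   (this is the global independence test);
3. otherwise the best covariate is split at the ANOVA-F-optimal point:
   numeric thresholds from midpoints of consecutive sorted unique
   values (smallest on ties), binary categoricals by value, k ≤ 8
   levels by exhaustive 2^(k−1)−1 partition search; both children must
   hold ≥ `min_leaf_size` samples.

Variable selection is separated from split search to avoid the
selection bias of exhaustive-search trees. Permutation p-values are
used rather than asymptotic conditional-inference distributions: exact
under exchangeability at any n, at the cost of Monte-Carlo resolution
1/(B+1). Missing covariate values are excluded from that covariate's
test and, when it is chosen, follow the larger child (no surrogate
splits). Defaults: α = 0.05, B = 9999 permutations, min node 10, min
leaf 5, max depth 4 — all in `TreeConfig`; every fit is deterministic
given the seed (per-node seeds are spawned from it). Stage is treated
as plain categorical; its ordering is not exploited.

## Synthetic case studies

The generator emulates the post-summarization output of a paired
normal/pathological exon-array experiment:

```
x[ps,s] = μ_g + a_ps + c_g·1(path) + δ·d_ps·1(path) + covariate effects + ε
```

with gene baseline μ_g ~ N(7, 1) log2 units, probeset affinity
a_ps ~ N(0, 1) shared across samples (emulating RMA's probe-affinity
structure without implementing RMA), gene-level disease shift
c_g = ±1 log2 units on a configured fraction of genes, splicing effect
δ (default 1 log2 unit) on one probeset per event gene (cassette: lost
in disease) or +δ/−δ on an adjacent exon pair (mutually exclusive, with
isoform annotation in which the two exons never co-occur), and
ε ~ N(0, σ²) with σ = 0.25 by default. Defaults mirror a small paired
cancer case study: 14 patients, one normal and one tumor sample each;
5–12 probesets per gene (exon-array core transcript clusters average
roughly this many); 10% of probesets unexpressed background with DABG
p ~ U(0,1) (expressed: U(0, 0.01)). Patient-level covariates are drawn
independently of condition — gender Bernoulli(½), age of onset uniform
integer 40–80 so a threshold of 60 is interior, optional stage — and a
planted covariate effect adds a constant to chosen probesets for
samples matching a categorical level or exceeding a numeric threshold.
Truth tables record every planted event with its expected SI sign.
Identical configs and seeds are bit-identical.

What the generator does **not** emulate: probe-level effects and RMA
itself, batch/array effects, correlated noise, heavy-tailed intensity
distributions, cross-hybridization, partial isoform usage (events are
all-or-nothing shifts), and annotation errors. Passing recovery tests
therefore show the statistics behave correctly under the stated additive
Gaussian model, not that they are robust to everything real arrays do.

## Problem sizes in tests and the acceptance script

Simulation checks use deliberately desk-scale designs: type-I
calibration on 2000 null probesets (250 genes × 8 probesets, 15 pairs);
cassette recovery with 200 planted events (400 genes, 15 pairs,
δ = 1, σ = 0.25); mutually-exclusive recovery on 100 event genes; SI
calibration on 30 events at 50 pairs, σ = 0.1; meta-statistics oracle
agreement on 500 genes; tree recovery on 100 runs each for gender and
age effects (n = 60, B = 999 permutations) and 500 null runs (n = 40);
determinism on a 100-gene double run. The full suite and the acceptance
script each complete in well under a minute on one CPU.

## Known limitations

* The ANOVA realization of the splicing p-value omits the
  variance-stabilization constant of the original algorithm; on
  low-intensity probesets the two will disagree.
* Median-polish cluster summaries attenuate large splicing effects
  slightly (see above) and break exact location equivariance.
* The per-gene mean-p meta component is a weak event signal in noise
  (uniform null p-values cap it near 0.5); rankings lean on the
  min-p and SI-extreme components.
* Trees treat covariates marginally at each node; correlated covariates
  can mask each other, and no surrogate splits means heavily missing
  covariates lose power.
* Categorical split search is exhaustive and limited to 8 levels.
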