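# Methods

This note documents the models, algorithmic choices, and limitations behind
`cbfmrd`, in the order the pipeline runs.

## Fusion-junction discovery

Discovery is a seed-and-extend split-read search against the two partner
transcript references (sense strand). A read votes for breakpoint `(i, j)` —
meaning the fusion transcript is `five_ref[:i] + three_ref[j:]` (0-based) —
when a prefix of at least `anchor` bases matches the 5′ reference exactly
(extended greedily to the mismatch point, ending at offset `i`) and the
remaining suffix, also at least `anchor` bases, matches the 3′ reference at
`j` with at most one mismatch. Both the read and its reverse complement are
tried. The modal breakpoint with at least `min_support` votes wins; ties are
broken by support, then leftmost `i`, then leftmost `j`, with a logged
warning.

When `five_ref[i-1] == three_ref[j-1]`, the pairs `(i, j)` and `(i-1, j-1)`
describe the same transcript; breakpoints are therefore reported in the
canonical leftmost form, and the synthetic generator canonicalizes its planted
truth the same way so recovery comparisons are exact.

Defaults: `anchor = 10`, `min_support = 2`, junction k-mer `k = 16`
(8 bases each side of the join), `max_mismatch = 1` for remission counting.
These were chosen so that a 100 bp read at 0.1–1% per-base error is counted
with high probability while the expected number of random matches stays far
below one per 3M reads: the chance that a random 16-mer window matches the
junction k-mer with ≤1 mismatch is `(1/4)¹⁶·(1+16·3) ≈ 1.1e-8`, so ~3M reads
× ~85 windows × 2 strands give ≈ 0.006 expected false counts per sample.

Remission counting requires a full-k-mer window match (≤ `max_mismatch`
substitutions) on either strand, which guarantees 8 bases of overhang on each
side of the join; each read counts at most once. A brute-force all-window
Hamming scan serves as the test oracle. Indels, spliced alignment, UMIs and
base-quality weighting are out of scope.

## MRD quantification and censoring

Normalization is reads-per-million; the MRD readout is
`log10(RPM_dx / RPM_cr)`. A remission sample with zero junction reads yields
a censored call reported as `≥ LOD`, with
`LOD = log10(j_dx · M_cr / M_dx)` — the reduction at which one junction read
is still expected. No pseudo-counts are used. The categorical "3-log or
deeper" flag is: achieved when the measured reduction ≥ 3, or when the call
is censored with `LOD ≥ 3`; a censored call whose LOD falls short of 3 logs
cannot support the claim and is flagged *indeterminate* and conservatively
treated as not achieved (with a logged warning). The detection-probability
helper assumes Poisson read sampling, `P(≥1 read) = 1 − e^{−rate}`.

## Mutation tracking

VAF is `alt/(ref+alt)`; positions are 1-based throughout. The remission
clearance flags are: complete clearance (zero remission alt reads) and MC03
(remission VAF strictly below 0.003; the boundary side is a convention and is
configurable). Indels are treated identically to SNVs — allele counts are the
upstream contract; no realignment is attempted. Background "mutation-like"
error at a site is the per-sample alt fraction across remission samples of
patients who lacked the mutation at diagnosis, summarized by median and IQR
with linear-interpolation (type-7) quantiles. Because published error
summaries rarely state the pooling, both the pooled-(site, sample) and the
per-site-median summaries are emitted, plus the pooled mean: at ~1645×
depth and ~8e-5 error most site/sample pairs contain zero error reads, so
the per-pair median collapses to 0 while the mean remains informative.

## Concordance with qPCR

Pearson correlation relates RNA-seq and qPCR log-reductions. Censored
(zero-read) RNA-seq values are excluded by default and can be included at
their LOD bound (`impute_lod`); qPCR positivity is an input flag, never
recomputed. The 2×2 diagnostic table calls a sample test-positive when the
measured reduction is shallower than the 3-log threshold, with qPCR as the
reference; metrics with empty denominators are returned as NaN and named in
an `undefined` list rather than raising. Co-clearance clusters classify each
tracked mutation by (mutation detectable at CR, fusion detectable at CR):
(T, T) → cluster 1, (F, F) → cluster 2, (F, T) → cluster 3; the fourth
combination — mutation persisting while the fusion cleared — is labeled
*discordant* and reported rather than dropped.

## Survival machinery

All estimators are implemented here and cross-checked in the test suite
against independent references (lifelines for KM/CIF/log-rank/Cox to 1e-10
or a few units in the last digits; frozen `cmprsk::cuminc` values and a
permutation null for Gray's test).

* **Kaplan–Meier** with Greenwood variance; at tied times events precede
  censorings. Curves are right-continuous; evaluation beyond the last time
  carries the last value forward.
* **Log-rank**: K-group score with hypergeometric covariance, χ² with
  K−1 degrees of freedom.
* **Aalen–Johansen CIF**: `CIF_k(t) = Σ_{u≤t} S(u−) d_k(u)/n(u)` with `S`
  the all-cause KM; equals `1 − KM` exactly when no competing events exist.
* **Gray's test** (ρ = 0): the subdistribution-hazard score with per-group
  effective risk sets `R_k(t) = Y_k(t)(1 − F_k(t−))/S_k(t−)`, so subjects
  failing from the competing cause keep contributing to the risk set. The
  variance is a hypergeometric-style plug-in on the effective risk sets
  rather than the full estimator that corrects for estimation of the weight
  functions; on simulated competing-risks data the statistic tracks the
  reference implementation within a few percent (slightly conservative) and
  the type-I error at α = 0.05 is calibrated within Monte-Carlo error (a
  property the suite re-verifies). With no competing events the statistic
  reduces exactly to the log-rank test.
* **Cox** (univariate): Newton–Raphson on the partial likelihood with
  Breslow tie handling and Wald 95% CIs. Monotone separation is detected
  (unbounded likelihood) and reported via `converged = False` instead of
  crashing.

P-values are two-sided from the χ² distribution. Fine–Gray regression
coefficients are deliberately not implemented; Gray's test plus
cause-specific Cox is the documented substitute.

## Risk model

The two-feature rule is deterministic: 3-log reduction achieved → low;
otherwise KIT-D816 mutated → high, wild-type → intermediate. Censored-at-LOD
patients enter through the censoring rule above unchanged. The tree inducer
is greedy recursive partitioning over binary features on the OS endpoint,
choosing at each node the split maximizing the two-group log-rank statistic,
subject to `min_node = 5` per child and `max_depth = 2`; a node with no
admissible split (including a best statistic of exactly zero) becomes a leaf.
Ties are broken by declared feature order. No pruning or cross-validation is
attempted — the published model is a depth-2 tree and the inducer exists to
show the structure is recoverable, not to select models. Three-group outcome
tests use the K-group generalizations (df = 2).

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, with
every draw flowing from one seeded NumPy generator (identical seed ⇒
byte-identical files). Defaults are the emulated study conditions:

| parameter | default | rationale |
|---|---|---|
| subtype split | P(t(8;21)) = 62/87 | observed cohort composition |
| KIT-D816 prevalence | 16/62 t(8;21), 3/25 inv(16) | observed |
| diagnostic junction reads | Poisson, mean 1618 / 239 per 3M mapped | observed means |
| patient expression factor | mean-one log-normal, σ = 0.2 | matches the reported IQR spread without biasing the mean |
| mapped reads | Poisson, mean 3.0e6 | reported depth |
| residual fraction at CR | point mass 0.1 at 0, else log-uniform on [1e-5, 1e-1] | only negativity is reported; log-uniform exercises the full dynamic range |
| DNA depth | Poisson, mean 1645 | reported on-target coverage |
| per-base error | 8e-5, uniform over alternatives | reported error-rate scale |
| complete mutation clearance | P = 53/99 | observed clearance fraction |
| residual VAF ratio if not cleared | log-uniform on [1e-3, 0.138] | reproduces the reported 86.2–100% reduction range (mean ≈ 98.7%) |
| qPCR noise | Gaussian σ = 0.5 on the log reduction, floored at 5 logs | yields RNA-seq/qPCR correlation ≈ 0.75 on uncensored pairs, the concordance regime observed |
| hazards per risk group | exponential, calibrated so OS(2y) = 0.87/0.74/0.33 and CIF_rel(2y) = 0.13/0.42/0.67 with a shared non-relapse-mortality hazard of 0.02/y | reported group outcomes; the relapse hazard solves `λr/(λr+λd)·(1−e^{−2(λr+λd)}) = CIF(2)` |

Junction reads are Poisson given the expected count and are placed uniformly
over read positions spanning the breakpoint with at least `anchor` bases on
each side; filler reads are drawn uniformly from the two partner transcripts;
half of all reads are emitted reverse-complemented. Carrier allele counts are
`Binomial(depth, VAF)`; error reads appear only at non-carrier panel sites
(`Binomial(depth, error_rate)`), so complete clearance is observable — at
carrier sites the true VAF dominates the error scale by orders of magnitude.
Survival times for the OS endpoint and for the relapse/NRM competing pair
are drawn independently, with administrative censoring uniform on 3–10
years. Reference transcripts are random sequences and hotspot coordinates
are schematic placeholders; gene names are kept only for readability.

What the generator does **not** model — and hence what passing tests do not
show about real data: transcriptome-wide expression, splice isoforms and
breakpoint microhomology, indel/structural sequencing errors, paired-end
reads, GC/coverage bias, clonal hematopoiesis, correlation between mutation
clearance and fusion reduction within a patient, and dependence between the
OS and relapse endpoints.

## Problem sizes

Read-level analyses and tests run on scaled-down cohorts (10–16 patients,
20k mapped reads per sample, junction means 200/80) — the package's chosen
desk scale, at which discovery and counting behave identically to full depth
because every rule is per-read. Study-depth quantities (detection limits,
concordance, risk-group outcomes) are computed at the count level with the
full 3M-read / 1618- and 239-junction-read configuration. Monte-Carlo checks
use 500–2000 replicates with fixed seeds and 3·SE acceptance bands.

## Known limitations

* Gray's test uses the plug-in variance described above; for definitive
  inference on real cohorts, confirm borderline p-values with a reference
  implementation.
* The qPCR assay is reduced to "true log reduction + noise, floored" with an
  externally supplied positivity flag; standard curves and replicate
  structure are out of scope.
* The discovery search assumes the two partner transcripts are known (the
  CBF-AML setting); it is not a genome-wide fusion caller.
* `cohort_reduction_summary` averages reduction rates across mutations,
  ignoring within-patient correlation, as cohort-level summaries of this
  kind conventionally do.
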