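# cbfmrd

Measurable residual disease (MRD) tracking for core-binding-factor acute
myeloid leukemia (CBF-AML) from bulk RNA sequencing, with the survival
machinery to evaluate its prognostic value.

CBF-AML is driven by a fusion gene — *RUNX1-RUNX1T1* in t(8;21) AML,
*CBFB-MYH11* in inv(16) AML — so the canonical MRD marker is the fusion
transcript itself, classically measured by qPCR. This package implements
an RNA-seq alternative: find the patient-specific fusion breakpoint in the
diagnostic sample, count junction-spanning reads (reads crossing the
breakpoint) at diagnosis and at complete remission (CR), and report the
log<sub>10</sub> reduction of the normalized fusion transcript level. It also
tracks the allele burden of co-occurring somatic mutations from allele-count
tables, compares the RNA-seq calls with qPCR, and stratifies patients into
risk groups with a two-feature rule.

It is written for computational hematology / genomics researchers who want a
tested, seedable reference implementation of this workflow — including a
synthetic cohort generator with known ground truth, so every estimator can be
checked against the quantity it is supposed to recover.

## The quantities computed

For a sample with `j` junction-spanning reads among `M` mapped reads, the
normalized level is `RPM = j / M × 10⁶`. The MRD readout for a
diagnosis/remission pair is

```
log-reduction = log10( RPM_dx / RPM_cr )
```

When the remission sample has zero junction reads the reduction is only
bounded below, and the call is censored at the per-sample limit of detection

```
LOD = log10( j_dx × M_cr / M_dx )
```

— the deepest reduction at which one junction read is still expected. With
~1618 diagnostic junction reads per ~3M mapped reads (typical for
*RUNX1-RUNX1T1*) the LOD is ≈3 logs; with ~239 (typical for *CBFB-MYH11*)
it is ≈2 logs. Detection of a residual fraction follows Poisson sampling:
`P(detect) = 1 − exp(−j_dx·f·M_cr/M_dx)`.

Mutations are tracked by variant allele fraction `VAF = alt/(ref+alt)`;
a mutation is *completely cleared* when no remission read supports it and
*MC03-cleared* when its remission VAF < 0.3%.

Outcomes use the standard toolkit, implemented here and cross-checked
against lifelines/cmprsk: Kaplan–Meier with Greenwood variance, the K-group
log-rank test, Aalen–Johansen cumulative incidence with death-without-relapse
as a competing risk, Gray's subdistribution test, and univariate Cox
regression (Breslow ties). Risk stratification uses a two-split rule —
3-log reduction achieved → low risk; otherwise KIT-D816 mutated → high risk,
wild-type → intermediate — plus a minimal log-rank survival-tree inducer
that re-derives this structure from data.

## Worked example

```python
from cbfmrd.fusion_mrd import quantify, log_reduction, detection_limit

dx = quantify(1618, 3_010_000)            # diagnosis: 1618 junction reads / 3.01M
cr = quantify(2, 2_920_000, timepoint="CR")
call = log_reduction(dx, cr)
print(f"{call.log_reduction:.3f}", call.censored, call.achieved_3log)
# 2.895 False False
print(f"{detection_limit(dx, 2_920_000):.3f}")
# 3.196
```

Two remission junction reads against 537.5 RPM at diagnosis is a 2.9-log
reduction — measured, not censored, and short of the 3-log threshold. Had the
remission sample contained zero junction reads, the call would be reported as
"≥ 3.196" and would count as achieving the 3-log threshold, because the
detection limit itself exceeds 3 logs.

The end-to-end analysis lives in `analysis/` (numbered scripts: simulate →
fusion MRD → variant tracking → concordance → survival/risk). On the bundled
synthetic configuration they print, among other things:

```
breakpoints recovered exactly: 16/16
RNA-seq vs qPCR on 135 t(8;21) pairs: Pearson rho = 0.771 (68 uncensored pairs)
limit of detection, RUNX1-RUNX1T1: 3.196 logs (approximately 3-log reduction)
limit of detection, CBFB-MYH11: 2.365 logs (approximately 2-log reduction)
induced tree split order: ['achieved_3log', 'kit_d816']
```

i.e. split-read discovery recovers every planted breakpoint, the RNA-seq
reduction correlates strongly with the simulated qPCR measurement, and the
tree inducer re-derives the two-feature risk rule from outcome data alone.

A `cbfmrd` command exposes the same stages
(`simulate`, `discover`, `quantify`, `mrd`, `track`, `concord`, `risk`,
`surv`, `run-all`); see `cbfmrd --help`.

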