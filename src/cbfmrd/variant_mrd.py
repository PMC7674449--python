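"""Longitudinal tracking of somatic mutation allele burden.

Secondary lesions (SNVs and short indels) are tracked from diagnosis to
remission through their variant allele fraction (VAF).  A mutation is
*completely cleared* when no remission read supports the variant allele,
and *MC03-cleared* when its remission VAF falls strictly below 0.3%
(configurable).  Background "mutation-like" sequencing error is
estimated from remission samples of patients who did not carry the
mutation at diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VariantObservation",
    "VariantTrack",
    "ErrorRateEstimate",
    "compute_vaf",
    "track_variant",
    "cohort_reduction_summary",
    "estimate_background_error",
]

MC03_CUTOFF = 0.003


@dataclass
class VariantObservation:
    """Allele counts for one mutation in one sample (1-based position)."""

    patient_id: str
    sample_id: str
    timepoint: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("allele counts must be >= 0")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def vaf(self) -> float:
        return compute_vaf(self.ref_count, self.alt_count)

    def locus(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class VariantTrack:
    """Diagnosis-to-remission trajectory of one mutation."""

    dx: VariantObservation
    cr: VariantObservation
    reduction_rate: float       # 1 - vaf_cr / vaf_dx, in (-inf, 1]
    cleared_complete: bool      # no remission reads support the variant
    cleared_mc03: bool          # remission VAF strictly below the cutoff
    detectable_at_cr: bool
    mc03_cutoff: float = MC03_CUTOFF


@dataclass
class ErrorRateEstimate:
    """Background mutation-like error at one site, across non-carriers."""

    site: tuple[str, int, str, str]
    rates: np.ndarray           # per-sample alt fraction
    median: float
    iqr: tuple[float, float]


def compute_vaf(ref_count: int, alt_count: int) -> float:
    """Variant allele fraction alt / (ref + alt)."""
    depth = ref_count + alt_count
    if depth <= 0:
        raise ValueError("VAF undefined at zero depth")
    return alt_count / depth


def track_variant(dx: VariantObservation, cr: VariantObservation,
                  mc03_cutoff: float = MC03_CUTOFF) -> VariantTrack:
    """Fill reduction rate and clearance flags for one mutation.

    ``cleared_mc03`` uses a strict inequality (remission VAF < cutoff);
    ``cleared_complete`` requires zero remission alt reads and therefore
    implies ``cleared_mc03``.
    """
    if dx.locus() != cr.locus() or dx.patient_id != cr.patient_id:
        raise ValueError(
            f"mismatched locus or patient: {dx.patient_id}/{dx.locus()} vs "
            f"{cr.patient_id}/{cr.locus()}"
        )
    dx_vaf = dx.vaf
    if dx_vaf <= 0:
        raise ValueError("variant not present at diagnosis (dx VAF = 0)")
    cr_vaf = cr.vaf if cr.depth > 0 else 0.0
    return VariantTrack(
        dx=dx,
        cr=cr,
        reduction_rate=1.0 - cr_vaf / dx_vaf,
        cleared_complete=cr.alt_count == 0,
        cleared_mc03=cr_vaf < mc03_cutoff,
        detectable_at_cr=cr.alt_count >= 1,
        mc03_cutoff=mc03_cutoff,
    )


def cohort_reduction_summary(tracks) -> dict:
    """Cohort summary: mean/range of reduction, clearance and detection counts."""
    tracks = list(tracks)
    if not tracks:
        raise ValueError("empty track list")
    reds = np.array([t.reduction_rate for t in tracks])
    return {
        "n": len(tracks),
        "mean_reduction": float(reds.mean()),
        "reduction_range": (float(reds.min()), float(reds.max())),
        "n_cleared_complete": int(sum(t.cleared_complete for t in tracks)),
        "n_cleared_mc03": int(sum(t.cleared_mc03 for t in tracks)),
        "n_detectable_at_cr": int(sum(t.detectable_at_cr for t in tracks)),
    }


def estimate_background_error(non_carrier_cr_obs) -> ErrorRateEstimate:
    """Mutation-like error rate at a site from non-carrier remission samples.

    Takes the per-sample alt fraction across remission samples of
    patients lacking the mutation at diagnosis and summarizes with the
    median and interquartile range (linear-interpolation quantiles).
    """
    obs = [o for o in non_carrier_cr_obs if o.depth > 0]
    if not obs:
        raise ValueError("no non-carrier observations with positive depth")
    sites = {o.locus() for o in obs}
    if len(sites) > 1:
        raise ValueError(f"observations span multiple sites: {sorted(sites)}")
    rates = np.array([o.vaf for o in obs])
    q1, med, q3 = np.percentile(rates, [25, 50, 75])
    return ErrorRateEstimate(site=obs[0].locus(), rates=rates,
                             median=float(med), iqr=(float(q1), float(q3)))


def pooled_background_error(obs_by_site: dict) -> dict:
    """Two pooled summaries of mutation-like error across sites.

    ``pooled_pairs`` treats every (site, sample) alt fraction as one
    observation; ``pooled_site_medians`` first takes the per-site median.
    Both are reported because published summaries rarely say which
    pooling was used.
    """
    per_site = {site: estimate_background_error(obs) for site, obs in obs_by_site.items()}
    all_rates = np.concatenate([est.rates for est in per_site.values()])
    site_medians = np.array([est.median for est in per_site.values()])
    return {
        "per_site": per_site,
        "pooled_pairs_median": float(np.median(all_rates)),
        "pooled_pairs_iqr": tuple(np.percentile(all_rates, [25, 75]).tolist()),
        "pooled_pairs_mean": float(all_rates.mean()),
        "pooled_site_medians_median": float(np.median(site_medians)),
        "n_pairs": int(all_rates.size),
    }
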