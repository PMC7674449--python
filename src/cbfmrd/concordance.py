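"""RNA-seq vs qPCR concordance and mutation/fusion co-clearance patterns.

Relates the RNA-seq fusion-transcript log-reduction to the qPCR
reference assay (correlation and 2x2 diagnostic metrics at the 3-log
cut-off), and classifies each tracked mutation by the joint
detectability of the mutation and the fusion transcript at remission
into three clusters (plus an explicit discordant category).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

__all__ = [
    "ConcordancePair",
    "DiagnosticMetrics",
    "ClusterLabel",
    "pearson_correlation",
    "diagnostic_metrics",
    "assign_cluster",
]


@dataclass
class ConcordancePair:
    patient_id: str
    rnaseq_log_reduction: float
    qpcr_log_reduction: float
    rnaseq_detectable: bool
    qpcr_positive: bool
    rnaseq_censored: bool = False  # RNA-seq reduction is a >= LOD bound


@dataclass
class DiagnosticMetrics:
    """2x2 agreement of the RNA-seq 3-log call against the qPCR reference.

    Positive = residual disease (did NOT achieve the threshold
    reduction).  A metric whose denominator is zero is NaN and listed in
    ``undefined``.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    undefined: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


class ClusterLabel(str, Enum):
    """Joint remission detectability of mutation and fusion transcript."""

    CLUSTER1 = "cluster1"      # mutation detected, fusion detected
    CLUSTER2 = "cluster2"      # neither detected
    CLUSTER3 = "cluster3"      # mutation cleared, fusion still detected
    DISCORDANT = "discordant"  # mutation detected, fusion cleared


def pearson_correlation(x, y) -> float:
    """Sample Pearson correlation of two equal-length sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    return float(stats.pearsonr(x, y).statistic)


def correlation_from_pairs(pairs, impute_lod: bool = False) -> tuple[float, int]:
    """Pearson correlation of RNA-seq vs qPCR log-reductions.

    Censored RNA-seq values (zero remission junction reads) are excluded
    by default; with ``impute_lod`` they enter at their detection-limit
    bound.  Returns (rho, n_used).
    """
    use = [p for p in pairs if impute_lod or not p.rnaseq_censored]
    x = [p.rnaseq_log_reduction for p in use]
    y = [p.qpcr_log_reduction for p in use]
    return pearson_correlation(x, y), len(use)


def diagnostic_metrics(pairs, threshold_log: float = 3.0) -> DiagnosticMetrics:
    """2x2 table of RNA-seq MRD calls against the qPCR reference.

    The RNA-seq test is positive when the measured reduction is shallower
    than ``threshold_log``; the qPCR reference positive status is taken
    from the input flag.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty input")
    tp = fp = fn = tn = 0
    for p in pairs:
        test_pos = p.rnaseq_log_reduction < threshold_log
        if p.qpcr_positive and test_pos:
            tp += 1
        elif p.qpcr_positive:
            fn += 1
        elif test_pos:
            fp += 1
        else:
            tn += 1
    undefined = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    return DiagnosticMetrics(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        ppv=ratio(tp, tp + fp, "ppv"),
        npv=ratio(tn, tn + fn, "npv"),
        undefined=tuple(undefined),
    )


def assign_cluster(mutation_detectable_at_cr: bool,
                   fusion_detectable_at_cr: bool) -> ClusterLabel:
    """Cluster by joint remission detectability (mutation, fusion).

    (True, True) -> cluster 1; (False, False) -> cluster 2;
    (False, True) -> cluster 3; the remaining combination (mutation
    persisting while the fusion cleared) is reported as discordant
    rather than dropped.
    """
    if mutation_detectable_at_cr is None or fusion_detectable_at_cr is None:
        raise ValueError("both detectability flags must be resolved")
    if mutation_detectable_at_cr and fusion_detectable_at_cr:
        return ClusterLabel.CLUSTER1
    if not mutation_detectable_at_cr and not fusion_detectable_at_cr:
        return ClusterLabel.CLUSTER2
    if not mutation_detectable_at_cr:
        return ClusterLabel.CLUSTER3
    return ClusterLabel.DISCORDANT
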