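"""Patient-specific fusion-junction discovery and MRD quantification.

The subtype-defining fusion transcripts of core-binding-factor AML
(RUNX1-RUNX1T1 in t(8;21), CBFB-MYH11 in inv(16)) are expressed at
diagnosis and tracked at remission by counting junction-spanning reads:
reads that cross the patient-specific breakpoint and therefore carry
sequence from both partner genes.

Workflow:

1. :func:`discover_junction` finds the breakpoint from diagnostic reads
   by a seed-and-extend split-read search against the two partner
   transcript references.
2. :func:`count_junction_reads` counts reads containing the junction
   k-mer (default 16 bases, 8 on each side of the join) with at most one
   mismatch, on either strand.
3. :func:`quantify` normalizes to reads-per-million (RPM) and
   :func:`log_reduction` converts a diagnosis/remission pair into an MRD
   call with censoring at the per-sample limit of detection when no
   junction read is seen at remission.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FusionJunction",
    "JunctionQuant",
    "MRDCall",
    "NoJunctionFoundError",
    "discover_junction",
    "count_junction_reads",
    "quantify",
    "log_reduction",
    "detection_limit",
    "detection_probability",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class NoJunctionFoundError(ValueError):
    """Raised when no breakpoint reaches the required read support."""


def canonical_breakpoint(five_ref: str, three_ref: str, i: int, j: int) -> tuple[int, int]:
    """Canonical (leftmost) representation of a breakpoint.

    When ``five_ref[i-1] == three_ref[j-1]`` the breakpoints (i, j) and
    (i-1, j-1) describe the same fusion transcript; the minimal pair is
    the canonical form.
    """
    while i > 0 and j > 0 and five_ref[i - 1] == three_ref[j - 1]:
        i -= 1
        j -= 1
    return i, j


@dataclass
class FusionJunction:
    """A patient-specific fusion breakpoint.

    Coordinates are 0-based offsets into the provided transcript
    references: breakpoint ``(i, j)`` means the fusion transcript is
    ``five_ref[:i] + three_ref[j:]``.  ``junction_kmer`` concatenates the
    last k/2 bases of the 5' context with the first k/2 bases of the 3'
    context and is the tracking probe used at remission.
    """

    patient_id: str
    five_prime_gene: str
    three_prime_gene: str
    five_context: str
    three_context: str
    breakpoint: tuple[int, int]
    support: int
    k: int = 16

    def __post_init__(self) -> None:
        if self.k % 2 != 0:
            raise ValueError("junction k-mer length must be even")
        if len(self.five_context) < self.k // 2 or len(self.three_context) < self.k // 2:
            raise ValueError("contexts must each provide at least k/2 bases")

    @property
    def junction_kmer(self) -> str:
        h = self.k // 2
        return self.five_context[-h:] + self.three_context[:h]


@dataclass
class JunctionQuant:
    """Junction read count for one sample with per-million normalization."""

    sample_id: str
    timepoint: str  # diagnosis | CR | relapse
    junction_reads: int
    mapped_reads: int

    def __post_init__(self) -> None:
        if self.mapped_reads <= 0:
            raise ValueError("mapped_reads must be > 0")
        if self.junction_reads < 0 or self.junction_reads > self.mapped_reads:
            raise ValueError("junction_reads must be in [0, mapped_reads]")

    @property
    def rpm(self) -> float:
        return self.junction_reads / self.mapped_reads * 1e6


@dataclass
class MRDCall:
    """Log10 reduction of the fusion transcript from diagnosis to remission.

    When the remission sample has zero junction reads the true reduction
    is only bounded below: ``censored`` is set and ``log_reduction``
    equals the per-sample limit of detection ``lod_log`` (report as
    ">= lod_log").  ``achieved_3log`` follows the categorical "3-log or
    deeper" usage: a censored call achieves it only if the detection
    limit itself reaches the threshold; otherwise the call is
    ``indeterminate`` and conservatively treated as not achieved.
    """

    patient_id: str
    log_reduction: float
    censored: bool
    lod_log: float
    achieved_3log: bool
    detectable_at_cr: bool
    indeterminate: bool = False
    threshold_log: float = 3.0

    def report(self) -> str:
        if self.censored:
            return f">= {self.log_reduction:.3f}"
        return f"{self.log_reduction:.3f}"


def _hamming_leq(a: str, b: str, limit: int) -> bool:
    """True if Hamming(a, b) <= limit (equal lengths assumed)."""
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


def discover_junction(
    dx_reads,
    five_ref: str,
    three_ref: str,
    *,
    patient_id: str = "",
    five_gene: str = "5p",
    three_gene: str = "3p",
    anchor: int = 10,
    min_support: int = 2,
    k: int = 16,
) -> FusionJunction:
    """Seed-and-extend split-read discovery of the fusion breakpoint.

    A read votes for breakpoint ``(i, j)`` when a prefix of >= ``anchor``
    bases matches ``five_ref`` exactly, ending at offset ``i``, and the
    remaining suffix (also >= ``anchor`` bases) matches ``three_ref``
    starting at offset ``j`` with at most one mismatch.  Both the read
    and its reverse complement are tried.  The modal ``(i, j)`` with at
    least ``min_support`` votes wins; ties are broken by support, then
    leftmost ``i``, then leftmost ``j``.
    """
    if anchor < 8:
        raise ValueError("anchor must be >= 8")
    if len(five_ref) < anchor or len(three_ref) < anchor:
        raise ValueError("references must each be >= anchor bases")

    five_ref = five_ref.upper()
    three_ref = three_ref.upper()
    # index exact anchor-mers of the 5' reference
    seed_index: dict[str, list[int]] = {}
    for p in range(len(five_ref) - anchor + 1):
        seed_index.setdefault(five_ref[p : p + anchor], []).append(p)

    votes: Counter[tuple[int, int]] = Counter()
    for raw in dx_reads:
        seq = str(raw).upper()
        for read in (seq, reverse_complement(seq)):
            if len(read) < 2 * anchor:
                continue
            seed = read[:anchor]
            for start in seed_index.get(seed, ()):
                # extend the exact 5' match as far as it goes
                p = anchor
                while (
                    p < len(read)
                    and start + p < len(five_ref)
                    and read[p] == five_ref[start + p]
                ):
                    p += 1
                i = start + p  # breakpoint offset in five_ref
                suffix = read[p:]
                if len(suffix) < anchor:
                    continue
                best = None  # (mismatches, j)
                for j in range(len(three_ref) - len(suffix) + 1):
                    window = three_ref[j : j + len(suffix)]
                    mism = sum(1 for x, y in zip(suffix, window) if x != y)
                    if mism <= 1 and (best is None or (mism, j) < best):
                        best = (mism, j)
                if best is not None:
                    votes[canonical_breakpoint(five_ref, three_ref, i, best[1])] += 1
                    break  # one vote per read orientation

    admissible = {bp: n for bp, n in votes.items() if n >= min_support}
    if not admissible:
        raise NoJunctionFoundError(
            f"no breakpoint reached min_support={min_support} "
            f"(best: {votes.most_common(1) or 'none'})"
        )
    top = max(admissible.values())
    ties = sorted(bp for bp, n in admissible.items() if n == top)
    if len(ties) > 1:
        logger.warning(
            "ambiguous modal breakpoint %s; resolved to leftmost %s", ties, ties[0]
        )
    i, j = ties[0]
    h = k // 2
    return FusionJunction(
        patient_id=patient_id,
        five_prime_gene=five_gene,
        three_prime_gene=three_gene,
        five_context=five_ref[max(0, i - max(h, anchor * 2)) : i],
        three_context=three_ref[j : j + max(h, anchor * 2)],
        breakpoint=(i, j),
        support=top,
        k=k,
    )


def _encode(reads: list[str], pad_to: int) -> np.ndarray:
    """Byte-encode reads into a padded uint8 matrix (pad byte never matches)."""
    buf = np.zeros((len(reads), pad_to), dtype=np.uint8)
    for r, read in enumerate(reads):
        b = np.frombuffer(read.encode("ascii"), dtype=np.uint8)[:pad_to]
        buf[r, : b.size] = b
    return buf


def count_junction_reads(reads, junction: FusionJunction, max_mismatch: int = 1) -> int:
    """Count reads containing the junction k-mer with <= max_mismatch.

    A read is counted when any window of length k matches the junction
    k-mer with at most ``max_mismatch`` substitutions, on the given or
    reverse-complemented strand; a full-k-mer match guarantees k/2 bases
    of overhang on each side of the join.  Each read counts at most once.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    kmer = junction.junction_kmer.upper()
    k = len(kmer)
    seqs = [str(r).upper() for r in reads]
    if not seqs:
        return 0
    max_len = max(len(s) for s in seqs)
    if max_len < k:
        return 0
    target = np.frombuffer(kmer.encode("ascii"), dtype=np.uint8)
    count_hit = np.zeros(len(seqs), dtype=bool)
    for strand in range(2):
        mat = _encode(seqs, max_len)
        hit = np.zeros(len(seqs), dtype=bool)
        for off in range(max_len - k + 1):
            mism = np.count_nonzero(mat[:, off : off + k] != target, axis=1)
            hit |= mism <= max_mismatch
        count_hit |= hit
        seqs = [reverse_complement(s) for s in seqs]
    return int(count_hit.sum())


def quantify(junction_reads: int, mapped_reads: int, *, sample_id: str = "",
             timepoint: str = "diagnosis") -> JunctionQuant:
    """Wrap a junction read count with per-million normalization."""
    return JunctionQuant(sample_id=sample_id, timepoint=timepoint,
                         junction_reads=junction_reads, mapped_reads=mapped_reads)


def detection_limit(dx: JunctionQuant, cr_mapped: int) -> float:
    """Per-sample limit of detection, in log10 reduction units.

    The deepest log-reduction at which one junction read is still
    expected at remission: log10(dx_junction_reads * cr_mapped /
    dx_mapped).  The integer-log summary is ``floor`` of this value.
    """
    if dx.junction_reads <= 0:
        raise ValueError("fusion not quantifiable at diagnosis (zero junction reads)")
    if cr_mapped <= 0:
        raise ValueError("cr_mapped must be > 0")
    return math.log10(dx.junction_reads * cr_mapped / dx.mapped_reads)


def log_reduction(dx: JunctionQuant, cr: JunctionQuant, *,
                  threshold_log: float = 3.0, patient_id: str = "") -> MRDCall:
    """MRD call from a diagnosis/remission quantification pair.

    With remission junction reads present the reduction is
    log10(dx.rpm / cr.rpm); with zero remission reads the reduction is
    censored at the limit of detection.
    """
    if dx.junction_reads <= 0:
        raise ValueError("fusion not quantifiable at diagnosis (zero junction reads)")
    lod = detection_limit(dx, cr.mapped_reads)
    if cr.junction_reads > 0:
        red = math.log10(dx.rpm / cr.rpm)
        return MRDCall(patient_id=patient_id, log_reduction=red, censored=False,
                       lod_log=lod, achieved_3log=red >= threshold_log,
                       detectable_at_cr=True, threshold_log=threshold_log)
    indeterminate = lod < threshold_log
    if indeterminate:
        logger.warning(
            "patient %s: zero remission junction reads but LOD %.3f < %.1f-log; "
            "call is indeterminate and treated as not achieved",
            patient_id or "?", lod, threshold_log,
        )
    return MRDCall(patient_id=patient_id, log_reduction=lod, censored=True,
                   lod_log=lod, achieved_3log=not indeterminate,
                   detectable_at_cr=False, indeterminate=indeterminate,
                   threshold_log=threshold_log)


def detection_probability(expected_cr_reads: float) -> float:
    """P(>=1 junction read) under Poisson sampling: 1 - exp(-rate)."""
    if expected_cr_reads < 0:
        raise ValueError("rate must be >= 0")
    return 1.0 - math.exp(-expected_cr_reads)
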