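"""Synthetic CBF-AML cohort generator with known ground truth.

Generates everything the analysis consumes — diagnostic and remission
read sets (FASTQ), partner-transcript references (FASTA), per-mutation
allele-count tables, qPCR measurements, and clinical outcomes — from a
single seeded RNG, and returns the generating truth so recovery can be
tested.

The defaults emulate the statistical structure of a real tracking study
of core-binding-factor AML: ~1618 junction-spanning reads per ~3M mapped
reads at diagnosis for RUNX1-RUNX1T1 and ~239 for CBFB-MYH11, remission
residual fusion fractions spanning 0 to 1e-1, ~1645x DNA coverage,
per-site background error around 8e-5, qPCR measurements correlated with
the true reduction, and exponential survival hazards per risk group
calibrated to 2-year OS of 87/74/33% and 2-year relapse incidence of
13/42/67%.

All genomic coordinates and reference sequences here are synthetic
(schematic hotspot panel, random transcript sequences); they carry real
gene names only to make outputs readable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .risk_model import classify_patient

__all__ = ["SimConfig", "GroundTruth", "simulate_cohort", "simulate_dilution_series",
           "draw_patients", "HOTSPOT_PANEL"]

SUBTYPES = ("t821", "inv16")
FUSION_GENES = {"t821": ("RUNX1", "RUNX1T1"), "inv16": ("CBFB", "MYH11")}

# Schematic (synthetic) hotspot panel: gene, chrom, pos, ref, alt.
# KIT-D816 is the prognostic hotspot; the rest are recurrently mutated
# genes in CBF-AML.  Coordinates are placeholders, not real genome
# positions.
HOTSPOT_PANEL: list[tuple[str, str, int, str, str]] = [
    ("KIT", "chr4", 55599321, "A", "T"),      # D816
    ("NRAS", "chr1", 114716126, "C", "T"),
    ("KRAS", "chr12", 25245350, "C", "T"),
    ("ASXL2", "chr2", 25741748, "G", "A"),
    ("TET2", "chr4", 105235942, "C", "T"),
    ("FLT3", "chr13", 28034147, "T", "A"),
    ("CBL", "chr11", 119278871, "G", "A"),
    ("JAK3", "chr19", 17834058, "G", "A"),
    ("U2AF1", "chr21", 43104346, "G", "A"),
    ("ZBTB7A", "chr19", 4045215, "C", "A"),
]
KIT_D816_SITE = HOTSPOT_PANEL[0]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _solve_relapse_hazard(cir2: float, nrm_hazard: float) -> float:
    """Cause-specific relapse hazard giving CIF_relapse(2y) = cir2.

    With exponential cause-specific hazards (lr, ld):
    CIF_rel(t) = lr/(lr+ld) * (1 - exp(-(lr+ld) t)).
    """

    def f(lr: float) -> float:
        tot = lr + nrm_hazard
        return lr / tot * (1 - math.exp(-2 * tot)) - cir2

    return brentq(f, 1e-6, 10.0)


def _default_hazards() -> dict:
    """Exponential hazards per risk group from the published 2-year rates."""
    os2 = {"low": 0.87, "intermediate": 0.74, "high": 0.33}
    cir2 = {"low": 0.13, "intermediate": 0.42, "high": 0.67}
    nrm = 0.02  # small group-independent non-relapse mortality hazard
    return {
        g: {
            "os": -math.log(os2[g]) / 2.0,
            "relapse": _solve_relapse_hazard(cir2[g], nrm),
            "nrm": nrm,
        }
        for g in os2
    }


@dataclass
class SimConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_patients: int = 42
    subtype_prob: float = 62 / 87          # P(t(8;21)) vs inv(16)
    kit_d816_prob: dict = field(
        default_factory=lambda: {"t821": 16 / 62, "inv16": 3 / 25})
    dx_junction_mean: dict = field(
        default_factory=lambda: {"t821": 1618.0, "inv16": 239.0})
    mapped_reads_mean: float = 3.0e6
    expression_log_sd: float = 0.2         # mean-one lognormal patient factor
    residual_zero_prob: float = 0.1        # point mass of true fraction 0 at CR
    residual_log_range: tuple = (1e-5, 1e-1)  # log-uniform support otherwise
    dna_depth: float = 1645.0
    error_rate: float = 8e-5               # per-base substitution rate
    clearance_prob: float = 53 / 99        # P(complete mutation clearance at CR)
    mutation_residual_range: tuple = (1e-3, 0.138)  # vaf_cr/vaf_dx if not cleared
    mutations_per_patient_mean: float = 2.0
    qpcr_noise_sd: float = 0.5             # Gaussian noise on log10 reduction
    qpcr_floor_log: float = 5.0            # assay limit (censoring floor)
    hazard_by_group: dict = field(default_factory=_default_hazards)
    followup_years: tuple = (3.0, 10.0)    # administrative censoring window
    read_length: int = 100
    anchor: int = 10
    ref_length: int = 1500
    threshold_log: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.read_length < 2 * self.anchor:
            raise ValueError("read_length must be >= 2 * anchor")
        for p in (self.subtype_prob, self.residual_zero_prob, self.clearance_prob,
                  *self.kit_d816_prob.values()):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0,1]: {p}")
        for m in (self.mapped_reads_mean, self.dna_depth,
                  *self.dx_junction_mean.values()):
            if m <= 0:
                raise ValueError("means must be > 0")
        lo, hi = self.residual_log_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("residual_log_range must satisfy 0 < lo <= hi <= 1")


@dataclass
class GroundTruth:
    """Per-patient and per-mutation generating truth."""

    patients: pd.DataFrame   # one row per patient
    mutations: pd.DataFrame  # one row per carried mutation

    def risk_groups_consistent(self, threshold_log: float = 3.0) -> bool:
        """Re-apply the two-feature rule to the stored truth."""
        for _, row in self.patients.iterrows():
            achieved = _true_achieved(row["residual_fraction"], threshold_log)
            if classify_patient(achieved, bool(row["kit_d816"])).value != row["risk_group"]:
                return False
        return True


def _true_achieved(fraction: float, threshold_log: float) -> bool:
    return fraction == 0.0 or -math.log10(fraction) >= threshold_log


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, reads: np.ndarray, error_rate: float) -> None:
    """Apply independent per-base substitutions in place (uint8 matrix)."""
    if error_rate <= 0:
        return
    mask = rng.random(reads.shape) < error_rate
    if not mask.any():
        return
    # uniform over the three alternative bases
    idx = np.nonzero(mask)
    current = reads[idx]
    shift = rng.integers(1, 4, size=current.size)
    base_idx = np.searchsorted(_BASES, current)  # ACGT are sorted by byte value
    reads[idx] = _BASES[(base_idx + shift) % 4]


def draw_patients(config: SimConfig, rng: np.random.Generator) -> GroundTruth:
    """Draw all per-patient scalar truth (no reads).

    This is the single source of the cohort's stochastic structure; the
    file-emitting :func:`simulate_cohort` consumes it, so count-level
    recovery tests exercise the same code path as the full pipeline.
    """
    rows, mut_rows = [], []
    lo, hi = config.residual_log_range
    panel_wo_kit = [s for s in HOTSPOT_PANEL if s != KIT_D816_SITE]
    for p in range(config.n_patients):
        pid = f"P{p + 1:03d}"
        subtype = "t821" if rng.random() < config.subtype_prob else "inv16"
        kit = bool(rng.random() < config.kit_d816_prob[subtype])
        expr = float(np.exp(rng.normal(-config.expression_log_sd ** 2 / 2,
                                       config.expression_log_sd)))
        if rng.random() < config.residual_zero_prob:
            fraction = 0.0
        else:
            fraction = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        n_dx = max(int(rng.poisson(config.mapped_reads_mean)), 1)
        n_cr = max(int(rng.poisson(config.mapped_reads_mean)), 1)
        mean_j = config.dx_junction_mean[subtype] * expr
        j_dx = int(rng.poisson(mean_j * n_dx / config.mapped_reads_mean))
        j_cr = int(rng.poisson(mean_j * fraction * n_cr / config.mapped_reads_mean))

        # breakpoint offsets into the two reference transcripts
        bp_i = int(rng.integers(config.ref_length // 3, 2 * config.ref_length // 3))
        bp_j = int(rng.integers(config.ref_length // 3, 2 * config.ref_length // 3))

        # clinical truth: the two-feature rule applied to true reduction
        achieved = _true_achieved(fraction, config.threshold_log)
        group = classify_patient(achieved, kit).value
        hz = config.hazard_by_group[group]
        censor = rng.uniform(*config.followup_years)
        death = rng.exponential(1.0 / hz["os"])
        os_years = min(death, censor)
        os_event = int(death <= censor)
        t_rel = rng.exponential(1.0 / hz["relapse"])
        t_nrm = rng.exponential(1.0 / hz["nrm"])
        first = min(t_rel, t_nrm, censor)
        event_type = 0 if first == censor else (1 if t_rel <= t_nrm else 2)

        # qPCR measurement of the true log reduction (t(8;21) assay only)
        if subtype == "t821":
            true_red = math.inf if fraction == 0 else -math.log10(fraction)
            measured = min(true_red, config.qpcr_floor_log) + rng.normal(
                0.0, config.qpcr_noise_sd)
            qpcr = float(min(max(measured, 0.0), config.qpcr_floor_log))
            qpcr_pos = bool(qpcr < config.qpcr_floor_log)
        else:
            qpcr, qpcr_pos = math.nan, False

        # somatic mutations carried at diagnosis
        n_mut = int(rng.poisson(config.mutations_per_patient_mean))
        sites = []
        if kit:
            sites.append(KIT_D816_SITE)
        extra = rng.choice(len(panel_wo_kit), size=min(n_mut, len(panel_wo_kit)),
                           replace=False)
        sites.extend(panel_wo_kit[i] for i in extra)
        for gene, chrom, pos, ref, alt in sites:
            if gene == "KIT":
                vaf_dx = float(rng.uniform(0.208, 0.464))
            else:
                vaf_dx = float(rng.uniform(0.05, 0.50))
            if rng.random() < config.clearance_prob:
                vaf_cr = 0.0
            else:
                rlo, rhi = config.mutation_residual_range
                vaf_cr = vaf_dx * float(np.exp(rng.uniform(np.log(rlo), np.log(rhi))))
            mut_rows.append(dict(patient_id=pid, gene=gene, chrom=chrom, pos=pos,
                                 ref=ref, alt=alt, vaf_dx=vaf_dx, vaf_cr=vaf_cr))

        rows.append(dict(
            patient_id=pid, subtype=subtype, kit_d816=kit,
            expression_factor=expr, residual_fraction=fraction,
            mapped_dx=n_dx, mapped_cr=n_cr, junction_dx=j_dx, junction_cr=j_cr,
            breakpoint_i=bp_i, breakpoint_j=bp_j,
            risk_group=group, os_years=os_years, os_event=os_event,
            relapse_years=first, event_type=event_type,
            qpcr_log_reduction=qpcr, qpcr_positive=qpcr_pos,
        ))
    return GroundTruth(patients=pd.DataFrame(rows), mutations=pd.DataFrame(mut_rows))


def _emit_sample_fastq(path: Path, rng: np.random.Generator, *, n_total: int,
                       n_junction: int, fusion: str, bp: int, partners: list[str],
                       read_length: int, anchor: int, error_rate: float) -> None:
    """Write one sample's reads: junction-spanning plus partner filler."""
    length = read_length
    starts_lo = max(bp - (length - anchor), 0)
    starts_hi = min(bp - anchor, len(fusion) - length)
    if starts_hi < starts_lo:
        raise ValueError("read_length too short to span the junction with anchors")
    reads = []
    for _ in range(n_junction):
        s = int(rng.integers(starts_lo, starts_hi + 1))
        reads.append(fusion[s : s + length])
    n_filler = n_total - n_junction
    for _ in range(n_filler):
        src = partners[int(rng.integers(0, len(partners)))]
        s = int(rng.integers(0, len(src) - length + 1))
        reads.append(src[s : s + length])
    mat = np.frombuffer("".join(reads).encode("ascii"), dtype=np.uint8).reshape(
        len(reads), length).copy()
    _mutate(rng, mat, error_rate)
    # half the reads on the reverse strand
    flip = rng.random(len(reads)) < 0.5
    qual = "I" * length
    with open(path, "w") as fh:
        for r in range(len(reads)):
            seq = mat[r].tobytes().decode("ascii")
            if flip[r]:
                seq = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            fh.write(f"@read{r}\n{seq}\n+\n{qual}\n")


def simulate_cohort(config: SimConfig, out_dir) -> GroundTruth:
    """Generate the full synthetic cohort on disk and return its truth.

    Writes, under ``out_dir``: ``refs.fasta`` (partner transcripts),
    ``reads/<patient>_{dx,cr}.fastq``, ``variants.tsv``, ``patients.tsv``,
    ``qpcr.tsv``, and ``truth_patients.tsv`` / ``truth_mutations.tsv``.
    Identical config (including seed) reproduces byte-identical files.
    """
    out = Path(out_dir)
    (out / "reads").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    refs = {}
    for subtype in SUBTYPES:
        for gene in FUSION_GENES[subtype]:
            refs[gene] = _random_seq(rng, config.ref_length)
    with open(out / "refs.fasta", "w") as fh:
        for gene in sorted(refs):
            fh.write(f">{gene}\n{refs[gene]}\n")

    truth = draw_patients(config, rng)

    # store breakpoints in canonical (leftmost-equivalent) form so that
    # discovery output is directly comparable to the planted truth
    from .fusion_mrd import canonical_breakpoint

    for idx, row in truth.patients.iterrows():
        five_gene, three_gene = FUSION_GENES[row["subtype"]]
        ci, cj = canonical_breakpoint(refs[five_gene], refs[three_gene],
                                      int(row["breakpoint_i"]), int(row["breakpoint_j"]))
        truth.patients.loc[idx, ["breakpoint_i", "breakpoint_j"]] = [ci, cj]

    for _, row in truth.patients.iterrows():
        five_gene, three_gene = FUSION_GENES[row["subtype"]]
        five, three = refs[five_gene], refs[three_gene]
        i, j = int(row["breakpoint_i"]), int(row["breakpoint_j"])
        fusion = five[:i] + three[j:]
        for tp, n_total, n_junc in (
            ("dx", int(row["mapped_dx"]), int(row["junction_dx"])),
            ("cr", int(row["mapped_cr"]), int(row["junction_cr"])),
        ):
            _emit_sample_fastq(
                out / "reads" / f"{row['patient_id']}_{tp}.fastq", rng,
                n_total=n_total, n_junction=n_junc, fusion=fusion, bp=i,
                partners=[five, three], read_length=config.read_length,
                anchor=config.anchor, error_rate=config.error_rate)

    _write_variants(out / "variants.tsv", config, rng, truth)
    _write_clinical(out, truth)
    truth.patients.to_csv(out / "truth_patients.tsv", sep="\t", index=False,
                          float_format="%.10g")
    truth.mutations.to_csv(out / "truth_mutations.tsv", sep="\t", index=False,
                           float_format="%.10g")
    return truth


def _write_variants(path: Path, config: SimConfig, rng: np.random.Generator,
                    truth: GroundTruth) -> None:
    """Allele-count table: carrier sites at dx and CR, full panel at CR.

    Carrier sites draw Binomial(depth, VAF); at non-carrier panel sites
    the alt reads are sequencing error, Binomial(depth, error_rate).
    """
    rows = []
    muts = truth.mutations
    for _, pat in truth.patients.iterrows():
        pid = pat["patient_id"]
        mine = muts[muts["patient_id"] == pid] if len(muts) else muts
        carried = set()
        for _, m in mine.iterrows():
            carried.add((m["chrom"], int(m["pos"])))
            for tp, vaf in (("diagnosis", m["vaf_dx"]), ("CR", m["vaf_cr"])):
                depth = max(int(rng.poisson(config.dna_depth)), 1)
                alt = int(rng.binomial(depth, min(vaf, 1.0)))
                rows.append(dict(patient_id=pid, sample_id=f"{pid}_{tp}",
                                 timepoint=tp, gene=m["gene"], chrom=m["chrom"],
                                 pos=int(m["pos"]), ref=m["ref"], alt=m["alt"],
                                 ref_count=depth - alt, alt_count=alt))
        for gene, chrom, pos, ref, alt_allele in HOTSPOT_PANEL:
            if (chrom, pos) in carried:
                continue
            depth = max(int(rng.poisson(config.dna_depth)), 1)
            alt = int(rng.binomial(depth, config.error_rate))
            rows.append(dict(patient_id=pid, sample_id=f"{pid}_CR",
                             timepoint="CR", gene=gene, chrom=chrom, pos=pos,
                             ref=ref, alt=alt_allele,
                             ref_count=depth - alt, alt_count=alt))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_clinical(out: Path, truth: GroundTruth) -> None:
    cols = ["patient_id", "subtype", "kit_d816", "qpcr_log_reduction",
            "os_years", "os_event", "relapse_years", "event_type"]
    pat = truth.patients[cols].copy()
    pat.to_csv(out / "patients.tsv", sep="\t", index=False, float_format="%.10g",
               na_rep=".")
    q = truth.patients[truth.patients["subtype"] == "t821"][
        ["patient_id", "qpcr_log_reduction", "qpcr_positive"]]
    q.to_csv(out / "qpcr.tsv", sep="\t", index=False, float_format="%.10g")


def simulate_dilution_series(dx_reads: float, fractions, replicates: int,
                             seed: int) -> pd.DataFrame:
    """Monte-Carlo detection table for an in-silico dilution series.

    For each residual fraction, draws ``replicates`` Poisson remission
    junction-read counts with mean ``dx_reads * fraction`` and reports
    the proportion of replicates with at least one read, with its
    Monte-Carlo standard error.
    """
    fractions = list(fractions)
    if not fractions:
        raise ValueError("empty fraction list")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if any(f < 0 or f > 1 for f in fractions):
        raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for f in fractions:
        rate = dx_reads * f
        detected = rng.poisson(rate, size=replicates) >= 1 if rate > 0 else np.zeros(
            replicates, dtype=bool)
        p = float(detected.mean())
        rows.append(dict(fraction=f, expected_reads=rate, detection_proportion=p,
                         mc_se=math.sqrt(p * (1 - p) / replicates),
                         replicates=replicates))
    return pd.DataFrame(rows)
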