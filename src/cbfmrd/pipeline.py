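"""End-to-end pipeline: discover -> quantify -> MRD -> track -> concord -> risk.

Each stage is a plain function over in-memory tables so the analysis
drivers and the CLI share one code path; :func:`run_pipeline` wires them
together on files, writes every output table plus a human-readable
report, and removes partial outputs if any stage fails.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .concordance import (ConcordancePair, assign_cluster, correlation_from_pairs,
                          diagnostic_metrics)
from .fusion_mrd import (FusionJunction, MRDCall, count_junction_reads,
                         discover_junction, log_reduction, quantify)
from .risk_model import classify_patient, group_outcomes
from .synthetic_cohort import FUSION_GENES
from .variant_mrd import (VariantObservation, cohort_reduction_summary,
                          pooled_background_error, track_variant)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "stage_fusion", "stage_variants", "stage_concordance",
           "stage_risk"]


def stage_fusion(refs: dict, reads_dir, patients: pd.DataFrame, *, k: int = 16,
                 anchor: int = 10, min_support: int = 2, max_mismatch: int = 1,
                 threshold_log: float = 3.0):
    """Per-patient junction discovery, counting, and MRD calls.

    Expects ``<patient_id>_dx.fastq`` and ``<patient_id>_cr.fastq`` under
    ``reads_dir``; mapped-read totals are the read counts of each file.
    Returns (junctions, quant, mrd) DataFrames plus the MRDCall objects.
    """
    reads_dir = Path(reads_dir)
    j_rows, q_rows, m_rows = [], [], []
    calls: dict[str, MRDCall] = {}
    for _, pat in patients.iterrows():
        pid = pat["patient_id"]
        five_gene, three_gene = FUSION_GENES[pat["subtype"]]
        dx_reads = [s for _, s in cio.read_fastq(reads_dir / f"{pid}_dx.fastq")]
        cr_reads = [s for _, s in cio.read_fastq(reads_dir / f"{pid}_cr.fastq")]
        junction = discover_junction(
            dx_reads, refs[five_gene], refs[three_gene], patient_id=pid,
            five_gene=five_gene, three_gene=three_gene, anchor=anchor,
            min_support=min_support, k=k)
        j_rows.append(dict(patient_id=pid, five_prime_gene=five_gene,
                           three_prime_gene=three_gene, i=junction.breakpoint[0],
                           j=junction.breakpoint[1], kmer=junction.junction_kmer,
                           support=junction.support))
        dx_q = quantify(count_junction_reads(dx_reads, junction, max_mismatch),
                        len(dx_reads), sample_id=f"{pid}_dx", timepoint="diagnosis")
        cr_q = quantify(count_junction_reads(cr_reads, junction, max_mismatch),
                        len(cr_reads), sample_id=f"{pid}_cr", timepoint="CR")
        for q in (dx_q, cr_q):
            q_rows.append(dict(sample_id=q.sample_id, timepoint=q.timepoint,
                               junction_reads=q.junction_reads,
                               mapped_reads=q.mapped_reads, rpm=q.rpm))
        call = log_reduction(dx_q, cr_q, threshold_log=threshold_log, patient_id=pid)
        calls[pid] = call
        m_rows.append(dict(patient_id=pid, log_reduction=call.log_reduction,
                           censored=call.censored, lod_log=call.lod_log,
                           achieved_3log=call.achieved_3log,
                           detectable_at_cr=call.detectable_at_cr,
                           indeterminate=call.indeterminate))
    return (pd.DataFrame(j_rows), pd.DataFrame(q_rows), pd.DataFrame(m_rows), calls)


def mrd_calls_from_counts(counts: pd.DataFrame, threshold_log: float = 3.0) -> pd.DataFrame:
    """MRD calls from a count-level table (no reads).

    ``counts`` needs columns patient_id, junction_dx, mapped_dx,
    junction_cr, mapped_cr — e.g. the truth table of the synthetic
    generator at full sequencing depth, where emitting FASTQ would be
    pointless.  Same call logic as the read-level path.
    """
    rows = []
    for _, r in counts.iterrows():
        if int(r["junction_dx"]) == 0:
            logger.warning("patient %s: fusion not quantifiable at diagnosis; skipped",
                           r["patient_id"])
            continue
        call = log_reduction(
            quantify(int(r["junction_dx"]), int(r["mapped_dx"])),
            quantify(int(r["junction_cr"]), int(r["mapped_cr"]), timepoint="CR"),
            threshold_log=threshold_log, patient_id=str(r["patient_id"]))
        rows.append(dict(patient_id=r["patient_id"],
                         log_reduction=call.log_reduction, censored=call.censored,
                         lod_log=call.lod_log, achieved_3log=call.achieved_3log,
                         detectable_at_cr=call.detectable_at_cr,
                         indeterminate=call.indeterminate))
    return pd.DataFrame(rows)


def _obs_from_row(row) -> VariantObservation:
    return VariantObservation(
        patient_id=row["patient_id"], sample_id=row["sample_id"],
        timepoint=row["timepoint"], gene=row["gene"], chrom=row["chrom"],
        pos=int(row["pos"]), ref=row["ref"], alt=row["alt"],
        ref_count=int(row["ref_count"]), alt_count=int(row["alt_count"]))


def stage_variants(variants: pd.DataFrame, mc03_cutoff: float = 0.003):
    """Pair diagnosis/remission observations and track each mutation.

    Returns (tracks DataFrame, VariantTrack objects, background-error
    summary over non-carrier remission panel sites).
    """
    locus_cols = ["patient_id", "chrom", "pos", "ref", "alt"]
    dx = variants[variants["timepoint"] == "diagnosis"]
    cr = variants[variants["timepoint"] == "CR"]
    carriers = {tuple(r) for r in dx[locus_cols].itertuples(index=False)}

    tracks, rows = [], []
    for _, d in dx.iterrows():
        key = tuple(d[locus_cols])
        match = cr[(cr[locus_cols] == pd.Series(key, index=locus_cols)).all(axis=1)]
        if match.empty:
            logger.warning("no CR observation for %s %s:%s; skipped",
                           d["patient_id"], d["chrom"], d["pos"])
            continue
        tr = track_variant(_obs_from_row(d), _obs_from_row(match.iloc[0]),
                           mc03_cutoff=mc03_cutoff)
        tracks.append(tr)
        rows.append(dict(patient_id=d["patient_id"], gene=d["gene"],
                         chrom=d["chrom"], pos=int(d["pos"]), ref=d["ref"],
                         alt=d["alt"], vaf_dx=tr.dx.vaf, vaf_cr=tr.cr.vaf,
                         reduction_rate=tr.reduction_rate,
                         cleared_complete=tr.cleared_complete,
                         cleared_mc03=tr.cleared_mc03,
                         detectable_at_cr=tr.detectable_at_cr))

    # background error at panel sites from non-carrier remission samples
    by_site: dict = {}
    for _, r in cr.iterrows():
        if (r["patient_id"], r["chrom"], r["pos"], r["ref"], r["alt"]) in carriers:
            continue
        site = (r["chrom"], int(r["pos"]), r["ref"], r["alt"])
        by_site.setdefault(site, []).append(_obs_from_row(r))
    background = pooled_background_error(by_site) if by_site else None
    return pd.DataFrame(rows), tracks, background


def stage_concordance(mrd: pd.DataFrame, qpcr: pd.DataFrame,
                      threshold_log: float = 3.0, impute_lod: bool = False) -> dict:
    """Correlation and 2x2 diagnostic metrics of RNA-seq MRD against qPCR."""
    merged = mrd.merge(qpcr, on="patient_id", how="inner")
    pairs = [ConcordancePair(
        patient_id=r["patient_id"],
        rnaseq_log_reduction=float(r["log_reduction"]),
        qpcr_log_reduction=float(r["qpcr_log_reduction"]),
        rnaseq_detectable=bool(r["detectable_at_cr"]),
        qpcr_positive=bool(r["qpcr_positive"]),
        rnaseq_censored=bool(r["censored"]),
    ) for _, r in merged.iterrows() if not math.isnan(r["qpcr_log_reduction"])]
    try:
        rho, n_used = correlation_from_pairs(pairs, impute_lod=impute_lod)
    except ValueError as exc:
        # e.g. too few uncensored pairs at shallow sequencing depth
        logger.warning("correlation not computable (%s); reporting NaN", exc)
        rho, n_used = math.nan, 0
    dm = diagnostic_metrics(pairs, threshold_log=threshold_log)
    return {
        "pearson_rho": rho, "n_pairs_correlated": n_used, "n_pairs": len(pairs),
        "impute_lod": impute_lod,
        "table": {"tp": dm.tp, "fp": dm.fp, "fn": dm.fn, "tn": dm.tn},
        "sensitivity": dm.sensitivity, "specificity": dm.specificity,
        "ppv": dm.ppv, "npv": dm.npv, "undefined": list(dm.undefined),
    }


def stage_clusters(tracks_df: pd.DataFrame, mrd: pd.DataFrame) -> pd.DataFrame:
    """Attach the mutation/fusion co-clearance cluster to each track."""
    fusion_det = mrd.set_index("patient_id")["detectable_at_cr"].to_dict()
    out = tracks_df.copy()
    out["cluster"] = [
        assign_cluster(bool(r["detectable_at_cr"]),
                       bool(fusion_det[r["patient_id"]])).value
        if r["patient_id"] in fusion_det else "."
        for _, r in tracks_df.iterrows()]
    return out


def stage_risk(mrd: pd.DataFrame, patients: pd.DataFrame,
               horizon_years: float = 2.0, subtype: str | None = "t821"):
    """Assign risk groups and summarize per-group outcomes.

    The two-feature rule was built for t(8;21) AML, so outcome summaries
    default to that subtype; pass ``subtype=None`` to use all patients.
    """
    df = patients.merge(mrd[["patient_id", "achieved_3log"]], on="patient_id")
    if subtype is not None:
        df = df[df["subtype"] == subtype]
    if df.empty:
        raise ValueError("no patients left for risk stratification")
    groups = np.array([classify_patient(bool(a), bool(k)).value
                       for a, k in zip(df["achieved_3log"], df["kit_d816"])])
    risk_df = pd.DataFrame({"patient_id": df["patient_id"].values, "group": groups})
    summary = group_outcomes(groups, df["os_years"].values, df["os_event"].values,
                             df["relapse_years"].values, df["event_type"].values,
                             horizon_years=horizon_years)
    return risk_df, summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return None if math.isnan(obj) else float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(vars(obj))
    return obj


def run_pipeline(config: cio.PipelineConfig) -> dict:
    """Run every stage on the configured inputs and write all artifacts.

    Outputs under ``config.out_dir``: junctions.tsv, quant.tsv, mrd.tsv,
    tracks.tsv, metrics.json (absent when no qPCR table is configured),
    risk.tsv, summary.json, report.txt.  A stage failure removes partial
    outputs and re-raises with a stage tag.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        cio.write_tsv(df, out / name)
        written.append(out / name)

    stage = "load"
    try:
        refs = cio.read_fasta(config.refs_fasta)
        patients = cio.read_patients_table(config.patients_tsv)
        variants = cio.read_variants_table(config.variants_tsv)

        stage = "fusion"
        junctions, quant, mrd, _calls = stage_fusion(
            refs, config.reads_dir, patients, k=config.k, anchor=config.anchor,
            min_support=config.min_support, max_mismatch=config.max_mismatch,
            threshold_log=config.threshold_log)
        emit(junctions, "junctions.tsv")
        emit(quant, "quant.tsv")
        emit(mrd, "mrd.tsv")

        stage = "track"
        tracks_df, tracks, background = stage_variants(variants, config.mc03_cutoff)
        tracks_df = stage_clusters(tracks_df, mrd)
        emit(tracks_df, "tracks.tsv")
        reduction = cohort_reduction_summary(tracks) if tracks else None

        stage = "concord"
        metrics = None
        if config.qpcr_tsv and Path(config.qpcr_tsv).exists():
            qpcr = cio.read_qpcr_table(config.qpcr_tsv)
            metrics = stage_concordance(mrd, qpcr, threshold_log=config.threshold_log)
            (out / "metrics.json").write_text(
                json.dumps(_jsonable(metrics), indent=2))
            written.append(out / "metrics.json")
        else:
            logger.info("no qPCR table configured; concordance stage skipped")

        stage = "risk"
        risk_df, summary = stage_risk(mrd, patients,
                                      horizon_years=config.horizon_years)
        emit(risk_df, "risk.tsv")
        full = {
            "risk_summary": _jsonable(summary),
            "reduction_summary": _jsonable(reduction),
            "background_error": _jsonable(
                {k: v for k, v in (background or {}).items() if k != "per_site"}),
            "concordance": _jsonable(metrics),
        }
        (out / "summary.json").write_text(json.dumps(full, indent=2))
        written.append(out / "summary.json")

        stage = "report"
        report = _format_report(patients, mrd, reduction, metrics, summary)
        (out / "report.txt").write_text(report)
        written.append(out / "report.txt")
        return full
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc


def _format_report(patients, mrd, reduction, metrics, summary) -> str:
    lines = ["CBF-AML MRD pipeline report", "=" * 32, ""]
    lines.append(f"patients: {len(patients)}  "
                 f"(t(8;21): {(patients['subtype'] == 't821').sum()}, "
                 f"inv(16): {(patients['subtype'] == 'inv16').sum()})")
    det = mrd["detectable_at_cr"].sum()
    lines.append(f"fusion detectable at CR: {det}/{len(mrd)}")
    ach = mrd["achieved_3log"].sum()
    lines.append(f"achieved 3-log reduction: {ach}/{len(mrd)}")
    if reduction:
        lines.append(f"mutations tracked: {reduction['n']}; "
                     f"mean VAF reduction {100 * reduction['mean_reduction']:.1f}%; "
                     f"completely cleared {reduction['n_cleared_complete']}")
    if metrics:
        lines.append(f"RNA-seq vs qPCR: Pearson rho {metrics['pearson_rho']:.3f} "
                     f"(n={metrics['n_pairs_correlated']}); sensitivity "
                     f"{metrics['sensitivity']:.2f}, specificity "
                     f"{metrics['specificity']:.2f}")
    lines.append("")
    lines.append(f"risk groups at {summary['horizon_years']:.0f}y horizon:")
    for grp, vals in summary["groups"].items():
        lines.append(f"  {grp:<13} n={vals['n']:<4} OS {100 * vals['os']:.0f}%  "
                     f"CIR {100 * vals['cir']:.0f}%")
    tests = summary["tests"]
    if summary.get("tests_applicable") and tests.get("os_logrank") is not None:
        lines.append(f"  log-rank p = {tests['os_logrank'].p_value:.3g}; "
                     f"Gray p = "
                     f"{tests['cir_gray'].p_value:.3g}" if tests.get("cir_gray")
                     else f"  log-rank p = {tests['os_logrank'].p_value:.3g}")
    lines.append("")
    return "\n".join(lines)
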