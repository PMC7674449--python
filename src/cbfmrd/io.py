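"""Readers and writers for the pipeline's file formats.

FASTQ/FASTA parsing goes through Biopython; tabular inputs are TSV
(UTF-8, '.' for missing values) validated against the declared schemas
before anything downstream runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

__all__ = ["read_fastq", "read_fasta", "read_variants_table",
           "read_patients_table", "read_qpcr_table", "write_tsv",
           "PipelineConfig", "load_config"]


class SchemaError(ValueError):
    """A table failed schema validation."""


def read_fastq(path) -> list[tuple[str, str]]:
    """Read a 4-line-record FASTQ file into (id, sequence) pairs.

    Qualities are parsed (the format requires them) but not retained.
    Malformed records raise a ValueError naming the offending line.
    """
    reads: list[tuple[str, str]] = []
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, _qual = next(it)
            except StopIteration:
                break
            except ValueError as exc:
                line = 4 * len(reads) + 1
                raise ValueError(
                    f"{path}: malformed FASTQ record starting at line {line}: {exc}"
                ) from exc
            reads.append((title.split()[0], seq))
    if not reads:
        logger.warning("%s: empty FASTQ file", path)
    return reads


def read_fasta(path) -> dict[str, str]:
    with open(path) as fh:
        return {title.split()[0]: seq.upper() for title, seq in SimpleFastaParser(fh)}


_VARIANT_COLS = ["patient_id", "sample_id", "timepoint", "gene", "chrom", "pos",
                 "ref", "alt", "ref_count", "alt_count"]
_PATIENT_COLS = ["patient_id", "subtype", "kit_d816", "qpcr_log_reduction",
                 "os_years", "os_event", "relapse_years", "event_type"]
_QPCR_COLS = ["patient_id", "qpcr_log_reduction", "qpcr_positive"]


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=True)
    unknown = [c for c in df.columns if c not in required]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if unknown:
        raise SchemaError(f"{path}: unknown column(s) {unknown}")
    return df


def read_variants_table(path) -> pd.DataFrame:
    """Validated per-sample allele-count table (1-based positions)."""
    df = _read_tsv(path, _VARIANT_COLS)
    bad_pos = df.index[df["pos"] < 1]
    if len(bad_pos):
        raise SchemaError(f"{path}: pos must be 1-based (>=1); bad row(s) "
                          f"{[i + 2 for i in bad_pos.tolist()]}")
    bad_tp = df.index[~df["timepoint"].isin(["diagnosis", "CR", "relapse"])]
    if len(bad_tp):
        raise SchemaError(f"{path}: bad timepoint in row(s) "
                          f"{[i + 2 for i in bad_tp.tolist()]}")
    if (df[["ref_count", "alt_count"]] < 0).any().any():
        raise SchemaError(f"{path}: negative allele counts")
    key = ["patient_id", "sample_id", "chrom", "pos", "ref", "alt"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        rows = [i + 2 for i in df.index[dup].tolist()]
        raise SchemaError(f"{path}: duplicate (patient, sample, locus) keys in "
                          f"rows {rows}")
    return df


def read_patients_table(path) -> pd.DataFrame:
    """Validated clinical table (event codes 0/1/2, os_event 0/1)."""
    df = _read_tsv(path, _PATIENT_COLS)
    bad = df.index[~df["event_type"].isin([0, 1, 2])]
    if len(bad):
        raise SchemaError(f"{path}: event_type must be in {{0,1,2}}; bad row(s) "
                          f"{[i + 2 for i in bad.tolist()]}")
    bad = df.index[~df["os_event"].isin([0, 1])]
    if len(bad):
        raise SchemaError(f"{path}: os_event must be 0/1; bad row(s) "
                          f"{[i + 2 for i in bad.tolist()]}")
    dup = df.duplicated(subset=["patient_id"], keep=False)
    if dup.any():
        raise SchemaError(f"{path}: duplicate patient_id in rows "
                          f"{[i + 2 for i in df.index[dup].tolist()]}")
    df["kit_d816"] = df["kit_d816"].astype(bool)
    return df


def read_qpcr_table(path) -> pd.DataFrame:
    df = _read_tsv(path, _QPCR_COLS)
    df["qpcr_positive"] = df["qpcr_positive"].astype(bool)
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.6g")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (see ``load_config``)."""

    refs_fasta: str
    reads_dir: str
    variants_tsv: str
    patients_tsv: str
    out_dir: str
    qpcr_tsv: str | None = None
    k: int = 16
    anchor: int = 10
    min_support: int = 2
    max_mismatch: int = 1
    threshold_log: float = 3.0
    mc03_cutoff: float = 0.003
    horizon_years: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k % 2 != 0 or self.k < 8:
            raise ValueError("k must be even and >= 8")
        if self.anchor < 8:
            raise ValueError("anchor must be >= 8")
        if self.max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")
        if not 0 < self.mc03_cutoff < 1:
            raise ValueError("mc03_cutoff must be in (0, 1)")


def load_config(path) -> PipelineConfig:
    """Load a YAML key-value pipeline configuration; paths are resolved
    relative to the config file's directory."""
    base = Path(path).parent
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("refs_fasta", "reads_dir", "variants_tsv", "patients_tsv",
                "qpcr_tsv", "out_dir"):
        if raw.get(key):
            raw[key] = str((base / raw[key]).resolve())
    return PipelineConfig(**raw)
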