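#!/usr/bin/env python
"""Mutation allele-burden tracking from diagnosis to remission.

Pairs each diagnostic mutation with its remission observation, computes
VAF reduction and clearance calls, estimates the background
mutation-like error from non-carrier remission samples, and attaches the
mutation/fusion co-clearance cluster labels.
"""

import json
from pathlib import Path

import pandas as pd

from cbfmrd.io import read_variants_table, write_tsv
from cbfmrd.pipeline import stage_clusters, stage_variants
from cbfmrd.variant_mrd import cohort_reduction_summary

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    variants = read_variants_table(COHORT / "variants.tsv")
    tracks_df, tracks, background = stage_variants(variants)
    mrd = pd.read_csv(RESULTS / "mrd.tsv", sep="\t")
    tracks_df = stage_clusters(tracks_df, mrd)
    write_tsv(tracks_df, RESULTS / "tracks.tsv")

    s = cohort_reduction_summary(tracks)
    print(f"tracked {s['n']} mutations; mean reduction "
          f"{100 * s['mean_reduction']:.1f}% "
          f"(range {100 * s['reduction_range'][0]:.1f}-"
          f"{100 * s['reduction_range'][1]:.1f}%)")
    print(f"completely cleared: {s['n_cleared_complete']}; "
          f"MC03-cleared: {s['n_cleared_mc03']}; "
          f"detectable at CR: {s['n_detectable_at_cr']}")
    print("cluster counts:", tracks_df["cluster"].value_counts().to_dict())

    err = {k: v for k, v in background.items() if k != "per_site"}
    (RESULTS / "background_error.json").write_text(json.dumps(err, indent=2))
    print(f"background mutation-like error over {err['n_pairs']} "
          f"(site, sample) pairs: median {err['pooled_pairs_median']:.2e} "
          f"(IQR {err['pooled_pairs_iqr'][0]:.1e}-{err['pooled_pairs_iqr'][1]:.1e}), "
          f"mean {err['pooled_pairs_mean']:.2e}")
    print("note: at ~1645x a per-site error rate of 8e-5 leaves most "
          "site/sample pairs with zero error reads, so the per-pair median "
          "sits at 0 while the mean recovers the generating rate")


if __name__ == "__main__":
    main()
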