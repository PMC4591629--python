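#!/usr/bin/env python
"""Quantify allele-specific silencing per gene.

Reads the simulated variant table and gene models from disk (exercising
the TSV/BED boundary), runs the allelic workflow (biallelic 0.3-0.7
filter, minimum-experimental-read phasing, 0.15 outlier removal,
4-read gate), and writes per-gene summaries plus the per-site audit
trail.  Prints the most silenced genes and compares the estimates
against the simulator's ground truth.
"""

from pathlib import Path

import pandas as pd

from cisspread import summarize_regions
from cisspread.io import load_config, read_bed, read_variant_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def run(dataset: str) -> pd.DataFrame:
    d = RESULTS / dataset
    config = load_config(d / "config.yaml")
    variants = read_variant_table(d / "variants.tsv")
    regions = read_bed(d / "genes.bed",
                       integration_pos=config.sim.integration_pos)
    summaries, audit = summarize_regions(variants, regions)
    summaries.to_csv(d / "allelic_summary.tsv", sep="\t", index=False)
    audit.to_csv(d / "allelic_audit.tsv", sep="\t", index=False)
    return summaries


def main():
    summaries = run("synthetic")
    truth = pd.read_csv(RESULTS / "synthetic" / "ground_truth.tsv", sep="\t")
    merged = summaries.merge(truth, left_on="region_id", right_on="gene_id")
    ok = merged["passed_min_reads"]
    print(f"{ok.sum()} / {len(merged)} genes pass the 4-read gate")
    top = merged[ok].nlargest(5, "percent_allelic_silencing")
    print("\nmost silenced genes (estimate vs truth):")
    for g in top.itertuples(index=False):
        expected = 100 * (0.5 - (1 - g.s_true) / (2 - g.s_true)) / 0.5
        print(f"  {g.region_id}  {g.distance_to_integration_x / 1e6:+6.2f} Mb  "
              f"est {g.percent_allelic_silencing:5.1f} %  "
              f"(expected {expected:5.1f} % at s={g.s_true:.2f})")

    null_summaries = run("synthetic_null")
    nok = null_summaries["passed_min_reads"]
    rate = (null_summaries.loc[nok, "percent_allelic_silencing"].abs() > 30).mean()
    print(f"\ncontrol integration: {100 * rate:.1f} % of genes exceed "
          f"|30 %| apparent silencing (expected ~0)")


if __name__ == "__main__":
    main()
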