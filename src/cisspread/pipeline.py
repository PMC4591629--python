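"""End-to-end run: simulate -> allelic -> stats -> chip -> hic.

Every stage logs input/output record counts; each filter's attrition is
asserted to account exactly (records in = retained + removed).  All
randomness flows from the single config seed, and the JSON report carries
the seed and every threshold so a run is reproducible from the report
alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from cisspread import __version__
from cisspread import hic as chic
from cisspread import io as cio
from cisspread import simulate as sim
from cisspread import stats as cstats
from cisspread import windows as cwin
from cisspread.allelic import RegionOfInterest, summarize_regions

log = logging.getLogger("cisspread")

__all__ = ["run_pipeline", "regions_from_genes"]


def regions_from_genes(genes: pd.DataFrame, integration_pos: int) -> list[RegionOfInterest]:
    return [
        RegionOfInterest(g.gene_id, g.chrom, int(g.start), int(g.end), "gene",
                         g.strand, (g.start + g.end) / 2.0 - integration_pos)
        for g in genes.itertuples(index=False)
    ]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: cio.RunConfig, outdir) -> dict:
    """Execute the configured stages; returns (and writes) the run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {k: v for k, v in config.to_dict().items() if k != "sim"},
        "sim_params": {k: v for k, v in config.to_dict()["sim"].items()
                       if k != "k27me3_baseline_profile"},
        "stages": {},
    }
    data: dict = {}
    for stage in config.stages:
        try:
            handler = _STAGES[stage]
        except KeyError:
            raise StageError(stage, ValueError("unknown stage")) from None
        try:
            log.info("running stage %s", stage)
            report["stages"][stage] = handler(config, data, outdir)
        except Exception as exc:  # halt naming the failing stage
            raise StageError(stage, exc) from exc
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _stage_simulate(config, data, outdir):
    ds = sim.simulate_dataset(config.sim)
    data.update(ds)
    cio.write_variant_table(ds["counts"], outdir / "variants.tsv")
    cio.write_bed(ds["genes"], outdir / "genes.bed")
    truth = ds["truth"].genes[["gene_id", "s_true", "distance_to_integration"]]
    truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    ds["expression"].to_csv(outdir / "expression.tsv", sep="\t", index=False)
    chip = ds["chip"]
    for name, track in (("k27me3_ctrl", chip.k27me3_ctrl),
                        ("k27me3_exp", chip.k27me3_exp),
                        ("k27ac_ctrl", chip.k27ac_ctrl),
                        ("k27ac_exp", chip.k27ac_exp)):
        cio.write_bedgraph(track, outdir / f"{name}.bedGraph")
    cio.write_contact_matrix(
        chic.ContactMatrix(ds["hic"].chrom, ds["hic"].bin_size, ds["hic"].matrix),
        outdir / "hic_40kb.txt")
    return {"n_genes": len(ds["genes"]), "n_variants": len(ds["counts"]),
            "n_windows": chip.k27me3_ctrl.n_windows,
            "n_hic_bins": ds["hic"].matrix.shape[0]}


def _stage_allelic(config, data, outdir):
    counts, genes = data["counts"], data["genes"]
    regions = regions_from_genes(genes, config.sim.integration_pos)
    summaries, audit = summarize_regions(
        counts, regions, mode=config.mode,
        biallelic_low=config.biallelic_low, biallelic_high=config.biallelic_high,
        deviation=config.deviation, depth_fold=config.depth_fold)
    # attrition accounting: every assigned site is retained or rejected
    rejected = (audit["zero_total"] | ~audit["biallelic_pass"]
                | ~audit["depth_pass"] | audit["deviation_outlier"])
    assert int(rejected.sum()) + int(audit["retained"].sum()) == len(audit), \
        "attrition accounting failed"
    summaries.to_csv(outdir / "allelic_summary.tsv", sep="\t", index=False)
    audit.to_csv(outdir / "allelic_audit.tsv", sep="\t", index=False)
    data["summaries"] = summaries
    return {"n_regions": len(summaries),
            "n_site_assignments": len(audit),
            "n_sites_retained": int(audit["retained"].sum()),
            "n_sites_rejected": int(rejected.sum()),
            "n_regions_passing_gate": int(summaries["passed_min_reads"].sum())}


def _stage_stats(config, data, outdir):
    summaries = data["summaries"].merge(data["expression"],
                                        left_on="region_id", right_on="gene_id")
    gated = summaries[cstats.fpkm_gate(summaries["fpkm_ctrl"],
                                       summaries["fpkm_exp"], config.fpkm_min)]
    total_pct = 100.0 * (gated["fpkm_ctrl"] - gated["fpkm_exp"]) / gated["fpkm_ctrl"]
    in_band = (total_pct >= config.band_low) & (total_pct <= config.band_high)
    near = gated["distance_to_integration"].abs() <= config.near_distance
    prop = cstats.proportion_vs_genome(in_band[near], in_band[~near]) \
        if near.any() and (~near).any() else None

    allelic_ok = summaries["passed_min_reads"] & summaries[
        "percent_allelic_silencing"].notna()
    calls = summaries[allelic_ok]
    silenced = calls["percent_allelic_silencing"] > config.allelic_call_threshold
    decay = cstats.distance_decay_permutation_test(
        silenced.to_numpy(), calls["distance_to_integration"].to_numpy(),
        n_bins=config.n_distance_bins, n_perm=config.n_perm,
        seed=config.seed)
    out = gated.assign(percent_total_silencing=total_pct, in_band_30_60=in_band)
    out.to_csv(outdir / "silencing_calls.tsv", sep="\t", index=False)
    rep = {
        "n_genes_gated": len(gated),
        "n_in_band": int(in_band.sum()),
        "n_allelic_calls": len(calls),
        "n_allelic_silenced": int(silenced.sum()),
        "distance_decay": {"statistic": decay.statistic, "p_value": decay.p_value,
                           "n_perm": decay.n_perm,
                           "bin_silenced": decay.bin_silenced,
                           "bin_sizes": decay.bin_sizes},
    }
    if prop is not None:
        rep["proportion_vs_genome"] = {"statistic": prop.statistic,
                                       "p_value": prop.p_value,
                                       "table": prop.table}
    return rep


def _stage_chip(config, data, outdir):
    chip = data["chip"]
    p = config.sim
    ctrl = cwin.WindowTrack(p.chrom, p.chip_window_size,
                            cwin.cpm(chip.k27me3_ctrl.values), p.chrom_length)
    exp = cwin.WindowTrack(p.chrom, p.chip_window_size,
                           cwin.cpm(chip.k27me3_exp.values), p.chrom_length)
    arm_p = cwin.arm_change_summary(ctrl, exp, "p_arm", (0, p.centromere_pos))
    arm_q = cwin.arm_change_summary(ctrl, exp, "q_arm",
                                    (p.centromere_pos, p.chrom_length))
    whole = cwin.arm_change_summary(ctrl, exp, "chromosome")
    corr = cwin.baseline_gain_correlation(chip.k27me3_ctrl, chip.k27me3_exp,
                                          (0, p.centromere_pos))
    delta = cwin.WindowTrack(p.chrom, p.chip_window_size,
                             exp.values - ctrl.values, p.chrom_length)
    cio.write_bedgraph(delta, outdir / "k27me3_delta.bedGraph")
    def arm_dict(a):
        return {"scope": a.scope, "n_windows": a.n_windows,
                "mean_delta": a.mean_delta, "t": a.t_statistic, "p": a.p_value}
    return {"arms": [arm_dict(a) for a in (arm_p, arm_q, whole)],
            "baseline_gain_spearman": {"rho": corr.estimate, "p": corr.p_value,
                                       "n": corr.n}}


def _stage_hic(config, data, outdir):
    raw = data["hic"]
    cm40 = chic.ContactMatrix(raw.chrom, raw.bin_size, raw.matrix)
    cm1mb = chic.rebin(cm40)
    profile = chic.anchor_profile(cm1mb, config.sim.integration_pos)
    track = cwin.WindowTrack(cm1mb.chrom, cm1mb.bin_size, profile.values,
                             chrom_length=cm1mb.extent)
    cio.write_bedgraph(track, outdir / "anchor_profile.bedGraph")
    pd.DataFrame({"bin": np.arange(len(profile.values)),
                  "contacts": profile.values}).to_csv(
        outdir / "anchor_profile.tsv", sep="\t", index=False)
    assert abs(cm40.total_mass() - cm1mb.total_mass()) <= 1e-6 * max(
        cm40.total_mass(), 1.0), "rebin mass not conserved"
    return {"anchor_bin": profile.anchor_bin,
            "n_1mb_bins": cm1mb.n_bins,
            "total_mass": cm1mb.total_mass(),
            "diagonal_value": profile.diagonal_value}


_STAGES = {
    "simulate": _stage_simulate,
    "allelic": _stage_allelic,
    "stats": _stage_stats,
    "chip": _stage_chip,
    "hic": _stage_hic,
}
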