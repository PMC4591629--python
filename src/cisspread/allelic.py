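"""Allele-specific silencing workflow.

The workflow quantifies loss of expression of the transgene-linked (cis)
allele at heterozygous sites:

1. sites with zero allelic reads in either condition are excluded;
2. only sites with a biallelic control ratio in [0.3, 0.7] are kept
   (bounds inclusive);
3. each site is phased by designating the allele with fewer experimental
   reads as the cis (silenced) allele — ties designate allele a with a
   flag;
4. sites are pooled per region of interest (read-weighted by default);
   sites whose condition-specific ratio deviates from the pooled ratio by
   more than 0.15 in either condition are removed once and the pooled
   ratio recomputed (a single pass, not iterated);
5. for ChIP regions, sites whose total reads differ more than 2-fold from
   the region's per-condition mean are excluded first (single pass
   against the original mean);
6. regions need at least 4 (RNA) or 5 (ChIP) allelic reads in both
   conditions;
7. percent allelic silencing = (control ratio - experimental ratio) /
   control ratio * 100, where the ratio is the pooled frequency of the
   designated silenced allele.

Because the designated allele is chosen as the per-site minimum in the
experimental condition, the estimator carries a finite-depth selection
bias of order 1/sqrt(depth) toward positive silencing under the null; it
vanishes as depth grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegionOfInterest",
    "GeneAllelicSummary",
    "UndefinedRatioError",
    "allelic_ratio",
    "filter_biallelic",
    "phase_to_cis",
    "phase_sites",
    "aggregate_region",
    "filter_chip_depth",
    "min_read_gate",
    "percent_allelic_silencing",
    "summarize_regions",
    "MIN_ALLELIC_READS",
]

#: minimum pooled allelic reads per region, in both conditions
MIN_ALLELIC_READS = {"rna": 4, "chip": 5}

SITE_COLUMNS = ["chrom", "pos", "allele_a_id", "allele_b_id",
                "ctrl_a", "ctrl_b", "exp_a", "exp_b"]


class UndefinedRatioError(ValueError):
    """Allelic ratio requested for a site with zero total reads."""


@dataclass
class RegionOfInterest:
    """A gene or analysis window, 0-based half-open, with signed distance
    from its midpoint to the integration position (negative = upstream)."""

    id: str
    chrom: str
    start: int
    end: int
    kind: str = "gene"
    strand: str = "."
    distance_to_integration: float | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"region {self.id}: start must be < end")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class GeneAllelicSummary:
    """Aggregated allelic ratios and percent allelic silencing for one region."""

    region_id: str
    n_sites_initial: int
    n_sites_retained: int
    ctrl_allelic_ratio: float
    exp_allelic_ratio: float
    allelic_reads_ctrl: int
    allelic_reads_exp: int
    percent_allelic_silencing: float
    qc_flags: set[str] = field(default_factory=set)
    n_tie_sites: int = 0


def allelic_ratio(count_x: int, count_y: int) -> float:
    """Frequency of allele x, count_x / (count_x + count_y)."""
    total = count_x + count_y
    if total <= 0:
        raise UndefinedRatioError("allelic ratio undefined for zero total reads")
    return count_x / total


def filter_biallelic(sites: pd.DataFrame, low: float = 0.3, high: float = 0.7) -> pd.DataFrame:
    """Keep sites whose control allelic ratio lies in [low, high] (inclusive).

    The control ratio is the frequency of allele a; the interval is
    symmetric so the choice of reference allele does not matter.
    """
    total = sites["ctrl_a"] + sites["ctrl_b"]
    if (total <= 0).any():
        raise UndefinedRatioError("control ratio undefined for zero-total sites; "
                                  "exclude them first")
    ratio = sites["ctrl_a"] / total
    return sites[(ratio >= low) & (ratio <= high)]


def phase_to_cis(exp_a: int, exp_b: int) -> tuple[str, bool]:
    """Designate the silenced (cis) allele: the one with fewer experimental reads.

    Returns ("a" or "b", tie_flag); ties designate allele a deterministically.
    """
    if exp_a < exp_b:
        return "a", False
    if exp_b < exp_a:
        return "b", False
    return "a", True


def phase_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """Vectorized phasing; adds silenced-allele counts and totals per condition.

    Adds columns ``silenced_allele`` ("a"/"b"), ``tie``, ``sil_ctrl``,
    ``tot_ctrl``, ``sil_exp``, ``tot_exp``.
    """
    out = sites.copy()
    a_is_min = out["exp_a"].to_numpy() <= out["exp_b"].to_numpy()
    out["silenced_allele"] = np.where(a_is_min, "a", "b")
    out["tie"] = out["exp_a"].to_numpy() == out["exp_b"].to_numpy()
    out["sil_ctrl"] = np.where(a_is_min, out["ctrl_a"], out["ctrl_b"])
    out["tot_ctrl"] = out["ctrl_a"] + out["ctrl_b"]
    out["sil_exp"] = np.where(a_is_min, out["exp_a"], out["exp_b"])
    out["tot_exp"] = out["exp_a"] + out["exp_b"]
    return out


def _pool(sil: np.ndarray, tot: np.ndarray, pooling: str) -> float:
    if pooling == "read_weighted":
        return float(sil.sum() / tot.sum())
    if pooling == "mean_of_ratios":
        return float(np.mean(sil / tot))
    raise ValueError(f"unknown pooling {pooling!r}")


def aggregate_region(
    sites: pd.DataFrame,
    region: RegionOfInterest | str,
    *,
    deviation: float = 0.15,
    pooling: str = "read_weighted",
    deviation_scope: str = "both",
) -> tuple[GeneAllelicSummary, pd.DataFrame]:
    """Pool phased sites into a region summary with one outlier-removal pass.

    (i) pool the designated silenced-allele reads per condition; (ii) drop
    sites whose site ratio deviates from the pooled ratio by more than
    ``deviation`` (strictly) in any checked condition; (iii) recompute the
    pooled ratio once from the retained sites.  Returns the summary and
    the per-site table with a ``deviation_outlier`` column.
    """
    region_id = region if isinstance(region, str) else region.id
    n0 = len(sites)
    if n0 == 0:
        raise ValueError("aggregate_region requires at least one phased site")
    sil_c = sites["sil_ctrl"].to_numpy(dtype=float)
    tot_c = sites["tot_ctrl"].to_numpy(dtype=float)
    sil_e = sites["sil_exp"].to_numpy(dtype=float)
    tot_e = sites["tot_exp"].to_numpy(dtype=float)
    if (tot_c <= 0).any() or (tot_e <= 0).any():
        raise UndefinedRatioError("zero-total sites must be excluded before pooling")

    r_c, r_e = _pool(sil_c, tot_c, pooling), _pool(sil_e, tot_e, pooling)
    dev_c = np.abs(sil_c / tot_c - r_c)
    dev_e = np.abs(sil_e / tot_e - r_e)
    if deviation_scope == "both":
        outlier = (dev_c > deviation) | (dev_e > deviation)
    elif deviation_scope == "control":
        outlier = dev_c > deviation
    elif deviation_scope == "experimental":
        outlier = dev_e > deviation
    else:
        raise ValueError(f"unknown deviation_scope {deviation_scope!r}")

    audit = sites.copy()
    audit["deviation_outlier"] = outlier
    keep = ~outlier
    flags: set[str] = set()
    n_tie = int(sites["tie"].sum()) if "tie" in sites else 0
    if not keep.any():
        summary = GeneAllelicSummary(region_id, n0, 0, float("nan"), float("nan"),
                                     0, 0, float("nan"), {"all_sites_removed"}, n_tie)
        return summary, audit

    r_c = _pool(sil_c[keep], tot_c[keep], pooling)
    r_e = _pool(sil_e[keep], tot_e[keep], pooling)
    reads_c = int(tot_c[keep].sum())
    reads_e = int(tot_e[keep].sum())
    if r_c > 0:
        percent = percent_allelic_silencing(r_c, r_e)
    else:
        percent = float("nan")
        flags.add("undefined_control_ratio")
    summary = GeneAllelicSummary(region_id, n0, int(keep.sum()), r_c, r_e,
                                 reads_c, reads_e, percent, flags, n_tie)
    return summary, audit


def filter_chip_depth(sites: pd.DataFrame, fold: float = 2.0) -> pd.DataFrame:
    """ChIP-only depth filter: keep sites within ``fold`` of the region mean.

    Single pass against the original per-condition mean total reads; a site
    must satisfy mean/fold <= total <= mean*fold in both conditions.
    """
    if len(sites) == 0:
        return sites
    tot_c = (sites["ctrl_a"] + sites["ctrl_b"]).to_numpy(dtype=float)
    tot_e = (sites["exp_a"] + sites["exp_b"]).to_numpy(dtype=float)
    mean_c, mean_e = tot_c.mean(), tot_e.mean()
    keep = ((tot_c >= mean_c / fold) & (tot_c <= mean_c * fold)
            & (tot_e >= mean_e / fold) & (tot_e <= mean_e * fold))
    return sites[keep]


def min_read_gate(summary: GeneAllelicSummary, mode: str = "rna") -> bool:
    """Region passes iff pooled allelic reads meet the minimum in BOTH conditions."""
    threshold = MIN_ALLELIC_READS[mode]
    ok = (summary.allelic_reads_ctrl >= threshold
          and summary.allelic_reads_exp >= threshold)
    if not ok:
        summary.qc_flags.add("failed_min_reads")
    return ok


def percent_allelic_silencing(ctrl_ratio: float, exp_ratio: float) -> float:
    """(control ratio - experimental ratio) / control ratio * 100.

    May be negative (allelic gain).
    """
    if ctrl_ratio <= 0:
        raise UndefinedRatioError("percent silencing undefined for zero control ratio")
    return 100.0 * (ctrl_ratio - exp_ratio) / ctrl_ratio


def assign_sites(variants: pd.DataFrame, region: RegionOfInterest) -> pd.DataFrame:
    """Sites falling inside a region; 1-based positions vs half-open intervals.

    A variant at 1-based ``pos`` lies in [start, end) iff start < pos <= end.
    A variant overlapping several regions contributes to each.
    """
    pos = variants["pos"]
    mask = (variants["chrom"] == region.chrom) & (pos > region.start) & (pos <= region.end)
    return variants[mask]


def summarize_regions(
    variants: pd.DataFrame,
    regions: list[RegionOfInterest],
    mode: str = "rna",
    *,
    biallelic_low: float = 0.3,
    biallelic_high: float = 0.7,
    deviation: float = 0.15,
    depth_fold: float = 2.0,
    pooling: str = "read_weighted",
    deviation_scope: str = "both",
    with_audit: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full allelic workflow over a variant table and regions.

    Returns (summaries, audit): one summary row per region and one audit
    row per site-region assignment recording every filter decision.
    Attrition is accounted exactly: assigned = retained + removed at every
    stage.  ``with_audit=False`` skips the per-site audit table (useful in
    simulation loops); the summaries are identical either way.
    """
    if mode not in MIN_ALLELIC_READS:
        raise ValueError(f"mode must be one of {sorted(MIN_ALLELIC_READS)}")
    v = variants.copy().reset_index(drop=True)
    v["site_id"] = np.arange(len(v))
    tot_c = v["ctrl_a"] + v["ctrl_b"]
    tot_e = v["exp_a"] + v["exp_b"]
    v["zero_total"] = (tot_c == 0) | (tot_e == 0)
    nonzero = v[~v["zero_total"]]
    biallelic = filter_biallelic(nonzero, biallelic_low, biallelic_high)
    v["biallelic_pass"] = v["site_id"].isin(biallelic["site_id"])
    phased = phase_sites(biallelic)

    summary_rows = []
    audit_rows = []
    for region in regions:
        assigned = assign_sites(v, region)
        usable = phased[phased["site_id"].isin(assigned["site_id"])]
        n_assigned = len(assigned)
        base = {
            "region_id": region.id, "chrom": region.chrom,
            "start": region.start, "end": region.end, "kind": region.kind,
            "distance_to_integration": region.distance_to_integration,
            "n_sites_assigned": n_assigned,
        }
        if with_audit:
            for s in assigned.itertuples(index=False):
                audit_rows.append({
                    "region_id": region.id, "site_id": s.site_id, "chrom": s.chrom,
                    "pos": s.pos, "zero_total": bool(s.zero_total),
                    "biallelic_pass": bool(s.biallelic_pass),
                    "depth_pass": True, "deviation_outlier": False, "retained": False,
                })
        idx0 = len(audit_rows) - (n_assigned if with_audit else 0)

        def mark(site_ids, key, value):
            if not with_audit:
                return
            ids = set(site_ids)
            for row in audit_rows[idx0:]:
                if row["site_id"] in ids:
                    row[key] = value

        if len(usable) == 0:
            summary_rows.append({**base, "n_sites_initial": 0, "n_sites_retained": 0,
                                 "ctrl_allelic_ratio": np.nan, "exp_allelic_ratio": np.nan,
                                 "allelic_reads_ctrl": 0, "allelic_reads_exp": 0,
                                 "percent_allelic_silencing": np.nan,
                                 "n_tie_sites": 0, "passed_min_reads": False,
                                 "qc_flags": "no_informative_sites"})
            continue
        if mode == "chip":
            kept = filter_chip_depth(usable, fold=depth_fold)
            dropped = set(usable["site_id"]) - set(kept["site_id"])
            mark(dropped, "depth_pass", False)
            usable = kept
        if len(usable) == 0:
            summary_rows.append({**base, "n_sites_initial": 0, "n_sites_retained": 0,
                                 "ctrl_allelic_ratio": np.nan, "exp_allelic_ratio": np.nan,
                                 "allelic_reads_ctrl": 0, "allelic_reads_exp": 0,
                                 "percent_allelic_silencing": np.nan,
                                 "n_tie_sites": 0, "passed_min_reads": False,
                                 "qc_flags": "all_sites_removed"})
            continue
        summary, site_audit = aggregate_region(
            usable, region, deviation=deviation, pooling=pooling,
            deviation_scope=deviation_scope)
        outliers = site_audit.loc[site_audit["deviation_outlier"], "site_id"]
        mark(outliers, "deviation_outlier", True)
        retained = site_audit.loc[~site_audit["deviation_outlier"], "site_id"]
        mark(retained, "retained", True)
        passed = min_read_gate(summary, mode)
        summary_rows.append({**base,
                             "n_sites_initial": summary.n_sites_initial,
                             "n_sites_retained": summary.n_sites_retained,
                             "ctrl_allelic_ratio": summary.ctrl_allelic_ratio,
                             "exp_allelic_ratio": summary.exp_allelic_ratio,
                             "allelic_reads_ctrl": summary.allelic_reads_ctrl,
                             "allelic_reads_exp": summary.allelic_reads_exp,
                             "percent_allelic_silencing": summary.percent_allelic_silencing,
                             "n_tie_sites": summary.n_tie_sites,
                             "passed_min_reads": passed,
                             "qc_flags": ",".join(sorted(summary.qc_flags))})
    summaries = pd.DataFrame(summary_rows)
    audit = pd.DataFrame(audit_rows, columns=[
        "region_id", "site_id", "chrom", "pos", "zero_total", "biallelic_pass",
        "depth_pass", "deviation_outlier", "retained"])
    return summaries, audit
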