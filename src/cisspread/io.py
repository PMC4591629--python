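"""Readers and writers for the pipeline's text formats.

Variant count tables are TSV with 1-based positions (VCF convention for
points); gene and region models are BED, 0-based half-open; window tracks
are bedGraph; contact matrices are dense whitespace-separated text with a
header line naming the chromosome and bin size (a sparse ``bin_i bin_j
count`` triplet format is also accepted).  Coordinate conversion happens
only at this boundary.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cisspread.allelic import RegionOfInterest
from cisspread.hic import ContactMatrix
from cisspread.params import SimParams
from cisspread.windows import WindowTrack

__all__ = [
    "VariantTableError",
    "read_variant_table",
    "write_variant_table",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_contact_matrix",
    "write_contact_matrix",
    "RunConfig",
    "load_config",
    "save_config",
    "parse_locus",
]

VARIANT_COLUMNS = ["chrom", "pos", "refAllele", "altAllele",
                   "ctrl_ref", "ctrl_alt", "exp_ref", "exp_alt"]
_CANONICAL = ["chrom", "pos", "allele_a_id", "allele_b_id",
              "ctrl_a", "ctrl_b", "exp_a", "exp_b"]


class VariantTableError(ValueError):
    """Structured parse/validation failure with line numbers."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def read_variant_table(path, dialect: str = "tsv", *,
                       ctrl_sample: str | None = None,
                       exp_sample: str | None = None) -> pd.DataFrame:
    """Read a variant allelic-count table (TSV schema or minimal VCF).

    TSV columns: chrom, pos (1-based), refAllele, altAllele, ctrl_ref,
    ctrl_alt, exp_ref, exp_alt.  The VCF dialect expects two samples
    (control first unless named) with per-sample AD fields.  Malformed
    records are rejected with line numbers.
    """
    if dialect == "tsv":
        return _read_variant_tsv(path)
    if dialect == "vcf":
        return _read_variant_vcf(path, ctrl_sample, exp_sample)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_variant_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise VariantTableError([f"missing columns: {', '.join(missing)}"])
    errors: list[str] = []
    numeric = ["pos", "ctrl_ref", "ctrl_alt", "exp_ref", "exp_alt"]
    parsed = {}
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[vals.isna()]:
            errors.append(f"line {i + 2}: non-numeric {col} {df.loc[i, col]!r}")
        parsed[col] = vals
    if not errors:
        for col in numeric:
            bad = parsed[col] < (1 if col == "pos" else 0)
            for i in df.index[bad]:
                errors.append(f"line {i + 2}: negative or zero {col} "
                              f"({df.loc[i, col]})")
        dup = df.duplicated(subset=["chrom", "pos"], keep=False)
        if dup.any():
            lines = ", ".join(str(i + 2) for i in df.index[dup])
            errors.append(f"duplicate (chrom, pos) records on lines {lines}")
    if errors:
        raise VariantTableError(errors)
    out = pd.DataFrame({
        "chrom": df["chrom"], "pos": parsed["pos"].astype(int),
        "allele_a_id": df["refAllele"], "allele_b_id": df["altAllele"],
        "ctrl_a": parsed["ctrl_ref"].astype(int),
        "ctrl_b": parsed["ctrl_alt"].astype(int),
        "exp_a": parsed["exp_ref"].astype(int),
        "exp_b": parsed["exp_alt"].astype(int),
    })
    return out


def _read_variant_vcf(path, ctrl_sample, exp_sample) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) < 2:
            raise VariantTableError(["VCF needs two samples (control, experimental)"])
        ctrl = ctrl_sample or samples[0]
        exp = exp_sample or samples[1]
        for rec in vcf:
            if not rec.alts:
                continue
            ad_c = rec.samples[ctrl].get("AD")
            ad_e = rec.samples[exp].get("AD")
            if ad_c is None or ad_e is None:
                raise VariantTableError(
                    [f"{rec.chrom}:{rec.pos}: missing AD field"])
            rows.append((rec.chrom, rec.pos, rec.ref, rec.alts[0],
                         ad_c[0], ad_c[1], ad_e[0], ad_e[1]))
    return pd.DataFrame(rows, columns=_CANONICAL)


def write_variant_table(variants: pd.DataFrame, path) -> None:
    """Write the canonical table back to the TSV schema."""
    cols = {"chrom": "chrom", "pos": "pos", "allele_a_id": "refAllele",
            "allele_b_id": "altAllele", "ctrl_a": "ctrl_ref", "ctrl_b": "ctrl_alt",
            "exp_a": "exp_ref", "exp_b": "exp_alt"}
    out = variants[list(cols)].rename(columns=cols)
    out.to_csv(path, sep="\t", index=False)


def read_bed(path, integration_pos: int | None = None,
             kind: str = "gene") -> list[RegionOfInterest]:
    """Read BED (>=4 columns: chrom start end name [score strand]).

    Output is sorted by (chrom, start).  With ``integration_pos`` the
    signed midpoint distance is filled in.
    """
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[:df.shape[1]]
    errors = []
    for i, row in df.iterrows():
        if int(row["start"]) < 0 or int(row["start"]) >= int(row["end"]):
            errors.append(f"line {i + 1}: invalid interval "
                          f"{row['start']}-{row['end']}")
    if errors:
        raise ValueError("; ".join(errors))
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    regions = []
    for i, row in df.iterrows():
        name = str(row["name"]) if "name" in df.columns else f"region{i}"
        strand = str(row["strand"]) if "strand" in df.columns else "."
        mid = (int(row["start"]) + int(row["end"])) / 2.0
        dist = None if integration_pos is None else mid - integration_pos
        regions.append(RegionOfInterest(name, str(row["chrom"]), int(row["start"]),
                                        int(row["end"]), kind, strand, dist))
    return regions


def write_bed(genes: pd.DataFrame, path) -> None:
    """Write genes as BED6 (score column 0)."""
    out = genes[["chrom", "start", "end", "gene_id"]].copy()
    out["score"] = 0
    out["strand"] = genes["strand"] if "strand" in genes else "."
    out.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(track: WindowTrack, path) -> None:
    starts = np.arange(track.n_windows) * track.window_size
    ends = np.minimum(starts + track.window_size, track.chrom_length)
    with open(path, "w") as fh:
        for s, e, v in zip(starts, ends, track.values):
            fh.write(f"{track.chrom}\t{s}\t{e}\t{v:.6f}\n")


def read_bedgraph(path) -> WindowTrack:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"], comment="#")
    if df.empty:
        raise ValueError("empty bedGraph")
    window_size = int(df.loc[0, "end"] - df.loc[0, "start"])
    return WindowTrack(str(df.loc[0, "chrom"]), window_size,
                       df["value"].to_numpy(), chrom_length=int(df["end"].max()))


def write_contact_matrix(cm: ContactMatrix, path, fmt: str = "dense") -> None:
    """Dense whitespace matrix (default) or sparse upper-triangle triplets."""
    with open(path, "w") as fh:
        fh.write(f"# chrom={cm.chrom} bin_size={cm.bin_size} "
                 f"n_bins={cm.n_bins} format={fmt}\n")
        if fmt == "dense":
            np.savetxt(fh, cm.matrix, fmt="%.6g")
        elif fmt == "triplet":
            iu, ju = np.nonzero(np.triu(cm.matrix))
            for i, j in zip(iu, ju):
                fh.write(f"{i}\t{j}\t{cm.matrix[i, j]:.6g}\n")
        else:
            raise ValueError(f"unknown format {fmt!r}")


def read_contact_matrix(path) -> ContactMatrix:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("contact matrix must start with a '# chrom=... "
                             "bin_size=...' header line")
        fields = dict(tok.split("=", 1) for tok in header[1:].split())
        chrom = fields.get("chrom", "chr")
        bin_size = int(fields["bin_size"])
        fmt = fields.get("format", "dense")
        if fmt == "dense":
            matrix = np.loadtxt(fh, ndmin=2)
        elif fmt == "triplet":
            n = int(fields["n_bins"])
            matrix = np.zeros((n, n))
            trip = np.loadtxt(fh, ndmin=2)
            for i, j, v in trip:
                matrix[int(i), int(j)] = v
                matrix[int(j), int(i)] = v
        else:
            raise ValueError(f"unknown format {fmt!r}")
    return ContactMatrix(chrom, bin_size, matrix)


@dataclasses.dataclass
class RunConfig:
    """One run's inputs, thresholds (all with workflow defaults), and seed."""

    sim: SimParams = dataclasses.field(default_factory=SimParams)
    mode: str = "rna"
    biallelic_low: float = 0.3
    biallelic_high: float = 0.7
    deviation: float = 0.15
    depth_fold: float = 2.0
    min_reads_rna: int = 4
    min_reads_chip: int = 5
    fpkm_min: float = 5.0
    band_low: float = 30.0
    band_high: float = 60.0
    allelic_call_threshold: float = 30.0
    near_distance: int = 30_000_000
    n_distance_bins: int = 5
    n_perm: int = 10_000
    flank: int = 10_000
    stages: tuple = ("simulate", "allelic", "stats", "chip", "hic")

    @property
    def seed(self) -> int:
        return self.sim.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["sim"]["resistant_domains"] = [list(x) for x in self.sim.resistant_domains]
        if d["sim"]["k27me3_baseline_profile"] is not None:
            d["sim"]["k27me3_baseline_profile"] = [
                float(x) for x in d["sim"]["k27me3_baseline_profile"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = dict(d.pop("sim", {}))
        sim["resistant_domains"] = [tuple(x) for x in sim.get("resistant_domains", [])]
        if sim.get("k27me3_baseline_profile") is not None:
            sim["k27me3_baseline_profile"] = np.asarray(
                sim["k27me3_baseline_profile"], dtype=float)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(sim=SimParams(**sim), **d)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def parse_locus(text: str) -> tuple[str, int]:
    """Parse 'chrom:pos' (1-based position in text; returned 0-based)."""
    chrom, _, pos = text.rpartition(":")
    if not chrom:
        raise ValueError("locus must look like 'chrom:pos'")
    return chrom, int(pos.replace(",", "")) - 1
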