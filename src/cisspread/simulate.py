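"""Synthetic data with known ground-truth silencing.

Generates a toy chromosome with non-overlapping genes carrying
heterozygous variant sites, overdispersed allelic read counts in a
control and an induced condition, chromatin window tracks in which the
repressive-mark gain mirrors the pre-existing level, and a
distance-decaying contact matrix.  Everything downstream of the simulator
sees only the count tables; the truth (per-gene silenced fraction and
per-variant phase) is kept separately so parameter-recovery and
phasing-accuracy tests are possible.

Count model: per-site depth is gamma-Poisson (negative binomial) with
mean ``depth_mean`` and shape ``depth_dispersion``.  In the control the
two alleles split the depth Binomial(depth, 1/2).  In the induced
condition the cis allele's output is scaled by (1 - s), so the expected
total depth scales by (2 - s)/2 and the cis allele frequency is
(1 - s) / (2 - s).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from cisspread.params import GroundTruth, SimParams, silenced_fraction
from cisspread.windows import WindowTrack

__all__ = [
    "generate_genes",
    "make_ground_truth",
    "simulate_allelic_counts",
    "simulate_expression",
    "simulate_chip_windows",
    "simulate_hic",
    "simulate_dataset",
    "ChipSim",
    "ContactSim",
]

_BASES = np.array(list("ACGT"))
# fixed sub-stream ids so each product is reproducible independently
_STREAMS = {"genes": 1, "phase": 2, "counts": 3, "expression": 4, "chip": 5, "hic": 6}
_MIN_SLOT = 1_000


def _rng(params: SimParams, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(params.seed), _STREAMS[stream]])


class SizingError(ValueError):
    """Chromosome too short for the requested gene count."""


def generate_genes(params: SimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place non-overlapping genes with heterozygous variant positions.

    Returns (genes, variants).  Genes are sorted, pairwise disjoint (one
    gene per equal-width slot), each with at least one variant.  Variant
    positions are 1-based; gene intervals 0-based half-open.  The signed
    distance from the gene midpoint to the integration position is
    recorded (positive = downstream of the integration site).
    """
    params.validate()
    if params.n_genes == 0:
        genes = pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "strand",
                                      "midpoint", "distance_to_integration"])
        variants = pd.DataFrame(columns=["gene_id", "chrom", "pos",
                                         "allele_a_id", "allele_b_id"])
        return genes, variants
    slot = params.chrom_length // params.n_genes
    if slot < _MIN_SLOT:
        raise SizingError(
            f"chromosome of {params.chrom_length} bp cannot host {params.n_genes} genes")
    rng = _rng(params, "genes")
    max_len = int(min(slot - 200, 100_000))
    lengths = rng.integers(500, max_len + 1, size=params.n_genes)
    offsets = rng.integers(0, slot - lengths + 1)
    starts = np.arange(params.n_genes) * slot + offsets
    ends = starts + lengths
    strands = rng.choice(np.array(["+", "-"]), size=params.n_genes)
    mid = (starts + ends) // 2
    genes = pd.DataFrame({
        "gene_id": [f"g{i:04d}" for i in range(params.n_genes)],
        "chrom": params.chrom, "start": starts, "end": ends, "strand": strands,
        "midpoint": mid,
        "distance_to_integration": mid - params.integration_pos,
    })
    var_rows = []
    n_vars = np.maximum(1, rng.poisson(params.variants_per_gene_mean,
                                       size=params.n_genes))
    for i in range(params.n_genes):
        nv = int(min(n_vars[i], lengths[i]))
        pos = np.sort(rng.choice(lengths[i], size=nv, replace=False)) + starts[i] + 1
        pair = rng.integers(0, 4, size=(nv, 2))
        pair[:, 1] = (pair[:, 0] + 1 + rng.integers(0, 3, size=nv)) % 4
        for j in range(nv):
            var_rows.append((genes.loc[i, "gene_id"], params.chrom, int(pos[j]),
                             _BASES[pair[j, 0]], _BASES[pair[j, 1]]))
    variants = pd.DataFrame(var_rows, columns=["gene_id", "chrom", "pos",
                                               "allele_a_id", "allele_b_id"])
    return genes, variants


def make_ground_truth(params: SimParams, genes: pd.DataFrame,
                      variants: pd.DataFrame) -> GroundTruth:
    """Attach the true silenced fraction per gene and a random phase per variant."""
    rng = _rng(params, "phase")
    genes = genes.copy()
    genes["s_true"] = silenced_fraction(genes["midpoint"].to_numpy(), params)
    variants = variants.copy()
    variants["cis_allele"] = np.where(rng.random(len(variants)) < 0.5, "a", "b")
    return GroundTruth(genes=genes, variants=variants)


def simulate_allelic_counts(genes: pd.DataFrame, truth: GroundTruth,
                            params: SimParams) -> pd.DataFrame:
    """Draw the two-allele read counts per variant in both conditions."""
    params.validate()
    rng = _rng(params, "counts")
    v = truth.variants
    s = truth.genes.set_index("gene_id")["s_true"].reindex(v["gene_id"]).to_numpy()
    n = len(v)
    k = params.depth_dispersion

    def nb_depth(mu):
        lam = rng.gamma(shape=k, scale=np.asarray(mu) / k, size=n)
        return rng.poisson(lam)

    d_ctrl = nb_depth(np.full(n, params.depth_mean))
    d_exp = nb_depth(params.depth_mean * (2.0 - s) / 2.0)
    cis_ctrl = rng.binomial(d_ctrl, 0.5)
    p_cis = np.divide(1.0 - s, 2.0 - s)
    cis_exp = rng.binomial(d_exp, p_cis)
    cis_is_a = (v["cis_allele"] == "a").to_numpy()
    out = pd.DataFrame({
        "chrom": v["chrom"].to_numpy(),
        "pos": v["pos"].to_numpy(),
        "allele_a_id": v["allele_a_id"].to_numpy(),
        "allele_b_id": v["allele_b_id"].to_numpy(),
        "ctrl_a": np.where(cis_is_a, cis_ctrl, d_ctrl - cis_ctrl),
        "ctrl_b": np.where(cis_is_a, d_ctrl - cis_ctrl, cis_ctrl),
        "exp_a": np.where(cis_is_a, cis_exp, d_exp - cis_exp),
        "exp_b": np.where(cis_is_a, d_exp - cis_exp, cis_exp),
    })
    return out


def simulate_expression(genes: pd.DataFrame, truth: GroundTruth,
                        params: SimParams) -> pd.DataFrame:
    """Total expression (FPKM) per gene in both conditions.

    With one of two alleles silenced by fraction s, total output drops to
    (2 - s)/2 of control, plus multiplicative log-normal noise.
    """
    rng = _rng(params, "expression")
    s = truth.genes["s_true"].to_numpy()
    n = len(genes)
    fpkm_ctrl = rng.lognormal(params.fpkm_log_mean, params.fpkm_log_sd, size=n)
    noise = np.exp(params.fpkm_noise_sd * rng.standard_normal(n))
    fpkm_exp = fpkm_ctrl * (2.0 - s) / 2.0 * noise
    return pd.DataFrame({
        "gene_id": genes["gene_id"].to_numpy(),
        "fpkm_ctrl": fpkm_ctrl, "fpkm_exp": fpkm_exp,
    })


def _smooth_profile(rng: np.random.Generator, n: int, sigma_log: float = 1.0,
                    smooth_windows: int = 3) -> np.ndarray:
    """Positive, spatially smooth baseline: smoothed Gaussian noise, exponentiated."""
    pad = 4 * smooth_windows
    z = rng.standard_normal(n + 2 * pad)
    x = np.arange(-pad, pad + 1)
    kern = np.exp(-0.5 * (x / smooth_windows) ** 2)
    kern /= kern.sum()
    smooth = np.convolve(z, kern, mode="same")[pad:pad + n]
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return np.exp(sigma_log * smooth)


@dataclass
class ChipSim:
    """Simulated chromatin window tracks with their noiseless expectations."""

    k27me3_ctrl: WindowTrack
    k27me3_exp: WindowTrack
    k27ac_ctrl: WindowTrack
    k27ac_exp: WindowTrack
    input_track: WindowTrack
    true_gain: np.ndarray          # noiseless expected K27me3 gain per window
    window_silencing: np.ndarray   # true silenced fraction per window
    promoter_window: np.ndarray


def simulate_chip_windows(params: SimParams,
                          genes: pd.DataFrame | None = None) -> ChipSim:
    """Window tracks for a repressive (K27me3) and an active (K27ac) mark.

    On the integration arm the induced repressive level is
    baseline * (1 + gain_coefficient * proximity_weight) with a
    proximity weight that halves every ``chip_gain_halflife`` bp, so the
    gain is proportional to the pre-existing level.  The active mark is
    concentrated at promoter windows and lost in proportion to the local
    silenced fraction (more strongly at promoters).  Noise is
    multiplicative log-normal with scale ``noise_sd``.
    """
    params.validate()
    rng = _rng(params, "chip")
    wsize = params.chip_window_size
    n_w = ceil(params.chrom_length / wsize)
    if params.k27me3_baseline_profile is not None:
        baseline = np.asarray(params.k27me3_baseline_profile, dtype=float)
        if len(baseline) != n_w:
            raise ValueError(
                f"baseline profile length {len(baseline)} != window count {n_w}")
        if (baseline < 0).any():
            raise ValueError("baseline profile must be non-negative")
    else:
        baseline = _smooth_profile(rng, n_w)

    track = lambda vals: WindowTrack(params.chrom, wsize, vals,
                                     chrom_length=params.chrom_length)
    mid = track(baseline).midpoints()
    on_p_arm = params.integration_pos < params.centromere_pos
    same_arm = (mid < params.centromere_pos) if on_p_arm else (mid >= params.centromere_pos)
    w = np.exp2(-np.abs(mid - params.integration_pos) / params.chip_gain_halflife)
    w = np.where(same_arm, w, 0.0)
    s_w = silenced_fraction(mid, params)

    def lognoise():
        return np.exp(params.noise_sd * rng.standard_normal(n_w))

    me3_exp = baseline * (1.0 + params.gain_coefficient * w) * lognoise()
    true_gain = baseline * params.gain_coefficient * w

    promoter = np.zeros(n_w, dtype=bool)
    if genes is not None and len(genes):
        tss = np.where(genes["strand"].to_numpy() == "+",
                       genes["start"].to_numpy(), genes["end"].to_numpy() - 1)
        promoter[np.clip(tss // wsize, 0, n_w - 1)] = True
    ac_base = _smooth_profile(rng, n_w, sigma_log=0.8) * np.where(promoter, 5.0, 1.0)
    loss = s_w * np.where(promoter, 0.8, 0.4)
    ac_exp = ac_base * (1.0 - loss) * lognoise()
    input_vals = _smooth_profile(rng, n_w, sigma_log=0.2)
    return ChipSim(track(baseline), track(me3_exp), track(ac_base), track(ac_exp),
                   track(input_vals), true_gain, s_w, promoter)


@dataclass
class ContactSim:
    chrom: str
    bin_size: int
    matrix: np.ndarray


def simulate_hic(params: SimParams) -> "ContactSim":
    """Symmetric contact matrix with power-law distance decay.

    Expected count at bin separation d is hic_depth * (1 + d)**(-alpha);
    with ``hic_noise`` the counts are Poisson draws (upper triangle drawn,
    then mirrored), otherwise the exact expectation is returned.
    """
    params.validate()
    n = ceil(params.chrom_length / params.hic_bin_size)
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    expected = params.hic_depth * (1.0 + d) ** (-params.hic_decay_exponent)
    if not params.hic_noise:
        return ContactSim(params.chrom, params.hic_bin_size, expected)
    rng = _rng(params, "hic")
    draw = rng.poisson(expected).astype(float)
    upper = np.triu(draw)
    matrix = upper + np.triu(upper, 1).T
    return ContactSim(params.chrom, params.hic_bin_size, matrix)


def simulate_dataset(params: SimParams) -> dict:
    """Convenience bundle: genes, variants, truth, counts, expression, chip, hic."""
    genes, variants = generate_genes(params)
    truth = make_ground_truth(params, genes, variants)
    counts = simulate_allelic_counts(genes, truth, params)
    expression = simulate_expression(genes, truth, params)
    chip = simulate_chip_windows(params, genes)
    hic = simulate_hic(params)
    truth.k27me3_true_gain = chip.true_gain
    truth.window_silencing = chip.window_silencing
    return {"params": params, "genes": genes, "variants": variants, "truth": truth,
            "counts": counts, "expression": expression, "chip": chip, "hic": hic}
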