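"""Simulation parameters and ground-truth containers.

The synthetic genome is a single toy chromosome carrying an inducible
silencer transgene at ``integration_pos``.  The true cis-silenced fraction
of a gene at distance ``d`` from the integration site decays exponentially,

    s(d) = silencing_max * 2 ** (-|d| / silencing_halflife)

and is forced to zero inside user-supplied "resistant" domains, emulating
the discontinuous spread of silencing (domains that are skipped).  The
half-life has no empirical estimate and is an explicitly arbitrary default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SimParams", "GroundTruth", "silenced_fraction", "null_params"]


@dataclass
class SimParams:
    """Parameters of the synthetic dataset.

    Distances and positions are in base pairs.  ``depth_dispersion`` is the
    shape parameter of the gamma-Poisson (negative-binomial) per-site depth
    model: variance = mean + mean**2 / dispersion.
    """

    chrom: str = "chrS"
    chrom_length: int = 50_000_000
    n_genes: int = 200
    variants_per_gene_mean: float = 6.0
    integration_pos: int = 5_000_000
    centromere_pos: int = 25_000_000
    silencing_max: float = 0.8
    silencing_halflife: float = 5_000_000.0
    resistant_domains: list[tuple[int, int]] = field(default_factory=list)
    depth_mean: float = 50.0
    depth_dispersion: float = 10.0
    # chromatin windows
    chip_window_size: int = 100_000
    k27me3_baseline_profile: np.ndarray | None = None
    gain_coefficient: float = 1.0
    chip_gain_halflife: float = 20_000_000.0
    noise_sd: float = 0.15
    # total-expression layer
    fpkm_log_mean: float = 3.0
    fpkm_log_sd: float = 1.0
    fpkm_noise_sd: float = 0.1
    # contacts
    hic_bin_size: int = 40_000
    hic_decay_exponent: float = 1.0
    hic_depth: float = 100.0
    hic_noise: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if not 0.0 <= self.silencing_max <= 1.0:
            raise ValueError("silencing_max must lie in [0, 1]")
        if self.silencing_halflife <= 0:
            raise ValueError("silencing_halflife must be positive")
        if not 0 <= self.integration_pos < self.chrom_length:
            raise ValueError("integration_pos must lie within the chromosome")
        if not 0 < self.centromere_pos <= self.chrom_length:
            raise ValueError("centromere_pos must lie within the chromosome")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth model parameters must be positive")
        if self.noise_sd < 0 or self.fpkm_noise_sd < 0:
            raise ValueError("noise scales must be non-negative")
        if self.chip_window_size <= 0 or self.hic_bin_size <= 0:
            raise ValueError("window/bin sizes must be positive")
        for lo, hi in self.resistant_domains:
            if not (0 <= lo < hi <= self.chrom_length):
                raise ValueError(f"invalid resistant domain ({lo}, {hi})")
        if self.k27me3_baseline_profile is not None:
            prof = np.asarray(self.k27me3_baseline_profile, dtype=float)
            if (prof < 0).any():
                raise ValueError("k27me3_baseline_profile must be non-negative")

    def replace(self, **kwargs) -> "SimParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Truth known to the simulator but hidden from the pipeline.

    ``genes`` carries the per-gene true cis-silenced fraction ``s_true``;
    ``variants`` records which allele (a or b) is on the transgene-bearing
    homolog (the phase, used only to score phasing accuracy); window-level
    arrays hold the noiseless expected chromatin changes.
    """

    genes: pd.DataFrame
    variants: pd.DataFrame
    k27me3_true_gain: np.ndarray | None = None
    window_silencing: np.ndarray | None = None


def silenced_fraction(pos, params: SimParams) -> np.ndarray:
    """True cis-silenced fraction at genomic position(s) ``pos``.

    Exponential (half-life) decay with distance from the integration site,
    zeroed inside resistant domains.
    """
    pos = np.asarray(pos, dtype=float)
    d = np.abs(pos - params.integration_pos)
    s = params.silencing_max * np.exp2(-d / params.silencing_halflife)
    for lo, hi in params.resistant_domains:
        s = np.where((pos >= lo) & (pos < hi), 0.0, s)
    return s


def null_params(params: SimParams, **kwargs) -> SimParams:
    """Parameters for a control-integration chromosome (no cis-silencing).

    Emulates a transgene integrated on a different chromosome: the genome
    under study carries no silenced fraction anywhere.
    """
    return params.replace(silencing_max=0.0, **kwargs)
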