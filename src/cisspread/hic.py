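"""Contact-matrix rebinning and anchored profiles.

A 40 kb binned, symmetric contact matrix is re-binned to 1 Mb by summing
the constituent 40 kb cells (25 x 25 blocks; the terminal megabase may be
partial), and the contact profile anchored at the 1 Mb bin containing the
transgene is the corresponding matrix row.  Bins are 0-based half-open,
so a position exactly on a boundary belongs to the higher bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ContactMatrix", "AnchorProfile", "rebin", "anchor_profile"]

MB = 1_000_000


@dataclass
class ContactMatrix:
    """Square, symmetric, non-negative binned contact counts."""

    chrom: str
    bin_size: int
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.validate()

    def validate(self, rtol: float = 1e-6) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if (m < 0).any():
            raise ValueError("contact counts must be non-negative")
        scale = np.abs(m).max() or 1.0
        if np.abs(m - m.T).max() > rtol * scale:
            raise ValueError("contact matrix is asymmetric beyond tolerance")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    @property
    def extent(self) -> int:
        return self.n_bins * self.bin_size

    def total_mass(self) -> float:
        return float(self.matrix.sum())


@dataclass
class AnchorProfile:
    """Contacts of every bin with the anchor bin (one matrix row).

    The intra-anchor (diagonal) entry is reported but flagged separately,
    since self-contacts dominate.
    """

    chrom: str
    bin_size: int
    anchor_bin: int
    values: np.ndarray
    flags: set[str] = field(default_factory=lambda: {"diagonal_included"})

    @property
    def diagonal_value(self) -> float:
        return float(self.values[self.anchor_bin])


def rebin(cm: ContactMatrix, target_bin_size: int = MB) -> ContactMatrix:
    """Sum constituent cells into coarser bins (e.g. 40 kb -> 1 Mb).

    The input bin size must divide the target; the last coarse bin may
    cover fewer fine bins.  Total mass and symmetry are preserved.
    """
    if target_bin_size % cm.bin_size != 0:
        raise ValueError("target bin size must be a multiple of the input bin size")
    factor = target_bin_size // cm.bin_size
    if factor == 1:
        return ContactMatrix(cm.chrom, cm.bin_size, cm.matrix.copy())
    starts = np.arange(0, cm.n_bins, factor)
    coarse = np.add.reduceat(np.add.reduceat(cm.matrix, starts, axis=0), starts, axis=1)
    return ContactMatrix(cm.chrom, target_bin_size, coarse)


def anchor_profile(cm: ContactMatrix, integration_pos: int) -> AnchorProfile:
    """Row of the matrix for the bin containing ``integration_pos``."""
    if not 0 <= integration_pos < cm.extent:
        raise ValueError(
            f"position {integration_pos} outside matrix extent {cm.extent}")
    anchor = int(integration_pos // cm.bin_size)
    return AnchorProfile(cm.chrom, cm.bin_size, anchor, cm.matrix[anchor].copy())
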