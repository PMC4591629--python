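"""Fixed-window ChIP signal quantification and summaries.

Signal is summed into non-overlapping windows (2 kb and 1 Mb are the usual
choices), the partial terminal window is kept, and per-condition library
normalization is counts-per-million.  Arm-level change summaries use a
paired t-test across windows; gene metaprofiles rescale every gene body to
a fixed number of bins with fixed-width flanks, oriented 5'->3'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from cisspread.stats import correlate

__all__ = [
    "WindowTrack",
    "ArmSummary",
    "MetaProfile",
    "quantify_windows",
    "cpm",
    "arm_change_summary",
    "gene_metaprofile",
    "baseline_gain_correlation",
]


@dataclass
class WindowTrack:
    """Signal per non-overlapping fixed-size window on one chromosome."""

    chrom: str
    window_size: int
    values: np.ndarray
    chrom_length: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.chrom_length is None:
            self.chrom_length = len(self.values) * self.window_size

    @property
    def n_windows(self) -> int:
        return len(self.values)

    def midpoints(self) -> np.ndarray:
        starts = np.arange(self.n_windows) * self.window_size
        ends = np.minimum(starts + self.window_size, self.chrom_length)
        return (starts + ends) / 2.0

    def widths(self) -> np.ndarray:
        starts = np.arange(self.n_windows) * self.window_size
        return np.minimum(starts + self.window_size, self.chrom_length) - starts

    def densities(self) -> np.ndarray:
        """Signal per bp; the partial last window uses its true width."""
        return self.values / self.widths()


@dataclass
class ArmSummary:
    """Per-scope (chromosome or arm) condition-change summary."""

    scope: str
    n_windows: int
    mean_delta: float
    t_statistic: float
    p_value: float
    flags: set[str] = field(default_factory=set)


@dataclass
class MetaProfile:
    """Mean signal profile across genes: upstream flank, scaled body, downstream flank."""

    values: np.ndarray
    n_flank_bins: int
    n_body_bins: int
    n_genes_used: int
    n_genes_skipped: int


def quantify_windows(
    coverage,
    window_size: int,
    *,
    bin_size: int = 1,
    chrom: str = "chr",
    normalize: str | None = None,
) -> WindowTrack:
    """Sum coverage into non-overlapping windows of ``window_size`` bp.

    ``coverage`` is a non-negative array of per-base counts (``bin_size=1``)
    or pre-binned counts whose bin evenly divides the window.  The partial
    terminal window is kept.  ``normalize="cpm"`` rescales to counts per
    million after summation.
    """
    coverage = np.asarray(coverage, dtype=float)
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if bin_size <= 0 or window_size % bin_size != 0:
        raise ValueError("bin_size must be positive and divide window_size")
    if (coverage < 0).any():
        raise ValueError("coverage must be non-negative")
    step = window_size // bin_size
    starts = np.arange(0, len(coverage), step)
    values = np.add.reduceat(coverage, starts) if len(coverage) else np.array([])
    if normalize == "cpm":
        values = cpm(values)
    elif normalize is not None:
        raise ValueError(f"unknown normalization {normalize!r}")
    return WindowTrack(chrom, window_size, values, chrom_length=len(coverage) * bin_size)


def cpm(values: np.ndarray) -> np.ndarray:
    """Counts-per-million library normalization."""
    values = np.asarray(values, dtype=float)
    total = values.sum()
    return values * 1e6 / total if total > 0 else values.copy()


def arm_change_summary(
    ctrl: WindowTrack,
    exp: WindowTrack,
    scope: str = "chromosome",
    bounds: tuple[int, int] | None = None,
) -> ArmSummary:
    """Paired t-test of per-window change (exp - ctrl) within a scope.

    ``bounds`` restricts to windows whose midpoint lies in [start, end);
    windows straddling an arm boundary follow their midpoint.
    """
    if ctrl.n_windows != exp.n_windows or ctrl.window_size != exp.window_size:
        raise ValueError("tracks must share the same windows")
    mask = np.ones(ctrl.n_windows, dtype=bool)
    if bounds is not None:
        mid = ctrl.midpoints()
        mask = (mid >= bounds[0]) & (mid < bounds[1])
    delta = exp.values[mask] - ctrl.values[mask]
    flags: set[str] = set()
    n = int(mask.sum())
    if n < 2:
        return ArmSummary(scope, n, float(delta.mean()) if n else float("nan"),
                          float("nan"), float("nan"), {"too_few_windows"})
    if np.ptp(delta) == 0:
        # zero-variance differences: the t statistic is degenerate
        flags.add("zero_variance")
        if delta[0] == 0:
            return ArmSummary(scope, n, 0.0, 0.0, 1.0, flags)
        return ArmSummary(scope, n, float(delta[0]),
                          float(np.inf) * np.sign(delta[0]), 0.0, flags)
    t, p = sps.ttest_rel(exp.values[mask], ctrl.values[mask])
    return ArmSummary(scope, n, float(delta.mean()), float(t), float(p), flags)


def _partition_bounds(length: int, n_bins: int) -> np.ndarray:
    """Integer bin boundaries splitting [0, length) into n_bins near-equal parts."""
    return (np.arange(n_bins + 1) * length) // n_bins


def _bin_means(values: np.ndarray, n_bins: int) -> np.ndarray:
    bounds = _partition_bounds(len(values), n_bins)
    out = np.empty(n_bins)
    for k in range(n_bins):
        seg = values[bounds[k]:bounds[k + 1]]
        out[k] = np.nan if len(seg) == 0 else seg.mean()
    return out


def gene_metaprofile(
    signal,
    genes: pd.DataFrame,
    *,
    flank: int = 10_000,
    n_body_bins: int = 40,
    n_flank_bins: int = 10,
) -> MetaProfile:
    """Average signal profile over genes with fixed-width flanks.

    ``signal`` is per-base; ``genes`` needs ``start``, ``end`` (0-based
    half-open) and ``strand``.  Each body is rescaled to ``n_body_bins``
    mean-signal bins; flanks use ``n_flank_bins`` fixed-width bins.  Minus
    strand genes are flipped so bin 0 is always the 5' (upstream) end.
    Flank bases beyond the chromosome and genes shorter than one base per
    body bin are skipped from the mean (the latter counted as skipped).
    """
    signal = np.asarray(signal, dtype=float)
    L = len(signal)
    rows, skipped = [], 0
    for g in genes.itertuples(index=False):
        start, end = int(g.start), int(g.end)
        if end - start < n_body_bins:
            skipped += 1
            continue
        body = _bin_means(signal[start:end], n_body_bins)

        def flank_bins(lo: int, hi: int) -> np.ndarray:
            # pad out-of-chromosome bases with NaN so edges do not bias the mean
            width = hi - lo
            buf = np.full(width, np.nan)
            s, e = max(lo, 0), min(hi, L)
            if e > s:
                buf[s - lo:e - lo] = signal[s:e]
            bounds = _partition_bounds(width, n_flank_bins)
            out = np.empty(n_flank_bins)
            for k in range(n_flank_bins):
                seg = buf[bounds[k]:bounds[k + 1]]
                out[k] = np.nanmean(seg) if np.isfinite(seg).any() else np.nan
            return out

        left = flank_bins(start - flank, start)
        right = flank_bins(end, end + flank)
        prof = np.concatenate([left, body, right])
        if getattr(g, "strand", "+") == "-":
            prof = prof[::-1]
        rows.append(prof)
    if not rows:
        values = np.full(2 * n_flank_bins + n_body_bins, np.nan)
    else:
        values = np.nanmean(np.vstack(rows), axis=0)
    return MetaProfile(values, n_flank_bins, n_body_bins, len(rows), skipped)


def baseline_gain_correlation(
    ctrl: WindowTrack,
    exp: WindowTrack,
    bounds: tuple[int, int] | None = None,
):
    """Spearman correlation of pre-existing level with the gain (exp - ctrl)."""
    if ctrl.n_windows != exp.n_windows:
        raise ValueError("tracks must share the same windows")
    mask = np.ones(ctrl.n_windows, dtype=bool)
    if bounds is not None:
        mid = ctrl.midpoints()
        mask = (mid >= bounds[0]) & (mid < bounds[1])
    delta = exp.values[mask] - ctrl.values[mask]
    return correlate(ctrl.values[mask], delta, method="spearman")
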