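"""Gene-level silencing statistics.

Percent-silencing operators, the 30-60 % total-reduction band used to call
a gene "silencing" while excluding trans effects, a 2x2 chi-square of the
near-integration proportion against the rest of the genome, a permutation
test for decay of silencing with distance, and correlation helpers.

The distance-decay test is a chi-square permutation test: genes are ranked
by absolute distance to the integration site and split into equal-count
bins; the observed statistic is the chi-square of silenced counts across
bins, and the null distribution comes from permuting the silenced labels
across genes.  A one-sided Cochran-Armitage-style trend variant is
available since the scientific claim (silencing decreases with distance)
is directional.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "pyro_percent_silencing",
    "total_percent_silencing",
    "classify_band",
    "fpkm_gate",
    "proportion_vs_genome",
    "distance_decay_permutation_test",
    "exact_distance_decay_p",
    "correlate",
    "holm_adjust",
    "ChiSquareResult",
    "PermutationResult",
    "CorrelationResult",
]


class UndefinedStatisticError(ValueError):
    """A statistic's precondition (e.g. a positive denominator) failed."""


@dataclass
class ChiSquareResult:
    statistic: float
    p_value: float
    table: np.ndarray
    flags: set[str] = field(default_factory=set)


@dataclass
class PermutationResult:
    statistic: float
    p_value: float
    n_perm: int
    bin_sizes: np.ndarray
    bin_silenced: np.ndarray
    method: str = "chisq"
    flags: set[str] = field(default_factory=set)


@dataclass
class CorrelationResult:
    estimate: float
    p_value: float
    n: int
    method: str
    flags: set[str] = field(default_factory=set)


def pyro_percent_silencing(freq_ctrl: float, freq_exp: float) -> float:
    """Percent silencing from allele frequencies, (ctrl - exp) / ctrl * 100.

    Negative values denote allelic gain.
    """
    if freq_ctrl <= 0:
        raise UndefinedStatisticError("control allele frequency must be > 0")
    return 100.0 * (freq_ctrl - freq_exp) / freq_ctrl


def total_percent_silencing(fpkm_ctrl: float, fpkm_exp: float) -> float:
    """Percent reduction in total expression, (ctrl - exp) / ctrl * 100."""
    if fpkm_ctrl <= 0:
        raise UndefinedStatisticError("control FPKM must be > 0")
    return 100.0 * (fpkm_ctrl - fpkm_exp) / fpkm_ctrl


def classify_band(percent: float, low: float = 30.0, high: float = 60.0) -> bool:
    """True iff the total reduction lies in the (inclusive) silencing band.

    The band's upper edge guards against trans effects: reductions above it
    are reported separately, not folded in.
    """
    return low <= percent <= high


def fpkm_gate(fpkm_ctrl, fpkm_exp, threshold: float = 5.0, mode: str = "mean"):
    """Expression gate for silencing calls (default: mean of conditions >= 5)."""
    fpkm_ctrl = np.asarray(fpkm_ctrl, dtype=float)
    fpkm_exp = np.asarray(fpkm_exp, dtype=float)
    if mode == "mean":
        return (fpkm_ctrl + fpkm_exp) / 2.0 >= threshold
    if mode == "ctrl":
        return fpkm_ctrl >= threshold
    if mode == "both":
        return (fpkm_ctrl >= threshold) & (fpkm_exp >= threshold)
    raise ValueError(f"unknown gate mode {mode!r}")


def proportion_vs_genome(in_band_near, in_band_rest) -> ChiSquareResult:
    """2x2 chi-square: silencing-band membership x near-integration vs rest.

    ``in_band_near``/``in_band_rest`` are boolean arrays over the genes
    within the distance cutoff and over the rest of the genome.  Uses the
    textbook (uncorrected) chi-square; expected cells < 1 set a
    small-sample flag.
    """
    near = np.asarray(in_band_near, dtype=bool)
    rest = np.asarray(in_band_rest, dtype=bool)
    if near.size == 0 or rest.size == 0:
        raise ValueError("both gene sets must be non-empty")
    table = np.array(
        [[near.sum(), near.size - near.sum()],
         [rest.sum(), rest.size - rest.sum()]],
        dtype=float,
    )
    flags: set[str] = set()
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return ChiSquareResult(0.0, 1.0, table, {"degenerate"})
    res = sps.chi2_contingency(table, correction=False)
    if (res.expected_freq < 1).any():
        flags.add("small_expected_cell")
    return ChiSquareResult(float(res.statistic), float(res.pvalue), table, flags)


def _bin_starts(n: int, n_bins: int) -> np.ndarray:
    return (np.arange(n_bins) * n) // n_bins


def _chisq_rows(counts: np.ndarray, sizes: np.ndarray, total_s: float, n: int) -> np.ndarray:
    """Chi-square of silenced/not counts across bins, for rows of permuted counts."""
    e = sizes * (total_s / n)
    # silenced and not-silenced cells share the factor (1/e + 1/(size - e))
    w = 1.0 / e + 1.0 / (sizes - e)
    return ((counts - e) ** 2 * w).sum(axis=-1)


def distance_decay_permutation_test(
    silenced,
    distance,
    *,
    n_bins: int = 5,
    n_perm: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    method: str = "chisq",
) -> PermutationResult:
    """Permutation test for decay of silencing with distance.

    Genes are sorted by |distance| and split into ``n_bins`` equal-count
    bins.  ``method="chisq"`` uses the chi-square of silenced counts across
    bins (two-sided in shape); ``method="trend"`` uses a one-sided
    decreasing-trend statistic (sum of bin-rank-weighted silenced counts,
    small when silencing concentrates near the integration site).  The
    empirical p applies the +1 correction so p is never 0.
    """
    silenced = np.asarray(silenced, dtype=bool)
    distance = np.asarray(distance, dtype=float)
    n = silenced.size
    if n != distance.size:
        raise ValueError("silenced and distance must have equal length")
    if n < 2:
        raise ValueError("need at least 2 genes")
    n_bins = min(n_bins, n)
    order = np.argsort(np.abs(distance), kind="stable")
    labels = silenced[order].astype(float)
    starts = _bin_starts(n, n_bins)
    sizes = np.diff(np.append(starts, n)).astype(float)
    obs_counts = np.add.reduceat(labels, starts)
    total_s = labels.sum()
    if total_s == 0 or total_s == n:
        return PermutationResult(0.0, 1.0, 0, sizes, obs_counts, method, {"degenerate"})
    if rng is None:
        rng = np.random.default_rng(seed)

    if method == "chisq":
        def stat(mat):
            counts = np.add.reduceat(mat, starts, axis=-1)
            return _chisq_rows(counts, sizes, total_s, n)
        tail_ge = True
    elif method == "trend":
        scores = np.repeat(np.arange(n_bins, dtype=float), sizes.astype(int))

        def stat(mat):
            return (mat * scores).sum(axis=-1)
        tail_ge = False  # decreasing trend: small statistic is extreme
    else:
        raise ValueError(f"unknown method {method!r}")

    observed = float(stat(labels[None, :])[0])
    perm = np.broadcast_to(labels, (n_perm, n)).copy()
    rng.permuted(perm, axis=1, out=perm)
    perm_stats = stat(perm)
    eps = 1e-9
    extreme = perm_stats >= observed - eps if tail_ge else perm_stats <= observed + eps
    p = (1.0 + int(extreme.sum())) / (1.0 + n_perm)
    return PermutationResult(observed, p, n_perm, sizes, obs_counts, method)


def exact_distance_decay_p(silenced, distance, *, n_bins: int = 3,
                           method: str = "chisq") -> float:
    """Exhaustive-enumeration p for the distance-decay test (tiny n only).

    Enumerates every label arrangement; intended as an oracle for the
    permutation p on toy inputs.
    """
    silenced = np.asarray(silenced, dtype=bool)
    distance = np.asarray(distance, dtype=float)
    n = silenced.size
    if n > 9:
        raise ValueError("exhaustive enumeration is for toy inputs (n <= 9)")
    n_bins = min(n_bins, n)
    order = np.argsort(np.abs(distance), kind="stable")
    labels = silenced[order].astype(float)
    starts = _bin_starts(n, n_bins)
    sizes = np.diff(np.append(starts, n)).astype(float)
    total_s = labels.sum()
    if total_s in (0, n):
        return 1.0
    if method == "chisq":
        def stat(row):
            counts = np.add.reduceat(row, starts)
            return float(_chisq_rows(counts[None, :], sizes, total_s, n)[0])
        observed = stat(labels)
        hits = total = 0
        for arrangement in itertools.permutations(labels):
            total += 1
            if stat(np.asarray(arrangement)) >= observed - 1e-9:
                hits += 1
        return hits / total
    raise ValueError("enumeration oracle implemented for the chisq statistic")


def correlate(x, y, method: str = "spearman") -> CorrelationResult:
    """Rank (spearman) or product-moment (pearson) correlation, two-sided p.

    Missing values are handled pairwise-complete; a constant vector yields
    NaN with a flag rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = int(mask.sum())
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), n, method, {"constant_input"})
    if method == "spearman":
        r, p = sps.spearmanr(x, y)
    elif method == "pearson":
        r, p = sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(float(r), float(p), n, method)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment for a family of per-gene p-values."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return p_values.copy()
    return multipletests(p_values, method="holm")[1]
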