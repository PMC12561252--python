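"""Nonparametric regional statistics.

The pointwise machinery is deliberately self-contained: the exact
signed-rank and rank-sum null distributions are computed by subset-sum
dynamic programming over the (mid)ranks, which handles ties exactly and
matches brute-force enumeration (the property suite checks this).  The
normal approximations carry tie and continuity corrections.

Zero differences are dropped before ranking (Wilcoxon's original
treatment), and a location needs at least five nonzero paired
differences to report a p-value at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import gaussian_kde, norm, rankdata

from .core import Cohort, PolarGrid
from .mapping import DEFAULT_ZONE_RADIUS, global_mean, record_passes_qc

__all__ = [
    "SignificanceMap",
    "DistributionSummary",
    "wilcoxon_signed_rank",
    "pointwise_signed_rank_map",
    "bh_adjust",
    "rank_sum_test",
    "spearman_r",
    "bootstrap_ci",
    "summarize_distribution",
    "group_correlation",
]

#: Minimum nonzero paired differences to report a signed-rank p-value.
MIN_PAIRS = 5
#: Largest n for which the signed-rank null is enumerated exactly.
EXACT_SIGNED_RANK_N = 25
#: Largest min(n, m) for which the untied rank-sum null is enumerated exactly.
EXACT_RANK_SUM_MIN_N = 10


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _signed_rank_counts(ranks2: tuple[int, ...]) -> np.ndarray:
    """Subset-sum counts of the doubled-rank statistic over all 2^n sign patterns."""
    total = int(sum(ranks2))
    f = np.zeros(total + 1)
    f[0] = 1.0
    for r in ranks2:
        f[r:] = f[r:] + f[:-r]
    return f


@lru_cache(maxsize=64)
def _untied_signed_rank_counts(n: int) -> np.ndarray:
    return _signed_rank_counts(tuple(2 * k for k in range(1, n + 1)))


def _two_sided_p_from_counts(counts: np.ndarray, stat2: int) -> float:
    total = counts.sum()
    cdf = counts[: stat2 + 1].sum() / total
    sf = counts[stat2:].sum() / total
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_signed_rank(differences) -> float:
    """Two-sided paired signed-rank p-value.

    Exact (enumeration over sign patterns, tie-aware via midranks) when
    the number of nonzero differences is <= 25; otherwise a normal
    approximation with tie and continuity corrections.  Returns NaN when
    fewer than 5 nonzero differences remain.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("empty differences")
    d = d[np.isfinite(d)]
    d = d[d != 0]
    n = d.size
    if n < MIN_PAIRS:
        return float("nan")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_SIGNED_RANK_N:
        ranks2 = tuple(int(round(2 * r)) for r in ranks)
        if ranks2 == tuple(2 * k for k in range(1, n + 1)):
            counts = _untied_signed_rank_counts(n)
        else:
            counts = _signed_rank_counts(tuple(sorted(ranks2)))
        return _two_sided_p_from_counts(counts, int(round(2 * w_plus)))
    # normal approximation with tie correction
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return 1.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-up FDR adjustment: adjusted p_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted <= q


# ---------------------------------------------------------------------------
# rank-sum (Wilcoxon-Mann-Whitney)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def _rank_sum_counts(n: int, total: int) -> np.ndarray:
    """Counts of rank-sum values over all C(total, n) subsets of ranks 1..total."""
    max_sum = sum(range(total - n + 1, total + 1))
    f = np.zeros((n + 1, max_sum + 1))
    f[0, 0] = 1.0
    for r in range(1, total + 1):
        for k in range(min(n, r), 0, -1):
            f[k, r:] += f[k - 1, :-r]
    return f[n]


def rank_sum_test(sample_a, sample_b) -> float:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Exact enumeration (via DP over rank sums) when min(n) <= 10 and the
    pooled sample has no ties; otherwise normal approximation with tie
    and continuity corrections.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    ra = float(ranks[: a.size].sum())
    n, m = a.size, b.size
    no_ties = np.unique(pooled).size == pooled.size
    if no_ties and min(n, m) <= EXACT_RANK_SUM_MIN_N:
        small, w = (n, ra) if n <= m else (m, float(ranks[a.size:].sum()))
        counts = _rank_sum_counts(small, n + m)
        return _two_sided_p_from_counts(counts, int(round(w)))
    mean = n * (n + m + 1) / 2.0
    var = n * m * (n + m + 1) / 12.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= n * m * (tie_counts**3 - tie_counts).sum() / (12.0 * (n + m) * (n + m - 1))
    if var <= 0:
        return 1.0
    z = (ra - mean - 0.5 * np.sign(ra - mean)) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# correlation, bootstrap, summaries
# ---------------------------------------------------------------------------

def spearman_r(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of midranks (NaN if degenerate)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    rx, ry = rankdata(x), rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return float("nan")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def bootstrap_ci(statistic, sample, n_boot: int = 10_000, level: float = 0.95,
                 rng=None) -> tuple[float, float]:
    """Seeded percentile bootstrap CI for ``statistic(sample)``."""
    sample = np.asarray(sample)
    n = sample.shape[0]
    if n < 3:
        raise ValueError("sample size must be >= 3")
    rng = np.random.default_rng(rng)
    idx = rng.integers(0, n, size=(n_boot, n))
    stats = np.array([statistic(sample[i]) for i in idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.nanpercentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


@dataclass(frozen=True)
class DistributionSummary:
    mean: float
    median: float
    mode: float
    sd: float
    min: float
    max: float


def summarize_distribution(values) -> DistributionSummary:
    """Mean/median/mode/sd/min/max of a sample of continuous global values.

    The mode is the peak of a Gaussian KDE (Silverman bandwidth), since
    a raw mode is ill-defined for continuous data.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty sample")
    if v.size == 1 or np.ptp(v) == 0:
        c = float(v[0])
        return DistributionSummary(c, c, c, 0.0, c, c)
    kde = gaussian_kde(v, bw_method="silverman")
    h = kde.factor * v.std(ddof=1)
    grid = np.linspace(v.min() - 3 * h, v.max() + 3 * h, 512)
    mode = float(grid[np.argmax(kde(grid))])
    return DistributionSummary(
        mean=float(v.mean()), median=float(np.median(v)), mode=mode,
        sd=float(v.std(ddof=1)), min=float(v.min()), max=float(v.max()),
    )


# ---------------------------------------------------------------------------
# pointwise significance mapping
# ---------------------------------------------------------------------------

@dataclass
class SignificanceMap:
    """Pointwise raw/adjusted p-values and the BH rejection mask on a grid."""

    grid: PolarGrid
    p_raw: np.ndarray
    p_adj: np.ndarray
    reject: np.ndarray
    n_pairs: np.ndarray
    alpha: float = 0.05

    def __post_init__(self):
        for arr in (self.p_raw, self.p_adj):
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("p-values must lie in [0, 1]")
        ok = np.isfinite(self.p_adj)
        if np.any(self.p_adj[ok] < self.p_raw[ok] - 1e-12):
            raise ValueError("adjusted p-values must dominate raw p-values")

    def rejected_fraction(self, r_min: float = 0.0, r_max: float = np.inf) -> float:
        """Fraction of tested cells rejected within a radial band [r_min, r_max]."""
        band = (self.grid.ring_radii >= r_min) & (self.grid.ring_radii <= r_max)
        tested = np.isfinite(self.p_adj[band, :])
        if tested.sum() == 0:
            return float("nan")
        return float(self.reject[band, :][tested].mean())


def pointwise_signed_rank_map(cohort: Cohort, group: str, alpha: float = 0.05,
                              min_coverage: float = 1.0) -> SignificanceMap:
    """Paired post-pre signed-rank test at every map cell, BH-adjusted per map.

    The BH family is all testable (non-missing, >= 5 nonzero pairs) cells
    of this one group/laterality comparison.
    """
    recs = [r for r in cohort if r.group == group and record_passes_qc(r, min_coverage)]
    if len(recs) < MIN_PAIRS:
        raise ValueError(
            f"group {group} has {len(recs)} QC-passing paired records; need >= {MIN_PAIRS}"
        )
    grid = recs[0].pre_map.grid
    diffs = np.stack([r.post_map.values - r.pre_map.values for r in recs])
    nr, nm = grid.shape
    p_raw = np.full((nr, nm), np.nan)
    n_pairs = np.zeros((nr, nm), dtype=int)

    flat = diffs.reshape(len(recs), -1)
    finite = np.isfinite(flat)
    nonzero = finite & (flat != 0)
    n_nonzero = nonzero.sum(axis=0)
    p_flat = np.full(flat.shape[1], np.nan)
    # fast path: complete untied columns share one exact null distribution
    for col in np.flatnonzero(n_nonzero >= MIN_PAIRS):
        d = flat[finite[:, col], col]
        p_flat[col] = wilcoxon_signed_rank(d)
    p_raw = p_flat.reshape(nr, nm)
    n_pairs = n_nonzero.reshape(nr, nm)

    tested = np.isfinite(p_raw)
    p_adj = np.full_like(p_raw, np.nan)
    reject = np.zeros_like(tested)
    if tested.any():
        adj, rej = bh_adjust(p_raw[tested], q=alpha)
        p_adj[tested] = adj
        reject[tested] = rej
    return SignificanceMap(grid=grid, p_raw=p_raw, p_adj=p_adj,
                           reject=reject, n_pairs=n_pairs, alpha=alpha)


def group_correlation(cohort: Cohort, group: str,
                      zone_radius: float = DEFAULT_ZONE_RADIUS,
                      n_boot: int = 10_000, rng=None,
                      min_coverage: float = 1.0) -> dict:
    """Spearman R (with bootstrap CI) between post-treatment global mean and wear days."""
    recs = [r for r in cohort if r.group == group and record_passes_qc(r, min_coverage)]
    if len(recs) < 3:
        raise ValueError(f"group {group}: need >= 3 QC-passing records")
    days = np.array([r.wear_days for r in recs], dtype=float)
    means = np.array([global_mean(r.post_map, zone_radius) for r in recs])
    r_val = spearman_r(days, means)
    pairs = np.column_stack([days, means])
    lo, hi = bootstrap_ci(lambda s: spearman_r(s[:, 0], s[:, 1]), pairs,
                          n_boot=n_boot, rng=rng)
    return {"group": group, "n": len(recs), "spearman_r": r_val,
            "ci_low": lo, "ci_high": hi}
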