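"""Exact change-point segmentation of a rank-ordered feature sequence.

Cells (or track windows) ordered by a 1D pseudotime rank are discretized
into ``n_bins`` equal-count bins, and the binned sequence is cut into
``K + 1`` segments by choosing break points that minimize the total
within-segment squared error

    sum_k E_k,   E_k = sum_{c in C_k} ||x_c - mu_k||^2,

where ``mu_k`` is the mean feature vector of segment ``k`` and ``C_k`` its
member cells. Break points are restricted to bin boundaries, so the optimum
is found exactly by dynamic programming over per-bin sufficient statistics
(count, vector sum, sum of squared norms): for any bin range the segment SSE
is ``sumsq - ||sum||^2 / count``. The number of change points is selected by
the elbow of the optimal-error-versus-K curve.

Segment membership uses half-open intervals: segment k covers bins
``(b_{k-1}, b_k]`` with sentinels ``b_0 = -1`` and ``b_{K+1} = n_bins - 1``,
so break points are the last-bin indices of all but the final segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np


@dataclass(frozen=True)
class BinnedProfile:
    """Per-bin sufficient statistics of feature vectors ordered by rank."""

    counts: np.ndarray  # (n_bins,) int
    sums: np.ndarray  # (n_bins, d)
    sumsqs: np.ndarray  # (n_bins,) sum of ||x||^2 within each bin

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def n_items(self) -> int:
        return int(self.counts.sum())

    @property
    def dim(self) -> int:
        return self.sums.shape[1]


@dataclass(frozen=True)
class Segmentation:
    """Optimal break points, per-segment means and total within-segment SSE."""

    break_points: np.ndarray  # (K,) strictly increasing bin indices
    segment_means: np.ndarray  # (K + 1, d)
    total_error: float
    n_bins: int

    @property
    def K(self) -> int:
        return len(self.break_points)

    def segment_of_bin(self) -> np.ndarray:
        """Segment index (0..K) of every bin."""
        labels = np.zeros(self.n_bins, dtype=int)
        prev = -1
        for k, b in enumerate(self.break_points):
            labels[prev + 1 : b + 1] = k
            prev = b
        labels[prev + 1 :] = self.K
        return labels

    def to_dict(self, error_curve=None) -> dict:
        d = {
            "n_bins": self.n_bins,
            "K": self.K,
            "break_points": [int(b) for b in self.break_points],
            "segment_means": self.segment_means.tolist(),
            "total_error": float(self.total_error),
        }
        if error_curve is not None:
            d["error_curve"] = [float(e) for e in error_curve]
        return d


def bin_sizes(n_items: int, n_bins: int) -> np.ndarray:
    """Equal-count bin sizes; the first ``n_items % n_bins`` bins get one extra."""
    q, r = divmod(n_items, n_bins)
    sizes = np.full(n_bins, q, dtype=int)
    sizes[:r] += 1
    return sizes


def bin_of_rank(n_items: int, n_bins: int) -> np.ndarray:
    """Bin index of each rank position 0..n_items-1."""
    return np.repeat(np.arange(n_bins), bin_sizes(n_items, n_bins))


def bin_by_rank(
    features: np.ndarray, ranks: np.ndarray, n_bins: int = 30
) -> BinnedProfile:
    """Discretize rank-ordered features into equal-count bins.

    Parameters
    ----------
    features:
        ``(n, d)`` feature matrix (``(n,)`` accepted for ``d = 1``).
    ranks:
        ``ranks[i]`` is the pseudotime rank of item ``i``; must be a
        permutation of ``0..n-1``.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    if np.isnan(features).any():
        raise ValueError("features contain NaN")
    n = len(features)
    ranks = np.asarray(ranks)
    if sorted(ranks) != list(range(n)):
        raise ValueError("ranks must be a permutation of 0..n-1")
    if n_bins > n:
        raise ValueError(f"n_bins={n_bins} exceeds number of items ({n})")

    order = np.argsort(ranks, kind="stable")
    ordered = features[order]
    bins = bin_of_rank(n, n_bins)
    d = ordered.shape[1]
    counts = np.bincount(bins, minlength=n_bins)
    sums = np.zeros((n_bins, d))
    np.add.at(sums, bins, ordered)
    sumsqs = np.bincount(bins, weights=(ordered**2).sum(axis=1), minlength=n_bins)
    return BinnedProfile(counts=counts, sums=sums, sumsqs=sumsqs)


def _prefix_stats(profile: BinnedProfile):
    c = np.concatenate(([0], np.cumsum(profile.counts)))
    s = np.vstack([np.zeros(profile.dim), np.cumsum(profile.sums, axis=0)])
    q = np.concatenate(([0.0], np.cumsum(profile.sumsqs)))
    return c, s, q


def _segment_cost(c, s, q, i: int, j: int) -> float:
    """SSE of the segment covering bins i..j inclusive (over items, exactly)."""
    n = c[j + 1] - c[i]
    if n == 0:
        return 0.0
    vec = s[j + 1] - s[i]
    return float(q[j + 1] - q[i] - (vec @ vec) / n)


def _means(profile: BinnedProfile, break_points: np.ndarray) -> np.ndarray:
    c, s, _ = _prefix_stats(profile)
    edges = np.concatenate(([-1], break_points, [profile.n_bins - 1]))
    means = np.empty((len(edges) - 1, profile.dim))
    for k in range(len(edges) - 1):
        i, j = edges[k] + 1, edges[k + 1]
        n = c[j + 1] - c[i]
        means[k] = (s[j + 1] - s[i]) / n if n else np.nan
    return means


def segment_dp(profile: BinnedProfile, K: int) -> Segmentation:
    """Globally optimal ``K``-change-point segmentation by dynamic programming.

    Runs in ``O(K * n_bins^2)`` using prefix sums; deterministic, and exact
    because the objective decomposes over segments and the per-segment SSE is
    available in O(1) from the sufficient statistics.
    """
    n = profile.n_bins
    if n == 0:
        raise ValueError("empty profile")
    if not 0 <= K < n:
        raise ValueError(f"need 0 <= K < n_bins, got K={K}, n_bins={n}")
    c, s, q = _prefix_stats(profile)

    cost = np.empty((n, n))  # cost[i, j] = SSE of bins i..j
    for i in range(n):
        for j in range(i, n):
            cost[i, j] = _segment_cost(c, s, q, i, j)

    # best[k][j] = minimal error of bins 0..j using k change points
    best = np.full((K + 1, n), np.inf)
    argbreak = np.zeros((K + 1, n), dtype=int)
    best[0] = cost[0]
    for k in range(1, K + 1):
        for j in range(k, n):
            cand = best[k - 1, k - 1 : j] + cost[k : j + 1, j]
            m = int(np.argmin(cand))  # first minimum: deterministic ties
            best[k, j] = cand[m]
            argbreak[k, j] = m + k - 1
    breaks = np.empty(K, dtype=int)
    j = n - 1
    for k in range(K, 0, -1):
        breaks[k - 1] = argbreak[k, j]
        j = breaks[k - 1]
    return Segmentation(
        break_points=breaks,
        segment_means=_means(profile, breaks),
        total_error=float(best[K, n - 1]),
        n_bins=n,
    )


def brute_force_segment(
    profile: BinnedProfile, K: int, cap: int = 200_000
) -> Segmentation:
    """Exhaustive-search optimum over all break-point placements (test oracle).

    Enumerates all C(n_bins - 1, K) placements; refuses instances above
    ``cap`` placements.
    """
    n = profile.n_bins
    if n == 0:
        raise ValueError("empty profile")
    if not 0 <= K < n:
        raise ValueError(f"need 0 <= K < n_bins, got K={K}, n_bins={n}")
    if comb(n - 1, K) > cap:
        raise ValueError(f"C({n - 1}, {K}) exceeds enumeration cap {cap}")
    c, s, q = _prefix_stats(profile)
    best_err = np.inf
    best_breaks = None
    for breaks in combinations(range(n - 1), K):
        edges = (-1, *breaks, n - 1)
        err = sum(
            _segment_cost(c, s, q, edges[k] + 1, edges[k + 1])
            for k in range(len(edges) - 1)
        )
        if err < best_err:
            best_err = err
            best_breaks = breaks
    breaks = np.array(best_breaks, dtype=int)
    return Segmentation(
        break_points=breaks,
        segment_means=_means(profile, breaks),
        total_error=float(best_err),
        n_bins=n,
    )


def select_k_elbow(
    error_curve: np.ndarray,
    tol: float = 1e-9,
    flatness_tol: float = 0.05,
) -> int:
    """Elbow selection of the number of change points.

    ``error_curve[K]`` is the optimal total error for K = 0..K_max. Both axes
    are min-max normalized and the K maximizing the perpendicular distance to
    the chord joining the curve's endpoints is returned; ties go to the
    smallest K.

    Two guards make the rule well defined on degenerate curves: the curve
    must be non-increasing within ``tol`` (relative), and if the total error
    drops by less than ``flatness_tol`` (relative to the K=0 error) over the
    whole curve the data carry no segmentation signal and K = 0 is returned.
    """
    e = np.asarray(error_curve, dtype=float)
    if len(e) < 3:
        raise ValueError("error curve must cover at least K = 0, 1, 2")
    scale = max(abs(e[0]), 1.0)
    if np.any(np.diff(e) > tol * scale):
        raise ValueError(
            "error curve increases beyond tolerance; segmentations are not optimal"
        )
    if e[0] <= 0 or (e[0] - e[-1]) / e[0] < flatness_tol:
        return 0
    x = np.linspace(0.0, 1.0, len(e))
    y = (e - e.min()) / (e.max() - e.min())
    # distance from (x, y) to the chord from (0, y0) to (1, y_last)
    dy = y[-1] - y[0]
    dist = np.abs(dy * x - (y - y[0])) / np.hypot(1.0, dy)
    # ties (within float noise on the normalized scale) go to the smallest K
    return int(np.flatnonzero(dist >= dist.max() - 1e-12)[0])


def error_curve(profile: BinnedProfile, k_max: int) -> np.ndarray:
    """Optimal total error for every K in 0..k_max."""
    k_max = min(k_max, profile.n_bins - 1)
    return np.array([segment_dp(profile, k).total_error for k in range(k_max + 1)])
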