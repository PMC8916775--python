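"""Nonparametric statistics: cluster-mass permutation test, FDR, signed rank.

The cluster-mass test controls the family-wise error of paired
comparisons over map-shaped statistics (depth x time or depth x
frequency).  Pixels whose paired statistic passes a pointwise threshold
form 4-connected clusters; each cluster's mass is the sum of |statistic|
over its pixels, and significance comes from the permutation distribution
of the maximal cluster mass under random per-session sign flips of the
condition difference (exact exchangeability under the paired null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = ["ClusterTestResult", "cluster_mass_test", "fdr_bh", "paired_signed_rank"]


@dataclass
class Cluster:
    pixels: np.ndarray  # (n_pixels, 2) row/col indices
    mass: float
    p_value: float


@dataclass
class ClusterTestResult:
    """Clusters with permutation p-values and the α-level significance mask."""

    clusters: list[Cluster]
    significance_mask: np.ndarray
    statistic_map: np.ndarray
    pointwise_threshold: float
    n_permutations: int
    alpha: float


def _paired_stat_maps(diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """One-sample t maps of sign-flipped session differences.

    ``diffs``: (n_sessions, *map_shape) flattened to pixels; ``signs``:
    (n_perm, n_sessions) of ±1.  Sign flips leave per-pixel second moments
    unchanged, so the t statistic needs only the flipped mean.
    """
    n = diffs.shape[0]
    flat = diffs.reshape(n, -1)
    sumsq = np.sum(flat**2, axis=0)  # invariant under sign flips
    means = signs @ flat / n  # (n_perm, n_pixels)
    var = (sumsq / n - means**2) * (n / (n - 1))
    var = np.maximum(var, 1e-300)
    return means / np.sqrt(var / n)


def cluster_mass_test(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    cluster_threshold_p: float = 0.05,
    seed: int = 0,
) -> ClusterTestResult:
    """Paired cluster-mass permutation test on session x map arrays.

    Parameters
    ----------
    maps_a, maps_b : ndarray (n_sessions, n_rows, n_cols)
        Paired condition maps (e.g. CSD profiles for large vs small
        stimuli).  The pixelwise statistic is the one-sample t of the
        per-session difference; the cluster-forming threshold is the
        two-sided t critical value at ``cluster_threshold_p``.
    n_permutations : at least 100; when 2^n_sessions ≤ 4096 the sign-flip
        null is enumerated exhaustively instead of sampled.
    """
    maps_a = np.asarray(maps_a, dtype=float)
    maps_b = np.asarray(maps_b, dtype=float)
    if maps_a.shape != maps_b.shape or maps_a.ndim != 3:
        raise ValueError("need paired (n_sessions, rows, cols) maps")
    n = maps_a.shape[0]
    if n < 2:
        raise ValueError("need at least two sessions")
    if n_permutations < 100:
        raise ValueError("n_permutations must be at least 100")
    if n < 6:
        import warnings

        warnings.warn(
            f"only {n} sessions: permutation p-values have resolution 2^-{n}",
            stacklevel=2,
        )
    diffs = maps_a - maps_b
    map_shape = diffs.shape[1:]
    threshold = float(scipy.stats.t.ppf(1 - cluster_threshold_p / 2, df=n - 1))

    if 2**n <= 4096:
        bits = np.arange(2**n)
        signs = 1 - 2 * ((bits[:, None] >> np.arange(n)[None, :]) & 1)
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
        signs[0] = 1.0  # include the identity so p > 0
        exhaustive = False
    signs = signs.astype(float)

    stat_maps = _paired_stat_maps(diffs, signs)
    observed = _paired_stat_maps(diffs, np.ones((1, n)))[0].reshape(map_shape)

    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity

    def max_mass(stat_flat: np.ndarray) -> float:
        m = stat_flat.reshape(map_shape)
        supra = np.abs(m) > threshold
        if not supra.any():
            return 0.0
        labels, n_lab = scipy.ndimage.label(supra, structure=structure)
        masses = scipy.ndimage.sum_labels(np.abs(m), labels, np.arange(1, n_lab + 1))
        return float(masses.max())

    null_max = np.array([max_mass(s) for s in stat_maps])

    supra = np.abs(observed) > threshold
    labels, n_lab = scipy.ndimage.label(supra, structure=structure)
    clusters: list[Cluster] = []
    mask = np.zeros(map_shape, dtype=bool)
    n_perm_eff = signs.shape[0]
    for lab in range(1, n_lab + 1):
        members = labels == lab
        mass = float(np.abs(observed)[members].sum())
        # Count ties tolerantly: permutation masses exactly equal to the
        # observed mass (common under sign flips) must count regardless of
        # floating-point summation order.
        ge = (null_max > mass) | np.isclose(null_max, mass, rtol=1e-9, atol=1e-12)
        p = float(ge.sum()) / n_perm_eff
        if not exhaustive:
            p = max(p, 1.0 / n_perm_eff)
        clusters.append(
            Cluster(pixels=np.argwhere(members), mass=mass, p_value=p)
        )
        if p < alpha:
            mask |= members
    clusters.sort(key=lambda c: c.p_value)
    return ClusterTestResult(
        clusters=clusters,
        significance_mask=mask,
        statistic_map=observed,
        pointwise_threshold=threshold,
        n_permutations=n_perm_eff,
        alpha=alpha,
    )


def fdr_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p.ravel(), method="fdr_bh")
    return adjusted.reshape(p.shape)


def paired_signed_rank(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired session values.

    Requires at least 5 pairs.  All-zero differences return p = 1 by
    convention (no evidence of a shift).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("a and b must be paired (same shape)")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("paired values must be finite")
    if a.size < 5:
        raise ValueError(f"signed-rank test needs n >= 5 pairs, got {a.size}")
    d = a - b
    if np.all(d == 0):
        return 1.0
    res = scipy.stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                               method="auto")
    return float(res.pvalue)
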