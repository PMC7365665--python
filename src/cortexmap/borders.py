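"""Observer-independent cortical border detection.

Each depth-normalized laminar profile is condensed into a 10-component feature
vector: five weighted-moment descriptors of the profile itself (mean amplitude,
centroid depth, dispersion, skewness, excess kurtosis, with the profile value
acting as the weight over cortical depth) and the same five descriptors of the
magnitude of its first differences.  A sliding pair of adjacent blocks of *b*
profiles is compared with the Mahalanobis distance between the block mean
vectors (pooled, bias-corrected covariance); Hotelling's T² converts each
distance into a p-value, Bonferroni-corrected over the positions evaluated in
the trace.  Significant local maxima of the distance function mark candidate
areal borders; repeating the procedure over a range of block sizes and keeping
positions supported by most sizes yields consensus border calls, which can
finally be cross-checked between adjoining sections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FeatureVector",
    "DistanceTrace",
    "BorderCall",
    "profile_features",
    "feature_matrix",
    "mahalanobis_d2",
    "hotelling_p",
    "md_trace",
    "blocksize_sweep",
    "cross_section_consistency",
]

FEATURE_NAMES = (
    "mean", "centroid", "dispersion", "skewness", "kurtosis",
    "d_mean", "d_centroid", "d_dispersion", "d_skewness", "d_kurtosis",
)

#: condition-number threshold above which covariance shrinkage engages
COND_THRESHOLD = 1e8


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray          # length 10, FEATURE_NAMES order

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (10,):
            raise ValueError("feature vector must have 10 components")


def _weighted_moments(weights: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """(mean amplitude, centroid, dispersion, skewness, excess kurtosis).

    ``weights`` is interpreted as an (unnormalized) distribution over the depth
    grid.  An all-zero weight vector is degenerate and maps to the documented
    sentinel (0, midpoint, 0, 0, 0).
    """
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    amp = w.mean()
    if total <= 0:
        warnings.warn("all-zero weight vector: degenerate feature block", stacklevel=3)
        mid = 0.5 * (grid[0] + grid[-1])
        return np.array([amp, mid, 0.0, 0.0, 0.0])
    p = w / total
    c = float(p @ grid)
    var = float(p @ (grid - c) ** 2)
    disp = np.sqrt(var)
    if disp == 0:
        return np.array([amp, c, 0.0, 0.0, 0.0])
    z = (grid - c) / disp
    skew = float(p @ z**3)
    kurt = float(p @ z**4) - 3.0
    return np.array([amp, c, disp, skew, kurt])


def profile_features(profile) -> FeatureVector:
    """10-feature parametrization of a laminar profile.

    Accepts a :class:`~cortexmap.profiles.LaminarProfile` or a plain 1-D array
    (assumed on a uniform 0-100 % depth grid).  Moments of the first-difference
    block are computed on the *absolute* differences, evaluated at the depth
    midpoints of consecutive samples.
    """
    if hasattr(profile, "values") and hasattr(profile, "depth_grid"):
        values = np.asarray(profile.values, dtype=float)
        grid = np.asarray(profile.depth_grid, dtype=float)
    else:
        values = np.asarray(profile, dtype=float)
        grid = np.linspace(0.0, 100.0, values.size)
    if values.ndim != 1 or values.size < 3:
        raise ValueError("profile must be 1-D with >= 3 samples")
    if np.any(values < 0):
        raise ValueError("profile values must be nonnegative")
    top = _weighted_moments(values, grid)
    dvals = np.abs(np.diff(values))
    dgrid = 0.5 * (grid[:-1] + grid[1:])
    bottom = _weighted_moments(dvals, dgrid)
    return FeatureVector(np.concatenate([top, bottom]))


def feature_matrix(profile_matrix: np.ndarray, grid: np.ndarray | None = None) -> np.ndarray:
    """Feature vectors for every row of an (n_profiles, depth) matrix.

    Vectorized equivalent of calling :func:`profile_features` per row; used by
    the sliding-window machinery where thousands of profiles are parametrized.
    """
    v = np.asarray(profile_matrix, dtype=float)
    if v.ndim != 2 or v.shape[1] < 3:
        raise ValueError("profile matrix must be (n, depth>=3)")
    if np.any(v < 0):
        raise ValueError("profile values must be nonnegative")
    if grid is None:
        grid = np.linspace(0.0, 100.0, v.shape[1])

    def block(w: np.ndarray, g: np.ndarray) -> np.ndarray:
        total = w.sum(axis=1)
        amp = w.mean(axis=1)
        out = np.zeros((w.shape[0], 5))
        out[:, 0] = amp
        ok = total > 0
        if not np.all(ok):
            warnings.warn("all-zero weight vector: degenerate feature block", stacklevel=2)
            out[~ok, 1] = 0.5 * (g[0] + g[-1])
        if np.any(ok):
            p = w[ok] / total[ok, None]
            c = p @ g
            var = np.einsum("ij,ij->i", p, (g[None, :] - c[:, None]) ** 2)
            disp = np.sqrt(var)
            out[ok, 1] = c
            out[ok, 2] = disp
            nz = disp > 0
            if np.any(nz):
                idx = np.flatnonzero(ok)[nz]
                z = (g[None, :] - c[nz, None]) / disp[nz, None]
                out[idx, 3] = np.einsum("ij,ij->i", p[nz], z**3)
                out[idx, 4] = np.einsum("ij,ij->i", p[nz], z**4) - 3.0
        return out

    top = block(v, np.asarray(grid, dtype=float))
    bottom = block(np.abs(np.diff(v, axis=1)),
                   0.5 * (np.asarray(grid)[:-1] + np.asarray(grid)[1:]))
    return np.hstack([top, bottom])


def _pooled_cov(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    sa = np.cov(a, rowvar=False, ddof=1) if na > 1 else np.zeros((a.shape[1],) * 2)
    sb = np.cov(b, rowvar=False, ddof=1) if nb > 1 else np.zeros((b.shape[1],) * 2)
    return ((na - 1) * np.atleast_2d(sa) + (nb - 1) * np.atleast_2d(sb)) / (na + nb - 2)


def _regularize(s: np.ndarray) -> tuple[np.ndarray, bool]:
    """Shrink toward the diagonal until the condition number is acceptable."""
    if np.isfinite(np.linalg.cond(s)) and np.linalg.cond(s) <= COND_THRESHOLD:
        return s, False
    d = np.diag(np.diag(s))
    if np.trace(d) <= 0:
        # fully degenerate blocks (e.g. noise-free synthetic profiles)
        return np.eye(s.shape[0]) * 1e-12, True
    for lam in (1e-6, 1e-4, 1e-2, 1e-1, 0.5, 1.0):
        s2 = (1 - lam) * s + lam * d
        if np.linalg.cond(s2) <= COND_THRESHOLD:
            return s2, True
    # diagonal itself ill-conditioned: add a ridge proportional to mean variance
    return d + np.eye(s.shape[0]) * (np.trace(d) / s.shape[0]) * 1e-8, True


def mahalanobis_d2(block_a: np.ndarray, block_b: np.ndarray,
                   regularize: bool = True) -> float:
    """Squared Mahalanobis distance between the mean vectors of two blocks.

    ``D² = (m̄_a − m̄_b)ᵀ S⁻¹ (m̄_a − m̄_b)`` with S the bias-corrected pooled
    covariance.  Symmetric in its arguments and invariant to any affine change
    of the feature units.  If the pooled covariance is ill-conditioned (e.g.
    fewer than ``p`` pooled degrees of freedom) shrinkage toward the diagonal
    engages when ``regularize`` is enabled, otherwise a numerical error names
    the condition.
    """
    a = np.atleast_2d(np.asarray(block_a, dtype=float))
    b = np.atleast_2d(np.asarray(block_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("blocks must share the feature dimension")
    s = _pooled_cov(a, b)
    s_use, was_reg = _regularize(s) if regularize else (s, False)
    if not regularize:
        cond = np.linalg.cond(s)
        if not np.isfinite(cond) or cond > COND_THRESHOLD:
            raise np.linalg.LinAlgError(
                f"pooled covariance is singular/ill-conditioned (cond={cond:.3g}); "
                "enable regularization or enlarge the blocks")
    diff = a.mean(axis=0) - b.mean(axis=0)
    d2 = float(diff @ np.linalg.solve(s_use, diff))
    return max(d2, 0.0)


def hotelling_p(d2: float, n_a: int, n_b: int, p_dim: int) -> float:
    """Two-sample Hotelling T² p-value from a squared Mahalanobis distance.

    ``T² = n_a n_b / (n_a + n_b) · D²`` and
    ``F = T² (n − p − 1) / (p (n − 2))`` with ``n = n_a + n_b`` follows an
    F(p, n − p − 1) distribution under equal means.
    """
    n = n_a + n_b
    dof = n - p_dim - 1
    if dof < 1:
        raise ValueError(
            f"insufficient degrees of freedom (n_a + n_b - p - 1 = {dof}); "
            "use larger blocks or fewer features")
    t2 = n_a * n_b / n * d2
    f = t2 * dof / (p_dim * (n - 2))
    return float(stats.f.sf(f, p_dim, dof))


@dataclass
class DistanceTrace:
    """Mahalanobis distance function for one block size along a ribbon."""

    block_size: int
    positions: np.ndarray       # profile index where the right block starts
    d2: np.ndarray
    p: np.ndarray
    p_adjusted: np.ndarray      # Bonferroni over positions in this trace
    significant: np.ndarray     # bool per position
    maxima: np.ndarray          # positions of significant local maxima
    alpha: float = 0.01
    regularized: bool = False

    def __post_init__(self):
        if np.any(self.d2 < 0):
            raise ValueError("D^2 must be nonnegative")


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; plateaus take the leftmost index."""
    n = y.size
    out = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        # plateau [i, j]; a maximum needs strictly lower neighbors on both sides
        if y[i] > y[i - 1] and j + 1 < n and y[i] > y[j + 1]:
            out.append(i)
        i = j + 1
    return np.array(out, dtype=int)


def md_trace(features: np.ndarray, block_size: int, alpha: float = 0.01) -> DistanceTrace:
    """Sliding-block Mahalanobis distance trace with Hotelling significance.

    At every interior position *i* with ``block_size`` profiles on each side,
    the blocks ``features[i-b:i]`` and ``features[i:i+b]`` are compared; the
    Bonferroni divisor is the number of evaluated positions in this trace and
    flagged maxima are strict local maxima with adjusted p below ``alpha``.
    """
    f = np.atleast_2d(np.asarray(features, dtype=float))
    n, p_dim = f.shape
    b = int(block_size)
    if n < 2 * b:
        raise ValueError(f"need at least 2*block_size = {2 * b} profiles, got {n}")
    positions = np.arange(b, n - b + 1)
    m = positions.size
    d2 = np.empty(m)
    pvals = np.empty(m)
    any_reg = False
    for k, i in enumerate(positions):
        a_blk, b_blk = f[i - b:i], f[i:i + b]
        s = _pooled_cov(a_blk, b_blk)
        s_use, reg = _regularize(s)
        any_reg |= reg
        diff = a_blk.mean(axis=0) - b_blk.mean(axis=0)
        d2[k] = max(float(diff @ np.linalg.solve(s_use, diff)), 0.0)
        pvals[k] = hotelling_p(d2[k], b, b, p_dim)
    p_adj = np.minimum(pvals * m, 1.0)
    significant = p_adj < alpha
    max_idx = _local_maxima(d2)
    maxima = positions[max_idx[significant[max_idx]]] if max_idx.size else np.array([], int)
    return DistanceTrace(b, positions, d2, pvals, p_adj, significant,
                         maxima, alpha=alpha, regularized=any_reg)


@dataclass
class BorderCall:
    """Consensus border position supported by several block sizes."""

    position: float
    supporting_block_sizes: tuple[int, ...]
    min_p_adjusted: float
    n_sections: int = 1
    confirmed: bool | None = None


def _cluster_positions(items: list[tuple[float, object]], tol: float) -> list[list]:
    """Greedy single-linkage grouping of (position, payload) by gaps > tol."""
    if not items:
        return []
    items = sorted(items, key=lambda t: t[0])
    groups: list[list] = [[items[0]]]
    for it in items[1:]:
        if it[0] - groups[-1][-1][0] <= tol:
            groups[-1].append(it)
        else:
            groups.append([it])
    return groups


def blocksize_sweep(features: np.ndarray, b_min: int = 10, b_max: int = 24,
                    alpha: float = 0.01, position_tol: float = 3.0,
                    support_fraction: float = 0.6) -> list[BorderCall]:
    """Consensus border calls across a sweep of block sizes.

    Significant maxima from all traces are grouped by position (single-linkage
    with gap tolerance ``position_tol``); a group becomes a border call when it
    is supported by at least ``support_fraction`` of the swept block sizes, at
    the median of its member positions.
    """
    f = np.atleast_2d(np.asarray(features, dtype=float))
    if f.shape[0] < 2 * b_max:
        raise ValueError(f"need at least 2*b_max = {2 * b_max} profiles")
    sizes = list(range(b_min, b_max + 1))
    hits: list[tuple[float, tuple[int, float]]] = []
    for b in sizes:
        tr = md_trace(f, b, alpha=alpha)
        for pos in tr.maxima:
            k = int(np.searchsorted(tr.positions, pos))
            hits.append((float(pos), (b, float(tr.p_adjusted[k]))))
    need = support_fraction * len(sizes)
    calls = []
    for grp in _cluster_positions(hits, position_tol):
        support = sorted({b for _, (b, _) in grp})
        if len(support) >= need:
            pos = float(np.median([p for p, _ in grp]))
            minp = min(p_adj for _, (_, p_adj) in grp)
            calls.append(BorderCall(pos, tuple(support), minp))
    return sorted(calls, key=lambda c: c.position)


def cross_section_consistency(calls_per_section: list[list[BorderCall]],
                              tol: float = 3.0, min_sections: int = 2
                              ) -> tuple[list[BorderCall], list[BorderCall]]:
    """Confirm calls that recur at matching positions in adjoining sections.

    Returns ``(confirmed, unconfirmed)``; unmatched calls are reported, never
    silently discarded.  Confirmed calls take the median position over the
    matching sections.
    """
    if len(calls_per_section) < 2:
        raise ValueError("need at least two sections")
    items = [(c.position, (sec, c))
             for sec, calls in enumerate(calls_per_section) for c in calls]
    confirmed, unconfirmed = [], []
    for grp in _cluster_positions(items, tol):
        sections = {sec for _, (sec, _) in grp}
        members = [c for _, (_, c) in grp]
        pos = float(np.median([c.position for c in members]))
        support = tuple(sorted({b for c in members for b in c.supporting_block_sizes}))
        minp = min(c.min_p_adjusted for c in members)
        call = BorderCall(pos, support, minp, n_sections=len(sections),
                          confirmed=len(sections) >= min_sections)
        (confirmed if call.confirmed else unconfirmed).append(call)
    return confirmed, unconfirmed
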