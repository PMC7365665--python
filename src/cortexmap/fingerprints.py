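"""Receptor fingerprints and their multivariate analysis.

A fingerprint is the vector of an area's 15 mean receptor densities (fmol/mg
protein) in a fixed canonical receptor order.  Fingerprints are compared after
z-scoring each receptor across areas (so that high- and low-density receptor
systems carry equal weight), using Euclidean distances, agglomerative
clustering with a k-means-based choice of the cluster count, and a 2-D
principal component projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "RECEPTOR_ORDER",
    "DensityTable",
    "Fingerprint",
    "ClusterResult",
    "zscore_table",
    "cluster_fingerprints",
    "pca_2d",
    "polar_export",
]

#: canonical receptor order used by every fingerprint and polar export
RECEPTOR_ORDER = (
    "AMPA", "kainate", "NMDA", "GABAA", "GABAB", "GABAA/BZ",
    "M1", "M2", "M3", "alpha1", "alpha2", "5-HT1A", "5-HT2", "A1", "D1",
)


@dataclass
class DensityTable:
    """Area x receptor mean (and sd) densities in fmol/mg protein."""

    means: pd.DataFrame
    sds: pd.DataFrame | None = None

    def __post_init__(self):
        if self.sds is not None and not self.means.index.equals(self.sds.index):
            raise ValueError("mean and sd tables must share the area index")
        bad = self.means.columns[(self.means <= 0).any()]
        if len(bad):
            raise ValueError(f"mean densities must be positive (receptor {bad[0]!r})")

    @classmethod
    def from_long(cls, frame: pd.DataFrame) -> "DensityTable":
        """Build from the long CSV layout (area, receptor, mean, sd)."""
        required = {"area", "receptor", "mean"}
        if not required.issubset(frame.columns):
            raise OSError("density table is corrupt: expected columns area, receptor, mean")
        order = [r for r in RECEPTOR_ORDER if r in set(frame["receptor"])]
        order += [r for r in frame["receptor"].unique() if r not in order]
        area_order = list(dict.fromkeys(frame["area"]))
        means = (frame.pivot(index="area", columns="receptor", values="mean")
                 .reindex(index=area_order, columns=order))
        sds = None
        if "sd" in frame.columns:
            sds = (frame.pivot(index="area", columns="receptor", values="sd")
                   .reindex(index=area_order, columns=order))
        return cls(means, sds)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for a in self.means.index:
            for r in self.means.columns:
                row = {"area": a, "receptor": r, "mean": self.means.loc[a, r]}
                if self.sds is not None:
                    row["sd"] = self.sds.loc[a, r]
                rows.append(row)
        return pd.DataFrame(rows)

    def fingerprint(self, area: str) -> "Fingerprint":
        return Fingerprint(area, self.means.loc[area].to_numpy(dtype=float),
                           tuple(self.means.columns))


@dataclass(frozen=True)
class Fingerprint:
    area: str
    densities: np.ndarray
    receptors: tuple[str, ...] = RECEPTOR_ORDER

    def __post_init__(self):
        d = np.asarray(self.densities, dtype=float)
        if d.size != len(self.receptors):
            raise ValueError("densities and receptor order length mismatch")
        object.__setattr__(self, "densities", d)


def zscore_table(table) -> pd.DataFrame:
    """Z-score every receptor column across areas (sample sd, ddof=1).

    Accepts a :class:`DensityTable` or a plain areas x receptors DataFrame and
    returns a DataFrame whose columns have mean 0 and sd 1.
    """
    means = table.means if isinstance(table, DensityTable) else table
    if means.shape[0] < 2:
        raise ValueError("need at least two areas to z-score")
    sd = means.std(axis=0, ddof=1)
    zero = sd.index[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance receptor column: {zero[0]!r}")
    return (means - means.mean(axis=0)) / sd


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    k: int
    labels: pd.Series               # area -> cluster id (1..k)
    merge_heights: np.ndarray
    silhouette_by_k: dict[int, float]
    linkage_method: str
    degenerate: bool = False

    def members(self) -> dict[int, list[str]]:
        return {int(c): sorted(self.labels.index[self.labels == c])
                for c in sorted(self.labels.unique())}

    def cut(self, k: int) -> pd.Series:
        """Flat labels from cutting the tree at ``k`` clusters."""
        lab = fcluster(self.linkage_matrix, k, criterion="maxclust")
        return pd.Series(lab, index=self.labels.index, name="cluster")


def cluster_fingerprints(z: pd.DataFrame, linkage_method: str = "ward",
                         k_range=range(2, 9), n_restarts: int = 50,
                         seed: int = 0) -> ClusterResult:
    """Agglomerative clustering of z-scored fingerprints with k-means k choice.

    The tree is built on Euclidean distances with the requested linkage
    (Ward by default).  The cluster count is the ``k`` in ``k_range``
    maximizing the mean silhouette of a multi-start k-means partition
    (``n_restarts`` restarts, fixed seed; ties take the smallest k); flat
    labels are the tree cut at that k.  If all fingerprints coincide the
    distances are degenerate and the result reports k = 1 with a flag.
    """
    ks = sorted(set(int(k) for k in k_range))
    n = z.shape[0]
    x = z.to_numpy(dtype=float)
    dists = pdist(x)
    lm = linkage(x, method=linkage_method)
    if np.allclose(dists, 0.0):
        labels = pd.Series(np.ones(n, dtype=int), index=z.index, name="cluster")
        return ClusterResult(lm, 1, labels, lm[:, 2].copy(), {}, linkage_method,
                             degenerate=True)
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, n_areas-1] = [2, {n - 1}]")
    sil: dict[int, float] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(x)
        sil[k] = float(silhouette_score(x, km.labels_))
    best_k = max(ks, key=lambda k: (sil[k], -k))
    labels = pd.Series(fcluster(lm, best_k, criterion="maxclust"),
                       index=z.index, name="cluster")
    return ClusterResult(lm, best_k, labels, lm[:, 2].copy(), sil, linkage_method)


def distance_matrix(z: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between fingerprints."""
    return pd.DataFrame(squareform(pdist(z.to_numpy(dtype=float))),
                        index=z.index, columns=z.index)


def pca_2d(z: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """First two principal components of the (column-centered) fingerprint matrix.

    Returns ``(scores, explained_variance_ratio, loadings)``.  Signs follow a
    deterministic convention: each component is flipped so that its
    largest-magnitude loading is positive.
    """
    if z.shape[0] < 3:
        raise ValueError("need at least three areas for a PCA")
    x = z.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    scores = u * s
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else var
    ncomp = min(2, s.size)
    score_df = pd.DataFrame(scores[:, :ncomp], index=z.index,
                            columns=[f"PC{i + 1}" for i in range(ncomp)])
    load_df = pd.DataFrame(vt[:ncomp].T, index=z.columns,
                           columns=[f"PC{i + 1}" for i in range(ncomp)])
    return score_df, ratio[:ncomp], load_df


def polar_export(fp: Fingerprint, scale_max: float = 2000.0,
                 plot_path=None) -> pd.DataFrame:
    """Polar-plot coordinates of a fingerprint: 15 equally spaced spokes.

    Angles advance by 360/15 degrees in the canonical receptor order starting
    at 90 deg (first receptor at the top); the radius is the raw density.  A
    density exceeding ``scale_max`` raises a warning but is exported unclipped.
    """
    n = len(fp.receptors)
    if np.any(fp.densities > scale_max):
        warnings.warn(f"fingerprint {fp.area}: density exceeds scale_max={scale_max}")
    angles = (90.0 - 360.0 * np.arange(n) / n) % 360.0
    out = pd.DataFrame({"receptor": list(fp.receptors),
                        "angle_deg": angles,
                        "radius": fp.densities})
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        theta = np.deg2rad(np.append(angles, angles[0]))
        r = np.append(fp.densities, fp.densities[0])
        fig = plt.figure(figsize=(4, 4))
        ax = fig.add_subplot(projection="polar")
        ax.plot(theta, r, lw=1.5)
        ax.fill(theta, r, alpha=0.25)
        ax.set_ylim(0, scale_max)
        ax.set_xticks(np.deg2rad(angles))
        ax.set_xticklabels(fp.receptors, fontsize=6)
        ax.set_title(fp.area)
        fig.savefig(plot_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return out
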