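"""Tag-density matrices around site centers, k-means-ordered heatmaps, and
average (meta-) profiles.

Each matrix row is one site; columns are fixed-width bins spanning +/- a
window around the site center (summit for peaks, midpoint otherwise).  Each
tag contributes once, to the bin containing its extended-fragment midpoint,
and values are scaled per million library tags so that libraries of
different depth are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenomicInterval, Peak, PeakSet, TagLibrary

__all__ = ["SignalMatrix", "tag_density_matrix", "kmeans_order", "average_profile", "pooled_top_sites"]


@dataclass
class SignalMatrix:
    """Rows = sites, columns = bins across +/- window; tags per million."""

    values: np.ndarray
    window: int
    bin_width: int

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def bin_centers(self) -> np.ndarray:
        n = self.values.shape[1]
        return -self.window + self.bin_width * (np.arange(n) + 0.5)


def _site_center(site) -> tuple[str, int]:
    if isinstance(site, GenomicInterval):
        return site.chrom, site.center
    return site.interval.chrom, site.center  # Peak: center == summit


def tag_density_matrix(
    sites, tags: TagLibrary, window: int = 3000, bin_width: int = 50
) -> SignalMatrix:
    """Per-site, per-bin normalized fragment-midpoint counts.

    Conservation: the matrix total equals (tags whose fragment midpoint
    falls in any window) / library size x 1e6.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("no sites")
    n_bins = 2 * window // bin_width
    values = np.zeros((len(sites), n_bins))
    total = tags.total
    if total == 0:
        return SignalMatrix(values, window, bin_width)
    midpoints: dict[str, np.ndarray] = {}
    for chrom in tags.chroms:
        starts, ends = tags.fragments(chrom)
        midpoints[chrom] = np.sort((starts + ends) // 2)
    scale = 1e6 / total
    for i, site in enumerate(sites):
        chrom, center = _site_center(site)
        mids = midpoints.get(chrom)
        if mids is None:
            continue
        lo = np.searchsorted(mids, center - window, side="left")
        hi = np.searchsorted(mids, center + window, side="left")
        if hi > lo:
            idx = (mids[lo:hi] - (center - window)) // bin_width
            np.add.at(values[i], idx, scale)
    return SignalMatrix(values, window, bin_width)


def kmeans_order(matrix: SignalMatrix, k: int, seed: int = 0, n_init: int = 10):
    """Cluster rows with k-means and order them for heatmap display.

    Returns (labels, order): cluster label per row (relabelled so cluster 0
    has the highest mean signal) and row indices ordered by cluster then by
    descending row mean.  Deterministic under a fixed seed.
    """
    from sklearn.cluster import KMeans

    n_rows = matrix.values.shape[0]
    if k < 1 or k > n_rows:
        raise ValueError(f"k must be in [1, {n_rows}]")
    if k == 1:
        labels = np.zeros(n_rows, dtype=int)
    else:
        km = KMeans(n_clusters=k, random_state=seed, n_init=n_init)
        labels = km.fit_predict(matrix.values)
    row_means = matrix.values.mean(axis=1)
    cluster_means = {c: row_means[labels == c].mean() for c in np.unique(labels)}
    relabel = {c: r for r, c in enumerate(sorted(cluster_means, key=lambda c: -cluster_means[c]))}
    labels = np.array([relabel[c] for c in labels])
    order = np.lexsort((-row_means, labels))
    return labels, order


def average_profile(matrix: SignalMatrix) -> np.ndarray:
    """Column means: the average signal profile across sites."""
    if matrix.values.shape[0] < 1:
        raise ValueError("matrix has no rows")
    return matrix.values.mean(axis=0)


def pooled_top_sites(sets: list[PeakSet], n_top: int = 500) -> list[Peak]:
    """Pool the top ``n_top`` peaks by score from each set, sorted by
    genomic position — the site list for combined cell-type heatmaps."""
    pooled: list[Peak] = []
    for s in sets:
        pooled.extend(s.ranked()[:n_top])
    return sorted(pooled, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
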