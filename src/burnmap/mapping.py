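"""Burned-area mask and four-class severity map from index differences.

Two selected index differences (by default dNDVI and dYNDVI) form a 2-D
feature vector per pixel. Bisecting K-means with K=2 separates burned from
unburned pixels without a fixed threshold; plain K-means with K=4 on the
burned pixels stratifies severity into four ordered classes:

    0  negligible to slight damage
    1  moderately damaged
    2  highly damaged
    3  destroyed

Cluster-to-label semantics: the burned cluster is the one whose centroid
has the larger coordinate sum (greater combined vegetation-index loss),
and severity classes are ordered by ascending centroid coordinate sum, so
the largest loss maps to "destroyed".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cluster import ClusterResult, bisecting_kmeans, kmeans
from .indices import DifferenceImage
from .io_geodata import GridGeometry, InputError

__all__ = [
    "SEVERITY_LABELS",
    "SEVERITY_NODATA",
    "BurnMask",
    "SeverityMap",
    "label_burned_cluster",
    "map_burned_area",
    "map_severity",
]

SEVERITY_LABELS = (
    "negligible to slight damage",
    "moderately damaged",
    "highly damaged",
    "destroyed",
)

#: In-memory nodata code for severity planes (written as 255 on disk).
SEVERITY_NODATA = -1


@dataclass
class BurnMask:
    """Boolean burned/unburned plane; ``valid`` marks pixels that were clustered."""

    values: np.ndarray
    grid: GridGeometry
    valid: np.ndarray
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.grid.shape or self.valid.shape != self.grid.shape:
            raise InputError("burn mask planes must match the grid shape")

    @property
    def n_burned(self) -> int:
        return int(self.values.sum())


@dataclass
class SeverityMap:
    """Ordered 4-class severity plane defined exactly on the burned pixels."""

    values: np.ndarray  # int plane; SEVERITY_NODATA outside the burn
    grid: GridGeometry
    class_counts: np.ndarray
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int16)
        if self.values.shape != self.grid.shape:
            raise InputError("severity plane must match the grid shape")
        self.class_counts = np.asarray(self.class_counts, dtype=np.int64)


def _feature_matrix(
    d1: DifferenceImage, d2: DifferenceImage, aoi: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Stack two difference images into (n_valid, 2) features + validity plane."""
    if d1.grid.shape != d2.grid.shape:
        raise InputError("difference images are on different grids")
    valid = ~d1.nodata_mask & ~d2.nodata_mask
    if aoi is not None:
        aoi = np.asarray(aoi, dtype=bool)
        if aoi.shape != d1.grid.shape:
            raise InputError("AOI plane does not match the grid shape")
        valid &= aoi
    X = np.column_stack([d1.values[valid], d2.values[valid]])
    return X, valid


def label_burned_cluster(result: ClusterResult) -> int:
    """Identify the burned cluster of a K=2 result.

    The burned cluster shows the greater combined index loss: larger
    centroid coordinate sum; on a tie, larger first coordinate; on an
    exact tie, cluster 0 (with a warning).
    """
    if result.k != 2:
        raise InputError("burned-cluster labeling expects a 2-cluster result")
    sums = result.centroids.sum(axis=1)
    if sums[0] != sums[1]:
        return int(np.argmax(sums))
    if result.centroids[0, 0] != result.centroids[1, 0]:
        return int(np.argmax(result.centroids[:, 0]))
    warnings.warn("cluster centroids coincide; defaulting to cluster 0", stacklevel=2)
    return 0


def map_burned_area(
    d1: DifferenceImage,
    d2: DifferenceImage,
    aoi: np.ndarray | None = None,
    *,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    n_trial_bisections: int = 5,
) -> tuple[BurnMask, ClusterResult]:
    """Burned/unburned segmentation by bisecting K-means in 2-D difference space.

    Degenerate inputs are flagged rather than silently mapped: coincident
    centroids (an all-constant difference field) yield a no-burn mask with a
    ``degenerate`` flag, and a centroid separation below twice the pooled
    within-cluster spread yields a ``low_separation`` flag (the split is
    likely carving noise, not a burn scar).
    """
    X, valid = _feature_matrix(d1, d2, aoi)
    if X.shape[0] < 2:
        raise InputError("fewer than 2 valid pixels to cluster")
    result = bisecting_kmeans(
        X, 2, seed=seed, max_iter=max_iter, tol=tol, n_trial_bisections=n_trial_bisections
    )
    flags = list(result.flags)
    values = np.zeros(d1.grid.shape, dtype=bool)

    separation = float(np.sqrt(((result.centroids[0] - result.centroids[1]) ** 2).sum()))
    if separation == 0.0 or np.allclose(result.centroids[0], result.centroids[1]):
        flags.append("degenerate")
        warnings.warn(
            "cluster centroids coincide (constant difference field); reporting no burn",
            stacklevel=2,
        )
        return BurnMask(values=values, grid=d1.grid, valid=valid, flags=flags), result

    # pooled within-cluster standard deviation per coordinate
    sigma = float(np.sqrt(result.total_sse / (X.shape[0] * X.shape[1])))
    if separation < 2.0 * sigma:
        flags.append("low_separation")
        warnings.warn(
            "centroid separation below the noise floor; burned mask unreliable",
            stacklevel=2,
        )

    burned_id = label_burned_cluster(result)
    values[valid] = result.labels == burned_id
    return BurnMask(values=values, grid=d1.grid, valid=valid, flags=flags), result


def map_severity(
    d1: DifferenceImage,
    d2: DifferenceImage,
    mask: BurnMask,
    *,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> tuple[SeverityMap | None, ClusterResult | None]:
    """Four-class severity stratification of the burned pixels by K-means.

    Clusters are ordered by ascending centroid coordinate sum and mapped to
    severity classes 0..3 (largest combined index loss = destroyed). With
    fewer than 4 burned pixels the severity stage is skipped (returns
    ``(None, None)``) with a warning.
    """
    if mask.grid.shape != d1.grid.shape:
        raise InputError("burn mask and difference images are on different grids")
    burned = mask.values
    if int(burned.sum()) < 4:
        warnings.warn("fewer than 4 burned pixels; severity mapping skipped", stacklevel=2)
        return None, None
    X, _ = _feature_matrix(d1, d2, burned)
    result = kmeans(X, 4, seed=seed, max_iter=max_iter, tol=tol)
    flags = list(result.flags)
    if "empty_cluster_repaired" in flags:
        flags.append("degenerate_severity")

    order = np.argsort(result.centroids.sum(axis=1), kind="stable")
    relabel = np.empty(4, dtype=int)
    relabel[order] = np.arange(4)
    classes = relabel[result.labels]

    values = np.full(d1.grid.shape, SEVERITY_NODATA, dtype=np.int16)
    values[burned] = classes
    counts = np.bincount(classes, minlength=4)
    sev = SeverityMap(values=values, grid=d1.grid, class_counts=counts, flags=flags)
    return sev, result
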