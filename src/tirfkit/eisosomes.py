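"""Nearest-eisosome distance mapping.

Condenses super-resolution blink localizations of an eisosome marker
(e.g. Sur7-YPet) into one centroid per eisosome by single-linkage
clustering, then computes for every protein localization (e.g.
Can1-mCardinal) the plain 2D Euclidean distance to the centroid of the
nearest eisosome, and bins those distances into comparable histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .io import Localization


@dataclass
class CentroidSet:
    """Eisosome centroid positions in micrometers."""

    centroids: np.ndarray  # (n, 2) of (x_um, y_um)
    source: str = ""

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return self.centroids.shape[0]


@dataclass
class DistanceDistribution:
    """Histogram of nearest-centroid distances, one per population label."""

    distances_um: np.ndarray
    bin_edges_um: np.ndarray
    counts: np.ndarray
    label: str | None = None


def cluster_centroids(
    localizations: list[Localization],
    radius_um: float,
    min_points: int = 1,
    source: str = "",
) -> CentroidSet:
    """Single-linkage clustering of blink localizations into centroids.

    Localizations within ``radius_um`` of each other (transitively) form one
    cluster; clusters with at least ``min_points`` members contribute their
    mean position as a centroid, smaller ones are discarded.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    if not localizations:
        return CentroidSet(np.empty((0, 2)), source=source)
    xy = np.array([[p.x_um, p.y_um] for p in localizations])
    tree = cKDTree(xy)
    pairs = tree.query_pairs(radius_um, output_type="ndarray")
    n = xy.shape[0]
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(graph, directed=False)
    centroids = []
    for c in range(n_comp):
        members = xy[labels == c]
        if members.shape[0] >= min_points:
            centroids.append(members.mean(axis=0))
    cents = np.array(centroids) if centroids else np.empty((0, 2))
    # deterministic ordering independent of input permutation
    if len(cents):
        cents = cents[np.lexsort((cents[:, 1], cents[:, 0]))]
    return CentroidSet(cents, source=source)


def nearest_centroid_distances(
    molecules: list[Localization], centroids: CentroidSet
) -> list[tuple[Localization, float, int]]:
    """Minimum Euclidean distance from each molecule to any centroid.

    Returns (molecule, distance_um, centroid_index) triples; exact ties go
    to the lowest centroid index.
    """
    if len(centroids) == 0:
        raise ValueError("centroid set is empty")
    if not molecules:
        return []
    xy = np.array([[m.x_um, m.y_um] for m in molecules])
    d = cdist(xy, centroids.centroids)
    idx = np.argmin(d, axis=1)  # argmin takes the lowest index on ties
    return [
        (m, float(d[i, idx[i]]), int(idx[i])) for i, m in enumerate(molecules)
    ]


def distance_histogram(
    distances_um,
    bin_width_um: float = 0.05,
    labels=None,
    max_um: float | None = None,
) -> list[DistanceDistribution]:
    """Left-closed right-open histograms of distances from zero.

    With ``labels`` given (one per distance), one histogram per distinct
    label is returned; all share the same bin edges so panels compare.
    The default 50 nm bin width matches the scale of single-molecule
    localization accuracy — finer bins would resolve nothing real.
    """
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be positive")
    distances_um = np.asarray(distances_um, dtype=float)
    if np.any(distances_um < 0):
        raise ValueError("distances must be non-negative")
    # all labels share one set of edges; the top bin is wide enough that the
    # largest distance still falls in a right-open bin
    if max_um is not None:
        n_bins = max(1, int(np.ceil(max_um / bin_width_um - 1e-12)))
    elif distances_um.size:
        n_bins = int(np.floor(float(distances_um.max()) / bin_width_um)) + 1
    else:
        n_bins = 1
    edges = np.arange(n_bins + 1) * bin_width_um
    if labels is None:
        groups = {None: distances_um}
    else:
        labels = np.asarray(labels)
        if labels.shape[0] != distances_um.shape[0]:
            raise ValueError("labels and distances must have equal length")
        groups = {lab: distances_um[labels == lab] for lab in np.unique(labels)}
    out = []
    for lab, vals in groups.items():
        bins = np.floor(vals / bin_width_um).astype(int)
        counts = np.bincount(bins[bins < n_bins], minlength=n_bins)
        out.append(
            DistanceDistribution(
                distances_um=vals, bin_edges_um=edges, counts=counts, label=lab
            )
        )
    return out
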