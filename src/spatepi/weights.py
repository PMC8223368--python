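"""Great-circle distances and spatial weight matrices over point clusters.

Survey clusters are GPS points spanning several degrees of latitude, so all
distances are haversine great-circle distances in kilometres (Earth radius
6371.0088 km).  Weights support the two conceptualizations used for point
data: k-nearest neighbours and a fixed distance band, optionally
row-standardized and optionally self-inclusive (Gi* requires w_ii > 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

EARTH_RADIUS_KM = 6371.0088


class IslandError(ValueError):
    """A distance band left one or more features without any neighbour."""

    def __init__(self, island_ids):
        self.island_ids = list(island_ids)
        super().__init__(
            f"distance band leaves {len(self.island_ids)} feature(s) with no "
            f"neighbour: {self.island_ids}"
        )


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.  Symmetric, nonnegative and
    exactly zero for identical points.
    """
    lat1a, lat2a = np.asarray(lat1, dtype=float), np.asarray(lat2, dtype=float)
    if np.any(np.abs(lat1a) > 90) or np.any(np.abs(lat2a) > 90):
        raise ValueError("latitude outside [-90, 90]")
    p1, p2 = np.radians(lat1a), np.radians(lat2a)
    dphi = p2 - p1
    dlmb = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def pairwise_distances_km(lon, lat):
    """Dense n x n haversine distance matrix for point arrays."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    return haversine_km(lon[None, :], lat[None, :], lon[:, None], lat[:, None])


def min_connecting_band(lon, lat):
    """Smallest distance band (km) giving every feature at least one neighbour.

    This is the ArcGIS-like default band: the maximum over features of the
    distance to their nearest neighbour.
    """
    d = pairwise_distances_km(lon, lat)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).max())


@dataclass
class SpatialWeights:
    """Sparse neighbour/weight structure over an ordered set of cluster ids.

    ``neighbors[i]`` holds 0-based positions into ``ids``; ``weights[i]`` the
    aligned nonnegative w_ij.  Row-standardized rows sum to one.
    """

    ids: np.ndarray
    neighbors: list = field(repr=False)
    weights: list = field(repr=False)
    row_standardized: bool = False
    includes_self: bool = False

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        if len(self.neighbors) != len(self.ids) or len(self.weights) != len(self.ids):
            raise ValueError("neighbors/weights not aligned with ids")
        for i, (nb, w) in enumerate(zip(self.neighbors, self.weights)):
            nb = np.asarray(nb, dtype=int)
            w = np.asarray(w, dtype=float)
            if nb.shape != w.shape:
                raise ValueError(f"row {i}: neighbor/weight length mismatch")
            if np.any(w < 0):
                raise ValueError(f"row {i}: negative weight")
            if nb.size and (nb.min() < 0 or nb.max() >= len(self.ids)):
                raise ValueError(f"row {i}: neighbor index out of range")
            if len(np.unique(nb)) != nb.size:
                raise ValueError(f"row {i}: duplicate neighbor")
            if self.row_standardized and nb.size and abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"row {i}: row-standardized row sums to {w.sum()}")
            self.neighbors[i] = nb
            self.weights[i] = w

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_sparse(self) -> sp.csr_matrix:
        rows = np.repeat(np.arange(self.n), [len(nb) for nb in self.neighbors])
        cols = np.concatenate(self.neighbors) if self.n else np.array([], dtype=int)
        data = np.concatenate(self.weights) if self.n else np.array([], dtype=float)
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def standardize(self) -> "SpatialWeights":
        """Return a row-standardized copy (each nonempty row sums to 1)."""
        wts = []
        for w in self.weights:
            s = w.sum()
            wts.append(w / s if s > 0 else w.copy())
        return SpatialWeights(
            self.ids, [nb.copy() for nb in self.neighbors], wts,
            row_standardized=True, includes_self=self.includes_self,
        )

    def binarize(self) -> "SpatialWeights":
        """Return the binary (0/1) structure underlying these weights."""
        return SpatialWeights(
            self.ids,
            [nb.copy() for nb in self.neighbors],
            [(w > 0).astype(float) for w in self.weights],
            row_standardized=False, includes_self=self.includes_self,
        )

    def to_triplets(self) -> pd.DataFrame:
        """Sparse triplet export (i_id, j_id, w)."""
        rec = []
        for i, (nb, w) in enumerate(zip(self.neighbors, self.weights)):
            for j, wij in zip(nb, w):
                rec.append((self.ids[i], self.ids[j], wij))
        return pd.DataFrame(rec, columns=["i_id", "j_id", "w"])


def build_weights(
    lon,
    lat,
    ids=None,
    method: str = "distance_band",
    param=None,
    row_standardize: bool = False,
    include_self: bool = False,
) -> SpatialWeights:
    """Build a spatial weight matrix over point features.

    Parameters
    ----------
    method : {"knn", "distance_band"}
        ``knn``: exactly ``param`` nearest neighbours per feature, distance
        ties broken by id order (lower id wins).  ``distance_band``: all
        features within ``param`` km; ``param=None`` uses the minimum band
        that leaves no feature isolated.
    include_self : add w_ii = 1 before any standardization (required by Gi*).
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n = lon.size
    if n < 2:
        raise ValueError("need at least 2 features")
    if ids is None:
        ids = np.arange(n)
    ids = np.asarray(ids)
    # rank of each feature in ascending id order; the documented tie-break
    id_rank = np.empty(n, dtype=int)
    id_rank[np.argsort(ids, kind="stable")] = np.arange(n)

    dist = pairwise_distances_km(lon, lat)
    neighbors, wts = [], []

    if method == "knn":
        k = int(param)
        if not 0 < k < n:
            raise ValueError(f"knn requires 0 < k < n; got k={k}, n={n}")
        for i in range(n):
            cand = np.delete(np.arange(n), i)
            order = np.lexsort((id_rank[cand], dist[i, cand]))
            nb = cand[order[:k]]
            neighbors.append(nb)
            wts.append(np.ones(k))
    elif method == "distance_band":
        band = min_connecting_band(lon, lat) if param is None else float(param)
        if band <= 0:
            raise ValueError("distance band must be positive")
        islands = []
        for i in range(n):
            nb = np.flatnonzero((dist[i] <= band) & (np.arange(n) != i))
            if nb.size == 0:
                islands.append(ids[i])
            neighbors.append(nb)
            wts.append(np.ones(nb.size))
        if islands:
            raise IslandError(islands)
    else:
        raise ValueError(f"unknown method {method!r}")

    if include_self:
        neighbors = [np.append(nb, i) for i, nb in enumerate(neighbors)]
        wts = [np.append(w, 1.0) for w in wts]

    W = SpatialWeights(ids, neighbors, wts, row_standardized=False,
                       includes_self=include_self)
    return W.standardize() if row_standardize else W
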