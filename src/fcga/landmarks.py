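"""Landmark selection and landmark time-series extraction.

A landmark is a reference location against which every vertex's connectivity
profile is measured: either a single vertex (chosen uniformly over the
geometry, or at random) or a parcel whose members are averaged.  Using k
landmarks instead of all n vertices reduces the connectivity representation
from n x n to n x k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ParcellationMap, TimeSeriesMatrix

__all__ = [
    "LandmarkSet",
    "select_random_vertices",
    "select_uniform_vertices",
    "landmarks_from_parcellation",
    "extract_landmark_timeseries",
]

UNIFORM = "uniform_vertices"
RANDOM = "random_vertices"
PARCELLATION = "parcellation"


@dataclass
class LandmarkSet:
    """k landmarks plus the sampling method that produced them."""

    method: str
    k: int
    vertex_indices: np.ndarray | None = None
    parcellation: ParcellationMap | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.method not in (UNIFORM, RANDOM, PARCELLATION):
            raise ValueError(f"unknown landmark method {self.method!r}")
        if self.k < 2:
            raise ValueError("need at least 2 landmarks")
        if self.method == PARCELLATION:
            if self.parcellation is None:
                raise ValueError("parcellation method requires a ParcellationMap")
            if self.parcellation.n_parcels != self.k:
                raise ValueError("k must equal the number of parcels")
        else:
            idx = np.asarray(self.vertex_indices, dtype=int)
            if idx.shape != (self.k,):
                raise ValueError("vertex_indices length must equal k")
            if len(np.unique(idx)) != self.k:
                raise ValueError("vertex_indices must be unique")
            if idx.min() < 0:
                raise ValueError("vertex_indices must be non-negative")
            self.vertex_indices = idx

    def provenance(self) -> dict:
        return {"landmark_method": self.method, "k": self.k, "seed": self.seed}


def select_random_vertices(n_vertices: int, k: int, seed: int) -> LandmarkSet:
    """Sample k distinct vertex indices uniformly without replacement."""
    if not 2 <= k <= n_vertices:
        raise ValueError(f"need 2 <= k <= n_vertices, got k={k}, n={n_vertices}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n_vertices, size=k, replace=False))
    return LandmarkSet(RANDOM, k, vertex_indices=idx, seed=seed)


def select_uniform_vertices(coords: np.ndarray, k: int, seed: int | None = None) -> LandmarkSet:
    """Spatially uniform landmarks by farthest-point sampling.

    Starting from the vertex farthest from the coordinate centroid (a
    deterministic, geometry-driven start, so the same landmark set is used
    for every individual), greedily adds the vertex farthest (Euclidean)
    from the current set.  The selected set is a deterministic function of
    (coords, k); ``seed`` is accepted for interface symmetry with the random
    sampler and recorded in provenance, but does not influence the set.
    Ties go to the lowest vertex index.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be an n x 3 matrix")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords must be finite")
    n = coords.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    start = int(np.argmax(np.linalg.norm(coords - coords.mean(axis=0), axis=1)))
    selected = [start]
    dist = np.linalg.norm(coords - coords[start], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(dist))  # argmax returns the lowest index on ties
        selected.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(coords - coords[nxt], axis=1))
    idx = np.sort(np.asarray(selected))
    return LandmarkSet(UNIFORM, k, vertex_indices=idx, seed=seed)


def landmarks_from_parcellation(p: ParcellationMap) -> LandmarkSet:
    """Use every parcel of a parcellation as one (averaged) landmark."""
    if p.n_parcels < 2:
        raise ValueError("parcellation must have at least 2 parcels")
    return LandmarkSet(PARCELLATION, p.n_parcels, parcellation=p)


def extract_landmark_timeseries(ts: TimeSeriesMatrix, lm: LandmarkSet) -> np.ndarray:
    """Return the k x T landmark signal matrix.

    Vertex landmarks copy rows verbatim; parcel landmarks take the unweighted
    mean over member vertices.  Rows are ordered by ascending vertex index /
    parcel id so downstream matrices have a canonical column order.
    """
    if lm.method == PARCELLATION:
        p = lm.parcellation
        if p.n_vertices != ts.n_vertices:
            raise ValueError(
                f"parcellation covers {p.n_vertices} vertices, "
                f"time series has {ts.n_vertices}"
            )
        out = np.empty((lm.k, ts.n_timepoints))
        for i, members in enumerate(p.parcel_members()):
            out[i] = ts.values[members].mean(axis=0)
        return out
    idx = lm.vertex_indices
    if idx.max() >= ts.n_vertices:
        raise ValueError(
            f"landmark index {idx.max()} out of range for {ts.n_vertices} vertices"
        )
    return ts.values[idx].copy()
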