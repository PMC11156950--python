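"""The fast connectivity gradient approximation (FCGA) engine.

The pipeline, given n vertex time series and k landmarks:

1. Pearson correlation of every vertex with every landmark -> CM (n x k),
   and of every landmark with every landmark -> CM (k x k).
2. Row-wise thresholding of both matrices, keeping the 10% strongest
   strictly-positive connections per row (``m = ceil(fraction * k)``).
3. Row-wise cosine similarity between vertex profiles (rows of the n x k
   matrix) and landmark profiles (rows of the k x k matrix) -> affinity
   matrix W (n x k).
4. PCA of W; the component scores are the connectivity gradients.

With every vertex as its own landmark the same code path computes the
classical full-matrix gradients, which serve as the reference the
approximation is judged against.  The approximation stores n*k affinity
entries instead of n^2, i.e. a fraction k/n of the full pipeline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GradientSet, TimeSeriesMatrix
from .landmarks import (
    PARCELLATION,
    RANDOM,
    LandmarkSet,
    extract_landmark_timeseries,
)

__all__ = [
    "ConnectivityMatrix",
    "AffinityMatrix",
    "pearson_connectivity",
    "threshold_rows_top_positive",
    "cosine_affinity",
    "pca_gradients",
    "fcga",
    "full_gradients",
    "landmark_connectivity_from_dense_fc",
    "fcga_from_dense_fc",
    "cost_summary",
    "DEFAULT_THRESHOLD_FRACTION",
    "DEFAULT_N_GRADIENTS",
]

DEFAULT_THRESHOLD_FRACTION = 0.10
DEFAULT_N_GRADIENTS = 25

VERTEX = "vertex"
LANDMARK = "landmark"


@dataclass
class ConnectivityMatrix:
    """Pearson correlations between row entities and column entities."""

    values: np.ndarray
    row_role: str = VERTEX
    col_role: str = LANDMARK
    thresholded: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("connectivity matrix must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class AffinityMatrix:
    """Cosine similarities between vertex and landmark connectivity profiles."""

    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("affinity matrix must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _standardized_rows(x: np.ndarray, zero_variance: str, who: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    bad = norms == 0.0
    if np.any(bad):
        if zero_variance == "raise":
            raise ValueError(
                f"{who}: zero-variance rows at indices "
                f"{np.flatnonzero(bad).tolist()[:10]}; correlation undefined "
                "(pass zero_variance='zero' to map them to r=0)"
            )
        warnings.warn(
            f"{who}: {int(bad.sum())} zero-variance rows mapped to r=0"
        )
        norms = np.where(bad, 1.0, norms)
        centered = np.where(bad[:, None], 0.0, centered)
    return centered / norms[:, None]


def pearson_connectivity(
    x: np.ndarray,
    y: np.ndarray,
    *,
    row_role: str = VERTEX,
    col_role: str = LANDMARK,
    zero_variance: str = "raise",
) -> ConnectivityMatrix:
    """Pearson correlation of every row of ``x`` with every row of ``y``.

    Both inputs are entities-by-timepoints with a shared time axis of length
    T >= 3.  ``zero_variance`` is ``"raise"`` (default) or ``"zero"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or y.ndim != 2:
        raise ValueError("inputs must be 2-D (entities x timepoints)")
    if x.shape[1] != y.shape[1]:
        raise ValueError(f"timepoint mismatch: {x.shape[1]} vs {y.shape[1]}")
    if x.shape[1] < 3:
        raise ValueError("need at least 3 timepoints for correlation")
    xs = _standardized_rows(x, zero_variance, "rows of x")
    ys = _standardized_rows(y, zero_variance, "rows of y")
    r = np.clip(xs @ ys.T, -1.0, 1.0)
    return ConnectivityMatrix(r, row_role=row_role, col_role=col_role)


def threshold_rows_top_positive(
    cm: ConnectivityMatrix, fraction: float = DEFAULT_THRESHOLD_FRACTION
) -> ConnectivityMatrix:
    """Keep only each row's strongest positive connections.

    Per row, the ``m = ceil(fraction * n_cols)`` largest strictly positive
    entries are retained and everything else (including all negative values)
    is set to zero.  Rows with fewer than m positive entries keep all their
    positives; a row with none becomes all-zero (warned, since its cosine
    affinity is undefined downstream).  Idempotent.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    values = cm.values
    n_cols = values.shape[1]
    m = math.ceil(fraction * n_cols)
    # entries ranked per row, largest first; stable sort so ties keep the
    # lowest column index, making the kept set deterministic
    order = np.argsort(-values, axis=1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(n_cols)[None, :], axis=1)
    keep = (ranks < m) & (values > 0.0)
    out = np.where(keep, values, 0.0)
    empty = ~keep.any(axis=1)
    if np.any(empty):
        warnings.warn(
            f"{int(empty.sum())} rows have no positive connections and were "
            "zeroed by thresholding"
        )
    return ConnectivityMatrix(
        out, row_role=cm.row_role, col_role=cm.col_role, thresholded=True
    )


def cosine_affinity(
    cm_nk: ConnectivityMatrix,
    cm_kk: ConnectivityMatrix,
    *,
    zero_rows: str = "zero",
    provenance: dict | None = None,
) -> AffinityMatrix:
    """Row-wise cosine similarity between vertex and landmark profiles.

    ``W[i, j]`` is the cosine of row i of the (thresholded) n x k matrix with
    row j of the (thresholded) k x k matrix.  All-zero rows make the cosine
    undefined; by default their entries are set to 0 with a warning
    (``zero_rows="raise"`` to fail instead).
    """
    if not (cm_nk.thresholded and cm_kk.thresholded):
        raise ValueError("cosine affinity expects thresholded inputs")
    a, b = cm_nk.values, cm_kk.values
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"column mismatch: {a.shape[1]} vs {b.shape[1]}")

    def _unit(rows: np.ndarray, who: str) -> np.ndarray:
        norms = np.linalg.norm(rows, axis=1)
        bad = norms == 0.0
        if np.any(bad):
            if zero_rows == "raise":
                raise ValueError(
                    f"{who}: all-zero rows at {np.flatnonzero(bad).tolist()[:10]}"
                )
            warnings.warn(
                f"{who}: {int(bad.sum())} all-zero rows; their affinities set to 0"
            )
            norms = np.where(bad, 1.0, norms)
        return rows / norms[:, None]

    w = np.clip(_unit(a, "vertex profiles") @ _unit(b, "landmark profiles").T, -1.0, 1.0)
    return AffinityMatrix(w, provenance=provenance or {})


def pca_gradients(w: AffinityMatrix, n_components: int) -> GradientSet:
    """PCA of the affinity matrix; component scores are the gradients.

    Columns of W are mean-centered (no variance scaling) and the singular
    value decomposition gives the principal components.  Scores are ordered
    by decreasing explained variance.  The sign of each component is fixed
    deterministically: the loading entry of largest absolute value is made
    positive (ties: lowest landmark index).
    """
    values = w.values
    n, k = values.shape
    if not 1 <= n_components <= min(n, k):
        raise ValueError(
            f"n_components must be in [1, {min(n, k)}], got {n_components}"
        )
    centered = values - values.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    tol = max(n, k) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds the matrix rank {rank}; "
            f"at most {rank} gradients are achievable"
        )
    # deterministic sign: largest-|loading| entry of each component positive
    lead = np.argmax(np.abs(vt), axis=1)
    signs = np.sign(vt[np.arange(vt.shape[0]), lead])
    signs[signs == 0] = 1.0
    u = u * signs[None, :]

    total_var = float(np.sum(s**2))
    evr = (s[:n_components] ** 2) / total_var
    scores = u[:, :n_components] * s[:n_components]
    provenance = dict(w.provenance)
    provenance["n_components"] = n_components
    return GradientSet(scores, evr, provenance)


def fcga(
    ts: TimeSeriesMatrix,
    lm: LandmarkSet,
    n_components: int = DEFAULT_N_GRADIENTS,
    fraction: float = DEFAULT_THRESHOLD_FRACTION,
    *,
    zero_variance: str = "raise",
    zero_rows: str = "zero",
) -> GradientSet:
    """Approximate connectivity gradients from k landmarks.

    Composes the full pipeline: landmark extraction, vertex-landmark and
    landmark-landmark Pearson correlation, row-wise positive thresholding
    at ``fraction``, cosine affinity, PCA.  Deterministic for fixed inputs.
    """
    lmts = extract_landmark_timeseries(ts, lm)
    cm_nk = pearson_connectivity(ts.values, lmts, zero_variance=zero_variance)
    cm_kk = pearson_connectivity(
        lmts, lmts, row_role=LANDMARK, zero_variance=zero_variance
    )
    provenance = lm.provenance()
    provenance["threshold_fraction"] = fraction
    w = cosine_affinity(
        threshold_rows_top_positive(cm_nk, fraction),
        threshold_rows_top_positive(cm_kk, fraction),
        zero_rows=zero_rows,
        provenance=provenance,
    )
    return pca_gradients(w, n_components)


def full_gradients(
    ts: TimeSeriesMatrix,
    n_components: int = DEFAULT_N_GRADIENTS,
    fraction: float = DEFAULT_THRESHOLD_FRACTION,
    *,
    max_vertices: int = 10_000,
    zero_variance: str = "raise",
    zero_rows: str = "zero",
) -> GradientSet:
    """Reference gradients from the full n x n connectivity matrix.

    Defined as the FCGA pipeline with every vertex its own landmark, which
    makes the approximation target exact: ``fcga`` with identity landmarks is
    bit-identical to this function.  Guarded by ``max_vertices`` because the
    dense pipeline needs O(n^2) memory.
    """
    n = ts.n_vertices
    if n > max_vertices:
        raise ValueError(
            f"n={n} exceeds the {max_vertices}-vertex guard for the dense "
            "pipeline; use fcga with a landmark subset instead"
        )
    lm = LandmarkSet(RANDOM, n, vertex_indices=np.arange(n), seed=None)
    out = fcga(
        ts,
        lm,
        n_components,
        fraction,
        zero_variance=zero_variance,
        zero_rows=zero_rows,
    )
    out.provenance["landmark_method"] = "full"
    return out


def landmark_connectivity_from_dense_fc(
    fc: ConnectivityMatrix, lm: LandmarkSet
) -> ConnectivityMatrix:
    """Reduce a precomputed dense n x n FC matrix to n x k landmark columns.

    For parcel landmarks the columns belonging to each parcel are averaged
    (the group-level variant: landmark connectivity is the mean of the
    precomputed vertex connectivities rather than recomputed from signal);
    for vertex landmarks the columns are selected.
    """
    if fc.thresholded:
        raise ValueError("expects an unthresholded dense FC matrix")
    values = fc.values
    if values.shape[0] != values.shape[1]:
        raise ValueError("dense FC matrix must be square")
    n = values.shape[0]
    if lm.method == PARCELLATION:
        p = lm.parcellation
        if p.n_vertices != n:
            raise ValueError("parcellation does not match FC matrix size")
        cols = np.empty((n, lm.k))
        for j, members in enumerate(p.parcel_members()):
            cols[:, j] = values[:, members].mean(axis=1)
    else:
        if lm.vertex_indices.max() >= n:
            raise ValueError("landmark index out of range for FC matrix")
        cols = values[:, lm.vertex_indices].copy()
    return ConnectivityMatrix(cols, row_role=VERTEX, col_role=LANDMARK)


def fcga_from_dense_fc(
    fc: ConnectivityMatrix,
    lm: LandmarkSet,
    n_components: int = DEFAULT_N_GRADIENTS,
    fraction: float = DEFAULT_THRESHOLD_FRACTION,
    *,
    zero_rows: str = "zero",
) -> GradientSet:
    """FCGA starting from a precomputed dense connectivity matrix.

    The n x k matrix is the landmark reduction of the dense FC; the k x k
    matrix is the same reduction applied to the landmark rows.  Thresholding
    happens after the reduction.
    """
    cm_nk = landmark_connectivity_from_dense_fc(fc, lm)
    if lm.method == PARCELLATION:
        p = lm.parcellation
        kk = np.empty((lm.k, lm.k))
        for i, members in enumerate(p.parcel_members()):
            kk[i] = cm_nk.values[members].mean(axis=0)
    else:
        kk = cm_nk.values[lm.vertex_indices].copy()
    cm_kk = ConnectivityMatrix(kk, row_role=LANDMARK, col_role=LANDMARK)
    provenance = lm.provenance()
    provenance["threshold_fraction"] = fraction
    provenance["source"] = "dense_fc"
    w = cosine_affinity(
        threshold_rows_top_positive(cm_nk, fraction),
        threshold_rows_top_positive(cm_kk, fraction),
        zero_rows=zero_rows,
        provenance=provenance,
    )
    return pca_gradients(w, n_components)


def cost_summary(n_vertices: int, k: int) -> dict:
    """Stored affinity entries of the approximation vs the full pipeline."""
    return {
        "affinity_entries": n_vertices * k,
        "full_entries": n_vertices * n_vertices,
        "ratio": k / n_vertices,
    }
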