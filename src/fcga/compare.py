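"""Aligning and comparing gradient sets.

PCA component signs (and, between datasets, component order) are arbitrary,
so two gradient sets are compared either after orthogonal Procrustes
alignment to a common reference (signed metrics are then meaningful) or
without alignment using sign-invariant absolute Spearman correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import orthogonal_procrustes
from scipy.stats import pearsonr, spearmanr

from .io_formats import GradientSet

__all__ = [
    "AlignmentResult",
    "SimilarityReport",
    "procrustes_align",
    "spearman_similarity",
    "vertexwise_profile_similarity",
    "landmark_similarity_curve",
]


@dataclass
class AlignmentResult:
    aligned: GradientSet
    transform: np.ndarray  # g x g orthogonal
    residual: float  # Frobenius norm of (aligned - reference)


@dataclass
class SimilarityReport:
    per_gradient_rho: np.ndarray
    mean_rho: float
    mode: str  # "signed" | "absolute"


def _check_match(a: GradientSet, b: GradientSet) -> None:
    if a.coefficients.shape != b.coefficients.shape:
        raise ValueError(
            f"gradient sets differ in shape: {a.coefficients.shape} vs "
            f"{b.coefficients.shape}"
        )


def procrustes_align(source: GradientSet, reference: GradientSet) -> AlignmentResult:
    """Rotate/reflect ``source`` onto ``reference`` (orthogonal Procrustes).

    Finds the orthogonal g x g matrix R minimizing ||source @ R - reference||_F
    (closed form via the SVD of source.T @ reference); no scaling or
    translation is applied.  This matches component order and coefficient
    signs between the two sets.
    """
    _check_match(source, reference)
    r, _ = orthogonal_procrustes(source.coefficients, reference.coefficients)
    aligned_coeffs = source.coefficients @ r
    residual = float(np.linalg.norm(aligned_coeffs - reference.coefficients))
    # after rotation the per-column variance shares are recomputed from the
    # rotated columns; they need not be ordered any more
    col_var = aligned_coeffs.var(axis=0)
    src_var = source.coefficients.var(axis=0)
    total = src_var.sum()
    evr_scale = source.explained_variance_ratio.sum() / total if total > 0 else 0.0
    provenance = dict(source.provenance)
    provenance["aligned_to_reference"] = True
    aligned = GradientSet(aligned_coeffs, col_var * evr_scale, provenance)
    return AlignmentResult(aligned=aligned, transform=r, residual=residual)


def spearman_similarity(
    a: GradientSet, b: GradientSet, mode: str = "absolute"
) -> SimilarityReport:
    """Component-wise Spearman rank correlation between two gradient sets.

    ``mode="absolute"`` (default) reports |rho| per gradient, appropriate when
    no alignment was applied and signs are arbitrary; ``mode="signed"`` is for
    use after Procrustes alignment.
    """
    if mode not in ("signed", "absolute"):
        raise ValueError("mode must be 'signed' or 'absolute'")
    _check_match(a, b)
    g = a.n_gradients
    rho = np.empty(g)
    for c in range(g):
        xa, xb = a.coefficients[:, c], b.coefficients[:, c]
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            raise ValueError(
                f"gradient column {c + 1} is constant; Spearman undefined"
            )
        rho[c] = spearmanr(xa, xb).statistic
    if mode == "absolute":
        rho = np.abs(rho)
    return SimilarityReport(rho, float(rho.mean()), mode)


def landmark_similarity_curve(
    ts,
    fractions=(0.005, 0.01, 0.05, 0.10, 1.0),
    n_components: int = 10,
    seed: int = 0,
    reference: GradientSet | None = None,
):
    """Mean |Spearman| between landmark and full-matrix gradients, per k.

    For each landmark fraction the expected similarity is estimated by
    averaging over several random landmark draws; small k levels get more
    draws because a single tiny draw is a noisy estimate of the level's
    similarity (64 draws for k <= 30, 10 for k <= 150, 5 above).  The
    fraction-1.0 level is the full pipeline itself and equals 1 exactly.

    Returns ``(fractions, mean_rhos)`` as two lists.
    """
    from .core import fcga as _fcga  # local import to avoid a cycle
    from .core import full_gradients
    from .landmarks import select_random_vertices

    n = ts.n_vertices
    full = reference
    if full is None:
        full = full_gradients(ts, n_components, zero_variance="zero")
    means = []
    for frac in fractions:
        k = int(np.ceil(frac * n))
        if k >= n:
            means.append(spearman_similarity(full, full).mean_rho)
            continue
        n_draws = 64 if k <= 30 else (10 if k <= 150 else 5)
        vals = []
        for d in range(n_draws):
            lm = select_random_vertices(n, k, seed=(seed + 7 * d) % (2**31 - 1))
            gs = _fcga(ts, lm, n_components, zero_variance="zero")
            vals.append(spearman_similarity(gs, full).mean_rho)
        means.append(float(np.mean(vals)))
    return list(fractions), means


def vertexwise_profile_similarity(
    a: GradientSet, b: GradientSet, metric: str = "pearson"
) -> np.ndarray:
    """Per-vertex correlation of gradient profiles across the g components.

    A vertex's gradient profile is its row of coefficients (length g); the
    returned vector holds its correlation between the two sets.  Vertices
    with a constant profile get NaN (counted and warned).
    """
    if metric not in ("pearson", "spearman"):
        raise ValueError("metric must be 'pearson' or 'spearman'")
    _check_match(a, b)
    n, g = a.coefficients.shape
    if g < 2:
        raise ValueError("profile similarity needs at least 2 gradients")
    out = np.full(n, np.nan)
    n_missing = 0
    for i in range(n):
        pa, pb = a.coefficients[i], b.coefficients[i]
        if np.ptp(pa) == 0 or np.ptp(pb) == 0:
            n_missing += 1
            continue
        if metric == "pearson":
            out[i] = pearsonr(pa, pb).statistic
        else:
            out[i] = spearmanr(pa, pb).statistic
    if n_missing:
        warnings.warn(
            f"{n_missing} vertices have constant gradient profiles; "
            "similarity recorded as NaN"
        )
    return out
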