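"""Brain-behavior prediction benchmark.

Two ways to build parcel-level gradient features for a cohort:

* gradients-to-parcellation (g2p): compute vertex-level gradients first
  (via the landmark approximation), align each subject to a common
  reference with orthogonal Procrustes, then average coefficients within
  parcels.
* parcellation-to-gradients (p2g): average the time series within parcels
  first, then compute gradients on the parcel-level data using all parcels
  as landmarks.

Prediction uses ridge regression inside a nested tenfold cross-validation:
the inner CV (on the outer training portion only) picks the penalty
minimizing mean absolute error, the refit model predicts the held-out fold,
and per repeat the fold predictions are aggregated before computing MAE and
Pearson r.  A shuffled-label baseline provides the chance distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest, pearsonr
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from .compare import procrustes_align
from .core import (
    DEFAULT_THRESHOLD_FRACTION,
    ConnectivityMatrix,
    cosine_affinity,
    pca_gradients,
    pearson_connectivity,
    threshold_rows_top_positive,
)
from .io_formats import GradientSet, ParcellationMap, TimeSeriesMatrix
from .landmarks import LandmarkSet, extract_landmark_timeseries, landmarks_from_parcellation

__all__ = [
    "FeatureTable",
    "PredictionReport",
    "ConstructionComparison",
    "parcel_average_gradients",
    "parcellated_gradients",
    "build_feature_table",
    "ridge_cv_predict",
    "permutation_baseline",
    "compare_constructions",
    "default_lambda_grid",
]

G2P = "gradients_to_parcellation"
P2G = "parcellation_to_gradients"
DEFAULT_N_FEATURE_GRADIENTS = 5


@dataclass
class FeatureTable:
    """Subjects x (parcels * g) features, parcel-major, gradient-minor."""

    features: np.ndarray
    construction: str
    n_parcels: int
    g: int = DEFAULT_N_FEATURE_GRADIENTS

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature table contains non-finite values")
        if self.features.shape[1] != self.n_parcels * self.g:
            raise ValueError("feature width must be n_parcels * g")


@dataclass
class PredictionReport:
    per_repeat_mae: np.ndarray
    per_repeat_r: np.ndarray
    predictions: np.ndarray  # repeats x subjects, fold-aggregated
    seed: int
    null_mae: np.ndarray | None = None
    null_r: np.ndarray | None = None
    p_value_r: float | None = None
    p_value_mae: float | None = None


@dataclass
class ConstructionComparison:
    report_g2p: PredictionReport
    report_p2g: PredictionReport
    mae_differences: np.ndarray  # p2g - g2p, per repeat (positive favors g2p)
    g2p_wins: int
    n_repeats: int
    p_value: float  # sign-test, Bonferroni-adjusted
    n_comparisons: int


# ---------------------------------------------------------------------------
# feature construction


def parcel_average_gradients(
    gs: GradientSet, p: ParcellationMap, g: int = DEFAULT_N_FEATURE_GRADIENTS
) -> np.ndarray:
    """Parcel-wise means of the first g vertex-level gradients, flattened.

    Order is parcel-major, gradient-minor: feature ``q * g + c`` is the mean
    of gradient ``c+1`` over parcel ``q+1``.
    """
    if p.n_vertices != gs.n_vertices:
        raise ValueError("parcellation and gradients cover different vertices")
    if g > gs.n_gradients:
        raise ValueError(f"requested {g} gradients, set has {gs.n_gradients}")
    coeffs = gs.coefficients[:, :g]
    out = np.empty((p.n_parcels, g))
    for q, members in enumerate(p.parcel_members()):
        out[q] = coeffs[members].mean(axis=0)
    return out.ravel()


def _parcellated_gradient_matrix(
    ts: TimeSeriesMatrix,
    p: ParcellationMap,
    g: int,
    fraction: float,
) -> GradientSet:
    """Gradients of the parcel-averaged data (all parcels as landmarks)."""
    if p.n_parcels < g + 1:
        raise ValueError("need more parcels than requested gradients")
    lm = landmarks_from_parcellation(p)
    parcel_ts = extract_landmark_timeseries(ts, lm)
    cm = pearson_connectivity(parcel_ts, parcel_ts, row_role="landmark")
    thr = threshold_rows_top_positive(cm, fraction)
    w = cosine_affinity(thr, thr, provenance={"landmark_method": "parcellation",
                                              "k": p.n_parcels,
                                              "threshold_fraction": fraction})
    return pca_gradients(w, g)


def parcellated_gradients(
    ts: TimeSeriesMatrix,
    p: ParcellationMap,
    g: int = DEFAULT_N_FEATURE_GRADIENTS,
    fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> np.ndarray:
    """Coarse-grained gradients: parcel-average the signal, then embed.

    Returns the P x g coefficients flattened in the same parcel-major order
    as :func:`parcel_average_gradients`.
    """
    return _parcellated_gradient_matrix(ts, p, g, fraction).coefficients.ravel()


def _group_reference_gradients(
    cms: list[tuple[np.ndarray, np.ndarray]], g: int, fraction: float
) -> GradientSet:
    """Gradients of the group-average connectome.

    Per-subject vertex-landmark and landmark-landmark correlation matrices
    are averaged across the cohort and the standard threshold -> cosine ->
    PCA pipeline runs on the average; the result is the common alignment
    reference, mirroring the use of a group-average dense connectome as the
    reference for individual-level alignment.
    """
    avg_nk = np.mean([nk for nk, _ in cms], axis=0)
    avg_kk = np.mean([kk for _, kk in cms], axis=0)
    w = cosine_affinity(
        threshold_rows_top_positive(ConnectivityMatrix(avg_nk), fraction),
        threshold_rows_top_positive(
            ConnectivityMatrix(avg_kk, row_role="landmark"), fraction
        ),
        provenance={"source": "group_average"},
    )
    return pca_gradients(w, g)


def build_feature_table(
    cohort_ts: list[TimeSeriesMatrix],
    p: ParcellationMap,
    construction: str,
    *,
    landmark_set: LandmarkSet | None = None,
    g: int = DEFAULT_N_FEATURE_GRADIENTS,
    n_align: int | None = None,
    fraction: float = DEFAULT_THRESHOLD_FRACTION,
    reference: GradientSet | None = None,
) -> FeatureTable:
    """Per-subject parcel-level gradient features for a cohort.

    For ``gradients_to_parcellation`` each subject's vertex-level gradients
    (FCGA with ``landmark_set``) are Procrustes-aligned to a common
    reference before parcel averaging, so components match across subjects;
    for ``parcellation_to_gradients`` the parcel-level gradient matrices are
    aligned analogously.  When no ``reference`` is passed it is built from
    the group-average connectivity of the cohort itself.

    Alignment happens in an ``n_align``-dimensional gradient space (default
    ``2 g``, capped by the achievable rank) and the first ``g`` aligned
    components become features: aligning in a larger space than the feature
    count absorbs component-order drift around the cut at g.
    """
    if construction not in (G2P, P2G):
        raise ValueError(f"unknown construction {construction!r}")

    if construction == G2P:
        if landmark_set is None:
            raise ValueError("gradients_to_parcellation needs a landmark_set")
        cms = []
        for ts in cohort_ts:
            lmts = extract_landmark_timeseries(ts, landmark_set)
            nk = pearson_connectivity(ts.values, lmts, zero_variance="zero")
            kk = pearson_connectivity(
                lmts, lmts, row_role="landmark", zero_variance="zero"
            )
            cms.append((nk.values, kk.values))
    else:
        lm_parc = landmarks_from_parcellation(p)
        cms = []
        for ts in cohort_ts:
            if p.n_parcels < g + 1:
                raise ValueError("need more parcels than requested gradients")
            parcel_ts = extract_landmark_timeseries(ts, lm_parc)
            kk = pearson_connectivity(
                parcel_ts, parcel_ts, row_role="landmark", zero_variance="zero"
            )
            cms.append((kk.values, kk.values))

    k_cols = cms[0][0].shape[1]
    if n_align is None:
        n_align = min(2 * g, k_cols - 1)
    n_align = max(n_align, g)

    ref = reference
    if ref is None:
        ref = _group_reference_gradients(cms, n_align, fraction)
    if ref.n_gradients < n_align:
        raise ValueError("reference has fewer gradients than n_align")

    rows = []
    for nk, kk in cms:
        w = cosine_affinity(
            threshold_rows_top_positive(ConnectivityMatrix(nk), fraction),
            threshold_rows_top_positive(
                ConnectivityMatrix(kk, row_role="landmark"), fraction
            ),
        )
        gs = procrustes_align(pca_gradients(w, n_align), ref).aligned
        if construction == G2P:
            rows.append(parcel_average_gradients(gs, p, g))
        else:
            rows.append(gs.coefficients[:, :g].ravel())
    return FeatureTable(np.asarray(rows), construction, p.n_parcels, g)


# ---------------------------------------------------------------------------
# ridge with nested cross-validation


def default_lambda_grid(features: np.ndarray, target: np.ndarray, n: int = 30) -> np.ndarray:
    """30 log-spaced penalties from 1e-3 * lambda_max to lambda_max.

    lambda_max is the largest absolute inner product between a z-scored
    feature and the centered target — the scale at which the ridge solution
    is fully shrunk toward zero.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    xs = x - x.mean(axis=0)
    sd = xs.std(axis=0)
    sd[sd == 0] = 1.0
    xs = xs / sd
    lam_max = float(np.abs(xs.T @ (y - y.mean())).max())
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(1e-3 * lam_max, lam_max, n)


def _zscore_train_apply(x_train: np.ndarray, x_other: np.ndarray):
    mean = x_train.mean(axis=0)
    sd = x_train.std(axis=0)
    sd[sd == 0] = 1.0
    return (x_train - mean) / sd, (x_other - mean) / sd


def nested_fold_indices(
    n_subjects: int, n_folds: int, random_state: int
):
    """Outer folds plus, per outer fold, inner folds over the training part.

    Yields ``(train_idx, test_idx, inner_splits)`` where ``inner_splits`` is a
    list of ``(inner_train, inner_val)`` index arrays *into the full subject
    axis*, all drawn from ``train_idx`` only — the held-out fold never enters
    hyperparameter selection.
    """
    outer = KFold(n_splits=n_folds, shuffle=True, random_state=random_state)
    idx = np.arange(n_subjects)
    for f, (train, test) in enumerate(outer.split(idx)):
        inner = KFold(n_splits=n_folds, shuffle=True,
                      random_state=random_state + 1000 + f)
        inner_splits = [
            (train[itr], train[ival]) for itr, ival in inner.split(train)
        ]
        yield train, test, inner_splits


def _one_cv_run(
    x: np.ndarray,
    y: np.ndarray,
    n_folds: int,
    lambda_grid: np.ndarray,
    random_state: int,
) -> tuple[float, float, np.ndarray]:
    """One repeat of nested tenfold CV; returns (mae, r, aggregated preds)."""
    n = x.shape[0]
    preds = np.empty(n)
    for train, test, inner_splits in nested_fold_indices(n, n_folds, random_state):
        inner_err = np.zeros(len(lambda_grid))
        for itr, ival in inner_splits:
            xtr, xval = _zscore_train_apply(x[itr], x[ival])
            ytr = y[itr]
            for li, lam in enumerate(lambda_grid):
                model = Ridge(alpha=lam)
                model.fit(xtr, ytr)
                inner_err[li] += np.abs(model.predict(xval) - y[ival]).mean()
        best_lam = lambda_grid[int(np.argmin(inner_err))]
        xtr, xte = _zscore_train_apply(x[train], x[test])
        model = Ridge(alpha=best_lam)
        model.fit(xtr, y[train])
        preds[test] = model.predict(xte)
    mae = float(np.abs(preds - y).mean())
    r = float(pearsonr(preds, y).statistic) if np.ptp(preds) > 0 else 0.0
    return mae, r, preds


def ridge_cv_predict(
    features: FeatureTable | np.ndarray,
    target: np.ndarray,
    n_folds: int = 10,
    n_repeats: int = 100,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
) -> PredictionReport:
    """Ridge regression under repeated nested tenfold cross-validation.

    Per repeat the outer split is re-randomized; the inner CV selects the
    penalty by mean absolute error on the outer-training subjects only; the
    fold predictions are aggregated and scored once per repeat.
    """
    x = features.features if isinstance(features, FeatureTable) else np.asarray(features, float)
    y = np.asarray(target, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValueError("target length must match number of subjects")
    if not np.all(np.isfinite(y)):
        raise ValueError("target contains non-finite values")
    if np.ptp(y) == 0:
        raise ValueError("target is constant; nothing to predict")
    if x.shape[0] < 3 * n_folds:
        raise ValueError(f"need at least {3 * n_folds} subjects for {n_folds} folds")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(x, y)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda grid is empty")

    maes = np.empty(n_repeats)
    rs = np.empty(n_repeats)
    preds = np.empty((n_repeats, x.shape[0]))
    for rep in range(n_repeats):
        maes[rep], rs[rep], preds[rep] = _one_cv_run(
            x, y, n_folds, lambda_grid, random_state=(seed + rep) % (2**31 - 1)
        )
    return PredictionReport(maes, rs, preds, seed=seed)


def permutation_baseline(
    features: FeatureTable | np.ndarray,
    target: np.ndarray,
    n_perm: int = 100,
    n_folds: int = 10,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
    observed: PredictionReport | None = None,
) -> PredictionReport:
    """Chance-level distributions from shuffled-label prediction runs.

    Each permutation run shuffles the target and performs one nested tenfold
    CV.  p-values use the add-one formula against the median observed
    statistic: ``p = (1 + #{null r >= median observed r}) / (1 + n_perm)``
    (analogously ``<=`` for MAE), so the minimum attainable p is
    ``1 / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    x = features.features if isinstance(features, FeatureTable) else np.asarray(features, float)
    y = np.asarray(target, dtype=float)
    if observed is None:
        observed = ridge_cv_predict(
            features, target, n_folds=n_folds, n_repeats=1,
            lambda_grid=lambda_grid, seed=seed,
        )
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(x, y)
    rng = np.random.default_rng(seed)
    null_mae = np.empty(n_perm)
    null_r = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        null_mae[i], null_r[i], _ = _one_cv_run(
            x, y_perm, n_folds, np.asarray(lambda_grid, float),
            random_state=(seed + 31 * (i + 1)) % (2**31 - 1),
        )
    obs_r = float(np.median(observed.per_repeat_r))
    obs_mae = float(np.median(observed.per_repeat_mae))
    p_r = (1 + int(np.sum(null_r >= obs_r))) / (1 + n_perm)
    p_mae = (1 + int(np.sum(null_mae <= obs_mae))) / (1 + n_perm)
    return PredictionReport(
        observed.per_repeat_mae, observed.per_repeat_r, observed.predictions,
        seed=seed, null_mae=null_mae, null_r=null_r,
        p_value_r=p_r, p_value_mae=p_mae,
    )


def compare_constructions(
    cohort_ts: list[TimeSeriesMatrix],
    p: ParcellationMap,
    target: np.ndarray,
    *,
    landmark_set: LandmarkSet,
    g: int = DEFAULT_N_FEATURE_GRADIENTS,
    n_align: int | None = None,
    fraction: float = DEFAULT_THRESHOLD_FRACTION,
    n_folds: int = 10,
    n_repeats: int = 100,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
    n_comparisons: int = 1,
) -> ConstructionComparison:
    """Paired benchmark of the two feature constructions on one cohort.

    Both arms share the same fold splits (same seeds), so per-repeat metric
    differences are paired.  Reports the per-repeat MAE difference
    (p2g - g2p; positive means the fine-grained construction predicted
    better), the number of repeats the g2p arm wins, and a sign-test p-value
    Bonferroni-adjusted for ``n_comparisons`` user comparisons.
    """
    if len(cohort_ts) != len(target):
        raise ValueError("one time series per subject is required")
    ft_g2p = build_feature_table(
        cohort_ts, p, G2P, landmark_set=landmark_set, g=g, n_align=n_align,
        fraction=fraction,
    )
    ft_p2g = build_feature_table(
        cohort_ts, p, P2G, g=g, n_align=n_align, fraction=fraction
    )
    shared = dict(n_folds=n_folds, n_repeats=n_repeats, seed=seed)
    rep_g2p = ridge_cv_predict(ft_g2p, target, lambda_grid=lambda_grid, **shared)
    rep_p2g = ridge_cv_predict(ft_p2g, target, lambda_grid=lambda_grid, **shared)
    diffs = rep_p2g.per_repeat_mae - rep_g2p.per_repeat_mae
    wins = int(np.sum(diffs > 0))
    n_eff = int(np.sum(diffs != 0))
    if n_eff > 0:
        p_raw = binomtest(int(np.sum(diffs[diffs != 0] > 0)), n_eff).pvalue
    else:
        p_raw = 1.0
    p_adj = min(1.0, p_raw * n_comparisons)
    return ConstructionComparison(
        report_g2p=rep_g2p,
        report_p2g=rep_p2g,
        mae_differences=diffs,
        g2p_wins=wins,
        n_repeats=n_repeats,
        p_value=float(p_adj),
        n_comparisons=n_comparisons,
    )
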