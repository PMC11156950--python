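"""Test-retest reliability of gradient measurements.

Two complementary statistics over panels of repeated measurements:

* ICC — intraclass correlation, two-way random effects, absolute agreement,
  single measure (ICC(2,1) / ICC(A,1)); a univariate per-vertex measure.
* Discriminability — a nonparametric multivariate statistic: the probability
  that two measurements of the same subject are closer to each other than a
  measurement of that subject is to one of a different subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .io_formats import GradientSet

__all__ = [
    "ReliabilityPanel",
    "ICCResult",
    "icc_absolute_agreement",
    "vertexwise_icc",
    "discriminability",
]

ICC_MODEL_TAG = "two-way random effects, absolute agreement, single measure"


@dataclass
class ICCResult:
    icc: float | np.ndarray
    model_tag: str = ICC_MODEL_TAG


@dataclass
class ReliabilityPanel:
    """Repeated measurements labeled by subject and session.

    ``data`` has shape (n_measurements, ...); trailing axes are the
    measurement's features (for gradient panels: n_vertices x g).
    """

    data: np.ndarray
    subject_ids: np.ndarray
    session_ids: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        self.session_ids = np.asarray(self.session_ids)
        n = self.data.shape[0]
        if self.subject_ids.shape != (n,) or self.session_ids.shape != (n,):
            raise ValueError("one subject_id and session_id per measurement")
        if len(np.unique(self.subject_ids)) < 2:
            raise ValueError("panel needs at least 2 subjects")

    @classmethod
    def from_gradient_sets(
        cls, sets: list[GradientSet], subject_ids, session_ids
    ) -> "ReliabilityPanel":
        shapes = {g.coefficients.shape for g in sets}
        if len(shapes) != 1:
            raise ValueError(f"gradient sets differ in shape: {shapes}")
        data = np.stack([g.coefficients for g in sets])
        return cls(data, np.asarray(subject_ids), np.asarray(session_ids))

    def flat(self) -> np.ndarray:
        """Measurements as flat feature vectors (n_measurements x d)."""
        return self.data.reshape(self.data.shape[0], -1)


def _icc_a1(tables: np.ndarray) -> np.ndarray:
    """Vectorized ICC(2,1) over tables shaped (..., subjects, repeats).

    Two-way ANOVA mean squares: with s subjects (rows) and r repeats
    (columns), ICC = (MSR - MSE) / (MSR + (r-1) MSE + (r/s)(MSC - MSE)).
    """
    tables = np.asarray(tables, dtype=float)
    s, r = tables.shape[-2], tables.shape[-1]
    if s < 2 or r < 2:
        raise ValueError("ICC needs at least 2 subjects and 2 repeats")
    if not np.all(np.isfinite(tables)):
        raise ValueError("ICC table contains non-finite values")
    grand = tables.mean(axis=(-2, -1), keepdims=True)
    row_means = tables.mean(axis=-1, keepdims=True)
    col_means = tables.mean(axis=-2, keepdims=True)
    ssr = r * ((row_means - grand) ** 2).sum(axis=(-2, -1))
    ssc = s * ((col_means - grand) ** 2).sum(axis=(-2, -1))
    sst = ((tables - grand) ** 2).sum(axis=(-2, -1))
    sse = np.maximum(sst - ssr - ssc, 0.0)  # guard tiny negative round-off
    msr = ssr / (s - 1)
    msc = ssc / (r - 1)
    mse = sse / ((s - 1) * (r - 1))
    denom = msr + (r - 1) * mse + (r / s) * (msc - mse)
    if np.any(denom == 0.0):
        raise ValueError("zero total variance; ICC undefined")
    return (msr - mse) / denom


def icc_absolute_agreement(table: np.ndarray) -> ICCResult:
    """ICC(2,1) of a subjects x repeats table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be subjects x repeats")
    return ICCResult(float(_icc_a1(table)))


def _balanced_tables(panel: ReliabilityPanel) -> np.ndarray:
    """Reshape a balanced panel to (subjects, repeats, ...feature axes)."""
    subjects = np.unique(panel.subject_ids)
    groups = []
    n_rep = None
    for s in subjects:
        idx = np.flatnonzero(panel.subject_ids == s)
        idx = idx[np.argsort(panel.session_ids[idx], kind="stable")]
        if n_rep is None:
            n_rep = len(idx)
        elif len(idx) != n_rep:
            raise ValueError(
                "unbalanced panel: subjects have different numbers of repeats"
            )
        groups.append(panel.data[idx])
    if n_rep is not None and n_rep < 2:
        raise ValueError("need at least 2 repeats per subject")
    return np.stack(groups)  # (s, r, ...)


def vertexwise_icc(panel: ReliabilityPanel, gradient_index: int) -> np.ndarray:
    """Per-vertex ICC(2,1) of one gradient's coefficients across repeats.

    The panel must be balanced (equal repeats per subject) and hold gradient
    measurements shaped (n_measurements, n_vertices, g).  Returns the
    n_vertices ICC map; its mean is the usual scalar summary.
    """
    if panel.data.ndim != 3:
        raise ValueError("vertexwise ICC needs (measurement, vertex, gradient) data")
    tables = _balanced_tables(panel)[..., gradient_index]  # (s, r, n_vertices)
    return _icc_a1(np.moveaxis(tables, -1, 0))  # (n_vertices, s, r) -> per vertex


def discriminability(panel: ReliabilityPanel, distance: str = "euclidean") -> float:
    """Probability that within-subject distances beat between-subject ones.

    For every ordered pair (i, j) of distinct same-subject measurements, the
    fraction of other-subject measurements w with d(i, w) > d(i, j); ties
    count one half.  The statistic is the mean over all such pairs: 1 means
    repeats of a subject are always closer to each other than to anyone else,
    0.5 is chance.
    """
    x = panel.flat()
    subj = panel.subject_ids
    d = cdist(x, x, metric=distance)
    n = x.shape[0]
    fracs = []
    for i in range(n):
        same = np.flatnonzero((subj == subj[i]) & (np.arange(n) != i))
        if same.size == 0:
            continue
        other = np.flatnonzero(subj != subj[i])
        for j in same:
            dij = d[i, j]
            wins = np.sum(d[i, other] > dij)
            ties = np.sum(d[i, other] == dij)
            fracs.append((wins + 0.5 * ties) / other.size)
    if not fracs:
        raise ValueError("no subject has 2 or more measurements")
    return float(np.mean(fracs))
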