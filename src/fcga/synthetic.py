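"""Synthetic cohorts with known ground truth.

Real vertex-level fMRI is large and access-controlled, so every statistical
claim in this package is exercised on generated data whose structure is known
by construction: a planar "toy cortex" grid, smooth orthonormal latent maps
playing the role of the true connectivity gradients, subject-specific
perturbations of those maps shared across a subject's sessions, and a
behavioral target driven linearly by vertex-level map features.

The vertex time series are ``X = G diag(s) S + noise`` with G the latent
maps, s decreasing component scales and S unit-variance component time
courses — so vertex-by-vertex connectivity is approximately rank-m plus
noise and the gradient pipeline has a well-defined target to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_formats import ParcellationMap, TimeSeriesMatrix

__all__ = [
    "ToyCortex",
    "SyntheticGroundTruth",
    "Cohort",
    "make_toy_cortex",
    "sample_latent_maps",
    "make_ground_truth",
    "simulate_timeseries",
    "simulate_cohort",
]


@dataclass
class ToyCortex:
    """A regular planar grid standing in for a cortical surface mesh."""

    grid_dims: tuple[int, int]
    coords: np.ndarray  # n x 3, grid embedded in 3-space (z = 0)

    @property
    def n_vertices(self) -> int:
        return self.grid_dims[0] * self.grid_dims[1]

    def block_parcellation(self, n_parcels: int) -> ParcellationMap:
        """Partition the grid into ``n_parcels`` rectangular blocks.

        Chooses the block layout (pr x pc with pr * pc = n_parcels) whose
        blocks are closest to square; errors if no layout tiles the grid.
        """
        rows, cols = self.grid_dims
        best = None
        for pr in range(1, n_parcels + 1):
            if n_parcels % pr:
                continue
            pc = n_parcels // pr
            if rows % pr or cols % pc:
                continue
            bh, bw = rows // pr, cols // pc
            aspect = abs(np.log(bh / bw))
            if best is None or aspect < best[0]:
                best = (aspect, pr, pc)
        if best is None:
            raise ValueError(
                f"no {n_parcels}-block layout tiles a {rows}x{cols} grid"
            )
        _, pr, pc = best
        bh, bw = rows // pr, cols // pc
        r_idx, c_idx = np.divmod(np.arange(self.n_vertices), cols)
        labels = (r_idx // bh) * pc + (c_idx // bw) + 1
        return ParcellationMap(labels.astype(int), space_tag="toy-grid")


def make_toy_cortex(rows: int, cols: int) -> ToyCortex:
    if rows < 2 or cols < 2:
        raise ValueError("grid must be at least 2 x 2")
    r_idx, c_idx = np.divmod(np.arange(rows * cols), cols)
    coords = np.column_stack([c_idx, r_idx, np.zeros(rows * cols)]).astype(float)
    return ToyCortex((rows, cols), coords)


def _smooth_fields(
    cortex: ToyCortex, m: int, smoothness: float, rng: np.random.Generator
) -> np.ndarray:
    """m seeded smooth random fields on the grid, columns of an n x m matrix."""
    rows, cols = cortex.grid_dims
    fields = np.empty((cortex.n_vertices, m))
    for c in range(m):
        noise = rng.standard_normal((rows, cols))
        fields[:, c] = gaussian_filter(noise, sigma=smoothness, mode="reflect").ravel()
    return fields


def _orthonormalize(maps: np.ndarray) -> np.ndarray:
    """QR orthonormalization with a deterministic sign convention."""
    q, r = np.linalg.qr(maps)
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    return q * signs[None, :]


def sample_latent_maps(
    cortex: ToyCortex,
    m: int,
    smoothness: float,
    seed: int,
    *,
    homogenize_amplitude: bool = True,
) -> np.ndarray:
    """Orthonormal smooth spatial components — the planted gradients.

    Smoothly varying random fields (Gaussian-filtered white noise at length
    scale ``smoothness``, in grid units) orthonormalized by QR.  With
    ``homogenize_amplitude`` (default) the vertex loading rows are scaled to
    equal norm before orthonormalization, so every vertex carries a
    comparable signal amplitude — mirroring variance-normalized functional
    data, and keeping the vertex connectivity profile a function of the
    loading *direction* alone.  Deterministic per seed.
    """
    if m >= cortex.n_vertices:
        raise ValueError("need m < n_vertices")
    rng = np.random.default_rng(seed)
    fields = _smooth_fields(cortex, m, smoothness, rng)
    if homogenize_amplitude:
        fields = fields / np.linalg.norm(fields, axis=1, keepdims=True)
    return _orthonormalize(fields)


@dataclass
class SyntheticGroundTruth:
    """Everything the generator plants: maps, scales, noise and behavior."""

    cortex: ToyCortex
    latent_maps: np.ndarray  # n x m, orthonormal columns
    component_scales: np.ndarray  # m positive, strictly decreasing
    noise_sd: float
    subject_perturbation_sd: float
    behavior_weights: np.ndarray  # n x m vertex-level weights
    behavior_noise_sd: float
    smoothness: float
    seed: int
    parcellation: ParcellationMap | None = field(default=None)

    def __post_init__(self) -> None:
        g = self.latent_maps
        m = g.shape[1]
        gram = g.T @ g
        if np.abs(gram - np.eye(m)).max() > 1e-8:
            raise ValueError("latent map columns must be orthonormal")
        s = np.asarray(self.component_scales, dtype=float)
        if s.shape != (m,) or np.any(s <= 0) or np.any(np.diff(s) >= 0):
            raise ValueError("component_scales must be positive, strictly decreasing")
        if self.noise_sd < 0 or self.subject_perturbation_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.behavior_weights.shape != g.shape:
            raise ValueError("behavior_weights must match latent_maps shape")
        self.component_scales = s

    @property
    def n_vertices(self) -> int:
        return self.latent_maps.shape[0]

    @property
    def n_components(self) -> int:
        return self.latent_maps.shape[1]


def make_ground_truth(
    cortex: ToyCortex,
    m: int = 5,
    *,
    smoothness: float = 1.0,
    scale_ratio: float = 0.9,
    noise_sd: float = 0.1,
    subject_perturbation_sd: float = 0.3,
    behavior_noise_sd: float = 0.05,
    seed: int = 0,
    parcellation: ParcellationMap | None = None,
    behavior_mode: str = "vertex",
) -> SyntheticGroundTruth:
    """Build a ground truth with field-realistic defaults.

    Component scales decay geometrically (``scale_ratio``, default 0.9 — a
    gently decreasing variance spectrum with distinct eigenvalues) and are
    multiplied by sqrt(n) so that a typical vertex carries O(1) signal
    amplitude against orthonormal maps; ``noise_sd=0.1`` then corresponds to
    roughly 10:1 signal-to-noise per vertex.

    ``behavior_mode`` selects the weight field driving the behavioral target:
    ``"vertex"`` (default) is a smooth vertex-level field that varies within
    parcels, ``"within_parcel_contrast"`` removes each parcel's mean so the
    target loads exclusively on within-parcel spatial contrasts (requires
    ``parcellation``).
    """
    rng = np.random.default_rng(seed)
    fields = _smooth_fields(cortex, m, smoothness, rng)
    maps = _orthonormalize(fields / np.linalg.norm(fields, axis=1, keepdims=True))
    scales = np.sqrt(cortex.n_vertices) * scale_ratio ** np.arange(m)
    weights = _smooth_fields(cortex, m, max(smoothness / 2.0, 0.5), rng)
    if behavior_mode == "within_parcel_contrast":
        if parcellation is None:
            raise ValueError("within_parcel_contrast mode requires a parcellation")
        for members in parcellation.parcel_members():
            weights[members] -= weights[members].mean(axis=0, keepdims=True)
    elif behavior_mode != "vertex":
        raise ValueError(f"unknown behavior_mode {behavior_mode!r}")
    weights /= np.linalg.norm(weights, axis=0, keepdims=True)
    return SyntheticGroundTruth(
        cortex=cortex,
        latent_maps=maps,
        component_scales=scales,
        noise_sd=noise_sd,
        subject_perturbation_sd=subject_perturbation_sd,
        behavior_weights=weights,
        behavior_noise_sd=behavior_noise_sd,
        smoothness=smoothness,
        seed=seed,
        parcellation=parcellation,
    )


def simulate_timeseries(
    gt: SyntheticGroundTruth,
    T: int,
    seed: int,
    *,
    maps: np.ndarray | None = None,
    space_tag: str = "toy-grid",
) -> TimeSeriesMatrix:
    """One acquisition: latent maps x scales x unit-variance time courses + noise.

    The m component time courses are decorrelated in-sample (QR of a seeded
    Gaussian draw, scaled to unit variance), so the planted diagonal source
    covariance holds exactly at finite T rather than only in expectation.
    """
    m = gt.n_components
    if T < 2 * m:
        raise ValueError(f"need T >= 2m = {2 * m} timepoints")
    g = gt.latent_maps if maps is None else maps
    rng = np.random.default_rng(seed)
    s = rng.standard_normal((m, T))
    q, r = np.linalg.qr(s.T)
    s = (q * np.sign(np.diag(r))[None, :]).T * np.sqrt(T)
    x = (g * gt.component_scales[None, :]) @ s
    if gt.noise_sd > 0:
        x = x + gt.noise_sd * rng.standard_normal(x.shape)
    return TimeSeriesMatrix(x, space_tag=space_tag, allow_constant_rows=True)


@dataclass
class Cohort:
    """Simulated multi-subject, multi-session acquisitions with a target."""

    timeseries: list[TimeSeriesMatrix]  # subject-major, session-minor order
    subject_ids: np.ndarray  # per measurement
    session_ids: np.ndarray  # per measurement
    behavior: np.ndarray  # per subject
    subject_maps: list[np.ndarray]  # per subject ground-truth latent maps
    ground_truth: SyntheticGroundTruth


def simulate_cohort(
    gt: SyntheticGroundTruth,
    n_subjects: int,
    n_sessions: int,
    T: int,
    seed: int,
) -> Cohort:
    """Generate a cohort of repeated acquisitions plus a behavioral target.

    Each subject's latent maps are the group maps plus a smooth perturbation
    at ``subject_perturbation_sd`` (re-orthonormalized), shared across that
    subject's sessions.  The behavioral target is the inner product of the
    subject maps with the vertex-level behavior weights, standardized across
    subjects, plus Gaussian noise at ``behavior_noise_sd``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if n_sessions < 1:
        raise ValueError("need at least 1 session")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) % (2**31) for s in ss.generate_state(n_subjects * (n_sessions + 1))]
    seed_iter = iter(child_seeds)

    timeseries: list[TimeSeriesMatrix] = []
    subject_ids, session_ids = [], []
    subject_maps: list[np.ndarray] = []
    signal = np.empty(n_subjects)
    for s_idx in range(n_subjects):
        pert_rng = np.random.default_rng(next(seed_iter))
        if gt.subject_perturbation_sd > 0:
            pert = _smooth_fields(gt.cortex, gt.n_components, gt.smoothness, pert_rng)
            # project out the group maps so the perturbation is pure novelty:
            # the re-orthonormalization then only applies (quadratic) volume
            # corrections instead of mixing group-map content back in
            pert -= gt.latent_maps @ (gt.latent_maps.T @ pert)
            # unit-norm columns: the sd parameter is the perturbation size
            # relative to the (unit-norm) group maps
            pert /= np.linalg.norm(pert, axis=0, keepdims=True)
            raw_s = gt.latent_maps + gt.subject_perturbation_sd * pert
            maps_s = _orthonormalize(raw_s)
        else:
            raw_s = gt.latent_maps
            maps_s = gt.latent_maps.copy()
        subject_maps.append(maps_s)
        # behavior contracts the weights with the raw (pre-orthonormalization)
        # perturbed maps: with within-parcel-contrast weights the target is
        # then exactly the contrast projection of the perturbation field,
        # untouched by the global mixing the QR step introduces
        signal[s_idx] = float(np.sum(gt.behavior_weights * raw_s))
        for sess in range(n_sessions):
            ts = simulate_timeseries(gt, T, next(seed_iter), maps=maps_s)
            timeseries.append(ts)
            subject_ids.append(s_idx)
            session_ids.append(sess)

    sd = signal.std()
    z = (signal - signal.mean()) / sd if sd > 0 else np.zeros_like(signal)
    noise_rng = np.random.default_rng(int(ss.generate_state(1)[0]) % (2**31))
    behavior = z + gt.behavior_noise_sd * noise_rng.standard_normal(n_subjects)
    return Cohort(
        timeseries=timeseries,
        subject_ids=np.asarray(subject_ids),
        session_ids=np.asarray(session_ids),
        behavior=behavior,
        subject_maps=subject_maps,
        ground_truth=gt,
    )
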