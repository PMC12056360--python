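"""Synthetic cohorts with planted ground truth.

Real resting-state cohorts of this kind are not publicly deposited, so
every downstream stage is exercised on simulated data whose generative
parameters are known exactly.

The generative model: each subject's ROI time series is drawn from a
zero-mean multivariate normal whose correlation matrix is a shared base
matrix perturbed at *planted* locations.

* Planted edge (i, j): the subject's correlation at (i, j) is the base
  value plus a per-subject latent trait delta_s ~ N(0, latent_sd^2); the
  clinical score picks up effect_size * atanh(r_s(i, j)).
* Planted node (i, metric): the whole off-diagonal row/column of node i is
  scaled by (1 + gamma_s), gamma_s a clipped latent trait, moving the
  node's thresholded graph metrics coherently; the clinical score picks up
  effect_size * AUC of the named metric computed from the subject's true
  correlation matrix.

The clinical score is the sum of these planted contributions plus
N(0, noise_sd^2) noise, standardized across the cohort before effects are
combined so that effect sizes are on a common scale.  Measures where a
lower score means better function (GAIT, TUG) are represented by negating
the latent score and flagging the direction in the clinical table.

Also provided: framewise-displacement traces with injected outlier
spikes, voxelized lesion/CST mask pairs with exactly specified per-slice
overlap, and a direct feature-matrix generator for exercising the
stability-selection procedure in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .connectivity import fisher_z
from .graph import DEFAULT_TAU_GRID, graph_metric_aucs
from .preprocess import RoiTimeSeriesPanel, SubjectTimeSeries

DEFAULT_LATENT_SD = 0.15     # per-subject sd of a planted edge correlation
DEFAULT_NODE_LATENT_SD = 0.3  # per-subject sd of the row-scaling trait
DEFAULT_BACKGROUND_R = 0.25  # exchangeable base correlation


def exchangeable_covariance(n_rois: int, background_r: float = DEFAULT_BACKGROUND_R) -> np.ndarray:
    """Unit-diagonal exchangeable correlation matrix (PD for -1/(n-1) < r < 1)."""
    C = np.full((n_rois, n_rois), float(background_r))
    np.fill_diagonal(C, 1.0)
    return C


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort generator."""

    n_subjects: int = 37
    n_rois: int = 24
    n_timepoints: int = 200
    tr_seconds: float = 3.0
    base_covariance: np.ndarray | None = None  # defaults to exchangeable(0.25)
    planted_edges: list[tuple[int, int, float]] = field(default_factory=list)
    planted_nodes: list[tuple[int, str, float]] = field(default_factory=list)
    noise_sd: float = 1.0
    latent_sd: float = DEFAULT_LATENT_SD
    node_latent_sd: float = DEFAULT_NODE_LATENT_SD
    outlier_frame_rate: float = 0.0
    measure_name: str = "score"
    higher_is_better: bool = True
    tau_grid: np.ndarray = field(default_factory=lambda: DEFAULT_TAU_GRID.copy())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 3:
            raise ValueError("n_rois must be >= 3")
        if not 0 <= self.outlier_frame_rate < 0.5:
            raise ValueError("outlier_frame_rate must lie in [0, 0.5)")
        if self.base_covariance is None:
            self.base_covariance = exchangeable_covariance(self.n_rois)
        C = np.asarray(self.base_covariance, dtype=float)
        if C.shape != (self.n_rois, self.n_rois):
            raise ValueError("base_covariance shape must be (n_rois, n_rois)")
        if not np.allclose(C, C.T):
            raise ValueError("base_covariance must be symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("base_covariance must have unit diagonal")
        self.base_covariance = C
        for i, j, eff in self.planted_edges:
            if i == j or not (0 <= i < self.n_rois) or not (0 <= j < self.n_rois):
                raise ValueError(f"invalid planted edge ({i}, {j})")
            if not np.isfinite(eff):
                raise ValueError("effect sizes must be finite")
        for i, metric, eff in self.planted_nodes:
            if not (0 <= i < self.n_rois):
                raise ValueError(f"invalid planted node {i}")
            if metric not in {"GE", "CC", "BC"}:
                raise ValueError(f"unknown metric {metric!r}")
            if not np.isfinite(eff):
                raise ValueError("effect sizes must be finite")


@dataclass
class SimulationTruth:
    """Everything the generator knows that the pipeline must recover."""

    planted_edges: list[tuple[int, int, float]]
    planted_nodes: list[tuple[int, str, float]]
    latent_scores: np.ndarray          # per-subject score before noise
    edge_z: np.ndarray                 # (n_subjects, n_planted_edges) true z values
    node_metric: np.ndarray            # (n_subjects, n_planted_nodes) true AUC values
    seed: int


class NotPositiveDefiniteError(ValueError):
    pass


def _subject_correlation(cfg: SimulationConfig, rng: np.random.Generator):
    """Draw one subject's true correlation matrix and its planted values."""
    C = cfg.base_covariance.copy()
    edge_r = np.empty(len(cfg.planted_edges))
    for k, (i, j, _eff) in enumerate(cfg.planted_edges):
        r = C[i, j] + rng.normal(0.0, cfg.latent_sd)
        r = float(np.clip(r, -0.97, 0.97))
        C[i, j] = C[j, i] = r
        edge_r[k] = r
    node_gamma = np.empty(len(cfg.planted_nodes))
    for k, (i, _metric, _eff) in enumerate(cfg.planted_nodes):
        gamma = float(np.clip(rng.normal(0.0, cfg.node_latent_sd), -0.8, 0.8))
        scale = 1.0 + gamma
        row = C[i].copy()
        row_scaled = row * scale
        C[i] = row_scaled
        C[:, i] = row_scaled
        C[i, i] = 1.0
        node_gamma[k] = gamma
    # validity check: the perturbed matrix must remain a correlation matrix
    eigmin = np.linalg.eigvalsh(C)[0]
    if eigmin <= 1e-10:
        offender = cfg.planted_edges[0][:2] if cfg.planted_edges else (
            cfg.planted_nodes[0][0] if cfg.planted_nodes else None)
        raise NotPositiveDefiniteError(
            f"perturbed covariance is not positive definite "
            f"(min eigenvalue {eigmin:.3g}); offending plant: {offender}"
        )
    return C, edge_r, node_gamma


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[RoiTimeSeriesPanel, pd.DataFrame, SimulationTruth]:
    """Simulate a cohort: time-series panel, clinical table, ground truth.

    Returns a panel of per-subject multivariate-normal BOLD series, a
    clinical table with one measure generated from the planted structure,
    and the :class:`SimulationTruth` record.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    subjects: list[SubjectTimeSeries] = []
    edge_z = np.zeros((cfg.n_subjects, len(cfg.planted_edges)))
    node_auc = np.zeros((cfg.n_subjects, len(cfg.planted_nodes)))
    for s in range(cfg.n_subjects):
        C, edge_r, _gamma = _subject_correlation(cfg, rng)
        L = np.linalg.cholesky(C)
        X = L @ rng.standard_normal((cfg.n_rois, cfg.n_timepoints))
        fd = np.abs(rng.normal(0.2, 0.05, cfg.n_timepoints))
        if cfg.outlier_frame_rate > 0:
            spikes = rng.random(cfg.n_timepoints) < cfg.outlier_frame_rate
            fd[spikes] = 0.9 + np.abs(rng.normal(0.5, 0.3, int(spikes.sum())))
        subjects.append(SubjectTimeSeries(subject_id=f"sub-{s:03d}", data=X, fd=fd))
        edge_z[s] = fisher_z(edge_r)
        if cfg.planted_nodes:
            aucs = graph_metric_aucs(C, grid=cfg.tau_grid)
            for k, (i, metric, _eff) in enumerate(cfg.planted_nodes):
                node_auc[s, k] = aucs.auc[metric][i]

    def _standardize(col: np.ndarray) -> np.ndarray:
        sd = col.std()
        return (col - col.mean()) / sd if sd > 0 else col - col.mean()

    latent = np.zeros(cfg.n_subjects)
    for k, (_i, _j, eff) in enumerate(cfg.planted_edges):
        latent += eff * _standardize(edge_z[:, k])
    for k, (_i, _metric, eff) in enumerate(cfg.planted_nodes):
        latent += eff * _standardize(node_auc[:, k])
    score = latent + rng.normal(0.0, cfg.noise_sd, cfg.n_subjects)
    if not cfg.higher_is_better:
        score = -score

    roi_labels = [f"roi{i:02d}" for i in range(cfg.n_rois)]
    panel = RoiTimeSeriesPanel(subjects, roi_labels, cfg.tr_seconds)
    clinical = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            cfg.measure_name: score,
        }
    ).set_index("subject_id")
    clinical.attrs["higher_is_better"] = {cfg.measure_name: cfg.higher_is_better}
    truth = SimulationTruth(
        planted_edges=list(cfg.planted_edges),
        planted_nodes=list(cfg.planted_nodes),
        latent_scores=latent,
        edge_z=edge_z,
        node_metric=node_auc,
        seed=cfg.seed,
    )
    return panel, clinical, truth


def simulate_motion_trace(
    n_timepoints: int,
    outlier_frame_rate: float,
    seed: int,
    fd_threshold_mm: float = 0.9,
) -> tuple[np.ndarray, np.ndarray]:
    """Framewise-displacement trace with spikes above the scrubbing threshold.

    Baseline FD is |N(0.2, 0.05)| mm (comfortably below 0.9 mm); each frame
    independently becomes a spike above threshold with the given rate.
    Returns (fd_series, spike_indices).
    """
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    rng = np.random.default_rng(seed)
    fd = np.abs(rng.normal(0.2, 0.05, n_timepoints))
    spikes = rng.random(n_timepoints) < outlier_frame_rate
    fd[spikes] = fd_threshold_mm + np.abs(rng.normal(0.5, 0.3, int(spikes.sum())))
    return fd, np.flatnonzero(spikes)


def simulate_feature_outcome(
    n_subjects: int,
    n_features: int,
    planted: list[tuple[int, float]],
    noise_sd: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct design-matrix generator: standard-normal features, linear outcome.

    ``planted`` lists (feature_index, standardized effect size); the outcome
    is X @ beta + N(0, noise_sd^2).  Used to exercise the elastic-net
    stability-selection machinery without the full imaging pipeline.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_subjects, n_features))
    beta = np.zeros(n_features)
    for idx, eff in planted:
        beta[idx] = eff
    y = X @ beta + rng.normal(0.0, noise_sd, n_subjects)
    return X, y


def simulate_lesion_volumes(
    shape: tuple[int, int, int],
    cst_profile: np.ndarray,
    lesion_spec: np.ndarray,
    seed: int = 0,
    axial_axis: int = 2,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Binary lesion and CST masks realizing exact per-slice areas/overlaps.

    ``cst_profile[k]`` is the CST voxel count in axial slice k;
    ``lesion_spec[k]`` the lesion-CST overlap there.  Voxel positions
    within a slice are drawn at random (seeded); the returned
    ``true_lesion_load`` applies the max-area/area slice weighting of
    :mod:`strokeconn.lesion`.
    """
    from .lesion import LesionVolumePair, weighted_lesion_load

    cst_profile = np.asarray(cst_profile, dtype=int)
    lesion_spec = np.asarray(lesion_spec, dtype=int)
    if cst_profile.shape != lesion_spec.shape:
        raise ValueError("cst_profile and lesion_spec must have equal length")
    if np.any(lesion_spec > cst_profile):
        k = int(np.flatnonzero(lesion_spec > cst_profile)[0])
        raise ValueError(f"slice {k}: overlap {lesion_spec[k]} exceeds CST area {cst_profile[k]}")
    n_slices = cst_profile.size
    if shape[axial_axis] < n_slices:
        raise ValueError("volume has fewer axial slices than the profile")
    plane_size = int(np.prod([d for a, d in enumerate(shape) if a != axial_axis]))
    if np.any(cst_profile > plane_size):
        raise ValueError("slice area exceeds the in-plane voxel count")
    rng = np.random.default_rng(seed)
    plane_shape = tuple(d for a, d in enumerate(shape) if a != axial_axis)
    cst_flat = np.zeros((shape[axial_axis], plane_size), dtype=np.uint8)
    les_flat = np.zeros_like(cst_flat)
    for k in range(n_slices):
        pos = rng.choice(plane_size, size=int(cst_profile[k]), replace=False)
        cst_flat[k, pos] = 1
        les_flat[k, pos[: int(lesion_spec[k])]] = 1
    cst = np.moveaxis(cst_flat.reshape((shape[axial_axis],) + plane_shape), 0, axial_axis)
    lesion = np.moveaxis(les_flat.reshape((shape[axial_axis],) + plane_shape), 0, axial_axis)
    pair = LesionVolumePair(lesion_mask=lesion, cst_mask=cst, axial_axis=axial_axis)
    return lesion, cst, weighted_lesion_load(pair)
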