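"""Core containers for voxel-based state space modeling.

Conventions used throughout the package:

* time runs along rows — one row per TR (repetition time, the fMRI
  sampling interval);
* voxels/variables run along columns;
* per-TR state labels are stored as tuples of strings so that a TR may
  carry zero, one, or several labels (tasks with non-mutually-exclusive
  states produce multi-label TRs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ActivityMatrix",
    "TaskDesign",
    "FeatureTimecourse",
    "EncodingModel",
    "StateSpaceModel",
    "StateTrajectory",
    "Gaussian",
    "ClusterSet",
    "normalize_labels",
]

LabelSet = tuple[str, ...]


def normalize_labels(labels) -> list[LabelSet]:
    """Coerce per-TR labels to a list of sorted tuples of strings.

    Accepts a sequence whose elements are strings (single-label),
    or iterables of strings (multi-label). Empty label sets are allowed.
    """
    out: list[LabelSet] = []
    for lab in labels:
        if isinstance(lab, str):
            out.append((lab,))
        else:
            out.append(tuple(sorted(str(x) for x in lab)))
    return out


def _as_2d_float(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        n_bad = int(np.size(arr) - np.isfinite(arr).sum())
        raise ValueError(f"{name} contains {n_bad} non-finite values")
    return arr


def _check_run_boundaries(run_boundaries, n_trs: int) -> tuple[int, ...]:
    rb = tuple(int(b) for b in (run_boundaries if run_boundaries else (0,)))
    if rb[0] != 0:
        raise ValueError("run_boundaries must start at TR index 0")
    if any(b2 <= b1 for b1, b2 in zip(rb, rb[1:])) or rb[-1] >= n_trs:
        raise ValueError(
            f"run_boundaries {rb} must be strictly increasing and < n_trs={n_trs}"
        )
    return rb


@dataclass
class ActivityMatrix:
    """A (TRs x voxels) real-valued activity timecourse.

    Parameters
    ----------
    values
        Matrix of shape (n_trs, n_voxels); rows are TRs.
    tr_seconds
        Sampling interval in seconds (must be positive).
    voxel_ids
        Ordered voxel identifiers — linear mask indices for data
        extracted from a 4-D volume, or column names for matrix files.
    run_boundaries
        TR indices at which acquisition runs start; first entry is 0.
        Detrending operates independently within each run segment.
    """

    values: np.ndarray
    tr_seconds: float = 2.0
    voxel_ids: tuple = ()
    run_boundaries: tuple = (0,)

    def __post_init__(self):
        self.values = _as_2d_float(self.values, "activity values")
        if not (np.isfinite(self.tr_seconds) and self.tr_seconds > 0):
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if not self.voxel_ids:
            self.voxel_ids = tuple(range(self.values.shape[1]))
        else:
            self.voxel_ids = tuple(self.voxel_ids)
            if len(self.voxel_ids) != self.values.shape[1]:
                raise ValueError("voxel_ids length must match number of columns")
        self.run_boundaries = _check_run_boundaries(
            self.run_boundaries, self.values.shape[0]
        )

    @property
    def n_trs(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def run_slices(self) -> list[slice]:
        """Slices delimiting each acquisition run."""
        starts = list(self.run_boundaries)
        stops = starts[1:] + [self.n_trs]
        return [slice(a, b) for a, b in zip(starts, stops)]

    def with_values(self, values: np.ndarray) -> "ActivityMatrix":
        """Copy with replaced values (same shape), metadata preserved."""
        return ActivityMatrix(
            values=values,
            tr_seconds=self.tr_seconds,
            voxel_ids=self.voxel_ids,
            run_boundaries=self.run_boundaries,
        )

    def subset(self, idx) -> "ActivityMatrix":
        """Row subset; run boundaries collapse to a single run."""
        return ActivityMatrix(
            values=self.values[np.asarray(idx)],
            tr_seconds=self.tr_seconds,
            voxel_ids=self.voxel_ids,
            run_boundaries=(0,),
        )


@dataclass
class TaskDesign:
    """A (TRs x variables) task-design matrix with per-TR state labels."""

    values: np.ndarray
    variable_names: tuple
    labels: list = field(default_factory=list)
    run_boundaries: tuple = (0,)

    def __post_init__(self):
        self.values = _as_2d_float(self.values, "design values")
        self.variable_names = tuple(str(n) for n in self.variable_names)
        if len(self.variable_names) != self.values.shape[1]:
            raise ValueError("variable_names length must match number of columns")
        if len(set(self.variable_names)) != len(self.variable_names):
            raise ValueError("duplicate variable names in design")
        if self.labels:
            self.labels = normalize_labels(self.labels)
            if len(self.labels) != self.values.shape[0]:
                raise ValueError("labels length must match number of TRs")
        self.run_boundaries = _check_run_boundaries(
            self.run_boundaries, self.values.shape[0]
        )

    @property
    def n_trs(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def subset(self, idx) -> "TaskDesign":
        """Row subset (labels follow; run boundaries collapse to one run)."""
        idx = np.asarray(idx)
        labels = [self.labels[i] for i in idx] if self.labels else []
        return TaskDesign(
            values=self.values[idx],
            variable_names=self.variable_names,
            labels=labels,
            run_boundaries=(0,),
        )


@dataclass
class FeatureTimecourse:
    """A (TRs x features) stimulus-feature matrix for encoding models."""

    values: np.ndarray
    feature_names: tuple
    tr_seconds: float = 2.0

    def __post_init__(self):
        self.values = _as_2d_float(self.values, "feature values")
        self.feature_names = tuple(str(n) for n in self.feature_names)
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must match number of columns")
        if not (np.isfinite(self.tr_seconds) and self.tr_seconds > 0):
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")

    @property
    def n_trs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class EncodingModel:
    """Fitted voxelwise FIR encoding model.

    ``fir_weights`` has shape (features, delays, voxels).  ``ridge_penalty``
    is the selected penalty per voxel (length n_voxels) or a scalar when a
    single shared penalty was selected.
    """

    fir_weights: np.ndarray
    delays_trs: tuple
    feature_names: tuple
    ridge_penalty: np.ndarray
    cv_folds: int
    seed: int

    def __post_init__(self):
        self.fir_weights = np.asarray(self.fir_weights, dtype=float)
        if self.fir_weights.ndim != 3:
            raise ValueError("fir_weights must be (features, delays, voxels)")
        self.delays_trs = tuple(int(d) for d in self.delays_trs)
        if any(d2 <= d1 for d1, d2 in zip(self.delays_trs, self.delays_trs[1:])):
            raise ValueError("delays must be strictly increasing")
        self.feature_names = tuple(str(n) for n in self.feature_names)


@dataclass
class StateSpaceModel:
    """The fitted task-related subspace.

    Attributes
    ----------
    weights_b
        OLS regression weights B, (variables x voxels).
    eigvecs_ul
        Top principal axes of activity U_L, (voxels x n_components).
    denoised_bl
        Denoised weights B_L = B projected onto span(U_L), (variables x voxels).
    basis_qs
        Orthonormal basis Q_S of the task subspace, (voxels x variables);
        column k is sign-fixed to have positive inner product with row k of
        ``denoised_bl``, so "variable present" projects positive.
    variance_explained
        Fraction of total activity variance captured by the retained
        principal components.
    """

    weights_b: np.ndarray
    eigvecs_ul: np.ndarray
    denoised_bl: np.ndarray
    basis_qs: np.ndarray
    n_components: int
    variable_names: tuple
    variance_explained: float

    @property
    def n_variables(self) -> int:
        return self.weights_b.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.weights_b.shape[1]


@dataclass
class StateTrajectory:
    """Projected activity: one point per TR in the task-related subspace."""

    coords: np.ndarray
    dim_names: tuple
    labels: list = field(default_factory=list)

    def __post_init__(self):
        self.coords = _as_2d_float(self.coords, "trajectory coords")
        self.dim_names = tuple(str(n) for n in self.dim_names)
        if len(self.dim_names) != self.coords.shape[1]:
            raise ValueError("dim_names length must match number of dimensions")
        if self.labels:
            self.labels = normalize_labels(self.labels)
            if len(self.labels) != self.coords.shape[0]:
                raise ValueError("labels length must match number of TRs")

    @property
    def n_trs(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]


@dataclass
class Gaussian:
    """A multivariate normal cluster fit: mean, covariance, point count."""

    mean: np.ndarray
    cov: np.ndarray
    count: int

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape must match mean dimensionality")


@dataclass
class ClusterSet:
    """Per-state Gaussian fits in the full state space."""

    clusters: dict  # label (str) -> Gaussian
    dim_names: tuple = ()
    flagged: tuple = ()  # labels with too few points relative to dims

    @property
    def labels(self) -> list:
        return sorted(self.clusters)

    def __getitem__(self, label: str) -> Gaussian:
        return self.clusters[label]

    def __len__(self) -> int:
        return len(self.clusters)
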