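"""Recovery of the task-related subspace and projection of activity into it.

The model assumes that task variables are represented in a low-dimensional
subspace of the full voxel activity space. The subspace is recovered in
four steps:

1. regress activity on the task design, ``Y = X B`` (ordinary least
   squares), giving one weight map per task variable;
2. compute the top principal axes ``U_L`` of the activity matrix and the
   associated orthogonal projector ``D = U_L U_L^T`` (the denoiser);
3. denoise the weight maps, ``B_L = D B``, discarding weight structure
   outside the dominant activity subspace;
4. orthonormalize: QR-factorize ``B_L^T = Q R`` and keep the first
   (variables) columns ``Q_S``.

Activity at TR ``i`` projects to ``p_i = y_i Q_S``, a point in the state
space with one axis per task variable.

The dense projector ``D`` (voxels x voxels) is never materialized; all
products use the factored form ``U_L (U_L^T *)``.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .types import ActivityMatrix, StateSpaceModel, StateTrajectory, TaskDesign

__all__ = [
    "fit_task_weights",
    "compute_denoiser",
    "denoise_weights",
    "orthonormalize",
    "project",
    "fit_state_space",
]

RANK_RTOL = 1e-10  # rank checks relative to the largest singular value


def _collinear_names(x: np.ndarray, names) -> list[str]:
    """Variables implicated in a rank deficiency (small QR pivot)."""
    r = np.linalg.qr(x, mode="r")
    diag = np.abs(np.diag(r))
    tol = max(diag.max(), 1.0) * RANK_RTOL * x.shape[0]
    return [names[i] for i in np.flatnonzero(diag <= tol)]


def fit_task_weights(
    x: TaskDesign, y: ActivityMatrix, center: bool = True
) -> np.ndarray:
    """OLS weights B mapping task variables to voxels (Y = XB).

    With ``center=True`` (default) the design columns are mean-centered
    and an intercept column is added; the intercept row is dropped from
    the returned B. Centering makes binary {0,1} indicators into signed
    axes: variable present projects positive, absent negative.

    Returns (variables x voxels). Raises ``ValueError`` naming the
    collinear variables when the design is rank deficient.
    """
    if x.n_trs != y.n_trs:
        raise ValueError(f"design has {x.n_trs} TRs but activity has {y.n_trs}")
    n_vars = x.n_variables
    if x.n_trs < n_vars + 1:
        raise ValueError("need at least variables + 1 TRs for OLS")
    design = x.values
    if center:
        design = design - design.mean(axis=0)
        design = np.column_stack([design, np.ones(x.n_trs)])
    s = np.linalg.svd(design, compute_uv=False)
    if s[-1] <= RANK_RTOL * s[0]:
        bad = _collinear_names(x.values - x.values.mean(axis=0) if center
                               else x.values, x.variable_names)
        raise ValueError(
            "task design is rank deficient; collinear variables: "
            f"{bad or list(x.variable_names)}"
        )
    b, *_ = np.linalg.lstsq(design, y.values, rcond=None)
    return b[:n_vars]


def compute_denoiser(
    y: ActivityMatrix,
    n_components: int = 24,
    variance_threshold: float | None = None,
) -> tuple[np.ndarray, float]:
    """Top principal axes of activity and the variance they capture.

    Returns ``(eigvecs_ul, variance_explained)`` where ``eigvecs_ul`` is
    (voxels x n_components) with orthonormal columns (the top right-singular
    vectors of Y) and ``variance_explained`` is the fraction of the total
    squared singular-value mass they carry. The matrix is decomposed as
    given — columns are assumed already z-scored, so no extra centering is
    applied.

    If ``variance_threshold`` is set, ``n_components`` is instead the
    smallest count whose cumulative variance fraction reaches it.
    """
    _, s, vt = scipy.linalg.svd(y.values, full_matrices=False)
    total = float((s**2).sum())
    if total == 0:
        raise ValueError("activity matrix is identically zero")
    frac = np.cumsum(s**2) / total
    if variance_threshold is not None:
        if not 0 < variance_threshold <= 1:
            raise ValueError("variance_threshold must be in (0, 1]")
        n_components = int(np.searchsorted(frac, variance_threshold) + 1)
    n_components = int(n_components)
    if n_components < 1:
        raise ValueError(f"n_components must be >= 1, got {n_components}")
    if n_components > min(y.n_trs, y.n_voxels):
        raise ValueError(
            f"n_components={n_components} exceeds min(TRs, voxels)="
            f"{min(y.n_trs, y.n_voxels)}"
        )
    return vt[:n_components].T.copy(), float(frac[n_components - 1])


def denoise_weights(b: np.ndarray, eigvecs_ul: np.ndarray) -> np.ndarray:
    """Project each weight map onto the span of the retained principal axes.

    Computes ``B_L = B U_L U_L^T`` in factored form; idempotent.
    """
    b = np.asarray(b, dtype=float)
    if b.shape[1] != eigvecs_ul.shape[0]:
        raise ValueError(
            f"weights have {b.shape[1]} voxels but eigenvectors have "
            f"{eigvecs_ul.shape[0]}"
        )
    return (b @ eigvecs_ul) @ eigvecs_ul.T


def orthonormalize(bl: np.ndarray, variable_names=()) -> np.ndarray:
    """Orthonormal basis Q_S of the task subspace via QR of the weight transpose.

    Factorizes ``B_L^T = Q R`` and returns the first (variables) columns.
    Column k's sign is fixed so its inner product with variable k's
    denoised weight vector (the k-th diagonal of R) is positive.

    Raises ``ValueError`` reporting the numerical rank and implicated
    variables when the weight rows are linearly dependent.
    """
    bl = np.asarray(bl, dtype=float)
    n_vars = bl.shape[0]
    names = tuple(variable_names) or tuple(f"var_{i}" for i in range(n_vars))
    s = np.linalg.svd(bl, compute_uv=False)
    rank = int((s > RANK_RTOL * s[0]).sum()) if s[0] > 0 else 0
    if rank < n_vars:
        q, r = np.linalg.qr(bl.T)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.flatnonzero(diag <= RANK_RTOL * max(diag.max(), 1.0))]
        raise ValueError(
            f"denoised weights have numerical rank {rank} < {n_vars} "
            f"variables; dependent variables: {bad or list(names)}"
        )
    q, r = np.linalg.qr(bl.T)
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    return q[:, :n_vars] * signs


def project(
    y: ActivityMatrix, basis_qs: np.ndarray, dim_names=(), labels=None
) -> StateTrajectory:
    """Project each TR's activity vector into the state space (p_i = y_i Q_S)."""
    basis_qs = np.asarray(basis_qs, dtype=float)
    if y.n_voxels != basis_qs.shape[0]:
        raise ValueError(
            f"activity has {y.n_voxels} voxels but basis has {basis_qs.shape[0]}"
        )
    names = tuple(dim_names) or tuple(f"dim_{i}" for i in range(basis_qs.shape[1]))
    return StateTrajectory(
        coords=y.values @ basis_qs,
        dim_names=names,
        labels=list(labels) if labels is not None else [],
    )


def fit_state_space(
    x: TaskDesign,
    y: ActivityMatrix,
    n_components: int = 24,
    variance_threshold: float | None = None,
    center: bool = True,
) -> StateSpaceModel:
    """Full subspace recovery: OLS fit, PCA denoiser, denoising, QR basis."""
    b = fit_task_weights(x, y, center=center)
    eigvecs, varexp = compute_denoiser(
        y, n_components=n_components, variance_threshold=variance_threshold
    )
    bl = denoise_weights(b, eigvecs)
    qs = orthonormalize(bl, x.variable_names)
    return StateSpaceModel(
        weights_b=b,
        eigvecs_ul=eigvecs,
        denoised_bl=bl,
        basis_qs=qs,
        n_components=eigvecs.shape[1],
        variable_names=x.variable_names,
        variance_explained=varexp,
    )
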