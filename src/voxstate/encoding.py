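"""Voxelwise FIR encoding model and hemodynamic deconvolution.

BOLD measurements are a delayed, smoothed readout of neural activity.
When task states switch on the order of seconds, this smoothing blurs
adjacent states together. To undo it, each voxel's timecourse is modeled
as a linear function of stimulus features delayed by a small set of TRs
(a finite impulse response, FIR, per feature), fit with ridge regression
under temporal cross-validation. Averaging each feature's FIR weights
over delays yields a single per-feature selectivity weight; multiplying
the feature timecourses by these averaged weights reconstructs activity
with the hemodynamic delay removed.

FIR design column order is feature-major, delay-minor: column
``f * n_delays + d`` holds feature ``f`` delayed by ``delays_trs[d]``
samples (zero padded at the start).
"""

from __future__ import annotations

import numpy as np

from .types import ActivityMatrix, EncodingModel, FeatureTimecourse

__all__ = [
    "build_fir_design",
    "fit_encoding",
    "average_fir_weights",
    "deconvolve",
    "DEFAULT_PENALTIES",
]

# 10 log-spaced ridge penalties spanning near-OLS to heavy shrinkage.
DEFAULT_PENALTIES = tuple(np.logspace(-2, 4, 10))


def build_fir_design(
    f: FeatureTimecourse, delays_trs=(1, 2, 3, 4)
) -> np.ndarray:
    """Stack delayed copies of each feature into a (TRs x features*delays) design.

    Each delayed copy is the feature shifted down by the delay, with zeros
    filling the first ``delay`` rows.
    """
    delays = [int(d) for d in delays_trs]
    if len(delays) == 0:
        raise ValueError("delay list must not be empty")
    n_trs, n_feat = f.values.shape
    if any(d <= 0 for d in delays):
        raise ValueError(f"delays must be positive integers, got {delays}")
    if any(d >= n_trs for d in delays):
        raise ValueError(f"delays {delays} must be smaller than n_trs={n_trs}")
    design = np.zeros((n_trs, n_feat * len(delays)))
    for fi in range(n_feat):
        for di, d in enumerate(delays):
            design[d:, fi * len(delays) + di] = f.values[: n_trs - d, fi]
    return design


def _contiguous_folds(n: int, folds: int) -> list[np.ndarray]:
    """Temporally contiguous CV blocks (respects BOLD autocorrelation)."""
    edges = np.linspace(0, n, folds + 1).astype(int)
    return [np.arange(a, b) for a, b in zip(edges, edges[1:])]

def _ridge_path(design: np.ndarray, y: np.ndarray, penalties) -> np.ndarray:
    """Ridge solutions for every penalty from one SVD of the design.

    Returns an array (n_penalties, n_predictors, n_voxels).
    """
    u, s, vt = np.linalg.svd(design, full_matrices=False)
    uty = u.T @ y
    out = np.empty((len(penalties), design.shape[1], y.shape[1]))
    for pi, alpha in enumerate(penalties):
        shrink = s / (s**2 + alpha)
        out[pi] = vt.T @ (shrink[:, None] * uty)
    return out


def _corr_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of matching columns; 0 where either is constant."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    denom = np.sqrt((a**2).sum(axis=0) * (b**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=0) / denom
    return np.where(denom > 0, r, 0.0)


def fit_encoding(
    design: np.ndarray,
    y: ActivityMatrix,
    penalties=DEFAULT_PENALTIES,
    folds: int = 10,
    seed: int = 0,
    delays_trs=(1, 2, 3, 4),
    feature_names=(),
    per_voxel: bool = True,
) -> EncodingModel:
    """Fit ridge FIR weights with temporal cross-validated penalty selection.

    For each candidate penalty, held-out Pearson correlation between
    predicted and observed voxel timecourses is averaged over ``folds``
    contiguous temporal blocks. The best penalty is selected per voxel
    (or a single shared penalty maximizing the mean correlation across
    voxels when ``per_voxel`` is False), and final weights are refit on
    all data at the selected penalty.

    The procedure is deterministic; ``seed`` is recorded in the model for
    provenance.
    """
    design = np.asarray(design, dtype=float)
    if design.shape[0] != y.n_trs:
        raise ValueError(
            f"design has {design.shape[0]} rows but activity has {y.n_trs} TRs"
        )
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    penalties = np.asarray(sorted(float(p) for p in penalties))
    if penalties.size == 0 or penalties[0] <= 0:
        raise ValueError(
            "ridge penalties must be positive; use a small positive floor "
            "(e.g. 1e-8) instead of 0 to keep singular designs solvable"
        )
    delays = tuple(int(d) for d in delays_trs)
    n_feat = design.shape[1] // len(delays)
    if n_feat * len(delays) != design.shape[1]:
        raise ValueError("design column count is not a multiple of len(delays)")
    if not feature_names:
        feature_names = tuple(f"feature_{i}" for i in range(n_feat))

    n_vox = y.n_voxels
    cv_corr = np.zeros((penalties.size, n_vox))
    for test_idx in _contiguous_folds(y.n_trs, folds):
        train_mask = np.ones(y.n_trs, dtype=bool)
        train_mask[test_idx] = False
        w_path = _ridge_path(design[train_mask], y.values[train_mask], penalties)
        for pi in range(penalties.size):
            pred = design[test_idx] @ w_path[pi]
            cv_corr[pi] += _corr_columns(pred, y.values[test_idx])
    cv_corr /= folds

    if per_voxel:
        best = np.argmax(cv_corr, axis=0)  # ties -> smaller penalty
    else:
        best = np.full(n_vox, int(np.argmax(cv_corr.mean(axis=1))))

    w_full = _ridge_path(design, y.values, penalties)
    weights = np.empty((design.shape[1], n_vox))
    for pi in np.unique(best):
        sel = best == pi
        weights[:, sel] = w_full[pi][:, sel]

    fir = weights.reshape(n_feat, len(delays), n_vox)
    return EncodingModel(
        fir_weights=fir,
        delays_trs=delays,
        feature_names=feature_names,
        ridge_penalty=penalties[best],
        cv_folds=folds,
        seed=seed,
    )


def average_fir_weights(m: EncodingModel) -> np.ndarray:
    """Mean FIR weight over delays: one selectivity weight per feature/voxel."""
    return m.fir_weights.mean(axis=1)


def deconvolve(
    avg_weights: np.ndarray,
    f: FeatureTimecourse,
    template: ActivityMatrix | None = None,
) -> ActivityMatrix:
    """Reconstruct HRF-free activity as feature timecourses times averaged weights.

    ``avg_weights`` is (features x voxels); the result is (TRs x voxels).
    Metadata (TR, voxel ids, run boundaries) is copied from ``template``
    when given.
    """
    avg_weights = np.asarray(avg_weights, dtype=float)
    if avg_weights.shape[0] != f.n_features:
        raise ValueError(
            f"weights have {avg_weights.shape[0]} feature rows but the "
            f"timecourse has {f.n_features} features ({list(f.feature_names)})"
        )
    values = f.values @ avg_weights
    if template is not None:
        if avg_weights.shape[1] != template.n_voxels:
            raise ValueError("weights voxel dimension does not match template")
        return template.with_values(values)
    return ActivityMatrix(values=values, tr_seconds=f.tr_seconds)
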