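"""Detrending and normalization of voxel timecourses.

Slow scanner drifts are estimated per voxel with a Savitzky-Golay filter
(240-s window, 3rd order by default) and subtracted; the detrended
timecourses are then z-scored to zero mean and unit variance per voxel.
The canonical order is detrend first, then z-score.

Conventions: the filter window length in samples is ``round(window_seconds
/ tr_seconds)``, incremented to the next odd integer (the filter requires
odd windows). Detrending is applied independently within each acquisition
run; run edges are handled by the filter's own polynomial fit on the
terminal window (no wrapping or reflection across runs). Variance uses the
population convention (divide by N).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import savgol_filter

from .types import ActivityMatrix

__all__ = ["detrend_voxels", "zscore_voxels", "savgol_window_length"]

logger = logging.getLogger(__name__)


def savgol_window_length(window_seconds: float, tr_seconds: float) -> int:
    """Filter window in samples: round(seconds / TR), forced odd."""
    if tr_seconds <= 0:
        raise ValueError(f"tr_seconds must be positive, got {tr_seconds}")
    if window_seconds <= 0:
        raise ValueError(f"window_seconds must be positive, got {window_seconds}")
    n = int(round(window_seconds / tr_seconds))
    if n % 2 == 0:
        n += 1
    return n


def detrend_voxels(
    y: ActivityMatrix,
    window_seconds: float = 240.0,
    poly_order: int = 3,
) -> ActivityMatrix:
    """Remove low-frequency drift per voxel with a Savitzky-Golay filter.

    The smoothed estimate is computed within each run independently and
    subtracted from the data. A polynomial of degree <= ``poly_order``
    whose support fits a single window is annihilated exactly; in
    particular constant columns become all zeros.

    Raises
    ------
    ValueError
        If any run segment is shorter than the filter window, or the
        window does not exceed the polynomial order.
    """
    window = savgol_window_length(window_seconds, y.tr_seconds)
    if window <= poly_order:
        raise ValueError(
            f"window of {window} samples must exceed poly_order={poly_order}; "
            "increase window_seconds or decrease poly_order"
        )
    out = np.empty_like(y.values)
    for run_idx, sl in enumerate(y.run_slices()):
        seg = y.values[sl]
        if seg.shape[0] < window:
            raise ValueError(
                f"run {run_idx} has {seg.shape[0]} TRs, shorter than the "
                f"{window}-sample detrending window; shorten the window or "
                "merge runs explicitly"
            )
        trend = savgol_filter(seg, window, poly_order, axis=0, mode="interp")
        out[sl] = seg - trend
    return y.with_values(out)


def zscore_voxels(y: ActivityMatrix, var_floor: float = 1e-12) -> ActivityMatrix:
    """Normalize each voxel column to zero mean and unit variance.

    Variance is the population variance (divide by N). Columns whose
    variance falls below ``var_floor`` carry no signal; they are set to
    zero and their voxel ids are reported through a logged warning.
    Applying the operation twice is a no-op.

    Raises
    ------
    ValueError
        If every column is (numerically) constant.
    """
    vals = y.values
    mean = vals.mean(axis=0)
    var = vals.var(axis=0)  # population convention
    dead = var < var_floor
    if dead.all():
        raise ValueError("all voxel columns are constant; no usable voxels")
    if dead.any():
        ids = [y.voxel_ids[i] for i in np.flatnonzero(dead)]
        logger.warning(
            "%d voxel column(s) with variance < %g zeroed: %s",
            len(ids), var_floor, ids[:20],
        )
    sd = np.sqrt(np.where(dead, 1.0, var))
    out = (vals - mean) / sd
    out[:, dead] = 0.0
    return y.with_values(out)
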