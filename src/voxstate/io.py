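"""Reading and writing the pipeline's file formats.

Activity comes either from a 4-D NIfTI volume plus a 3-D binary mask
(in-mask voxels are extracted in C-order linear index order — the order
of ``np.flatnonzero(mask)`` — so exported weight maps re-embed
correctly), or from a delimited numeric matrix with TRs as rows. Designs,
labels, trajectories, and metric tables are tab-separated text with
headers; multi-label cells join labels with ``|``. Fitted state-space
models are stored in a single HDF5 container. Every writer can emit a
key-value manifest sufficient to re-run the stage.
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import ActivityMatrix, FeatureTimecourse, StateSpaceModel, StateTrajectory, TaskDesign

__all__ = [
    "read_activity",
    "write_activity",
    "read_design",
    "write_design",
    "read_features",
    "write_model",
    "read_model",
    "write_trajectory",
    "read_trajectory",
    "write_weight_map_nifti",
    "write_manifest",
    "read_manifest",
]

logger = logging.getLogger(__name__)

LABEL_SEP = "|"
LABEL_COL = "label"
RUN_COL = "run"


def _is_nifti(path) -> bool:
    name = str(path)
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_activity(
    path,
    mask_path=None,
    tr_seconds: float | None = None,
    run_boundaries=(0,),
) -> ActivityMatrix:
    """Load an activity matrix from NIfTI (+mask) or a delimited table.

    For NIfTI input the TR is taken from the header unless ``tr_seconds``
    is given (an explicit value wins, with a logged warning on mismatch).
    Voxels are the in-mask columns, ordered by C-order linear index.
    """
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"expected a 4-D volume, got shape {data.shape}")
        header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
        if tr_seconds is None:
            tr_seconds = header_tr
        elif header_tr > 0 and abs(header_tr - tr_seconds) > 1e-6:
            logger.warning(
                "TR mismatch: header says %.4g s, config says %.4g s; using config",
                header_tr, tr_seconds,
            )
        if mask_path is None:
            mask = np.ones(data.shape[:3], dtype=bool)
        else:
            mask_img = nib.load(str(mask_path))
            if mask_img.shape != data.shape[:3]:
                raise ValueError(
                    f"mask grid {mask_img.shape} does not match volume grid "
                    f"{data.shape[:3]}"
                )
            mask = np.asanyarray(mask_img.dataobj) > 0
        voxel_ids = tuple(int(i) for i in np.flatnonzero(mask))
        values = data[mask].T  # (TRs, voxels), C-order of mask indices
        if not np.all(np.isfinite(values)):
            n_bad = int(values.size - np.isfinite(values).sum())
            raise ValueError(f"volume contains {n_bad} non-finite in-mask values")
        logger.info("loaded %d TRs x %d in-mask voxels", *values.shape)
        return ActivityMatrix(
            values=values,
            tr_seconds=tr_seconds,
            voxel_ids=voxel_ids,
            run_boundaries=run_boundaries,
        )

    df = pd.read_csv(path, sep=_sep_for(path))
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        n_bad = int(values.size - np.isfinite(values).sum())
        raise ValueError(f"matrix contains {n_bad} non-finite values")
    logger.info("loaded %d TRs x %d voxels", *values.shape)
    return ActivityMatrix(
        values=values,
        tr_seconds=2.0 if tr_seconds is None else tr_seconds,
        voxel_ids=tuple(df.columns),
        run_boundaries=run_boundaries,
    )


def write_activity(path, y: ActivityMatrix) -> None:
    """Write an activity matrix as a delimited table (columns = voxels)."""
    df = pd.DataFrame(y.values, columns=[str(v) for v in y.voxel_ids])
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.10g")


def _format_labels(labels) -> list[str]:
    return [LABEL_SEP.join(labs) for labs in labels]


def _parse_labels(cells) -> list:
    out = []
    for cell in cells:
        if pd.isna(cell) or cell == "":
            out.append(())
        else:
            out.append(tuple(str(cell).split(LABEL_SEP)))
    return out


def read_design(path, labels_path=None) -> TaskDesign:
    """Load a task design table; reserved columns: 'label', 'run'.

    Variable columns are every column except the reserved ones. Labels may
    instead come from a separate single-column file. Multi-label cells
    join labels with '|'; empty cells mean no label.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep_for(path))
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate variable names in design: {dupes}")
    df = pd.read_csv(path, sep=_sep_for(path))
    labels = []
    if LABEL_COL in df.columns:
        labels = _parse_labels(df[LABEL_COL])
    run_boundaries = (0,)
    if RUN_COL in df.columns:
        runs = df[RUN_COL].to_numpy()
        starts = [0] + [i for i in range(1, len(runs)) if runs[i] != runs[i - 1]]
        run_boundaries = tuple(starts)
    var_cols = [c for c in df.columns if c not in (LABEL_COL, RUN_COL)]
    if labels_path is not None:
        lab_df = pd.read_csv(labels_path, sep=_sep_for(labels_path))
        cells = lab_df.iloc[:, 0]
        if len(cells) != len(df):
            raise ValueError(
                f"labels file has {len(cells)} rows but design has {len(df)} TRs"
            )
        labels = _parse_labels(cells)
    return TaskDesign(
        values=df[var_cols].to_numpy(dtype=float),
        variable_names=tuple(var_cols),
        labels=labels,
        run_boundaries=run_boundaries,
    )


def write_design(path, x: TaskDesign) -> None:
    """Write a design with its labels and run column as one table."""
    df = pd.DataFrame(x.values, columns=list(x.variable_names))
    if x.labels:
        df[LABEL_COL] = _format_labels(x.labels)
    run_ids = np.zeros(x.n_trs, dtype=int)
    for r, start in enumerate(x.run_boundaries):
        run_ids[start:] = r
    df[RUN_COL] = run_ids
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.10g")


def read_features(path, tr_seconds: float = 2.0) -> FeatureTimecourse:
    """Load a (TRs x features) table with a header of feature names."""
    df = pd.read_csv(path, sep=_sep_for(path))
    return FeatureTimecourse(
        values=df.to_numpy(dtype=float),
        feature_names=tuple(df.columns),
        tr_seconds=tr_seconds,
    )


def write_model(path, model: StateSpaceModel, settings: dict | None = None) -> None:
    """Serialize a fitted state-space model to one HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("weights_b", data=model.weights_b)
        f.create_dataset("eigvecs_ul", data=model.eigvecs_ul)
        f.create_dataset("denoised_bl", data=model.denoised_bl)
        f.create_dataset("basis_qs", data=model.basis_qs)
        f.attrs["n_components"] = model.n_components
        f.attrs["variance_explained"] = model.variance_explained
        f.attrs["variable_names"] = list(model.variable_names)
        for key, val in (settings or {}).items():
            f.attrs[f"setting_{key}"] = val


def read_model(path) -> StateSpaceModel:
    with h5py.File(path, "r") as f:
        return StateSpaceModel(
            weights_b=f["weights_b"][()],
            eigvecs_ul=f["eigvecs_ul"][()],
            denoised_bl=f["denoised_bl"][()],
            basis_qs=f["basis_qs"][()],
            n_components=int(f.attrs["n_components"]),
            variable_names=tuple(str(n) for n in f.attrs["variable_names"]),
            variance_explained=float(f.attrs["variance_explained"]),
        )


def write_trajectory(path, t: StateTrajectory) -> None:
    df = pd.DataFrame(t.coords, columns=list(t.dim_names))
    if t.labels:
        df[LABEL_COL] = _format_labels(t.labels)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.10g")


def read_trajectory(path) -> StateTrajectory:
    df = pd.read_csv(path, sep=_sep_for(path))
    labels = []
    if LABEL_COL in df.columns:
        labels = _parse_labels(df[LABEL_COL])
        df = df.drop(columns=[LABEL_COL])
    return StateTrajectory(
        coords=df.to_numpy(dtype=float),
        dim_names=tuple(df.columns),
        labels=labels,
    )


def write_weight_map_nifti(path, weights: np.ndarray, mask_path) -> None:
    """Re-embed a per-voxel weight vector into the mask grid as 3-D NIfTI.

    Uses the same C-order linear index convention as ``read_activity``.
    """
    import nibabel as nib

    mask_img = nib.load(str(mask_path))
    mask = np.asanyarray(mask_img.dataobj) > 0
    weights = np.asarray(weights, dtype=float).ravel()
    if weights.size != int(mask.sum()):
        raise ValueError(
            f"weight vector has {weights.size} voxels but mask has {int(mask.sum())}"
        )
    vol = np.zeros(mask.shape)
    vol[mask] = weights
    nib.save(nib.Nifti1Image(vol, mask_img.affine), str(path))


def write_manifest(path, entries: dict) -> None:
    """Write a flat key = value manifest (one entry per line)."""
    from . import __version__

    lines = [f"voxstate_version = {__version__}"]
    for key in sorted(entries):
        lines.append(f"{key} = {entries[key]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            key, _, val = line.partition("=")
            out[key.strip()] = val.strip()
    return out
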