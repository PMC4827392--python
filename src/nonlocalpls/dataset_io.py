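"""Volume I/O and assembly of subject x voxel matrices.

A cohort is held as a :class:`MultimodalDataset`: two matrices ``X``
(predictor modality) and ``Y`` (predicted modality) of shape
``subjects x voxels``, where the voxel axis enumerates the ``True`` entries
of a boolean mask flattened in row-major (C) order.  Voxel coordinates are
0-based; the same flattening convention is used everywhere in the package.

Volumes are read and written as NIfTI-1 via nibabel.  Column-mean centering
(required before any cross-covariance decomposition) records the per-voxel
means on the dataset so predictions can be returned in original units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "MultimodalDataset",
    "load_image_pairs",
    "load_labels_csv",
    "write_image",
    "center_dataset",
    "unmask",
]


@dataclass
class MultimodalDataset:
    """Paired subject x voxel matrices with labels, mask and grid geometry."""

    X: np.ndarray
    Y: np.ndarray
    subject_ids: list[str]
    group_labels: np.ndarray
    mask: np.ndarray
    grid_shape: tuple[int, ...]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    x_mean: np.ndarray | None = None
    y_mean: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.group_labels = np.asarray(self.group_labels)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but Y has {self.Y.shape[0]}"
            )
        n_mask = int(self.mask.sum())
        for name, mat in (("X", self.X), ("Y", self.Y)):
            if mat.shape[1] != n_mask:
                raise ValueError(
                    f"{name} has {mat.shape[1]} columns but the mask has {n_mask} voxels"
                )
        if len(self.subject_ids) != self.X.shape[0]:
            raise ValueError("subject_ids length does not match matrix rows")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject_ids must be unique")
        if self.group_labels.shape[0] != self.X.shape[0]:
            raise ValueError("group_labels length does not match matrix rows")
        if tuple(self.mask.shape) != tuple(self.grid_shape):
            raise ValueError("mask shape does not match grid_shape")

    # -- conveniences ----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    @property
    def is_centered(self) -> bool:
        return self.x_mean is not None

    def subset(self, indices: Sequence[int]) -> "MultimodalDataset":
        """Row subset (new uncentered dataset; means are not carried over)."""
        idx = np.asarray(indices)
        return MultimodalDataset(
            X=self.X[idx].copy(),
            Y=self.Y[idx].copy(),
            subject_ids=[self.subject_ids[i] for i in idx],
            group_labels=self.group_labels[idx].copy(),
            mask=self.mask,
            grid_shape=self.grid_shape,
            affine=self.affine,
        )


def _load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with the file name
        raise OSError(f"could not read volume {path!s}: {exc}") from exc
    return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine)


def load_image_pairs(
    x_paths: Sequence[str | Path],
    y_paths: Sequence[str | Path],
    labels: Sequence[str],
    mask_path: str | Path | None = None,
) -> MultimodalDataset:
    """Assemble a dataset from per-subject NIfTI pairs.

    Rows follow the input path order; masked voxels are flattened row-major.
    With no mask all voxels are included.  Subject ids are the x-file stems.
    """
    if not (len(x_paths) == len(y_paths) == len(labels)):
        raise ValueError("x_paths, y_paths and labels must have equal length")
    if len(x_paths) == 0:
        raise ValueError("no input volumes given")

    first, affine = _load_volume(x_paths[0])
    grid_shape = first.shape
    if mask_path is None:
        mask = np.ones(grid_shape, dtype=bool)
    else:
        mask_vol, _ = _load_volume(mask_path)
        if mask_vol.shape != grid_shape:
            raise ValueError(
                f"mask {mask_path!s} has shape {mask_vol.shape}, volumes have {grid_shape}"
            )
        mask = mask_vol != 0
        if not mask.any():
            raise ValueError(f"mask {mask_path!s} selects no voxels")

    flat = mask.ravel()

    def load_rows(paths: Sequence[str | Path]) -> np.ndarray:
        rows = np.empty((len(paths), int(mask.sum())))
        for i, p in enumerate(paths):
            vol, _ = _load_volume(p)
            if vol.shape != grid_shape:
                raise ValueError(
                    f"volume {p!s} has shape {vol.shape}, expected {grid_shape}"
                )
            rows[i] = vol.ravel()[flat]
        return rows

    return MultimodalDataset(
        X=load_rows(x_paths),
        Y=load_rows(y_paths),
        subject_ids=[Path(p).name.split(".")[0] for p in x_paths],
        group_labels=np.asarray(labels),
        mask=mask,
        grid_shape=tuple(grid_shape),
        affine=affine,
    )


def load_labels_csv(path: str | Path) -> pd.DataFrame:
    """Read a two-column (subject_id, label) CSV."""
    df = pd.read_csv(path)
    missing = {"subject_id", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"labels file {path!s} lacks columns {sorted(missing)}")
    return df


def unmask(vector: np.ndarray, mask: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Scatter a masked voxel vector back into a full volume."""
    vector = np.asarray(vector)
    if vector.shape[-1] != int(mask.sum()):
        raise ValueError(
            f"vector length {vector.shape[-1]} does not match mask size {int(mask.sum())}"
        )
    vol = np.full(mask.shape, fill, dtype=float)
    vol[mask] = vector
    return vol


def write_image(vector: np.ndarray, dataset: MultimodalDataset, path: str | Path) -> None:
    """Write a masked voxel vector as a NIfTI volume (background = 0)."""
    vol = unmask(vector, dataset.mask)
    nib.Nifti1Image(vol, dataset.affine).to_filename(str(path))


def center_dataset(dataset: MultimodalDataset) -> MultimodalDataset:
    """Subtract per-voxel column means from X and Y independently.

    The means are stored on the returned dataset so predictions can be
    mapped back to original units.  No unit-variance scaling is applied:
    voxel units are commensurate within a modality, and covariance
    maximisation only requires centering.
    """
    if dataset.is_centered:
        raise ValueError("dataset is already centered; re-centering is not allowed")
    x_mean = dataset.X.mean(axis=0)
    y_mean = dataset.Y.mean(axis=0)
    return replace(
        dataset,
        X=dataset.X - x_mean,
        Y=dataset.Y - y_mean,
        subject_ids=list(dataset.subject_ids),
        x_mean=x_mean,
        y_mean=y_mean,
    )
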