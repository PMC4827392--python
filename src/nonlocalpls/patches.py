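"""Local cross-modality synthesis by nearest-patch lookup.

The local comparator to the latent-variable model: given a database of
spatially aligned atlas pairs (predictor volume, target volume), the target
intensity at a voxel is copied from the atlas whose predictor *patch* around
that location is closest to the query's patch in the L2 metric.  This is a
pure lookup — no regression — so it can only exploit correlations that are
spatially local at the patch scale.

Patches are cubic with odd side (default 5 voxels).  At volume boundaries
the patch window is clamped to the grid; no padding values are invented.
Optionally a small search window of voxel offsets around the query location
is scanned (default radius 0: same location across the aligned atlases).
Ties are broken by lowest atlas index, then lexicographic offset.

The per-candidate sum of squared differences over every (clamped) window is
computed with a separable box filter, so synthesis of a whole volume against
a whole database is a handful of array operations rather than a per-voxel
loop.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .dataset_io import MultimodalDataset, unmask

__all__ = ["PatchDatabase", "build_patch_db", "synthesize_target", "leave_one_out_synthesis"]


@dataclass
class PatchDatabase:
    """Aligned atlas pairs plus the patch-search geometry."""

    atlas_x: np.ndarray  # (n_atlas, *grid_shape)
    atlas_y: np.ndarray
    patch_side: int = 5
    search_radius: int = 0
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    aggregate: str = "center"

    def __post_init__(self) -> None:
        if self.patch_side < 1 or self.patch_side % 2 == 0:
            raise ValueError(f"patch_side must be odd and >= 1, got {self.patch_side}")
        if self.search_radius < 0:
            raise ValueError("search_radius must be >= 0")
        if self.aggregate not in ("center", "mean"):
            raise ValueError("aggregate must be 'center' or 'mean'")
        if self.atlas_x.shape != self.atlas_y.shape:
            raise ValueError("atlas_x and atlas_y must have identical shapes")
        if self.n_atlases == 0:
            raise ValueError("patch database is empty")
        if self.mask is None:
            self.mask = np.ones(self.grid_shape, dtype=bool)

    @property
    def n_atlases(self) -> int:
        return self.atlas_x.shape[0]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.atlas_x.shape[1:]


def build_patch_db(
    dataset: MultimodalDataset,
    patch_side: int = 5,
    search_radius: int = 0,
    aggregate: str = "center",
) -> PatchDatabase:
    """Turn a dataset's subjects into an atlas database (volumes, background 0)."""
    vols_x = np.stack([unmask(r, dataset.mask) for r in dataset.X])
    vols_y = np.stack([unmask(r, dataset.mask) for r in dataset.Y])
    return PatchDatabase(vols_x, vols_y, patch_side, search_radius, dataset.mask, aggregate)


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _boxsum(arr: np.ndarray, side: int, n_spatial: int) -> np.ndarray:
    """Sum over the centered window clamped to the trailing spatial axes."""
    size = (1,) * (arr.ndim - n_spatial) + (side,) * n_spatial
    return uniform_filter(arr, size=size, mode="constant", cval=0.0) * float(side**n_spatial)


def _shift(arr: np.ndarray, offset: tuple[int, ...], n_spatial: int) -> np.ndarray:
    """``out[..., v] = arr[..., v + offset]`` with zero fill outside the grid."""
    out = np.zeros_like(arr)
    src, dst = [slice(None)] * (arr.ndim - n_spatial), [slice(None)] * (arr.ndim - n_spatial)
    for o, n in zip(offset, arr.shape[arr.ndim - n_spatial:]):
        lo, hi = max(0, -o), min(n, n - o)
        if lo >= hi:
            return np.zeros_like(arr)
        dst.append(slice(lo, hi))
        src.append(slice(lo + o, hi + o))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def synthesize_target(X_new: np.ndarray, db: PatchDatabase) -> np.ndarray:
    """Synthesise the target modality for query predictor images.

    ``X_new`` holds masked voxel rows (or a single row).  For every masked
    voxel the atlas (and offset within ``search_radius``) with the smallest
    patch SSD is selected and its target intensity at the matched center (or
    the patch mean, per ``db.aggregate``) is copied.  Returns rows aligned
    with ``X_new``.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    grid = db.grid_shape
    ndim = len(grid)
    if X_new.shape[1] != int(db.mask.sum()):
        raise ValueError(
            f"query has {X_new.shape[1]} voxels, database mask has {int(db.mask.sum())}"
        )
    r = db.search_radius
    offsets = list(itertools.product(*[range(-r, r + 1)] * ndim))
    n_off = len(offsets)

    ingrid = np.ones(grid)
    out = np.empty_like(X_new)
    for qi, row in enumerate(X_new):
        qvol = unmask(row, db.mask)
        q2 = qvol**2
        best = np.full(grid, np.inf)
        best_rank = np.full(grid, np.iinfo(np.int64).max, dtype=np.int64)
        best_y = np.zeros(grid)
        for o_idx, off in enumerate(offsets):
            ax = _shift(db.atlas_x, off, ndim)
            ay = _shift(db.atlas_y, off, ndim)
            valid = _shift(ingrid, off, ndim)
            # clamped-window SSD; positions whose atlas voxel falls outside
            # the grid are excluded by subtracting their query-only term
            d = _boxsum((qvol[None] - ax) ** 2, db.patch_side, ndim)
            d -= _boxsum(q2 * (1.0 - valid), db.patch_side, ndim)[None]
            d = np.where(valid.astype(bool)[None], d, np.inf)
            if db.aggregate == "mean":
                counts = np.maximum(_boxsum(valid, db.patch_side, ndim), 1.0)
                yv = _boxsum(ay, db.patch_side, ndim) / counts[None]
            else:
                yv = ay
            jmin = np.argmin(d, axis=0)  # first occurrence = lowest atlas index
            dmin = np.take_along_axis(d, jmin[None], axis=0)[0]
            ymin = np.take_along_axis(yv, jmin[None], axis=0)[0]
            rank = jmin.astype(np.int64) * n_off + o_idx
            better = (dmin < best) | ((dmin == best) & (rank < best_rank))
            best = np.where(better, dmin, best)
            best_rank = np.where(better, rank, best_rank)
            best_y = np.where(better, ymin, best_y)
        out[qi] = best_y[db.mask]
    return out


def leave_one_out_synthesis(
    dataset: MultimodalDataset,
    patch_side: int = 5,
    search_radius: int = 0,
    aggregate: str = "center",
) -> np.ndarray:
    """Predict every subject from a database excluding that subject."""
    K = dataset.n_subjects
    if K < 2:
        raise ValueError("leave-one-out synthesis needs at least two subjects")
    vols_x = np.stack([unmask(r, dataset.mask) for r in dataset.X])
    vols_y = np.stack([unmask(r, dataset.mask) for r in dataset.Y])
    out = np.empty_like(dataset.X)
    for k in range(K):
        keep = np.arange(K) != k
        db = PatchDatabase(
            vols_x[keep], vols_y[keep], patch_side, search_radius, dataset.mask, aggregate
        )
        out[k] = synthesize_target(dataset.X[k], db)[0]
    return out
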