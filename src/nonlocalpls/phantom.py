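"""Synthetic multimodal cohorts with planted non-local correlation structure.

The generator emulates the statistical situation the modelling code is built
for: two co-registered scalar volumes per subject (a structural "grey-matter"
style predictor and a metabolic "uptake" style target) whose joint variation
is driven by a small number of latent components.  Each component has one
smooth spatial support per modality, and the two supports may be placed in
*disjoint* anatomical locations — the non-local correlation structure the
latent-variable model is meant to capture and a purely local patch model
cannot.  Per-subject component loadings are Gaussian around group-dependent
means, a shared "ventricle-like" confound region is added to both modalities,
volumes are smoothed to a standardized resolution, and i.i.d. voxel noise is
added.

Everything is driven by a single :class:`PhantomSpec` and a seed, so each
cohort is bit-reproducible and ships with its ground truth
(:class:`PhantomTruth`): the planted spatial maps, the per-subject loadings,
the group labels and a region atlas built over the target-modality supports.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .dataset_io import MultimodalDataset, write_image

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "default_spec",
    "make_components",
    "sample_cohort",
    "make_region_atlas",
    "reference_regional_values",
    "write_cohort",
]

#: conversion between full width at half maximum and Gaussian sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548...

_DEFAULT_GROUP_MEANS: dict[str, tuple[float, ...]] = {
    # component 1 tracks disease stage, component 2 is an MCI-weighted
    # pattern, component 3 is disease-unrelated anatomical variability.
    "HC": (0.0, 0.0, 0.0),
    "MCI": (1.0, 1.5, 0.0),
    "AD": (2.5, 0.2, 0.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic cohort.

    Parameters
    ----------
    grid_shape
        Voxels per axis; every entry must be at least 4.
    n_components
        Number of planted latent components ``m_true``.
    component_centers_x, component_centers_y
        Per-component blob centers (voxel coordinates) in the predictor and
        target modality.  Centers may be disjoint across modalities, which is
        the non-local regime.
    blob_sigma
        Spatial width (in voxels) of the Gaussian blob of every component.
    smoothing_fwhm
        Post-hoc Gaussian smoothing width (voxels, FWHM), the toy analogue of
        resampling every volume to a standardized point-spread function.
    group_means
        Mapping group name -> per-component mean loading.  Group order is the
        mapping order and is preserved in the sampled cohort.
    loading_sd
        Within-group standard deviation of the loadings (same for all
        components).
    noise_sd
        Standard deviation of additive i.i.d. voxel noise.
    confound_amplitude
        Mean per-subject amplitude of the shared "ventricle-like" region that
        appears in both modalities; 0 disables the confound.
    confound_center, confound_sigma
        Geometry of the confound blob; ``None`` center means the grid center.
    subjects_per_group
        Mapping group name -> cohort size.
    region_threshold
        Fraction of a target-modality component map's maximum above which a
        voxel belongs to that component's atlas region.
    seed
        Seed for all randomness in :func:`sample_cohort`.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    n_components: int = 3
    component_centers_x: tuple[tuple[int, ...], ...] = ((4, 4, 4), (11, 4, 8), (4, 11, 11))
    component_centers_y: tuple[tuple[int, ...], ...] = ((11, 11, 11), (4, 12, 4), (12, 5, 8))
    blob_sigma: float = 1.5
    smoothing_fwhm: float = 2.0
    group_means: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_GROUP_MEANS)
    )
    loading_sd: float = 1.0
    noise_sd: float = 0.2
    confound_amplitude: float = 0.5
    confound_center: tuple[int, ...] | None = None
    confound_sigma: float = 2.0
    subjects_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"HC": 80, "MCI": 80, "AD": 80}
    )
    region_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if len(self.grid_shape) not in (2, 3):
            raise ValueError("grid_shape must have 2 or 3 axes")
        if any(int(g) < 4 for g in self.grid_shape):
            raise ValueError(f"every grid_shape entry must be >= 4, got {self.grid_shape}")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        for name, centers in (
            ("component_centers_x", self.component_centers_x),
            ("component_centers_y", self.component_centers_y),
        ):
            if len(centers) != self.n_components:
                raise ValueError(
                    f"{name} has {len(centers)} entries, expected n_components={self.n_components}"
                )
            for c in centers:
                self._check_center(c, name)
        if self.confound_center is not None:
            self._check_center(self.confound_center, "confound_center")
        if self.loading_sd <= 0:
            raise ValueError("loading_sd must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 < self.region_threshold < 1:
            raise ValueError("region_threshold must lie in (0, 1)")
        for g, means in self.group_means.items():
            if len(means) != self.n_components:
                raise ValueError(
                    f"group_means[{g!r}] has {len(means)} entries, expected {self.n_components}"
                )
        if set(self.subjects_per_group) != set(self.group_means):
            raise ValueError("subjects_per_group and group_means must list the same groups")
        if any(n < 1 for n in self.subjects_per_group.values()):
            raise ValueError("every group needs at least one subject")

    def _check_center(self, center: Sequence[int], name: str) -> None:
        if len(center) != len(self.grid_shape):
            raise ValueError(f"{name} center {center} does not match grid dimensionality")
        if any(not 0 <= c < g for c, g in zip(center, self.grid_shape)):
            raise ValueError(f"{name} center {center} lies outside grid {self.grid_shape}")

    # -- bookkeeping -----------------------------------------------------
    @property
    def groups(self) -> list[str]:
        return list(self.group_means)

    @property
    def n_subjects(self) -> int:
        return int(sum(self.subjects_per_group.values()))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_means"] = {g: list(m) for g, m in self.group_means.items()}
        d["subjects_per_group"] = dict(self.subjects_per_group)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhantomSpec":
        d = dict(d)
        for key in ("grid_shape", "confound_center"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        for key in ("component_centers_x", "component_centers_y"):
            if key in d:
                d[key] = tuple(tuple(c) for c in d[key])
        if "group_means" in d:
            d["group_means"] = {g: tuple(m) for g, m in d["group_means"].items()}
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PhantomTruth:
    """Ground truth of a sampled cohort.

    ``components_x``/``components_y`` are unit-norm spatial maps of shape
    ``(m_true, *grid_shape)``; ``loadings`` is subjects x components; the
    ``atlas`` labels each target-modality component support (0 = background)
    and ``atlas_table`` names the labels.  The confound map and per-subject
    confound amplitudes are recorded so noiseless reference images can be
    reconstructed exactly.
    """

    components_x: np.ndarray
    components_y: np.ndarray
    loadings: np.ndarray
    group_labels: np.ndarray
    atlas: np.ndarray
    atlas_table: pd.DataFrame
    confound_map: np.ndarray
    confound_loadings: np.ndarray


def default_spec(**overrides) -> PhantomSpec:
    """The standard cohort: 16^3 grid, 3 disjoint components, 80/group."""
    return dataclasses.replace(PhantomSpec(), **overrides) if overrides else PhantomSpec()


# ---------------------------------------------------------------------------
# component construction
# ---------------------------------------------------------------------------

def _blob(grid_shape: Sequence[int], center: Sequence[int], sigma: float) -> np.ndarray:
    axes = np.ogrid[tuple(slice(0, g) for g in grid_shape)]
    sq = sum((ax - c) ** 2 for ax, c in zip(axes, center))
    return np.exp(-sq / (2.0 * sigma**2))


def _smooth(volume: np.ndarray, fwhm: float) -> np.ndarray:
    if fwhm <= 0:
        return volume
    return gaussian_filter(volume, sigma=fwhm * FWHM_TO_SIGMA)


def make_components(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Build the planted spatial maps of both modalities.

    Each map is a Gaussian blob at the specified center, smoothed with the
    spec's FWHM and normalised to unit Euclidean norm.  Returns two arrays of
    shape ``(n_components, *grid_shape)``.
    """
    spec.validate()
    out = []
    for centers in (spec.component_centers_x, spec.component_centers_y):
        maps = np.empty((spec.n_components, *spec.grid_shape))
        for j, center in enumerate(centers):
            v = _smooth(_blob(spec.grid_shape, center, spec.blob_sigma), spec.smoothing_fwhm)
            maps[j] = v / np.linalg.norm(v)
        out.append(maps)
    return out[0], out[1]


def _confound_map(spec: PhantomSpec) -> np.ndarray:
    center = spec.confound_center
    if center is None:
        center = tuple(g // 2 for g in spec.grid_shape)
    v = _smooth(_blob(spec.grid_shape, center, spec.confound_sigma), spec.smoothing_fwhm)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

def make_region_atlas(spec: PhantomSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Integer region labels over the target-modality component supports.

    Region ``j+1`` is the set of voxels where target component ``j`` exceeds
    ``region_threshold`` of its own maximum; overlaps are resolved by nearest
    blob center.  Label 0 is background.  Returns the label volume and a
    sidecar table (label, component, center).
    """
    _, comps_y = make_components(spec)
    atlas = np.zeros(spec.grid_shape, dtype=np.int16)
    claimed = np.zeros(spec.grid_shape, dtype=bool)
    coords = np.stack(
        np.meshgrid(*[np.arange(g) for g in spec.grid_shape], indexing="ij"), axis=-1
    ).astype(float)
    masks = [comps_y[j] >= spec.region_threshold * comps_y[j].max()
             for j in range(spec.n_components)]
    overlap_dist = np.full(spec.grid_shape, np.inf)
    for j, m in enumerate(masks):
        dist = np.linalg.norm(coords - np.asarray(spec.component_centers_y[j], float), axis=-1)
        take = m & (~claimed | (dist < overlap_dist))
        atlas[take] = j + 1
        overlap_dist = np.where(take, dist, overlap_dist)
        claimed |= m
    table = pd.DataFrame(
        {
            "label": np.arange(1, spec.n_components + 1),
            "component": np.arange(spec.n_components),
            "center": [tuple(c) for c in spec.component_centers_y],
        }
    )
    return atlas, table


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def sample_cohort(spec: PhantomSpec) -> tuple[MultimodalDataset, PhantomTruth]:
    """Draw a full cohort: paired flattened volumes plus ground truth.

    Subject ``k`` of group ``g`` has images

    ``X_k = sum_j s_kj * components_x[j] + a_k * confound + noise`` and
    ``Y_k = sum_j s_kj * components_y[j] + a_k * confound + noise``

    with loadings ``s_kj ~ N(group_means[g][j], loading_sd)`` shared across
    modalities (one latent score drives both maps — the structure a
    cross-covariance decomposition assumes), confound amplitudes
    ``a_k ~ N(confound_amplitude, confound_amplitude/4)`` shared across
    modalities, and independent ``N(0, noise_sd)`` voxel noise.  The noise
    field is passed through the same resolution kernel as the signal
    (``smoothing_fwhm``): the whole image, not just its structure, lives at
    the standardized smoothed resolution, so the acquisition noise in the
    generated volumes is spatially correlated with reduced per-voxel
    variance, exactly as in smoothed real acquisitions.  ``noise_sd`` is the
    white (pre-filter) standard deviation.  All draws come from a single
    generator seeded with ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    comps_x, comps_y = make_components(spec)
    conf = _confound_map(spec)
    n = spec.n_subjects
    n_vox = int(np.prod(spec.grid_shape))

    labels = np.concatenate(
        [np.repeat(g, spec.subjects_per_group[g]) for g in spec.groups]
    )
    mean_rows = np.concatenate(
        [
            np.tile(np.asarray(spec.group_means[g], float), (spec.subjects_per_group[g], 1))
            for g in spec.groups
        ]
    )
    loadings = rng.normal(mean_rows, spec.loading_sd)
    if spec.confound_amplitude > 0:
        conf_amp = rng.normal(spec.confound_amplitude, spec.confound_amplitude / 4.0, size=n)
    else:
        conf_amp = np.zeros(n)

    cx = comps_x.reshape(spec.n_components, n_vox)
    cy = comps_y.reshape(spec.n_components, n_vox)
    cflat = conf.reshape(n_vox)
    X = loadings @ cx + np.outer(conf_amp, cflat)
    Y = loadings @ cy + np.outer(conf_amp, cflat)
    if spec.noise_sd > 0:
        sigma = spec.smoothing_fwhm * FWHM_TO_SIGMA
        for block in (X, Y):
            noise = rng.normal(0.0, spec.noise_sd, size=(n, *spec.grid_shape))
            if sigma > 0:
                # smooth the spatial axes only: acquisition noise is filtered
                # by the same point-spread function as the anatomy
                noise = gaussian_filter(noise, sigma=(0,) + (sigma,) * len(spec.grid_shape))
            block += noise.reshape(n, n_vox)

    atlas, atlas_table = make_region_atlas(spec)
    dataset = MultimodalDataset(
        X=X,
        Y=Y,
        subject_ids=[f"S{k:04d}" for k in range(n)],
        group_labels=labels,
        mask=np.ones(spec.grid_shape, dtype=bool),
        grid_shape=tuple(spec.grid_shape),
    )
    truth = PhantomTruth(
        components_x=comps_x,
        components_y=comps_y,
        loadings=loadings,
        group_labels=labels,
        atlas=atlas,
        atlas_table=atlas_table,
        confound_map=conf,
        confound_loadings=conf_amp,
    )
    return dataset, truth


def reference_regional_values(truth: PhantomTruth) -> pd.DataFrame:
    """Noiseless per-subject regional means of the target modality.

    The phantom analogue of independently reported reference regional uptake
    values: regional means of the noise-free target image reconstructed from
    the planted loadings and confound.  Returns a tidy frame with columns
    ``subject``, ``region``, ``reference``.
    """
    m, n_vox = truth.components_y.shape[0], truth.components_y[0].size
    cy = truth.components_y.reshape(m, n_vox)
    clean = truth.loadings @ cy + np.outer(truth.confound_loadings, truth.confound_map.ravel())
    atlas_flat = truth.atlas.ravel()
    rows = []
    for region in np.unique(atlas_flat[atlas_flat > 0]):
        sel = atlas_flat == region
        vals = clean[:, sel].mean(axis=1)
        for k, v in enumerate(vals):
            rows.append((k, int(region), v))
    return pd.DataFrame(rows, columns=["subject", "region", "reference"])


def write_cohort(dataset: MultimodalDataset, truth: PhantomTruth, outdir: str | Path) -> None:
    """Export a cohort as NIfTI volumes plus CSV truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for k, sid in enumerate(dataset.subject_ids):
        write_image(dataset.X[k], dataset, outdir / f"{sid}_x.nii")
        write_image(dataset.Y[k], dataset, outdir / f"{sid}_y.nii")
    write_image(truth.atlas.ravel()[dataset.mask.ravel()].astype(float),
                dataset, outdir / "atlas.nii")
    truth.atlas_table.to_csv(outdir / "atlas_table.csv", index=False)
    pd.DataFrame(
        truth.loadings, columns=[f"component_{j}" for j in range(truth.loadings.shape[1])]
    ).assign(subject=dataset.subject_ids, group=dataset.group_labels).to_csv(
        outdir / "true_loadings.csv", index=False
    )
    pd.DataFrame({"subject_id": dataset.subject_ids, "label": dataset.group_labels}).to_csv(
        outdir / "labels.csv", index=False
    )
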