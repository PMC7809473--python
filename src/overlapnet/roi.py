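"""Region-of-interest extraction: volumetric images -> participants x regions matrix.

Pipeline: Gaussian smoothing (FWHM in mm), spherical averaging around atlas
coordinates (sphere diameter in mm, membership tested on voxel-center
Euclidean distance), then across-participant z-scoring. Conventions the
source text leaves open (mm->voxel rounding, boundary handling, SD ddof) are
fixed here and documented on each function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import SocialBrainAtlas
from .errors import (
    AffineError,
    GridMismatchError,
    NonPositiveError,
    OutOfBoundsError,
    ShapeMismatchError,
    ZeroVarianceError,
)

GAUSS_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class GreyMatterImage:
    """3-D grey-matter map with a voxel->mm affine and a participant id."""

    data: np.ndarray
    affine: np.ndarray
    participant_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise AffineError(f"expected 3-D data, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise AffineError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise AffineError("affine is singular")
        if not np.all(np.isfinite(self.data)):
            raise AffineError(f"non-finite voxels in image {self.participant_id!r}")

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm (norms of affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @classmethod
    def from_nifti(cls, path: str | Path, participant_id: str = "") -> "GreyMatterImage":
        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata(), dtype=float), img.affine,
                   participant_id or Path(path).stem)

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data, self.affine), str(path))


@dataclass
class Scaler:
    """Per-region mean/SD (population SD, ddof=0) for z-scoring."""

    mean: np.ndarray
    sd: np.ndarray


@dataclass
class VolumeMatrix:
    """Participants x regions grey-matter volumes."""

    values: np.ndarray
    participant_ids: list[str]
    region_names: list[str]
    standardized: bool = False
    scaler: Scaler | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.participant_ids), len(self.region_names)):
            raise ShapeMismatchError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.participant_ids)} participants x {len(self.region_names)} regions"
            )
        if not np.all(np.isfinite(self.values)):
            raise ShapeMismatchError("volume matrix contains non-finite entries")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.participant_ids, name="participant_id"),
                            columns=self.region_names)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, standardized: bool = False) -> "VolumeMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), [str(i) for i in df.index],
                   [str(c) for c in df.columns], standardized=standardized)


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian sigma in mm for a given full width at half maximum."""
    if fwhm_mm <= 0:
        raise NonPositiveError(f"FWHM must be positive, got {fwhm_mm}")
    return fwhm_mm / GAUSS_FWHM_FACTOR


def smooth_image(img: GreyMatterImage, fwhm_mm: float) -> GreyMatterImage:
    """Gaussian-smooth with per-axis sigma = sigma_mm / voxel_size.

    Reflect padding at the boundary so total intensity is conserved.
    ``fwhm_mm == 0`` is allowed and returns a copy (no smoothing).
    """
    if fwhm_mm == 0:
        return GreyMatterImage(img.data.copy(), img.affine.copy(), img.participant_id)
    sigma_mm = fwhm_to_sigma(fwhm_mm)
    voxel = img.voxel_sizes
    if np.any(voxel <= 0):
        raise AffineError(f"non-positive voxel sizes {voxel}")
    smoothed = ndimage.gaussian_filter(img.data, sigma=sigma_mm / voxel, mode="reflect")
    return GreyMatterImage(smoothed, img.affine.copy(), img.participant_id)


def sphere_voxel_offsets(diameter_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Integer voxel offsets within a sphere of the given diameter.

    Membership: ||offset * voxel_size||_2 <= diameter / 2. Returned in
    deterministic lexicographic order as an (m, 3) int array.
    """
    if diameter_mm <= 0 or voxel_size_mm <= 0:
        raise NonPositiveError("diameter and voxel size must be positive")
    radius = diameter_mm / 2.0
    reach = int(math.floor(radius / voxel_size_mm))
    rng = np.arange(-reach, reach + 1)
    ii, jj, kk = np.meshgrid(rng, rng, rng, indexing="ij")
    offsets = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    dist2 = np.sum((offsets * voxel_size_mm) ** 2, axis=1)
    keep = offsets[dist2 <= radius**2 + 1e-12]
    order = np.lexsort((keep[:, 2], keep[:, 1], keep[:, 0]))
    return keep[order]


def _mm_to_voxel(affine: np.ndarray, xyz_mm: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    hom = np.append(np.asarray(xyz_mm, dtype=float), 1.0)
    return (inv @ hom)[:3]


def extract_region_volumes(
    images: Sequence[GreyMatterImage],
    atlas: SocialBrainAtlas,
    diameter_mm: float = 5.0,
    fwhm_mm: float = 5.0,
) -> VolumeMatrix:
    """Average smoothed images in spheres at atlas coordinates.

    The sphere center is the voxel nearest each region's mm coordinate
    (inverse affine, rounded). All images must share grid shape and affine.
    """
    if not images:
        raise GridMismatchError("no images given")
    shape = images[0].data.shape
    affine = images[0].affine
    for img in images[1:]:
        if img.data.shape != shape or not np.allclose(img.affine, affine):
            raise GridMismatchError(
                f"image {img.participant_id!r} grid differs from the first image"
            )
    voxel_sizes = images[0].voxel_sizes
    if not np.allclose(voxel_sizes, voxel_sizes[0], rtol=1e-6):
        raise GridMismatchError(
            f"anisotropic voxels {voxel_sizes} not supported for spherical averaging"
        )
    offsets = sphere_voxel_offsets(diameter_mm, float(voxel_sizes[0]))

    centers = []
    for region in atlas.regions:
        center = np.rint(_mm_to_voxel(affine, np.array(region.mni_xyz))).astype(int)
        coords = center[None, :] + offsets
        if np.any(coords < 0) or np.any(coords >= np.array(shape)[None, :]):
            raise OutOfBoundsError(
                f"sphere for region {region.name!r} at voxel {center.tolist()} "
                f"exceeds image bounds {shape}"
            )
        centers.append(coords)

    values = np.empty((len(images), len(atlas)), dtype=float)
    ids = []
    for i, img in enumerate(images):
        smoothed = smooth_image(img, fwhm_mm)
        for r, coords in enumerate(centers):
            values[i, r] = smoothed.data[coords[:, 0], coords[:, 1], coords[:, 2]].mean()
        ids.append(img.participant_id or f"sub-{i:05d}")

    return VolumeMatrix(values, ids, atlas.region_names, standardized=False)


def zscore_fit(vm: VolumeMatrix) -> Scaler:
    """Fit per-region mean/SD (ddof=0). Raises on zero-variance regions."""
    mean = vm.values.mean(axis=0)
    sd = vm.values.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd <= 0)
    if zero.size:
        names = [vm.region_names[j] for j in zero]
        raise ZeroVarianceError(f"zero variance in regions {names}")
    return Scaler(mean=mean, sd=sd)


def zscore_apply(vm: VolumeMatrix, scaler: Scaler) -> VolumeMatrix:
    """Apply a fitted scaler: (x - mean) / sd per region."""
    if scaler.mean.shape[0] != vm.n_regions:
        raise ShapeMismatchError(
            f"scaler has {scaler.mean.shape[0]} regions, matrix has {vm.n_regions}"
        )
    z = (vm.values - scaler.mean) / scaler.sd
    return VolumeMatrix(z, list(vm.participant_ids), list(vm.region_names),
                        standardized=True, scaler=scaler)


def zscore_invert(vm: VolumeMatrix) -> VolumeMatrix:
    """Undo z-scoring using the stored scaler."""
    if not vm.standardized or vm.scaler is None:
        raise ShapeMismatchError("matrix is not standardized with a stored scaler")
    raw = vm.values * vm.scaler.sd + vm.scaler.mean
    return VolumeMatrix(raw, list(vm.participant_ids), list(vm.region_names),
                        standardized=False)
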