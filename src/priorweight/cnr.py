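"""Contrast quantification for neuromelanin-sensitive MR volumes.

The contrast-to-noise ratio of voxel j is its signal contrasted with a
reference region: CNR(j) = (x(j) - mu_ref) / sigma_ref, with mu_ref and
sigma_ref the mean and standard deviation (n-1 denominator) over reference
voxels; the contrast ratio replaces the denominator with mu_ref.  Arrays
use index order (k, i, j) — slice, row, column; no world-space resampling
is performed.  NIfTI I/O is available through nibabel when installed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Volume",
    "RoiMask",
    "compute_cnr_map",
    "compute_contrast_ratio_map",
    "mean_roi_value",
    "generate_phantom",
    "load_nifti",
    "save_nifti",
]


@dataclass(frozen=True)
class Volume:
    """A 3-D signal array in arbitrary scanner units."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", np.asarray(self.data, dtype=float))
        if self.data.ndim != 3:
            raise ValueError("volume must be 3-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass(frozen=True)
class RoiMask:
    """A binary mask congruent with a volume.

    ``threshold`` records the probabilistic-atlas threshold the mask came
    from (e.g. 0.05 or 0.25); atlas construction itself is upstream of this
    module.
    """

    mask: np.ndarray
    label: str = "custom"
    threshold: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not self.mask.any():
            raise ValueError("mask must contain at least one voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _check_congruent(vol: Volume, roi: RoiMask) -> None:
    if vol.shape != roi.mask.shape:
        raise ValueError("volume and mask shapes differ")


def compute_cnr_map(vol: Volume, ref: RoiMask) -> Volume:
    """Voxelwise contrast-to-noise ratio relative to a reference region."""
    _check_congruent(vol, ref)
    ref_vals = vol.data[ref.mask]
    mu = ref_vals.mean()
    sd = ref_vals.std(ddof=1) if len(ref_vals) > 1 else 0.0
    if sd == 0.0:
        raise ValueError("degenerate reference: zero standard deviation")
    return Volume((vol.data - mu) / sd, vol.voxel_size)


def compute_contrast_ratio_map(vol: Volume, ref: RoiMask) -> Volume:
    """Voxelwise contrast ratio (reference-mean normalisation)."""
    _check_congruent(vol, ref)
    mu = vol.data[ref.mask].mean()
    if mu == 0.0:
        raise ValueError("degenerate reference: zero mean signal")
    return Volume((vol.data - mu) / mu, vol.voxel_size)


def mean_roi_value(vol_map: Volume, roi: RoiMask) -> float:
    """Arithmetic mean of a map over an ROI (e.g. mean locus coeruleus CNR)."""
    _check_congruent(vol_map, roi)
    return float(vol_map.data[roi.mask].mean())


def generate_phantom(
    shape: tuple[int, int, int] = (20, 24, 24),
    ref_level: float = 100.0,
    roi_effect: float = 3.0,
    noise_sd: float = 5.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[Volume, RoiMask, RoiMask]:
    """Synthetic phantom with a known expected ROI contrast.

    Background and reference voxels are N(ref_level, noise_sd^2); an
    ellipsoidal blob (the locus-coeruleus stand-in) is elevated by
    roi_effect x noise_sd so its expected CNR equals ``roi_effect``.  The
    reference region is a slab well separated from the blob; the two never
    overlap.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    if min(shape) < 8:
        raise ValueError("phantom must be at least 8 voxels per axis")
    data = rng.normal(ref_level, noise_sd, size=shape)

    ref_mask = np.zeros(shape, dtype=bool)
    ref_mask[1: max(2, nz // 4), :, :] = True

    zc, yc, xc = int(nz * 0.7), ny // 2, nx // 2
    rz, ry, rx = max(2, nz // 8), max(2, ny // 6), max(2, nx // 6)
    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    blob = (((zz - zc) / rz) ** 2 + ((yy - yc) / ry) ** 2
            + ((xx - xc) / rx) ** 2) <= 1.0
    if (blob & ref_mask).any():
        raise ValueError("phantom configuration: ROI overlaps the reference")
    data[blob] += roi_effect * noise_sd
    vol = Volume(data)
    return (
        vol,
        RoiMask(blob, label="locus_coeruleus"),
        RoiMask(ref_mask, label="reference"),
    )


def load_nifti(path) -> Volume:
    """Read a NIfTI volume (requires nibabel)."""
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return Volume(np.asarray(img.get_fdata(), dtype=float),
                  tuple(float(z) for z in zooms))


def save_nifti(vol: Volume, path) -> None:
    """Write a volume as NIfTI with a diagonal affine from the voxel size."""
    import nibabel as nib

    affine = np.diag(list(vol.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(vol.data, affine), str(path))
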