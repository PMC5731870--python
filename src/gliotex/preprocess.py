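"""Preprocessing chain: NAWM intensity normalization, isotropic reslicing,
and gray-level quantization.

The chain assumes bias-field-corrected input volumes (N3 correction is an
upstream, external step; typical parameters are signal threshold 1.0, field
distance 50 mm, kernel FWHM 0.15).  Stages are applied in the order
normalize -> reslice -> quantize:

1. ``normalize_to_nawm`` divides every voxel by the mean intensity over the
   contralateral normal-appearing white matter (NAWM) mask, making tumor
   intensities comparable across scanners and sites.
2. ``reslice_isotropic`` resamples volume and masks to isotropic voxels
   (default 1 mm), trilinear for intensities, nearest-neighbor for masks.
3. ``quantize`` maps in-mask intensities to G equal-width gray levels
   (default G=8) spanning the per-ROI min-max range; this makes all texture
   features invariant to positive affine intensity transforms.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from scipy import ndimage

from .image import QuantizedROI, ROIMask, VolumeImage


def reslice_isotropic(
    vol: VolumeImage,
    masks: Sequence[ROIMask] = (),
    target_mm: float = 1.0,
) -> Tuple[VolumeImage, Tuple[ROIMask, ...]]:
    """Resample a volume (and aligned masks) to isotropic voxels.

    Intensities are trilinearly interpolated; masks are resampled with
    nearest-neighbor so they stay crisp binary fields.  The output grid is
    half-voxel-centered over the same physical extent as the input (extent
    preserved to within one voxel).

    Parameters
    ----------
    vol : VolumeImage
    masks : sequence of ROIMask
        Masks on the same grid as ``vol``.
    target_mm : float
        Isotropic output voxel size in mm.

    Returns
    -------
    (VolumeImage, tuple of ROIMask)
    """
    if target_mm <= 0:
        raise ValueError(f"target_mm must be positive, got {target_mm}")
    shape = vol.shape
    if any(n < 2 for n in shape):
        raise ValueError(
            f"cannot reslice a degenerate (single-slice) axis: shape {shape}"
        )
    for m in masks:
        if m.shape != shape:
            raise ValueError("mask grid does not match volume grid")

    factors = tuple(s / target_mm for s in vol.spacing_mm)
    out = ndimage.zoom(vol.values, factors, order=1, mode="nearest", grid_mode=True)
    new_vol = VolumeImage(
        values=out, spacing_mm=(target_mm,) * 3, modality=vol.modality
    )
    new_masks = []
    for m in masks:
        mm = ndimage.zoom(
            m.values.astype(np.uint8), factors, order=0, mode="nearest", grid_mode=True
        )
        new_masks.append(
            ROIMask(values=mm > 0, spacing_mm=(target_mm,) * 3, role=m.role)
        )
    return new_vol, tuple(new_masks)


def normalize_to_nawm(
    vol: VolumeImage, tumor: ROIMask, nawm: ROIMask
) -> VolumeImage:
    """Divide every voxel by the mean intensity over the NAWM mask.

    After normalization the NAWM mean is exactly 1, so tumor intensities are
    expressed relative to normal white matter.  The operation is invariant
    to multiplying the input by any positive constant.
    """
    if nawm.shape != vol.shape or tumor.shape != vol.shape:
        raise ValueError("mask grid does not match volume grid")
    if nawm.is_empty():
        raise ValueError("NAWM mask is empty; cannot normalize")
    ref = float(vol.values[nawm.values].mean())
    if ref <= 0:
        raise ValueError(f"NAWM mean intensity must be positive, got {ref}")
    return VolumeImage(
        values=vol.values / ref, spacing_mm=vol.spacing_mm, modality=vol.modality
    )


def quantize(vol: VolumeImage, tumor: ROIMask, n_levels: int = 8) -> QuantizedROI:
    """Quantize in-mask intensities to ``n_levels`` equal-width gray levels.

    Bins span the per-ROI [min, max] intensity range:
    ``level = 1 + floor(G * (x - min) / (max - min))`` with the maximum
    clamped to level G.  A constant ROI maps to all level 1.
    """
    if tumor.shape != vol.shape:
        raise ValueError("mask grid does not match volume grid")
    if tumor.is_empty():
        raise ValueError("tumor mask is empty; nothing to quantize")
    if n_levels < 2:
        raise ValueError(f"G must be >= 2, got {n_levels}")

    inside = vol.values[tumor.values]
    lo, hi = float(inside.min()), float(inside.max())
    levels = np.zeros(vol.shape, dtype=np.int64)
    if hi == lo:
        levels[tumor.values] = 1
    else:
        scaled = np.floor(n_levels * (inside - lo) / (hi - lo)).astype(np.int64) + 1
        np.clip(scaled, 1, n_levels, out=scaled)
        levels[tumor.values] = scaled
    return QuantizedROI(
        levels=levels, mask=tumor, n_levels=n_levels, spacing_mm=vol.spacing_mm
    )


def preprocess_patient(
    vol: VolumeImage,
    tumor: ROIMask,
    nawm: ROIMask,
    target_mm: float = 1.0,
    n_levels: int = 8,
) -> Tuple[VolumeImage, ROIMask, QuantizedROI]:
    """Full per-modality chain: normalize, reslice, quantize.

    Returns the resliced normalized volume, the resliced tumor mask, and the
    quantized ROI (all on the isotropic grid).
    """
    normed = normalize_to_nawm(vol, tumor, nawm)
    resliced, (tumor_r, _nawm_r) = reslice_isotropic(
        normed, (tumor, nawm), target_mm=target_mm
    )
    q = quantize(resliced, tumor_r, n_levels=n_levels)
    return resliced, tumor_r, q
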