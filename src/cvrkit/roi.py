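"""Tissue-mask conditioning and ROI mean-signal extraction.

Before CVR estimation the tissue masks are conditioned to limit partial
volume and large-vessel contamination:

1. erode the subcortical grey matter (SGM) and normal-appearing white
   matter (NAWM) masks by 1 mm in all directions;
2. dilate the ventricle mask anisotropically (5 mm left/right, 4 mm
   anterior/posterior and superior/inferior) to capture the large veins
   running along the ventricles;
3. subtract the dilated ventricle mask from the NAWM and WMH masks;
4. optionally subtract a manually drawn large-vessel exclusion mask.

Structuring elements are axis-aligned boxes: the per-direction millimetre
extents map directly onto box half-widths, and the mm-to-voxel conversion
uses ceil so the stated physical margin is always guaranteed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from cvrkit.errors import (
    EmptyROIError,
    GridMismatchError,
    InvalidArgumentError,
    OrientationError,
)

__all__ = [
    "ROIMaskSet",
    "ROISeries",
    "axis_map_from_affine",
    "condition_masks",
    "dilate_ventricles_anisotropic",
    "erode_isotropic",
    "extract_roi_mean_series",
    "subtract_mask",
]

logger = logging.getLogger(__name__)

TISSUE_LABELS = ("sgm", "nawm", "wmh")


@dataclass
class ROIMaskSet:
    """Binary 3-D masks on a common grid with voxel spacing and provenance.

    ``masks`` maps labels (sgm, nawm, wmh, ventricles, optionally
    large_vessel_exclusion) to boolean arrays.  ``provenance`` records the
    morphology steps applied, in order.
    """

    masks: dict
    voxel_spacing_mm: tuple
    affine: np.ndarray | None = None
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.voxel_spacing_mm) != 3 or any(s <= 0 for s in self.voxel_spacing_mm):
            raise InvalidArgumentError("voxel spacing must be 3 positive values")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise GridMismatchError(f"masks on different grids: {shapes}")
        self.masks = {k: np.asarray(v).astype(bool) for k, v in self.masks.items()}

    @property
    def shape(self) -> tuple:
        return next(iter(self.masks.values())).shape

    def voxel_count(self, label: str) -> int:
        return int(self.masks[label].sum())


@dataclass(frozen=True)
class ROISeries:
    """Mean BOLD signal per volume over one ROI."""

    label: str
    mean_signal: np.ndarray
    n_voxels: int

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise EmptyROIError(f"ROI {self.label!r} has no voxels")
        object.__setattr__(self, "mean_signal", np.asarray(self.mean_signal, dtype=float))


def _box_element(half_widths_vox) -> np.ndarray:
    return np.ones([2 * int(h) + 1 for h in half_widths_vox], dtype=bool)


def _half_widths(extents_mm, spacing_mm) -> list:
    # ceil guarantees at least the stated physical margin
    return [int(np.ceil(e / s)) if e > 0 else 0 for e, s in zip(extents_mm, spacing_mm)]


def erode_isotropic(mask: np.ndarray, radius_mm: float, spacing_mm) -> np.ndarray:
    """Erode a binary mask by ``radius_mm`` in every direction.

    The box structuring element has half-width ceil(radius_mm / spacing) per
    axis; radius 0 is the identity.  An empty result is allowed.
    """
    if radius_mm < 0:
        raise InvalidArgumentError("radius_mm must be >= 0")
    mask = np.asarray(mask).astype(bool)
    if radius_mm == 0:
        return mask.copy()
    hw = _half_widths([radius_mm] * 3, spacing_mm)
    return ndimage.binary_erosion(mask, structure=_box_element(hw), border_value=0)


def axis_map_from_affine(affine: np.ndarray) -> dict:
    """Map anatomical axes (LR, AP, SI) to array axes from a NIfTI affine.

    Uses the dominant direction cosine per array axis; oblique acquisitions
    fall back to the dominant axis with a logged warning.
    """
    if affine is None:
        raise OrientationError("anatomical axis mapping requires an affine or explicit map")
    rotation = np.asarray(affine, dtype=float)[:3, :3]
    if not np.all(np.isfinite(rotation)) or np.linalg.matrix_rank(rotation) < 3:
        raise OrientationError("affine rotation block is singular")
    anat_names = ("LR", "AP", "SI")
    axis_map: dict = {}
    for array_axis in range(3):
        col = rotation[:, array_axis]
        dominant = int(np.argmax(np.abs(col)))
        dominance = np.abs(col[dominant]) / np.linalg.norm(col)
        if dominance < 0.95:
            logger.warning(
                "oblique orientation: array axis %d assigned to %s with dominance %.2f",
                array_axis,
                anat_names[dominant],
                dominance,
            )
        axis_map[anat_names[dominant]] = array_axis
    if set(axis_map) != {"LR", "AP", "SI"}:
        raise OrientationError(f"could not assign all anatomical axes: {axis_map}")
    return axis_map


def dilate_ventricles_anisotropic(
    ventricle_mask: np.ndarray,
    spacing_mm,
    lr_mm: float = 5.0,
    ap_mm: float = 4.0,
    si_mm: float = 4.0,
    axis_map: dict | None = None,
    affine: np.ndarray | None = None,
) -> np.ndarray:
    """Dilate the ventricle mask with per-anatomical-axis extents.

    Defaults: 5 mm left/right, 4 mm anterior/posterior, 4 mm
    superior/inferior.  ``axis_map`` maps 'LR'/'AP'/'SI' to array axes; if
    omitted it is derived from ``affine``.
    """
    if axis_map is None:
        axis_map = axis_map_from_affine(affine)
    extents = [0.0, 0.0, 0.0]
    for name, mm in (("LR", lr_mm), ("AP", ap_mm), ("SI", si_mm)):
        if mm < 0:
            raise InvalidArgumentError("dilation extents must be >= 0")
        extents[axis_map[name]] = mm
    mask = np.asarray(ventricle_mask).astype(bool)
    if all(e == 0 for e in extents):
        return mask.copy()
    hw = _half_widths(extents, spacing_mm)
    return ndimage.binary_dilation(mask, structure=_box_element(hw), border_value=0)


def subtract_mask(target: np.ndarray, exclusion: np.ndarray) -> np.ndarray:
    """Voxelwise set difference: target AND NOT exclusion."""
    target = np.asarray(target).astype(bool)
    exclusion = np.asarray(exclusion).astype(bool)
    if target.shape != exclusion.shape:
        raise GridMismatchError(f"mask grids differ: {target.shape} vs {exclusion.shape}")
    return target & ~exclusion


def extract_roi_mean_series(bold_4d: np.ndarray, mask: np.ndarray, label: str = "roi") -> ROISeries:
    """Arithmetic mean BOLD signal over the mask voxels, per volume."""
    bold_4d = np.asarray(bold_4d, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if bold_4d.ndim != 4:
        raise InvalidArgumentError("bold_4d must be a 4-D (x, y, z, t) array")
    if bold_4d.shape[:3] != mask.shape:
        raise GridMismatchError(
            f"mask grid {mask.shape} does not match BOLD grid {bold_4d.shape[:3]}"
        )
    n_voxels = int(mask.sum())
    if n_voxels == 0:
        raise EmptyROIError(f"ROI {label!r} is empty")
    return ROISeries(label=label, mean_signal=bold_4d[mask].mean(axis=0), n_voxels=n_voxels)


def condition_masks(
    maskset: ROIMaskSet,
    erode_mm: float = 1.0,
    ventricle_dilate_mm=(5.0, 4.0, 4.0),
    axis_map: dict | None = None,
) -> ROIMaskSet:
    """Apply the full mask-conditioning sequence, recording provenance.

    Order: erode SGM and NAWM -> dilate ventricles anisotropically ->
    subtract the dilated ventricles from NAWM and WMH -> subtract the
    optional large-vessel exclusion mask from all tissue ROIs.  WMH masks are
    not eroded (they are often thin; erosion would empty them).
    """
    masks = dict(maskset.masks)
    provenance = list(maskset.provenance)
    spacing = maskset.voxel_spacing_mm

    for label in ("sgm", "nawm"):
        if label in masks:
            masks[label] = erode_isotropic(masks[label], erode_mm, spacing)
            provenance.append(f"erode[{label}] {erode_mm}mm isotropic box")

    if "ventricles" in masks:
        lr, ap, si = ventricle_dilate_mm
        dilated = dilate_ventricles_anisotropic(
            masks["ventricles"], spacing, lr_mm=lr, ap_mm=ap, si_mm=si,
            axis_map=axis_map, affine=maskset.affine,
        )
        provenance.append(f"dilate[ventricles] LR={lr}mm AP={ap}mm SI={si}mm box")
        for label in ("nawm", "wmh"):
            if label in masks:
                masks[label] = subtract_mask(masks[label], dilated)
                provenance.append(f"subtract[{label}] dilated ventricles")

    if "large_vessel_exclusion" in masks:
        for label in TISSUE_LABELS:
            if label in masks:
                masks[label] = subtract_mask(masks[label], masks["large_vessel_exclusion"])
                provenance.append(f"subtract[{label}] large_vessel_exclusion")

    return ROIMaskSet(
        masks=masks,
        voxel_spacing_mm=spacing,
        affine=maskset.affine,
        provenance=provenance,
    )
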