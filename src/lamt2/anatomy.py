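"""Segmentation post-processing and anatomical landmarking.

Raw network output is cleaned per label by (1) filling background regions
fully enclosed within a slice, (2) keeping only the largest 3D connected
component (26-connectivity), and (3) shaving one-voxel-wide in-plane spikes.
The pass is iterated to a fixpoint, which makes the operation idempotent.

Landmarks for the medial/lateral split come from the bone segmentation: the
fibula centroid fixes which end of the slice axis is lateral, and the
intercondylar notch (the slice of minimal femoral cross-section between the
two condylar area maxima) separates the compartments.  The central
(weight-bearing) femoral region of interest is taken, per slice, as the
anterior--posterior extent covered by the tibia.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import LabelMask

__all__ = [
    "Landmarks",
    "LandmarkError",
    "postprocess_mask",
    "derive_landmarks",
    "split_plates",
]

_CROSS2D = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_CONN26 = np.ones((3, 3, 3), dtype=bool)


class LandmarkError(ValueError):
    """Raised when the bone mask cannot support landmark derivation."""


@dataclass
class Landmarks:
    lateral_side: str                       # "low" | "high" end of the slice axis
    ml_boundary_slice: int
    tibial_ap_extent: dict[int, tuple[int, int]]  # slice -> [col_lo, col_hi)
    low_confidence: bool = False


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------

def postprocess_mask(mask: LabelMask, max_hole_voxels: int | None = None,
                     max_iter: int = 50) -> LabelMask:
    """Clean a label mask; output labels are always a subset of input labels."""
    out = np.asarray(mask.labels).copy()
    values = [v for v in np.unique(out) if v != 0]
    # labels interact (removing one label's fragment can expose another
    # label's enclosed hole), so the whole pass iterates to a fixpoint
    for _ in range(max_iter):
        prev = out.copy()
        for value in values:
            binary = out == value
            forbidden = (out != 0) & ~binary
            cleaned = _clean_binary(binary, forbidden, max_hole_voxels, max_iter)
            out[binary & ~cleaned] = 0
            out[cleaned & (out == 0)] = value
        if np.array_equal(out, prev):
            break
    return LabelMask(out, dict(mask.label_dict), mask.spacing_mm)


def _clean_binary(binary: np.ndarray, forbidden: np.ndarray,
                  max_hole_voxels, max_iter) -> np.ndarray:
    # holes occupied by another label are not background and stay unfilled;
    # excluding them inside the loop keeps the returned set a true fixpoint
    cur = binary.copy()
    for _ in range(max_iter):
        new = _fill_holes(cur, max_hole_voxels) & ~forbidden
        new = _largest_component(new)
        new = _shave_spikes(new)
        if np.array_equal(new, cur):
            return new
        cur = new
    return cur


def _fill_holes(binary: np.ndarray, max_hole_voxels) -> np.ndarray:
    out = binary.copy()
    for z in range(binary.shape[0]):
        sl = binary[z]
        if not sl.any():
            continue
        filled = ndimage.binary_fill_holes(sl)
        if max_hole_voxels is not None:
            holes, n = ndimage.label(filled & ~sl)
            for i in range(1, n + 1):
                hole = holes == i
                if hole.sum() > max_hole_voxels:
                    filled[hole] = False
        out[z] = filled
    return out


def _largest_component(binary: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(binary, structure=_CONN26)
    if n <= 1:
        return binary
    sizes = ndimage.sum_labels(binary, lab, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return lab == keep


def _shave_spikes(binary: np.ndarray) -> np.ndarray:
    """Remove in-plane voxels with at most one 4-neighbour inside the label
    (tips of one-voxel-wide protrusions)."""
    out = binary.copy()
    for z in range(binary.shape[0]):
        sl = out[z]
        if not sl.any():
            continue
        nb = ndimage.convolve(sl.astype(np.int8), _CROSS2D.astype(np.int8) * 1,
                              mode="constant", cval=0) - sl.astype(np.int8)
        out[z] = sl & (nb >= 2)
    return out


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

def derive_landmarks(bone_mask: LabelMask) -> Landmarks:
    """Locate the lateral side, the medial/lateral boundary slice, and the
    per-slice tibial anterior--posterior extent."""
    for required in ("femur", "tibia"):
        if required not in bone_mask.label_dict or not bone_mask.binary(required).any():
            raise LandmarkError(f"bone mask lacks a {required} segmentation")
    femur = bone_mask.binary("femur")
    tibia = bone_mask.binary("tibia")
    n_slices = femur.shape[0]

    # lateral side from the fibula centroid; fallback: larger tibial area side
    low_confidence = False
    fibula = (bone_mask.binary("fibula")
              if "fibula" in bone_mask.label_dict else np.zeros_like(femur))
    if fibula.any():
        centroid_slice = np.argwhere(fibula)[:, 0].mean()
        lateral_side = "low" if centroid_slice < (n_slices - 1) / 2 else "high"
    else:
        low_confidence = True
        areas = tibia.reshape(n_slices, -1).sum(axis=1)
        half = n_slices // 2
        lateral_side = "low" if areas[:half].sum() > areas[half:].sum() else "high"

    # intercondylar notch: minimal femoral area between the two condylar maxima
    fem_areas = femur.reshape(n_slices, -1).sum(axis=1)
    present = np.flatnonzero(fem_areas > 0)
    lo, hi = present[0], present[-1]
    mid = (lo + hi) // 2
    peak_a = lo + int(np.argmax(fem_areas[lo:mid + 1]))
    peak_b = mid + int(np.argmax(fem_areas[mid:hi + 1]))
    if peak_b <= peak_a + 1:
        boundary = mid
    else:
        boundary = peak_a + 1 + int(np.argmin(fem_areas[peak_a + 1:peak_b]))

    extents: dict[int, tuple[int, int]] = {}
    for z in range(n_slices):
        cols = np.flatnonzero(tibia[z].any(axis=0))
        if cols.size:
            extents[z] = (int(cols[0]), int(cols[-1]) + 1)

    return Landmarks(
        lateral_side=lateral_side,
        ml_boundary_slice=int(boundary),
        tibial_ap_extent=extents,
        low_confidence=low_confidence,
    )


# ---------------------------------------------------------------------------
# Plate splitting
# ---------------------------------------------------------------------------

PLATE_VALUES = {"MT": 1, "cMF": 2, "LT": 3, "cLF": 4}


def split_plates(cartilage_mask: LabelMask, landmarks: Landmarks) -> LabelMask:
    """Split tibial/femoral cartilage into MT, cMF, LT, cLF.

    Tibial cartilage is partitioned exactly at the medial/lateral boundary
    slice.  Femoral cartilage is split likewise and then restricted to the
    central (weight-bearing) region of interest: per slice, voxels whose
    anterior--posterior position falls within that slice's tibial extent.
    Femoral voxels outside the ROI are dropped.
    """
    for required in ("tibial", "femoral"):
        if required not in cartilage_mask.label_dict:
            raise ValueError(f"cartilage mask lacks a '{required}' label")
    tib = cartilage_mask.binary("tibial")
    fem = cartilage_mask.binary("femoral")
    n_slices = tib.shape[0]
    b = landmarks.ml_boundary_slice
    slice_idx = np.arange(n_slices)[:, None, None]
    if landmarks.lateral_side == "high":
        medial = np.broadcast_to(slice_idx < b, tib.shape)
    else:
        medial = np.broadcast_to(slice_idx > b, tib.shape)

    out = np.zeros(tib.shape, dtype=np.int16)
    out[tib & medial] = PLATE_VALUES["MT"]
    out[tib & ~medial] = PLATE_VALUES["LT"]

    roi = np.zeros(tib.shape, dtype=bool)
    for z, (c0, c1) in landmarks.tibial_ap_extent.items():
        roi[z, :, c0:c1] = True
    fem_central = fem & roi
    out[fem_central & medial] = PLATE_VALUES["cMF"]
    out[fem_central & ~medial] = PLATE_VALUES["cLF"]
    return LabelMask(out, dict(PLATE_VALUES), cartilage_mask.spacing_mm)
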