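"""Voxelwise T2 fitting, laminar (deep/superficial) partitioning and regional means.

Cartilage T2 is estimated per voxel by fitting the mono-exponential decay
``S(TE) = S0 * exp(-TE / T2)`` to the multi-echo signal, initialised by
log-linear regression and refined by damped Gauss--Newton least squares.
Each cartilage plate is then split into its deep (bone-side) and superficial
(surface-side) 50% according to the normalised distance of each voxel between
the bone interface and the articular surface, and mean T2 is aggregated per
plate and layer.  Compartment values are unweighted means of plate values:
MFTC = (MT + cMF)/2, LFTC = (LT + cLF)/2, FTJ = mean of all four plates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import LabelMask, MESEVolume

__all__ = [
    "T2Map",
    "LayerPartition",
    "RegionalT2",
    "PLATES",
    "LAYERS",
    "fit_t2",
    "fit_t2_signals",
    "compute_depth",
    "partition_layers",
    "aggregate",
]

PLATES = ("MT", "cMF", "LT", "cLF")
LAYERS = ("deep", "superficial")

#: derived regions and the plates they average (unweighted)
DERIVED_REGIONS = {
    "MFTC": ("MT", "cMF"),
    "LFTC": ("LT", "cLF"),
    "FTJ": ("MT", "cMF", "LT", "cLF"),
}

LAYER_NONE, LAYER_DEEP, LAYER_SUPERFICIAL = 0, 1, 2


@dataclass
class T2Map:
    """Per-voxel fitted T2/S0 with a validity flag.

    ``valid`` is True where the fit converged, S0 > 0 and 0 < T2 <= t2_cap.
    Invalid voxels are excluded from every aggregate.
    """

    t2_ms: np.ndarray
    s0: np.ndarray
    valid: np.ndarray


@dataclass
class LayerPartition:
    """Deep/superficial assignment with the underlying depth fraction.

    ``depth_fraction`` is 0 at the bone interface and 1 at the articular
    surface; NaN where depth is undefined (cartilage with no bone adjacency).
    """

    layer: np.ndarray
    depth_fraction: np.ndarray


@dataclass
class RegionalT2:
    """Mean T2 (ms) and voxel count per (region, layer) cell.

    Plate cells are voxel means; MFTC/LFTC/FTJ are unweighted means of the
    constituent plate means.  Empty cells hold NaN, not 0.
    """

    values: dict = field(default_factory=dict)  # (region, layer) -> (mean_t2, n)

    def mean(self, region: str, layer: str) -> float:
        return self.values[(region, layer)][0]

    def n(self, region: str, layer: str) -> int:
        return self.values[(region, layer)][1]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": r, "layer": l, "mean_t2_ms": m, "n_voxels": n}
            for (r, l), (m, n) in self.values.items()
        ]
        return pd.DataFrame(rows, columns=["region", "layer", "mean_t2_ms", "n_voxels"])

    @classmethod
    def from_plate_means(cls, plate_means: dict, plate_counts: dict | None = None) -> "RegionalT2":
        """Build a full regional table from per-(plate, layer) means.

        Parameters
        ----------
        plate_means
            ``{(plate, layer): mean_t2_ms}`` for the four plates.
        plate_counts
            Optional ``{(plate, layer): n_voxels}``; defaults to 0.
        """
        counts = plate_counts or {}
        out = cls()
        for key, m in plate_means.items():
            out.values[key] = (float(m), int(counts.get(key, 0)))
        for region, plates in DERIVED_REGIONS.items():
            for layer in LAYERS:
                ms = [plate_means.get((p, layer), np.nan) for p in plates]
                ns = [counts.get((p, layer), 0) for p in plates]
                out.values[(region, layer)] = (float(np.mean(ms)), int(np.sum(ns)))
        return out


# ---------------------------------------------------------------------------
# Mono-exponential fitting
# ---------------------------------------------------------------------------

def fit_t2_signals(
    signals: np.ndarray,
    echo_times_ms,
    t2_cap: float = 100.0,
    drop_first_echo: bool = False,
    max_iter: int = 60,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit ``S0 * exp(-TE/T2)`` to each row of ``signals``.

    Parameters
    ----------
    signals
        Array of shape ``(n_voxels, n_echoes)``.
    echo_times_ms
        Echo times matching the second axis.
    t2_cap
        Upper physiological bound; fits above it are flagged invalid
        (guards against synovial fluid and partial-volume voxels).
    drop_first_echo
        Exclude TE1 from the fit (offered because some T2 methodologies do);
        all echoes are used by default.

    Returns
    -------
    (t2_ms, s0, valid) arrays of length ``n_voxels``.
    """
    te = np.asarray(echo_times_ms, dtype=np.float64)
    y = np.asarray(signals, dtype=np.float64)
    if y.ndim == 1:
        y = y[None, :]
    if drop_first_echo:
        te, y = te[1:], y[:, 1:]
    if te.size < 3:
        raise ValueError("at least 3 echoes are required for a 2-parameter fit")

    n = y.shape[0]
    # log-linear initialisation: log S = log S0 - TE/T2
    logy = np.log(np.clip(y, 1e-12, None))
    te_c = te - te.mean()
    slope = (logy * te_c).sum(axis=1) / (te_c**2).sum()
    s0 = np.exp(logy.mean(axis=1) - slope * te.mean())
    r2 = -slope  # decay rate 1/T2

    decaying = r2 > 1e-9
    r2 = np.where(decaying, r2, 1e-9)
    s0 = np.clip(s0, 1e-12, None)

    # damped Gauss--Newton on (s0, r2), vectorised over voxels
    lam = np.full(n, 1e-3)
    cost = _cost(s0, r2, te, y)
    converged = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        e = np.exp(-np.outer(r2, te))            # (n, E)
        resid = s0[:, None] * e - y
        j0 = e                                    # d/ds0
        j1 = -s0[:, None] * te[None, :] * e       # d/dr2
        g0 = (j0 * resid).sum(axis=1)
        g1 = (j1 * resid).sum(axis=1)
        h00 = (j0 * j0).sum(axis=1)
        h01 = (j0 * j1).sum(axis=1)
        h11 = (j1 * j1).sum(axis=1)
        a00 = h00 * (1 + lam)
        a11 = h11 * (1 + lam)
        det = a00 * a11 - h01 * h01
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        d_s0 = -(a11 * g0 - h01 * g1) / det
        d_r2 = -(a00 * g1 - h01 * g0) / det
        s0_new = np.clip(s0 + d_s0, 1e-12, None)
        r2_new = np.clip(r2 + d_r2, 1e-12, None)
        cost_new = _cost(s0_new, r2_new, te, y)
        better = cost_new <= cost
        step = np.maximum(
            np.abs(d_s0) / np.maximum(np.abs(s0), 1e-12),
            np.abs(d_r2) / np.maximum(np.abs(r2), 1e-12),
        )
        converged |= better & (step < 1e-9)
        s0 = np.where(better, s0_new, s0)
        r2 = np.where(better, r2_new, r2)
        cost = np.where(better, cost_new, cost)
        lam = np.where(better, lam * 0.3, lam * 5.0)
        if converged.all():
            break
    # near-flat signals never decay meaningfully -> not converged to a
    # physiological fit even if the optimiser is stationary
    converged &= decaying | (r2 > 1e-6)
    t2 = 1.0 / r2
    valid = converged & (t2 > 0) & (t2 <= t2_cap) & (s0 > 0)
    return t2, s0, valid


def _cost(s0, r2, te, y):
    resid = s0[:, None] * np.exp(-np.outer(r2, te)) - y
    return (resid**2).sum(axis=1)


def fit_t2(volume: MESEVolume, mask: LabelMask, t2_cap: float = 100.0,
           drop_first_echo: bool = False) -> T2Map:
    """Fit voxelwise T2 within the nonzero voxels of ``mask``."""
    if volume.n_echoes < 3:
        raise ValueError("at least 3 echoes are required")
    if mask.labels.shape != volume.spatial_shape:
        raise ValueError("mask grid does not match the volume grid")
    sel = mask.labels > 0
    shape = volume.spatial_shape
    t2_ms = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    if sel.any():
        sig = volume.intensities[:, sel].T  # (n_voxels, n_echoes)
        t2v, s0v, okv = fit_t2_signals(sig, volume.echo_times_ms, t2_cap=t2_cap,
                                       drop_first_echo=drop_first_echo)
        t2_ms[sel] = t2v
        s0[sel] = s0v
        valid[sel] = okv
    return T2Map(t2_ms=t2_ms, s0=s0, valid=valid)


# ---------------------------------------------------------------------------
# Depth and layers
# ---------------------------------------------------------------------------

_CROSS2D = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def compute_depth(cartilage_mask: LabelMask, bone_mask: LabelMask) -> np.ndarray:
    """Normalised cartilage depth: 0 at the bone interface, 1 at the surface.

    Distances are computed in-plane (2D, per sagittal slice, physical mm),
    because the slice spacing dwarfs the in-plane spacing.  The bone-interface
    set holds cartilage boundary voxels 4-adjacent to bone; the surface set
    holds cartilage boundary voxels 4-adjacent to non-bone exterior.  Each
    cartilage voxel gets ``d_bone / (d_bone + d_surface)`` with the 0/0 case
    (single-voxel-thick cartilage) defined as 0.5.  Cartilage connected
    components with no bone adjacency in a slice get NaN (excluded from
    laminar aggregates).
    """
    cart = cartilage_mask.labels > 0
    bone = bone_mask.labels > 0
    if (cart & bone).any():
        raise ValueError("cartilage and bone masks must be disjoint")
    if cart.shape != bone.shape:
        raise ValueError("cartilage and bone masks must share a grid")
    sp = cartilage_mask.spacing_mm[1:]  # in-plane (row, col)
    depth = np.full(cart.shape, np.nan)
    for z in range(cart.shape[0]):
        c2 = cart[z]
        if not c2.any():
            continue
        b2 = bone[z]
        inside = ndimage.binary_erosion(c2, structure=_CROSS2D, border_value=1)
        boundary = c2 & ~inside
        near_bone = ndimage.binary_dilation(b2, structure=_CROSS2D) & c2
        exterior = ~c2 & ~b2
        near_ext = ndimage.binary_dilation(exterior, structure=_CROSS2D, border_value=0) & c2
        interface = boundary & near_bone
        surface = boundary & near_ext
        d_bone = _dist_to_set(interface, sp)
        d_surf = _dist_to_set(surface, sp)
        comp_lab, n_comp = ndimage.label(c2, structure=_CROSS2D)
        d2 = np.full(c2.shape, np.nan)
        for ci in range(1, n_comp + 1):
            comp = comp_lab == ci
            if not (interface & comp).any():
                continue  # flagged: depth undefined for this component
            db = d_bone[comp]
            ds = d_surf[comp] if (surface & comp).any() else np.zeros(db.shape)
            if not (surface & comp).any():
                # degenerate: every boundary voxel touches bone
                d2[comp] = np.where(db + 0.0 == 0, 0.5, 0.0)
                continue
            tot = db + ds
            d2[comp] = np.where(tot == 0, 0.5, db / np.where(tot == 0, 1.0, tot))
        depth[z] = d2
    return depth


def _dist_to_set(member: np.ndarray, sampling) -> np.ndarray:
    """Euclidean distance (mm) from every pixel to the nearest set member."""
    if not member.any():
        return np.full(member.shape, np.inf)
    return ndimage.distance_transform_edt(~member, sampling=sampling)


def partition_layers(depth_fraction: np.ndarray) -> LayerPartition:
    """Threshold normalised depth at 0.5: superficial if >= 0.5, else deep."""
    d = np.asarray(depth_fraction, dtype=float)
    layer = np.zeros(d.shape, dtype=np.int8)
    on = np.isfinite(d)
    layer[on & (d >= 0.5)] = LAYER_SUPERFICIAL
    layer[on & (d < 0.5)] = LAYER_DEEP
    return LayerPartition(layer=layer, depth_fraction=d)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate(t2: T2Map, partition: LayerPartition, plates: LabelMask) -> RegionalT2:
    """Mean T2 per (plate, layer) over valid voxels, plus derived compartments."""
    if t2.t2_ms.shape != plates.labels.shape or partition.layer.shape != plates.labels.shape:
        raise ValueError("t2 map, partition and plate mask must share a grid")
    means: dict = {}
    counts: dict = {}
    layer_value = {"deep": LAYER_DEEP, "superficial": LAYER_SUPERFICIAL}
    for plate in PLATES:
        if plate in plates.label_dict:
            psel = plates.binary(plate)
        else:
            psel = np.zeros(plates.labels.shape, dtype=bool)
        for layer in LAYERS:
            sel = psel & (partition.layer == layer_value[layer]) & t2.valid
            n = int(sel.sum())
            means[(plate, layer)] = float(t2.t2_ms[sel].mean()) if n else np.nan
            counts[(plate, layer)] = n
    return RegionalT2.from_plate_means(means, counts)
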