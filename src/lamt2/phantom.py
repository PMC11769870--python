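"""Synthetic multi-echo spin-echo knee phantoms with known ground truth.

The phantom hosts a simplified sagittal knee: a femoral slab superiorly and a
tibial slab inferiorly (the femur narrows to an intercondylar waist at the
compartment boundary), a small fibula blob on the lateral side, and a
cartilage band on each bone split into the four femorotibial plates
(MT/cMF/LT/cLF) across the slice (medial--lateral) axis.  Every voxel carries
a true T2 and proton density; the multi-echo signal follows the
mono-exponential forward model with optional Rician noise, and optional
high-T2 synovial-fluid pockets sit tangent to the femoral cartilage surface.

Axis convention: axis 0 = sagittal slices (medial--lateral), axis 1 =
superior--inferior rows, axis 2 = anterior--posterior columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import LabelMask, MESEVolume
from . import t2map as _t2
from .t2map import LAYER_DEEP, LAYER_SUPERFICIAL, LayerPartition, RegionalT2, T2Map

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "simulate_signal",
    "generate_phantom",
    "BONE_LABELS",
    "PLATE_LABELS",
    "CARTILAGE_LABELS",
]

BONE_LABELS = {"femur": 1, "tibia": 2, "fibula": 3}
PLATE_LABELS = {"MT": 1, "cMF": 2, "LT": 3, "cLF": 4}
#: merged 2-label dictionary used to train the cartilage network
CARTILAGE_LABELS = {"tibial": 1, "femoral": 2}

DEFAULT_TISSUES = {
    # tissue -> (proton density S0, T2 ms)
    "background": (50.0, 30.0),   # muscle-like surround
    "bone": (15.0, 8.0),
    "fluid": (140.0, 300.0),
    "cartilage_deep": (100.0, 38.0),
    "cartilage_superficial": (100.0, 48.0),
}


@dataclass
class PhantomSpec:
    """Parameters of a synthetic knee acquisition.

    Defaults mirror the target acquisition: 7 echoes at TE 10..70 ms,
    TR 2700 ms, 0.31 mm in-plane resolution and 3 mm slices with a 0.5 mm
    gap (stored as 3.5 mm slice spacing).
    """

    grid_shape: tuple[int, int, int] = (20, 96, 96)
    spacing_mm: tuple[float, float, float] = (3.5, 0.31, 0.31)
    echo_times_ms: tuple[float, ...] = (10, 20, 30, 40, 50, 60, 70)
    repetition_time_ms: float = 2700.0
    tissue_params: dict = field(default_factory=lambda: dict(DEFAULT_TISSUES))
    cartilage_t2_gradient: bool = False
    noise_sigma: float = 3.0
    fluid_pockets: int = 0
    cartilage_thickness: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times_ms, dtype=float)
        if np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")
        for name, (s0, t2) in self.tissue_params.items():
            if t2 <= 0 or s0 <= 0:
                raise ValueError(f"tissue '{name}' must have positive S0 and T2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if any(g < 8 for g in self.grid_shape):
            raise ValueError("grid_shape entries must be >= 8")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    bone_mask: LabelMask
    cartilage_mask: LabelMask            # four plates MT/cMF/LT/cLF
    layer_mask: np.ndarray               # 0 none, 1 deep, 2 superficial
    true_t2: np.ndarray                  # per-voxel T2 (ms), all tissues
    true_regional: RegionalT2
    lateral_side: str = "high"           # end of the slice axis that is lateral
    ml_boundary_slice: int = 0

    def cartilage_binary_mask(self) -> LabelMask:
        """Two-label (tibial/femoral) mask used for cartilage network training."""
        lab = np.zeros(self.cartilage_mask.labels.shape, dtype=np.int16)
        lab[np.isin(self.cartilage_mask.labels,
                    [PLATE_LABELS["MT"], PLATE_LABELS["LT"]])] = CARTILAGE_LABELS["tibial"]
        lab[np.isin(self.cartilage_mask.labels,
                    [PLATE_LABELS["cMF"], PLATE_LABELS["cLF"]])] = CARTILAGE_LABELS["femoral"]
        return LabelMask(lab, dict(CARTILAGE_LABELS), self.cartilage_mask.spacing_mm)


def simulate_signal(t2_ms: float, s0: float, echo_times_ms) -> np.ndarray:
    """Noise-free mono-exponential echo train ``S0 * exp(-TE/T2)``."""
    if t2_ms <= 0 or s0 <= 0:
        raise ValueError("t2_ms and s0 must be positive")
    te = np.asarray(echo_times_ms, dtype=float)
    return s0 * np.exp(-te / t2_ms)


def generate_phantom(spec: PhantomSpec) -> tuple[MESEVolume, PhantomTruth]:
    """Build the phantom volume and its ground truth (deterministic per seed)."""
    S, R, C = spec.grid_shape
    rng = np.random.default_rng(spec.seed)
    hc = spec.cartilage_thickness

    mid_row = R // 2
    # joint space rows [mid_row-1, mid_row]; cartilage above/below, bone beyond
    fem_cart_rows = (mid_row - 1 - hc, mid_row - 1)       # [lo, hi)
    tib_cart_rows = (mid_row + 1, mid_row + 1 + hc)
    fem_bone_rows = (max(2, R // 8), fem_cart_rows[0])
    tib_bone_rows = (tib_cart_rows[1], R - max(2, R // 8))
    if fem_bone_rows[1] - fem_bone_rows[0] < 2 or tib_bone_rows[1] - tib_bone_rows[0] < 2:
        raise ValueError("grid too small to host bones, cartilage and joint space")

    # the joint spans the full AP extent so the cartilage bands have no free
    # in-plane ends: the laminar depth field is then exactly row-based
    cart_lo, cart_hi = 0, C
    s_lo, s_hi = 1, S - 1                                  # slices hosting the joint
    boundary_slice = S // 2                                # intercondylar waist

    bone = np.zeros((S, R, C), dtype=np.int16)
    cart = np.zeros((S, R, C), dtype=np.int16)
    layer = np.zeros((S, R, C), dtype=np.int8)

    # femur: condyles shaped by varying the number of superior rows, with the
    # cross-sectional area strictly minimal at the intercondylar waist slice;
    # the inferior rows always support the femoral cartilage
    fem_height = fem_bone_rows[1] - fem_bone_rows[0]
    max_dip = max(2, fem_height - 2)
    halfspan = max(1, (s_hi - 1 - s_lo) / 2)
    for s in range(s_lo, s_hi):
        closeness = max(0.0, 1.0 - abs(s - boundary_slice) / halfspan)
        dip = int(round((max_dip - 1) * closeness))
        if s == boundary_slice:
            dip = max_dip                                  # unique minimum
        bone[s, fem_bone_rows[0] + dip:fem_bone_rows[1], :] = BONE_LABELS["femur"]
        bone[s, tib_bone_rows[0]:tib_bone_rows[1], :] = BONE_LABELS["tibia"]

    # fibula: small blob on the lateral (high slice index) side, below the
    # tibial plateau rows so it stays clear of the joint line
    fib_s = slice(S - 3, S - 1)
    fib_r = slice(min(tib_bone_rows[1] + 1, R - 4), min(tib_bone_rows[1] + 4, R - 1))
    fib_c = slice(C // 2 - 2, C // 2 + 2)
    bone[fib_s, fib_r, fib_c] = BONE_LABELS["fibula"]

    # cartilage bands (skip the waist slice: intercondylar notch has none)
    for s in range(s_lo, s_hi):
        if s == boundary_slice:
            continue
        medial = s < boundary_slice
        tib_lab = PLATE_LABELS["MT"] if medial else PLATE_LABELS["LT"]
        fem_lab = PLATE_LABELS["cMF"] if medial else PLATE_LABELS["cLF"]
        cart[s, tib_cart_rows[0]:tib_cart_rows[1], cart_lo:cart_hi] = tib_lab
        cart[s, fem_cart_rows[0]:fem_cart_rows[1], cart_lo:cart_hi] = fem_lab
        # layers: deep = bone side (lower half of femoral band is surface side)
        t_half = tib_cart_rows[0] + hc // 2
        layer[s, tib_cart_rows[0]:t_half, cart_lo:cart_hi] = LAYER_SUPERFICIAL
        layer[s, t_half:tib_cart_rows[1], cart_lo:cart_hi] = LAYER_DEEP
        f_half = fem_cart_rows[0] + hc // 2
        layer[s, fem_cart_rows[0]:f_half, cart_lo:cart_hi] = LAYER_DEEP
        layer[s, f_half:fem_cart_rows[1], cart_lo:cart_hi] = LAYER_SUPERFICIAL

    # true T2 / S0 fields
    s0_bg, t2_bg = spec.tissue_params["background"]
    true_t2 = np.full((S, R, C), t2_bg)
    true_s0 = np.full((S, R, C), s0_bg)
    s0_bone, t2_bone = spec.tissue_params["bone"]
    true_t2[bone > 0] = t2_bone
    true_s0[bone > 0] = s0_bone
    s0_cd, t2_deep = spec.tissue_params["cartilage_deep"]
    s0_cs, t2_sup = spec.tissue_params["cartilage_superficial"]
    if spec.cartilage_t2_gradient:
        frac = _geometric_depth_fraction(cart, layer, hc, fem_cart_rows, tib_cart_rows)
        sel = cart > 0
        true_t2[sel] = t2_deep + (t2_sup - t2_deep) * frac[sel]
        true_s0[sel] = 0.5 * (s0_cd + s0_cs)
    else:
        true_t2[layer == LAYER_DEEP] = t2_deep
        true_s0[layer == LAYER_DEEP] = s0_cd
        true_t2[layer == LAYER_SUPERFICIAL] = t2_sup
        true_s0[layer == LAYER_SUPERFICIAL] = s0_cs

    # synovial fluid pockets tangent to the femoral cartilage surface
    s0_fl, t2_fl = spec.tissue_params["fluid"]
    placed = 0
    attempts = 0
    while placed < spec.fluid_pockets and attempts < 50 * max(1, spec.fluid_pockets):
        attempts += 1
        s = int(rng.integers(s_lo, s_hi))
        if s == boundary_slice:
            continue
        c = int(rng.integers(cart_lo + 2, cart_hi - 2))
        r0 = fem_cart_rows[1]  # just below femoral cartilage surface (joint space)
        rr = slice(r0, min(r0 + 2, R))
        cc = slice(c - 1, c + 2)
        region = (slice(s, min(s + 1, S)), rr, cc)
        if (cart[region] > 0).any() or (bone[region] > 0).any():
            continue
        true_t2[region] = t2_fl
        true_s0[region] = s0_fl
        placed += 1

    # forward signal + Rician noise
    te = np.asarray(spec.echo_times_ms, dtype=float)
    signal = true_s0[None] * np.exp(-te[:, None, None, None] / true_t2[None])
    if spec.noise_sigma > 0:
        n1 = rng.normal(0.0, spec.noise_sigma, signal.shape)
        n2 = rng.normal(0.0, spec.noise_sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)

    volume = MESEVolume(signal, spec.spacing_mm, tuple(te), spec.repetition_time_ms)
    bone_mask = LabelMask(bone, dict(BONE_LABELS), spec.spacing_mm)
    cart_mask = LabelMask(cart, dict(PLATE_LABELS), spec.spacing_mm)

    t2_field = T2Map(t2_ms=true_t2.copy(), s0=true_s0.copy(), valid=cart > 0)
    part = LayerPartition(layer=layer.copy(), depth_fraction=np.where(
        cart > 0, (layer == LAYER_SUPERFICIAL).astype(float), np.nan))
    true_regional = _t2.aggregate(t2_field, part, cart_mask)

    truth = PhantomTruth(
        bone_mask=bone_mask,
        cartilage_mask=cart_mask,
        layer_mask=layer,
        true_t2=true_t2,
        true_regional=true_regional,
        lateral_side="high",
        ml_boundary_slice=boundary_slice,
    )
    return volume, truth


def _geometric_depth_fraction(cart, layer, hc, fem_rows, tib_rows):
    """Linear 0..1 ramp from the bone interface to the articular surface."""
    S, R, C = cart.shape
    frac = np.zeros((S, R, C))
    rows = np.arange(R)[None, :, None] * np.ones((S, 1, C))
    tib = (cart > 0) & (rows >= tib_rows[0]) & (rows < tib_rows[1])
    fem = (cart > 0) & (rows >= fem_rows[0]) & (rows < fem_rows[1])
    # tibial: bone below (high rows) -> depth 1 at low rows
    frac[tib] = (tib_rows[1] - 1 - rows[tib] + 0.5) / hc
    # femoral: bone above (low rows) -> depth 1 at high rows
    frac[fem] = (rows[fem] - fem_rows[0] + 0.5) / hc
    return np.clip(frac, 0.0, 1.0)
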