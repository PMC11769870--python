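# Methods

## Signal model and T2 fitting

Each voxel of a multi-echo spin-echo (MESE) acquisition is modelled as a
mono-exponential decay `S(TE) = S0 · exp(−TE/T2)` over the echo train
(default TE = 10, 20, …, 70 ms, TR = 2700 ms).  The fit is a two-parameter
nonlinear least squares per voxel: a log-linear regression of `log S` on TE
provides the starting point, refined by a damped (Levenberg-style)
Gauss–Newton iteration vectorised over all masked voxels.  A voxel is
*valid* when the iteration converged, `S0 > 0`, and `0 < T2 ≤ t2_cap`.

Tunable parameters:

- `t2_cap` (default **100 ms**): physiological upper bound; voxels above it
  (synovial fluid, partial-volume mixtures; fluid T2 is an order of
  magnitude longer than cartilage) are excluded from every aggregate rather
  than clamped.  Flat, non-decaying signals are likewise invalid.
- `drop_first_echo` (default **off**): some T2 methodologies discard TE₁
  because of stimulated-echo contamination; the default fits all echoes, and
  the switch isolates this choice behind one flag.

All echoes fitting by full nonlinear least squares (rather than plain
log-linear regression) was chosen because it is exact on noise-free data and
less biased under Rician noise at low signal; the log-linear estimate is
retained as the initialiser.

## Laminar partition

Cartilage T2 rises from the bone interface to the articular surface, so each
plate is split into its deep and superficial 50%.  Per sagittal slice (2D,
physical millimetres — the ~3.5 mm slice spacing would dominate any 3D
distance given 0.31 mm in-plane resolution), the cartilage boundary is
divided into a bone-interface set (boundary voxels 4-adjacent to bone) and a
surface set (boundary voxels 4-adjacent to non-bone exterior).  Each
cartilage voxel receives `depth = d_bone / (d_bone + d_surface)` from
Euclidean distance transforms to the two sets; the degenerate
single-voxel-thick case (0/0) is defined as 0.5, and `depth ≥ 0.5` is
superficial (the tie goes to the superficial layer, reading "top 50%" as
inclusive).  Cartilage components with no bone adjacency get undefined depth
and are excluded from laminar aggregates.  Voxels on the volume border are
not treated as boundary by themselves, so a band spanning the full grid
width has no spurious lateral "surface".

Regional aggregation uses the arithmetic mean of valid voxel T2 per
(plate, layer); compartments are **unweighted means of plate values**:
MFTC = (MT + cMF)/2, LFTC = (LT + cLF)/2, FTJ = mean of the four plates.
Empty cells propagate as missing (NaN), never as 0.

## Segmentation networks

The segmenter is a classic 2D U-Net: per level two 3×3 convolutions + ReLU,
channel doubling, 2×2 max-pooling; the decoder mirrors the encoder with 2×2
transposed convolutions and skip concatenations; a 1×1 convolution and
per-voxel softmax produce class probabilities.  Defaults: 4 levels, 32 base
filters (16 at desk scale).  Inputs are standardised per volume and channel
to zero mean/unit variance.  Bones and cartilage are separate models; the
bone network (labels femur/tibia/fibula, loss weights 0.25/0.25/0.3,
background 0.2) supplies landmarks, the cartilage network (tibial/femoral,
0.4/0.4, background 0.2) supplies the tissue of interest.  The all-echo
variant consumes 7 input channels; the first-echo variant 1.

Training minimises the weighted cross-entropy (probabilities clamped at
1e-7) with Adam at an initial learning rate of 0.01 on mini-batches of 4
slices, drawn from all sagittal slices in a per-epoch shuffled order, for a
fixed number of epochs without early stopping (50 by default, 10 at desk
scale); the retained checkpoint maximises the mean validation Dice,
computed as the unweighted mean of per-label foreground Dice averaged over
validation volumes (the averaging convention was an open choice).  Weights
are initialised with a variance-scaling (He) scheme.  No augmentation is
applied.  Because no deep-learning framework is part of the dependency set,
the forward pass, the backward pass (im2col convolutions; input gradients as
convolutions with flipped kernels) and Adam are implemented in NumPy and are
verified against central finite differences in the test suite; training is
deterministic given the config seed.

## Post-processing and landmarks

Raw per-label masks are cleaned by (1) filling background regions fully
enclosed within a slice (any hole size by default; `--max-hole-voxels`
bounds it), (2) keeping only the largest 3D connected component
(26-connectivity) per label, and (3) shaving in-plane voxels with at most
one 4-neighbour inside the label — the tips of one-voxel-wide protrusions.
A plain 3×3 opening would annihilate two-voxel-thick cartilage bands, which
are the norm at desk resolution, hence the milder spike operator.  The
fill/component/shave pass iterates to a fixpoint across all labels (labels
interact: removing one label's fragment can expose another label's hole), so
the operation is idempotent.

Landmarks come from the bone segmentation: the fibula centroid fixes which
end of the slice axis is lateral (fallback when the fibula is missing: the
side with the larger tibial cross-section, flagged low-confidence); the
medial/lateral boundary is the slice of minimal femoral cross-sectional area
between the two condylar maxima (intercondylar notch).  Tibial cartilage is
partitioned exactly at that slice into MT/LT; femoral cartilage is split the
same way and then restricted to the central weight-bearing region of
interest, defined per slice as the anterior–posterior extent covered by the
tibia — a deliberately simple proxy for the condylar ROI, isolated in one
function so it can be swapped for a different construction.

## Agreement and statistics

Boundary voxels are labelled voxels with a 6-connected neighbour outside the
label; Hausdorff (true maximum) and average symmetric surface distances are
measured between boundary voxel centres in millimetres with anisotropic
spacing; DSC and VOE are voxel-count ratios, with identical inputs scoring
perfectly by convention (empty/empty: DSC 1, VOE 0).  DSC ≥ 0.80 is reported
as "high agreement".

Paired comparisons use the t-test on differences with Cohen's
*D* = mean(diff)/SD(diff) — the convention consistent with the paired test;
unpaired comparisons default to the pooled-variance Student t (Welch by
flag) with *D* = mean difference / pooled SD.  Confidence intervals for *D*
use the normal approximation (SE² = 1/n + D²/2n paired;
(n₁+n₂)/(n₁n₂) + D²/2(n₁+n₂) unpaired), which reproduces published
intervals; an exact noncentral-t interval is available as an option.
Bland–Altman reports bias and bias ± 1.96·SD limits of agreement plus the
per-pair (mean, diff) table.  Case–control matching is greedy 1:1 — exact on
sex and pain frequency, nearest age within ±5 years, ties broken by nearest
BMI within ±5 kg/m², each control used once, case order seed-shuffled —
because the matching criteria, not the algorithm, are what the design
specifies; unmatched cases are reported, not fatal.

## Phantom

The phantom emulates a sagittal knee MESE acquisition on a regular grid
(default 20×96×96 voxels at (3.5, 0.31, 0.31) mm — 3 mm slices plus 0.5 mm
gap; desk-scale 8×64×64): a femoral slab whose cross-sectional area dips to
a unique minimum at the intercondylar waist between two condylar maxima, a
tibial slab, a small lateral fibula blob, and 4-voxel-thick cartilage bands
on each bone split into the four plates across the slice axis, with the
waist slice left bare (notch).  The joint spans the full anterior–posterior
extent so the cartilage bands have no free in-plane ends and the geometric
deep/superficial labels (exact 50/50 per plate) coincide with the
distance-based partition.  Tissue defaults (S0, T2 ms): cartilage deep
(100, 38), superficial (100, 48) — or a linear depth ramp between them —
muscle-like surround (50, 30), bone (15, 8), synovial fluid (140, 300).
Optional fluid pockets sit in the joint space tangent to the femoral
cartilage surface, emulating the first-echo confusion between fluid and
cartilage.  Rician noise `sqrt((S+n₁)² + n₂²)` with constant σ across echoes
(the standard magnitude-noise model) is applied with a seeded generator;
σ = 3 on cartilage S0 = 100 (first-echo SNR ≈ 25–30) is the default, chosen
once as a realistic mid-range level since the source acquisitions' SNR is
not documented.  Volumes are bit-identical for identical spec + seed.

What the phantom does **not** emulate: realistic anatomy and curvature,
B1/stimulated-echo artifacts, multi-coil noise correlation, partial-volume
mixing, or inter-subject anatomical variability.  Passing tests therefore
demonstrate the correctness of the algorithmic chain and its statistical
machinery under the stated signal model — not segmentation performance on
clinical images.

## Problem sizes

The desk-scale study trains the 7-channel cartilage U-Net (16 base filters,
10 epochs, mini-batch 4) on 8 phantoms with 2 for validation checkpointing
and 2 held out, at 8×64×64 with σ = 3 — about a minute on one CPU, reaching
held-out cartilage Dice well above the 0.80 high-agreement mark.  The group
effect recovery suites use cohorts of 8 + 8 phantoms with per-phantom
superficial T2 drawn from N(48 + effect, 1) and an injected effect of
+1.8 ms, matching the magnitude of the superficial-layer difference the
method is meant to detect.

## Known limitations

- The central femoral ROI (tibial coverage per slice) is a stand-in for the
  original condylar landmark construction.
- The greedy matcher does not guarantee maximum-cardinality matching in
  adversarial cohorts (it attains it on the tested ones).
- Training at clinical resolution/epoch counts is possible but slow in pure
  NumPy; the defaults target desk-scale reproduction, not GPU-scale runs.
- The Rician noise level is a free parameter, not calibrated to any scanner.
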