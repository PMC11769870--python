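# lamt2 — automated laminar cartilage T2 analysis for MESE knee MRI

Cartilage transverse relaxation time (T2) reflects cartilage hydration and
collagen integrity and changes early in knee osteoarthritis, before
radiographic damage.  Measuring it requires segmenting the femorotibial
cartilage plates on every slice of a multi-echo spin-echo (MESE) acquisition
— a task traditionally done by expert readers at great cost.  `lamt2`
implements a fully automated alternative aimed at imaging scientists and
osteoarthritis researchers:

1. **Segmentation** — trainable 2D U-Nets for bones (femur/tibia/fibula) and
   femorotibial cartilage, in an all-echo (7-channel) and a first-echo
   (1-channel) variant, trained with weighted cross-entropy and Adam and
   checkpointed at the best validation Dice.  The network, its backward pass
   and the optimiser are implemented in NumPy.
2. **Anatomical post-processing** — hole filling, largest-component
   selection and spike smoothing; landmarks derived from the bone masks
   (fibula → lateral side, intercondylar notch → medial/lateral boundary)
   split the cartilage into the four plates MT, cMF, LT and cLF, with the
   central (weight-bearing) femoral region defined by tibial coverage.
3. **Relaxometry** — voxelwise mono-exponential fit `S(TE) = S0·exp(−TE/T2)`
   (log-linear initialisation + damped Gauss–Newton), laminar partition into
   the deep and superficial 50% by normalised bone–surface distance, and
   regional means with the compartment aggregates
   MFTC = (MT+cMF)/2, LFTC = (LT+cLF)/2, FTJ = mean of all four plates.
4. **Validation statistics** — Dice, Hausdorff, average symmetric surface
   distance and volume overlap error; paired/unpaired t-tests with Cohen's
   *D* and its confidence interval; Pearson correlation; Bland–Altman limits
   of agreement; greedy 1:1 case–control matching with calipers.

Because real cohort MRIs cannot ship with the package, a **phantom module**
generates synthetic MESE knees (mono-exponential decay per tissue,
depth-dependent cartilage T2, Rician magnitude noise, optional synovial
fluid pockets) with exact ground-truth masks, layer labels and regional T2,
so the entire chain is testable end to end.

## Worked example

```sh
lamt2 phantom --seed 3 --out p0
lamt2 plates --cartilage p0/cartilage.nii.gz --cartilage-labels p0/cartilage_labels.json \
             --bones p0/bones.nii.gz --bone-labels p0/bones_labels.json --out plates.nii.gz
lamt2 t2 --volume p0/mese.nii.gz --sidecar p0/mese.json \
         --plates plates.nii.gz --plate-labels plates.nii.gz.labels.json \
         --bones p0/bones.nii.gz --bone-labels p0/bones_labels.json --out regional.csv
head -5 regional.csv
```

prints

```
region,layer,mean_t2_ms,n_voxels
MT,deep,38.350662977257606,1728
MT,superficial,48.45180278360484,1728
cMF,deep,38.32848493583941,1728
cMF,superficial,48.30830271382812,1728
```

The phantom's true layer T2 is 38 ms (deep) and 48 ms (superficial); the
small positive offset (~0.3–0.5 ms) is the expected Rician-noise bias of the
magnitude-signal fit at the default noise level (σ = 3 on S0 = 100).  With
`noise_sigma: 0` in a `--spec` file the fit recovers 38/48 exactly.  The same
workflow is available as library calls (`lamt2.pipeline.run_case`), and
`lamt2 train` / `lamt2 segment` train and apply the U-Nets so the full
automated path — network segmentation instead of reference masks — can be
exercised on phantom cohorts.

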