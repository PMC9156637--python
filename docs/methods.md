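# Methods

This note records the model, the synthetic data, the numerical choices and
the open design points of the package, in enough detail that a maintainer
can judge what a passing test suite does and does not establish.

## Phantoms: what they emulate and what they do not

Each phantom is a 48×64×64 voxel grid at (1, 4, 4) mm spacing — a 1-mm
slice increment so slabs of 1–11 mm are meaningful, and an in-plane matrix
that feeds the 64-pixel test-scale model directly. The geometry is an
elliptic-cylinder soft-tissue body (+40 HU) in air (−1000 HU), two
ellipsoidal lungs of noisy parenchyma (−850 ± 40 HU), bright tilted
cylindrical vessels (+50 HU, radius 5 mm) whose in-plane position drifts
1–3 mm per mm of depth, and, for emphysema phantoms, spherical lesions of
−980 ± 10 HU (default three lesions of 12 mm radius). Global scan noise of
20 HU is added and HU are quantised to integers, so identical specs and
seeds give bit-identical volumes and file round-trips are exact.

Consequences of these defaults: normal phantoms carry ≈1.2 %LAA (the
Gaussian tail of parenchyma below −950 HU) and lesion phantoms ≈5.5–8 %LAA,
so the densitometric 5% cutoff separates the classes; lesions sit
unambiguously below −950 HU while parenchyma sits above it; and the tilted
vessels give minIP something real to suppress. What the phantoms do *not*
emulate: reconstruction-kernel noise correlation (phantom noise is white),
anatomical texture, airways, fissures, lobe boundaries, or the diffuse,
multi-focal appearance of real emphysema. Passing tests therefore
demonstrate that the pipeline recovers localized low-attenuation anomalies
under controlled conditions — not clinical-grade performance.

## Windowing

Model inputs are windowed to (−1000, −600) HU and mapped affinely to
[−1, 1]. This is a lung window: parenchyma sits mid-range, lesions near
−1, and everything brighter than −600 HU (vessels, chest wall) clips flat
at +1. An earlier candidate window of (−1000, 400) HU left vessels and
body in-range; their reconstruction errors then dominated the residual
tail and drowned the lesion signal. Clipping them flat removes that error
source by construction and spends the entire dynamic range on the
attenuation interval where emphysema lives. The wide window remains
available (`FULL_WINDOW_HU`) for rendering.

## minIP convention

Slabs are centred and stride-1: output slice *i* is the minimum over
slices [i−(k−1)/2, i+(k−1)/2], clamped at volume edges (no padding value
is neutral for a minimum). k is the largest odd slice count whose span
does not exceed the requested thickness, never below 1. Centred stride-1
slabs keep slice indexing aligned with per-slice ground truth; whether
slabs overlap and how edges are handled is a convention of this package,
not a property inherited from the screening protocol it follows.

## Architecture and training at test scale

Layer counts scale with image size: log2(size) − 1 down-sampling steps, so
512-pixel inputs give the full 8-encoder + 8-decoder generator and
8-layer discriminator, while the 64-pixel test scale uses 5+5 and 5. Both
networks use 4×4 kernels, stride 2, batch norm (none on the first layer),
leaky ReLU (slope 0.2), a tanh output for the generator and a single-logit
head for the discriminator. Optimisation is Adam (lr 2e-4, β₁ = 0.5),
batch 32, 30 epochs at test scale; discriminator-input augmentation
(horizontal flip, ±size/8 translation, cutout) is applied with probability
0.3 per batch, identically to the real and generated image so the
discriminator cannot key on augmentation artifacts.

**Skip connections.** The generator supports U-Net skip connections with
dropout (`skip_levels`; `None` = every level reproduces the full-scale
layout). At the 64-pixel test scale the default is `skip_levels=0`:
measured during development, *any* informative skip level — even 8×8
feature maps — lets the decoder copy a 6-pixel lesion into the
reconstruction, which collapses the residual signal the anomaly score
depends on (and the collapse worsens the longer one trains). At full
512-pixel scale with large, diffuse real lesions this trade-off may differ;
the machinery is there to re-enable skips, but the test-scale default
favours a strict information bottleneck.

## Anomaly scoring

The raw score combines two standardised terms,
raw = 0.9·z(contextual) + 0.1·z(latent):

* **contextual** — mean of max(0, (X′ − X) − τ) over the *eroded* lung
  mask (2 erosion iterations). Three deliberate choices: the signed
  residual, because emphysema makes the input darker than the
  reconstruction while vessel misplacement errs in the opposite
  direction; the threshold τ (95th percentile of signed residuals in
  normal calibration lungs), because sub-threshold noise residual would
  otherwise dilute a small lesion's contribution to the mean; and the
  eroded mask, because segmentation-boundary pixels carry edge residuals
  unrelated to disease. A slab whose eroded lung is empty (extreme
  apex/base) has no reliable parenchyma and scores 0.
* **latent** — mean squared difference of the discriminator's
  last-convolution feature maps of X and X′.

Both are z-scored against the normal calibration set (training normals)
so the 0.9/0.1 weighting is scale-free. Scored sets are min–max
normalised into [0, 1]; a single slice scored without a calibrated range
falls back to a sigmoid squashing (documented, ordering-preserving).
Without lung masks the contextual term degrades gracefully to the plain
whole-slice L1.

## Detection maps

Candidate regions are (residual > τ) ∧ eroded-lung, with connected
components under 5 pixels (at 64-px scale, scaled quadratically) removed.
The binarisation residual is the emphysema-direction (X′ − X)₊ with τ at
the 95th percentile of normal-lung values — the published protocol names
no binarisation rule, so this package adopts the same one-sided logic as
the scorer. `residual_map` itself returns the symmetric |X − X′| for
inspection. Overlays tint candidate pixels green on the grayscale input
and are pure rendering.

## Screening and evaluation protocol

Slices are sampled evenly (rounded linear spacing, endpoints included)
over the lung span; the participant is positive iff any slice score
reaches the operating threshold, chosen by Youden's J on the validation
split (ties toward sensitivity). The experiment runner trains one model
per slab thickness on 80% of normals, validates on the held-out normals
plus all emphysema participants, reports AUC with a percentile bootstrap
CI (1,000 iterations; single-class resamples redrawn), sensitivity,
specificity, F1, FN/FP, and compares the top two thicknesses with
McNemar's test (exact binomial below 25 discordant pairs, else
continuity-corrected chi-square).

## Benchmark problem sizes

The acceptance benchmark trains on 10 slices from each of 60 normal
phantoms (600 slices/epoch, 30 epochs) and evaluates 400 slices from
20 normal + 20 emphysema held-out phantoms, at 1-mm and 11-mm slabs,
repeated over three seeds. These sizes keep a full from-scratch run in
the tens of minutes on one CPU core while leaving the class-separation
measurements stable across seeds.

Two slice-level label conventions are reported side by side, because they
measure different things. Against exact slab-window truth (lesion voxels
anywhere in the projected window — available only because phantoms have
voxel ground truth), thin slabs score *higher*: phantom noise is white,
so a 1-mm slab is an unrealistically clean view of a high-contrast lesion.
Against participant labels (every slice of a diseased participant counts
positive — the only label real screening cohorts provide), thick slabs
win consistently: an 11-mm minimum spreads each lesion across more
sampled slices, so fewer positive-labelled slices are genuinely
lesion-free. The thick-beats-thin comparison is therefore made under
participant labels, which is also the mechanism by which thicker slabs
help the participant-level screen.

## Numerical and implementation notes

* The conv-net engine is pure numpy in float32; conv/transposed-conv are
  exact adjoints via im2col/col2im, verified against central finite
  differences (float64) in the tests, so training failures cannot hide in
  gradient bugs.
* Determinism: every stochastic step (phantom noise, weight init, batch
  shuffling, augmentation, dropout, bootstrap) draws from generators
  seeded by the configuration; per-participant and per-thickness seeds
  derive from the master seed via `SeedSequence`.
* Batch norm keeps running statistics (momentum 0.1); scoring runs in
  eval mode. Batches of fewer than 2 samples are skipped during training.
* %LAA uses strict `<` at −950 HU; the 5% categorisation boundary maps
  5.0% to non-emphysema.
* Lung segmentation: threshold −320 HU, border-connected components
  removed, two largest components kept, 3³ closing and hole filling.
  On phantoms it reaches Dice ≥ 0.95 against truth; it has no notion of
  airways or lobes.
* Rounding for comparison against printed 2-decimal metrics is half away
  from zero.

## Known limitations

* Test-scale results do not transfer claims to 512-pixel clinical data;
  in particular the skip-connection default and the thin-slab advantage
  under slab-truth labels are properties of the phantom regime.
* The discriminator probability is exposed (`discriminator_prob`) but not
  used in the default score; reconstruction+latent scoring was the more
  stable choice on small data.
* The screening threshold is chosen on the same validation split the
  metrics are reported on, mirroring a protocol that reports an operating
  point without naming a third split; with real data one would nest this.
* Lesion placement rejects lesions that do not fit inside a lung after
  200 attempts rather than shrinking them; specs requesting many large
  lesions can fail loudly.
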