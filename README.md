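# minipae

Unsupervised emphysema screening for low-dose chest CT, built around
**minimum intensity projection (minIP)** as a disease-specific input
augmentation and an **adversarial auto-encoder** trained only on scans
without emphysema.

## Who this is for

Researchers working on emphysema quantification or anomaly detection in
lung-cancer-screening CT who need a fully testable reference pipeline:
every stage — from volume I/O to the final bootstrap statistics — runs on
synthetic chest-CT phantoms with exact ground truth, so no clinical data
are required to develop against or to verify the implementation.

## The method

Emphysema destroys parenchyma and appears as abnormally low attenuation
(below −950 HU, vs roughly −850 HU for normally aerated lung). The
pipeline exploits this in four stages:

1. **minIP slabs.** Each axial slice *i* is replaced by the voxelwise
   minimum over a centred window of *k* slices, where *k* is the largest
   odd number of slices fitting the requested slab thickness (1–11 mm in
   2-mm steps by default). Minima preserve low-attenuation lesions while
   suppressing bright vessels whose in-plane position drifts with depth.
2. **Adversarial auto-encoder.** A fully convolutional encoder–decoder
   generator (4×4 kernels, stride 2, batch norm + leaky ReLU) reconstructs
   windowed minIP slices; a mirrored convolutional discriminator judges
   real vs reconstructed. Training minimises three losses on slices from
   *non-emphysema participants only*:
   L_total = w_c·‖X − X′‖₁ + w_l·‖f(X) − f(X′)‖₂² + w_a·BCE(D(X′), 1),
   with weights (50, 1, 1), where f(·) are the discriminator's
   last-convolution feature maps. Because the model never sees emphysema,
   low-attenuation lesions reconstruct poorly at inference.
3. **Anomaly score.** raw = w_r·contextual + (1−w_r)·latent with
   w_r = 0.9, both terms standardised against a normal calibration set;
   scored sets are min–max normalised into [0, 1]. Residual detection
   maps — the emphysema-direction residual (X′ − X)₊ thresholded inside
   the lungs — localise what was flagged.
4. **Screening rule.** n slices are sampled evenly over the lung height;
   a participant is negative only if *every* slice is below threshold
   (equivalently, the participant score is the max slice score). Reports
   include ROC-AUC with 1,000-iteration bootstrap CIs, sensitivity,
   specificity, F1, McNemar's paired test between slab settings and
   Cohen's kappa between categorisations.

The package also implements the standard densitometric measure, **%LAA**
(percentage of lung voxels strictly below −950 HU, emphysema if > 5%),
with automatic threshold-and-morphology lung segmentation.

## Worked example

```sh
python examples/04_train_and_score.py
```

trains on minIP-11 slices of 12 normal phantoms (10 epochs) and scores 6
held-out phantoms:

```
 participant      label  mean score  max score
       P0000     normal        0.13       1.00
       P0001     normal       -0.10       1.39
       P0002     normal        0.12       1.48
       P0003  emphysema        6.64      10.98
       P0004  emphysema        7.66      12.13
       P0005  emphysema        8.62      14.31
```

Scores are standardised against the normal calibration slices, so values
near 0 mean "typical healthy lung" and large positives mean the
reconstruction could not explain dark lung content — the emphysema
signature. The other `examples/` scripts cover phantom generation, slab
projection, densitometry, detection-map overlays and the evaluation
statistics, each printing a short interpretation of its output.

A thin CLI wraps the same functions: `minipae phantom`, `minipae minip`,
`minipae laa`, `minipae run-experiment` (see `minipae --help`).

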