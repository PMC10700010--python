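# Methods

This note records the models implemented in `softspot`, their assumptions,
the parameter defaults that matter, and the design choices made where the
design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Synthetic fruit images

A fruit photographed apex-side-up on a black background is emulated as a
shaded disk: base colour (default RGB (0.85, 0.55, 0.20)) with a radial
quadratic brightness falloff, per-fruit multiplicative colour jitter
(sd 0.03 per channel), additive pixel noise (sd 0.01), and a near-black
background (0.02). The disk preserves the only geometry the downstream
analysis uses — an outer contour and a normalized distance from it — and
nothing else; no calyx, no 3-D shape, no photographic texture.

Class information is carried exclusively by planted blemishes: soft
quadratic-profile colour offsets (direction (0.3, 1.0, 0.8), i.e. a
brownish darkening) at radial positions drawn from a configurable mixture
over normalized contour distance *d*. The default placement is an equal
mixture of the apex band *d* ∈ [0.75, 1] and the peripheral band
*d* ∈ [0, 0.1]. Negatives receive no blemish, so at blemish amplitude 0
the two classes are draws from the same distribution — a property the test
suite checks and the degenerate case any classifier must fail on.

Two **amplitude regimes** are used deliberately:

* the default amplitude **0.05** models the motivating situation — a
  premonitory symptom hard to see by eye and, at this desk scale (tens of
  training images, a few dozen epochs), essentially unlearnable;
* the **separable regime (amplitude 0.25–0.3)** is used wherever a test or
  demonstration needs a trainable classifier: the blemish is well above the
  pixel-noise floor while still being a small local feature. End-to-end
  localisation checks and the pipeline default run in this regime.

At desk scale, apically planted blemishes are markedly easier to learn than
peripheral ones (whose disks are clipped by the contour and whose relevance
smears across a thin band); the pipeline's demo default therefore plants
apically, while the end-to-end tests exercise both bands and require only
the band *flip* — not high AUC — for the peripheral condition.

Camera profiles are per-channel affine gains (gain × white-balance) applied
after scene noise, so two "cameras" photographing the same fruit differ by
an exact known affine transform up to clipping — the simplest model of the
two-camera acquisition the design calls for, and one the tests can invert.

Images are rendered directly at the classifier's input size (default
224 px; 96 px in the desk-scale end-to-end runs) rather than at high
resolution plus a resize, since only the resized image is ever consumed.

## Classifier

A small VGG-style stack — default block widths (8, 16, 32, 32), each block
one 3×3 convolution + ReLU + 2×2 max-pool, then a dense embedding layer and
a two-way softmax — implemented, with its backward passes, in NumPy inside
the package. Training from scratch follows the stated protocol: SGD at
learning rate 0.001 (plus classical momentum 0.9, a free choice), weighted
categorical cross-entropy, 20–100 epochs, stratified 3:1 train/validation
split, flip/±3 px-shift augmentation. Class weights default to
n/(2·n_c). The decision threshold is 0.5 with ties called positive. Seeds
control initialisation, splitting and augmentation independently.

Two named layers, `conv_last` (deepest) and `conv_shallow` (one block up,
double the spatial resolution), anchor the saliency-layer contrast.

## Saliency

* **Grad-CAM** at layer *l*: channel weights are spatial means of
  ∂(class logit)/∂(feature map); the map is the ReLU of the weighted channel
  sum, computed at the layer's native grid, bilinearly upsampled to the
  image, and max-normalised to [0, 1]. The pre-softmax logit is used as the
  class score; the target class is always "positive" for the sampling
  analyses.
* **Guided backpropagation**: the input gradient with every ReLU backward
  pass zeroed where the forward activation or the incoming gradient is
  negative; reduced per pixel as the max absolute channel gradient (the
  channel reduction is unstated in the literature's common usage; max is
  conservative about washing out single-channel evidence).
* **Guided Grad-CAM**: elementwise product of the two, max-normalised.

Per-image max normalisation (rather than cohort-level) is a choice: it
makes every fruit contribute comparable relevance mass to the pooled
histogram regardless of its absolute gradient scale.

## Relevance geometry

Fruit segmentation is a luminance threshold (default 0.1) followed by
morphological closing, hole filling and largest-component selection — valid
precisely because the scene guarantees a dark background. The normalized
contour distance is the Euclidean distance transform divided by its
per-fruit maximum, so *d* = 0 on the contour and *d* = 1 at the deepest
interior pixel (the centre, for a disk). Geodesic distance would coincide
with Euclidean for convex fruit.

**H(r, d)** pools all in-mask pixels of a cohort into a 20 × 20 histogram
on [0, 1]²; final bins are right-inclusive so r = 1 and d = 1 are counted.
The band summary reports high-relevance mass (default r ≥ 0.8) in the
bands [0, 0.1], (0.1, 0.75], (0.75, 1.0] — periphery, mid, apex — whose
edges align exactly with the default binning.

Sampling windows are fully-interior squares found by summed-area-table
scans (exact, and checked against brute force): the featured window
maximises mean relevance (ties to smallest row, then column); the
non-featured window minimises it subject to a centre separation of at
least 2 window sides (default). The default window side is 0.14 × image
side ≈ 32 px at 224 px, roughly a 10 mm face on a ~7 cm fruit.

## Synthetic transcriptome

Counts are NB: gene lengths log-normal (median ≈ 1.5 kb), relative
abundances length-weighted and normalised per sample to a simplex, expected
counts = library size × abundance, library sizes uniform in 5–15 M reads,
per-gene dispersions Gamma(2, 0.1) (mean 0.2; dispersion ranges are not
observable from the motivating design, so this is an assumption typical of
bulk RNA-seq). The recorded `library_size` is the realised column sum.

Planted structure, all multiplicative on the log2 scale:

* criteria-(i) DEGs (default 5 % up + 5 % down, |log2FC| = 2) expressed
  only in a *responder* half of the RS fruits and in one mislabeled control
  fruit — reproducing, respectively, the half-consistent heat-map pattern
  and the known control-that-behaves-like-a-positive failure mode of
  imperfect prediction;
* criteria-(ii) DEGs (a disjoint 5 % + 5 %, |log2FC| = 2) present in RS-F
  (featured) samples only, absent in the paired RS-NF sample;
* a per-fruit, per-gene random effect (sd 0.5 log2 units; 1.0 in the
  power-comparison scenarios) shared by both samples of a fruit — exactly
  the component a paired analysis cancels, and the reason the paired test
  dominates the unpaired one on this design.

What the generator does **not** emulate: compositional normalisation
artefacts beyond simplex renormalisation, GC/length biases, batch effects,
count outliers, or correlated gene modules. Passing tests therefore
establish correctness of the statistical machinery under the stated model,
not robustness to everything real libraries exhibit.

## Differential expression

Per-gene NB log-linear models with a log library-size offset are fitted by
IRLS, vectorised across genes (coefficients agree with per-gene
`statsmodels` NB GLM fits to ~1e-6; the test suite checks this). Designs:
intercept + group for criteria (i); intercept + fruit blocks + region for
criteria (ii), requiring ≥ 3 complete pairs.

Dispersion is estimated per gene from full-model Pearson residuals
(a moment estimator scaled by S/(S−p)), then shrunk toward a trend
α(μ) = a₀ + a₁/μ fitted across genes, with 20 prior degrees of freedom.
Significance is a **quasi-likelihood moderated F test**: the deviance drop
for the tested coefficient is scaled by a per-gene quasi-dispersion
(full-model deviance / residual df, shrunk toward 1 with 10 prior df) and
referred to F(1, prior + residual df). An unscaled chi-square LRT is
anticonservative at these sample sizes because it ignores dispersion-
estimation error; the moderation restores type-I control (verified on
10 000-gene null simulations in the acceptance suite). These estimators
are the package's own, deliberately simpler than DESeq2's or edgeR's;
correctness is established by calibration and planted-truth recovery, not
by numeric identity with those packages.

Filtering retains genes with mean RPKM strictly above 1 in at least one of
the two compared groups. Fold changes always have RS-F in the numerator;
BH adjustment is applied within each criteria's tested gene set; the
reporting thresholds are P < 0.05 for criteria (i) and FDR < 0.1 for
criteria (ii). Overlap counts direction-matched genes significant under
both criteria; concordance is the Pearson correlation of log2FCs over the
union of DEGs. PCA operates on gene-centred log2(RPKM + 1) (the pseudocount
is a choice; the transform is otherwise unspecified in the motivating
analysis), with two-sided t-tests on each PC between group pairs.
Enrichment is the upper-tail hypergeometric per gene set with BH across
sets.

## Pipeline

`run_pipeline` chains seven stages — simulate_images, train, ensemble,
explain, regions, simulate_counts, diffexp — writing plain-text artifacts
and a JSON manifest with SHA-256 content hashes. One run seed fans out to
per-stage integer seeds via `SeedSequence.generate_state`, so a rerun with
the same config and seed is bit-identical (asserted in the acceptance
suite). The count simulation is conditioned on the image stages: the
numbers of RS and control fruits equal the numbers of selected
extreme-confidence positives and negatives, and the fruit mapping is
recorded. `report` renders ROC curves, the A-vs-B confidence scatter, the
H(r, d) heat map and the criteria overlap scatter from a completed run.

Desk-scale problem sizes (96 px images, 60 + 60 training fruits per
camera, 40 epochs for the end-to-end checks; 25 epochs in the demo config;
2 000-gene effect simulations, 10 000-gene null simulations) were chosen so
the full suite and the acceptance script each run in minutes on one CPU
while keeping every estimate's Monte-Carlo error well inside the margins
being asserted.

## Known limitations

* The blemish model is an assumption: the real premonitory symptom is
  uncharacterised beyond "colour unevenness", so recovery results speak to
  the pipeline's ability to localise planted evidence, not to persimmon
  biology.
* The CNN is far smaller than production image classifiers; its accuracy
  ceiling on subtle (amplitude ≤ 0.1) blemishes at small sample sizes is
  low, which is why the hard regime is kept as the default data model but
  not used for end-to-end claims.
* The DE machinery assumes a correctly specified NB model with shared
  library-size offsets; it implements no outlier handling or robust
  dispersion estimation.
* Enrichment uses synthetic gene sets; no ontology is shipped.
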