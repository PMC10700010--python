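# softspot

**Explainable-CNN-guided tissue sampling and differential expression for
fruit disorder prediction, on fully synthetic data with known ground truth.**

Some fruit disorders — the motivating case is rapid post-harvest
over-softening in persimmon — are invisible at harvest even to experts, yet
a CNN trained on ordinary RGB photographs can predict which fruits will
succumb. If the classifier can predict the fate, its evidence must live
somewhere on the fruit surface: saliency methods can localise those
*premonitory* regions, and tissue sampled from them can be profiled by
RNA-seq to ask what is physiologically different there, before any visible
symptom exists.

`softspot` implements that whole loop as a tested, reusable pipeline,
exercised end-to-end on synthetic images and synthetic counts where the
ground truth is planted and therefore checkable:

1. **Synthetic fruit images** — shaded disks on a black background, two
   camera profiles, and class-discriminative colour blemishes planted at a
   controlled normalized contour distance *d* (apex, *d* ∈ [0.75, 1], or
   periphery, *d* ∈ [0, 0.1]), with pixel-exact truth masks.
2. **CNN classifier** — a small VGG-style network (stacked 3×3 conv +
   max-pool blocks, softmax head) trained from scratch with SGD
   (lr = 0.001), categorical cross-entropy, class weights, and a stratified
   3:1 train/validation split; evaluated by ROC-AUC, accuracy and per-class
   precision at a 0.5 confidence threshold.
3. **Two-model ensemble** — models trained on the two camera datasets are
   AND-combined; a grid search over per-model confidence thresholds
   maximises accuracy subject to a positive-precision floor; the
   extreme-confidence fruits (top-k by min(conf_A, conf_B), bottom-k by
   max(conf_A, conf_B)) are selected for sampling.
4. **Saliency** — from-scratch Grad-CAM, guided backpropagation, and guided
   Grad-CAM at any named convolutional layer. Grad-CAM at layer *l* with
   class score *y^c* and feature maps *A^k* is
   `ReLU(Σ_k α_k A^k)` with `α_k = mean_{ij} ∂y^c/∂A^k_{ij}`,
   upsampled bilinearly and max-normalised; a shallower layer gives a finer
   relevance grid.
5. **Relevance geometry** — fruit segmentation, normalized contour distance
   *d* (Euclidean distance transform over its per-fruit maximum, so the
   contour is 0 and the deepest point 1), the pooled 2-D histogram
   **H(r, d)** of relevance *r* against *d*, and square sampling windows:
   the featured window (RS-F / C-F) maximises mean relevance, the
   non-featured window (RS-NF) minimises it at a minimum separation.
6. **Synthetic transcriptome** — negative-binomial counts for the
   three-group design (10 RS-F, 4 paired RS-NF, 10 C-F by default) with
   planted DEG sets, half-responding positive fruits, one mislabeled
   control, shared within-fruit random effects and gamma-distributed
   dispersions.
7. **Differential expression** — RPKM normalisation with an RPKM > 1
   filter, then per-gene NB log-linear models fitted by vectorised IRLS:
   criteria (i), unpaired RS-F vs C-F; criteria (ii), paired RS-F vs RS-NF
   with fruit as a blocking factor. Significance is a quasi-likelihood
   moderated F test with Benjamini–Hochberg adjustment, plus DEG
   overlap/concordance, PCA with group t-tests, and hypergeometric gene-set
   enrichment.

## Worked example

```bash
softspot run --out runs/demo --seed 11
```

runs every stage at desk scale (96 px images, 120 training fruits per
camera, 40 epochs, 2 000 genes, apically planted blemishes in the
separable regime) and writes `runs/demo/report/report.md`. The run above
printed:

```
- confidence correlation A vs B: r = 0.893
- threshold search: {'accuracy': 0.8, 'feasible': True, 'n_called': 15,
  'positive_precision': 1.0, 't_a': 0.5, 't_b': 0.5}
- H(r,d) pooled over 25 predicted positives, 91028 pixels
- high-relevance mass per d-band: {'apex': 71.0, 'mid': 0.0, 'periphery': 0.0}
- DEGs criteria (i) P<0.05: 128 up / 269 down
- DEGs criteria (ii) FDR<0.1: 90 up / 103 down
- direction-matched common DEGs: 82 up / 94 down; log2FC correlation r = 0.878
- PC1 / PC2 variance fractions: 0.178 / 0.105
```

Reading it: the two camera-specific models (held-out AUC 1.0 and 0.98)
agree on this separable cohort (r = 0.893); AND-filtering keeps positive
precision at 1.0 with 80 % accuracy; all pooled high-relevance mass sits
in the apex band d ∈ [0.75, 1], matching where the blemishes were planted;
both DE criteria recover planted DEG sets of 100 genes per direction
(criteria (i) counts also pick up the region-effect genes, which differ
between RS-F and C-F too), with direction-matched overlap and strong
fold-change concordance (r = 0.878) between the criteria; and PCA shows no
dominant group separation, consistent with effects confined to a minority
of genes.

Every stage is also callable as a library function (`softspot.render_fruit`,
`softspot.train_classifier`, `softspot.guided_grad_cam`,
`softspot.relevance_histogram`, `softspot.de_paired`, ...) or as a
subcommand (`softspot simulate-images`, `explain`, `simulate-counts`, `de`,
`report`).

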