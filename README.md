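# nucseg

Nuclei segmentation for H&E-stained cytological images: color
deconvolution, semantic nuclei-mask generation (patch CNN or intensity
thresholding), morphometric clump detection, conditional-erosion seeding,
seeded-watershed separation, and an object-level Hausdorff/Jaccard
evaluation protocol. A synthetic scene generator with exact ground truth
makes every stage testable without clinical data.

## Pipeline

1. **stains** — Beer–Lambert optical density (`OD = -log10(I/I0)`, base 10
   throughout) and color deconvolution with the ImageJ H&E vectors; per
   patch-position standardization statistics.
2. **semantic** — binary nuclei mask from one of three back-ends:
   * `cnn`: per-pixel 4-class patch classifier (nucleus / nucleus border /
     cytoplasm / background), conv–conv–pool–conv–conv–pool–dense(512)–
     dense(4) with ReLU, SGD, Xavier init and dropout, implemented in
     numpy (no deep-learning framework available at runtime). Border
     pixels are excluded from the mask, which is what keeps touching
     nuclei apart.
   * `otsu`: global Otsu threshold on the hematoxylin image.
   * `adaptive`: local-mean threshold (`mean - offset`).
3. **morphometrics** — 8-connected labeling; area, Crofton perimeter,
   roundness `4*pi*A/P^2`; gates: single nucleus iff area in [309, 7801] px
   and roundness in [0.31, 0.99]; smaller objects are debris, the rest are
   clumps.
4. **seeds** — two-phase conditional erosion per clump: 7×7 octagon while
   component area ≥ T1=350, then 3×3 cross while ≥ T2=50, with per-component
   vanish protection (a component that would disappear keeps its last
   non-empty state).
5. **watershed** — Euclidean distance map, seed imposition by grayscale
   morphological reconstruction (iterated 4-connected geodesic dilation to
   stability), Meyer priority-queue flooding with FIFO tie-breaking, then
   re-gating of the fragments; persistent clumps are rejected.
6. **evaluate** — per-object Hausdorff (full pixel sets) and Jaccard
   distances, greedy nearest-first one-to-one matching under thresholds
   (HD 30 px / JD 0.5), TP/FP/FN counting and per-group summaries.
7. **synth** — elliptical hematoxylin-dominant nuclei on eosin-dominant
   cytoplasm rendered through the same Beer–Lambert model the stain module
   inverts; exact label masks, silhouettes and semantic maps (1-px border
   ring), controllable overlap; clump and patch-corpus generators.

## CLI

```sh
nucseg synth --n-images 5 --nuclei 30 --overlap 0.3 --seed 42 --out scenes/
nucseg separate-stains --input scenes/scene_000.tif --out stains/
nucseg train --train train_dir/ --val val_dir/ --model-out model.npz
nucseg segment --input scenes/scene_000.tif --mask-method otsu \
    --out labels.tif --report report.json
nucseg evaluate --pred labels.tif --ref scenes/scene_000_labels.tif \
    --metric jaccard --out eval.json
nucseg show-se              # print the built-in structuring elements
```

All thresholds (gates, T1/T2, HD/JD, i0, adaptive window) live in one YAML
config (`nucseg.config.PipelineConfig`, `--config cfg.yaml` on the CLI).

## Conventions

* Semantic-map palette: 0 indeterminate, 1 background, 2 cytoplasm,
  3 nucleus, 4 nucleus border (8-bit indexed PNG).
* Stain images: 32-bit float TIFF; label masks: 16-bit TIFF/PNG.
* Patch statistics use the population (1/N) std, floored at 1e-6.
* Argmax ties in prediction resolve in the fixed class order
  nucleus < nucleus_border < cytoplasm < background.
* All randomness flows from explicit seeds; identical inputs + seed give
  bitwise-identical results.
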