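# histomut

Predicting mutation-biomarker status from H&E histopathology images, at
desk scale.

Digitized hematoxylin-and-eosin (H&E) slides carry morphological signatures
of common driver mutations. `histomut` implements the full patch-based
pipeline that turns a whole slide into per-gene mutation probabilities for
eight lung-cancer biomarkers (TP53, EGFR, STK11, POLE, POLD1, PBRM1, DNMT3A,
KRAS):

1. **Tiling** — the annotated tumor region is cut into non-overlapping
   square windows (512×512 at full scale); windows that are more than 75%
   background, or mostly outside the tumor mask, are discarded, and slides
   whose blank + blurred area exceeds a noise-ratio threshold are rejected.
2. **Stain normalization** — pixel colors are modeled as a 3-component
   Gaussian mixture, P(x) = Σₙ Wₙ·N(x | Vₙ, Cₙ), with one component per
   tissue color class (nucleus, cytoplasm, background). The mixture is
   fitted per slide by expectation-maximization on the log-likelihood
   Σₖ ln P(xₖ); each pixel is assigned to its most responsible component
   and mapped onto the matched component of a reference slide by the
   whitening–coloring transform x′ = V_ref + C_ref^{1/2} C_src^{−1/2}(x − V_src).
3. **Classification** — a small residual CNN (3×3 conv stem, identity-
   shortcut residual blocks with batch normalization and ReLU, global
   average pooling, 8 sigmoid outputs) maps each tile to per-biomarker
   probabilities. Tiles inherit their slide's labels (weak supervision);
   training is seeded SGD with momentum under a multi-label binary
   cross-entropy, with twofold slide-level cross-validation and a 4-D
   hyperparameter grid (filter count, block count, batch size, loss).
4. **Aggregation** — a slide's score per biomarker is the mean of its tile
   probabilities; performance is the per-biomarker ROC/AUC over slides
   (AUC = Mann–Whitney concordance, ties ½), and per-pixel probability
   heat maps (red = high, blue = low) are built by scanning windows.

Everything is exercisable without external data: a synthetic-histology
module generates H&E-like slides (disk-union tissue, Poisson-placed
elliptical nuclei, colors drawn from a known mixture) in which mutated
slides differ only morphologically — nucleus density scaled by (1 + δ) —
with full ground truth for every stage.

## Worked example

```python
import numpy as np
from histomut import (SynthParams, generate_dataset, tile_slide,
                      cross_validate)
from histomut.experiments import DESK_NET

params = SynthParams(n_slides=20, effect_size=1.0,
                     signal_biomarker="TP53", seed=1)
slides, labels, _ = generate_dataset(params)
X, sids = [], []
for rec in slides:
    for t in tile_slide(rec, size=64):
        X.append(t.pixels); sids.append(rec.slide_id)
report = cross_validate(np.stack(X), np.asarray(sids), labels,
                        seed=1, **DESK_NET)
print({b: round(a, 2) for b, a in report.mean_auc.items()})
```

prints (seed 1, ~40 s on one CPU):

```
{'TP53': 1.0, 'EGFR': 0.31, 'STK11': 0.5, 'POLE': 0.53, 'POLD1': 0.73,
 'PBRM1': 0.35, 'DNMT3A': 0.57, 'KRAS': 0.47}
```

TP53 — the biomarker whose mutated slides carry doubled nucleus density —
is recovered perfectly at the slide level, while the seven biomarkers whose
labels are independent of morphology scatter around chance (AUC ≈ 0.5).

The same pipeline is available from the shell:

```bash
histomut simulate --n-slides 20 --size 256 --delta 1.0 --seed 1 --out cohort/
histomut tile      --slides cohort/ --size 64 --out tiles/
histomut train     --slides cohort/ --seed 1 --out model.pkl
histomut predict   --checkpoint model.pkl --slides cohort/ --out preds.json
histomut evaluate  --predictions preds.json --labels cohort/labels.csv --out rocs.json
histomut heatmap   --checkpoint model.pkl --slide cohort/S000.png \
                   --mask cohort/S000_mask.png --biomarker TP53 --out hm.png
```

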