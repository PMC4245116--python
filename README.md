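# ricedeficit

Diagnosis of nitrogen, phosphorus and potassium (NPK) deficiency in rice
from flatbed-scanned images of the top three fully expanded leaves and
their sheaths.

Rice shows characteristic macronutrient-deficiency symptoms: N-starved
plants turn light green with tip chlorosis and, under severe stress, a
whitish sheath base; P-starved plants are stunted and "dirty" dark green
with narrow, short leaves and red/purple sheaths (anthocyanin); K-starved
plants develop yellowish-brown leaf tips on otherwise dark-green leaves.
`ricedeficit` quantifies those symptoms from calibrated scans and turns
them into an automatic diagnosis, aimed at plant-phenotyping and crop
nutrient-management workflows.

## Method

1. **Segmentation** — each scanned organ is separated from the near-white
   scanner background (min-channel threshold, holes filled, largest
   8-connected component) and measured in a dpi-calibrated frame
   (1 px = 2.54/dpi cm).
2. **Characteristics** — a registry of 32 features per plant and focal
   leaf position: leaf/sheath RGB means, lightness, leaf length, width,
   area, perimeter, seven shape ratios (eccentricity, rectangularity, area
   convexity, circularity, form factor 4πA/P², A/L, A/P), leaf-tip color
   over the distal 1/5 of the blade, cross-leaf length/color differences,
   sheath-length spacings, and the white-region area (WRA, cm²) of the
   sheath base.
3. **Feature selection (SVFS)** — backward elimination with a soft-margin
   linear SVM: each feature is scored by the perturbation of the margin
   objective when it is removed (w² for a linear kernel), redundant
   survivors (|r| > 0.95) are collapsed, and the smallest subset within
   tolerance of the best cross-validated accuracy is kept.
4. **Hierarchical Fisher cascade** — three two-class Fisher discriminants
   y = a₁x₁ + … + aₙxₙ with weights (S_w + εI)⁻¹(μ_A − μ_B):
   stage 1 separates Normal from deficient plants, stage 2 N-deficient
   from the P/K pool, stage 3 P from K. Default per-stage subsets are the
   reference ones (8, 5 and 7 characteristics); `auto` re-derives them by
   SVFS per stage. Models are trained and compared per leaf position —
   the oldest (3rd) leaf carries the strongest symptoms.

The study scans themselves are not publicly deposited, so the package
ships a first-class synthetic generator (`ricedeficit.synth`) that
emulates the four symptom classes with analytic ground truth (lanceolate
Bézier leaf outlines, stadium-shaped sheaths, per-position symptom
attenuation, tip-chlorosis gradients, geometry jitter and channel noise).
All tests and the reproduction script run on it.

## Worked example

```python
import numpy as np
from ricedeficit import synth, features, hierarchy

train = synth.generate_dataset(n_per_class=50, dpi=50, seed=1)
table = features.extract_table(train.samples)

model = hierarchy.train_cascade(table, subsets="table9", position=3)
val = synth.generate_dataset(n_per_class=25, dpi=50, seed=10001)
vtable = features.extract_table(val.samples, positions=(3,))
report = hierarchy.evaluate(model, vtable)
print(report.to_text())
```

```
leaf position: 3
overall accuracy: 100.00%
per-class accuracy: Normal 100.00%, Ndef 100.00%, Pdef 100.00%, Kdef 100.00%
stage accuracies: stage1 100.00%, stage2 100.00%, stage3 100.00%
confusion matrix (rows = true, columns = predicted):
        Normal  Ndef  Pdef  Kdef
Normal      25     0     0     0
Ndef         0    25     0     0
Pdef         0     0    25     0
Kdef         0     0     0    25
```

Under the default symptom profiles the classes are constructed to be
well separated, so a correctly working cascade identifies held-out
simulated plants essentially perfectly; the interesting failure modes
(P↔K confusion, stage-1 leakage) appear as the profiles are pushed
closer together or the noise raised.

The same pipeline is available from the shell:

```sh
ricedeficit simulate --n-per-class 20 --dpi 50 --seed 1 --out scans/
ricedeficit extract  --images scans/ --dpi 50 --out features.csv
ricedeficit train    --features features.csv --position 3 --out model.json
ricedeficit evaluate --model model.json --features features.csv
```

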