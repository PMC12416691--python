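# phantomqc

Automated quality-control scoring of ACR-style mammography
accreditation phantom radiographs.

Mammography sites prove image quality by radiographing a standard
phantom: an acrylic block with a wax insert carrying 16 artificial
lesions in a 4×4 grid — six nylon **fibers**, five **speck groups** of
six microcalcification-like dots, and five low-contrast **masses**,
each family in decreasing size and contrast.  Reviewers grade every
lesion 0.0 / 0.5 / 1.0 by visibility at the correct location (plus an
auxiliary *N/A* for visible-but-below-0.5 cases), total the grades per
feature under a sequential stopping rule, and pass the phantom when the
fiber total is ≥ 4.0 and the speck and mass totals are ≥ 3.0.  Reading
thousands of these images a year is repetitive expert work; this
package implements the full scoring pipeline so it can be automated,
studied, and stress-tested end to end.

Because real accreditation corpora are not redistributable, the package
includes a first-class **synthetic phantom generator** with exactly
known ground truth: every downstream stage is developed and verified
against renders whose correct grades are known by construction.

## What is inside

| module | role |
| --- | --- |
| `phantomqc.synth` | renders stylized phantom radiographs (DICOM or arrays) with per-lesion visibility parameters, artifacts, blur/noise/orientation, and derives guideline ground-truth grades |
| `phantomqc.preprocess` | 4-stage standardization: monochrome1→2 inversion; Otsu + largest-component localization and rotation to bottom-center; line-profile lesion-area cropping; rhombus-window normalization, 224×224 resize, 16-tile split |
| `phantomqc.rules` | deterministic guideline scorers (longest continuous fiber run, visible-speck count, mass contour circularity) |
| `phantomqc.learned` | trainable dual-output classifier: `p_exist` and `p_abnormal` per tile, masked focal loss, inverse-frequency class weights, SGD, gradient saliency maps, interpretation sweeps |
| `phantomqc.qualify` | sequential feature totals, pass/fail verdicts, early-termination scoring |
| `phantomqc.evaluate` | confusion metrics, existence/abnormality ROC, F1-maximizing thresholds, bootstrap CIs, stratified splitting, hierarchical system evaluation |
| `phantomqc.cli` | `phantomqc synth / preprocess / score / train / qualify / evaluate / interpret / run` |

The label encoding of the dual-output classifier: grade 1.0 → `[1, 0]`,
grade 0.5 → `[1, 1]`, grade 0.0 → `[0, ·]` with the abnormality loss
term masked (no lesion, no basis for judging abnormality).  Decoding
inverts this with per-output decision thresholds chosen to maximize F1
on a held-out split.

## Worked example

```python
import numpy as np
from phantomqc import synth, preprocess, rules, qualify

# render a radiograph whose ground truth is known
results = synth.sample_dataset(1, seed=7)
res = results[0]
print("truth:", [str(s) for s in res.truth.scores], res.truth.qualified)

# standardize and score it
std = preprocess.run_pipeline(res.image)
tiles = preprocess.split_grid(std)
scores = rules.RuleBasedScorer().predict(tiles)
verdict = qualify.qualify_phantom(scores)
print("scores:", [str(s) for s in scores])
print("totals:", verdict.totals, "qualified:", verdict.qualified)
```

prints

```
truth: ['1.0', '1.0', '1.0', '1.0', '1.0', '1.0', '1.0', '1.0', '1.0', '1.0', '1.0', '1.0', '1.0', '1.0', '1.0', '1.0'] True
scores: ['1.0', '1.0', '1.0', '1.0', '1.0', '1.0', '1.0', '1.0', '1.0', '1.0', '1.0', '1.0', '1.0', '1.0', '1.0', '1.0']
totals: (6.0, 5.0, 5.0) qualified: True
```

— a fully visible phantom: every lesion graded 1.0, feature totals
6.0/5.0/5.0 against thresholds 4.0/3.0/3.0, verdict *qualified*.  The
same flow from a shell:

```bash
phantomqc synth --n 25 --seed 7 --out data/
phantomqc run --in data/ --out results/
```

Training and probing the learned scorer:

```python
from phantomqc import learned
X, y = ...  # tiles and grades, e.g. from synth.render_subimages
clf = learned.DualOutputClassifier(epochs=12, random_state=0).fit(X, y)
sweep = learned.interpretation_sweep(clf, "mass_deformation", steps=10)
```

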