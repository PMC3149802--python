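# vertasm

Active Shape Model (ASM) segmentation of vertebral bodies in grey-level,
radiograph-like images, with a semiautomatic two-click initialization.

Delineating cervical vertebrae on lateral X-rays is the first step of
any mobility or deformity analysis, and plain intensity-based methods
struggle with the low contrast and clutter of radiographs.  An ASM
attacks the problem statistically: a training set of landmarked
examples yields a *point distribution model* — a mean shape x̄ plus the
principal modes P of landmark variation — and any segmentation is
constrained to the family

    x = x̄ + P b,      |b_i| ≤ 3 √λ_i,

so the result is always an anatomically plausible shape.  At search
time each landmark slides along its contour normal to the position
whose grey-level gradient profile g best matches the trained
per-landmark statistics under the Mahalanobis distance

    D = (g − ḡ)ᵀ S_g⁻¹ (g − ḡ),

after which the point cloud is projected back onto the model
(similarity pose + clamped b).  The loop stops by a 10% rule: when the
number of landmarks still moving drops to a tenth of the previous
iteration's count.

Because ASM quality hinges on initialization, the package includes the
semiautomatic corner initializer: from just two user clicks (upper
anterior corner of the first vertebra, lower anterior corner of the
last), it crops the search window, detects Canny edges and Harris
interest points, filters out candidates that are isolated from long
contours or whose contour angle lies outside [10°, 160°], and then
finds the 2N anterior corners as the shortest alternating path whose
step lengths match the spine geometry prior: vertebra height
α = 4d/(5N−1) and intervertebral gap β = α/4, derived from the anchor
distance d.

The library is organised around a scikit-learn-style estimator; no
clinical data ships with it — a seeded synthetic spine-phantom
generator with exact ground truth supports training, testing and the
reproducibility script.

## Worked example

```python
from vertasm import (ActiveShapeModel, SyntheticSpec,
                     generate_training_set, detect_corners,
                     evaluate_segmentation)
from vertasm.synthetic import heldout_spec

spec = SyntheticSpec(n_vertebrae=5, seed=0)
_, train = generate_training_set(spec, 75)
est = ActiveShapeModel(model_kind="vertebra")
est.fit([s.image for s in train], [s.shape for s in train])

_, test = generate_training_set(heldout_spec(spec), 2)
sp = test[0]
seq, diag = detect_corners(sp.image, sp.anchor_top, sp.anchor_bottom, 5)
final, sdiag = est.segment(sp.image, seq.corner_pairs())
rep = evaluate_segmentation(final, sp.shape)
```

Output:

```
trained on 375 vertebra shapes; 2 modes explain 99.8% of shape variance
corner candidates: 10 -> 10 -> 10 after filtering; optimal path length 239.5 px
converged: True after 4 iterations
mean point-to-line error: 0.35 px
mean point-to-point error: 0.58 px
```

The two retained PCA modes are exactly the two deformation modes the
phantom generator uses, the initializer's shortest path picks the 10
anterior corners of the 5 vertebrae, and the converged contour sits a
third of a pixel from the ground truth (point-to-line: distance from
each segmented landmark to the true contour polygon; point-to-point:
distance between corresponding landmarks, which also penalises sliding
along the contour).

The same workflow is available from the shell:

```sh
vertasm simulate --n-images 75 --n-vertebrae 5 --seed 0 --out data/
vertasm train --data data/ --out model.json
vertasm detect-corners --image data/spine_000.png --anchors 26,25,26,265 \
        --n-vertebrae 5 --out corners.csv
vertasm segment --image data/spine_000.png --model model.json \
        --init corners.csv --out result.pts
vertasm evaluate --pred preds/ --truth data/ --threshold 2
```

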