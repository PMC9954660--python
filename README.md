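# rdaunet

Slice-wise segmentation of bladder-like organs and their lesions in
abdominal CT, built around a **residual–dense–attention (RDA) U-Net**: a
five-level encoder–decoder whose first two encoder stages are residual
convolution blocks, whose last three are densely connected blocks, and
whose decoder suppresses irrelevant image regions with additive attention
gates on every skip connection.

The package is aimed at researchers who want a complete, testable version
of this pipeline without access to clinical data: every stage — Hounsfield
windowing, joint five-transform augmentation, the network, Adam training,
and the four-metric evaluation suite — runs end to end on seeded synthetic
phantoms with exact ground truth.

## The model

For a windowed slice `x ∈ [0,1]^{H×W}` the network produces a probability
map `p = σ(f(x))` and a mask by thresholding at 0.5. Encoder stages
(widths 24, 48, 96, 96, 697) each end in 2×2 max pooling:

* residual block: `y = ReLU(BN(conv(BN–ReLU(conv(x)))) + proj(x))`
* dense block (3 layers, growth 12): layer *i* maps
  `concat(x, y_1, …, y_{i−1})` to 12 new channels; a 3×3 transition conv
  sets the stage width
* attention gate on skip `s` with gate `g`:
  `α = σ(ψ(ReLU(θ(s) + φ(g)))) ∈ [0,1]^{H×W}`, output `α ⊙ s`

The default configuration instantiates with **exactly 13,053,861 trainable
parameters**, the architecture's fingerprint, verified by
`count_parameters`. Training follows the standard recipe: Adam, learning
rate 10⁻³, batch 8, binary cross-entropy, 200 epochs (organ) / 100
(lesion). Evaluation reports pixel accuracy, Dice (DSC), IoU and the
average Hausdorff distance (AVGDIST, pixels), plus rank-based ROC-AUC:

    ACC = (TP+TN)/(TP+TN+FP+FN)   DSC = 2TP/(FP+2TP+FN)
    IoU = TP/(FP+TP+FN)           AVGDIST = (d̄(G→S) + d̄(S→G))/2

There is no GPU dependency: the network runs on a small tape-based numpy
autodiff engine shipped in `rdaunet.nn`, with gradients verified against
finite differences in the test suite.

## Worked example

```python
import numpy as np
from rdaunet import build_rda_unet, count_parameters
from rdaunet.benchmark import run_phantom_benchmark

total, breakdown = count_parameters(build_rda_unet())
print(total)                      # 13053861

res = run_phantom_benchmark()     # 200 phantoms, 64x64, base width 8, 15 epochs
print(round(res.dsc_mean, 4), round(res.dsc_min, 4))
```

prints

```
13053861
0.9665 0.8869
```

meaning: the default architecture carries 13,053,861 trainable parameters,
and a width-reduced network trained for 15 epochs on 160 synthetic phantom
slices segments the 40 held-out slices with mean Dice 0.9665 (worst slice
0.8869) — the phantom task is separable by construction, so numbers far
from 1.0 would indicate a pipeline defect rather than a hard task.

The same pipeline is scriptable from the shell:

```bash
rdaunet phantom --n 712 --out data/ --seed 1          # synthetic corpus
rdaunet augment --manifest data/organ/manifest.csv \
                --out data/organ_aug --multiplier 3 --seed 1   # 712 -> 2136
rdaunet model summary                                  # per-stage parameters
rdaunet train --manifest data/organ_aug/manifest.csv --out runs/organ \
              --task organ --net-config cfg.json --epochs 15
rdaunet evaluate --pred runs/organ/pred --gt data/organ/masks --out report.csv
```

See `docs/methods.md` for the full model description, parameter
calibration, phantom design and known limitations.

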