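# res2fuse

MR–CT image fusion for intracranial imaging, built around a Res2Net
autoencoder and a parameter-free spatial-mean-attention fusion layer.

CT shows bone brightly but renders tumors and soft tissue nearly flat; MR
inverts this, with dark bone and rich soft-tissue detail. Radiotherapy
target delineation wants both at once. `res2fuse` trains a small
convolutional autoencoder — a feature extractor of two 3×3 convolutions
plus a scale-4 Res2Net block, and a four-layer reconstructor — to
reproduce single images under a hybrid loss `L = (1 − SSIM) + MSE`. At
inference, features of a registered CT/MR pair are combined per pixel with
weights

    ω_i(x, y) = Q_i(x, y) / (Σ_j Q_j(x, y) + ε),

where `Q_i` is the channel-wise mean of source *i*'s feature stack, and
the weighted features are decoded into the fused image. The package also
implements the eight standard fusion-quality metrics (AG, SF, EN, MI,
PSNR, SSIM, Qabf, VIFF), a paired t-test utility for method comparisons,
and a seeded generator of registered synthetic CT/MR head phantoms so the
whole pipeline trains and evaluates with no external data. The network,
backpropagation and Adam optimizer are implemented directly in NumPy; see
`docs/methods.md` for the model, conventions and limitations.

## Worked example

```sh
# 1. generate 20 registered synthetic CT/MR pairs
res2fuse phantom --n 20 --size 96 --seed 0 --out-dir work/data

# 2. train the autoencoder (fusion layer absent during training)
res2fuse train --data-dir work/data --epochs 30 --crop 64 --seed 0 \
               --out work/model.npz

# 3. fuse one registered pair with the trained weights
res2fuse fuse --ct work/data/ct_0000.png --mr work/data/mr_0000.png \
              --checkpoint work/model.npz --out work/fused_0000.png

# 4. score the fused image against its sources: add a fused_path column
#    to the manifest, then evaluate
python -c "
import pandas as pd
m = pd.read_csv('work/data/manifest.csv').head(1)
m['fused_path'] = '../fused_0000.png'
m.to_csv('work/data/eval.csv', index=False)
"
res2fuse evaluate --manifest work/data/eval.csv --out work/metrics.csv
```

The training run prints a falling loss curve ending near

```
epoch 30/30: loss 0.06811 (ssim 0.06393, pixel 0.00418) in 3.1s
final epoch loss 0.06811; checkpoint at work/model.npz
```

(the SSIM term starts near 1 for an untrained network and the pixel term
near the image variance). `evaluate` prints the mean metric row of the
CSV it writes:

```
ag       0.028803
sf       0.096750
en       4.965170
mi       3.991432
psnr    14.319912
ssim     0.660539
qabf     0.580259
viff     0.377220
```

Reading these: the fused phantom carries about 5.0 bits of entropy
(versus 4.40 for its CT source — soft-tissue texture imported from MR),
retains ≈ 4.0 bits of joint source information, and preserves 58 % of the
sources' edge information by Qabf — versus roughly 0.24 for a naive
feature-average baseline under the same trained weights (paired t-test
p ≈ 2e-21 over 20 pairs, recomputed by `scripts/acceptance.py`). Absolute
values are not comparable to clinical numbers — they are properties of
the synthetic phantom distribution.

Every subcommand writes a `*_provenance.json` (settings with origins,
seeds, checkpoint hash, package version) next to its outputs, and all
randomness is seeded, so any artifact is reproducible from its provenance
file.

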