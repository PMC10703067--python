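# tunet — hybrid transformer/U-Net ultrasound image segmentation

Ultrasound images are hard to segment: coherent imaging produces
multiplicative speckle, low signal-to-noise ratio and blurred or missing
boundaries, and the targets of clinical interest — a fetal head outline, a
brachial-plexus nerve bundle — vary enormously in size and shape, sometimes
vanishing from a frame entirely.  Purely convolutional encoder–decoder
networks capture local texture well but lack global context; pure
vision-transformer segmenters capture global relations but lose localization.

`tunet` implements **TU-Net**, a hybrid of the two, together with everything
needed to train and evaluate it: a Dice + TopK joint loss, surface-distance
evaluation metrics, an ablation harness with Friedman-test comparison, a
synthetic ultrasound-phantom generator, and a scikit-learn style estimator
(`TUNetSegmenter`) tying it all together.  It is aimed at researchers in
medical image analysis who want a transparent, CPU-runnable reference
implementation of this family of architectures.

## The model

A five-stage convolutional encoder (channel widths 64, 128, 256, 512, 1024)
produces skip features at strides 1–8 and a bottleneck at stride 16.  The
bottleneck feeds a **parallel attention mechanism** with two branches:

* **Transformer branch.** The bottleneck grid is reshaped into N = H·W/P²
  patch tokens (P = 16 at input scale, so a 320×320 image gives 400 tokens),
  linearly projected to width D with learned position embeddings added, and
  passed through L = 12 pre-norm transformer blocks

      z′_l = MSA(LN(z_{l−1})) + z_{l−1}
      z_l  = MLP(LN(z′_l)) + z′_l ,      l = 1…L

* **Convolutional branch.** Four cascaded 3×3 atrous convolutions with
  dilation rates r = 1, 3, 5, 7 followed by pyramid pooling over receptive
  fields 2×2, 4×4, 8×8 and 16×16 (pool → 1×1 conv → bilinear upsample →
  concatenate → 1×1 conv).

The branch outputs are fused (concatenation + 1×1 convolution) and decoded
back to input resolution by repeated (upsample ×2, concatenate skip, two 3×3
convolutions), ending in a single-channel sigmoid probability map.

Training minimizes the joint loss

    L_total = L_Dice + L_TopK

where `L_Dice = 1 − 2|X∩Y|/(|X|+|Y|)` (soft relaxation) and `L_TopK` is the
mean two-class cross-entropy over the k% = 10% hardest pixels of each image —
an online hard-example-mining variant of cross-entropy that counteracts the
foreground/background imbalance of ultrasound masks.  Optimization is
mini-batch SGD (lr 0.01, momentum 0.9, weight decay 1e-4, batch size 10, lr
stepped every 100 epochs).

Evaluation reports per-image Dice, precision and recall on the binarized
prediction, plus two boundary metrics in millimetres: the exact Hausdorff
distance (HD) and the average symmetric surface distance (ASD) between the
4-connectivity boundary point sets of prediction and ground truth.

The network is implemented on a small numpy reverse-mode autodiff engine
(`tunet.autodiff`); its gradients are verified against finite differences in
the test suite.

## Worked example

Train a reduced configuration on synthetic 64×64 phantoms (a full-size model
on real data needs GPU-scale compute; this runs in a couple of minutes on
one CPU core):

```python
import numpy as np
from tunet import TUNetSegmenter, PhantomSpec, generate_phantom

spec = PhantomSpec(image_size=64, target_kind="blob", seed=7)
train = [generate_phantom(spec, i) for i in range(16)]
test = [generate_phantom(spec, 100 + i) for i in range(4)]
X = np.stack([s.image for s in train]); y = np.stack([s.mask for s in train])
Xt = np.stack([s.image for s in test]); yt = np.stack([s.mask for s in test])

seg = TUNetSegmenter(base_channels=(8, 16, 32, 64, 128), embed_dim=64,
                     num_layers=2, num_heads=4, mlp_dim=128,
                     pool_fields=(1, 2, 2, 4), image_size=64,
                     batch_size=8, epochs=50, random_state=0)
seg.fit(X, y)
print("trainable parameters:", seg.n_parameters_)
print("final training loss: %.4f" % seg.history_["loss"].iloc[-1])
print("held-out mean Dice: %.4f" % seg.score(Xt, yt))
table, summary = seg.evaluate(Xt, yt, spacing=1.0)
print(summary.to_string(index=False))
```

Output:

```
trainable parameters: 1327353
final training loss: 0.1096
held-out mean Dice: 0.9622
   metric     mean      std  n  n_excluded
     dice 0.962237 0.015172  4           0
precision 0.968265 0.011079  4           0
   recall 0.956402 0.021136  4           0
       hd 3.402125 2.987565  4           0
      asd 0.486019 0.120018  4           0
```

The model recovers the speckled phantom targets with Dice ≈ 0.96; the mean
Hausdorff distance of ≈ 3.4 mm (at 1 mm/px) says the worst boundary error on
a typical test image is a few pixels, while the ASD of ≈ 0.5 mm says the
boundary is on average within half a pixel of the truth.  `n_excluded`
counts images whose empty masks make the surface distances undefined.

A command-line interface mirrors the library: `tunet synth`, `tunet train`,
`tunet eval`, `tunet ablate`, `tunet compare` (Friedman test) and
`tunet build-report` (per-module parameter counts); see `tunet --help`.

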