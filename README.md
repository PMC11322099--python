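# clib — background-ignoring contrastive representation learning

Self-supervised pretraining for subject-centered images whose backgrounds
are a nuisance — the motivating case is underwater fish imagery, where the
same species appears over many backgrounds and the same background behind
many species, so background texture is a spurious cue that ordinary
instance-discrimination methods happily learn.

The method splits every image geometrically into a **subject** (the
centered crop of height α·H and width β·W) and a **background** (the four
γ·H × δ·W corner rectangles pieced into a mosaic), and trains an encoder
f(·) with projection head g(·) on three views per image with a multi-view
NT-Xent loss. For embeddings z = g(f(t(·))), cosine similarity sim and
temperature τ, each anchor i (an original or subject slot) with positive j
(its counterpart) contributes

    ℓ(i, j) = −log  exp(sim(z_i, z_j)/τ) / Σ_{k≠i} exp(sim(z_i, z_k)/τ)

with the sum over all 3N − 1 other samples: the subject is the original's
*only* positive, and all N background mosaics enter every denominator as
extra negatives. Pulling originals toward their subjects while pushing them
away from backgrounds makes the representation encode the center content
and discard background texture. The package also provides the SimCLR
baseline, the ablation that merely appends background negatives to SimCLR,
a frozen-backbone linear-probe protocol (1:1:8 stratified split, validation
model selection, accuracy + macro precision/recall/F1), and a synthetic
background-confounded benchmark generator. Everything runs on one CPU; the
neural-network layers and their backward passes are implemented directly on
numpy and checked against finite differences.

Intended users: researchers studying spurious-correlation robustness in
self-supervised learning, and practitioners who need a small, fully
reproducible testbed for background-invariant representation learning.

## Worked example

Pretrain on images whose background texture predicts the class 90% of the
time, probe with 10% of the labels, and test on images whose backgrounds
are uninformative:

```python
import numpy as np
from clib import ContrastiveEncoder, SplitSpec, SyntheticSpec, generate_dataset
from clib.evaluation import evaluate, split_dataset, train_probe

spec = SyntheticSpec(n_classes=5, per_class=100, confound=0.9, seed=0)
train = generate_dataset(spec)
test = generate_dataset(spec, rng=np.random.default_rng(1), confound=0.0)

encoder = ContrastiveEncoder(variant="clib", epochs=30, random_state=0)
encoder.fit(train.images.pixels)
print(f"pretraining loss: {encoder.loss_curve_[0]:.3f} -> "
      f"{encoder.loss_curve_[-1]:.3f} (best epoch {encoder.best_epoch_})")

tr, va, te = split_dataset(train.labels, SplitSpec(seed=0))  # 1:1:8
probe = train_probe(encoder, train.images.pixels, train.labels, tr, va,
                    epochs=20, seed=0)
report = evaluate(encoder, probe, test.images.pixels, test.labels)
print(f"decorrelated-background test accuracy: {report.accuracy:.3f}")
print(f"macro F1: {report.f1:.3f}  (chance accuracy: 0.200)")
```

which prints (about a minute on one CPU core):

```
pretraining loss: 4.195 -> 2.756 (best epoch 20)
decorrelated-background test accuracy: 0.462
macro F1: 0.450  (chance accuracy: 0.200)
```

The contrastive loss falls from near its collapse value ln(3N − 1) ≈ 4.55
(N = 32) as the embedding space organizes, and the probe generalizes well
above chance even though its own training labels were confounded with the
background — switch `variant="simclr"` and the test accuracy drops toward
chance, because the baseline representation leans on the background cue
that vanished at test time.

`ContrastiveEncoder` and `LinearProbe` are scikit-learn estimators
(`get_params`/`set_params`, fitted attributes with trailing underscores) and
compose with sklearn model selection; `clib.views`, `clib.loss`,
`clib.training`, `clib.evaluation` and `clib.synthetic` expose the
underlying operations (crop extraction, the three loss variants, the
pretraining loop and sweep harness, the split/probe/metrics protocol, the
generator). A thin CLI mirrors them:

```sh
clib synth --out data/ --n-classes 5 --per-class 100 --confound 0.9 --seed 0
clib pretrain --data data/ --variant clib --seed 0 --out ckpt.npz
clib probe --data data/ --checkpoint ckpt.npz
clib benchmark --variant clib --seed 0
```

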