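# painstn

Facial pain-intensity estimation from single face images, built around a
spatial transformer, per-channel sigmoid attention gating and a plain
CNN classifier — with a fully synthetic face generator so the entire
pipeline runs and is tested without access-restricted clinical data.

## Who this is for

Researchers working on automatic pain assessment from facial
expressions (e.g. on the UNBC-McMaster shoulder-pain archive protocol)
who need a transparent, dependency-light reference implementation of
the transform–attend–classify pipeline, its PSPI-based labeling rules
and its evaluation metrics — or who want to reproduce the published
metric arithmetic exactly from printed confusion matrices.

## The method

Ground truth per frame is the Prkachin–Solomon Pain Intensity computed
from six FACS action units,

```
PSPI = AU4 + max(AU6, AU7) + max(AU9, AU10) + AU43   ∈ {0, …, 16}
```

binned into four levels: 0 → none, 1–2 → weak, 3–5 → intense, ≥6 →
excruciating. The classifier composes:

1. **Spatial transformer** — a small CNN regresses a 2-D affine θ ∈ R⁶;
   a grid generator maps the output grid through A_θ in normalized
   coordinates; a bilinear sampler (zero-padded outside the source)
   resamples the input, undoing translation/rotation/scale/skew
   nuisance.
2. **Attention gating** — each color channel is gated elementwise by
   V′ = V ⊙ σ(conv₃ₓ₃(V)), letting the network down-weight background
   clutter relative to informative face regions.
3. **CNN + softmax** — six conv/ReLU/max-pool blocks
   (64, 64, 128, 128, 256, 256 filters) reduce 192×192×3 to 3×3×256; a
   4-neuron FC layer and softmax cross-entropy finish the job.

Everything (convolutions, pooling, sampler, backprop, He init, SGD with
momentum 0.9 and learning rate 10⁻⁴) is implemented in numpy with
explicit, finite-difference-verified gradients. Two ablation switches
(`use_stn`, `use_attention`) give the four study modes. See
`docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
from painstn import AUCoding, compute_pspi, bin_pspi
from painstn import PainLevelClassifier, generate_arrays
from painstn.synthetic import NuisanceConfig

# PSPI labeling
au = AUCoding(au4=1, au6=2, au7=1, au9=0, au10=3, au43=0)
print(compute_pspi(au), bin_pspi(compute_pspi(au)).description)
# -> 6 Excruciating

# synthetic faces: none-vs-excruciating at 48x48, mild affine nuisance
ds = generate_arrays(500, distribution=(0.5, 0, 0, 0.5), n_subjects=25,
                     nuisance=NuisanceConfig().scaled(0.25),
                     image_size=48, seed=0)
train, dev, test = np.split(np.arange(500), [300, 400])

clf = PainLevelClassifier(use_stn=False, use_attention=False,
                          image_size=48, backbone_filters=(8, 16, 16, 32),
                          learning_rate=1e-2, batch_size=32, max_epochs=20,
                          dtype="float32", random_state=0)
clf.fit(ds.images[train], ds.levels[train],
        X_dev=ds.images[dev], y_dev=ds.levels[dev])
report, cm = clf.evaluate(ds.images[test], ds.levels[test])
print(f"accuracy {report.accuracy:.1f}%  level-MSE {report.mse:.3f}")
# -> accuracy 96.0%  level-MSE 0.360
```

The printed accuracy is the percentage of test frames assigned their
true pain level; the level-MSE is the mean squared difference between
predicted and true level indices (an ordinal error — confusing levels 0
and 3 costs 9, adjacent levels cost 1).

Reference metric arithmetic on a published confusion matrix:

```python
from painstn import metrics_from_confusion
from painstn.published import MODE_CONFUSIONS

rep = metrics_from_confusion(MODE_CONFUSIONS["stn-att"])
print(f"{rep.accuracy:.2f}% MSE {rep.mse:.4f} "
      f"level-0 recall {rep.recall[0]:.1f}% precision {rep.precision[0]:.1f}%")
# -> 51.06% MSE 1.1014 level-0 recall 91.3% precision 54.5%
```

## Command line

```bash
painstn generate --out data/ --n 500 --image-size 48 --seed 0

cat > net.yaml <<EOF        # narrow network for 48x48 experiments
loc_filters: 8
backbone_filters: [8, 16, 16, 32]
loc_lr_scale: 0.5
loc_head_damp: 0.05
stn_identity_anchor: 0.03
dtype: float32
EOF
painstn train --data data/ --out run/ --mode stn-att --seed 0 \
              --epochs 30 --learning-rate 0.01 --batch-size 32 --config net.yaml

painstn evaluate --checkpoint run/checkpoint.npz --data data/ \
                 --split-manifest run/split.json --out eval/
painstn evaluate --confusion-in my_confusion.csv --out eval/   # metrics only
```

Every command honors `--seed`; each run writes a manifest with its full
configuration.

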