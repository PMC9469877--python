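# semnet

Learning **semantic movement features** from windowed wearable-sensor
signals with a heterogeneous-sparse deep belief network, and checking that
what the network learns actually corresponds to human-interpretable motion
primitives.

## The problem

Human activity recognition (HAR) classifies high-level activities
("walking", "chest press") from body-worn accelerometer streams. Between
the raw signal and the activity label sits a mid-level vocabulary of
*semantic attributes* — movement primitives such as "arm up" or "arm curl"
whose combination defines an activity. Hand-labeling such attributes is
expensive and subjective; this package learns them without supervision and
then measures, by correlation against labeled attributes, whether the
learned features carry that semantic meaning.

## The model

The network stacks two restricted Boltzmann machines (RBMs) with
*heterogeneous sparsity*:

- **Layer 1 — Gaussian-visible RBM with dropout.** Energy
  `E(v,h) = ||v − b_vis||²/2 − hᵀWv − b_hidᵀh` over standardized
  real-valued windows `v` and binary hidden units `h`; trained with
  contrastive divergence (CD-1) while a fresh Bernoulli mask (drop rate
  0.3) removes hidden units at every iteration.
- **Layer 2 — binary RBM gated by a Beta-Bernoulli (Indian buffet process)
  prior.** Each hidden unit `k` carries a stick weight
  `π_k ~ Beta(α/K, β(K−1)/K)` (α = 1, β = 5) and each instance a binary
  selection vector `z` with `z_k ~ Bernoulli(π_k)`; only selected units
  enter the energy `E(v,h,z) = −(z⊗h)ᵀWv − b_hidᵀ(z⊗h) − b_visᵀv`.
  Inference draws each `(h_k, z_k)` jointly from its four-state conditional
  and `π` from its conjugate Beta posterior.

Layers are trained greedily: layer 1 is frozen and its mean-field
activations become layer-2 data. Features are the deterministic forward
pass with a ReLU readout on the last layer. Evaluation is
**leave-one-subject-out (LOSO)**: every fitted statistic — channel
standardization, the DBN, the classifier's scaler — comes from the
remaining subjects only, and a one-vs-rest linear SVM classifies the
held-out subject. Semantic matching scores every (attribute, feature) pair
with the Pearson correlation `r = Σ(x−x̄)(y−ȳ)/√(Σ(x−x̄)²Σ(y−ȳ)²)` and
reports the best |r| feature per attribute.

Because the reference recordings are not redistributable, the package ships
a synthetic generator that emulates their structure: multiple subjects,
ten activities built as binary combinations of eight latent attribute
waveforms, nine channels, 64-sample windows, per-subject channel-gain
shift. Every attribute is a known waveform, so semantic recovery can be
scored exactly.

## Worked example

```python
import numpy as np
from semnet import dbn, evaluation, preprocessing, semantics, synthetic

spec = synthetic.SyntheticSpec(seed=1)
windows, truth = synthetic.generate_dataset(spec, np.random.default_rng(1))

config = dbn.TrainConfig(layer_sizes=(64, 32), epochs=30, seed=1)
std, stats = preprocessing.standardize(windows)
X = preprocessing.flatten_windows(std)
model = dbn.init_model(config, X.shape[1])
dbn.train_layerwise(model, X, config)
features = dbn.extract_features(model, X)

report = semantics.correlation_matrix(features, truth.attributes)
for a, (j, r) in enumerate(semantics.match_attributes(report)):
    print(f"attribute {a}: best feature f{j}, r = {r:+.3f}")

stat = evaluation.loso_evaluate(windows, evaluation.statistical_feature_fn())
comb = evaluation.loso_evaluate(windows, evaluation.combined_feature_fn(config))
print(f"LOSO accuracy, statistical baseline: {stat.mean_accuracy:.3f}")
print(f"LOSO accuracy, statistical + DBN:    {comb.mean_accuracy:.3f}")
```

Output:

```
attribute 0: best feature f9, r = +0.741
attribute 1: best feature f26, r = +0.717
attribute 2: best feature f23, r = +0.901
attribute 3: best feature f16, r = +0.797
attribute 4: best feature f29, r = +0.670
attribute 5: best feature f25, r = +0.724
attribute 6: best feature f11, r = +0.932
attribute 7: best feature f29, r = +0.670
LOSO accuracy, statistical baseline: 0.775
LOSO accuracy, statistical + DBN:    1.000
```

Every latent attribute finds a last-layer feature correlated above 0.5
even though the network never saw attribute labels, and appending the
learned features to the per-channel-mean baseline lifts cross-subject
accuracy substantially — the two findings the package exists to
demonstrate.

The same workflow is available from the shell:

```bash
semnet generate --out-dir data/ --seed 1
semnet train --data data/data.csv --model-out model.npz
semnet extract --model model.npz --data data/data.csv --features-out features.csv
semnet correlate --features features.csv --attributes data/attributes.csv --out corr.csv
semnet evaluate --data data/data.csv --features both --out loso.csv
```

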