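# Methods

## Model

The package implements a two-layer deep belief network over fixed-length
sensor windows, with a different sparsity mechanism per hidden layer.

**Layer 1: Gaussian-Bernoulli RBM with dropout.** Accelerometer samples are
real-valued, so the first layer uses unit-variance Gaussian visible units
on per-channel standardized data. Its energy is

    E(v, h) = ||v - b_vis||^2 / 2 - h^T W v - b_hid^T h,

which leaves the hidden conditional `p(h_k = 1 | v) = σ(W_k·v + b_hid_k)`
identical to the binary case and makes the visible conditional a Normal
with mean `W^T h + b_vis`. During training an i.i.d. Bernoulli keep-mask
(drop probability 0.3) is redrawn every minibatch; masked units are removed
from both CD phases, so their gradient rows vanish.

**Layer 2: binary RBM with a Beta-Bernoulli (IBP) gate.** Per hidden unit
`k`, `π_k ~ Beta(α/K, β(K-1)/K)`; per instance, `z_k ~ Bernoulli(π_k)`
selects which units participate in the gated energy
`E(v,h,z) = -(z⊗h)^T W v - b_hid^T (z⊗h) - b_vis^T v`. For large `K` the
prior mean activation `α/(α + β(K-1))` is tiny, so the gate starts almost
closed and the conjugate posterior
`π_k ~ Beta(α/K + Σ_j z_k^j, β(K-1)/K + Σ_j (1-z_k^j))` reopens exactly the
units the data uses. The per-unit joint conditional of `(h_k, z_k)` has
four states with unnormalized weights `π e^{s_k}`, `π`, `1-π`, `1-π` for
(1,1), (0,1), (0,0), (1,0), where `s_k` is the hidden pre-activation. A
dropped unit contributes no energy, so given `z_k = 0` both values of `h_k`
are equally likely — the gate, not the hidden state, carries the sparsity.

**Stacking and readout.** Layers are trained greedily; a layer is frozen
before its mean-field activations (dropout layers scaled by the keep
probability, the standard expectation-preserving rule) become the next
layer's data. Mean-field probabilities rather than binary samples feed the
upper layer: deterministic and lower-variance, at the cost of ignoring
sampling noise the generative model would have. Feature extraction is the
deterministic forward pass; the last layer's pre-activation passes through
ReLU by default (configurable to logistic). Training itself always uses the
logistic conditionals — they are the model's mathematics — while ReLU is a
readout choice for the extracted representation; this is the only reading
consistent with logistic energies and a ReLU feature map coexisting.

## Training details and defaults

| parameter | default | role |
| --- | --- | --- |
| layer widths | 2048, 1024 | reference network size (tests use 64/32) |
| dropout rate | 0.3 | layer-1 drop probability per iteration |
| α, β | 1, 5 | IBP gate prior; prior activation `α/(α+β(K−1))` |
| weight init | N(0, 0.005²) | biases start at zero |
| weight decay | 0.998 | multiplicative, weights only, every update |
| momentum | 0.95 | velocity accumulation on all parameters |
| learning rate | 0.01 | CD ascent step |
| epochs / batch | 100 / 100 | per layer; minibatches reshuffled each epoch |
| CD steps k | 1 | standard CD-1 |

The 0.998/0.95 pair is assigned as weight decay/momentum: 0.998 is
implausibly high as a momentum coefficient and is the conventional
magnitude for multiplicative decay. Learning rate, epochs, batch size and
`k` are conventional CD settings and fully configurable.

CD gradients follow the standard estimator: analytic hidden probabilities
for the data term, `k` alternations of sampled hiddens and mean-field
visible reconstructions for the model term, with the final step's hidden
probabilities in the statistics. The IBP layer substitutes the gated
activation `z⊗h` (its analytic mean `p(h=1, z=1 | v, π)` for statistics,
samples for the chain) wherever the plain estimator uses `h`; with all
gates pinned open the two estimators coincide draw for draw. Because
training is minibatched while the conjugate π-posterior sums selection
counts over all M training instances, the counts of each minibatch are
scaled by `M / batch_size` before resampling π — a stochastic approximation
of the full conditional. `z` is redrawn at every visit rather than
persisted: the four-state table is a full conditional given `v` and `π`.

## Numerical choices

- Pre-activations entering `exp()` in the four-state gate conditional are
  clipped at ±300 (saturated to machine precision far earlier).
- Beta shape parameters are clamped below at 1e-6 (`K = 1` would otherwise
  make the second shape exactly 0), and π is kept inside
  [1e-12, 1 − 1e-12].
- The hidden bias is included in the gate conditional's exponent for
  consistency with the ungated hidden conditional;
  `TrainConfig.literal_hz_conditional=True` drops it for comparison.
- Exact likelihood/gradient oracles enumerate all states and are refused
  beyond `n_visible + n_hidden = 20`.
- Constant features have undefined Pearson correlation and are excluded
  from attribute matching (not scored 0); ties in the |r| argmax go to the
  lowest feature index. Window label/attribute majority votes break ties
  with the window's first sample.
- Zero-variance channels standardize to 0 with the sd clamped to 1.

## Synthetic benchmark

The generator emulates a multi-subject exercise-recording corpus: 8
subjects × 10 activities × 20 windows, 9 channels (three tri-axial
devices), 64-sample windows. Each activity is a unique combination of 1–3
of 8 latent attributes; each attribute is a multichannel waveform mixing
two random-phase sinusoids at attribute-specific integer frequencies
(mutually orthogonal over the window) plus per-channel DC offsets. Windows
are the sum of their activity's signatures, scaled by per-subject channel
gains `~ N(1, 0.25²)` and corrupted by white noise (sd 1.2).

The defaults were fixed once against three identifiability requirements and
not revisited: the per-channel-mean baseline must be informative but
imperfect under LOSO (measured 0.76–0.90 across seeds — the DC offsets
carry partial class information and the gain shift degrades it across
subjects), the full waveform must be nearly fully identifiable (OLS of
windows onto the true signatures recovers ≥99% of attribute patterns), and
waveform-using features must close most of the remaining gap (combined
features reach ≈1.0). What the generator does *not* model: temporal warping
within an activity, activity transitions inside a window, sensor drift,
nonlinear attribute mixing, or heavy-tailed noise. Passing tests therefore
show the machinery is correct and that semantic recovery works when
attributes are additive waveform components — not that comparable accuracy
would be reached on real recordings.

Benchmark-scale runs in the test suite and the acceptance script use a
64/32-unit stack trained for 30 epochs on the 1,600-window default dataset;
this keeps a full five-seed LOSO sweep (each fold retrains the network from
scratch) to a few minutes on one CPU while leaving every qualitative
finding intact.

## Known limitations

- Two hidden layers are the tested configuration; deeper stacks are
  accepted by the config (middle layers train as plain binary RBMs) but
  untested.
- No persistent CD, parallel tempering, or supervised fine-tuning.
- The gate count scaling treats minibatch selection frequencies as
  representative of the full training set; very small batches make the
  π-updates noisy.
- LOSO retrains the network per fold, so evaluation cost grows linearly
  with the number of subjects.
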