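# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `spikeae`.

## Autoencoder variants

All dense variants share one skeleton: encoder layers with ReLU, a tanh code
layer, a mirrored decoder (ReLU hidden layers) and a tanh output layer. tanh
is used at the code and output because reconstruction needs negative values
and a bounded nonlinearity; inputs are min-max scaled to [0, 1] beforehand,
which lies inside tanh's range. Layer counting convention: `n_layers` counts
hidden plus code layers (the deep variant: 8 + 1 + 8 = 17); the output
reconstruction layer also carries weights but is not counted.

Training: Adam with learning rate 1e-3, MSE over shuffled mini-batches of 64
(batch size exposed in `AEConfig`), L1 of 1e-7 on the code activations.
The L1 coefficient is nominally "10e-7"-style in common descriptions, which
literally reads 1e-6; we default to 1e-7 and expose the knob. The default
epoch count is 500 with 50 as the fast preset used throughout the
experiment drivers; the sweep driver shows the clustering metrics are
already saturated at 50 epochs on easy data. Weight init is Glorot uniform
(zero biases) for every layer; we verified this is markedly more stable for
both the shallow and the deep funnel than He initialization on these data.
There is no train/test split: the model is unsupervised and the entire
dataset is both the training set and the set being embedded.

* **tied**: each decoder matrix is the transpose of its encoder partner at
  all times — the decoder layers own only biases, and gradients from both
  directions accumulate into the shared matrix, so tying is exact after
  every step (asserted in tests via a step callback).
* **pretrained**: greedy layer-wise pretraining trains a one-hidden-layer
  autoencoder per stage (linear output, MSE), saves its encoder/decoder
  weights and biases, and feeds its codes to the next stage down to the code
  size; the saved parameters initialize the full network (stage *i* encoder
  → encoder layer *i*, stage *i* decoder → the mirrored decoder layer).
  Default 20 pretraining epochs per stage.
* **pca_hybrid**: code size 20; after training, a PCA postmap fitted on the
  codes provides the final 2-D embedding.
* **lstm**: each waveform is a length-79 sequence of scalars. Encoder:
  stacked LSTMs (60, 40 returning sequences; 20 returning its final state)
  into a dense tanh code of 2. Decoder: the code repeated 79 times through
  mirrored LSTMs and a per-timestep dense tanh output. BPTT is implemented
  in full and finite-difference-checked. The sequence convention (scalar
  tokens, final-state readout) is our choice; nothing standard exists.
* **ft / wft**: the network trains on the real part of the per-spike FFT
  half-spectrum (length 40 for 79 samples), Blackman-windowed for `wft`;
  the spectra are min-max rescaled to [0, 1] by a scaler fitted at training
  time and reused at encode time. The real part is the default descriptor
  because it carries the most separability among the descriptor options.
* **orthogonal**: adds `w_o · Σ‖WᵀW − I‖²_F` over all weight matrices and
  `w_d · Σ_{i≠j} Cov(z)_ij²` over the batch code covariance. The
  coefficients are unstated in the literature this follows; both default to
  0.01 and are exposed.
* **contractive**: the loss adds `λ‖J_f(x)‖²_F`, the squared Frobenius norm
  of the encoder Jacobian, summed over the batch (λ default 1e-4, exposed).
  The *reported* penalty uses the exact Jacobian, computed as the chain
  product `J = D_L W_L … D_1 W_1` with `D_l = diag(σ'(z_l))`. The *training
  gradient* uses a Hutchinson estimator: a forward-mode JVP with one
  Gaussian probe per sample gives `‖Jε‖²` with `E_ε‖Jε‖² = ‖J‖²_F` exactly,
  and its parameter gradient is backpropagated analytically (including the
  σ''(z) path). This avoids the double-backprop machinery an exact deep
  Jacobian-norm gradient would need while staying unbiased; both the exact
  Jacobian and the estimator gradient are finite-difference-checked to
  better than 1e-8 in the tests.

## Preprocessing

Alignment shifts each spike so its reference peak (maximum by default;
minimum selectable) lands at a common index via
`new_start = old_start − (index_align − peak)`. The default target is the
middle of the window (`floor(n/2) = 39` for 79 samples), which keeps both
the pre- and post-peak course informative. Two modes: `recut-from-signal`
re-cuts the window from the continuous trace (needs per-spike window
origins, carried in `LabeledSpikeSet.origin_indices`; edge spikes are
skipped and logged) and `shift-extracted` shifts within the fixed window,
replicating the edge value into vacated samples — chosen so no spike is
discarded when only waveforms exist.

Scaling is one global min-max affine map of the whole set into [0, 1].
Per-spike scaling would destroy the amplitude differences that separate
units, so it is deliberately global; the scaler can be fitted once and
reused (`UnitScaler`). Shuffling applies one seeded permutation to
waveforms and labels jointly — benchmark files store spikes grouped by
unit, which would otherwise make early mini-batches single-class.

Fourier descriptors are computed over the non-redundant rFFT half-spectrum
(the output dimensionality is not standardized; the half-spectrum is the
minimal faithful choice). `concatenation` stacks real and imaginary parts
and is exactly invertible; the phase of a zero coefficient is defined as 0.

## Synthetic data

`SimulationSpec` emulates the structure of the public benchmark
simulations: 79-sample spikes at 24 kHz; per-unit Poisson firing with mean
rates in [0.1, 2] Hz; single-unit amplitudes from normal draws min-max
rescaled into [0.9, 2] per dataset; one multi-unit background cluster
(label 0) mixing 20 shapes at fixed amplitude 0.5, each shape firing
independently at 0.25 Hz (5 Hz composite); at least 0.3 ms between any two
spikes; additive Gaussian noise; optional uniform peak jitter to exercise
alignment. Choices the source conditions leave open, fixed once here:

* **Templates** are procedural biphasic shapes (a sharp positive Gaussian
  lobe minus a broader delayed negative lobe, peak normalized to 1) with
  unit-specific widths/asymmetry, since the original recorded shape library
  cannot be shipped.
* **Amplitude structure**: each unit gets a characteristic mean (its
  electrode distance) with within-unit spread 0.15 in draw units before the
  global rescale — without a per-unit mean, amplitude would not separate
  units, which contradicts how recorded data behave.
* **duration** defaults to 600 s, which at these rates yields datasets of a
  few thousand spikes, the scale of the benchmark simulations.
* **noise_sd** defaults to 0.05 (≈ 5–10% of single-unit peak amplitude);
  the simulations' noise model is unspecified, so it is exposed.

`generate_recording` places the same templates on a noise trace at
Poisson-thinned times honoring the minimum separation and returns ground
truth. What the generator does **not** model: electrode drift, waveform
overlap/superposition, correlated or non-Gaussian noise, multi-channel
geometry, bursting. Tests passing on this generator therefore demonstrate
correctness of the pipeline and qualitative reproductions (alignment
benefit, learning-rate collapse), not performance on real tissue.

## Detection

Zero-phase (forward-backward) Butterworth band-pass, order 3, 300–7000 Hz
defaults; threshold at k·SD of the filtered trace with k = 4 (the customary
3–5 range); one detection per suprathreshold excursion at its local
maximum, with a 0.3 ms refractory lockout (the minimum inter-spike
separation, since no lockout is standard); windows of 79 samples with
`floor(w/2)` pre-peak samples, edge windows skipped and logged. At 4 SD an
occasional noise excursion is detected — this is realistic and recall, not
precision, is the asserted property.

## Metrics

ARI, AMI and V-Measure are computed from the contingency table; AMI uses
the **exact** permutation-model expected MI (hypergeometric sum, log-gamma
stabilized) rather than Monte-Carlo, for determinism. Degenerate-case
conventions, logged when triggered: both labelings trivial → ARI and AMI
are 1; zero entropy → homogeneity/completeness 1; coincident centroids
(DBS) and zero within-cluster dispersion (CHS) raise; singleton clusters
score 0 in the silhouette. Internal metrics use ground-truth labels
whenever ground truth exists (they then characterize the embedding) and
predicted labels otherwise. Borda aggregation converts per-metric ranks
(Davies-Bouldin inverted) to points `m − rank`, ties sharing averaged
points. K-Means is scikit-learn's, k-means++, `n_init=10`, seeded; k equals
the number of ground-truth clusters on labeled data and is a required
parameter otherwise.

Silhouette/DBS/CHS distances are computed with exact per-pair norms
(`scipy.spatial.distance.cdist`), not the quadratic-expansion shortcut, so
they agree with direct-definition loop oracles to ~1e-15 (the shortcut is
only accurate to ~1e-8).

## Experiment drivers and problem sizes

The benchmark pipeline is align → scale → shuffle → extract → K-Means →
metrics; labels touch only the metric computation and the choice of k.
The committed experiment configurations use the fast presets: 50 epochs for
sweeps and alignment runs, 100 for the deep-variant learning-rate contrast,
generated datasets of 300–600 s (≈1.5–4.5 k spikes) — sizes at which every
reported contrast is already stable across seeds. Runtime is logged per row
and never asserted.

## Known limitations

* The LSTM variant is computationally heavy in pure numpy (minutes per fit
  at realistic sizes); it is exercised at reduced size in the tests.
* Isomap on a disconnected neighborhood graph embeds only the largest
  component (dropped rows are NaN-flagged); small neighbor counts on
  clumpy data trigger this.
* The exact file layouts of the public benchmark simulations vary between
  distributions; `load_simulation`'s default variable mapping is a
  documented guess and unknown layouts fail loudly rather than guess.
* Reproductions of published table values that require the downloaded
  benchmark files run only when those files are present locally.
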