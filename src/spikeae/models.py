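"""Autoencoder feature extractors for spike sorting.

Ten variants of a mirrored, symmetric autoencoder whose bottleneck (code)
layer provides the low-dimensional feature space that is clustered
downstream: a shallow dense net (60,40,20), a deep one
(70,60,50,40,30,20,10,5), a weight-tied deep net, a PCA hybrid (code 20
projected to 2 principal components), a greedily pretrained deep net, a
stacked-LSTM net, two Fourier-domain variants (plain and Blackman-windowed
spectra), an orthogonality/decorrelation-regularized net, and a contractive
net penalizing the encoder Jacobian.

Hidden layers use ReLU; code and output layers use tanh (negative values are
needed for reconstruction). Training is Adam at learning rate 1e-3 on MSE,
with an L1 penalty of 1e-7 on the code activations. The whole dataset is used
for training — an autoencoder is unsupervised, so no train/test split is
needed.

The modelling surface follows the model/results convention: build a
:class:`SpikeAutoencoder` from data and a config, call :meth:`fit`, and get a
:class:`TrainedEncoder` carrying the loss history, the encoder, and
``summary()``.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .datasets import LabeledSpikeSet
from .nn import (
    Adam,
    Dense,
    LSTM,
    contractive_forward_backward,
    encoder_jacobians,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VARIANTS",
    "AEConfig",
    "FeatureSet",
    "SpikeAutoencoder",
    "TrainedEncoder",
    "build_model",
    "train",
    "encode",
    "greedy_pretrain",
    "contractive_loss",
    "orthogonal_penalties",
    "pca_ae_embed",
    "variant_config",
]

VARIANTS = (
    "shallow",
    "deep",
    "tied",
    "pca_hybrid",
    "pretrained",
    "lstm",
    "ft",
    "wft",
    "orthogonal",
    "contractive",
)

_DEEP_LAYERS = [70, 60, 50, 40, 30, 20, 10, 5]
_SHALLOW_LAYERS = [60, 40, 20]


@dataclass
class FeatureSet:
    """An n_spikes x d embedding, rows aligned with the source spike order."""

    features: np.ndarray
    method_tag: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D")

    @property
    def d(self) -> int:
        return self.features.shape[1]

    @property
    def n(self) -> int:
        return self.features.shape[0]


@dataclass
class AEConfig:
    """Architecture and training hyperparameters of one variant."""

    variant: str = "deep"
    input_dim: int = 79
    encoder_layers: list = field(default_factory=lambda: list(_DEEP_LAYERS))
    code_size: int = 2
    hidden_activation: str = "relu"
    code_and_output_activation: str = "tanh"
    code_l1: float = 1e-7
    learning_rate: float = 0.001
    epochs: int = 500
    loss: str = "mse"
    contractive_lambda: float = 1e-4
    orthogonality_weight: float = 0.01
    decorrelation_weight: float = 0.01
    batch_size: int = 64
    pretrain_epochs: int = 20

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.code_size < 1:
            raise ValueError("code_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if any(
            a <= b for a, b in zip(self.encoder_layers, self.encoder_layers[1:])
        ):
            raise ValueError("encoder_layers must be strictly decreasing")
        if any(w <= self.code_size for w in self.encoder_layers):
            raise ValueError("all encoder widths must exceed code_size")
        if self.loss not in ("mse", "contractive"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.contractive_lambda < 0:
            raise ValueError("contractive_lambda must be >= 0")


def variant_config(variant: str, input_dim: int = 79, **overrides) -> AEConfig:
    """Canonical configuration for a named variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    kw: dict = {"variant": variant, "input_dim": input_dim}
    if variant == "shallow":
        kw["encoder_layers"] = list(_SHALLOW_LAYERS)
    elif variant == "pca_hybrid":
        kw["encoder_layers"] = [70, 60, 50, 40, 30]
        kw["code_size"] = 20
    elif variant == "lstm":
        kw["encoder_layers"] = list(_SHALLOW_LAYERS)
    else:
        kw["encoder_layers"] = list(_DEEP_LAYERS)
    if variant == "contractive":
        kw["loss"] = "contractive"
    kw.update(overrides)
    return AEConfig(**kw)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

class DenseNetwork:
    """Mirrored dense autoencoder: enc widths, code, reversed widths, output.

    ``n_layers`` counts the weight-bearing hidden layers plus the code layer
    (the output reconstruction layer is not counted), so the deep variant
    reports 8 + 1 + 8 = 17.
    """

    def __init__(self, config: AEConfig, rng: np.random.Generator, net_input_dim=None):
        d_in = net_input_dim or config.input_dim
        enc = list(config.encoder_layers)
        hid = config.hidden_activation
        out_act = config.code_and_output_activation
        tied = config.variant == "tied"

        self.layers: list[Dense] = []
        prev = d_in
        for w in enc:
            self.layers.append(Dense(prev, w, hid, rng))
            prev = w
        self.code_index = len(enc)
        self.layers.append(Dense(prev, config.code_size, out_act, rng))
        prev = config.code_size
        # decoder mirrors the encoder (tied layers transpose their partner)
        enc_stack = self.layers[: len(enc) + 1]
        for j, w in enumerate(reversed(enc)):
            partner = enc_stack[len(enc) - j] if tied else None
            self.layers.append(Dense(prev, w, hid, rng, tied_to=partner))
            prev = w
        partner = enc_stack[0] if tied else None
        self.layers.append(Dense(prev, d_in, out_act, rng, tied_to=partner))
        self.code: np.ndarray | None = None

    @property
    def encoder_layers(self) -> list[Dense]:
        return self.layers[: self.code_index + 1]

    @property
    def n_layers(self) -> int:
        return len(self.layers) - 1  # hidden + code; output excluded

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers)

    def forward(self, X: np.ndarray) -> np.ndarray:
        A = X
        for i, layer in enumerate(self.layers):
            A = layer.forward(A)
            if i == self.code_index:
                self.code = A
        return A

    def backward(self, dOut: np.ndarray, dCode: np.ndarray | None = None) -> None:
        g = dOut
        for i in range(len(self.layers) - 1, -1, -1):
            if i == self.code_index and dCode is not None:
                g = g + dCode
            g = self.layers[i].backward(g)

    def encode(self, X: np.ndarray) -> np.ndarray:
        A = X
        for layer in self.encoder_layers:
            A = layer.forward(A)
        return A

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()


class LSTMNetwork:
    """Stacked-LSTM autoencoder: each waveform is a length-T sequence of
    scalars; recurrent layers return sequences and the last one feeds its
    final state to a dense tanh code. The decoder repeats the code T times
    through mirrored LSTMs and a per-timestep dense output layer."""

    def __init__(self, config: AEConfig, rng: np.random.Generator, net_input_dim=None):
        self.T = net_input_dim or config.input_dim
        widths = list(config.encoder_layers)
        self.enc_lstm = []
        prev = 1
        for w in widths[:-1]:
            self.enc_lstm.append(LSTM(prev, w, rng, return_sequences=True))
            prev = w
        self.enc_lstm.append(LSTM(prev, widths[-1], rng, return_sequences=False))
        self.code_layer = Dense(
            widths[-1], config.code_size, config.code_and_output_activation, rng
        )
        self.dec_lstm = []
        prev = config.code_size
        for w in reversed(widths):
            self.dec_lstm.append(LSTM(prev, w, rng, return_sequences=True))
            prev = w
        self.out_layer = Dense(prev, 1, config.code_and_output_activation, rng)
        self.layers = self.enc_lstm + [self.code_layer] + self.dec_lstm + [self.out_layer]
        self.code_index = len(self.enc_lstm)
        self.code: np.ndarray | None = None

    @property
    def n_layers(self) -> int:
        return len(self.enc_lstm) + 1 + len(self.dec_lstm)

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers)

    def forward(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        A = X[:, :, None]
        for l in self.enc_lstm:
            A = l.forward(A)
        self.code = self.code_layer.forward(A)
        B = np.repeat(self.code[:, None, :], self.T, axis=1)
        for l in self.dec_lstm:
            B = l.forward(B)
        flat = self.out_layer.forward(B.reshape(n * self.T, -1))
        return flat.reshape(n, self.T)

    def backward(self, dOut: np.ndarray, dCode: np.ndarray | None = None) -> None:
        n = dOut.shape[0]
        g = self.out_layer.backward(dOut.reshape(n * self.T, 1))
        g = g.reshape(n, self.T, -1)
        for l in reversed(self.dec_lstm):
            g = l.backward(g)
        g = g.sum(axis=1)  # repeat-vector adjoint
        if dCode is not None:
            g = g + dCode
        g = self.code_layer.backward(g)
        for l in reversed(self.enc_lstm):
            g = l.backward(g)

    def encode(self, X: np.ndarray) -> np.ndarray:
        A = X[:, :, None]
        for l in self.enc_lstm:
            A = l.forward(A)
        return self.code_layer.forward(A)

    def zero_grad(self) -> None:
        for l in self.layers:
            l.zero_grad()


# ---------------------------------------------------------------------------
# Results object
# ---------------------------------------------------------------------------

class _MinMax:
    """Tiny global min-max scaler for the Fourier variants' inputs."""

    def __init__(self, lo=0.0, hi=1.0):
        self.lo, self.hi = lo, hi

    def fit(self, X):
        self.lo, self.hi = float(X.min()), float(X.max())
        if self.hi == self.lo:
            self.hi = self.lo + 1.0
        return self

    def transform(self, X):
        return (X - self.lo) / (self.hi - self.lo)


class TrainedEncoder:
    """Results object of a fitted (or to-be-fitted) autoencoder variant.

    Carries the config, the network parameters, the per-epoch loss history,
    and, for the PCA hybrid, the fitted linear postmap. ``encode`` maps
    spikes to the code-layer features; ``features`` additionally applies the
    postmap where one exists.
    """

    def __init__(self, config: AEConfig, network=None):
        config.validate()
        self.config = config
        self.network = network
        self.loss_history: list[float] = []
        self.fitted_postmap = None  # sklearn PCA for pca_hybrid
        self.input_scaler: _MinMax | None = None  # ft/wft input scaling
        self.trained = False

    # -- construction ------------------------------------------------------
    @classmethod
    def build(cls, config: AEConfig, seed: int = 0) -> "TrainedEncoder":
        config.validate()
        rng = np.random.default_rng(seed)
        net_dim = config.input_dim
        if config.variant in ("ft", "wft"):
            net_dim = config.input_dim // 2 + 1  # real half-spectrum length
        if config.variant == "lstm":
            net = LSTMNetwork(config, rng, net_input_dim=config.input_dim)
        else:
            net = DenseNetwork(config, rng, net_input_dim=net_dim)
        return cls(config, net)

    # -- data plumbing -----------------------------------------------------
    def _prepare(self, spikes, fit_scaler: bool = False) -> np.ndarray:
        X = spikes.waveforms if isinstance(spikes, LabeledSpikeSet) else np.asarray(spikes)
        if self.config.variant in ("ft", "wft"):
            from .preprocessing import FourierSpec, fourier_features

            window = "blackman" if self.config.variant == "wft" else "none"
            src = (
                spikes
                if isinstance(spikes, LabeledSpikeSet)
                else LabeledSpikeSet(X, sampling_rate=1.0)
            )
            F = fourier_features(src, FourierSpec(part="real", window=window)).features
            if fit_scaler or self.input_scaler is None:
                self.input_scaler = _MinMax().fit(F)
            X = self.input_scaler.transform(F)
        return X

    # -- training ----------------------------------------------------------
    def fit(self, spikes, seed: int = 0, step_callback=None) -> "TrainedEncoder":
        """Train for ``config.epochs`` full passes of shuffled mini-batches."""
        cfg = self.config
        X = self._prepare(spikes, fit_scaler=True)
        if X.shape[1] != (
            self.network.T
            if isinstance(self.network, LSTMNetwork)
            else self.network.layers[0].n_in
        ):
            raise ValueError(
                f"input dimension {X.shape[1]} does not match the network input"
            )
        rng = np.random.default_rng(seed)

        if cfg.variant == "pretrained" and not self.loss_history:
            store = greedy_pretrain(cfg, spikes, seed)
            self.load_initial_parameters(store)

        opt = Adam(self.network.layers, lr=cfg.learning_rate)
        n = X.shape[0]
        bs = min(cfg.batch_size, n)
        self.loss_history = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            total, nb = 0.0, 0
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                Xb = X[idx]
                loss = self._train_step(Xb, opt, rng)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}: {loss!r} "
                        f"(variant={cfg.variant}, lr={cfg.learning_rate})"
                    )
                total += loss
                nb += 1
                if step_callback is not None:
                    step_callback(self.network)
            self.loss_history.append(total / nb)
        self.trained = True

        if cfg.variant == "pca_hybrid":
            from sklearn.decomposition import PCA

            codes = self._codes(X)
            if codes.shape[0] < 2:
                raise ValueError("pca_hybrid postmap needs at least 2 samples")
            self.fitted_postmap = PCA(n_components=2, random_state=0).fit(codes)
        return self

    def _train_step(self, Xb, opt, rng) -> float:
        cfg = self.config
        net = self.network
        net.zero_grad()
        recon = net.forward(Xb)
        m = Xb.shape[0]
        err = recon - Xb
        loss = float(np.mean(err * err))
        dOut = 2.0 * err / err.size

        code = net.code
        dCode = np.zeros_like(code)
        if cfg.code_l1 > 0:
            loss += cfg.code_l1 * float(np.abs(code).sum()) / m
            dCode += cfg.code_l1 * np.sign(code) / m

        if cfg.variant == "orthogonal" and m > 1:
            p_dec, dZc = _decorrelation_penalty_and_grad(code)
            loss += cfg.decorrelation_weight * p_dec
            dCode += cfg.decorrelation_weight * dZc

        net.backward(dOut, dCode=dCode)

        if cfg.variant == "orthogonal":
            p_orth = 0.0
            for layer in net.layers:
                if isinstance(layer, Dense) and layer.tied_to is None:
                    W = layer.W_own
                    G = W.T @ W - np.eye(W.shape[1])
                    p_orth += float(np.sum(G * G))
                    layer.dW += cfg.orthogonality_weight * 4.0 * (W @ G)
            loss += cfg.orthogonality_weight * p_orth

        if cfg.loss == "contractive":
            loss += contractive_forward_backward(
                net.encoder_layers, Xb, rng, cfg.contractive_lambda
            )

        opt.step()
        return loss

    # -- inference ---------------------------------------------------------
    def _codes(self, X: np.ndarray) -> np.ndarray:
        return self.network.encode(X)

    def encode(self, spikes) -> FeatureSet:
        """Code-layer features, one row per input spike (order preserved)."""
        if not self.trained:
            raise RuntimeError("model is not trained; call fit() first")
        X = self._prepare(spikes)
        return FeatureSet(self._codes(X), method_tag=self.config.variant)

    def features(self, spikes) -> FeatureSet:
        """Final embedding: the code, post-mapped to 2-D for pca_hybrid."""
        if self.config.variant == "pca_hybrid":
            return pca_ae_embed(self, spikes)
        return self.encode(spikes)

    def reconstruct(self, spikes) -> np.ndarray:
        X = self._prepare(spikes)
        return self.network.forward(X)

    # -- initialization / persistence -------------------------------------
    def load_initial_parameters(self, store: dict) -> None:
        """Install a greedy-pretraining parameter store as the init."""
        for key, (W, b) in store["init"].items():
            layer = self.network.layers[key]
            if layer.W_own is not None:
                if layer.W_own.shape != W.shape:
                    raise ValueError(
                        f"layer {key}: expected {layer.W_own.shape}, got {W.shape}"
                    )
                layer.W_own[...] = W
            layer.b[...] = b

    def mean_jacobian_norm(self, spikes) -> float:
        """Mean squared Frobenius norm of the encoder Jacobian over spikes."""
        X = self._prepare(spikes)
        J = encoder_jacobians(self.network.encoder_layers, X)
        return float(np.mean(np.sum(J * J, axis=(1, 2))))

    def summary(self) -> str:
        cfg = self.config
        buf = io.StringIO()
        buf.write("Spike autoencoder feature extractor\n")
        buf.write("=" * 43 + "\n")
        rows = [
            ("variant", cfg.variant),
            ("input dim", cfg.input_dim),
            ("encoder widths", tuple(cfg.encoder_layers)),
            ("code size", cfg.code_size),
            ("layers (hidden+code)", self.network.n_layers),
            ("parameters", self.network.n_params),
            ("epochs trained", len(self.loss_history)),
            ("learning rate", cfg.learning_rate),
            ("loss", cfg.loss),
        ]
        if self.loss_history:
            rows.append(("final training loss", f"{self.loss_history[-1]:.6f}"))
        for k, v in rows:
            buf.write(f"{k:<22}{v}\n")
        return buf.getvalue()

    def save(self, path) -> None:
        payload = {"config_json": np.array(json.dumps(asdict(self.config)))}
        for i, layer in enumerate(self.network.layers):
            for name, p, _ in layer.params():
                payload[f"layer{i}_{name}"] = p
        payload["loss_history"] = np.asarray(self.loss_history)
        if self.input_scaler is not None:
            payload["input_scale"] = np.array([self.input_scaler.lo, self.input_scaler.hi])
        if self.fitted_postmap is not None:
            payload["postmap_components"] = self.fitted_postmap.components_
            payload["postmap_mean"] = self.fitted_postmap.mean_
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "TrainedEncoder":
        with np.load(path, allow_pickle=False) as z:
            cfg = AEConfig(**json.loads(str(z["config_json"])))
            model = cls.build(cfg, seed=0)
            for i, layer in enumerate(model.network.layers):
                for name, p, _ in layer.params():
                    p[...] = z[f"layer{i}_{name}"]
            model.loss_history = list(z["loss_history"])
            model.trained = len(model.loss_history) > 0
            if "input_scale" in z:
                lo, hi = z["input_scale"]
                model.input_scaler = _MinMax(float(lo), float(hi))
            if "postmap_components" in z:
                from sklearn.decomposition import PCA

                pca = PCA(n_components=z["postmap_components"].shape[0])
                pca.components_ = z["postmap_components"]
                pca.mean_ = z["postmap_mean"]
                model.fitted_postmap = pca
        return model


class SpikeAutoencoder:
    """Model object: spike data plus a variant configuration.

    ``fit(seed)`` trains and returns a :class:`TrainedEncoder`.
    """

    def __init__(self, spikes, config: AEConfig | str | None = None, **overrides):
        if isinstance(config, str):
            dim = (
                spikes.n_samples
                if isinstance(spikes, LabeledSpikeSet)
                else np.asarray(spikes).shape[1]
            )
            config = variant_config(config, input_dim=dim, **overrides)
        elif config is None:
            dim = (
                spikes.n_samples
                if isinstance(spikes, LabeledSpikeSet)
                else np.asarray(spikes).shape[1]
            )
            config = variant_config("deep", input_dim=dim, **overrides)
        config.validate()
        self.spikes = spikes
        self.config = config

    @classmethod
    def from_dataframe(cls, df, config=None, label_column="label", **overrides):
        """Build from a DataFrame of waveforms (one spike per row)."""
        cols = [c for c in df.columns if c != label_column]
        W = df[cols].to_numpy(dtype=float)
        labels = df[label_column].to_numpy() if label_column in df.columns else None
        spikes = LabeledSpikeSet(W, sampling_rate=24000.0, labels=labels)
        return cls(spikes, config, **overrides)

    def fit(self, seed: int = 0, step_callback=None) -> TrainedEncoder:
        model = TrainedEncoder.build(self.config, seed=seed)
        return model.fit(self.spikes, seed=seed, step_callback=step_callback)


# ---------------------------------------------------------------------------
# Spec-surface operations (thin wrappers over the objects above)
# ---------------------------------------------------------------------------

def build_model(config: AEConfig, seed: int = 0) -> TrainedEncoder:
    """Build an untrained encoder/decoder for the given configuration."""
    return TrainedEncoder.build(config, seed=seed)


def train(model: TrainedEncoder, spikes, seed: int = 0) -> TrainedEncoder:
    """Train a built model on the (scaled) spikes; labels are ignored."""
    return model.fit(spikes, seed=seed)


def encode(model: TrainedEncoder, spikes) -> FeatureSet:
    return model.encode(spikes)


def greedy_pretrain(config: AEConfig, spikes, seed: int = 0) -> dict:
    """Greedy layer-wise pretraining.

    Stage by stage: train a one-hidden-layer autoencoder, save its weights
    and biases, feed its codes to the next stage, repeat until the code size
    is reached, and assemble everything as the full model's initialization.
    The first stage for input 79 and width 70 therefore holds 79x70 encoder
    weights, 70x79 decoder weights and 70 hidden biases, and emits codes of
    size 70.
    """
    config.validate()
    X = spikes.waveforms if isinstance(spikes, LabeledSpikeSet) else np.asarray(spikes)
    widths = [X.shape[1]] + list(config.encoder_layers) + [config.code_size]
    k_e = len(config.encoder_layers)
    rng = np.random.default_rng(seed)

    stages = []
    cur = X
    for s in range(len(widths) - 1):
        d_in, d_h = widths[s], widths[s + 1]
        hid_act = config.hidden_activation if s < k_e else config.code_and_output_activation
        enc = Dense(d_in, d_h, hid_act, rng)
        dec = Dense(d_h, d_in, "linear", rng)
        opt = Adam([enc, dec], lr=config.learning_rate)
        n = cur.shape[0]
        bs = min(config.batch_size, n)
        for epoch in range(config.pretrain_epochs):
            order = rng.permutation(n)
            for start in range(0, n, bs):
                Xb = cur[order[start : start + bs]]
                enc.zero_grad()
                dec.zero_grad()
                recon = dec.forward(enc.forward(Xb))
                err = recon - Xb
                loss = float(np.mean(err * err))
                if not np.isfinite(loss):
                    raise RuntimeError(f"pretraining stage {s} diverged (loss={loss!r})")
                enc.backward(dec.backward(2.0 * err / err.size))
                opt.step()
        codes = enc.forward(cur)
        stages.append(
            {
                "W_enc": enc.W_own.copy(),
                "b_enc": enc.b.copy(),
                "W_dec": dec.W_own.copy(),
                "b_dec": dec.b.copy(),
                "code_dim": d_h,
            }
        )
        cur = codes

    # layer ordering in DenseNetwork: enc 0..k_e-1, code k_e, dec, output
    init = {}
    n_total = 2 * (k_e + 1)
    for s, st in enumerate(stages):
        init[s] = (st["W_enc"], st["b_enc"])
        init[n_total - 1 - s] = (st["W_dec"], st["b_dec"])
    return {"stages": stages, "init": init}


def contractive_loss(
    inputs: np.ndarray,
    reconstructions: np.ndarray,
    code_jacobian: np.ndarray,
    lam: float,
) -> float:
    """Batch-summed contractive objective:
    sum_x [ L(x, g(f(x))) + lambda * ||J_f(x)||_F^2 ].

    ``code_jacobian`` holds one encoder Jacobian per sample
    (shape (n, d_in, d_code) or (n, d_code, d_in)).
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    inputs = np.asarray(inputs, dtype=float)
    reconstructions = np.asarray(reconstructions, dtype=float)
    J = np.asarray(code_jacobian, dtype=float)
    err = reconstructions - inputs
    rec = float(np.sum(np.mean(err * err, axis=1)))
    pen = float(lam * np.sum(J * J))
    return rec + pen


def orthogonal_penalties(encoder_weights, codes: np.ndarray):
    """(orthogonality, decorrelation) penalties of the orthogonal variant.

    Orthogonality: sum over weight matrices of ||W^T W - I||_F^2.
    Decorrelation: sum of squared off-diagonal entries of the batch code
    covariance (undefined for a single-sample batch).
    """
    if isinstance(encoder_weights, np.ndarray):
        encoder_weights = [encoder_weights]
    p_orth = 0.0
    for W in encoder_weights:
        W = np.asarray(W, dtype=float)
        G = W.T @ W - np.eye(W.shape[1])
        p_orth += float(np.sum(G * G))
    codes = np.asarray(codes, dtype=float)
    if codes.shape[0] < 2:
        raise ValueError("decorrelation penalty needs a batch of size >= 2")
    C = np.cov(codes, rowvar=False)
    C = np.atleast_2d(C)
    p_dec = float(np.sum(C * C) - np.sum(np.diag(C) ** 2))
    return p_orth, p_dec


def _decorrelation_penalty_and_grad(codes: np.ndarray):
    """Penalty sum_{i!=j} Cov_ij^2 and its gradient w.r.t. the codes."""
    m = codes.shape[0]
    Zc = codes - codes.mean(axis=0)
    C = (Zc.T @ Zc) / (m - 1)
    M = 1.0 - np.eye(C.shape[0])
    p = float(np.sum((C * M) ** 2))
    dZc = (4.0 / (m - 1)) * Zc @ (C * M)
    dZ = dZc - dZc.mean(axis=0)
    return p, dZ


def pca_ae_embed(model: TrainedEncoder, spikes) -> FeatureSet:
    """Project the PCA-hybrid variant's 20-d codes onto 2 principal axes."""
    if model.config.variant != "pca_hybrid":
        raise ValueError("pca_ae_embed applies to the pca_hybrid variant")
    if model.fitted_postmap is None:
        raise RuntimeError("postmap not fitted; train the model first")
    codes = model.encode(spikes).features
    return FeatureSet(model.fitted_postmap.transform(codes), method_tag="pca_hybrid")
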