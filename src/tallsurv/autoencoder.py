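"""Five-layer autoencoder exposing 100 bottleneck features per sample.

Architecture: input d -> 500 -> 100 (bottleneck) -> 500 -> d, tanh hidden
activations (relu/sigmoid selectable), identity output, 50% dropout after each hidden layer during
training only, mean-squared reconstruction error minimised with Adam for a
fixed number of epochs (default 10). Implemented as a compact seeded numpy
network: weight initialisation, minibatch shuffling and dropout masks all
derive from one integer seed, so training is bit-reproducible on a fixed
BLAS, and encoding is deterministic (dropout disabled at inference).

The bottleneck activations are the latent features handed to Cox screening
and K-means subtyping downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from tallsurv.io_preprocess import EncoderInputTransform, ExpressionMatrix


@dataclass
class AutoencoderSpec:
    """Architecture and training hyperparameters.

    ``hidden_widths`` must have odd length; the middle entry is the
    bottleneck (default 100, per the 500-100-500 design).
    """

    hidden_widths: tuple[int, ...] = (500, 100, 500)
    dropout_rate: float = 0.5
    epochs: int = 10
    hidden_activation: str = "tanh"
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_widths) % 2 == 0 or not self.hidden_widths:
            raise ValueError("hidden_widths must have odd length (middle = bottleneck)")
        if any(w <= 0 for w in self.hidden_widths):
            raise ValueError("layer widths must be positive")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.hidden_activation not in ("relu", "tanh", "sigmoid"):
            raise ValueError(f"unsupported hidden activation {self.hidden_activation!r}")
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")

    @property
    def bottleneck_width(self) -> int:
        return self.hidden_widths[len(self.hidden_widths) // 2]

    def layer_widths(self, d: int) -> list[int]:
        return [d, *self.hidden_widths, d]


@dataclass
class LatentFeatures:
    """Samples x bottleneck-width latent feature matrix."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.sample_ids):
            raise ValueError("latent feature matrix must be n_samples x width")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("latent features contain non-finite values")


@dataclass
class EncoderModel:
    """Trained autoencoder: weights, the gene set and input transform it expects."""

    spec: AutoencoderSpec
    gene_ids: list[str]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    loss_history: list[float] = field(default_factory=list)  # [initial, epoch1, ..., epochE]
    transform: EncoderInputTransform | None = None

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def bottleneck_layer(self) -> int:
        return (len(self.weights) + 1) // 2  # encoder half ends at the middle hidden layer

    def save(self, path: str | Path) -> None:
        meta = {
            "spec": self.spec.__dict__ | {"hidden_widths": list(self.spec.hidden_widths)},
            "gene_ids": self.gene_ids,
            "loss_history": self.loss_history,
            "transform": None
            if self.transform is None
            else {"gene_ids": self.transform.gene_ids, "pseudocount": self.transform.pseudocount},
        }
        arrays = {f"W{i}": w for i, w in enumerate(self.weights)}
        arrays |= {f"b{i}": b for i, b in enumerate(self.biases)}
        if self.transform is not None:
            arrays["t_log_min"] = self.transform.log_min
            arrays["t_log_max"] = self.transform.log_max
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "EncoderModel":
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        spec_d = dict(meta["spec"])
        spec_d["hidden_widths"] = tuple(spec_d["hidden_widths"])
        spec = AutoencoderSpec(**spec_d)
        n = len(spec.hidden_widths) + 1
        transform = None
        if meta["transform"] is not None:
            transform = EncoderInputTransform(
                gene_ids=meta["transform"]["gene_ids"],
                pseudocount=meta["transform"]["pseudocount"],
                log_min=data["t_log_min"],
                log_max=data["t_log_max"],
            )
        return cls(
            spec=spec,
            gene_ids=list(meta["gene_ids"]),
            weights=[data[f"W{i}"] for i in range(n)],
            biases=[data[f"b{i}"] for i in range(n)],
            loss_history=list(meta["loss_history"]),
            transform=transform,
        )


# activation and its derivative expressed through the (pre-dropout) activation value
_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda a: (a > 0).astype(float)),
    "tanh": (np.tanh, lambda a: 1.0 - a**2),
    "sigmoid": (lambda z: 1.0 / (1.0 + np.exp(-z)), lambda a: a * (1.0 - a)),
}


def _forward_inference(model_w, model_b, X: np.ndarray, activation: str, upto: int | None = None) -> np.ndarray:
    """Deterministic forward pass; ``upto`` stops after that many layers
    (post-activation), None runs the full network."""
    act, _ = _ACTIVATIONS[activation]
    a = X
    n = len(model_w)
    stop = n if upto is None else upto
    for i in range(stop):
        z = a @ model_w[i] + model_b[i]
        a = z if i == n - 1 else act(z)  # identity output layer
    return a


def _check_genes(model: EncoderModel, X: ExpressionMatrix) -> None:
    if list(X.gene_ids) != list(model.gene_ids):
        missing = sorted(set(model.gene_ids) - set(X.gene_ids))
        extra = sorted(set(X.gene_ids) - set(model.gene_ids))
        raise ValueError(
            f"gene set mismatch with the trained encoder: {len(missing)} missing "
            f"(e.g. {missing[:5]}), {len(extra)} unexpected, or order differs"
        )


def train_autoencoder(X: ExpressionMatrix, spec: AutoencoderSpec, transform: EncoderInputTransform | None = None) -> EncoderModel:
    """Train on a prepared (log/min-max) matrix for exactly ``spec.epochs`` epochs.

    Records the mean training reconstruction error before training and after
    each epoch in ``loss_history``. Raises if the loss goes non-finite,
    naming the epoch.
    """
    V = np.asarray(X.values, dtype=float)
    n, d = V.shape
    if n < spec.batch_size:
        raise ValueError(f"need at least batch_size={spec.batch_size} samples, got {n}")
    if not np.all(np.isfinite(V)):
        raise ValueError("training matrix contains non-finite values")

    rng = np.random.default_rng(spec.seed)
    widths = spec.layer_widths(d)
    weights, biases = [], []
    for w_in, w_out in zip(widths[:-1], widths[1:]):
        # Glorot-normal init, matched to the bounded hidden activations
        weights.append(rng.normal(0.0, np.sqrt(2.0 / (w_in + w_out)), size=(w_in, w_out)))
        biases.append(np.zeros(w_out))

    # Adam state
    mw = [np.zeros_like(w) for w in weights]
    vw = [np.zeros_like(w) for w in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t_step = 0
    keep = 1.0 - spec.dropout_rate
    n_layers = len(weights)

    act, dact = _ACTIVATIONS[spec.hidden_activation]

    def full_loss() -> float:
        recon = _forward_inference(weights, biases, V, spec.hidden_activation)
        return float(np.mean((V - recon) ** 2))

    losses = [full_loss()]
    for epoch in range(1, spec.epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, spec.batch_size):
            batch = V[order[start:start + spec.batch_size]]
            # forward with dropout on hidden layers
            dropped = [batch]   # layer inputs (post-dropout)
            raw_acts = [batch]  # pre-dropout activations, for the derivative
            masks = []
            a = batch
            for i in range(n_layers):
                z = a @ weights[i] + biases[i]
                if i == n_layers - 1:
                    a = z
                    raw_acts.append(z)
                else:
                    a = act(z)
                    raw_acts.append(a)
                    if keep < 1.0:
                        mask = (rng.uniform(size=a.shape) < keep) / keep
                        a = a * mask
                        masks.append(mask)
                    else:
                        masks.append(None)
                dropped.append(a)
            resid = dropped[-1] - batch
            batch_loss = float(np.mean(resid**2))
            epoch_losses.append(batch_loss)
            # backward
            grad = 2.0 * resid / resid.size
            t_step += 1
            g_w = [None] * n_layers
            g_b = [None] * n_layers
            delta = grad
            for i in range(n_layers - 1, -1, -1):
                g_w[i] = dropped[i].T @ delta
                g_b[i] = delta.sum(axis=0)
                if i > 0:
                    delta = delta @ weights[i].T
                    if masks[i - 1] is not None:
                        delta = delta * masks[i - 1]
                    delta = delta * dact(raw_acts[i])
            for i in range(n_layers):
                for g, w, m, v in ((g_w[i], weights[i], mw[i], vw[i]), (g_b[i], biases[i], mb[i], vb[i])):
                    m *= beta1
                    m += (1 - beta1) * g
                    v *= beta2
                    v += (1 - beta2) * g**2
                    m_hat = m / (1 - beta1**t_step)
                    v_hat = v / (1 - beta2**t_step)
                    w -= spec.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        if not np.isfinite(np.mean(epoch_losses)):
            raise RuntimeError(f"non-finite training loss at epoch {epoch}")
        losses.append(full_loss())

    return EncoderModel(
        spec=spec,
        gene_ids=list(X.gene_ids),
        weights=weights,
        biases=biases,
        loss_history=losses,
        transform=transform,
    )


def encode(model: EncoderModel, X: ExpressionMatrix) -> LatentFeatures:
    """Bottleneck activations in inference mode (no dropout)."""
    _check_genes(model, X)
    h = _forward_inference(model.weights, model.biases, np.asarray(X.values, dtype=float),
                           model.spec.hidden_activation, upto=model.bottleneck_layer)
    return LatentFeatures(list(X.sample_ids), h)


def reconstruction_error(model: EncoderModel, X: ExpressionMatrix) -> float:
    """Mean squared entry-wise difference between X and its reconstruction."""
    _check_genes(model, X)
    V = np.asarray(X.values, dtype=float)
    recon = _forward_inference(model.weights, model.biases, V, model.spec.hidden_activation)
    return float(np.mean((V - recon) ** 2))
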