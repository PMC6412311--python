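"""Sparse stacked auto-encoder with KL sparsity penalty and dropout.

Each layer is a sigmoid auto-encoder x -> h -> x̂ with h = f(Wx + b),
f the element-wise logistic function.  A layer is trained by minimizing

    sum_i || x̂(x_i) - x_i ||^2  +  α ||W||^2  +  β sum_j KL(p ‖ p̂_j)

where p̂_j is the mean (pre-dropout) activation of hidden unit j over
the batch, p the
sparsity target, α the weight-decay strength and β the sparsity weight.
Layers are trained greedily (layer ℓ auto-encodes the encoded output of
layer ℓ-1); inverted dropout is applied to hidden activations at train
time only.  Supervised fine-tuning attaches a sigmoid output unit and
back-propagates a binary cross-entropy loss through every encoder layer.

Losses are reported in sum-over-samples form; gradient-descent updates
divide gradients by the minibatch size so the learning rate acts
per-sample regardless of batch size.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .io_formats import RpistackError, ValidationError

_PHAT_CLIP = 1e-8


@dataclass
class SaeConfig:
    """Hyper-parameters of the stacked auto-encoder.

    Dropout probability 0.5 and batch size / epoch count of 100 follow
    the training protocol this model family is normally run with; the
    sparsity target p, weight decay α, sparsity weight β and the hidden
    widths are conventional sparse-auto-encoder defaults.
    """

    layer_sizes: tuple[int, ...] = (256, 128)
    sparsity_target: float = 0.05
    weight_decay: float = 1e-4
    sparsity_weight: float = 3.0
    dropout_rate: float = 0.5
    batch_size: int = 100
    epochs: int = 100
    learning_rate: float = 0.01
    fine_tune_learning_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.layer_sizes:
            raise ValidationError("layer_sizes must be non-empty")
        if any(s < 1 for s in self.layer_sizes):
            raise ValidationError("layer sizes must be positive")
        if not 0.0 < self.sparsity_target < 1.0:
            raise ValidationError("sparsity_target must lie in (0, 1)")
        if self.weight_decay < 0 or self.sparsity_weight < 0:
            raise ValidationError("weight_decay and sparsity_weight must be >= 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError("dropout_rate must lie in [0, 1)")
        if self.learning_rate <= 0 or self.fine_tune_learning_rate <= 0:
            raise ValidationError("learning rates must be positive")
        self.layer_sizes = tuple(int(s) for s in self.layer_sizes)


@dataclass
class AeLayer:
    """One auto-encoder layer: sigmoid encoder and sigmoid decoder."""

    w_enc: np.ndarray
    b_enc: np.ndarray
    w_dec: np.ndarray
    b_dec: np.ndarray

    def encode(self, X: np.ndarray) -> np.ndarray:
        return expit(X @ self.w_enc + self.b_enc)

    def decode(self, H: np.ndarray) -> np.ndarray:
        return expit(H @ self.w_dec + self.b_dec)


@dataclass
class SaeModel:
    """A trained stack of auto-encoder layers, optionally with a
    supervised sigmoid head attached by :func:`fine_tune`."""

    layers: list[AeLayer]
    config: SaeConfig
    head_w: np.ndarray | None = None
    head_b: float = 0.0
    history: list[list[float]] = field(default_factory=list, repr=False)
    fine_tune_history: list[float] = field(default_factory=list, repr=False)

    @property
    def input_dim(self) -> int:
        return self.layers[0].w_enc.shape[0]

    @property
    def output_dim(self) -> int:
        return self.layers[-1].w_enc.shape[1]


def kl_divergence(p: float, p_hat) -> np.ndarray | float:
    """Bernoulli Kullback–Leibler divergence KL(p ‖ p̂).

    p must lie strictly inside (0, 1); p̂ is clipped away from {0, 1}
    before evaluation.  Always >= 0, with equality iff p̂ = p.
    """
    if not 0.0 < p < 1.0:
        raise ValidationError(f"sparsity target p = {p} outside (0, 1)")
    p_hat = np.clip(np.asarray(p_hat, dtype=np.float64), _PHAT_CLIP, 1.0 - _PHAT_CLIP)
    out = p * np.log(p / p_hat) + (1.0 - p) * np.log((1.0 - p) / (1.0 - p_hat))
    return float(out) if out.ndim == 0 else out


def _layer_forward(layer: AeLayer, X: np.ndarray, mask: np.ndarray | None):
    H = layer.encode(X)
    Hd = H * mask if mask is not None else H
    Xhat = layer.decode(Hd)
    return H, Hd, Xhat


def layer_loss_and_grads(
    layer: AeLayer,
    X: np.ndarray,
    config: SaeConfig,
    mask: np.ndarray | None = None,
):
    """Sum-form auto-encoder loss of one layer on a batch and its exact
    analytic gradients (including the weight-decay and KL terms).

    ``mask`` is an optional inverted-dropout mask (already scaled by
    1/(1-rate)) applied to hidden activations.  Returns (loss, grads)
    with grads keyed by parameter name.
    """
    a = X.shape[0]
    alpha, beta, p = config.weight_decay, config.sparsity_weight, config.sparsity_target
    H, Hd, Xhat = _layer_forward(layer, X, mask)
    diff = Xhat - X
    rec = float(np.sum(diff * diff))
    # mean activation over the clean (pre-dropout) hidden layer; the
    # inverted-dropout scaling would otherwise push p_hat outside [0, 1]
    p_hat = H.mean(axis=0)
    p_hat_c = np.clip(p_hat, _PHAT_CLIP, 1.0 - _PHAT_CLIP)
    loss = (
        rec
        + alpha * (np.sum(layer.w_enc**2) + np.sum(layer.w_dec**2))
        + beta * float(np.sum(kl_divergence(p, p_hat)))
    )
    dz2 = 2.0 * diff * Xhat * (1.0 - Xhat)
    g_w_dec = Hd.T @ dz2 + 2.0 * alpha * layer.w_dec
    g_b_dec = dz2.sum(axis=0)
    d_hd = dz2 @ layer.w_dec.T
    d_h = d_hd * mask if mask is not None else d_hd
    if beta > 0:
        # d KL / d p_hat, propagated through p_hat = mean over the batch;
        # acts on the clean activation path, bypassing the dropout mask
        d_kl = (-p / p_hat_c + (1.0 - p) / (1.0 - p_hat_c)) / a
        d_h = d_h + beta * d_kl[None, :]
    dz1 = d_h * H * (1.0 - H)
    g_w_enc = X.T @ dz1 + 2.0 * alpha * layer.w_enc
    g_b_enc = dz1.sum(axis=0)
    grads = {"w_enc": g_w_enc, "b_enc": g_b_enc, "w_dec": g_w_dec, "b_dec": g_b_dec}
    return loss, grads


def sae_loss(model: SaeModel, X: np.ndarray, config: SaeConfig) -> float:
    """Total stacked loss: each layer's auto-encoder objective evaluated
    on its own input (the encoded output of the previous layer),
    dropout off."""
    if X.shape[0] == 0:
        raise ValidationError("empty batch")
    total = 0.0
    cur = np.asarray(X, dtype=np.float64)
    for layer in model.layers:
        loss, _ = layer_loss_and_grads(layer, cur, config)
        total += loss
        cur = layer.encode(cur)
    return float(total)


def _init_layer(rng: np.random.Generator, n_in: int, n_hid: int) -> AeLayer:
    # Glorot-uniform initialization for sigmoid units
    lim_enc = np.sqrt(6.0 / (n_in + n_hid))
    lim_dec = np.sqrt(6.0 / (n_hid + n_in))
    return AeLayer(
        w_enc=rng.uniform(-lim_enc, lim_enc, size=(n_in, n_hid)),
        b_enc=np.zeros(n_hid),
        w_dec=rng.uniform(-lim_dec, lim_dec, size=(n_hid, n_in)),
        b_dec=np.zeros(n_in),
    )


def _sgd_step(layer: AeLayer, grads: dict, lr: float, batch_len: int) -> None:
    scale = lr / batch_len
    layer.w_enc -= scale * grads["w_enc"]
    layer.b_enc -= scale * grads["b_enc"]
    layer.w_dec -= scale * grads["w_dec"]
    layer.b_dec -= scale * grads["b_dec"]


def sae_train(X: np.ndarray, config: SaeConfig) -> SaeModel:
    """Greedy layer-wise unsupervised pre-training.

    Expects features scaled to [0, 1] (sigmoid decoder range).  Each
    layer is trained as a sparse auto-encoder on the encoded output of
    the previous one by seeded minibatch gradient descent; the per-epoch
    full-data loss (dropout off) is recorded in ``model.history``.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValidationError("training data must be a non-empty 2-D matrix")
    if not np.isfinite(X).all():
        raise ValidationError("training data contains non-finite values")
    rng = np.random.default_rng(config.seed)
    layers: list[AeLayer] = []
    history: list[list[float]] = []
    cur = X
    n_in = X.shape[1]
    for n_hid in config.layer_sizes:
        layer = _init_layer(rng, n_in, n_hid)
        epoch_losses: list[float] = []
        n = cur.shape[0]
        for _ in range(config.epochs):
            order = rng.permutation(n)
            for start in range(0, n, config.batch_size):
                batch = cur[order[start : start + config.batch_size]]
                mask = None
                if config.dropout_rate > 0:
                    keep = 1.0 - config.dropout_rate
                    mask = (
                        rng.random((batch.shape[0], n_hid)) < keep
                    ).astype(np.float64) / keep
                loss, grads = layer_loss_and_grads(layer, batch, config, mask)
                if not np.isfinite(loss):
                    raise RpistackError(
                        f"non-finite loss while pre-training layer of width "
                        f"{n_hid}; lower the learning rate"
                    )
                _sgd_step(layer, grads, config.learning_rate, batch.shape[0])
            full_loss, _ = layer_loss_and_grads(layer, cur, config)
            epoch_losses.append(float(full_loss))
        layers.append(layer)
        history.append(epoch_losses)
        cur = layer.encode(cur)
        n_in = n_hid
    return SaeModel(layers=layers, config=config, history=history)


def sae_encode(model: SaeModel, X: np.ndarray) -> np.ndarray:
    """Deterministic forward pass through the encoder stack (dropout off).

    Output width equals the last hidden width; entries lie in (0, 1).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise ValidationError(
            f"input width {X.shape[-1] if X.ndim else '?'} does not match "
            f"model input width {model.input_dim}"
        )
    cur = X
    for layer in model.layers:
        cur = layer.encode(cur)
    return cur


def head_predict(model: SaeModel, X: np.ndarray) -> np.ndarray:
    """Probability output of the fine-tuned sigmoid head."""
    if model.head_w is None:
        raise ValidationError("model has no fine-tuned head")
    H = sae_encode(model, X)
    return expit(H @ model.head_w + model.head_b)


class _Adam:
    """Deterministic Adam updates (beta1=0.9, beta2=0.999)."""

    def __init__(self, lr: float):
        self.lr = lr
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, key: str, grad):
        self.m[key] = 0.9 * self.m.get(key, 0.0) + 0.1 * grad
        self.v[key] = 0.999 * self.v.get(key, 0.0) + 0.001 * grad * grad
        m_hat = self.m[key] / (1.0 - 0.9**self.t)
        v_hat = self.v[key] / (1.0 - 0.999**self.t)
        return -self.lr * m_hat / (np.sqrt(v_hat) + 1e-8)


def fine_tune(
    model: SaeModel, X: np.ndarray, labels: np.ndarray, config: SaeConfig
) -> SaeModel:
    """Supervised fine-tuning: attach a sigmoid output unit and
    back-propagate binary cross-entropy through all encoder layers.

    Optimized with Adam at ``config.fine_tune_learning_rate`` — the
    supervised phase has to reshape a pre-trained representation within
    a fixed epoch budget, which plain fixed-step gradient descent does
    not achieve at any stable step size.  Returns a new model (the
    pre-trained input is left untouched); deterministic given
    ``config.seed``.  With ``config.epochs == 0`` the layer parameters
    are returned unchanged.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValidationError("X and labels disagree in length")
    classes = np.unique(y)
    if not np.isin(classes, [0.0, 1.0]).all():
        raise ValidationError("labels must be binary {0, 1}")
    if classes.size < 2:
        raise ValidationError("fine-tuning needs both classes present")
    if X.shape[1] != model.input_dim:
        raise ValidationError("input width does not match model input width")
    tuned = copy.deepcopy(model)
    tuned.head_w = np.zeros(tuned.output_dim)
    tuned.head_b = 0.0
    tuned.fine_tune_history = []
    rng = np.random.default_rng(config.seed + 1)
    opt = _Adam(config.fine_tune_learning_rate)
    alpha = config.weight_decay
    n = X.shape[0]
    eps = 1e-12
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], y[idx]
            a = xb.shape[0]
            # forward with inverted dropout on every hidden layer
            acts = [xb]
            masks = []
            cur = xb
            for layer in tuned.layers:
                cur = layer.encode(cur)
                if config.dropout_rate > 0:
                    keep = 1.0 - config.dropout_rate
                    mask = (rng.random(cur.shape) < keep).astype(np.float64) / keep
                    cur = cur * mask
                    masks.append(mask)
                else:
                    masks.append(None)
                acts.append(cur)
            z = acts[-1] @ tuned.head_w + tuned.head_b
            yhat = expit(z)
            loss = -float(
                np.sum(yb * np.log(yhat + eps) + (1 - yb) * np.log(1 - yhat + eps))
            )
            if not np.isfinite(loss):
                raise RpistackError("non-finite loss during fine-tuning")
            opt.t += 1
            dz = (yhat - yb) / a  # per-sample mean gradient
            g_head_w = acts[-1].T @ dz + 2.0 * alpha * tuned.head_w
            g_head_b = float(dz.sum())
            d_cur = np.outer(dz, tuned.head_w)
            for li in range(len(tuned.layers) - 1, -1, -1):
                layer = tuned.layers[li]
                if masks[li] is not None:
                    d_cur = d_cur * masks[li]
                # recover pre-dropout activation h = sigmoid(z)
                h = layer.encode(acts[li])
                dz_l = d_cur * h * (1.0 - h)
                g_w = acts[li].T @ dz_l + 2.0 * alpha * layer.w_enc
                g_b = dz_l.sum(axis=0)
                d_cur = dz_l @ layer.w_enc.T
                layer.w_enc += opt.step(f"w_enc_{li}", g_w)
                layer.b_enc += opt.step(f"b_enc_{li}", g_b)
            tuned.head_w += opt.step("head_w", g_head_w)
            tuned.head_b += opt.step("head_b", g_head_b)
        # epoch-level training loss for monitoring
        yhat_full = head_predict(tuned, X)
        tuned.fine_tune_history.append(
            -float(
                np.sum(y * np.log(yhat_full + eps) + (1 - y) * np.log(1 - yhat_full + eps))
            )
        )
    return tuned
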