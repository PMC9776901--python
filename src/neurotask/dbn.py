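"""Restricted Boltzmann machines and greedy layer-wise deep belief networks.

An RBM is a bipartite energy-based model over binary visible units ``v``
(length m) and hidden units ``h`` (length n):

    E(v, h) = - v^T W h - b_vis^T v - b_hid^T h
    P(v, h) = exp(-E(v, h)) / Z

With no intra-layer connections the conditionals factorize into
independent logistic units:

    P(h_j = 1 | v) = sigma(sum_i W_ij v_i + b_hid_j)
    P(v_i = 1 | h) = sigma(sum_j W_ij h_j + b_vis_i)

Training uses contrastive divergence (CD-k): the intractable model
expectation of ``v h^T`` is replaced by a k-step alternating Gibbs chain
started at the data.  A deep belief network (DBN) stacks RBMs greedily:
each layer is trained unsupervised on the hidden-unit probabilities of
the layer below, and the forward transform propagates probabilities
(never samples), giving a deterministic map into a compact latent space.

Inputs are expected in [0, 1] and treated as Bernoulli means — the
feature module's min-max scaling guarantees this.  Defaults follow the
mental-task recognition protocol: layer widths 30 -> 15 -> 5 (two
stacked RBMs), CD-5, learning rate 0.001, 1000 epochs, batch size 250.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "RBMParams",
    "TrainConfig",
    "DBNModel",
    "sigmoid",
    "rbm_energy",
    "prob_h_given_v",
    "prob_v_given_h",
    "reconstruction_error",
    "cd_update",
    "train_rbm",
    "train_dbn",
    "dbn_transform",
    "save_dbn",
    "load_dbn",
]

DEFAULT_LAYER_SIZES = (30, 15, 5)


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically safe logistic function."""
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class RBMParams:
    """One RBM: ``W`` is (m visible, n hidden); biases per layer."""

    W: np.ndarray
    b_vis: np.ndarray
    b_hid: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        self.b_vis = np.asarray(self.b_vis, dtype=np.float64)
        self.b_hid = np.asarray(self.b_hid, dtype=np.float64)
        m, n = self.W.shape
        if self.b_vis.shape != (m,) or self.b_hid.shape != (n,):
            raise ValueError("bias shapes inconsistent with the weight matrix")
        if not (np.isfinite(self.W).all() and np.isfinite(self.b_vis).all()
                and np.isfinite(self.b_hid).all()):
            raise ValueError("RBM parameters must be finite")

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    @classmethod
    def initialize(cls, m: int, n: int, rng: np.random.Generator,
                   scale: float = 0.01) -> "RBMParams":
        """Small-Gaussian weights, zero biases — the standard starting point."""
        return cls(scale * rng.standard_normal((m, n)), np.zeros(m), np.zeros(n))


@dataclass
class TrainConfig:
    """Contrastive-divergence hyperparameters (protocol defaults)."""

    k_gibbs: int = 5
    learning_rate: float = 0.001
    epochs: int = 1000
    batch_size: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k_gibbs, self.batch_size) < 1 or self.epochs < 0:
            raise ValueError("k_gibbs and batch_size must be >= 1, epochs >= 0")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")


@dataclass
class DBNModel:
    """Ordered RBM stack; adjacent layer sizes chain."""

    rbms: list[RBMParams]
    layer_sizes: list[int]
    recon_errors: list[list[float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = list(zip(self.layer_sizes[:-1], self.layer_sizes[1:]))
        shapes = [(r.n_visible, r.n_hidden) for r in self.rbms]
        if shapes != expected:
            raise ValueError(
                f"RBM shapes {shapes} do not chain through layer sizes "
                f"{self.layer_sizes}"
            )


def rbm_energy(v: np.ndarray, h: np.ndarray, rbm: RBMParams) -> float:
    """Energy of one joint configuration."""
    v = np.asarray(v, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    if v.shape != (rbm.n_visible,) or h.shape != (rbm.n_hidden,):
        raise ValueError("configuration shapes do not match the RBM")
    return float(-(v @ rbm.W @ h) - rbm.b_vis @ v - rbm.b_hid @ h)


def prob_h_given_v(rbm: RBMParams, v: np.ndarray) -> np.ndarray:
    """Hidden Bernoulli means for one vector or a (batch, m) matrix."""
    v = np.asarray(v, dtype=np.float64)
    return sigmoid(v @ rbm.W + rbm.b_hid)


def prob_v_given_h(rbm: RBMParams, h: np.ndarray) -> np.ndarray:
    """Visible Bernoulli means for one vector or a (batch, n) matrix."""
    h = np.asarray(h, dtype=np.float64)
    return sigmoid(h @ rbm.W.T + rbm.b_vis)


def reconstruction_error(rbm: RBMParams, data: np.ndarray) -> float:
    """Mean squared one-step reconstruction error ||v - P(v | P(h|v))||^2."""
    data = np.atleast_2d(data)
    recon = prob_v_given_h(rbm, prob_h_given_v(rbm, data))
    return float(np.mean(np.sum((data - recon) ** 2, axis=1)))


def cd_update(rbm: RBMParams, batch: np.ndarray, cfg: TrainConfig,
              rng: np.random.Generator) -> RBMParams:
    """One CD-k parameter update on a mini-batch (rows in [0, 1]).

    Positive statistics pair the data with its hidden probabilities; the
    negative chain alternates binary sampling of hidden and visible units
    for ``k_gibbs`` steps, with probabilities used for the final
    statistics (the usual variance-reduction convention).
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=np.float64))
    if batch.size == 0:
        raise ValueError("empty batch")
    if batch.shape[1] != rbm.n_visible:
        raise ValueError("batch width does not match the visible layer")
    n_rows = batch.shape[0]

    ph0 = prob_h_given_v(rbm, batch)
    h = (rng.random(ph0.shape) < ph0).astype(np.float64)
    for _ in range(cfg.k_gibbs):
        pv = prob_v_given_h(rbm, h)
        v = (rng.random(pv.shape) < pv).astype(np.float64)
        ph = prob_h_given_v(rbm, v)
        h = (rng.random(ph.shape) < ph).astype(np.float64)

    lr = cfg.learning_rate
    dW = (batch.T @ ph0 - v.T @ ph) / n_rows
    db_vis = (batch - v).mean(axis=0)
    db_hid = (ph0 - ph).mean(axis=0)
    return RBMParams(rbm.W + lr * dW, rbm.b_vis + lr * db_vis,
                     rbm.b_hid + lr * db_hid)


def train_rbm(data: np.ndarray, n_hidden: int, cfg: TrainConfig,
              rng: np.random.Generator) -> tuple[RBMParams, list[float]]:
    """CD-k training with shuffled mini-batches; logs per-epoch recon error."""
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    rbm = RBMParams.initialize(data.shape[1], n_hidden, rng)
    log = []
    n = data.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            rbm = cd_update(rbm, data[order[start:start + cfg.batch_size]],
                            cfg, rng)
        log.append(reconstruction_error(rbm, data))
    return rbm, log


def train_dbn(data: np.ndarray, layer_sizes=DEFAULT_LAYER_SIZES,
              cfg: TrainConfig | None = None) -> DBNModel:
    """Greedy layer-wise unsupervised training.

    The first RBM fits the data; each subsequent RBM fits the hidden
    probabilities of the trained layer below.  No labels are consumed.
    """
    if cfg is None:
        cfg = TrainConfig()
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    layer_sizes = list(layer_sizes)
    if data.shape[1] != layer_sizes[0]:
        raise ValueError(
            f"data width {data.shape[1]} does not match the input layer "
            f"({layer_sizes[0]})"
        )
    rng = np.random.default_rng(cfg.seed)
    rbms, logs = [], []
    current = data
    for m, n in zip(layer_sizes[:-1], layer_sizes[1:]):
        rbm, log = train_rbm(current, n, cfg, rng)
        rbms.append(rbm)
        logs.append(log)
        current = prob_h_given_v(rbm, current)
    return DBNModel(rbms, layer_sizes, logs)


def dbn_transform(model: DBNModel, data: np.ndarray) -> np.ndarray:
    """Deterministic latent map: sequential hidden probabilities per layer."""
    out = np.atleast_2d(np.asarray(data, dtype=np.float64))
    if out.shape[1] != model.layer_sizes[0]:
        raise ValueError("data width does not match the DBN input layer")
    for rbm in model.rbms:
        out = prob_h_given_v(rbm, out)
    return out


def save_dbn(model: DBNModel, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["layer_sizes"] = model.layer_sizes
        for i, rbm in enumerate(model.rbms):
            g = f.create_group(f"rbm{i}")
            g.create_dataset("W", data=rbm.W)
            g.create_dataset("b_vis", data=rbm.b_vis)
            g.create_dataset("b_hid", data=rbm.b_hid)


def load_dbn(path: str) -> DBNModel:
    with h5py.File(path, "r") as f:
        layer_sizes = [int(s) for s in f.attrs["layer_sizes"]]
        rbms = []
        for i in range(len(layer_sizes) - 1):
            g = f[f"rbm{i}"]
            rbms.append(RBMParams(g["W"][()], g["b_vis"][()], g["b_hid"][()]))
    return DBNModel(rbms, layer_sizes)
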