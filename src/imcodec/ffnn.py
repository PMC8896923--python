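"""Bottleneck feed-forward autoencoder trained by per-sample backprop.

The network maps an n-pixel normalized block through a smaller logistic
hidden layer of p units back to n outputs (n -> p -> n; the default codec
uses 64 -> 16 -> 64 on 8x8 blocks).  The hidden activations are the
compressed code.  Weights can be trained by plain stochastic
backpropagation from small random values, or first evolved by the hybrid
GA/PSO optimizer over a flat genome and then refined by backprop
(:func:`train_genpso_bp`).

Update rules, per training pair (x, t):
    sigma_k = (t_k - y_k) f'(y_in_k)            output deltas
    sigma_j = (sum_k sigma_k w_jk) f'(z_in_j)   hidden deltas
    w_jk += alpha sigma_k z_j ;  w_ok += alpha sigma_k
    v_ij += alpha sigma_j x_i ;  v_oj += alpha sigma_j
with the logistic f(x) = 1/(1+e^-x), f'(x) expressed as z(1-z).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genpso import GenPSOConfig, run_genpso
from .image_io import BlockSet

__all__ = [
    "NetworkWeights",
    "ForwardTrace",
    "Gradients",
    "TrainConfig",
    "GenomeLayout",
    "activation",
    "activation_deriv",
    "forward",
    "forward_batch",
    "bp_update",
    "train_bp",
    "genome_layout",
    "genome_encode",
    "genome_decode",
    "train_genpso_bp",
    "encode_blocks",
    "decode_hidden",
    "random_weights",
    "reconstruction_loss",
    "save_weights",
    "load_weights",
]

HIDDEN_SIZES = (2, 4, 8, 16, 32, 64)


@dataclass
class NetworkWeights:
    """All weight/bias arrays: v_ji (n x p), v_oj (p), w_jk (p x m), w_ok (m)."""

    v_ji: np.ndarray
    v_oj: np.ndarray
    w_jk: np.ndarray
    w_ok: np.ndarray

    def __post_init__(self) -> None:
        n, p = self.v_ji.shape
        p2, m = self.w_jk.shape
        if p != p2 or self.v_oj.shape != (p,) or self.w_ok.shape != (m,):
            raise ValueError("inconsistent weight array shapes")
        for arr in (self.v_ji, self.v_oj, self.w_jk, self.w_ok):
            if not np.all(np.isfinite(arr)):
                raise ValueError("weights must be finite")

    @property
    def n_in(self) -> int:
        return self.v_ji.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.v_ji.shape[1]

    @property
    def n_out(self) -> int:
        return self.w_jk.shape[1]

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(
            self.v_ji.copy(), self.v_oj.copy(), self.w_jk.copy(), self.w_ok.copy()
        )


@dataclass
class ForwardTrace:
    z_in: np.ndarray
    z: np.ndarray
    y_in: np.ndarray
    y: np.ndarray


@dataclass
class Gradients:
    sigma_k: np.ndarray
    sigma_j: np.ndarray
    dw_jk: np.ndarray
    dw_ok: np.ndarray
    dv_ij: np.ndarray
    dv_oj: np.ndarray
    alpha: float


@dataclass
class TrainConfig:
    """Backprop settings; ``hidden_size`` is the bottleneck width p."""

    alpha: float = 0.5
    epochs: int = 100
    shuffle: bool = True
    seed: int = 0
    hidden_size: int = 16

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("learning rate alpha must be > 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.hidden_size not in HIDDEN_SIZES:
            raise ValueError(f"hidden_size must be one of {HIDDEN_SIZES}")


def activation(x):
    """Logistic sigmoid 1 / (1 + e^-x), output in (0, 1)."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def activation_deriv(z):
    """Sigmoid derivative in terms of the activation value: z (1 - z)."""
    z = np.asarray(z, dtype=np.float64)
    return z * (1.0 - z)


def forward(wts: NetworkWeights, x: np.ndarray) -> ForwardTrace:
    """One forward pass; records pre-activations for backprop."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (wts.n_in,):
        raise ValueError(f"input length {x.shape} != ({wts.n_in},)")
    z_in = wts.v_oj + x @ wts.v_ji
    z = activation(z_in)
    y_in = wts.w_ok + z @ wts.w_jk
    y = activation(y_in)
    return ForwardTrace(z_in=z_in, z=z, y_in=y_in, y=y)


def forward_batch(wts: NetworkWeights, xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized forward pass over rows of ``xs``; returns (Z, Y)."""
    xs = np.asarray(xs, dtype=np.float64)
    z = activation(xs @ wts.v_ji + wts.v_oj)
    y = activation(z @ wts.w_jk + wts.w_ok)
    return z, y


def bp_update(
    wts: NetworkWeights, x: np.ndarray, t: np.ndarray, alpha: float
) -> tuple[NetworkWeights, Gradients]:
    """One stochastic gradient step on the squared error for the pair (x, t)."""
    x = np.asarray(x, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if t.shape != (wts.n_out,):
        raise ValueError(f"target length {t.shape} != ({wts.n_out},)")
    tr = forward(wts, x)
    sigma_k = (t - tr.y) * activation_deriv(tr.y)
    sigma_in_j = wts.w_jk @ sigma_k
    sigma_j = sigma_in_j * activation_deriv(tr.z)
    dw_jk = alpha * np.outer(tr.z, sigma_k)
    dw_ok = alpha * sigma_k
    dv_ij = alpha * np.outer(x, sigma_j)
    dv_oj = alpha * sigma_j
    new = NetworkWeights(
        v_ji=wts.v_ji + dv_ij,
        v_oj=wts.v_oj + dv_oj,
        w_jk=wts.w_jk + dw_jk,
        w_ok=wts.w_ok + dw_ok,
    )
    grads = Gradients(sigma_k, sigma_j, dw_jk, dw_ok, dv_ij, dv_oj, alpha)
    return new, grads


def reconstruction_loss(wts: NetworkWeights, xs: np.ndarray) -> float:
    """Mean squared autoencoding error over all rows of ``xs``."""
    _, y = forward_batch(wts, xs)
    return float(np.mean((y - xs) ** 2))


def random_weights(
    n: int, p: int, m: int, rng: np.random.Generator, scale: float = 0.5
) -> NetworkWeights:
    """Small uniform [-scale, scale] initial weights for plain backprop."""
    return NetworkWeights(
        v_ji=rng.uniform(-scale, scale, (n, p)),
        v_oj=rng.uniform(-scale, scale, p),
        w_jk=rng.uniform(-scale, scale, (p, m)),
        w_ok=rng.uniform(-scale, scale, m),
    )


def train_bp(
    wts: NetworkWeights, blocks: BlockSet, cfg: TrainConfig
) -> tuple[NetworkWeights, list[float]]:
    """Autoencoder training: per-sample updates with targets = inputs.

    Returns the trained weights and the per-epoch mean squared
    reconstruction loss history (measured after each epoch).
    """
    if not blocks.normalized:
        raise ValueError("train_bp expects a normalized BlockSet")
    xs = np.asarray(blocks.blocks, dtype=np.float64)
    if xs.shape[0] == 0:
        raise ValueError("cannot train on an empty BlockSet")
    if xs.shape[1] != wts.n_in or wts.n_out != wts.n_in:
        raise ValueError("autoencoder requires block length == n_in == n_out")
    rng = np.random.default_rng(cfg.seed)
    wts = wts.copy()
    history: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(xs.shape[0]) if cfg.shuffle else np.arange(xs.shape[0])
        for i in order:
            wts, _ = bp_update(wts, xs[i], xs[i], cfg.alpha)
        history.append(reconstruction_loss(wts, xs))
    return wts, history


@dataclass
class GenomeLayout:
    """Flat packing of a network genome and the per-node slices within it.

    Packing order: v_ji row-major, v_oj, w_jk row-major, w_ok.
    ``node_indices`` lists, for every hidden then every output node, the
    genome positions of its incoming weights plus bias (n+1 entries per
    hidden node, p+1 per output node) — the unit the node-crossover
    operator swaps between parents.
    """

    n: int
    p: int
    m: int
    node_indices: list[np.ndarray] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.n * self.p + self.p + self.p * self.m + self.m


def genome_layout(n: int, p: int, m: int) -> GenomeLayout:
    layout = GenomeLayout(n=n, p=p, m=m)
    off_voj = n * p
    off_wjk = off_voj + p
    off_wok = off_wjk + p * m
    for j in range(p):  # hidden node j: column j of v_ji plus v_oj[j]
        idx = np.concatenate([np.arange(n) * p + j, [off_voj + j]])
        layout.node_indices.append(idx)
    for k in range(m):  # output node k: column k of w_jk plus w_ok[k]
        idx = np.concatenate([off_wjk + np.arange(p) * m + k, [off_wok + k]])
        layout.node_indices.append(idx)
    return layout


def genome_encode(wts: NetworkWeights) -> np.ndarray:
    return np.concatenate(
        [wts.v_ji.ravel(), wts.v_oj, wts.w_jk.ravel(), wts.w_ok]
    )


def genome_decode(vec: np.ndarray, layout: GenomeLayout) -> NetworkWeights:
    vec = np.asarray(vec, dtype=np.float64)
    if vec.shape != (layout.length,):
        raise ValueError(
            f"genome length {vec.size} != layout length {layout.length}"
        )
    n, p, m = layout.n, layout.p, layout.m
    o1 = n * p
    o2 = o1 + p
    o3 = o2 + p * m
    return NetworkWeights(
        v_ji=vec[:o1].reshape(n, p).copy(),
        v_oj=vec[o1:o2].copy(),
        w_jk=vec[o2:o3].reshape(p, m).copy(),
        w_ok=vec[o3:].copy(),
    )


def train_genpso_bp(
    blocks: BlockSet,
    gcfg: GenPSOConfig,
    tcfg: TrainConfig,
    max_fitness_blocks: int = 512,
) -> NetworkWeights:
    """Evolve autoencoder weights with GA+PSO, then refine by backprop.

    The optimizer's fitness is the mean squared reconstruction error on a
    fixed subset of at most ``max_fitness_blocks`` blocks (chosen by
    ``gcfg.seed``); node-mode crossover is used so whole neurons are the
    recombination unit.  The best evolved genome is decoded and refined by
    :func:`train_bp`; if refinement does not improve the full-set loss the
    evolved weights are returned unchanged.
    """
    if not blocks.normalized:
        raise ValueError("train_genpso_bp expects a normalized BlockSet")
    xs = np.asarray(blocks.blocks, dtype=np.float64)
    n = xs.shape[1]
    p = tcfg.hidden_size
    layout = genome_layout(n, p, n)
    if gcfg.dim != layout.length:
        raise ValueError(
            f"gcfg.dim = {gcfg.dim} must equal genome length {layout.length}"
        )
    sub_rng = np.random.default_rng(gcfg.seed)
    if xs.shape[0] > max_fitness_blocks:
        sel = sub_rng.choice(xs.shape[0], size=max_fitness_blocks, replace=False)
        eval_xs = xs[sel]
    else:
        eval_xs = xs

    def fitness(genome: np.ndarray) -> float:
        wts = genome_decode(genome, layout)
        return reconstruction_loss(wts, eval_xs)

    cfg = GenPSOConfig(
        **{
            **gcfg.__dict__,
            "crossover_mode": "node",
            "node_layout": layout,
        }
    )
    best, _ = run_genpso(fitness, cfg)
    evolved = genome_decode(best.position, layout)
    if tcfg.epochs == 0:
        return evolved
    refined, _ = train_bp(evolved, blocks, tcfg)
    if reconstruction_loss(refined, xs) <= reconstruction_loss(evolved, xs):
        return refined
    return evolved


def save_weights(wts: NetworkWeights, path) -> None:
    """Write weights to a standalone file for reuse.

    Byte layout (little-endian): u16 n, u16 p, u16 m, then the float64
    genome in packing order (v_ji row-major, v_oj, w_jk row-major, w_ok).
    """
    import struct

    header = struct.pack("<HHH", wts.n_in, wts.n_hidden, wts.n_out)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(genome_encode(wts).astype("<f8").tobytes())


def load_weights(path) -> NetworkWeights:
    import struct

    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 6:
        raise ValueError("weight file truncated")
    n, p, m = struct.unpack_from("<HHH", data, 0)
    layout = genome_layout(n, p, m)
    genome = np.frombuffer(data, dtype="<f8", count=layout.length, offset=6)
    return genome_decode(genome.astype(np.float64), layout)


def encode_blocks(wts: NetworkWeights, blocks: BlockSet) -> np.ndarray:
    """Hidden-layer codes: one p-vector (entries in (0,1)) per block."""
    if not blocks.normalized:
        raise ValueError("encode_blocks expects a normalized BlockSet")
    z, _ = forward_batch(wts, np.asarray(blocks.blocks, dtype=np.float64))
    return z


def decode_hidden(
    wts: NetworkWeights, hidden: np.ndarray, geometry: BlockSet
) -> BlockSet:
    """Run hidden codes through the output half; returns a normalized BlockSet
    with the grid geometry of ``geometry``."""
    hidden = np.asarray(hidden, dtype=np.float64)
    if hidden.ndim != 2 or hidden.shape[1] != wts.n_hidden:
        raise ValueError(
            f"hidden vectors must be (N, {wts.n_hidden}); got {hidden.shape}"
        )
    y = activation(hidden @ wts.w_jk + wts.w_ok)
    return BlockSet(
        blocks=y,
        block_side=geometry.block_side,
        grid_rows=geometry.grid_rows,
        grid_cols=geometry.grid_cols,
        orig_h=geometry.orig_h,
        orig_w=geometry.orig_w,
        normalized=True,
    )
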