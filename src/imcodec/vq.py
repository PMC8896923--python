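"""Vector quantization: training sets, strided codebook init, L1 coding,
and GA/PSO codebook search.

A codebook is an M x k matrix of real codewords.  Coding assigns every
training vector to its nearest codeword under the city-block (L1)
distance; the per-block codeword indices plus the codebook are the
compressed representation.  ``train_codebook_genpso`` searches codebook
space with the hybrid GA/PSO optimizer (fitness = reconstruction PSNR,
minimized as its negative), elitist-seeded with the strided codebook, and
polishes the winner with Lloyd iterations so codewords land on cluster
centroids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .genpso import GenPSOConfig, run_genpso
from .image_io import BlockSet

__all__ = [
    "TrainingSet",
    "Codebook",
    "IndexMap",
    "build_training_set",
    "init_codebook_strided",
    "distance",
    "assign",
    "codebook_fitness",
    "train_codebook_genpso",
    "lloyd_refine",
    "quantize",
    "dequantize",
    "write_codebook_csv",
    "read_codebook_csv",
]

# finite stand-in for -PSNR of a perfect reconstruction
_PERFECT_SCORE_CAP = -(10.0 * math.log10(255.0**2) + 100.0)


@dataclass
class TrainingSet:
    """N x k matrix of vectors to be quantized.

    ``source`` records whether rows are raw image blocks or autoencoder
    hidden activations; ``peak`` is the dynamic range top used when
    converting distortion to PSNR (255 for pixel blocks, 1 for hidden
    codes).
    """

    vectors: np.ndarray
    source: str = "image-blocks"  # or "hidden-activations"
    peak: float = 255.0

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] < 1:
            raise ValueError("training set must be a non-empty (N, k) matrix")

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def k(self) -> int:
        return self.vectors.shape[1]


@dataclass
class Codebook:
    codewords: np.ndarray

    def __post_init__(self) -> None:
        self.codewords = np.asarray(self.codewords, dtype=np.float64)
        if self.codewords.ndim != 2 or self.codewords.shape[0] < 1:
            raise ValueError("codebook must be a non-empty (M, k) matrix")
        if not np.all(np.isfinite(self.codewords)):
            raise ValueError("codewords must be finite")

    @property
    def m(self) -> int:
        return self.codewords.shape[0]

    @property
    def k(self) -> int:
        return self.codewords.shape[1]


@dataclass
class IndexMap:
    """Per-block codeword indices plus the block-grid shape."""

    indices: np.ndarray
    grid_rows: int
    grid_cols: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.ndim != 1:
            raise ValueError("indices must be a flat vector")
        if self.indices.size != self.grid_rows * self.grid_cols:
            raise ValueError("index count does not match the block grid")
        if self.indices.size and self.indices.min() < 0:
            raise ValueError("indices must be non-negative")


def build_training_set(bs: BlockSet) -> TrainingSet:
    """One training vector per block, order preserved (N = block count)."""
    return TrainingSet(
        vectors=np.asarray(bs.blocks, dtype=np.float64),
        source="image-blocks",
        peak=1.0 if bs.normalized else 255.0,
    )


def init_codebook_strided(ts: TrainingSet, m: int) -> Codebook:
    """Pick every floor(N/M)-th training vector, starting at index 0."""
    if m > ts.n:
        raise ValueError(f"codebook size {m} exceeds training-set size {ts.n}")
    stride = ts.n // m
    idx = np.arange(m) * stride
    return Codebook(ts.vectors[idx].copy())


def distance(y: np.ndarray, x: np.ndarray) -> float:
    """City-block distance sum_j |y_j - x_j|."""
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if y.shape != x.shape:
        raise ValueError(f"vector lengths differ: {y.shape} vs {x.shape}")
    return float(np.sum(np.abs(y - x)))


def assign(ts: TrainingSet, cb: Codebook) -> tuple[IndexMap, float]:
    """Nearest-codeword index per vector (L1, ties to the lowest index)
    and the mean distance to the assigned codeword (the distortion).

    The returned :class:`IndexMap` has a flat 1 x N grid; callers with a
    block grid reshape via :func:`quantize`.
    """
    if ts.k != cb.k:
        raise ValueError(f"dimension mismatch: vectors k={ts.k}, codebook k={cb.k}")
    d = cdist(ts.vectors, cb.codewords, metric="cityblock")
    idx = np.argmin(d, axis=1)  # argmin takes the first (lowest) minimizer
    distortion = float(np.mean(d[np.arange(ts.n), idx]))
    return IndexMap(indices=idx, grid_rows=1, grid_cols=ts.n), distortion


def codebook_fitness(genome: np.ndarray, ts: TrainingSet) -> float:
    """Negated reconstruction PSNR of the codebook encoded in ``genome``.

    The genome is a flattened (M, k) codebook.  Reconstructing every
    training vector by its nearest codeword gives an MSE; the score is
    -10 log10(peak^2 / MSE), i.e. lower is better, and a finite cap
    replaces -inf when the reconstruction is exact.
    """
    genome = np.asarray(genome, dtype=np.float64)
    if genome.size % ts.k != 0:
        raise ValueError(f"genome length {genome.size} not a multiple of k={ts.k}")
    cb = Codebook(genome.reshape(-1, ts.k))
    d = cdist(ts.vectors, cb.codewords, metric="cityblock")
    idx = np.argmin(d, axis=1)
    err = ts.vectors - cb.codewords[idx]
    m = float(np.mean(err * err))
    if m == 0.0:
        return _PERFECT_SCORE_CAP
    return -10.0 * math.log10(ts.peak**2 / m)


def _repair_empty_cells(
    cb: np.ndarray, ts: TrainingSet, idx: np.ndarray, dmin: np.ndarray
) -> np.ndarray:
    """Reseed codewords with no assigned vectors from the training vectors
    farthest from their current codeword (deterministic repair)."""
    counts = np.bincount(idx, minlength=cb.shape[0])
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        order = np.argsort(-dmin, kind="stable")
        for cell, src in zip(empty, order[: empty.size]):
            cb[cell] = ts.vectors[src]
    return cb


def _farthest_point_seed(
    ts: TrainingSet, m: int, rng: np.random.Generator
) -> Codebook:
    """Greedy farthest-point codebook seed (random first vector)."""
    first = int(rng.integers(0, ts.n))
    chosen = [first]
    dmin = cdist(ts.vectors, ts.vectors[[first]], metric="cityblock").ravel()
    while len(chosen) < m:
        nxt = int(np.argmax(dmin))
        chosen.append(nxt)
        d_new = cdist(ts.vectors, ts.vectors[[nxt]], metric="cityblock").ravel()
        dmin = np.minimum(dmin, d_new)
    return Codebook(ts.vectors[chosen].copy())


def lloyd_refine(
    cb: Codebook, ts: TrainingSet, max_iters: int = 50
) -> Codebook:
    """Generalized-Lloyd polish under the city-block distortion: alternate
    nearest assignment (L1) and per-coordinate cell-median updates (the L1
    centroid) until assignments stabilize; empty cells are reseeded from
    the farthest-assigned training vectors."""
    codewords = cb.codewords.copy()
    prev_idx = None
    for _ in range(max_iters):
        d = cdist(ts.vectors, codewords, metric="cityblock")
        idx = np.argmin(d, axis=1)
        dmin = d[np.arange(ts.n), idx]
        codewords = _repair_empty_cells(codewords, ts, idx, dmin)
        counts = np.bincount(idx, minlength=codewords.shape[0])
        if np.any(counts == 0):  # re-assign after repair
            d = cdist(ts.vectors, codewords, metric="cityblock")
            idx = np.argmin(d, axis=1)
        if prev_idx is not None and np.array_equal(idx, prev_idx):
            break
        prev_idx = idx
        for cell in range(codewords.shape[0]):
            members = ts.vectors[idx == cell]
            if members.shape[0]:
                codewords[cell] = np.median(members, axis=0)
    return Codebook(codewords)


def train_codebook_genpso(
    ts: TrainingSet, m: int, gcfg: GenPSOConfig | None = None, **cfg_overrides
) -> Codebook:
    """GA/PSO search over flattened codebooks, elitist-seeded with the
    strided codebook and Lloyd-polished.

    Guarantee: the returned codebook's distortion never exceeds the
    strided-init codebook's distortion (the strided seed is kept if the
    search somehow ends worse).
    """
    if m > ts.n:
        raise ValueError(f"codebook size {m} exceeds training-set size {ts.n}")
    strided = init_codebook_strided(ts, m)
    lo = float(ts.vectors.min())
    hi = float(ts.vectors.max())
    if hi <= lo:
        hi = lo + 1.0  # degenerate constant training set
    dim = m * ts.k
    if gcfg is None:
        gcfg = GenPSOConfig(
            dim=dim,
            bounds=(lo, hi),
            pop_size=cfg_overrides.pop("pop_size", 30),
            total_iters=cfg_overrides.pop("total_iters", 40),
            mutation_sigma=0.05,
            **cfg_overrides,
        )
    if gcfg.dim != dim:
        raise ValueError(f"gcfg.dim = {gcfg.dim} must equal M*k = {dim}")

    def fitness(genome: np.ndarray) -> float:
        return codebook_fitness(genome, ts)

    best, _ = run_genpso(fitness, gcfg, init=[strided.codewords.ravel()])
    # polish a handful of starts: the GenPSO winner, the strided seed, and
    # farthest-point seeds — Lloyd basins differ, keep the best by
    # distortion
    candidates = [Codebook(best.position.reshape(m, ts.k)), strided]
    rng = np.random.default_rng(gcfg.seed)
    for _ in range(3):
        candidates.append(_farthest_point_seed(ts, m, rng))
    _, d_strided = assign(ts, strided)
    best_cb, best_d = strided, d_strided
    for cand in candidates:
        polished = lloyd_refine(cand, ts)
        _, d = assign(ts, polished)
        if d < best_d:
            best_cb, best_d = polished, d
    return best_cb


def write_codebook_csv(cb: Codebook, path) -> None:
    """Export a codebook as plain CSV, one codeword per row."""
    np.savetxt(path, cb.codewords, delimiter=",", fmt="%.9g")


def read_codebook_csv(path) -> Codebook:
    return Codebook(np.atleast_2d(np.loadtxt(path, delimiter=",")))


def quantize(bs: BlockSet, cb: Codebook) -> IndexMap:
    """Map every block to its nearest codeword index (block grid preserved)."""
    ts = build_training_set(bs)
    im, _ = assign(ts, cb)
    return IndexMap(
        indices=im.indices, grid_rows=bs.grid_rows, grid_cols=bs.grid_cols
    )


def dequantize(im: IndexMap, cb: Codebook, geometry: BlockSet) -> BlockSet:
    """Replace every index with its codeword; inverse of :func:`quantize`
    up to quantization loss."""
    if im.indices.size and int(im.indices.max()) >= cb.m:
        raise ValueError(
            f"corrupt index map: index {int(im.indices.max())} >= M = {cb.m}"
        )
    blocks = cb.codewords[im.indices]
    return BlockSet(
        blocks=blocks,
        block_side=geometry.block_side,
        grid_rows=im.grid_rows,
        grid_cols=im.grid_cols,
        orig_h=geometry.orig_h,
        orig_w=geometry.orig_w,
        normalized=geometry.normalized,
    )
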