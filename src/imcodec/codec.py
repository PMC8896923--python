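"""End-to-end lossy codec: block VQ, optional autoencoder front end,
bitstream serialization and quality evaluation.

Two modes:

* ``vq_direct`` — 4x4 pixel blocks quantized straight against a
  GA/PSO-trained codebook (payload: one codeword index per block).
* ``ann_vq`` — 8x8 blocks pushed through a trained n->p->n bottleneck
  autoencoder; the p-dimensional hidden codes are vector-quantized.  The
  decoder needs the output half of the network, so the weights travel in
  the stream.

Bitstream (little-endian): magic ``IOMC``, u8 version, u8 mode, u16
orig_h, u16 orig_w, u8 block_side, u8 index_bits, u16 M, u16 k, u16 p,
u16 grid_rows, u16 grid_cols, codewords as float32 row-major, indices
bit-packed MSB-first, then (ann_vq only) a u32-length-prefixed weights
section.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field

import numpy as np

from . import metrics as mt
from .ffnn import (
    NetworkWeights,
    TrainConfig,
    decode_hidden,
    encode_blocks,
    genome_decode,
    genome_encode,
    genome_layout,
    train_genpso_bp,
)
from .genpso import GenPSOConfig
from .image_io import BlockSet, from_blocks, to_blocks
from .vq import (
    Codebook,
    IndexMap,
    TrainingSet,
    assign,
    dequantize,
    quantize,
    train_codebook_genpso,
)

__all__ = [
    "MAGIC",
    "VERSION",
    "CodecConfig",
    "CompressedImage",
    "FormatError",
    "compress_vq",
    "compress_ann_vq",
    "compress",
    "decompress",
    "serialize",
    "deserialize",
    "evaluate",
    "index_bits_for",
    "codebook_size_for_target",
]

MAGIC = b"IOMC"
VERSION = 1
MODES = {"vq_direct": 0, "ann_vq": 1}
MODE_NAMES = {v: k for k, v in MODES.items()}


class FormatError(ValueError):
    """Malformed, truncated or corrupted bitstream."""


def index_bits_for(m: int) -> int:
    """Fixed-length bits per codeword index: ceil(log2 M), at least 1."""
    if m < 1:
        raise ValueError("codebook size must be >= 1")
    return max(1, math.ceil(math.log2(m))) if m > 1 else 1


def codebook_size_for_target(
    h: int, w: int, b: int, target_percent: float
) -> int:
    """Largest power-of-two codebook whose index payload fits the target.

    ``target_percent`` is the compressed payload as a percent of the
    original 8 bpp image (25.0 = a quarter of the original size).  Each of
    the ceil(H/b)*ceil(W/b) blocks costs ceil(log2 M) bits, so the budget
    per block is target_percent/100 * 8 * b^2 bits.
    """
    if target_percent <= 0:
        raise ValueError("target_percent must be positive")
    n_blocks = math.ceil(h / b) * math.ceil(w / b)
    budget_bits = target_percent / 100.0 * 8 * h * w
    bits_per_block = int(budget_bits // n_blocks)
    if bits_per_block < 1:
        raise ValueError(
            f"target {target_percent}% leaves no room for even 1 bit per block"
        )
    # M can neither exceed 2^16 (u16 header field) nor the block count
    max_bits = min(16, int(math.log2(n_blocks))) if n_blocks > 1 else 1
    return 2 ** min(bits_per_block, max_bits)


@dataclass
class CodecConfig:
    """Compression settings for one run.

    ``block_side`` defaults to 4 in vq_direct mode and 8 in ann_vq mode;
    ``codebook_size`` M need not be a power of two (index bits round up).
    ``genpso``/``train`` override the optimizer and backprop settings used
    for codebook search and autoencoder training; when None, modest
    defaults sized for per-image training are built internally.
    """

    mode: str = "vq_direct"
    block_side: int | None = None
    codebook_size: int = 16
    hidden_size: int = 16
    seed: int = 0
    genpso_iters: int = 40
    genpso_pop: int = 30
    bp_epochs: int = 60
    bp_alpha: float = 1.0
    use_genpso_codebook: bool = True
    use_genpso_weights: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {sorted(MODES)}")
        if self.block_side is None:
            self.block_side = 4 if self.mode == "vq_direct" else 8

    @property
    def b(self) -> int:
        return self.block_side


@dataclass
class CompressedImage:
    """In-memory twin of the serialized stream."""

    mode: str
    orig_h: int
    orig_w: int
    block_side: int
    codebook: Codebook
    index_map: IndexMap
    weights: NetworkWeights | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "ann_vq" and self.weights is None:
            raise ValueError("ann_vq streams must carry network weights")
        expect = (
            math.ceil(self.orig_h / self.block_side)
            * math.ceil(self.orig_w / self.block_side)
        )
        if self.index_map.indices.size != expect:
            raise ValueError(
                f"index map has {self.index_map.indices.size} entries; "
                f"header implies {expect}"
            )

    @property
    def index_bits(self) -> int:
        return index_bits_for(self.codebook.m)

    @property
    def payload_bits(self) -> int:
        """Bits spent on codeword indices alone (no side information)."""
        return self.index_map.indices.size * self.index_bits


def _geometry(ci: CompressedImage, normalized: bool) -> BlockSet:
    b = ci.block_side
    gr, gc = ci.index_map.grid_rows, ci.index_map.grid_cols
    dummy = np.zeros((gr * gc, b * b))
    return BlockSet(
        blocks=dummy, block_side=b, grid_rows=gr, grid_cols=gc,
        orig_h=ci.orig_h, orig_w=ci.orig_w, normalized=normalized,
    )


def _default_gcfg(dim: int, bounds, cfg: CodecConfig, seed_shift: int) -> GenPSOConfig:
    return GenPSOConfig(
        dim=dim,
        bounds=bounds,
        pop_size=cfg.genpso_pop,
        total_iters=cfg.genpso_iters,
        mutation_sigma=0.05,
        stagnation_window=max(10, cfg.genpso_iters // 2),
        seed=(cfg.seed + seed_shift) % (2**31),
    )


def compress_vq(img: np.ndarray, cfg: CodecConfig) -> CompressedImage:
    """Direct block VQ: blocks -> GA/PSO codebook -> index map."""
    if cfg.mode != "vq_direct":
        raise ValueError("compress_vq requires mode 'vq_direct'")
    bs = to_blocks(img, cfg.b, normalize=False)
    ts = TrainingSet(bs.blocks.astype(np.float64), source="image-blocks", peak=255.0)
    if cfg.codebook_size > ts.n:
        raise ValueError(
            f"codebook size {cfg.codebook_size} exceeds block count {ts.n}"
        )
    if cfg.use_genpso_codebook:
        gcfg = _default_gcfg(cfg.codebook_size * ts.k, (0.0, 255.0), cfg, 1)
        cb = train_codebook_genpso(ts, cfg.codebook_size, gcfg)
    else:
        rng = np.random.default_rng(cfg.seed)
        cb = Codebook(rng.uniform(0.0, 255.0, (cfg.codebook_size, ts.k)))
    im = quantize(bs, cb)
    return CompressedImage(
        mode="vq_direct", orig_h=img.shape[0], orig_w=img.shape[1],
        block_side=cfg.b, codebook=cb, index_map=im,
    )


def compress_ann_vq(img: np.ndarray, cfg: CodecConfig) -> CompressedImage:
    """Autoencoder + VQ: train the bottleneck net, quantize hidden codes."""
    if cfg.mode != "ann_vq":
        raise ValueError("compress_ann_vq requires mode 'ann_vq'")
    bs = to_blocks(img, cfg.b, normalize=True)
    n = cfg.b * cfg.b
    tcfg = TrainConfig(
        alpha=cfg.bp_alpha, epochs=cfg.bp_epochs, shuffle=True,
        seed=cfg.seed, hidden_size=cfg.hidden_size,
    )
    layout = genome_layout(n, cfg.hidden_size, n)
    if cfg.use_genpso_weights:
        gcfg = _default_gcfg(layout.length, (-1.0, 1.0), cfg, 2)
        wts = train_genpso_bp(bs, gcfg, tcfg)
    else:
        from .ffnn import random_weights, train_bp

        rng = np.random.default_rng(cfg.seed)
        wts, _ = train_bp(random_weights(n, cfg.hidden_size, n, rng), bs, tcfg)
    hidden = encode_blocks(wts, bs)
    ts = TrainingSet(hidden, source="hidden-activations", peak=1.0)
    if cfg.codebook_size > ts.n:
        raise ValueError(
            f"codebook size {cfg.codebook_size} exceeds block count {ts.n}"
        )
    if cfg.use_genpso_codebook:
        gcfg = _default_gcfg(cfg.codebook_size * ts.k, (0.0, 1.0), cfg, 3)
        cb = train_codebook_genpso(ts, cfg.codebook_size, gcfg)
    else:
        rng = np.random.default_rng(cfg.seed + 3)
        cb = Codebook(rng.uniform(0.0, 1.0, (cfg.codebook_size, ts.k)))
    im_flat, _ = assign(ts, cb)
    im = IndexMap(
        indices=im_flat.indices, grid_rows=bs.grid_rows, grid_cols=bs.grid_cols
    )
    return CompressedImage(
        mode="ann_vq", orig_h=img.shape[0], orig_w=img.shape[1],
        block_side=cfg.b, codebook=cb, index_map=im, weights=wts,
    )


def compress(img: np.ndarray, cfg: CodecConfig) -> CompressedImage:
    if cfg.mode == "vq_direct":
        return compress_vq(img, cfg)
    return compress_ann_vq(img, cfg)


def decompress(ci: CompressedImage) -> np.ndarray:
    """Reconstruct the image from codebook + index map (+ weights)."""
    if ci.index_map.indices.size and int(ci.index_map.indices.max()) >= ci.codebook.m:
        raise FormatError("corrupt stream: codeword index out of range")
    if ci.mode == "vq_direct":
        geometry = _geometry(ci, normalized=False)
        bs = dequantize(ci.index_map, ci.codebook, geometry)
        return from_blocks(bs)
    geometry = _geometry(ci, normalized=True)
    hidden = ci.codebook.codewords[ci.index_map.indices]
    bs = decode_hidden(ci.weights, hidden, geometry)
    return from_blocks(bs)


# --- bitstream ---------------------------------------------------------

_HEADER = struct.Struct("<4sBBHHBBHHHHH")


def _pack_indices(indices: np.ndarray, bits: int) -> bytes:
    if indices.size == 0:
        raise ValueError("cannot serialize an empty index map")
    shifts = np.arange(bits - 1, -1, -1)
    bitmat = ((indices[:, None] >> shifts) & 1).astype(np.uint8)
    return np.packbits(bitmat.ravel()).tobytes()


def _unpack_indices(payload: bytes, count: int, bits: int) -> np.ndarray:
    need = count * bits
    raw = np.unpackbits(np.frombuffer(payload, dtype=np.uint8))
    if raw.size < need:
        raise FormatError("truncated stream: index payload too short")
    bitmat = raw[:need].reshape(count, bits).astype(np.int64)
    weights = 1 << np.arange(bits - 1, -1, -1)
    return bitmat @ weights


def serialize(ci: CompressedImage) -> bytes:
    """Encode a :class:`CompressedImage` to its byte stream."""
    bits = ci.index_bits
    header = _HEADER.pack(
        MAGIC, VERSION, MODES[ci.mode],
        ci.orig_h, ci.orig_w, ci.block_side, bits,
        ci.codebook.m, ci.codebook.k,
        ci.weights.n_hidden if ci.weights is not None else 0,
        ci.index_map.grid_rows, ci.index_map.grid_cols,
    )
    out = bytearray(header)
    out += ci.codebook.codewords.astype("<f4").tobytes()
    out += _pack_indices(ci.index_map.indices, bits)
    if ci.mode == "ann_vq":
        genome = genome_encode(ci.weights).astype("<f4")
        wsec = struct.pack(
            "<HHH", ci.weights.n_in, ci.weights.n_hidden, ci.weights.n_out
        ) + genome.tobytes()
        out += struct.pack("<I", len(wsec)) + wsec
    return bytes(out)


def deserialize(data: bytes) -> CompressedImage:
    """Decode a byte stream back to a :class:`CompressedImage`."""
    if len(data) < _HEADER.size:
        raise FormatError("truncated stream: header incomplete")
    (magic, version, mode_id, orig_h, orig_w, b, bits, m, k, p,
     grid_rows, grid_cols) = _HEADER.unpack_from(data, 0)
    if magic != MAGIC:
        raise FormatError(f"bad magic {magic!r}")
    if version != VERSION:
        raise FormatError(f"unsupported stream version {version}")
    if mode_id not in MODE_NAMES:
        raise FormatError(f"unknown mode id {mode_id}")
    mode = MODE_NAMES[mode_id]
    off = _HEADER.size
    cb_bytes = m * k * 4
    if len(data) < off + cb_bytes:
        raise FormatError("truncated stream: codebook incomplete")
    codewords = (
        np.frombuffer(data, dtype="<f4", count=m * k, offset=off)
        .astype(np.float64)
        .reshape(m, k)
    )
    off += cb_bytes
    n_idx = grid_rows * grid_cols
    idx_bytes = math.ceil(n_idx * bits / 8)
    if len(data) < off + idx_bytes:
        raise FormatError("truncated stream: index payload incomplete")
    indices = _unpack_indices(data[off : off + idx_bytes], n_idx, bits)
    off += idx_bytes
    weights = None
    if mode == "ann_vq":
        if len(data) < off + 4:
            raise FormatError("truncated stream: weights length missing")
        (wlen,) = struct.unpack_from("<I", data, off)
        off += 4
        if len(data) < off + wlen:
            raise FormatError("truncated stream: weights section incomplete")
        n_in, p_w, n_out = struct.unpack_from("<HHH", data, off)
        layout = genome_layout(n_in, p_w, n_out)
        genome = np.frombuffer(
            data, dtype="<f4", count=layout.length, offset=off + 6
        ).astype(np.float64)
        weights = genome_decode(genome, layout)
        off += wlen
    ci = CompressedImage(
        mode=mode, orig_h=orig_h, orig_w=orig_w, block_side=b,
        codebook=Codebook(codewords),
        index_map=IndexMap(indices=indices, grid_rows=grid_rows, grid_cols=grid_cols),
        weights=weights,
    )
    if int(indices.max()) >= m:
        raise FormatError("corrupt stream: codeword index out of range")
    if bits != ci.index_bits:
        raise FormatError("corrupt stream: index_bits disagrees with M")
    _ = p
    return ci


def evaluate(original: np.ndarray, ci: CompressedImage) -> mt.MetricReport:
    """Decode and score a compressed image against its original.

    The headline compression ratio counts the full serialized stream
    (codebook and, in ann_vq mode, network weights included); the
    payload-only figure counts just the bit-packed index map.
    """
    recon = decompress(ci)
    if recon.shape != original.shape:
        raise ValueError("reconstruction dimensions disagree with the original")
    original_bits = 8 * original.shape[0] * original.shape[1]
    stream_bits = 8 * len(serialize(ci))
    ratio, percent = mt.compression_ratio(original_bits, stream_bits)
    pratio, ppercent = mt.compression_ratio(original_bits, ci.payload_bits)
    return mt.MetricReport(
        psnr=mt.psnr(original, recon),
        mse=mt.mse(original, recon),
        rmse=mt.rmse(original, recon),
        ssim=mt.ssim(original, recon),
        snr=mt.snr(original, recon),
        nmse=mt.nmse(original, recon),
        cr_ratio=ratio,
        cr_percent=percent,
        cr_ratio_payload=pratio,
        cr_percent_payload=ppercent,
    )
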