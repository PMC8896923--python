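"""Grayscale image I/O and block (de)composition.

Images are plain ``numpy`` arrays of dtype ``uint8`` and shape ``(H, W)``.
The codec operates on fixed-size square blocks; :func:`to_blocks` flattens an
image into a row-major set of ``b*b`` vectors (edge-replicating the image up
to a multiple of ``b`` first) and :func:`from_blocks` is its exact inverse.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "BlockSet",
    "read_gray_image",
    "write_gray_image",
    "to_blocks",
    "from_blocks",
]

# integer-rounded BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])

_SUPPORTED_EXT = {".pgm", ".pnm", ".png"}


@dataclass
class BlockSet:
    """A grid of flattened square pixel blocks.

    Attributes
    ----------
    blocks : (N, b*b) float or int array, one flattened block per row,
        emitted row-major over the padded image, each block itself
        flattened row-major.
    block_side : side length b of each square block.
    grid_rows, grid_cols : block-grid shape; ``N == grid_rows * grid_cols``.
    orig_h, orig_w : pre-padding image dimensions, needed to crop on
        reassembly.
    normalized : if True entries live in [0, 1] (pixel / 255), else they
        are integer intensities in [0, 255].
    """

    blocks: np.ndarray
    block_side: int
    grid_rows: int
    grid_cols: int
    orig_h: int
    orig_w: int
    normalized: bool = False

    def __post_init__(self) -> None:
        self.blocks = np.asarray(self.blocks)
        if self.blocks.ndim != 2:
            raise ValueError("blocks must be a 2-D (N, b*b) array")
        n, k = self.blocks.shape
        if n != self.grid_rows * self.grid_cols:
            raise ValueError(
                f"block count {n} != grid {self.grid_rows}x{self.grid_cols}"
            )
        if k != self.block_side**2:
            raise ValueError(
                f"block length {k} != block_side^2 = {self.block_side ** 2}"
            )

    @property
    def n_blocks(self) -> int:
        return self.blocks.shape[0]

    @property
    def block_dim(self) -> int:
        return self.blocks.shape[1]


def _validate_image(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValueError("a grayscale image must be a non-empty 2-D array")
    if pixels.dtype != np.uint8:
        if np.any((pixels < 0) | (pixels > 255)):
            raise ValueError("intensities must lie in [0, 255]")
        if not np.all(pixels == np.round(pixels)):
            raise ValueError("intensities must be integers")
        pixels = pixels.astype(np.uint8)
    return pixels


def read_gray_image(path: str | Path) -> np.ndarray:
    """Read a PGM or PNG file as an 8-bit grayscale image.

    Color inputs are reduced to luma with integer-rounded BT.601 weights
    (0.299 R + 0.587 G + 0.114 B).  Images deeper than 8 bits per channel
    are rejected.
    """
    path = Path(path)
    try:
        img = Image.open(path)
        img.load()
    except (OSError, Image.UnidentifiedImageError) as exc:
        raise IOError(f"cannot read image file: {path}") from exc
    if img.mode in ("I", "I;16", "I;16B", "I;16L", "F"):
        raise ValueError(f"unsupported bit depth (>8 per channel): {path}")
    if img.mode in ("L", "1", "P"):
        arr = np.asarray(img.convert("L"), dtype=np.uint8)
    else:
        rgb = np.asarray(img.convert("RGB"), dtype=np.float64)
        arr = np.rint(rgb @ _LUMA).clip(0, 255).astype(np.uint8)
    return _validate_image(arr)


def write_gray_image(img: np.ndarray, path: str | Path) -> Path:
    """Write an image as binary PGM (P5) or 8-bit grayscale PNG by extension."""
    img = _validate_image(img)
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in _SUPPORTED_EXT:
        raise ValueError(
            f"unsupported output format {ext!r}; use one of {sorted(_SUPPORTED_EXT)}"
        )
    try:
        Image.fromarray(img, mode="L").save(path)
    except OSError as exc:
        raise IOError(f"cannot write image file: {path}") from exc
    return path


def _pad_to_multiple(img: np.ndarray, b: int) -> np.ndarray:
    h, w = img.shape
    pad_h = (-h) % b
    pad_w = (-w) % b
    if pad_h or pad_w:
        img = np.pad(img, ((0, pad_h), (0, pad_w)), mode="edge")
    return img


def to_blocks(img: np.ndarray, b: int, normalize: bool = False) -> BlockSet:
    """Cut an image into flattened b x b blocks (row-major).

    The image is edge-replicated up to a multiple of ``b`` in each
    dimension, so the grid always has ``ceil(H/b) * ceil(W/b)`` blocks.
    With ``normalize`` the entries are divided by 255 into [0, 1].
    """
    if b < 1:
        raise ValueError(f"block side must be >= 1, got {b}")
    img = _validate_image(img)
    h, w = img.shape
    padded = _pad_to_multiple(img, b)
    gr, gc = padded.shape[0] // b, padded.shape[1] // b
    blocks = (
        padded.reshape(gr, b, gc, b)
        .transpose(0, 2, 1, 3)
        .reshape(gr * gc, b * b)
    )
    if normalize:
        blocks = blocks.astype(np.float64) / 255.0
    else:
        blocks = blocks.astype(np.int64)
    return BlockSet(
        blocks=blocks,
        block_side=b,
        grid_rows=gr,
        grid_cols=gc,
        orig_h=h,
        orig_w=w,
        normalized=normalize,
    )


def from_blocks(bs: BlockSet) -> np.ndarray:
    """Reassemble an image from a :class:`BlockSet` (inverse of :func:`to_blocks`).

    Reassembles row-major, crops back to the original size, de-normalizes
    (x 255) when the set is normalized, rounds half-up and clamps to
    [0, 255].
    """
    b = bs.block_side
    gr, gc = bs.grid_rows, bs.grid_cols
    vals = np.asarray(bs.blocks, dtype=np.float64)
    if bs.normalized:
        vals = vals * 255.0
    # round half-up, then clamp
    vals = np.floor(vals + 0.5)
    vals = np.clip(vals, 0, 255)
    img = (
        vals.reshape(gr, gc, b, b)
        .transpose(0, 2, 1, 3)
        .reshape(gr * b, gc * b)
    )
    return img[: bs.orig_h, : bs.orig_w].astype(np.uint8)
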