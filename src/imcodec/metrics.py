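"""Full-reference image quality metrics and compression-ratio accounting.

All metrics compare an original image ``f`` against a reconstruction ``g``
of the same shape.  PSNR uses the 8-bit peak 255; SSIM is the
global-statistics form (whole-image means/variances, one window) with the
population (1/n) variance convention.  ``snr`` and ``nmse`` are
signal-power ratios: SNR = 10 log10(sum f^2 / sum (f-g)^2) and
NMSE = sum (f-g)^2 / sum f^2 = 10^(-SNR/10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SsimConstants",
    "MetricReport",
    "mse",
    "rmse",
    "psnr",
    "ssim",
    "snr",
    "nmse",
    "compression_ratio",
]

PEAK = 255.0


@dataclass(frozen=True)
class SsimConstants:
    """SSIM stabilization constants c1 = (K1 L)^2, c2 = (K2 L)^2."""

    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 255.0

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0 or self.dynamic_range <= 0:
            raise ValueError("SSIM constants must be positive")

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2


@dataclass
class MetricReport:
    """Flat bundle of quality and rate figures for one codec run."""

    psnr: float
    mse: float
    rmse: float
    ssim: float
    snr: float
    nmse: float
    cr_ratio: float
    cr_percent: float
    cr_ratio_payload: float | None = None
    cr_percent_payload: float | None = None
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "psnr": self.psnr,
            "mse": self.mse,
            "rmse": self.rmse,
            "ssim": self.ssim,
            "snr": self.snr,
            "nmse": self.nmse,
            "cr_ratio": self.cr_ratio,
            "cr_percent": self.cr_percent,
        }
        if self.cr_ratio_payload is not None:
            d["cr_ratio_payload"] = self.cr_ratio_payload
            d["cr_percent_payload"] = self.cr_percent_payload
        d.update(self.extra)
        return d


def _pair(f: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    f = np.asarray(f, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if f.shape != g.shape:
        raise ValueError(f"image shapes differ: {f.shape} vs {g.shape}")
    return f, g


def mse(f: np.ndarray, g: np.ndarray) -> float:
    """Mean squared error over all pixels."""
    f, g = _pair(f, g)
    return float(np.mean((f - g) ** 2))


def rmse(f: np.ndarray, g: np.ndarray) -> float:
    """Root of the mean squared error."""
    return math.sqrt(mse(f, g))


def psnr(f: np.ndarray, g: np.ndarray, peak: float = PEAK) -> float:
    """Peak signal-to-noise ratio, 10 log10(peak^2 / MSE) in dB.

    Identical images have zero error; +inf is returned as the sentinel.
    """
    err = mse(f, g)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(peak * peak / err)


def ssim(
    f: np.ndarray, g: np.ndarray, consts: SsimConstants = SsimConstants()
) -> float:
    """Global (single-window) structural similarity index.

    (2 mu_f mu_g + c1)(2 cov_fg + c2) /
    ((mu_f^2 + mu_g^2 + c1)(var_f + var_g + c2)), with population (1/n)
    variances over the whole image.
    """
    f, g = _pair(f, g)
    mu_f, mu_g = f.mean(), g.mean()
    var_f, var_g = f.var(), g.var()
    cov = float(np.mean((f - mu_f) * (g - mu_g)))
    c1, c2 = consts.c1, consts.c2
    num = (2 * mu_f * mu_g + c1) * (2 * cov + c2)
    den = (mu_f**2 + mu_g**2 + c1) * (var_f + var_g + c2)
    return float(num / den)


def snr(f: np.ndarray, g: np.ndarray) -> float:
    """Signal-to-noise ratio 10 log10(sum f^2 / sum (f-g)^2) in dB."""
    f, g = _pair(f, g)
    sig = float(np.sum(f * f))
    if sig == 0.0:
        raise ValueError("SNR undefined: reference image is all zero")
    noise = float(np.sum((f - g) ** 2))
    if noise == 0.0:
        return math.inf
    return 10.0 * math.log10(sig / noise)


def nmse(f: np.ndarray, g: np.ndarray) -> float:
    """Normalized MSE, sum (f-g)^2 / sum f^2; equals 10^(-SNR/10)."""
    f, g = _pair(f, g)
    sig = float(np.sum(f * f))
    if sig == 0.0:
        raise ValueError("NMSE undefined: reference image is all zero")
    return float(np.sum((f - g) ** 2) / sig)


def compression_ratio(
    original_bits: int, compressed_bits: int
) -> tuple[float, float]:
    """Return (ratio, percent): original/compressed and 100*compressed/original."""
    if original_bits <= 0 or compressed_bits <= 0:
        raise ValueError("bit counts must be positive")
    return (
        original_bits / compressed_bits,
        100.0 * compressed_bits / original_bits,
    )
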