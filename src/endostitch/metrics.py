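"""Image-quality metrics for stitched mosaics: PSNR, RMSE, SSIM, TV.

All metrics operate on [0,1]-scaled images and accept an optional binary
region mask (overlap, union footprint, or full frame).  SSIM follows the
standard definition: luminance conversion, 11-pixel Gaussian window with
sigma 1.5, stability constants K1=0.01, K2=0.03 at dynamic range 1.  TV is
the anisotropic variant normalised by pixel count, so values are comparable
across canvas sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["rmse", "psnr", "ssim", "tv", "MetricsReport", "evaluate_stitch"]

#: luminance weights (ITU-R BT.709, as used by standard grayscale conversion)
_LUMA = np.array([0.2125, 0.7154, 0.0721])
_K1, _K2 = 0.01, 0.03
_SIGMA, _TRUNCATE = 1.5, 3.5  # kernel radius 5 → effective 11-pixel window


def _prep(a: np.ndarray, b: np.ndarray, mask):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("image shapes differ")
    if mask is None:
        mask = np.ones(a.shape[:2], dtype=bool)
    else:
        mask = np.asarray(mask) > 0.5
    if not mask.any():
        raise ValueError("empty mask")
    return a, b, mask


def rmse(a: np.ndarray, b: np.ndarray, mask=None) -> float:
    """Root mean squared difference over masked pixels and channels."""
    a, b, mask = _prep(a, b, mask)
    d = (a - b)[mask]
    return float(np.sqrt(np.mean(d * d)))


def psnr(a: np.ndarray, b: np.ndarray, mask=None) -> float:
    """10·log10(1/MSE) dB with peak 1.0; +inf when the images agree exactly."""
    a, b, mask = _prep(a, b, mask)
    d = (a - b)[mask]
    mse = float(np.mean(d * d))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(1.0 / mse))


def _to_gray(a: np.ndarray) -> np.ndarray:
    if a.ndim == 3:
        return a @ _LUMA
    return a


def ssim(a: np.ndarray, b: np.ndarray, mask=None) -> float:
    """Mean local structural similarity over masked window centres.

    Gaussian-weighted 11x11 windows (sigma 1.5) on the luminance channel with
    population statistics; window centres within 5 pixels of the border are
    excluded, as are centres outside the mask.
    """
    a, b, mask = _prep(a, b, mask)
    ga, gb = _to_gray(a), _to_gray(b)
    if min(ga.shape) < 11:
        raise ValueError("image smaller than the 11-pixel SSIM window")
    filt = lambda x: gaussian_filter(x, sigma=_SIGMA, truncate=_TRUNCATE)
    ua, ub = filt(ga), filt(gb)
    vaa = filt(ga * ga) - ua * ua
    vbb = filt(gb * gb) - ub * ub
    vab = filt(ga * gb) - ua * ub
    c1, c2 = _K1**2, _K2**2
    smap = ((2 * ua * ub + c1) * (2 * vab + c2)) / ((ua**2 + ub**2 + c1) * (vaa + vbb + c2))
    pad = 5
    valid = np.zeros_like(mask)
    valid[pad:-pad, pad:-pad] = mask[pad:-pad, pad:-pad]
    if not valid.any():
        raise ValueError("mask empty after window-border exclusion")
    return float(smap[valid].mean())


def tv(a: np.ndarray, mask=None) -> float:
    """Anisotropic total variation: mean |horizontal| + mean |vertical| step.

    Differences are counted only where both neighbouring pixels are inside
    the mask; channel values are averaged.
    """
    a = np.asarray(a, dtype=np.float64)
    if mask is None:
        mask = np.ones(a.shape[:2], dtype=bool)
    else:
        mask = np.asarray(mask) > 0.5
    if not mask.any():
        raise ValueError("empty mask")
    if a.ndim == 2:
        a = a[:, :, None]
    dh = np.abs(a[:, 1:] - a[:, :-1]).mean(axis=2)
    mh = mask[:, 1:] & mask[:, :-1]
    dv = np.abs(a[1:] - a[:-1]).mean(axis=2)
    mv = mask[1:] & mask[:-1]
    total = 0.0
    if mh.any():
        total += float(dh[mh].mean())
    if mv.any():
        total += float(dv[mv].mean())
    return total


@dataclass
class MetricsReport:
    psnr: float
    rmse: float
    ssim: float
    tv: float
    region: str

    def as_dict(self) -> dict:
        return {
            "psnr": self.psnr,
            "rmse": self.rmse,
            "ssim": self.ssim,
            "tv": self.tv,
            "region": self.region,
        }


def evaluate_stitch(out, canvas, region: str = "overlap") -> MetricsReport:
    """Score a fused mosaic against the aligned reference image.

    ``region`` selects the comparison support: the overlap of both warped
    footprints (default — the only part with a direct counterpart in both
    views), their union, or the full canvas.
    """
    if region == "overlap":
        mask = canvas.overlap_mask
    elif region == "union":
        mask = np.maximum(canvas.mask_reference, canvas.mask_target)
    elif region == "full":
        mask = np.ones_like(canvas.mask_reference)
    else:
        raise ValueError(f"unknown region {region!r}")
    fused = out.fused
    ref = canvas.warped_reference
    return MetricsReport(
        psnr=psnr(fused, ref, mask),
        rmse=rmse(fused, ref, mask),
        ssim=ssim(fused, ref, mask),
        tv=tv(fused, mask),
        region=region,
    )
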