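"""Fiber segmentation with a rotated elongated Laplace-of-Gaussian bank.

Stress fibers appear as bright ridges a few pixels wide.  An elongated
Laplace-of-Gaussian (eLoG) kernel — the Laplacian of an anisotropic
Gaussian, long axis along the fiber — responds maximally when its long axis
is parallel to a ridge.  Convolving with a bank of rotated copies yields,
per pixel, (i) the maximum response over orientations, thresholded into a
binary fiber mask, and (ii) the local orientation of fibers (LOF): the
rotation angle of the winning kernel.

Orientation convention: axial angles in [0, pi) radians; 0 points toward
the image bottom edge (increasing row index), pi/2 is the left-right
direction.  The bank default is 30 kernels at pi/30 steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from skimage.filters import apply_hysteresis_threshold, threshold_otsu

__all__ = ["KernelBank", "FiberSegmentation", "build_kernel_bank", "segment"]


@dataclass
class KernelBank:
    kernels: np.ndarray          # (n, s, s) stack, rotations of one base kernel
    angles_rad: np.ndarray       # (n,) strictly increasing in [0, pi)
    sigma_along: float
    sigma_across: float

    @property
    def n(self) -> int:
        return len(self.angles_rad)

    @property
    def support(self) -> int:
        return self.kernels.shape[-1]

    @property
    def angles_deg(self) -> np.ndarray:
        return np.degrees(self.angles_rad)


def _elog_kernel(theta_rad: float, sigma_along: float, sigma_across: float,
                 support: int) -> np.ndarray:
    """Negated Laplacian of an anisotropic Gaussian at orientation theta.

    Negation makes bright ridges give positive responses.  The discrete
    kernel is mean-subtracted so the response ignores constant offsets.
    """
    half = support // 2
    r, c = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    # along-axis unit vector (cos, sin) in (row, col) coordinates
    a = r * math.cos(theta_rad) + c * math.sin(theta_rad)
    x = -r * math.sin(theta_rad) + c * math.cos(theta_rad)
    g = np.exp(-(a**2) / (2 * sigma_along**2) - (x**2) / (2 * sigma_across**2))
    log = g * ((a**2 / sigma_along**4 - 1.0 / sigma_along**2)
               + (x**2 / sigma_across**4 - 1.0 / sigma_across**2))
    k = -log
    k -= k.mean()
    return k


def build_kernel_bank(
    n: int = 30,
    sigma_along: float = 12.0,
    sigma_across: float = 1.5,
    support: int | None = None,
) -> KernelBank:
    """Build ``n`` rotations of the base eLoG kernel at pi/n steps.

    ``sigma_across`` should match the apparent fiber half-width (diffraction
    limited at typical magnifications); ``sigma_along`` sets the orientation
    selectivity and must exceed ``sigma_across``.
    """
    if n < 2:
        raise ValueError("need at least 2 orientations")
    if sigma_across <= 0 or sigma_along <= 0:
        raise ValueError("kernel widths must be positive")
    if sigma_along <= sigma_across:
        raise ValueError("kernel must be elongated: sigma_along > sigma_across")
    if support is None:
        support = int(math.ceil(6 * sigma_along)) | 1  # odd
    if support % 2 == 0:
        support += 1
    angles = np.arange(n) * math.pi / n
    kernels = np.stack([_elog_kernel(t, sigma_along, sigma_across, support)
                        for t in angles])
    return KernelBank(kernels, angles, sigma_along, sigma_across)


@dataclass
class FiberSegmentation:
    """Binary fiber mask with its local-orientation-of-fibers (LOF) map.

    ``lof_rad`` holds the winning kernel angle on mask pixels and NaN
    elsewhere; ``full_lof_rad`` keeps the argmax angle everywhere so later
    stages can assign orientations to pixels added by refinement.
    """

    mask: np.ndarray
    lof_rad: np.ndarray
    max_response: np.ndarray
    full_lof_rad: np.ndarray
    threshold: float = float("nan")

    @property
    def lof_deg(self) -> np.ndarray:
        return np.degrees(self.lof_rad)

    def with_mask(self, mask: np.ndarray) -> "FiberSegmentation":
        lof = np.where(mask, self.full_lof_rad, np.nan)
        return FiberSegmentation(mask, lof, self.max_response, self.full_lof_rad,
                                 self.threshold)


def bank_responses(image: np.ndarray, bank: KernelBank) -> np.ndarray:
    """Response stack (n, H, W) with reflective boundary handling."""
    image = np.asarray(image, dtype=float)
    if min(image.shape) < bank.support:
        raise ValueError("image smaller than kernel support")
    half = bank.support // 2
    padded = np.pad(image, half, mode="reflect")
    out = np.empty((bank.n,) + image.shape)
    for i, k in enumerate(bank.kernels):
        full = fftconvolve(padded, k, mode="same")
        out[i] = full[half:-half, half:-half]
    return out


def interpolated_argmax_angle(responses: np.ndarray, bank: KernelBank) -> np.ndarray:
    """Per-pixel winning orientation with sub-step quadratic refinement.

    The raw argmax quantizes orientations to pi/n steps; fibers lying
    between two bank angles then split their pixels across adjacent bins,
    which is noise for any orientation-agreement statistic.  Fitting a
    parabola through the response at the winning angle and its two
    (circular) neighbours refines the estimate to a fraction of a step.
    """
    idx = responses.argmax(axis=0)
    n = bank.n
    grid = np.ogrid[0 : responses.shape[1], 0 : responses.shape[2]]
    y0 = responses[idx, grid[0], grid[1]]
    ym = responses[(idx - 1) % n, grid[0], grid[1]]
    yp = responses[(idx + 1) % n, grid[0], grid[1]]
    denom = ym - 2 * y0 + yp
    with np.errstate(divide="ignore", invalid="ignore"):
        offset = np.where(denom < 0, 0.5 * (ym - yp) / denom, 0.0)
    offset = np.clip(offset, -0.5, 0.5)
    return ((idx + offset) * math.pi / n) % math.pi


def segment(
    image: np.ndarray,
    bank: KernelBank | None = None,
    threshold: float | None = None,
    relative_threshold: float | None = None,
    cell_mask: np.ndarray | None = None,
    hysteresis_low: float | None = 0.55,
) -> FiberSegmentation:
    """Segment fibers and their local orientations.

    The per-pixel maximum over the rotated responses is thresholded (Otsu
    on the positive responses inside ``cell_mask`` by default; an absolute
    ``threshold`` or a ``relative_threshold`` — a fraction of the maximum
    response — can override it) and the winning rotation angle becomes the
    LOF value.  By default the cut is applied with hysteresis: pixels above
    ``hysteresis_low`` times the threshold are kept when connected to an
    above-threshold ridge, so the full width of a fiber survives without
    admitting isolated background pixels (set ``hysteresis_low=None`` for a
    plain cut).  A constant image yields an empty mask.
    """
    if bank is None:
        bank = build_kernel_bank()
    responses = bank_responses(image, bank)
    max_resp = responses.max(axis=0)
    full_lof = interpolated_argmax_angle(responses, bank)

    region = max_resp if cell_mask is None else max_resp[cell_mask]
    if threshold is not None:
        thr = threshold
    elif relative_threshold is not None:
        thr = relative_threshold * float(region.max()) if region.size else np.inf
    else:
        positive = region[region > 0]
        # responses indistinguishable from FFT round-off mean a blank image
        blank_scale = 1e-9 * max(1.0, float(np.abs(image).max()))
        if positive.size < 2 or np.ptp(positive) <= blank_scale:
            thr = np.inf  # blank / constant image: nothing to segment
        else:
            thr = threshold_otsu(positive)
    if np.isfinite(thr) and hysteresis_low is not None:
        mask = apply_hysteresis_threshold(max_resp, hysteresis_low * thr, thr)
    else:
        mask = max_resp > thr
    if cell_mask is not None:
        mask &= cell_mask
    lof = np.where(mask, full_lof, np.nan)
    return FiberSegmentation(mask, lof, max_resp, full_lof,
                             float(thr) if np.isfinite(thr) else float("nan"))
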