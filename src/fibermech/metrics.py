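"""Descriptors of cytoskeletal architecture and cell geometry.

* Fiber alignment (FA) and mean orientation from circular statistics of the
  LOF angles: FA = 1 - sqrt(C^2 + S^2) with C, S the mean cosine and sine
  of the per-pixel orientations.  FA near 0 means strongly aligned fibers.
  (Applied to axial angles on [0, 180) this statistic gives 1 - 2/pi for a
  uniform orientation distribution; an optional angle-doubled variant gives
  the conventional axial order statistic, which reaches 1 for uniform.)
* Apparent fiber thickness (FT): the mean F-protein intensity over fiber
  pixels, optionally rescaled by the GFP-expression calibration factor
  (1 + P_endo / P_GFP) to a total-protein scale.
* Radial location (RL): the cell mask is peeled into 1-pixel-thick
  concentric rings by iterated morphological erosion; the ring radii are
  normalized (1 = cell edge, 0 = innermost) and RL is the radius of the
  ring with the highest mean F-protein intensity.
* Cell geometry: area, aspect ratio and major-axis direction from the
  second-moment ellipse of the cell mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .background import FProteinMap

__all__ = [
    "fiber_alignment",
    "fiber_thickness",
    "radial_location",
    "cell_geometry",
    "erosion_rings",
]


def fiber_alignment(lof_rad: np.ndarray, axial: bool = False):
    """Fiber alignment FA and circular mean orientation of a LOF map.

    Parameters
    ----------
    lof_rad : ndarray
        Orientations in radians, [0, pi); NaNs (off-mask pixels) ignored.
    axial : bool
        When True, compute the statistic on doubled angles (the standard
        axial-data convention) and halve the resulting mean direction.

    Returns
    -------
    (fa, theta_bar_rad)
        FA in [0, 1] (0 = perfectly aligned) and the mean orientation in
        [0, pi).
    """
    theta = np.asarray(lof_rad, dtype=float).ravel()
    theta = theta[np.isfinite(theta)]
    if theta.size == 0:
        raise ValueError("empty LOF: fiber alignment undefined")
    mult = 2.0 if axial else 1.0
    c = float(np.mean(np.cos(mult * theta)))
    s = float(np.mean(np.sin(mult * theta)))
    fa = 1.0 - math.hypot(c, s)
    theta_bar = math.atan2(s, c) / mult
    return fa, theta_bar % math.pi


def fiber_thickness(fprotein: FProteinMap, p_gfp: float | None = None,
                    p_endo: float = 0.0):
    """Apparent fiber thickness (mean fiber-pixel intensity).

    Returns ``(ft_gfp, ft)`` where ``ft`` is the calibrated value
    ``ft_gfp * (1 + P_endo / P_GFP)``; with no calibration the two match.
    """
    if not fprotein.mask.any():
        raise ValueError("empty fiber mask: fiber thickness undefined")
    ft_gfp = float(fprotein.values[fprotein.mask].mean())
    if p_gfp is None or p_endo == 0.0:
        return ft_gfp, ft_gfp
    if p_gfp <= 0:
        raise ValueError("P_GFP must be positive")
    return ft_gfp, ft_gfp * (1.0 + p_endo / p_gfp)


_CROSS = ndimage.generate_binary_structure(2, 1)


def erosion_rings(cell_mask: np.ndarray) -> list[np.ndarray]:
    """Peel the cell mask into 1-pixel-thick concentric rings.

    Ring 0 is the outermost.  The rings are disjoint and their union is the
    cell mask exactly.
    """
    rings = []
    current = cell_mask.copy()
    while current.any():
        inner = ndimage.binary_erosion(current, structure=_CROSS)
        rings.append(current & ~inner)
        current = inner
    return rings


def radial_location(fprotein: FProteinMap | np.ndarray, cell_mask: np.ndarray):
    """Normalized radius of peak fiber density.

    Returns ``(rl, radii, densities)``.  Ring ``i`` of ``K`` maps to radius
    ``1 - i/(K-1)`` (outermost ring = 1, innermost = 0); its density is the
    mean F-protein intensity over the ring (0 where the ring holds no fiber
    signal).  Ties in the maximum go to the outermost ring.
    """
    values = fprotein.values if isinstance(fprotein, FProteinMap) else np.asarray(fprotein)
    rings = erosion_rings(cell_mask)
    if len(rings) < 2:
        raise ValueError("cell mask thinner than 2 erosion rings")
    k = len(rings)
    radii = 1.0 - np.arange(k) / (k - 1)
    densities = np.array([float(values[r].mean()) for r in rings])
    rl = float(radii[int(np.argmax(densities))])  # argmax -> first max -> outermost
    return rl, radii, densities


@dataclass
class CellGeometry:
    area_um2: float
    aspect_ratio: float
    major_axis_deg: float  # axial angle, 0 = toward image bottom edge


def cell_geometry(cell_mask: np.ndarray, pixel_size_um: float) -> CellGeometry:
    """Area, aspect ratio and major-axis direction of the cell mask.

    Aspect ratio and orientation come from the eigenvalues/eigenvectors of
    the second central moments of the mask; the angle uses the same
    convention as the LOF map (0 toward the bottom edge, 90 left-right).
    """
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    rr, cc = np.nonzero(cell_mask)
    n = rr.size
    r0, c0 = rr.mean(), cc.mean()
    mu20 = np.mean((rr - r0) ** 2)
    mu02 = np.mean((cc - c0) ** 2)
    mu11 = np.mean((rr - r0) * (cc - c0))
    phi = 0.5 * math.atan2(2 * mu11, mu20 - mu02)  # angle from row axis
    common = math.hypot(mu20 - mu02, 2 * mu11)
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    aspect = math.sqrt(lam1 / lam2) if lam2 > 0 else math.inf
    return CellGeometry(
        area_um2=float(n) * pixel_size_um**2,
        aspect_ratio=float(aspect),
        major_axis_deg=math.degrees(phi % math.pi),
    )
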