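"""GFP-expression calibration: from F_GFP to total filamentous protein.

GFP-tagged monomers compete with the endogenous pool for incorporation into
fibers.  Assuming equal incorporation probability for tagged and untagged
monomers,

    F_endo / P_endo = F_GFP / P_GFP = F_total / P_total,
    P_total = P_endo + P_GFP,

so the total filamentous amount is

    F_total = F_GFP * (1 + P_endo / P_GFP)

and the filamentous fraction F_total / P_total equals F_GFP / P_GFP — an
identity that makes the fraction independent of the (unknown) endogenous
pool.  P_endo still matters for absolute amounts (F_total, calibrated fiber
thickness): it is estimated batch-wise from cells imaged in both the GFP
channel and an independent dye channel, as the value for which the linear
fit of dye-derived fiber intensity against F_total passes through the
origin.  P_endo is a property of one cell line / transfection protocol and
must be re-estimated per experimental batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "CalibrationModel",
    "f_total",
    "filamentous_fraction",
    "estimate_p_endo",
]


@dataclass
class CalibrationModel:
    """Batch-level calibration: the endogenous-pool scaling factor."""

    p_endo: float
    batch: str = ""
    n_cells: int = 0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.p_endo < 0:
            raise ValueError("P_endo must be non-negative")


def f_total(f_gfp, p_gfp, p_endo):
    """Total filamentous protein: F_GFP * (1 + P_endo / P_GFP)."""
    p_gfp = np.asarray(p_gfp, dtype=float)
    if np.any(p_gfp <= 0):
        raise ValueError("P_GFP must be positive (untransfected cell?)")
    out = np.asarray(f_gfp, dtype=float) * (1.0 + p_endo / p_gfp)
    return out if out.ndim else float(out)


def filamentous_fraction(f_total_val, p_gfp, p_endo):
    """Fraction of the protein pool in filamentous form: F_total / P_total.

    Algebraically equals F_GFP / P_GFP, hence invariant to scaling all
    intensities by a common factor.  Values above 1 indicate a
    quantification failure and are flagged with a ValueError.
    """
    denom = p_endo + np.asarray(p_gfp, dtype=float)
    if np.any(denom <= 0):
        raise ValueError("P_endo + P_GFP must be positive")
    frac = np.asarray(f_total_val, dtype=float) / denom
    if np.any(frac > 1.0 + 1e-9):
        raise ValueError("filamentous fraction exceeds 1: quantification failure")
    out = np.clip(frac, 0.0, 1.0)
    return out if out.ndim else float(out)


def _fit_intercept(f_dye, f_tot):
    slope, intercept = np.polyfit(f_tot, f_dye, 1)
    return intercept


def estimate_p_endo(
    f_gfp: np.ndarray,
    p_gfp: np.ndarray,
    f_dye: np.ndarray,
    p_endo_max: float | None = None,
    rel_tol: float = 1e-6,
    batch: str = "",
) -> CalibrationModel:
    """Estimate P_endo from paired GFP/dye quantifications.

    For each candidate P_endo the dye-channel fiber intensity is regressed
    (ordinary least squares) on F_total(P_endo); the estimate is the root of
    the fit intercept as a function of P_endo, found by bisection on
    [0, p_endo_max] (default 100x the median P_GFP).  The intercept is
    monotone in P_endo for fixed data, so the root is unique when it exists.
    """
    f_gfp = np.asarray(f_gfp, dtype=float)
    p_gfp = np.asarray(p_gfp, dtype=float)
    f_dye = np.asarray(f_dye, dtype=float)
    if f_gfp.size < 3:
        raise ValueError("need at least 3 calibration cells")
    if np.ptp(p_gfp) == 0:
        raise ValueError("calibration cells must span a range of P_GFP")
    if p_endo_max is None:
        p_endo_max = 100.0 * float(np.median(p_gfp))

    def intercept(p):
        return _fit_intercept(f_dye, f_total(f_gfp, p_gfp, p))

    scale = float(np.mean(np.abs(f_dye))) or 1.0
    i0 = intercept(0.0)
    if abs(i0) <= rel_tol * scale:
        root = 0.0
    else:
        # The intercept is monotone near the physical root but can curl back
        # toward zero again at implausibly large P_endo, so bracket the
        # FIRST sign change scanning up from zero.
        grid = np.concatenate([[0.0], np.geomspace(
            max(1e-6 * p_endo_max, 1e-12), p_endo_max, 400)])
        vals = np.array([i0] + [intercept(g) for g in grid[1:]])
        sign_change = np.nonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))[0]
        if sign_change.size == 0:
            best = int(np.argmin(np.abs(vals)))
            if abs(vals[best]) > 1e-3 * scale:
                raise ValueError(
                    "no origin-crossing fit in [0, P_endo_max]; "
                    f"min |intercept| = {vals[best]:.3g} at P_endo = {grid[best]:.3g}"
                )
            root = float(grid[best])
        else:
            lo, hi = grid[sign_change[0]], grid[sign_change[0] + 1]
            root = brentq(intercept, lo, hi, xtol=rel_tol * max(hi, 1.0),
                          rtol=8.9e-16)
    return CalibrationModel(
        p_endo=float(root),
        batch=batch,
        n_cells=int(f_gfp.size),
        diagnostics={
            "residual_intercept": float(intercept(root)),
            "intercept_at_zero": float(i0),
            "p_endo_max": float(p_endo_max),
        },
    )
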