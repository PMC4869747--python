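"""AFM force-curve analysis with the bottom-effect cone correction (BECC).

A conical tip indenting a thin sample bonded to a rigid substrate produces
more force than Sneddon's half-space solution predicts.  The BECC model adds
two correction terms in the ratio of indentation to local sample height, so
Young's modulus can be fitted reliably even where the cell is thin:

    F = (8 E tan(theta) delta^2) / (3 pi)
        * { 1 + 1.7795 * (2 tan(theta) / pi^2) * (delta / h)
              + 16 * 1.7795^2 * tan^2(theta) * (delta^2 / h^2) }

with theta the half-opening angle of the cone, delta the indentation, h the
local sample height and Poisson's ratio fixed at 0.5 (the 0.5 value is baked
into the numerical constants and is not configurable).

Force balance and kinematics for a cantilever of spring constant k:

    F = k d                  (d: cantilever deflection)
    delta = (Z - Z_cp) - d   (Z: piezo displacement, Z_cp: contact point)
    h = Z_glass - Z_cp       (Z_glass: piezo position at glass contact)

Z increases as the tip approaches the sample, so the bare-glass contact lies
beyond the cell-surface contact and ``Z_glass - Z_cp`` is the local height.

The contact point is found by a sequential search: every admissible sample
index is tried as Z_cp, the modulus is fitted on the samples beyond it, and
the candidate maximizing the coefficient of determination r^2 wins.  Fits
with r^2 <= 0.75 are flagged as rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "BECC_CONSTANT",
    "ForceCurve",
    "IndentationFit",
    "NoContactError",
    "becc_force",
    "baseline_correct",
    "fit_modulus",
    "find_contact_point",
    "pool_cell",
]

#: First-order bottom-effect coefficient for a cone on a bonded sample.
BECC_CONSTANT = 1.7795

#: r^2 acceptance gate for individual force-curve fits.
R2_GATE = 0.75

#: Height thresholds (um) used to pool fits into cytoskeletal and
#: nuclear-region classes; heights inside [4, 5] um belong to neither.
CSK_MAX_HEIGHT_UM = 4.0
NR_MIN_HEIGHT_UM = 5.0


class NoContactError(ValueError):
    """Raised when no plausible tip-sample contact is found in a ramp."""


def becc_force(e_pa, theta_deg, delta_m, h_m):
    """Indentation force (N) of a cone on a finite-thickness bonded sample.

    Parameters
    ----------
    e_pa : float
        Young's modulus in Pa.
    theta_deg : float
        Half-opening angle of the conical tip, degrees, in (0, 90).
    delta_m : float or ndarray
        Indentation depth in meters, >= 0.
    h_m : float
        Local sample height in meters, > 0.

    Returns
    -------
    float or ndarray
        Applied force in newtons.
    """
    delta_m = np.asarray(delta_m, dtype=float)
    if not 0.0 < theta_deg < 90.0:
        raise ValueError(f"tip half-angle must be in (0, 90) deg, got {theta_deg}")
    if h_m <= 0:
        raise ValueError(f"sample height must be positive, got {h_m}")
    if np.any(delta_m < 0):
        raise ValueError("indentation must be non-negative")
    tan_t = math.tan(math.radians(theta_deg))
    base = 8.0 * e_pa * tan_t * delta_m**2 / (3.0 * math.pi)
    ratio = delta_m / h_m
    correction = (
        1.0
        + BECC_CONSTANT * (2.0 * tan_t / math.pi**2) * ratio
        + 16.0 * BECC_CONSTANT**2 * tan_t**2 * ratio**2
    )
    out = base * correction
    return out if out.ndim else float(out)


def becc_shape(theta_deg, delta_m, h_m):
    """BECC force per unit modulus (``becc_force`` with E = 1 Pa).

    The model is linear in E, so least squares on the contact segment
    reduces to a one-parameter projection onto this shape function.
    """
    return becc_force(1.0, theta_deg, delta_m, h_m)


@dataclass
class ForceCurve:
    """One AFM approach ramp in calibrated units.

    ``z_nm`` is the piezo displacement (increasing toward the sample) and
    ``d_nm`` the cantilever deflection; both in nanometers.
    """

    z_nm: np.ndarray
    d_nm: np.ndarray
    k_n_per_m: float
    theta_deg: float
    z_glass_nm: float
    curve_id: str = ""

    def __post_init__(self):
        self.z_nm = np.asarray(self.z_nm, dtype=float)
        self.d_nm = np.asarray(self.d_nm, dtype=float)
        if self.z_nm.shape != self.d_nm.shape or self.z_nm.ndim != 1:
            raise ValueError("z and d must be 1-D arrays of equal length")
        dz = np.diff(self.z_nm)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("piezo displacement must be strictly monotone")
        if self.k_n_per_m <= 0:
            raise ValueError("spring constant must be positive")
        if not 0.0 < self.theta_deg < 90.0:
            raise ValueError("tip half-angle must be in (0, 90) deg")
        if np.all(dz < 0):  # store ramps in approach order
            self.z_nm = self.z_nm[::-1].copy()
            self.d_nm = self.d_nm[::-1].copy()

    def __len__(self):
        return self.z_nm.size


@dataclass
class IndentationFit:
    """Result of fitting one force curve with the BECC model."""

    z_cp_nm: float
    e_pa: float
    r2: float
    h_um: float
    accepted: bool
    n_contact: int = 0
    curve_id: str = ""


def baseline_correct(curve: ForceCurve, fraction: float = 0.25) -> ForceCurve:
    """Remove deflection offset and tilt fitted on the first ``fraction`` of samples."""
    n0 = max(2, int(round(fraction * len(curve))))
    coef = np.polyfit(curve.z_nm[:n0], curve.d_nm[:n0], 1)
    d = curve.d_nm - np.polyval(coef, curve.z_nm)
    return ForceCurve(curve.z_nm, d, curve.k_n_per_m, curve.theta_deg,
                      curve.z_glass_nm, curve.curve_id)


def fit_modulus(curve: ForceCurve, z_cp_nm: float, min_contact: int = 10):
    """Fit Young's modulus for a fixed contact-point candidate.

    Returns ``(e_pa, r2, h_um, n_contact)``.  The modulus enters the BECC
    force linearly, so the least-squares solution is the projection of the
    measured contact forces onto the BECC shape function evaluated at the
    indentations ``delta = (Z - Z_cp) - d``.
    """
    h_nm = curve.z_glass_nm - z_cp_nm
    if h_nm <= 0:
        raise ValueError("candidate contact point lies beyond the glass reference")
    contact = curve.z_nm > z_cp_nm
    delta_nm = (curve.z_nm[contact] - z_cp_nm) - curve.d_nm[contact]
    ok = delta_nm > 0
    if ok.sum() < min_contact:
        raise NoContactError(
            f"only {int(ok.sum())} contact samples beyond Z_cp={z_cp_nm:g} nm"
        )
    delta_m = delta_nm[ok] * 1e-9
    force_n = curve.k_n_per_m * curve.d_nm[contact][ok] * 1e-9
    g = becc_shape(curve.theta_deg, delta_m, h_nm * 1e-9)
    gg = float(g @ g)
    e_pa = max(0.0, float(g @ force_n) / gg) if gg > 0 else 0.0
    resid = force_n - e_pa * g
    ss_tot = float(np.sum((force_n - force_n.mean()) ** 2))
    ss_res = float(resid @ resid)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return e_pa, r2, h_nm * 1e-3, int(ok.sum())


def find_contact_point(
    curve: ForceCurve,
    min_contact_fraction: float = 0.10,
    min_contact: int = 10,
    correct_baseline: bool = True,
    baseline_fraction: float = 0.25,
) -> IndentationFit:
    """Locate the contact point by exhaustive search over sample indices.

    Every index leaving at least ``min_contact_fraction`` of the ramp in
    contact (and a positive height below the glass reference) is tried as
    Z_cp; the candidate with the highest contact-segment r^2 wins, ties
    resolved toward the larger (shallower-contact) Z_cp.
    """
    if len(curve) < 50:
        raise ValueError("curve too short for contact-point search")
    work = baseline_correct(curve, baseline_fraction) if correct_baseline else curve
    n = len(work)
    n_keep = max(min_contact, int(math.ceil(min_contact_fraction * n)))
    best = None
    for i in range(n - n_keep):
        z_cp = work.z_nm[i]
        if work.z_glass_nm - z_cp <= 0:
            continue
        try:
            e_pa, r2, h_um, n_contact = fit_modulus(work, z_cp, min_contact)
        except NoContactError:
            continue
        # ">=" keeps the later (larger Z_cp) candidate on exact ties
        if best is None or r2 >= best.r2:
            best = IndentationFit(z_cp, e_pa, r2, h_um, r2 > R2_GATE,
                                  n_contact, curve.curve_id)
    if best is None:
        raise NoContactError("no admissible contact-point candidate")
    # Guard against pure-baseline ramps: the fitted contact forces must rise
    # clearly above the baseline force noise.
    n0 = max(2, int(round(baseline_fraction * n)))
    sigma_f = curve.k_n_per_m * 1e-9 * float(
        1.4826 * np.median(np.abs(work.d_nm[:n0] - np.median(work.d_nm[:n0])))
    )
    max_model_force = best.e_pa * becc_shape(
        work.theta_deg,
        max(0.0, (work.z_nm[-1] - best.z_cp_nm)) * 1e-9,
        (work.z_glass_nm - best.z_cp_nm) * 1e-9,
    )
    if max_model_force <= 10.0 * sigma_f:
        raise NoContactError("deflection never rises above baseline noise")
    return best


def pool_cell(
    fits: Sequence[IndentationFit],
    csk_max_height_um: float = CSK_MAX_HEIGHT_UM,
    nr_min_height_um: float = NR_MIN_HEIGHT_UM,
):
    """Pool accepted per-location fits into per-cell stiffness values.

    Locations with height below ``csk_max_height_um`` contribute to the
    cytoskeletal pool, locations above ``nr_min_height_um`` to the
    nuclear-region pool; heights in between are discarded.  Each pool is
    summarized by its median modulus; an empty pool yields NaN.

    Returns ``(e_csk_pa, e_nr_pa)``.
    """
    csk = [f.e_pa for f in fits if f.accepted and f.h_um < csk_max_height_um]
    nr = [f.e_pa for f in fits if f.accepted and f.h_um > nr_min_height_um]
    e_csk = float(np.median(csk)) if csk else float("nan")
    e_nr = float(np.median(nr)) if nr else float("nan")
    return e_csk, e_nr
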