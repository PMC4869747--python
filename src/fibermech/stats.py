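"""Statistical layer: stiffness-vs-fiber-amount fits and architecture models.

Three analyses connect the image-derived quantities to the AFM moduli:

1. A linear stiffness model per protein and compartment,
   ``E = E0 + alpha [F]``, optionally on points binned by sorted
   filamentous fraction (bins of 10 cells for cytoskeletal fits, 4 for
   nuclear-region fits, following the pooling used to reduce single-cell
   scatter).
2. Analysis of covariance comparing two such fits (equal-slope and
   equal-intercept contrasts within the joint interaction regression, with
   a Scheffe adjustment for the two-contrast family).
3. A modulation model for the residual ratio E / E_fit,
   ``E/E_fit = a + b FA/<FA> + c FT/<FT> + d RL/<RL>``,
   with the regressor subset chosen by nested F-tests over all 2^3 subsets
   (forward stepwise at alpha = 0.05).

``derived_quantities`` computes the two headline numbers implied by the
fitted linear models: the asymptotic myosin-to-actin fraction ratio at
equal predicted stiffness, and the critical actin fraction where the
predicted cytoskeletal and nuclear-region stiffnesses cross.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "LinearFitResult",
    "ModulationFitResult",
    "bin_cells",
    "fit_stiffness_model",
    "compare_fits_ancova",
    "fit_modulation_model",
    "derived_quantities",
]

#: Required columns of a per-cell record table for the stiffness fits.
STIFFNESS_COLUMNS = ("fraction", "e_kpa")
#: Additional columns required by the modulation model.
MODULATION_COLUMNS = ("fa", "ft", "rl")


@dataclass
class LinearFitResult:
    """OLS fit of E (kPa) on the filamentous fraction."""

    e0_kpa: float
    alpha_kpa: float
    se_e0: float
    se_alpha: float
    p_model: float          # model-vs-constant F-test
    r2: float
    n: int

    def predict(self, fraction):
        return self.e0_kpa + self.alpha_kpa * np.asarray(fraction, dtype=float)

    def ci_e0(self, level=0.95):
        z = sps.t.ppf(0.5 + level / 2, max(1, self.n - 2))
        return self.e0_kpa - z * self.se_e0, self.e0_kpa + z * self.se_e0

    def ci_alpha(self, level=0.95):
        z = sps.t.ppf(0.5 + level / 2, max(1, self.n - 2))
        return self.alpha_kpa - z * self.se_alpha, self.alpha_kpa + z * self.se_alpha


def bin_cells(records: pd.DataFrame, bin_size: int,
              drop_incomplete: bool = True) -> pd.DataFrame:
    """Average consecutive cells after sorting by filamentous fraction.

    Returns one row per bin with the mean fraction, mean modulus and bin
    size.  The trailing short bin is dropped by default.
    """
    df = records.dropna(subset=list(STIFFNESS_COLUMNS)).sort_values("fraction")
    if len(df) < bin_size:
        raise ValueError("fewer records than one bin")
    rows = []
    for start in range(0, len(df), bin_size):
        chunk = df.iloc[start : start + bin_size]
        if drop_incomplete and len(chunk) < bin_size:
            break
        rows.append({"fraction": chunk["fraction"].mean(),
                     "e_kpa": chunk["e_kpa"].mean(),
                     "n": len(chunk)})
    return pd.DataFrame(rows)


def fit_stiffness_model(points: pd.DataFrame, robust: bool = True) -> LinearFitResult:
    """OLS of ``e_kpa`` on ``fraction`` with the model-vs-constant p-value.

    ``robust=True`` reports heteroscedasticity-consistent (HC3) standard
    errors: per-cell stiffness scatter grows with the mean, and plain OLS
    intervals undercover the slope in that regime.
    """
    df = points.dropna(subset=list(STIFFNESS_COLUMNS))
    if len(df) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(df["fraction"].to_numpy()) == 0:
        raise ValueError("degenerate fractions: all equal")
    x = sm.add_constant(df["fraction"].to_numpy())
    fit = sm.OLS(df["e_kpa"].to_numpy(), x).fit(
        cov_type="HC3" if robust else "nonrobust")
    return LinearFitResult(
        e0_kpa=float(fit.params[0]),
        alpha_kpa=float(fit.params[1]),
        se_e0=float(fit.bse[0]),
        se_alpha=float(fit.bse[1]),
        p_model=float(fit.f_pvalue),
        r2=float(fit.rsquared),
        n=int(fit.nobs),
    )


def compare_fits_ancova(data_a: pd.DataFrame, data_b: pd.DataFrame) -> dict:
    """ANCOVA between two stiffness cohorts.

    Fits the joint regression ``E ~ F + group + F:group`` and tests the
    group contrasts: different intercepts (``group``), different slopes
    (``F:group``) and the joint hypothesis that the two regressions are
    identical.  ``p_slope_scheffe`` / ``p_intercept_scheffe`` adjust the
    single-contrast tests for the two-comparison family by Scheffe's
    method (contrast F compared against ``q * F_{q,df}`` with q = 2).
    """
    a = data_a.dropna(subset=list(STIFFNESS_COLUMNS))
    b = data_b.dropna(subset=list(STIFFNESS_COLUMNS))
    f = np.concatenate([a["fraction"], b["fraction"]])
    e = np.concatenate([a["e_kpa"], b["e_kpa"]])
    g = np.concatenate([np.zeros(len(a)), np.ones(len(b))])
    x = np.column_stack([np.ones_like(f), f, g, f * g])
    fit = sm.OLS(e, x).fit()
    df_resid = fit.df_resid
    q = 2  # family: intercept and slope contrasts

    def contrast_p(idx):
        t = fit.tvalues[idx]
        p_raw = 2 * sps.t.sf(abs(t), df_resid)
        p_scheffe = sps.f.sf(t**2 / q, q, df_resid)
        return float(p_raw), float(p_scheffe)

    p_int, p_int_s = contrast_p(2)
    p_slope, p_slope_s = contrast_p(3)
    joint = fit.f_test(np.array([[0, 0, 1, 0], [0, 0, 0, 1]]))
    return {
        "p_intercept": p_int,
        "p_slope": p_slope,
        "p_intercept_scheffe": p_int_s,
        "p_slope_scheffe": p_slope_s,
        "p_joint": float(joint.pvalue),
        "slope_difference_kpa": float(fit.params[3]),
        "intercept_difference_kpa": float(fit.params[2]),
    }


@dataclass
class ModulationFitResult:
    """Architecture-modulation fit of the stiffness residual ratio."""

    terms: tuple[str, ...]                 # subset of ("fa", "ft", "rl")
    coefficients: dict = field(default_factory=dict)   # incl. "a" intercept
    standard_errors: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    normalizers: dict = field(default_factory=dict)    # <FA>, <FT>, <RL>
    r2: float = 0.0
    n: int = 0
    selection_path: list = field(default_factory=list)

    _LETTER = {"fa": "b", "ft": "c", "rl": "d"}


def _modulation_design(df, terms, normalizers):
    cols = [np.ones(len(df))]
    for t in terms:
        cols.append(df[t].to_numpy() / normalizers[t])
    return np.column_stack(cols)


def fit_modulation_model(
    records: pd.DataFrame,
    fit: LinearFitResult,
    terms: tuple[str, ...] | None = None,
    select_alpha: float = 0.05,
) -> ModulationFitResult:
    """Fit (or select) the normalized architecture-modulation model.

    The response is ``E / E_fit`` with ``E_fit = E0 + alpha [F]`` per cell;
    cells with non-positive predicted stiffness are excluded with a
    warning.  Regressors are the requested descriptors divided by their
    sample means over the included cells, so each normalized regressor
    averages 1 and the intercept ``a`` sits on the grand-mean scale.

    With ``terms=None`` the regressor subset is chosen by forward stepwise
    nested F-tests over all subsets of {FA, FT, RL}: starting from the
    constant model, the most significant single-term addition is accepted
    while its F-test p-value is below ``select_alpha``.
    """
    needed = list(STIFFNESS_COLUMNS) + list(MODULATION_COLUMNS)
    df = records.dropna(subset=needed).copy()
    e_fit = fit.predict(df["fraction"])
    bad = e_fit <= 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} cells with non-positive E_fit")
        df = df[~bad]
        e_fit = e_fit[~bad]
    y = df["e_kpa"].to_numpy() / np.asarray(e_fit)
    normalizers = {t: float(df[t].mean()) for t in MODULATION_COLUMNS}

    def ols(term_set):
        x = _modulation_design(df, term_set, normalizers)
        return sm.OLS(y, x).fit()

    path = []
    if terms is None:
        y_scale = float(y @ y)
        current: tuple[str, ...] = ()
        model = ols(current)
        while True:
            if model.ssr <= 1e-16 * max(y_scale, 1e-300):
                break  # current model already exact to rounding
            candidates = [t for t in MODULATION_COLUMNS if t not in current]
            if not candidates:
                break
            best_t, best_p, best_model = None, 1.0, None
            for t in candidates:
                trial = ols(current + (t,))
                # nested F-test: one added regressor
                ssr0, ssr1 = model.ssr, trial.ssr
                dfree = trial.df_resid
                if ssr0 - ssr1 <= 1e-14 * max(ssr0, 1e-300):
                    p = 1.0  # no improvement (including exact zero-residual fits)
                elif ssr1 <= 0:
                    p = 0.0
                else:
                    fstat = (ssr0 - ssr1) / (ssr1 / dfree)
                    p = float(sps.f.sf(fstat, 1, dfree))
                if p < best_p:
                    best_t, best_p, best_model = t, p, trial
            path.append((current + (best_t,), best_p))
            if best_p < select_alpha:
                current = current + (best_t,)
                model = best_model
            else:
                break
        terms = current
    else:
        terms = tuple(terms)
        model = ols(terms)

    names = ["a"] + [ModulationFitResult._LETTER[t] for t in terms]
    return ModulationFitResult(
        terms=terms,
        coefficients=dict(zip(names, map(float, model.params))),
        standard_errors=dict(zip(names, map(float, model.bse))),
        p_values=dict(zip(names, map(float, model.pvalues))),
        normalizers={k.upper(): v for k, v in normalizers.items()},
        r2=float(model.rsquared),
        n=int(model.nobs),
        selection_path=path,
    )


def derived_quantities(
    actin_csk: LinearFitResult,
    myosin_csk: LinearFitResult,
    actin_nr: LinearFitResult,
) -> dict:
    """Headline quantities implied by the linear stiffness fits.

    * ``myosin_actin_slope``: setting the actin and myosin cytoskeletal
      models to the same predicted E gives
      [M] = (E0_A - E0_M)/alpha_M + (alpha_A/alpha_M) [A]; at high
      fractions the two grow in parallel with slope alpha_A / alpha_M.
    * ``critical_actin_pct``: the actin fraction (in percent) where the
      cytoskeletal and nuclear-region predictions cross,
      A* = (E0_NR - E0_CSK) / (alpha_CSK - alpha_NR).  Equal slopes leave
      no crossing (returned as NaN with a flag).
    """
    if myosin_csk.alpha_kpa == 0:
        raise ValueError("myosin slope is zero: slope ratio undefined")
    slope = actin_csk.alpha_kpa / myosin_csk.alpha_kpa
    d_alpha = actin_csk.alpha_kpa - actin_nr.alpha_kpa
    if d_alpha == 0:
        critical = float("nan")
    else:
        critical = 100.0 * (actin_nr.e0_kpa - actin_csk.e0_kpa) / d_alpha
    return {
        "myosin_actin_slope": float(slope),
        "critical_actin_pct": float(critical),
        "has_crossing": d_alpha != 0,
    }
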