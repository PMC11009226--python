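"""Van't Hoff thermodynamics of the two-state hydration equilibrium.

The integrated absorption area of each amide-I sub-band is proportional
to (concentration) x (transition dipole)^2, so the equilibrium constant
of the weakly hydrogen-bonded state is

    K_eq = C_WHB / C_SHB = (A_WHB * mu_SHB^2) / (A_SHB * mu_WHB^2).

A linear fit of ln K_eq against 1/T gives the enthalpy (slope = -dH/R)
and entropy (intercept = dS/R) of the SHB -> WHB transition, and
dG(T) = dH - T dS.  The dipole-sensitivity analysis rescales every K_eq
by an alternative squared-dipole ratio and refits: dH is invariant under
any constant rescaling, while dS shifts by exactly R ln(factor).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.stats import linregress

from .constants import R
from .types import ThermoResult, TwoComponentFit

__all__ = [
    "equilibrium_constant",
    "vant_hoff_fit",
    "gibbs",
    "dipole_sensitivity",
    "thermo_from_fits",
]


def equilibrium_constant(area_whb: float, area_shb: float,
                         mu_shb: float, mu_whb: float) -> float:
    """Dipole-corrected equilibrium constant of WHB formation.

    K_eq = (A_WHB * mu_SHB^2) / (A_SHB * mu_WHB^2); all inputs must be
    positive.  Doubling both areas leaves K_eq unchanged.
    """
    for name, v in (("area_whb", area_whb), ("area_shb", area_shb),
                    ("mu_shb", mu_shb), ("mu_whb", mu_whb)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return (area_whb * mu_shb**2) / (area_shb * mu_whb**2)


def vant_hoff_fit(temperatures_K: Sequence[float],
                  keq: Sequence[float],
                  weights: Optional[Sequence[float]] = None):
    """Fit ln K_eq = -dH/(R T) + dS/R by least squares.

    Parameters
    ----------
    temperatures_K:
        Absolute temperatures, Kelvin (>= 3 points).
    keq:
        Positive equilibrium constants at those temperatures.
    weights:
        Optional per-point weights for ln K_eq (inverse variances); the
        default is an unweighted ordinary least-squares fit.

    Returns
    -------
    (dH, dH_se, dS, dS_se):
        Enthalpy in kJ/mol and entropy in J/(mol K) with standard errors
        from the regression covariance.
    """
    T = np.asarray(temperatures_K, dtype=float)
    K = np.asarray(keq, dtype=float)
    if T.size < 3:
        raise ValueError("van't Hoff fit needs >= 3 temperatures")
    if T.size != K.size:
        raise ValueError("temperatures and keq must have equal length")
    if np.any(K <= 0):
        raise ValueError("equilibrium constants must be positive")
    x = 1.0 / T
    y = np.log(K)
    if weights is None:
        res = linregress(x, y)
        slope, slope_se = res.slope, res.stderr
        intercept, intercept_se = res.intercept, res.intercept_stderr
    else:
        w = np.asarray(weights, dtype=float)
        (slope, intercept), cov = np.polyfit(x, y, 1, w=np.sqrt(w), cov="unscaled")
        slope_se, intercept_se = np.sqrt(np.diag(cov))
    dH = -slope * R / 1000.0
    dH_se = slope_se * R / 1000.0
    dS = intercept * R
    dS_se = intercept_se * R
    return float(dH), float(dH_se), float(dS), float(dS_se)


def gibbs(dH: float, dS: float, temperature_K: float,
          dH_se: float = 0.0, dS_se: float = 0.0, cov_HS: float = 0.0):
    """Free-energy difference dG = dH - T dS (kJ/mol).

    dH in kJ/mol, dS in J/(mol K), temperature in Kelvin.  The standard
    error propagates the dH and dS uncertainties (with their covariance
    when supplied, in (kJ/mol)*(J/mol/K) units).
    """
    if temperature_K <= 0:
        raise ValueError("temperature must be positive (Kelvin)")
    dG = dH - temperature_K * dS / 1000.0
    var = dH_se**2 + (temperature_K / 1000.0) ** 2 * dS_se**2 \
        - 2.0 * (temperature_K / 1000.0) * cov_HS
    return float(dG), float(np.sqrt(max(var, 0.0)))


def thermo_from_fits(fits: Sequence[TwoComponentFit],
                     mu_shb: float, mu_whb: float) -> ThermoResult:
    """Full thermodynamic analysis from per-temperature two-Voigt fits.

    Converts each fit's areas to K_eq via the dipole-corrected relation,
    runs the van't Hoff fit, and evaluates dG at every fit temperature.
    """
    if len(fits) < 3:
        raise ValueError("thermodynamic analysis needs >= 3 temperatures")
    T = np.array([f.temperature for f in fits], dtype=float) + 273.15
    keq = np.array([
        equilibrium_constant(f.whb.area, f.shb.area, mu_shb, mu_whb)
        for f in fits])
    dH, dH_se, dS, dS_se = vant_hoff_fit(T, keq)
    dG = np.empty_like(T)
    dG_se = np.empty_like(T)
    for i, t in enumerate(T):
        dG[i], dG_se[i] = gibbs(dH, dS, t, dH_se, dS_se)
    return ThermoResult(
        temperatures_K=T, keq=keq,
        dH=dH, dH_se=dH_se, dS=dS, dS_se=dS_se,
        dG=dG, dG_se=dG_se,
        dipole_ratio_sq=(mu_shb / mu_whb) ** 2,
    )


def dipole_sensitivity(base: ThermoResult,
                       mu_whb_alternatives: Sequence[float],
                       mu_shb: Optional[float] = None) -> list:
    """Refit the van't Hoff line under alternative WHB transition dipoles.

    Every K_eq in ``base`` was computed with the squared dipole ratio
    ``base.dipole_ratio_sq``; an alternative mu_WHB rescales each K_eq by
    the constant factor (mu_SHB/mu_WHB_alt)^2 / base_ratio_sq.  The refit
    leaves dH invariant and shifts dS by R ln(factor).

    Returns a list of dicts with keys ``mu_whb``, ``factor``, ``dH``,
    ``dH_se``, ``dS``, ``dS_se``.
    """
    if not np.isfinite(base.dipole_ratio_sq):
        raise ValueError("base result carries no dipole ratio")
    if mu_shb is None:
        # dipole_ratio_sq = (mu_shb/mu_whb)^2 fixes only the ratio; any
        # consistent mu_shb works since only ratios enter below
        mu_shb = 1.0
        mu_whb_base = mu_shb / np.sqrt(base.dipole_ratio_sq)
    else:
        mu_whb_base = mu_shb / np.sqrt(base.dipole_ratio_sq)
    out = []
    for mu_alt in mu_whb_alternatives:
        if mu_alt <= 0:
            raise ValueError("alternative dipole must be positive")
        factor = (mu_whb_base / mu_alt) ** 2
        dH, dH_se, dS, dS_se = vant_hoff_fit(
            base.temperatures_K, base.keq * factor)
        out.append({
            "mu_whb": float(mu_alt),
            "factor": float(factor),
            "dH": dH, "dH_se": dH_se,
            "dS": dS, "dS_se": dS_se,
        })
    return out
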