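"""Chemical-exchange kinetics from waiting-time 2D IR series.

The extraction protocol:

1. :func:`normalize_series` - divide every matrix by the absolute value
   of its own integral over a diagonal-peak window (the 1->2 transition
   of the low-frequency state), removing vibrational/orientational
   population decay from the waiting-time dependence.
2. :func:`subtract_reference` - subtract the T_w = 0 spectrum, isolating
   what changed during the waiting time.
3. :func:`cross_peak_trace` - integrate the difference over a small
   window at the cross-peak position (pump on one state, probe on the
   other); the growth of this signed integral tracks the exchange.
4. :func:`fit_exchange` - fit m(T_w) = A (1 - exp(-T_w/tau)); k1 = 1/tau
   is the forward exchange rate constant.

:func:`arrhenius_fit` turns rate constants at several temperatures into
an activation energy, and :func:`reverse_rate` applies detailed balance
k1 = k-1 exp(-dG/(R T)) to obtain the reverse rate from the forward one
and the free-energy difference.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .constants import R
from .types import ArrheniusResult, ExchangeKinetics, SpectralWindow, Spectrum2DSeries

__all__ = [
    "window_integral",
    "normalize_series",
    "subtract_reference",
    "cross_peak_trace",
    "fit_exchange",
    "arrhenius_fit",
    "reverse_rate",
    "extract_forward_kinetics",
]

#: normalization aborts when a window integral falls below this fraction
#: of the matrix maximum
NORMALIZATION_FLOOR = 1e-12


def window_integral(series_axes: Tuple[np.ndarray, np.ndarray],
                    matrix: np.ndarray, window: SpectralWindow) -> float:
    """Signed 2D trapezoidal integral of a matrix over a window.

    ``series_axes`` is (omega_tau, omega_t); the matrix is indexed
    [omega_t, omega_tau].
    """
    omega_tau, omega_t = series_axes
    if window.tau_lo < omega_tau[0] or window.tau_hi > omega_tau[-1] \
            or window.t_lo < omega_t[0] or window.t_hi > omega_t[-1]:
        raise ValueError(
            f"window ({window.tau_lo}-{window.tau_hi}, "
            f"{window.t_lo}-{window.t_hi}) cm^-1 lies outside the axes")
    m_tau = (omega_tau >= window.tau_lo) & (omega_tau <= window.tau_hi)
    m_t = (omega_t >= window.t_lo) & (omega_t <= window.t_hi)
    if m_tau.sum() < 2 or m_t.sum() < 2:
        raise ValueError("window covers fewer than 2 grid points on an axis")
    sub = matrix[np.ix_(m_t, m_tau)]
    inner = np.trapezoid(sub, omega_tau[m_tau], axis=1)
    return float(np.trapezoid(inner, omega_t[m_t]))


def normalize_series(series: Spectrum2DSeries,
                     norm_window: SpectralWindow) -> Spectrum2DSeries:
    """Divide each matrix by |its own window integral|.

    The normalized series is scale invariant: multiplying the raw input
    by any positive constant leaves it unchanged.  The per-waiting-time
    normalization factors are logged in ``metadata["normalization"]``.
    """
    axes = (series.omega_tau, series.omega_t)
    factors = []
    matrices = []
    for tw, m in zip(series.waiting_times, series.matrices):
        integral = window_integral(axes, m, norm_window)
        floor = NORMALIZATION_FLOOR * max(np.abs(m).max(), 1.0)
        if abs(integral) < floor:
            raise ValueError(
                f"normalization window integral {integral:.3g} at "
                f"T_w = {tw} ps is below the floor {floor:.3g}")
        factors.append(abs(integral))
        matrices.append(m / abs(integral))
    meta = dict(series.metadata)
    meta["normalization"] = {
        "window": (norm_window.tau_lo, norm_window.tau_hi,
                   norm_window.t_lo, norm_window.t_hi),
        "factors": factors,
    }
    return Spectrum2DSeries(
        omega_tau=series.omega_tau.copy(), omega_t=series.omega_t.copy(),
        waiting_times=series.waiting_times.copy(), matrices=matrices,
        temperature=series.temperature, metadata=meta)


def subtract_reference(series: Spectrum2DSeries) -> Spectrum2DSeries:
    """Subtract the T_w = 0 matrix from every matrix in the series.

    The T_w = 0 entry becomes identically zero and is retained, so the
    difference series keeps the same waiting-time grid.
    """
    ref = series.matrix_at(0.0)
    matrices = [m - ref for m in series.matrices]
    meta = dict(series.metadata)
    meta["reference_subtracted"] = True
    return Spectrum2DSeries(
        omega_tau=series.omega_tau.copy(), omega_t=series.omega_t.copy(),
        waiting_times=series.waiting_times.copy(), matrices=matrices,
        temperature=series.temperature, metadata=meta)


def cross_peak_trace(diff_series: Spectrum2DSeries,
                     cross_window: SpectralWindow) -> np.ndarray:
    """Signed window integral of each difference matrix.

    Returns an array of shape (n_waiting_times, 2): column 0 the waiting
    time (ps), column 1 the integrated cross-peak magnitude.
    """
    axes = (diff_series.omega_tau, diff_series.omega_t)
    vals = [window_integral(axes, m, cross_window)
            for m in diff_series.matrices]
    return np.column_stack([diff_series.waiting_times, vals])


def fit_exchange(trace: np.ndarray,
                 temperature: Optional[float] = None) -> ExchangeKinetics:
    """Fit a saturating exponential m(T_w) = A (1 - exp(-T_w/tau)).

    Parameters
    ----------
    trace:
        Array of (T_w in ps, magnitude) rows, >= 4 waiting times.
    temperature:
        Sample temperature (deg C) stored on the result.

    Returns
    -------
    ExchangeKinetics with tau_forward (ps), its standard error, and the
    fitted amplitude; k1 = 1/tau_forward.

    Raises
    ------
    RuntimeError
        On non-convergence or when tau runs into its bounds (e.g. for a
        constant nonzero trace, which the model class cannot represent).
    """
    trace = np.asarray(trace, dtype=float)
    tw, m = trace[:, 0], trace[:, 1]
    if tw.size < 4:
        raise ValueError("exchange fit needs >= 4 waiting times")
    span = tw.max() - tw.min()
    tau_hi = 100.0 * span
    tau_lo = 1e-4 * span

    def model(t, A, tau):
        return A * (1.0 - np.exp(-t / tau))

    a0 = m[np.argmax(tw)]
    if a0 == 0.0:
        a0 = 1.0
    try:
        popt, pcov = curve_fit(
            model, tw, m, p0=[a0, 0.3 * span],
            bounds=([-np.inf, tau_lo], [np.inf, tau_hi]), maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"exchange fit did not converge: {exc}") from exc
    A, tau = popt
    dt_min = float(np.min(np.diff(np.unique(tw))))
    if tau >= 0.99 * tau_hi or tau <= max(1.01 * tau_lo, 0.2 * dt_min):
        # a constant nonzero trace drives tau below the waiting-time
        # resolution (the model cannot be constant and nonzero)
        raise RuntimeError(
            f"exchange fit ran into its tau bound (tau = {tau:.3g} ps, "
            f"resolution {dt_min:.3g} ps, bounds [{tau_lo:.3g}, "
            f"{tau_hi:.3g}]); the trace is not a resolvable saturating "
            "exponential")
    tau_se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("nan")
    return ExchangeKinetics(
        temperature=temperature if temperature is not None else float("nan"),
        tau_forward=float(tau), tau_forward_se=tau_se, amplitude=float(A))


def arrhenius_fit(rates: Sequence[Tuple[float, float]]) -> ArrheniusResult:
    """Arrhenius fit ln k = ln A - Ea/(R T) of (temperature K, k ps^-1) pairs.

    Returns Ea in kJ/mol with its standard error, and the natural log of
    the pre-exponential factor (ln of k in ps^-1).
    """
    rates = np.asarray(rates, dtype=float)
    if rates.ndim != 2 or rates.shape[1] != 2:
        raise ValueError("rates must be (temperature, k) pairs")
    if rates.shape[0] < 3:
        raise ValueError("Arrhenius fit needs >= 3 points")
    T, k = rates[:, 0], rates[:, 1]
    if np.any(T <= 0) or np.any(k <= 0):
        raise ValueError("temperatures and rates must be positive")
    res = linregress(1.0 / T, np.log(k))
    return ArrheniusResult(
        Ea=float(-res.slope * R / 1000.0),
        Ea_se=float(res.stderr * R / 1000.0),
        ln_prefactor=float(res.intercept),
        ln_prefactor_se=float(res.intercept_stderr),
        n_points=int(rates.shape[0]))


def reverse_rate(k_forward: float, dG: float, temperature_K: float) -> float:
    """Detailed-balance reverse rate k-1 = k1 exp(+dG/(R T)).

    dG is the free-energy difference of the forward (SHB -> WHB)
    transition in kJ/mol; a positive dG makes the reverse process faster
    than the forward one.
    """
    if temperature_K <= 0:
        raise ValueError("temperature must be positive (Kelvin)")
    if k_forward <= 0:
        raise ValueError("k_forward must be positive")
    return float(k_forward * np.exp(dG * 1000.0 / (R * temperature_K)))


def extract_forward_kinetics(series: Spectrum2DSeries,
                             norm_window: SpectralWindow,
                             cross_window: SpectralWindow,
                             dG: Optional[float] = None) -> ExchangeKinetics:
    """Run the full protocol on one series: normalize, subtract the
    T_w = 0 reference, integrate the cross window, fit the exponential.

    When ``dG`` (kJ/mol) is supplied the detailed-balance reverse time
    constant is filled in as well (requires the series temperature).
    """
    normalized = normalize_series(series, norm_window)
    diff = subtract_reference(normalized)
    trace = cross_peak_trace(diff, cross_window)
    kin = fit_exchange(trace, temperature=series.temperature)
    if dG is not None:
        if series.temperature is None:
            raise ValueError("series temperature is required to derive k_reverse")
        T = series.temperature + 273.15
        k_rev = reverse_rate(kin.k_forward, dG, T)
        kin = replace(kin, tau_reverse=1.0 / k_rev, dG_used=float(dG))
    return kin
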