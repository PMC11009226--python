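"""Synthetic data generators standing in for the spectrometer and the MD box.

Three generators with the statistical structure the analysis stages assume:

* :func:`simulate_ftir` - temperature series of two-component amide-I
  absorption spectra.  The two Voigt sub-bands represent the strongly
  (SHB) and weakly (WHB) hydrogen-bonded carbonyl states; their area
  ratio follows van't Hoff thermodynamics through the dipole-weighted
  equilibrium constant, and the band centers drift linearly with
  temperature.
* :func:`simulate_2dir_series` - waiting-time series of chemical-exchange
  2D IR spectra: each population pathway i -> j contributes a positive
  0->1 / negative 1->2 Gaussian peak pair, cross peaks growing with
  waiting time.
* :func:`simulate_trajectory` - toy hydration trajectories (extended-XYZ
  style atom roles) with designed shell structure or telegraph-switching
  hydrogen-bond dynamics.

Everything is deterministic under a seed; molar energies use R (J/mol/K).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import voigt_profile as _scipy_voigt

from .constants import R, celsius_to_kelvin
from .types import Spectrum1D, Spectrum2DSeries, Trajectory

__all__ = [
    "FTIRGenParams",
    "ExchangeGenParams",
    "TrajGenParams",
    "simulate_ftir",
    "exchange_populations",
    "simulate_2dir_series",
    "simulate_trajectory",
]


# --------------------------------------------------------------------------
# FTIR generator
# --------------------------------------------------------------------------

def _default_grid() -> np.ndarray:
    return np.arange(1530.0, 1700.0 + 0.5, 1.0)


@dataclass
class FTIRGenParams:
    """Parameters of the two-component amide-I FTIR generator.

    Centers are the sub-band positions at ``ref_temperature_c`` (deg C);
    they drift linearly at ``shift_rate_*`` cm^-1 per deg C.  The area
    ratio at temperature T follows

        A_WHB / A_SHB = K_eq(T) * (mu_WHB / mu_SHB)^2,

    with K_eq(T) = exp(-dH/(R T) + dS/R), the inverse of the
    dipole-corrected equilibrium-constant relation used downstream.  The
    summed area shrinks by ``extinction_slope`` (fractional loss per deg C)
    to emulate the weak temperature dependence of the molar extinction.
    """

    center_shb: float = 1607.8          # cm^-1 at reference temperature
    center_whb: float = 1620.9          # cm^-1
    shift_rate_shb: float = 0.07        # cm^-1 / degC
    shift_rate_whb: float = 0.02        # cm^-1 / degC
    gaussian_sigma_shb: float = 3.0     # cm^-1
    gaussian_sigma_whb: float = 3.0     # cm^-1
    lorentzian_gamma_shb: float = 3.0   # cm^-1
    lorentzian_gamma_whb: float = 3.0   # cm^-1
    total_area: float = 1.0             # absorbance * cm^-1
    dH: float = 6.22                    # kJ/mol (SHB -> WHB)
    dS: float = 15.34                   # J/mol/K
    mu_shb: float = 0.344               # Debye
    mu_whb: float = 0.321               # Debye
    extinction_slope: float = 0.002     # fractional area loss per degC
    noise_sd: float = 0.0               # absorbance
    ref_temperature_c: float = 23.0     # degC
    grid: np.ndarray = field(default_factory=_default_grid)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        for name in ("gaussian_sigma_shb", "gaussian_sigma_whb",
                     "lorentzian_gamma_shb", "lorentzian_gamma_whb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if (self.gaussian_sigma_shb == 0 and self.lorentzian_gamma_shb == 0) or \
           (self.gaussian_sigma_whb == 0 and self.lorentzian_gamma_whb == 0):
            raise ValueError("each component needs a nonzero width")
        if self.mu_shb <= 0 or self.mu_whb <= 0:
            raise ValueError("transition dipoles must be positive")
        if self.total_area < 0:
            raise ValueError("total_area must be non-negative")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")

    def keq(self, temperature_c: float) -> float:
        """Equilibrium constant K_eq(T) = exp(-dH/(R T) + dS/R)."""
        T = celsius_to_kelvin(temperature_c)
        return float(np.exp(-self.dH * 1000.0 / (R * T) + self.dS / R))

    def area_ratio_whb_to_shb(self, temperature_c: float) -> float:
        """A_WHB/A_SHB implied by the thermodynamics and dipoles."""
        return self.keq(temperature_c) * (self.mu_whb / self.mu_shb) ** 2

    def with_room_temperature_ratio(self, ratio_shb_to_whb: float) -> "FTIRGenParams":
        """Return a copy whose dS is adjusted so the SHB:WHB area ratio at
        the reference temperature equals ``ratio_shb_to_whb`` exactly.

        Only the entropy is moved (dH fixed), i.e. the van't Hoff line is
        shifted vertically until it passes through the requested point.
        """
        if ratio_shb_to_whb <= 0:
            raise ValueError("area ratio must be positive")
        T = celsius_to_kelvin(self.ref_temperature_c)
        keq_target = (1.0 / ratio_shb_to_whb) * (self.mu_shb / self.mu_whb) ** 2
        dS_new = R * (np.log(keq_target) + self.dH * 1000.0 / (R * T))
        return replace(self, dS=float(dS_new))


def _voigt_band(x: np.ndarray, center: float, sigma: float, gamma: float,
                area: float) -> np.ndarray:
    """Area-normalized Voigt profile scaled by ``area``.

    Degenerate limits are handled by scipy's Faddeeva-based profile,
    which accepts sigma == 0 (pure Lorentzian); gamma == 0 is the pure
    Gaussian.
    """
    return area * _scipy_voigt(x - center, sigma, gamma)


def simulate_ftir(params: FTIRGenParams,
                  temperatures: Sequence[float],
                  seed: Optional[int] = None) -> list:
    """Generate a temperature-ordered list of two-component FTIR spectra.

    Parameters
    ----------
    params:
        Generator parameters; see :class:`FTIRGenParams`.
    temperatures:
        Sample temperatures in degrees Celsius, each in [0, 100].
    seed:
        Seed for the additive Gaussian noise (ignored when
        ``params.noise_sd == 0``).

    Returns
    -------
    list of Spectrum1D, ordered by increasing temperature.
    """
    temps = sorted(float(t) for t in temperatures)
    if any(t < 0.0 or t > 100.0 for t in temps):
        raise ValueError("temperatures must lie in the 0-100 degC range")

    # the grid must cover both drifted centers with 5-width margins
    for t in temps:
        for name, center, sig, gam, rate in (
            ("center_shb", params.center_shb, params.gaussian_sigma_shb,
             params.lorentzian_gamma_shb, params.shift_rate_shb),
            ("center_whb", params.center_whb, params.gaussian_sigma_whb,
             params.lorentzian_gamma_whb, params.shift_rate_whb),
        ):
            c = center + rate * (t - params.ref_temperature_c)
            margin = 5.0 * max(sig, gam)
            if c - margin < params.grid[0] or c + margin > params.grid[-1]:
                raise ValueError(
                    f"grid [{params.grid[0]}, {params.grid[-1]}] does not cover "
                    f"{name} = {c:.1f} cm^-1 (+/- {margin:.1f}) at {t} degC"
                )

    rng = np.random.default_rng(seed)
    spectra = []
    for t in temps:
        ratio = params.area_ratio_whb_to_shb(t)
        total = params.total_area * (
            1.0 - params.extinction_slope * (t - params.ref_temperature_c))
        if total < 0:
            raise ValueError(f"extinction slope drives total area negative at {t} degC")
        a_shb = total / (1.0 + ratio)
        a_whb = total - a_shb
        c_shb = params.center_shb + params.shift_rate_shb * (t - params.ref_temperature_c)
        c_whb = params.center_whb + params.shift_rate_whb * (t - params.ref_temperature_c)
        y = np.zeros_like(params.grid)
        if a_shb > 0:
            y += _voigt_band(params.grid, c_shb, params.gaussian_sigma_shb,
                             params.lorentzian_gamma_shb, a_shb)
        if a_whb > 0:
            y += _voigt_band(params.grid, c_whb, params.gaussian_sigma_whb,
                             params.lorentzian_gamma_whb, a_whb)
        if params.noise_sd > 0:
            y = y + rng.normal(0.0, params.noise_sd, size=y.shape)
        spectra.append(Spectrum1D(
            wavenumber=params.grid.copy(),
            absorbance=y,
            temperature=t,
            metadata={
                "generator": "simulate_ftir",
                "area_shb": a_shb,
                "area_whb": a_whb,
                "center_shb_cm1": c_shb,
                "center_whb_cm1": c_whb,
                "noise_sd": params.noise_sd,
                "seed": seed,
            },
        ))
    return spectra


# --------------------------------------------------------------------------
# Two-state exchange kinetics core
# --------------------------------------------------------------------------

def exchange_populations(k_forward: float, k_reverse: float, tw: float) -> np.ndarray:
    """Conditional-probability matrix of the two-state exchange process.

    State order is (SHB, WHB).  Returns P with P[j, i] = P(final=j |
    initial=i) = [exp(K tw)]_{ji} for the rate matrix

        K = [[-k_f,  k_r],
             [ k_f, -k_r]].

    Columns sum to one; the closed form of the 2x2 matrix exponential is
    used (eigenvalues 0 and -(k_f + k_r)).
    """
    if k_forward < 0 or k_reverse < 0:
        raise ValueError("rate constants must be non-negative")
    if tw < 0:
        raise ValueError("waiting time must be non-negative")
    ktot = k_forward + k_reverse
    if ktot == 0.0:
        return np.eye(2)
    decay = np.exp(-ktot * tw)
    p_shb_eq = k_reverse / ktot
    p_whb_eq = k_forward / ktot
    return np.array([
        [p_shb_eq + p_whb_eq * decay, p_shb_eq * (1.0 - decay)],
        [p_whb_eq * (1.0 - decay),    p_whb_eq + p_shb_eq * decay],
    ])


# --------------------------------------------------------------------------
# 2D IR generator
# --------------------------------------------------------------------------

def _default_waiting_times() -> np.ndarray:
    return np.round(np.arange(0.0, 3.0 + 0.05, 0.1), 10)


def _default_grid_2d() -> np.ndarray:
    return np.arange(1560.0, 1660.0 + 0.25, 0.5)


@dataclass
class ExchangeGenParams:
    """Parameters of the chemical-exchange 2D IR generator.

    Each population pathway i -> j (i, j in {SHB, WHB}) contributes a
    positive Gaussian peak at (omega_i(0->1), omega_j(0->1)) and a
    negative one shifted down the probe axis by the anharmonicity.  The
    pathway weight depends on ``mode``:

    * ``"phenomenological"`` (default): cross-peak weights grow as
      1 - exp(-T_w / tau) with tau the forward (SHB->WHB) or reverse
      (WHB->SHB) time constant, while diagonal weights stay at one.  The
      downstream protocol (normalize / subtract / integrate / single
      exponential) then recovers the generating time constants exactly,
      mirroring the assignment of the fitted cross-peak growth rate to
      the forward rate constant.
    * ``"master_equation"``: weights are the conditional probabilities of
      the two-state master equation, whose cross-peak growth eigenvalue
      is k_f + k_r (documented divergence from the phenomenological
      assignment).

    Vibrational-lifetime damping exp(-T_w / T1) uses the lifetime of the
    *pumped* state: the normalization window shares the pumped state with
    the cross peak, so the damping cancels from the normalized trace -
    that cancellation is the point of the normalization step.
    """

    freq_shb_01: float = 1607.8        # cm^-1
    freq_whb_01: float = 1620.9        # cm^-1
    anharmonicity: float = 13.0        # cm^-1, 1->2 red-shift
    tau_forward: float = 0.53          # ps, SHB -> WHB
    tau_reverse: float = 0.27          # ps, WHB -> SHB
    t1_shb: float = 0.67               # ps
    t1_whb: float = 0.72               # ps
    linewidth_pump_shb: float = 3.0    # Gaussian sigma, cm^-1
    linewidth_pump_whb: float = 3.0
    linewidth_probe_shb: float = 3.0
    linewidth_probe_whb: float = 3.0
    keq: float = 0.508                 # initial WHB/SHB population ratio
    waiting_times: np.ndarray = field(default_factory=_default_waiting_times)
    mode: str = "phenomenological"
    grid_tau: np.ndarray = field(default_factory=_default_grid_2d)
    grid_t: np.ndarray = field(default_factory=_default_grid_2d)
    diagonal_correlation: float = 0.0  # pump-probe correlation of diagonal peaks
    spectral_diffusion_tau: float = 1.0  # ps, decay of that correlation

    def __post_init__(self) -> None:
        self.waiting_times = np.asarray(self.waiting_times, dtype=float)
        self.grid_tau = np.asarray(self.grid_tau, dtype=float)
        self.grid_t = np.asarray(self.grid_t, dtype=float)
        for name in ("tau_forward", "tau_reverse", "t1_shb", "t1_whb",
                     "linewidth_pump_shb", "linewidth_pump_whb",
                     "linewidth_probe_shb", "linewidth_probe_whb",
                     "spectral_diffusion_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.anharmonicity <= 0:
            raise ValueError("anharmonicity must be positive")
        if self.keq <= 0:
            raise ValueError("keq must be positive")
        if np.any(self.waiting_times < 0):
            raise ValueError("waiting times must be non-negative")
        if not np.any(np.isclose(self.waiting_times, 0.0)):
            raise ValueError("waiting_times must include 0")
        if self.mode not in ("phenomenological", "master_equation"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (-1.0 < self.diagonal_correlation < 1.0):
            raise ValueError("diagonal_correlation must lie in (-1, 1)")

    @property
    def initial_populations(self) -> tuple:
        """(p_SHB, p_WHB) derived from keq; they sum to one."""
        p_whb = self.keq / (1.0 + self.keq)
        return 1.0 - p_whb, p_whb


def _gaussian_peak_2d(tau_mesh, t_mesh, tau_center, t_center,
                      sigma_tau, sigma_t, corr=0.0):
    """Bivariate Gaussian peak of unit maximum on the 2D grid."""
    x = (tau_mesh - tau_center) / sigma_tau
    y = (t_mesh - t_center) / sigma_t
    if corr == 0.0:
        return np.exp(-0.5 * (x * x + y * y))
    q = (x * x - 2.0 * corr * x * y + y * y) / (1.0 - corr * corr)
    return np.exp(-0.5 * q)


def simulate_2dir_series(params: ExchangeGenParams) -> Spectrum2DSeries:
    """Generate a waiting-time series of chemical-exchange 2D IR spectra.

    Matrices are indexed [omega_t, omega_tau]; positive peaks are 0->1
    pathways, negative peaks the anharmonically red-shifted 1->2
    pathways.  At T_w = 0 every cross-peak weight is exactly zero.
    """
    freqs = {"shb": params.freq_shb_01, "whb": params.freq_whb_01}
    sig_pump = {"shb": params.linewidth_pump_shb, "whb": params.linewidth_pump_whb}
    sig_probe = {"shb": params.linewidth_probe_shb, "whb": params.linewidth_probe_whb}
    t1 = {"shb": params.t1_shb, "whb": params.t1_whb}
    taus = {"shb": params.tau_forward, "whb": params.tau_reverse}

    # every 0->1 and 1->2 peak center must sit on both grids
    for state, f01 in freqs.items():
        for axis_name, grid in (("grid_tau", params.grid_tau), ("grid_t", params.grid_t)):
            lo_needed = f01 - params.anharmonicity if axis_name == "grid_t" else f01
            if f01 > grid[-1] or lo_needed < grid[0]:
                raise ValueError(
                    f"{axis_name} [{grid[0]}, {grid[-1]}] does not cover the "
                    f"{state} peaks at {f01} / {f01 - params.anharmonicity} cm^-1"
                )

    p0 = dict(zip(("shb", "whb"), params.initial_populations))
    tau_mesh, t_mesh = np.meshgrid(params.grid_tau, params.grid_t)

    matrices = []
    for tw in params.waiting_times:
        if params.mode == "master_equation":
            P = exchange_populations(1.0 / params.tau_forward,
                                     1.0 / params.tau_reverse, tw)
            idx = {"shb": 0, "whb": 1}
            weight = {(i, j): P[idx[j], idx[i]]
                      for i in ("shb", "whb") for j in ("shb", "whb")}
        else:
            weight = {}
            for i in ("shb", "whb"):
                grow = 1.0 - np.exp(-tw / taus[i])
                for j in ("shb", "whb"):
                    weight[(i, j)] = grow if i != j else 1.0
        corr = params.diagonal_correlation * np.exp(-tw / params.spectral_diffusion_tau)
        M = np.zeros_like(tau_mesh)
        for i in ("shb", "whb"):
            damping = np.exp(-tw / t1[i])      # pumped-state lifetime
            for j in ("shb", "whb"):
                amp = p0[i] * weight[(i, j)] * damping
                if amp == 0.0:
                    continue
                c = corr if i == j else 0.0
                M += amp * _gaussian_peak_2d(
                    tau_mesh, t_mesh, freqs[i], freqs[j],
                    sig_pump[i], sig_probe[j], c)
                M -= amp * _gaussian_peak_2d(
                    tau_mesh, t_mesh, freqs[i], freqs[j] - params.anharmonicity,
                    sig_pump[i], sig_probe[j], c)
        matrices.append(M)

    return Spectrum2DSeries(
        omega_tau=params.grid_tau.copy(),
        omega_t=params.grid_t.copy(),
        waiting_times=params.waiting_times.copy(),
        matrices=matrices,
        metadata={
            "generator": "simulate_2dir_series",
            "mode": params.mode,
            "tau_forward_ps": params.tau_forward,
            "tau_reverse_ps": params.tau_reverse,
        },
    )


# --------------------------------------------------------------------------
# Toy trajectory generator
# --------------------------------------------------------------------------

_OH_BOND = 0.96          # Angstrom, water O-H bond
_HOH_ANGLE = np.deg2rad(104.5)
_NH_BOND = 0.95          # Angstrom, amide N-H
_MIN_SEPARATION = 0.5    # Angstrom, atoms closer than this are resampled
_BULK_EXCLUSION = 3.7    # Angstrom, bulk water O kept this far from carbonyl O


@dataclass
class TrajGenParams:
    """Parameters of the toy hydration-trajectory generator.

    Modes
    -----
    ``"uniform"``
        Ideal-gas water placement (RDF == 1 reference case).
    ``"designed_shell"``
        ``n_shell_waters`` waters each point one H at the carbonyl O,
        with the O...H distance drawn from a narrow Gaussian around
        ``shell_r_peak``; all remaining waters stay outside the shell.
    ``"telegraph_hbond"``
        One water H pinned at the strong-bond distance (1.65 A); a second,
        tagged water switches its near H between a bound distance (1.85 A)
        and an unbound distance (3.0 A) via a continuous-time two-state
        telegraph process with rates ``telegraph_rates`` = (on, off) in
        ps^-1, started from its stationary distribution.
    """

    n_frames: int = 200
    n_waters: int = 50
    box_length: float = 20.0           # Angstrom
    shell_model: str = "designed_shell"
    shell_r_peak: float = 1.65         # Angstrom
    shell_r_sd: float = 0.08           # Angstrom
    n_shell_waters: int = 2
    bound_distance: float = 1.85       # Angstrom, telegraph bound state
    unbound_distance: float = 3.0      # Angstrom, telegraph unbound state
    telegraph_rates: tuple = (2.0, 1.0)  # (on, off), ps^-1
    frame_dt: float = 0.1              # ps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames <= 0 or self.n_waters <= 0:
            raise ValueError("counts must be positive")
        if self.shell_model not in ("uniform", "designed_shell", "telegraph_hbond"):
            raise ValueError(f"unknown shell_model {self.shell_model!r}")
        if any(r < 0 for r in self.telegraph_rates):
            raise ValueError("telegraph rates must be non-negative")
        max_radius = max(self.shell_r_peak, self.unbound_distance, _BULK_EXCLUSION)
        if self.box_length <= 2.0 * max_radius:
            raise ValueError("box_length must exceed twice the largest shell radius")
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")
        # crude density guard: each water needs ~a (2 A)^3 cell
        if self.n_waters * 8.0 > 0.5 * self.box_length**3:
            raise ValueError("impossible water density for this box")


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _water_from_oxygen(rng: np.random.Generator, ow: np.ndarray) -> np.ndarray:
    """Coordinates (3, 3): OW and two HW in a random orientation."""
    u = _random_unit_vectors(rng, 1)[0]
    # second bond direction at the HOH angle, random azimuth about u
    a = _random_unit_vectors(rng, 1)[0]
    perp = a - np.dot(a, u) * u
    norm = np.linalg.norm(perp)
    while norm < 1e-8:
        a = _random_unit_vectors(rng, 1)[0]
        perp = a - np.dot(a, u) * u
        norm = np.linalg.norm(perp)
    perp /= norm
    v = np.cos(_HOH_ANGLE) * u + np.sin(_HOH_ANGLE) * perp
    return np.stack([ow, ow + _OH_BOND * u, ow + _OH_BOND * v])


def _water_pointing_at(rng: np.random.Generator, target: np.ndarray,
                       distance: float) -> np.ndarray:
    """Water with one H at ``distance`` from ``target``, O-H aimed at it."""
    direction = _random_unit_vectors(rng, 1)[0]
    h1 = target + distance * direction
    ow = target + (distance + _OH_BOND) * direction
    a = _random_unit_vectors(rng, 1)[0]
    axis = -direction  # O -> H1 direction
    perp = a - np.dot(a, axis) * axis
    norm = np.linalg.norm(perp)
    while norm < 1e-8:
        a = _random_unit_vectors(rng, 1)[0]
        perp = a - np.dot(a, axis) * axis
        norm = np.linalg.norm(perp)
    perp /= norm
    v = np.cos(_HOH_ANGLE) * axis + np.sin(_HOH_ANGLE) * perp
    h2 = ow + _OH_BOND * v
    return np.stack([ow, h1, h2])


def _min_image(delta: np.ndarray, box: Optional[float]) -> np.ndarray:
    if box is not None:
        delta = delta - box * np.round(delta / box)
    return delta


def _telegraph_states(rng: np.random.Generator, times: np.ndarray,
                      k_on: float, k_off: float) -> np.ndarray:
    """Bound(True)/unbound(False) state at each frame time.

    Exact continuous-time simulation: exponential holding times, initial
    state drawn from the stationary distribution, so the marginal bound
    probability at every frame is exactly k_on / (k_on + k_off).
    """
    if k_on + k_off == 0.0:
        return np.ones(times.size, dtype=bool)
    p_bound = k_on / (k_on + k_off)
    state = bool(rng.random() < p_bound)
    states = np.empty(times.size, dtype=bool)
    t_now = times[0]
    t_next = t_now + rng.exponential(1.0 / (k_off if state else k_on))
    for i, t in enumerate(times):
        while t_next <= t:
            state = not state
            rate = k_off if state else k_on
            t_next += rng.exponential(1.0 / rate)
        states[i] = state
    return states


def simulate_trajectory(params: TrajGenParams) -> Trajectory:
    """Generate a toy hydration trajectory around a single amide group.

    Atom order per frame: OC, N, HN, then (OW, HW, HW) per water.  The
    solute sits at the box center.  Output is deterministic under
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    L = params.box_length
    center = np.full(3, L / 2.0)

    oc = center
    n_pos = center + np.array([2.4, 0.0, 0.0])
    hn = n_pos + _NH_BOND * np.array(
        [np.cos(np.deg2rad(60.0)), np.sin(np.deg2rad(60.0)), 0.0])
    solute = np.stack([oc, n_pos, hn])

    labels = ["OC", "N", "HN"] + ["OW", "HW", "HW"] * params.n_waters
    times = np.round(np.arange(params.n_frames) * params.frame_dt, 10)

    special = 0
    if params.shell_model == "designed_shell":
        special = params.n_shell_waters
        if special > params.n_waters:
            raise ValueError("n_shell_waters exceeds n_waters")
    elif params.shell_model == "telegraph_hbond":
        special = 2
        if params.n_waters < 2:
            raise ValueError("telegraph_hbond needs at least 2 waters")
        bound = _telegraph_states(rng, times, *params.telegraph_rates)

    frames = np.empty((params.n_frames, len(labels), 3))
    for f in range(params.n_frames):
        atoms = [solute]
        placed = solute.copy()

        def _place_shell_water(distance: float) -> np.ndarray:
            nonlocal placed
            for _attempt in range(200):
                w = _water_pointing_at(rng, oc, distance)
                d = np.linalg.norm(
                    _min_image(w[:, None, :] - placed[None, :, :], L), axis=2)
                # the aimed H sits `distance` from OC by construction;
                # only clashes with previously placed atoms are rejected
                if d.min() >= _MIN_SEPARATION:
                    placed = np.vstack([placed, w])
                    return w
            raise RuntimeError("could not place a shell water without overlap")

        if params.shell_model == "designed_shell":
            for _ in range(special):
                # truncate so the whole water keeps exactly one H inside
                # the 2.55 A shell: below ~1.35 A the second H swings in
                while True:
                    r = rng.normal(params.shell_r_peak, params.shell_r_sd)
                    if 1.35 < r < 2.45:
                        break
                atoms.append(_place_shell_water(r))
        elif params.shell_model == "telegraph_hbond":
            atoms.append(_place_shell_water(1.65))
            r2 = params.bound_distance if bound[f] else params.unbound_distance
            atoms.append(_place_shell_water(r2))

        n_bulk = params.n_waters - special
        for _ in range(n_bulk):
            for _attempt in range(200):
                ow = rng.uniform(0.0, L, size=3)
                if params.shell_model != "uniform":
                    d_oc = np.linalg.norm(_min_image(ow - oc, L))
                    if d_oc < _BULK_EXCLUSION:
                        continue
                w = _water_from_oxygen(rng, ow)
                d = np.linalg.norm(
                    _min_image(w[:, None, :] - placed[None, :, :], L), axis=2)
                if d.min() >= _MIN_SEPARATION:
                    break
            else:
                raise RuntimeError("could not place a water without overlap")
            atoms.append(w)
            placed = np.vstack([placed, w])

        frames[f] = np.vstack(atoms)

    return Trajectory(labels=labels, coords=frames, times=times, box_length=L)
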