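"""Core data containers shared across the pipeline stages.

The containers are deliberately small: numpy arrays plus the metadata the
downstream stage needs (temperature, waiting times, axis vectors).  All
validate their invariants on construction so that malformed inputs fail
at the boundary rather than deep inside a fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Spectrum1D",
    "Spectrum2DSeries",
    "SpectralWindow",
    "VoigtComponent",
    "TwoComponentFit",
    "ThermoResult",
    "ExchangeKinetics",
    "ArrheniusResult",
    "Trajectory",
    "HydrationStats",
]


@dataclass
class Spectrum1D:
    """A 1D absorption spectrum on a strictly increasing wavenumber grid.

    Parameters
    ----------
    wavenumber:
        Wavenumber axis, cm^-1, strictly increasing, length >= 16.
    absorbance:
        Absorbance values, same length as ``wavenumber``.
    temperature:
        Sample temperature in degrees Celsius, or None if unknown.
    metadata:
        Free-form key/value annotations (generator parameters, filenames,
        processing flags such as edge handling of derivative filters).
    """

    wavenumber: np.ndarray
    absorbance: np.ndarray
    temperature: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumber.ndim != 1 or self.absorbance.ndim != 1:
            raise ValueError("wavenumber and absorbance must be 1-D vectors")
        if self.wavenumber.size != self.absorbance.size:
            raise ValueError(
                f"axis length {self.wavenumber.size} != absorbance length "
                f"{self.absorbance.size}"
            )
        if self.wavenumber.size < 16:
            raise ValueError("a spectrum needs at least 16 points")
        if np.any(np.diff(self.wavenumber) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")

    @property
    def npoints(self) -> int:
        return self.wavenumber.size

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        """True when the grid spacing is uniform to relative tolerance."""
        d = np.diff(self.wavenumber)
        return bool(np.all(np.abs(d - d[0]) <= rtol * abs(d[0])))


@dataclass
class Spectrum2DSeries:
    """A waiting-time series of real-valued 2D IR spectra.

    Matrices are indexed [omega_t, omega_tau]: rows follow the probe
    (detection) axis, columns the pump (excitation) axis.  The series must
    contain the zero waiting time, which the subtraction protocol uses as
    its reference.
    """

    omega_tau: np.ndarray
    omega_t: np.ndarray
    waiting_times: np.ndarray
    matrices: list
    temperature: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.omega_tau = np.asarray(self.omega_tau, dtype=float)
        self.omega_t = np.asarray(self.omega_t, dtype=float)
        self.waiting_times = np.asarray(self.waiting_times, dtype=float)
        self.matrices = [np.asarray(m, dtype=float) for m in self.matrices]
        for name, ax in (("omega_tau", self.omega_tau), ("omega_t", self.omega_t)):
            if ax.ndim != 1 or np.any(np.diff(ax) <= 0):
                raise ValueError(f"{name} must be a strictly increasing vector")
        if len(self.matrices) != self.waiting_times.size:
            raise ValueError("one matrix per waiting time is required")
        shape = (self.omega_t.size, self.omega_tau.size)
        for tw, m in zip(self.waiting_times, self.matrices):
            if m.shape != shape:
                raise ValueError(
                    f"matrix at T_w={tw} ps has shape {m.shape}, expected {shape}"
                )
        if not np.any(np.isclose(self.waiting_times, 0.0)):
            raise ValueError("the series must include T_w = 0")

    def matrix_at(self, tw: float) -> np.ndarray:
        """Return the matrix at waiting time ``tw`` (exact/close match)."""
        idx = np.flatnonzero(np.isclose(self.waiting_times, tw))
        if idx.size == 0:
            raise KeyError(f"no matrix at T_w = {tw} ps")
        return self.matrices[int(idx[0])]


@dataclass(frozen=True)
class SpectralWindow:
    """A rectangular integration window in the (omega_tau, omega_t) plane."""

    tau_lo: float
    tau_hi: float
    t_lo: float
    t_hi: float

    def __post_init__(self) -> None:
        if not (self.tau_lo < self.tau_hi and self.t_lo < self.t_hi):
            raise ValueError("window bounds must satisfy lo < hi on both axes")

    @property
    def area(self) -> float:
        """Window area in cm^-2."""
        return (self.tau_hi - self.tau_lo) * (self.t_hi - self.t_lo)

    @classmethod
    def centered(cls, tau_center: float, t_center: float, size: float = 5.0) -> "SpectralWindow":
        """Square window of side ``size`` cm^-1 centered at a point."""
        h = size / 2.0
        return cls(tau_center - h, tau_center + h, t_center - h, t_center + h)


@dataclass
class VoigtComponent:
    """One Voigt sub-band: center, Gaussian/Lorentzian widths, area.

    Standard errors default to NaN (unknown) until a fit fills them in.
    """

    center: float
    gaussian_sigma: float
    lorentzian_gamma: float
    area: float
    center_se: float = float("nan")
    gaussian_sigma_se: float = float("nan")
    lorentzian_gamma_se: float = float("nan")
    area_se: float = float("nan")

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0 or self.lorentzian_gamma < 0:
            raise ValueError("Voigt widths must be non-negative")
        if self.gaussian_sigma == 0 and self.lorentzian_gamma == 0:
            raise ValueError("sigma and gamma cannot both be zero (delta profile)")
        if self.area <= 0:
            raise ValueError("component area must be positive")

    @property
    def fwhm(self) -> float:
        """Approximate Voigt FWHM (Olivero-Longbothum formula)."""
        fl = 2.0 * self.lorentzian_gamma
        fg = 2.0 * np.sqrt(2.0 * np.log(2.0)) * self.gaussian_sigma
        return 0.5346 * fl + np.sqrt(0.2166 * fl**2 + fg**2)


@dataclass
class TwoComponentFit:
    """Result of the two-Voigt amide-I decomposition at one temperature.

    ``shb`` is always the lower-frequency component (strongly H-bonded
    state) and ``whb`` the higher-frequency one; the constructor enforces
    the labeling regardless of fit initialization order.
    """

    shb: VoigtComponent
    whb: VoigtComponent
    baseline_offset: float = 0.0
    baseline_slope: float = 0.0
    residual_rms: float = 0.0
    temperature: Optional[float] = None

    def __post_init__(self) -> None:
        if self.shb.center > self.whb.center:
            self.shb, self.whb = self.whb, self.shb
        if self.shb.center == self.whb.center:
            raise ValueError("the two components have identical centers")
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be non-negative")

    @property
    def area_ratio_shb_to_whb(self) -> float:
        """A_SHB / A_WHB, the low- to high-frequency integrated-area ratio."""
        return self.shb.area / self.whb.area

    @property
    def center_split(self) -> float:
        """Frequency difference between the sub-bands, cm^-1."""
        return self.whb.center - self.shb.center


@dataclass
class ThermoResult:
    """Van't Hoff thermodynamics of the SHB -> WHB equilibrium.

    dH in kJ/mol, dS in J/(mol K), dG in kJ/mol at each input temperature
    (Kelvin).  ``dipole_ratio_sq`` is (mu_SHB/mu_WHB)^2, the squared
    transition-dipole ratio used to convert area ratios to K_eq.
    """

    temperatures_K: np.ndarray
    keq: np.ndarray
    dH: float
    dH_se: float
    dS: float
    dS_se: float
    dG: np.ndarray
    dG_se: np.ndarray
    dipole_ratio_sq: float = float("nan")

    def __post_init__(self) -> None:
        self.temperatures_K = np.asarray(self.temperatures_K, dtype=float)
        self.keq = np.asarray(self.keq, dtype=float)
        self.dG = np.asarray(self.dG, dtype=float)
        self.dG_se = np.asarray(self.dG_se, dtype=float)
        if np.any(self.keq <= 0):
            raise ValueError("equilibrium constants must be positive")
        expected = self.dH - self.temperatures_K * self.dS / 1000.0
        if np.any(np.abs(self.dG - expected) > 1e-9):
            raise ValueError("dG inconsistent with dH - T*dS beyond 1e-9 kJ/mol")


@dataclass
class ExchangeKinetics:
    """Forward exchange kinetics at one temperature, plus the
    detailed-balance reverse rate when a free-energy difference is given.

    tau_forward in ps (k1 = 1/tau_forward in ps^-1); dG_used in kJ/mol.
    """

    temperature: float
    tau_forward: float
    tau_forward_se: float = float("nan")
    amplitude: float = float("nan")
    tau_reverse: float = float("nan")
    dG_used: float = float("nan")

    def __post_init__(self) -> None:
        if self.tau_forward <= 0:
            raise ValueError("tau_forward must be positive")

    @property
    def k_forward(self) -> float:
        """Forward rate constant k1, ps^-1."""
        return 1.0 / self.tau_forward

    @property
    def k_reverse(self) -> float:
        """Reverse rate constant k-1, ps^-1 (NaN if not derived)."""
        return 1.0 / self.tau_reverse


@dataclass
class ArrheniusResult:
    """Arrhenius parameters from a linear fit of ln k versus 1/T."""

    Ea: float
    Ea_se: float
    ln_prefactor: float
    ln_prefactor_se: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("an Arrhenius fit needs at least 3 points")


#: Role vocabulary for trajectory atoms: carbonyl oxygen, amide nitrogen,
#: amide hydrogen, water oxygen, water hydrogen.
TRAJECTORY_ROLES = ("OC", "N", "HN", "OW", "HW")


@dataclass
class Trajectory:
    """Frames of labeled atom coordinates with an optional periodic box.

    ``labels`` is one role label per atom (shared across frames);
    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom; ``times`` is
    the frame time stamp in ps.  ``box_length`` is the edge of a cubic
    periodic box in Angstrom, or None for a non-periodic trajectory.
    """

    labels: list
    coords: np.ndarray
    times: np.ndarray
    box_length: Optional[float] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.labels) != self.coords.shape[1]:
            raise ValueError("one label per atom is required")
        if self.times.size != self.coords.shape[0]:
            raise ValueError("one time stamp per frame is required")
        unknown = set(self.labels) - set(TRAJECTORY_ROLES)
        if unknown:
            raise ValueError(f"unknown atom roles: {sorted(unknown)}")
        if self.box_length is not None and self.box_length <= 0:
            raise ValueError("box_length must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def indices(self, role: str) -> np.ndarray:
        """Atom indices carrying a given role label."""
        return np.flatnonzero(np.asarray(self.labels) == np.asarray(role))


@dataclass
class HydrationStats:
    """Summary statistics of a hydration-shell analysis.

    rdf maps a pair-class name (e.g. "OC-HW") to (r_centers, g_r);
    histograms are (bin_centers, probability_density) pairs normalized to
    unit integral.
    """

    rdf: dict = field(default_factory=dict)
    coordination: float = float("nan")
    hbond_mean: float = float("nan")
    r1_hist: Optional[tuple] = None
    r2_hist: Optional[tuple] = None
    shb_fraction: float = float("nan")
    shb_fraction_se: float = float("nan")
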