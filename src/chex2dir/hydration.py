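"""Hydration-shell statistics on labeled toy or real trajectories.

Implements the standard solvation-structure toolbox around a single
amide group: radial distribution functions with minimum-image periodic
boundaries (orthorhombic/cubic boxes), shell coordination numbers by
integrating rho g(r) 4 pi r^2, geometric hydrogen-bond counting, the
nearest and second-nearest water-hydrogen distances to the carbonyl
oxygen, and the SHB/WHB classification of frames by the second-nearest
distance.

Hydrogen-bond angle convention: the geometric criterion "donor-acceptor
distance < d_max and angle < theta_max" is implemented by default as the
deviation angle between the donor->hydrogen and donor->acceptor vectors
(small angle = near-linear bond), the common practice.  The literal
angle at the donor-proton-acceptor vertex is available through
``angle_convention="hydrogen"`` (there a near-linear bond has an angle
near 180 degrees, so a < 40 degree test would keep only strongly bent
geometries); both conventions are selectable because published criteria
are frequently ambiguous on this point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .types import HydrationStats, Trajectory

__all__ = [
    "RDFResult",
    "rdf",
    "coordination_number",
    "hbond_count",
    "nearest_hw_distances",
    "classify_hydration",
    "hydration_report",
]


def _min_image(delta: np.ndarray, box: Optional[float]) -> np.ndarray:
    if box is not None:
        delta = delta - box * np.round(delta / box)
    return delta


def _pair_distances(traj: Trajectory, frame: int,
                    idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Minimum-image distance matrix (len(idx_a), len(idx_b)) in one frame."""
    a = traj.coords[frame, idx_a]
    b = traj.coords[frame, idx_b]
    d = _min_image(a[:, None, :] - b[None, :, :], traj.box_length)
    return np.linalg.norm(d, axis=2)


@dataclass
class RDFResult:
    """A radial distribution function with its normalization context."""

    r: np.ndarray          # bin centers, Angstrom
    g: np.ndarray          # g(r)
    bin_width: float       # Angstrom
    rho: float             # partner number density, Angstrom^-3
    pair: str              # e.g. "OC-HW"
    counts: np.ndarray     # raw pair counts per bin (all frames)
    n_frames: int = 1
    n_centers: int = 1


def rdf(traj: Trajectory, center_role: str, partner_role: str,
        bin_width: float = 0.05, r_max: float = 10.0) -> RDFResult:
    """Radial distribution function of partner atoms around center atoms.

    Pair distances use the minimum-image convention when the trajectory
    is periodic; the histogram is normalized by the ideal-gas shell
    expectation rho * (4 pi / 3)(r_hi^3 - r_lo^3) per center per frame,
    with the partner density rho taken from the box volume.

    Raises
    ------
    ValueError
        On an empty selection, or when ``r_max`` exceeds half the box.
    """
    idx_c = traj.indices(center_role)
    idx_p = traj.indices(partner_role)
    if idx_c.size == 0 or idx_p.size == 0:
        raise ValueError(
            f"empty selection: {center_role} x{idx_c.size}, "
            f"{partner_role} x{idx_p.size}")
    if traj.box_length is not None and r_max > traj.box_length / 2.0:
        raise ValueError(
            f"r_max = {r_max} A exceeds half the box ({traj.box_length / 2} A)")
    if traj.box_length is None:
        raise ValueError("rdf requires a periodic box (density normalization)")

    edges = np.arange(0.0, r_max + bin_width / 2.0, bin_width)
    counts = np.zeros(edges.size - 1)
    for f in range(traj.n_frames):
        d = _pair_distances(traj, f, idx_c, idx_p).ravel()
        d = d[d > 1e-9]  # drop self pairs if roles coincide
        counts += np.histogram(d, bins=edges)[0]

    volume = traj.box_length**3
    rho = idx_p.size / volume
    shell = (4.0 * np.pi / 3.0) * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = traj.n_frames * idx_c.size * rho * shell
    g = counts / norm
    r_centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(r=r_centers, g=g, bin_width=bin_width, rho=rho,
                     pair=f"{center_role}-{partner_role}", counts=counts,
                     n_frames=traj.n_frames, n_centers=int(idx_c.size))


def coordination_number(rdf_result: RDFResult, rho: float, r_cut: float) -> float:
    """Coordination number n(r_cut) = rho * integral_0^r_cut g(r) 4 pi r^2 dr.

    Integrated by the trapezoidal rule on the histogram bin centers,
    with the inner boundary closed at r = 0 where r^2 g vanishes.
    """
    r, g = rdf_result.r, rdf_result.g
    if r_cut > r[-1] + rdf_result.bin_width / 2.0:
        raise ValueError(f"r_cut = {r_cut} A beyond the histogram range")
    mask = r <= r_cut
    rr = np.concatenate([[0.0], r[mask]])
    integrand = np.concatenate([[0.0], g[mask] * 4.0 * np.pi * r[mask] ** 2])
    return float(rho * np.trapezoid(integrand, rr))


def _water_donor_map(traj: Trajectory, frame: int) -> np.ndarray:
    """Index of the nearest water oxygen for each water hydrogen."""
    idx_hw = traj.indices("HW")
    idx_ow = traj.indices("OW")
    d = _pair_distances(traj, frame, idx_hw, idx_ow)
    return idx_ow[np.argmin(d, axis=1)]


def hbond_count(traj: Trajectory, d_max: float = 3.5, theta_max: float = 40.0,
                angle_convention: str = "donor",
                include_nh_donor: bool = False):
    """Geometric hydrogen-bond count between water and the carbonyl group.

    A water O-H...O=C bond is counted when the donor-acceptor (OW-OC)
    distance is below ``d_max`` and the angle criterion (see the module
    docstring for the two conventions) is below ``theta_max`` degrees.
    With ``include_nh_donor`` the amide N-H...OW bonds are counted too.

    Returns
    -------
    (per_frame, mean):
        Integer bond count per frame and the trajectory mean.
    """
    if angle_convention not in ("donor", "hydrogen"):
        raise ValueError("angle_convention must be 'donor' or 'hydrogen'")
    for role in ("OC", "OW", "HW"):
        if traj.indices(role).size == 0:
            raise ValueError(f"missing role {role} in trajectory")
    if include_nh_donor and (traj.indices("N").size == 0
                             or traj.indices("HN").size == 0):
        raise ValueError("N/HN roles required when include_nh_donor is set")

    box = traj.box_length
    idx_hw = traj.indices("HW")
    idx_oc = traj.indices("OC")
    per_frame = np.zeros(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        donors = _water_donor_map(traj, f)  # OW index per HW
        n = 0
        for h, d_idx in zip(idx_hw, donors):
            for a_idx in idx_oc:
                n += _is_hbond(traj.coords[f], d_idx, h, a_idx, box,
                               d_max, theta_max, angle_convention)
        if include_nh_donor:
            n_idx = int(traj.indices("N")[0])
            hn_idx = int(traj.indices("HN")[0])
            for a_idx in traj.indices("OW"):
                n += _is_hbond(traj.coords[f], n_idx, hn_idx, a_idx, box,
                               d_max, theta_max, angle_convention)
        per_frame[f] = n
    return per_frame, float(per_frame.mean())


def _is_hbond(coords: np.ndarray, donor: int, hydrogen: int, acceptor: int,
              box: Optional[float], d_max: float, theta_max: float,
              convention: str) -> bool:
    da = _min_image(coords[acceptor] - coords[donor], box)
    r_da = np.linalg.norm(da)
    if r_da >= d_max or r_da < 1e-9:
        return False
    if convention == "donor":
        v1 = _min_image(coords[hydrogen] - coords[donor], box)
        v2 = da
    else:  # angle at the hydrogen between H->D and H->A
        v1 = _min_image(coords[donor] - coords[hydrogen], box)
        v2 = _min_image(coords[acceptor] - coords[hydrogen], box)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return bool(angle < theta_max)


def nearest_hw_distances(traj: Trajectory, bins: int = 80,
                         r_range: Tuple[float, float] = (1.0, 5.0)):
    """Nearest (r1) and second-nearest (r2) water-H distance to the
    carbonyl oxygen, per frame, with normalized histograms.

    Returns
    -------
    (r1, r2, r1_hist, r2_hist):
        Per-frame distance arrays (r1 <= r2) and (bin_centers, density)
        histogram pairs integrating to one.
    """
    idx_oc = traj.indices("OC")
    idx_hw = traj.indices("HW")
    if idx_hw.size < 2:
        raise ValueError("need at least 2 water hydrogens per frame")
    r1 = np.empty(traj.n_frames)
    r2 = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        d = np.sort(_pair_distances(traj, f, idx_oc, idx_hw).ravel())
        r1[f], r2[f] = d[0], d[1]
    hists = []
    for r in (r1, r2):
        density, edges = np.histogram(r, bins=bins, range=r_range, density=True)
        hists.append((0.5 * (edges[:-1] + edges[1:]), density))
    return r1, r2, hists[0], hists[1]


def classify_hydration(r2_series: np.ndarray, r_cut: float = 2.55):
    """Classify frames as SHB (r2 < r_cut) or WHB (r2 >= r_cut).

    The cutoff defaults to the first RDF valley of water hydrogens
    around the carbonyl oxygen: below it the second-nearest water H is
    still inside the first hydration shell (two strong bonds), above it
    the second bond is weak or absent.

    Returns
    -------
    (labels, shb_fraction, shb_fraction_se):
        Per-frame labels ("SHB"/"WHB"), the SHB fraction, and its
        binomial standard error.
    """
    r2 = np.asarray(r2_series, dtype=float)
    if r2.size == 0:
        raise ValueError("empty r2 series")
    if r_cut <= 0:
        raise ValueError("r_cut must be positive")
    shb = r2 < r_cut
    labels = np.where(shb, "SHB", "WHB")
    p = float(shb.mean())
    se = float(np.sqrt(p * (1.0 - p) / r2.size))
    return labels, p, se


def hydration_report(traj: Trajectory, bin_width: float = 0.05,
                     r_max: float = 10.0, shell_cut: float = 2.55,
                     d_max: float = 3.5, theta_max: float = 40.0) -> HydrationStats:
    """One-call summary: OC-HW RDF, shell coordination number, H-bond
    mean, r1/r2 histograms, and the SHB frame fraction."""
    g = rdf(traj, "OC", "HW", bin_width=bin_width, r_max=r_max)
    coord = coordination_number(g, g.rho, shell_cut)
    _, hb_mean = hbond_count(traj, d_max=d_max, theta_max=theta_max)
    r1, r2, h1, h2 = nearest_hw_distances(traj)
    _, frac, frac_se = classify_hydration(r2, r_cut=shell_cut)
    return HydrationStats(
        rdf={g.pair: (g.r, g.g)},
        coordination=coord,
        hbond_mean=hb_mean,
        r1_hist=h1, r2_hist=h2,
        shb_fraction=frac, shb_fraction_se=frac_se)
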