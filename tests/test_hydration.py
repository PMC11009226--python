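"""Hydration-shell statistics against brute-force and analytic oracles."""

import numpy as np
import pytest

from chex2dir import (TrajGenParams, Trajectory, classify_hydration,
                      coordination_number, hbond_count, nearest_hw_distances,
                      rdf, simulate_trajectory)


def _manual_traj(atoms, box=30.0, n_frames=1):
    """Trajectory from a list of (label, xyz) with the solute at origin
    shifted to the box center."""
    labels = [a[0] for a in atoms]
    coords = np.array([a[1] for a in atoms], dtype=float) + box / 2.0
    coords = np.tile(coords, (n_frames, 1, 1))
    return Trajectory(labels=labels, coords=coords,
                      times=np.arange(n_frames, dtype=float), box_length=box)


class TestRDF:
    def test_single_partner_delta_configuration(self):
        """One HW fixed at 4.2 A: g(r) is nonzero only in that bin."""
        traj = _manual_traj([("OC", (0, 0, 0)), ("HW", (4.2, 0, 0))])
        g = rdf(traj, "OC", "HW", bin_width=0.1, r_max=10.0)
        nonzero = np.flatnonzero(g.g > 0)
        assert nonzero.size == 1
        assert abs(g.r[nonzero[0]] - 4.2) <= 0.05

    def test_ideal_gas_is_flat(self):
        traj = simulate_trajectory(TrajGenParams(
            shell_model="uniform", n_frames=120, n_waters=120,
            box_length=21.0, seed=21))
        g = rdf(traj, "OC", "HW", bin_width=0.25, r_max=10.0)
        sel = (g.r >= 3.0) & (g.r <= 10.0)
        # paired hydrogens at most double the Poisson bin variance
        sigma = g.g[sel] * np.sqrt(2.0 / np.maximum(g.counts[sel], 1.0))
        assert np.all(np.abs(g.g[sel] - 1.0) <= 3.0 * sigma)

    def test_designed_shell_peak_position(self):
        """Shell H placed around 1.65 A: argmax of g(r) within one bin."""
        traj = simulate_trajectory(TrajGenParams(
            n_frames=60, n_waters=20, shell_r_peak=1.65, seed=17))
        g = rdf(traj, "OC", "HW", bin_width=0.05, r_max=9.0)
        assert abs(g.r[np.argmax(g.g)] - 1.65) <= 0.05

    def test_error_scaling_with_sample_size(self):
        """Ideal-gas noise shrinks roughly as 1/sqrt(frames): quadrupling
        the frame count about halves the RMS deviation from 1."""
        rms = {}
        for frames in (30, 120):
            traj = simulate_trajectory(TrajGenParams(
                shell_model="uniform", n_frames=frames, n_waters=100,
                box_length=21.0, seed=29))
            g = rdf(traj, "OC", "HW", bin_width=0.25, r_max=10.0)
            sel = (g.r >= 3.0) & (g.r <= 10.0)
            rms[frames] = np.sqrt(np.mean((g.g[sel] - 1.0) ** 2))
        assert rms[120] < rms[30]
        assert 1.2 < rms[30] / rms[120] < 3.5

    def test_empty_selection_rejected(self):
        traj = _manual_traj([("OC", (0, 0, 0)), ("HW", (4.2, 0, 0))])
        with pytest.raises(ValueError, match="empty"):
            rdf(traj, "OC", "OW")

    def test_r_max_beyond_half_box_rejected(self):
        traj = _manual_traj([("OC", (0, 0, 0)), ("HW", (4.2, 0, 0))], box=12.0)
        with pytest.raises(ValueError, match="half the box"):
            rdf(traj, "OC", "HW", r_max=8.0)


class TestCoordinationNumber:
    def test_uniform_gas_matches_sphere_volume(self):
        """n(r_cut) = rho (4/3) pi r_cut^3 for an ideal gas, within 2%."""
        traj = simulate_trajectory(TrajGenParams(
            shell_model="uniform", n_frames=150, n_waters=150,
            box_length=21.0, seed=31))
        g = rdf(traj, "OC", "HW", bin_width=0.1, r_max=10.0)
        r_cut = 6.0
        expected = g.rho * (4.0 / 3.0) * np.pi * r_cut**3
        assert coordination_number(g, g.rho, r_cut) == pytest.approx(
            expected, rel=0.02)

    def test_empty_inner_shell_gives_zero(self):
        traj = _manual_traj([("OC", (0, 0, 0)), ("HW", (4.2, 0, 0))])
        g = rdf(traj, "OC", "HW", bin_width=0.1, r_max=10.0)
        assert coordination_number(g, g.rho, 0.1) == 0.0

    def test_cutoff_beyond_range_rejected(self):
        traj = _manual_traj([("OC", (0, 0, 0)), ("HW", (4.2, 0, 0))])
        g = rdf(traj, "OC", "HW", bin_width=0.1, r_max=5.0)
        with pytest.raises(ValueError, match="beyond"):
            coordination_number(g, g.rho, 7.0)


class TestHbondCount:
    @staticmethod
    def _water_donating(distance, deviation_deg, extra=()):
        """OW donating to OC along x, with the O-H bond tilted by
        ``deviation_deg`` from the O->acceptor direction."""
        th = np.deg2rad(deviation_deg)
        ow = np.array([distance, 0.0, 0.0])
        h1 = ow - 0.96 * np.array([np.cos(th), np.sin(th), 0.0])
        h2 = ow + np.array([0.3, 0.9, 0.0])
        atoms = [("OC", (0, 0, 0)), ("N", (0, 5, 5)), ("HN", (0, 5.9, 5.2)),
                 ("OW", tuple(ow)), ("HW", tuple(h1)), ("HW", tuple(h2))]
        atoms += list(extra)
        return _manual_traj(atoms)

    def test_ideal_linear_geometry_counted(self):
        traj = self._water_donating(2.8, 0.0)
        _, mean = hbond_count(traj)
        assert mean == 1.0

    def test_distance_cutoff_excludes(self):
        traj = self._water_donating(3.6, 0.0)
        _, mean = hbond_count(traj)
        assert mean == 0.0

    def test_angle_cutoff_excludes(self):
        traj = self._water_donating(2.8, 55.0)
        _, mean = hbond_count(traj)
        assert mean == 0.0

    def test_hydrogen_vertex_convention_differs(self):
        """Under the literal donor-proton-acceptor vertex angle a
        near-linear bond (~180 deg at the proton) is excluded by a 40
        degree threshold."""
        traj = self._water_donating(2.8, 0.0)
        _, mean = hbond_count(traj, angle_convention="hydrogen")
        assert mean == 0.0

    def test_matches_brute_force_oracle_exactly(self):
        """Randomized 50-water frames against an independent pure-python
        double loop (same nearest-oxygen donor assignment)."""
        traj = simulate_trajectory(TrajGenParams(
            shell_model="uniform", n_frames=4, n_waters=50,
            box_length=21.0, seed=13))
        per_frame, _ = hbond_count(traj, d_max=5.0, theta_max=60.0)

        def mic(v, L):
            return v - L * np.round(v / L)

        labels = np.asarray(traj.labels)
        idx_oc = np.flatnonzero(labels == "OC")
        idx_ow = np.flatnonzero(labels == "OW")
        idx_hw = np.flatnonzero(labels == "HW")
        L = traj.box_length
        for f in range(traj.n_frames):
            count = 0
            for h in idx_hw:
                dists = [np.linalg.norm(mic(traj.coords[f, h] - traj.coords[f, o], L))
                         for o in idx_ow]
                donor = idx_ow[int(np.argmin(dists))]
                for acc in idx_oc:
                    da = mic(traj.coords[f, acc] - traj.coords[f, donor], L)
                    if np.linalg.norm(da) >= 5.0:
                        continue
                    dh = mic(traj.coords[f, h] - traj.coords[f, donor], L)
                    cosang = np.dot(dh, da) / (np.linalg.norm(dh) * np.linalg.norm(da))
                    if np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 60.0:
                        count += 1
            assert per_frame[f] == count

    def test_invariant_under_rigid_translation(self):
        traj = simulate_trajectory(TrajGenParams(
            n_frames=3, n_waters=15, seed=19))
        moved = Trajectory(labels=traj.labels,
                           coords=traj.coords + np.array([5.3, -2.1, 11.0]),
                           times=traj.times, box_length=traj.box_length)
        a, _ = hbond_count(traj)
        b, _ = hbond_count(moved)
        np.testing.assert_array_equal(a, b)

    def test_missing_roles_rejected(self):
        traj = _manual_traj([("OC", (0, 0, 0)), ("HW", (2.0, 0, 0))])
        with pytest.raises(ValueError, match="OW"):
            hbond_count(traj)


class TestNearestDistances:
    def test_pinned_two_water_geometry(self):
        """Hydrogens pinned at 1.65 and 1.85 A give delta-like r1/r2."""
        traj = _manual_traj([
            ("OC", (0, 0, 0)),
            ("HW", (1.65, 0, 0)), ("HW", (0, 1.85, 0)),
            ("HW", (4.0, 4.0, 0)), ("HW", (-5.0, 0, 3.0))])
        r1, r2, h1, h2 = nearest_hw_distances(traj)
        np.testing.assert_allclose(r1, 1.65, atol=1e-12)
        np.testing.assert_allclose(r2, 1.85, atol=1e-12)

    def test_sort_invariant_and_brute_force_agreement(self):
        traj = simulate_trajectory(TrajGenParams(
            shell_model="uniform", n_frames=5, n_waters=20,
            box_length=21.0, seed=23))
        r1, r2, _, _ = nearest_hw_distances(traj)
        assert np.all(r1 <= r2)

        def mic(v, L):
            return v - L * np.round(v / L)

        labels = np.asarray(traj.labels)
        oc = int(np.flatnonzero(labels == "OC")[0])
        idx_hw = np.flatnonzero(labels == "HW")
        for f in range(traj.n_frames):
            d = sorted(
                float(np.linalg.norm(mic(traj.coords[f, h] - traj.coords[f, oc],
                                         traj.box_length)))
                for h in idx_hw)
            assert r1[f] == pytest.approx(d[0], abs=1e-12)
            assert r2[f] == pytest.approx(d[1], abs=1e-12)

    def test_histograms_normalized(self):
        traj = simulate_trajectory(TrajGenParams(n_frames=50, n_waters=10,
                                                 seed=27))
        _, _, (c1, p1), (c2, p2) = nearest_hw_distances(traj)
        dw = c1[1] - c1[0]
        assert np.sum(p1) * dw == pytest.approx(1.0, rel=1e-9)
        assert np.sum(p2) * dw == pytest.approx(1.0, rel=1e-9)

    def test_fewer_than_two_hydrogens_rejected(self):
        traj = _manual_traj([("OC", (0, 0, 0)), ("HW", (1.65, 0, 0))])
        with pytest.raises(ValueError, match="2"):
            nearest_hw_distances(traj)


class TestClassifyHydration:
    def test_printed_modes_fall_on_opposite_sides(self):
        labels, frac, _ = classify_hydration(np.array([1.85, 3.0]))
        assert list(labels) == ["SHB", "WHB"]
        assert frac == 0.5

    def test_telegraph_fraction_matches_stationary_distribution(self):
        traj = simulate_trajectory(TrajGenParams(
            shell_model="telegraph_hbond", telegraph_rates=(2.0, 1.0),
            n_frames=500, n_waters=4, frame_dt=2.0, seed=37))
        _, r2, _, _ = nearest_hw_distances(traj)
        _, frac, se = classify_hydration(r2)
        assert abs(frac - 2.0 / 3.0) <= 3.0 * np.sqrt((2 / 9) / traj.n_frames)

    def test_all_below_cutoff(self):
        _, frac, se = classify_hydration(np.full(10, 1.9))
        assert frac == 1.0
        assert se == 0.0

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify_hydration(np.array([]))
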