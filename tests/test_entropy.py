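"""Torsion entropy estimators and the 2PT density-of-states machinery."""

import numpy as np
import pytest


from idpdissect.entropy import (KB, PLANCK_H, R_GAS, TorsionDataset,
                                compute_dos, compute_torsions,
                                decompose_rigid_water_dos, dihedral,
                                integrate_entropy, mist_total_entropy,
                                mutual_information, nn_relative_entropy,
                                rigid_rotor_entropy, solid_weight,
                                solve_fluidicity, two_phase_partition,
                                virtual_ca_torsions)
from idpdissect.synthetic import (VelocityTrace, generate_ho_velocities,
                                  sample_torsions, vonmises_entropy)


# ---------------------------------------------------------------------------
# Dihedrals
# ---------------------------------------------------------------------------

class TestDihedral:
    def test_cis_is_zero(self):
        # four atoms in a plane, last one on the same side: cis
        p = np.array([[1.0, 1.0, 0], [0, 0, 0], [1, 0, 0], [2, 1.0, 0]])
        assert dihedral(*p) == pytest.approx(0.0, abs=1e-12)

    def test_trans_is_pi(self):
        p = np.array([[1.0, 1.0, 0], [0, 0, 0], [1, 0, 0], [2, -1.0, 0]])
        assert abs(dihedral(*p)) == pytest.approx(np.pi, abs=1e-12)

    def test_matches_mdtraj_on_random_coordinates(self):
        import mdtraj as md

        rng = np.random.default_rng(0)
        xyz = rng.random((25, 4, 3)).astype(np.float64)
        top = md.Topology()
        chain = top.add_chain()
        res = top.add_residue("ALA", chain)
        atoms = [top.add_atom(f"A{i}", md.element.carbon, res)
                 for i in range(4)]
        traj = md.Trajectory(xyz.astype(np.float32), top)
        ref = md.compute_dihedrals(traj, [[0, 1, 2, 3]])[:, 0]
        mine = dihedral(xyz[:, 0], xyz[:, 1], xyz[:, 2], xyz[:, 3])
        # mdtraj uses float32 coordinates
        assert np.allclose(mine, ref, atol=1e-5)

    def test_virtual_ca_torsion_shape(self):
        coords = np.random.default_rng(1).random((7, 10, 3))
        tors = virtual_ca_torsions(coords)
        assert tors.shape == (7, 7)
        assert tors.min() > -np.pi - 1e-12 and tors.max() <= np.pi + 1e-12


def test_compute_torsions_from_full_topology():
    """phi/psi/chi extraction from a real peptide topology."""
    import mdtraj as md

    # build a tiny tripeptide from explicit atoms (ALA-ALA-ALA backbone)
    top = md.Topology()
    chain = top.add_chain()
    rng = np.random.default_rng(2)
    for r in range(3):
        res = top.add_residue("ALA", chain, resSeq=r + 1)
        for name, el in [("N", md.element.nitrogen),
                         ("CA", md.element.carbon),
                         ("CB", md.element.carbon),
                         ("C", md.element.carbon),
                         ("O", md.element.oxygen)]:
            top.add_atom(name, el, res)
    top.create_standard_bonds()
    xyz = rng.random((5, top.n_atoms, 3)).astype(np.float32)
    traj = md.Trajectory(xyz, top)
    ds = compute_torsions(traj)
    kinds = {k for _, k in ds.labels}
    assert "phi" in kinds and "psi" in kinds
    assert ds.angles.shape[0] == 5
    assert ds.angles.min() > -np.pi - 1e-9
    assert ds.angles.max() <= np.pi + 1e-9


# ---------------------------------------------------------------------------
# Nearest-neighbor entropy
# ---------------------------------------------------------------------------

class TestNnEntropy:
    def test_uniform_relative_entropy_near_zero(self):
        s = sample_torsions("uniform", 100_000, seed=0)
        assert nn_relative_entropy(s.angles) == pytest.approx(0.0, abs=0.01)

    def test_vonmises_matches_analytic(self):
        s = sample_torsions(("von_mises", 1.0), 100_000, seed=1)
        expected = vonmises_entropy(1.0) - np.log(2 * np.pi)
        assert expected == pytest.approx(-0.2104, abs=1e-3)
        got = nn_relative_entropy(s.angles)
        assert got == pytest.approx(expected, abs=0.02)
        joules = nn_relative_entropy(s.angles, in_joules=True)
        assert joules == pytest.approx(got * R_GAS, rel=1e-12)

    def test_entropy_decreases_with_concentration(self):
        vals = [nn_relative_entropy(
            sample_torsions(("von_mises", k), 20_000, seed=3).angles)
            for k in (0.5, 2.0, 8.0, 32.0)]
        assert all(a > b for a, b in zip(vals[:-1], vals[1:]))

    def test_duplicate_jitter_guard_warns(self):
        x = np.zeros(500)
        with pytest.warns(UserWarning, match="jitter"):
            val = nn_relative_entropy(x)
        assert np.isfinite(val)
        assert val < -5  # near-delta: strongly negative

    def test_mutual_information_independent_near_zero(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(-np.pi, np.pi, 20_000)
        b = rng.uniform(-np.pi, np.pi, 20_000)
        assert mutual_information(a, b) == pytest.approx(0.0, abs=0.02)

    def test_mutual_information_detects_correlation(self):
        s = sample_torsions(("correlated_pair", 0.9), 20_000, seed=5)
        assert mutual_information(s.angles[:, 0], s.angles[:, 1]) > 0.3


# ---------------------------------------------------------------------------
# MIST
# ---------------------------------------------------------------------------

class TestMist:
    def _dataset(self, angles, kinds=None):
        kinds = kinds or ["phi"] * angles.shape[1]
        labels = [(i + 1, k) for i, k in enumerate(kinds)]
        return TorsionDataset(angles, labels)

    def test_independent_uniform_total_near_zero(self):
        rng = np.random.default_rng(6)
        ds = self._dataset(rng.uniform(-np.pi, np.pi, (20_000, 2)))
        dec = mist_total_entropy(ds)
        assert dec.total_nats == pytest.approx(0.0, abs=0.05)

    def test_order2_never_exceeds_order1(self):
        s = sample_torsions(("correlated_pair", 0.8), 10_000, seed=7)
        ds = self._dataset(s.angles)
        dec2 = mist_total_entropy(ds, order=2)
        dec1 = mist_total_entropy(ds, order=1)
        assert dec2.total_nats <= dec1.total_nats + 1e-12
        assert dec2.total_nats <= dec2.marginal_sum_nats + 1e-12

    def test_duplicated_torsion_cancellation(self):
        """Adding an exact copy of a torsion must not raise the MIST total,
        and the copy pair must carry the maximum-MI tree edge."""
        s = sample_torsions(("von_mises", 1.0), 5_000, seed=8).angles[:, 0]
        rng = np.random.default_rng(9)
        other = rng.uniform(-np.pi, np.pi, 5_000)
        base = self._dataset(np.column_stack([s, other]))
        with_copy = self._dataset(np.column_stack([s, other, s]))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # duplicate jitter guard
            dec_base = mist_total_entropy(base)
            dec_copy = mist_total_entropy(with_copy)
        assert dec_copy.total_nats <= dec_base.total_nats + 0.05
        top_edge = max(dec_copy.tree_edges, key=lambda e: e[2])
        assert {top_edge[0], top_edge[1]} == {0, 2}

    def test_backbone_sidechain_split(self):
        rng = np.random.default_rng(10)
        angles = np.column_stack([
            rng.vonmises(0, 2.0, 5_000),   # phi
            rng.vonmises(0, 2.0, 5_000),   # psi
            rng.uniform(-np.pi, np.pi, 5_000)])  # chi1
        ds = self._dataset(angles, kinds=["phi", "psi", "chi1"])
        dec = mist_total_entropy(ds)
        assert dec.backbone_total < dec.sidechain_total  # more concentrated
        assert set(dec.per_residue) == {1, 2, 3}

    def test_insufficient_frames_rejected(self):
        ds = self._dataset(np.zeros((10, 2)))
        with pytest.raises(ValueError, match="frames"):
            mist_total_entropy(ds)

    def test_state_ordering_by_concentration(self):
        """More concentrated torsions (higher kappa) -> lower entropy,
        the ordering the per-state analysis relies on."""
        totals = []
        for kappa in (0.5, 2.0, 8.0):
            rng = np.random.default_rng(11)
            ds = self._dataset(rng.vonmises(0, kappa, size=(8_000, 4)))
            totals.append(mist_total_entropy(ds).total)
        assert totals[0] > totals[1] > totals[2]


# ---------------------------------------------------------------------------
# Density of states
# ---------------------------------------------------------------------------

class TestDos:
    def test_zero_velocities_zero_spectrum(self):
        tr = VelocityTrace(np.array([18.0]), np.zeros((64, 1, 3)), 0.01, 300.0)
        dos = compute_dos(tr)
        assert np.allclose(dos.intensity, 0.0)

    def test_harmonic_line_and_normalization(self):
        tr = generate_ho_velocities([10.0], 300.0, 4096, 0.01, seed=0)
        dos = compute_dos(tr)
        peak = dos.frequencies[np.argmax(dos.intensity)]
        assert peak == pytest.approx(10.0, abs=dos.frequencies[1])
        assert dos.integral() == pytest.approx(3.0, rel=0.02)

    def test_langevin_green_kubo_consistency(self):
        """I(0) equals (2m/kBT) * S_v(0) = (2m/kBT) * 2D per degree of
        freedom, with D obtained independently from the Green-Kubo integral
        of the empirical velocity autocorrelation."""
        rng = np.random.default_rng(1)
        gamma, dt, n, m, temp = 2.0, 0.01, 30_000, 18.0, 300.0
        kbt = KB * temp
        n_part = 8
        a = np.exp(-gamma * dt)
        sd = np.sqrt(kbt / m * (1 - a * a))
        v = np.empty((n, n_part, 3))
        cur = rng.normal(scale=np.sqrt(kbt / m), size=(n_part, 3))
        for i in range(n):
            v[i] = cur
            cur = a * cur + sd * rng.normal(size=(n_part, 3))
        tr = VelocityTrace(np.full(n_part, m), v, dt, temp)
        dos = compute_dos(tr)
        assert dos.integral() == pytest.approx(3.0 * n_part, rel=0.02)
        # Green-Kubo D from the empirical VACF (per channel)
        max_lag = 400
        flat = v.reshape(n, -1)
        vacf = np.array([np.mean(flat[:n - lag] * flat[lag:])
                         for lag in range(max_lag)])
        d_gk = np.trapezoid(vacf, dx=dt)
        i0_theory = 3 * n_part * (m / kbt) * 4 * d_gk
        i0_measured = dos.intensity[:10].mean()
        assert i0_measured > 0
        assert i0_measured == pytest.approx(i0_theory, rel=0.3)


class TestRigidWaterDos:
    def _water_geometry(self):
        # 3-site rigid molecule, roughly SPC-like, nm
        sites = np.array([[0.0, 0.0, 0.0],
                          [0.1, 0.0, 0.0],
                          [-0.0333, 0.0943, 0.0]])
        masses = np.array([15.999, 1.008, 1.008])
        return sites, masses

    def test_pure_translation_has_zero_rotation(self):
        sites, masses = self._water_geometry()
        n, dt = 512, 0.004
        t = np.arange(n) * dt
        vel_com = 0.3 * np.cos(2 * np.pi * 5.0 * t)
        coords = np.empty((n, 1, 3, 3))
        vels = np.empty((n, 1, 3, 3))
        pos = np.cumsum(vel_com) * dt
        for i in range(n):
            coords[i, 0] = sites + np.array([pos[i], 0, 0])
            vels[i, 0] = np.array([[vel_com[i], 0, 0]] * 3)
        dos = decompose_rigid_water_dos(coords, vels, masses, dt, 300.0)
        rot_frac = (np.trapezoid(dos.components["rot"], dos.frequencies)
                    / max(np.trapezoid(dos.components["trn"],
                                       dos.frequencies), 1e-12))
        assert rot_frac < 1e-6

    def test_librational_line_at_oscillation_frequency(self):
        """Small-amplitude angular oscillation (cosine angular velocity)
        about one principal axis puts a rotational DoS line at its
        frequency, with no translational leakage."""
        sites, masses = self._water_geometry()
        com = (masses[:, None] * sites).sum(axis=0) / masses.sum()
        rel0 = sites - com
        n, dt, nu = 1000, 0.002, 20.0
        t = np.arange(n) * dt
        w_z = 3.0 * np.cos(2 * np.pi * nu * t)  # rad/ps about lab z
        coords = np.tile(rel0, (n, 1, 1, 1)).reshape(n, 1, 3, 3)
        vels = np.empty((n, 1, 3, 3))
        for i in range(n):
            vels[i, 0] = np.cross([0.0, 0.0, w_z[i]], rel0)
        dos = decompose_rigid_water_dos(coords, vels, masses, dt, 300.0)
        rot_i = dos.components["rot"]
        peak = dos.frequencies[np.argmax(rot_i)]
        assert peak == pytest.approx(nu, abs=2 * dos.frequencies[1])
        trn_frac = (np.trapezoid(dos.components["trn"], dos.frequencies)
                    / np.trapezoid(rot_i, dos.frequencies))
        assert trn_frac < 1e-6

    def test_six_dof_per_molecule(self):
        """Thermal rigid-body motion: trn + rot integrals = 6 DoF/molecule."""
        sites, masses = self._water_geometry()
        rng = np.random.default_rng(3)
        n, n_mol, dt, temp = 2048, 4, 0.004, 300.0
        kbt = KB * temp
        com = (masses[:, None] * sites).sum(axis=0) / masses.sum()
        rel0 = sites - com
        r2 = np.sum(rel0**2, axis=1)
        inertia_full = (masses[:, None, None]
                        * (r2[:, None, None] * np.eye(3)[None]
                           - rel0[:, :, None] * rel0[:, None, :])).sum(axis=0)
        moments, axes = np.linalg.eigh(inertia_full)
        coords = np.empty((n, n_mol, 3, 3))
        vels = np.empty((n, n_mol, 3, 3))
        t = np.arange(n) * dt
        for mol in range(n_mol):
            vcom = np.sqrt(2 * kbt / masses.sum()) * np.cos(
                2 * np.pi * rng.uniform(3, 12, 3)[None, :] * t[:, None]
                + rng.uniform(0, 2 * np.pi, 3)[None, :])
            # small-amplitude angular oscillation about each principal axis
            w_amp = np.sqrt(2 * kbt / moments)
            wfreq = rng.uniform(3, 12, 3)
            phases = rng.uniform(0, 2 * np.pi, 3)
            w_body = w_amp[None, :] * np.cos(
                2 * np.pi * wfreq[None, :] * t[:, None] + phases[None, :])
            w_lab = w_body @ axes.T
            for i in range(n):
                coords[i, mol] = rel0
                vels[i, mol] = vcom[i] + np.cross(w_lab[i], rel0)
        dos = decompose_rigid_water_dos(coords, vels, masses, dt, temp)
        trn = np.trapezoid(dos.components["trn"], dos.frequencies)
        rot = np.trapezoid(dos.components["rot"], dos.frequencies)
        assert trn == pytest.approx(3 * n_mol, rel=0.02)
        assert rot == pytest.approx(3 * n_mol, rel=0.02)


# ---------------------------------------------------------------------------
# Two-phase partition + entropy integration
# ---------------------------------------------------------------------------

class TestTwoPhase:
    def test_pure_solid_zero_fluidicity(self):
        # frequency on an exact FFT bin so the line does not leak into nu=0
        tr = generate_ho_velocities([8.0], 300.0, 4000, 0.01, seed=2)
        dos = compute_dos(tr)
        part = two_phase_partition(dos, 33.0, 300.0, 18.0, 1)
        assert part.fluidicity == 0.0
        assert np.allclose(part.gas_dos, 0.0)

    def test_high_diffusivity_limit_fluid(self):
        assert solve_fluidicity(1e6) > 0.99
        assert solve_fluidicity(0.0) == 0.0

    def test_gas_integral_scaling_contract(self):
        # diffusive Lorentzian-like DoS with substantial I(0)
        freqs = np.linspace(0.0, 50.0, 2000)
        n_mol = 10
        s0 = 12.0
        intensity = s0 / (1 + (freqs / 2.0) ** 2)
        intensity *= 3 * n_mol / np.trapezoid(intensity, freqs)
        from idpdissect.entropy import DoSSpectrum

        dos = DoSSpectrum(freqs, intensity)
        part = two_phase_partition(dos, 33.0, 300.0, 18.0, n_mol)
        assert 0 < part.fluidicity <= 1
        gas_int = np.trapezoid(part.gas_dos, freqs)
        expect = part.fluidicity * 3 * n_mol
        assert gas_int <= expect * 1.01
        assert gas_int == pytest.approx(expect, rel=0.15)  # clipped vs ideal

    def test_solid_weight_closed_form(self):
        # beta h nu = 1  ->  1/(e-1) - ln(1 - 1/e) = 1.04066
        nu = KB * 300.0 / PLANCK_H
        assert solid_weight(np.array([nu]), 300.0)[0] == pytest.approx(
            1.04066, abs=1e-5)

    def test_frozen_mode_contributes_nothing(self):
        assert solid_weight(np.array([1e6]), 300.0)[0] == 0.0

    def test_harmonic_trace_end_to_end_matches_quantum_ho(self):
        tr = generate_ho_velocities([6.25], 300.0, 8192, 0.01, seed=3)
        dos = compute_dos(tr)
        part = two_phase_partition(dos, 33.0, 300.0, 18.0, 1)
        s = integrate_entropy(part, 300.0)
        bhv = PLANCK_H * 6.25 / (KB * 300.0)
        exact = 3 * (bhv / np.expm1(bhv) - np.log1p(-np.exp(-bhv)))
        assert s == pytest.approx(exact, rel=0.03)

    def test_bad_partition_rejected(self):
        from idpdissect.entropy import TwoPhasePartition

        freqs = np.linspace(0, 10, 100)
        solid = np.full(100, 1.0)  # finite at nu=0: invalid solid DoS
        part = TwoPhasePartition(0.0, np.zeros(100), solid, freqs, 0.0,
                                 float(np.trapezoid(solid, freqs)), 1)
        with pytest.raises(ValueError, match="partition"):
            integrate_entropy(part, 300.0)

    def test_rigid_rotor_entropy_positive_for_water_scale(self):
        # principal moments of a water-like molecule, amu nm^2
        s = rigid_rotor_entropy(300.0, [6.0e-3, 1.1e-2, 1.8e-2], 2.0)
        assert 3.0 < s < 12.0
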