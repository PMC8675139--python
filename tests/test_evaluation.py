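"""Beyond-RMSE battery: metrics, relaxation, normal modes, scans, MD."""

import numpy as np
import pytest
from scipy.stats import special_ortho_group

from aceff.constants import KB_EV, SQRT_EV_A2_AMU_TO_INVCM, atomic_mass
from aceff.evaluation import (
    bond_scan,
    dihedral_angle,
    dihedral_scan,
    error_metrics,
    normal_modes,
    relax_geometry,
    run_langevin_md,
    sample_md,
)
from aceff.structures import AtomicConfiguration
from aceff.synthetic import HarmonicPotential, MorseAnglePotential, make_toy_molecules


class _ZeroPotential:
    def energy_and_forces(self, config):
        return 0.0, np.zeros_like(config.positions)


class _QuadraticBowl:
    """E = 0.5 k |x - x0|^2 per atom: closed-form minimum at x0."""

    def __init__(self, targets, k=3.0):
        self.targets = np.asarray(targets, dtype=float)
        self.k = k

    def energy_and_forces(self, config):
        d = config.positions - self.targets
        return 0.5 * self.k * float((d * d).sum()), -self.k * d


class TestErrorMetrics:
    def test_exact_model_scores_zero(self, planted_model, rng):
        from conftest import random_cluster

        data = []
        for _ in range(4):
            c = random_cluster(rng)
            c.energy, c.forces = planted_model.energy_and_forces(c)
            data.append(c)
        m = error_metrics(planted_model, data)
        assert all(v == 0.0 for v in m.values())

    def test_constant_zero_model_energy_mae(self):
        c = AtomicConfiguration(["H", "H"], np.array([[0.0, 0, 0], [0.9, 0, 0]]))
        c.energy = -4.0
        c.forces = np.zeros((2, 3))
        m = error_metrics(_ZeroPotential(), [c])
        assert m["energy_mae_per_atom_meV"] == pytest.approx(2000.0)

    def test_mae_bounded_by_rmse(self, planted_model, rng):
        from conftest import random_cluster

        data = []
        for _ in range(5):
            c = random_cluster(rng)
            E, F = planted_model.energy_and_forces(c)
            c.energy = E + rng.normal() * 0.1
            c.forces = F + rng.normal(size=F.shape) * 0.05
            data.append(c)
        m = error_metrics(planted_model, data)
        assert m["energy_mae_per_atom_meV"] <= m["energy_rmse_per_atom_meV"] + 1e-12
        assert m["force_mae_meV_per_A"] <= m["force_rmse_meV_per_A"] + 1e-12

    def test_unlabeled_rejected(self, planted_model):
        c = AtomicConfiguration(["C"], np.zeros((1, 3)))
        with pytest.raises(ValueError):
            error_metrics(planted_model, [c])


class TestRelaxation:
    def test_quadratic_bowl_reaches_known_minimum(self, rng):
        targets = rng.normal(size=(4, 3))
        calc = _QuadraticBowl(targets)
        start = AtomicConfiguration(["C"] * 4, targets + rng.normal(size=(4, 3)) * 0.4)
        out = relax_geometry(calc, start, force_tol=1e-8)
        assert out.info["converged"]
        assert np.abs(out.positions - targets).max() < 1e-6

    def test_stationary_start_unchanged(self, rng):
        targets = rng.normal(size=(3, 3))
        calc = _QuadraticBowl(targets)
        start = AtomicConfiguration(["C"] * 3, targets.copy())
        out = relax_geometry(calc, start, force_tol=1e-6)
        assert np.abs(out.positions - targets).max() < 1e-8

    def test_energy_never_increases(self, rng):
        targets = rng.normal(size=(3, 3))
        calc = _QuadraticBowl(targets)
        start = AtomicConfiguration(["C"] * 3, targets + 0.5)
        E0, _ = calc.energy_and_forces(start)
        out = relax_geometry(calc, start)
        assert out.energy <= E0 + 1e-12


class TestNormalModes:
    def test_harmonic_diatomic_closed_form(self):
        k, re = 30.0, 1.1
        calc = HarmonicPotential(bonds=[(0, 1, k, re)])
        c = AtomicConfiguration(["O", "H"], np.array([[0.0, 0, 0], [re, 0, 0]]))
        result = normal_modes(calc, c)
        mu = 1.0 / (1.0 / atomic_mass("O") + 1.0 / atomic_mass("H"))
        expected = SQRT_EV_A2_AMU_TO_INVCM * np.sqrt(k / mu)
        finite = result.finite_frequencies
        assert len(finite) == 1
        assert finite[0] == pytest.approx(expected, rel=1e-3)

    def test_bent_triatomic_mode_counts(self):
        mols = make_toy_molecules()
        tri = mols["triatomic"]
        calc = MorseAnglePotential(
            bonds=[(0, 1, 4.0, 0.96, 2.0), (1, 2, 4.0, 0.96, 2.0)],
            angles=[(0, 1, 2, 3.0, np.radians(104.5))],
        )
        result = normal_modes(calc, tri, zero_tol=1.0)
        # nonlinear 3-atom molecule: 3N - 6 = 3 finite, 6 near-zero modes
        assert result.n_zero_modes == 6
        assert len(result.finite_frequencies) == 3
        assert result.n_imaginary == 0

    def test_rotated_geometry_same_frequencies(self):
        mols = make_toy_molecules()
        tri = mols["triatomic"]
        calc = MorseAnglePotential(
            bonds=[(0, 1, 4.0, 0.96, 2.0), (1, 2, 4.0, 0.96, 2.0)],
            angles=[(0, 1, 2, 3.0, np.radians(104.5))],
        )
        f0 = normal_modes(calc, tri).finite_frequencies
        Q = special_ortho_group.rvs(3, random_state=5)
        rot = AtomicConfiguration(tri.elements, tri.positions @ Q.T)
        calc_rot = MorseAnglePotential(
            bonds=calc.bonds, angles=calc.angles
        )
        f1 = normal_modes(calc_rot, rot).finite_frequencies
        assert np.abs(f0 - f1).max() < 0.01

    def test_mode_orthonormality(self):
        calc = HarmonicPotential(bonds=[(0, 1, 25.0, 1.0)])
        c = AtomicConfiguration(["C", "C"], np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        result = normal_modes(calc, c)
        G = result.modes.T @ result.modes
        assert np.abs(G - np.eye(6)).max() < 1e-10

    def test_unrelaxed_input_warns(self):
        calc = HarmonicPotential(bonds=[(0, 1, 25.0, 1.0)])
        c = AtomicConfiguration(["C", "C"], np.array([[0.0, 0, 0], [1.4, 0, 0]]))
        with pytest.warns(UserWarning):
            normal_modes(calc, c)


class TestScans:
    def test_flat_scan_for_dihedral_independent_potential(self):
        chain = make_toy_molecules()["chain"]
        quad = chain.info["dihedrals"]["beta"]
        grid = [-180.0, -90.0, 0.0, 90.0, 180.0]
        result = dihedral_scan(_ZeroPotential(), chain, quad, grid)
        assert np.abs(result.energies).max() < 1e-8

    def test_scan_endpoint_periodicity(self):
        chain = make_toy_molecules()["chain"]
        from aceff.synthetic import default_morse_reference

        calc = default_morse_reference(chain)
        quad = chain.info["dihedrals"]["gamma"]
        result = dihedral_scan(calc, chain, quad, [-180.0, 180.0])
        assert result.converged.all()
        assert abs(result.energies[0] - result.energies[1]) < 1e-8

    def test_equilibrium_grid_point_is_scan_minimum(self):
        chain = make_toy_molecules()["chain"]
        from aceff.synthetic import default_morse_reference

        calc = default_morse_reference(chain)
        quad = chain.info["dihedrals"]["beta"]
        eq = dihedral_angle(chain.positions, quad)
        away = eq - 25.0 if eq > 0 else eq + 25.0
        result = dihedral_scan(calc, chain, quad, [eq, away])
        # the template is the Morse reference minimum: zero at equilibrium
        assert result.energies[0] == pytest.approx(0.0, abs=1e-8)
        assert result.energies[1] > 0.0

    def test_grid_validation(self):
        chain = make_toy_molecules()["chain"]
        with pytest.raises(ValueError):
            dihedral_scan(_ZeroPotential(), chain, (0, 1, 2, 3), [-200.0])

    def test_bond_scan_morse_closed_form(self):
        De, re, a = 4.5, 0.97, 2.1
        calc = MorseAnglePotential(bonds=[(0, 1, De, re, a)])
        c = AtomicConfiguration(["O", "H"], np.array([[0.0, 0, 0], [re, 0, 0]]))
        d = np.linspace(0.7, 3.0, 40)
        result = bond_scan(calc, c, (0, 1), d)
        closed = De * ((1 - np.exp(-a * (d - re))) ** 2 - 1.0)
        closed -= closed.min()
        assert np.abs(result.energies - closed).max() < 1e-10

    def test_bond_scan_plateau_beyond_cutoff(self, planted_model):
        # stretch H away from C: beyond r_out the energy must plateau exactly
        c = AtomicConfiguration(["C", "H"], np.array([[0.0, 0, 0], [1.1, 0, 0]]))
        r_out = planted_model.radial.r_out
        d = [r_out + 0.5, r_out + 1.5, r_out + 3.0]
        result = bond_scan(planted_model, c, (0, 1), d)
        diffs = np.abs(np.diff(result.absolute_energies))
        assert diffs.max() < 1e-10
        # with isolated-atom one-body terms the plateau is the fragment sum
        expected = planted_model.one_body["C"] + planted_model.one_body["H"]
        assert result.absolute_energies[-1] == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_distance_rejected(self, planted_model):
        c = AtomicConfiguration(["C", "H"], np.array([[0.0, 0, 0], [1.1, 0, 0]]))
        with pytest.raises(ValueError):
            bond_scan(planted_model, c, (0, 1), [1.0, -0.2])


class TestLangevinMD:
    def _harmonic_system(self, n=3, k=5.0):
        sites = np.array([[0.0, 0, 0], [2.0, 0, 0], [0.0, 2.0, 0]])[:n]
        calc = HarmonicPotential(tethers=[(i, k, sites[i]) for i in range(n)])
        config = AtomicConfiguration(["C"] * n, sites.copy())
        return calc, config

    def test_bitwise_reproducible_with_fixed_seed(self):
        calc, config = self._harmonic_system()
        a = run_langevin_md(calc, config, 300.0, 0.5, 200, seed=7)
        b = run_langevin_md(calc, config, 300.0, 0.5, 200, seed=7)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)
        c = run_langevin_md(calc, config, 300.0, 0.5, 200, seed=8)
        assert not np.array_equal(a.positions, c.positions)

    def test_zero_friction_energy_drift(self):
        # friction -> 0, thermostat off: symplectic limit, tiny drift
        calc, config = self._harmonic_system()
        config.positions[0] += 0.05  # displace to get motion
        out = run_langevin_md(
            calc, config, temperature=0.0, timestep_fs=0.1, n_steps=1000,
            friction_per_fs=0.0, seed=0, initialize_velocities=False,
        )
        etot = out.potential_energies + out.kinetic_energies
        assert np.abs(etot - etot[0]).max() < 1e-5
        assert not out.terminated_early

    def test_equipartition_mean_kinetic_energy(self):
        calc, config = self._harmonic_system(n=3, k=5.0)
        T = 300.0
        out = run_langevin_md(
            calc, config, temperature=T, timestep_fs=0.5, n_steps=40_000,
            friction_per_fs=0.05, seed=3, record_every=1,
        )
        ke = out.kinetic_energies[2000:]
        expected = 1.5 * config.n_atoms * KB_EV * T
        assert abs(np.mean(ke) - expected) / expected < 0.05

    def test_hole_detection_terminates_run(self):
        class Collapsing:
            """A potential with a deep spurious well pulling two atoms together."""

            def energy_and_forces(self, config):
                d = config.positions[1] - config.positions[0]
                r = float(np.linalg.norm(d))
                E = -5.0 / (r + 0.01)
                g = 5.0 / (r + 0.01) ** 2 * d / r  # attraction toward collapse
                return E, np.array([g, -g])

        config = AtomicConfiguration(["H", "H"], np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        out = run_langevin_md(
            Collapsing(), config, 300.0, 0.05, 5000, seed=1,
            hole_energy_offset=3.0, hole_min_distance=0.5,
        )
        assert out.terminated_early
        assert out.termination_reason in (
            "potential-energy hole", "pair distance below inner cutoff",
        )

    def test_sampling_protocol_counts(self):
        calc, config = self._harmonic_system()
        samples = sample_md(
            calc, config, temperature=200.0, timestep_fs=0.5,
            n_equilibration=50, n_samples=5, sample_stride=20, seed=2,
        )
        assert len(samples) == 5
        assert samples[0].info["md_step"] == 70
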