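"""Beyond-RMSE evaluation battery.

Mean error metrics are only a proxy for force-field quality; this module
implements the property tests that probe the shape of the fitted potential
energy surface directly:

* energy/force MAE and RMSE (energies per atom, reported in meV and meV/A),
* geometry relaxation and normal-mode analysis (frequencies in cm^-1 from a
  finite-difference Hessian of the analytic forces),
* constrained dihedral scans and rigid bond-stretch scans (extrapolation far
  from the training distribution, including bond breaking),
* seeded Langevin molecular dynamics with "hole" detection: a fitted
  polynomial PES can have spurious low-energy regions reachable by dynamics,
  and a run that falls into one is terminated and flagged.

Any object exposing ``energy_and_forces(config) -> (E, F)`` can be evaluated,
so reference potentials and fitted models are interchangeable here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .constants import ACC_EV_PER_A_AMU_TO_A_FS2, KB_EV, SQRT_EV_A2_AMU_TO_INVCM, atomic_mass
from .structures import AtomicConfiguration

__all__ = [
    "error_metrics",
    "relax_geometry",
    "NormalModeResult",
    "normal_modes",
    "ScanResult",
    "dihedral_angle",
    "dihedral_scan",
    "bond_scan",
    "MDResult",
    "run_langevin_md",
    "sample_md",
]


# ---------------------------------------------------------------------------
# error metrics
# ---------------------------------------------------------------------------


def error_metrics(calc, test_set: list[AtomicConfiguration]) -> dict:
    """Energy MAE/RMSE per atom and force-component MAE/RMSE on a labeled
    test set, in meV and meV/A."""
    e_res, f_res = [], []
    for k, config in enumerate(test_set):
        if config.energy is None or config.forces is None:
            raise ValueError(f"configuration {k} is missing labels")
        E, F = calc.energy_and_forces(config)
        e_res.append((E - config.energy) / config.n_atoms)
        f_res.append((F - config.forces).reshape(-1))
    e = np.array(e_res)
    f = np.concatenate(f_res)
    return {
        "energy_mae_per_atom_meV": float(np.mean(np.abs(e)) * 1e3),
        "energy_rmse_per_atom_meV": float(np.sqrt(np.mean(e ** 2)) * 1e3),
        "force_mae_meV_per_A": float(np.mean(np.abs(f)) * 1e3),
        "force_rmse_meV_per_A": float(np.sqrt(np.mean(f ** 2)) * 1e3),
    }


# ---------------------------------------------------------------------------
# relaxation and normal modes
# ---------------------------------------------------------------------------


def _pack(calc, config):
    def fun(x):
        c = AtomicConfiguration(config.elements, x.reshape(-1, 3))
        E, F = calc.energy_and_forces(c)
        return E, -F.reshape(-1)

    return fun


def relax_geometry(
    calc,
    config: AtomicConfiguration,
    force_tol: float = 1e-4,
    max_steps: int = 2000,
) -> AtomicConfiguration:
    """Quasi-Newton (BFGS) minimization until the maximum force component is
    below ``force_tol`` (eV/A); deterministic from a fixed start.  The result
    carries ``info['converged']`` and the relaxed energy."""
    fun = _pack(calc, config)
    x = config.positions.reshape(-1).copy()
    converged = False
    for _ in range(3):
        res = scipy.optimize.minimize(
            fun,
            x,
            jac=True,
            method="BFGS",
            options={"gtol": 0.2 * force_tol, "maxiter": max_steps, "norm": np.inf},
        )
        x = res.x
        if np.abs(res.jac).max() <= force_tol:
            converged = True
            break
    out = AtomicConfiguration(list(config.elements), x.reshape(-1, 3))
    E, F = calc.energy_and_forces(out)
    out.energy = E
    out.forces = F
    out.info["converged"] = converged
    out.info["max_force"] = float(np.abs(F).max())
    return out


@dataclass
class NormalModeResult:
    """Harmonic analysis at a stationary point: all 3N frequencies sorted
    ascending (negative values stand for imaginary frequencies), mass-weighted
    eigenvectors, and the count of near-zero translational/rotational modes."""

    frequencies: np.ndarray        # cm^-1, ascending; negative = imaginary
    modes: np.ndarray              # (3N, 3N) mass-weighted eigenvectors (columns)
    n_zero_modes: int
    zero_tol: float
    relaxed: bool = True

    @property
    def finite_frequencies(self) -> np.ndarray:
        return self.frequencies[np.abs(self.frequencies) > self.zero_tol]

    @property
    def n_imaginary(self) -> int:
        return int(np.sum(self.frequencies < -self.zero_tol))


def normal_modes(
    calc,
    config: AtomicConfiguration,
    h: float = 0.001,
    zero_tol: float = 1.0,
    force_tol: float = 1e-4,
) -> NormalModeResult:
    """Mass-weighted Hessian by central finite differences of the analytic
    forces (step ``h`` in Angstrom, symmetrized), eigendecomposition, and
    conversion of sqrt-eigenvalues to cm^-1.

    A nonlinear N-atom molecule at a true minimum yields 3N-6 finite
    frequencies (3N-5 if linear); modes with |frequency| below ``zero_tol``
    (cm^-1) are counted as the translational/rotational null space.
    """
    n = config.n_atoms
    _, F0 = calc.energy_and_forces(config)
    relaxed = bool(np.abs(F0).max() <= force_tol)
    if not relaxed:
        import warnings

        warnings.warn(
            f"normal_modes called on an unrelaxed geometry "
            f"(max |F| = {np.abs(F0).max():.3g} eV/A); proceeding",
            stacklevel=2,
        )
    H = np.zeros((3 * n, 3 * n))
    pos = config.positions
    for k in range(n):
        for d in range(3):
            pp = pos.copy()
            pp[k, d] += h
            pm = pos.copy()
            pm[k, d] -= h
            _, Fp = calc.energy_and_forces(AtomicConfiguration(config.elements, pp))
            _, Fm = calc.energy_and_forces(AtomicConfiguration(config.elements, pm))
            H[:, 3 * k + d] = -(Fp - Fm).reshape(-1) / (2.0 * h)
    H = 0.5 * (H + H.T)
    masses = np.array([atomic_mass(z) for z in config.elements])
    minv = np.repeat(1.0 / np.sqrt(masses), 3)
    Hmw = H * minv[:, None] * minv[None, :]
    # project rigid translations/rotations out of the mass-weighted Hessian
    # (finite-difference curvature otherwise leaks a few cm^-1 into them)
    sqm = np.repeat(np.sqrt(masses), 3)
    com = (masses[:, None] * pos).sum(axis=0) / masses.sum()
    tr = []
    for d in range(3):
        t = np.zeros((n, 3))
        t[:, d] = 1.0
        tr.append(t.reshape(-1) * sqm)
    for d in range(3):
        axis = np.zeros(3)
        axis[d] = 1.0
        r = np.cross(np.broadcast_to(axis, (n, 3)), pos - com)
        tr.append(r.reshape(-1) * sqm)
    Vtr = np.array(tr).T
    q, s, _ = np.linalg.svd(Vtr, full_matrices=False)
    q = q[:, s > 1e-8 * s[0]]  # 5 columns for linear molecules, else 6
    P = np.eye(3 * n) - q @ q.T
    Hmw = P @ Hmw @ P
    evals, vecs = np.linalg.eigh(Hmw)
    freqs = np.sign(evals) * np.sqrt(np.abs(evals)) * SQRT_EV_A2_AMU_TO_INVCM
    n_zero = int(np.sum(np.abs(freqs) <= zero_tol))
    return NormalModeResult(
        frequencies=freqs, modes=vecs, n_zero_modes=n_zero, zero_tol=zero_tol,
        relaxed=relaxed,
    )


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    """Energies along a scan coordinate, reported relative to the scan
    minimum (min = 0)."""

    coordinate: np.ndarray
    energies: np.ndarray          # eV, relative to scan minimum
    converged: np.ndarray         # bool flags per point
    absolute_energies: np.ndarray
    configurations: list = field(default_factory=list)


def dihedral_angle(positions: np.ndarray, quad) -> float:
    """Signed dihedral (IUPAC convention) in degrees, in (-180, 180]."""
    i, j, k, l = quad
    b0 = positions[i] - positions[j]
    b1 = positions[k] - positions[j]
    b2 = positions[l] - positions[k]
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def _wrap_deg(a: float) -> float:
    """Map an angle difference to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return a if a != -180.0 else 180.0


def _dihedral_and_grad(x: np.ndarray, quad, n: int):
    """Dihedral (radians) and its gradient w.r.t. all coordinates, by central
    differences (the constraint only needs ~1e-3 deg accuracy)."""
    h = 1e-6
    pos = x.reshape(n, 3)
    val = np.radians(dihedral_angle(pos, quad))
    grad = np.zeros_like(x)
    for a in quad:
        for d in range(3):
            xp = pos.copy()
            xp[a, d] += h
            xm = pos.copy()
            xm[a, d] -= h
            dp = np.radians(dihedral_angle(xp, quad))
            dm = np.radians(dihedral_angle(xm, quad))
            diff = np.arctan2(np.sin(dp - dm), np.cos(dp - dm))
            grad[3 * a + d] = diff / (2.0 * h)
    return val, grad


def _bond_graph(config: AtomicConfiguration, scale: float = 1.25):
    """Crude covalent-radius bond detection, for choosing which atoms rotate
    when initializing a dihedral scan point."""
    radii = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "S": 1.05,
             "Cl": 1.02, "P": 1.07, "B": 0.84}
    n = config.n_atoms
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            rmax = scale * (
                radii.get(config.elements[i], 0.8) + radii.get(config.elements[j], 0.8)
            )
            if np.linalg.norm(config.positions[i] - config.positions[j]) < rmax:
                adj[i].add(j)
                adj[j].add(i)
    return adj


def _rotating_side(config, quad):
    """Atoms on the l-side of the j-k bond (connected component of k with the
    j-k edge removed), excluding k itself -- these rotate about the axis."""
    i, j, k, l = quad
    adj = _bond_graph(config)
    adj[j].discard(k)
    adj[k].discard(j)
    seen = {k}
    stack = [k]
    while stack:
        a = stack.pop()
        for b in adj[a]:
            if b not in seen:
                seen.add(b)
                stack.append(b)
    seen.discard(k)
    return sorted(seen)


def _set_dihedral(config, quad, target_deg):
    """Rigid rotation of the l-side about the j-k axis to hit the target."""
    i, j, k, l = quad
    cur = dihedral_angle(config.positions, quad)
    delta = np.radians(_wrap_deg(target_deg - cur))
    axis = config.positions[k] - config.positions[j]
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    Rm = np.eye(3) + np.sin(delta) * K + (1 - np.cos(delta)) * (K @ K)
    out = config.copy()
    movers = _rotating_side(config, quad)
    origin = config.positions[k]
    for a in movers:
        out.positions[a] = origin + Rm @ (config.positions[a] - origin)
    return out


def dihedral_scan(
    calc,
    config: AtomicConfiguration,
    dihedral,
    grid_deg,
    constraint_tol_deg: float = 0.1,
    force_tol: float = 1e-3,
    max_steps: int = 500,
) -> ScanResult:
    """Constrained relaxation at each grid value of the dihedral.

    The constraint is enforced by an equality-constrained SLSQP minimization
    (the residual angle is kept within ``constraint_tol_deg``); each point
    starts from the input geometry with the rotating side rigidly turned to
    the target angle.  Energies are reported relative to the scan minimum.
    """
    grid = np.asarray(grid_deg, dtype=float)
    if np.any(grid < -180.0) or np.any(grid > 180.0):
        raise ValueError("grid angles must lie in [-180, 180]")
    n = config.n_atoms
    energies = np.empty(len(grid))
    flags = np.zeros(len(grid), dtype=bool)
    configs = []
    fun = _pack(calc, config)
    for g, target in enumerate(grid):
        start = _set_dihedral(config, dihedral, target)

        def constraint(x, target=target):
            pos = x.reshape(n, 3)
            return np.radians(_wrap_deg(dihedral_angle(pos, dihedral) - target))

        def constraint_jac(x):
            _, grad = _dihedral_and_grad(x, dihedral, n)
            return grad

        res = scipy.optimize.minimize(
            fun,
            start.positions.reshape(-1),
            jac=True,
            method="SLSQP",
            constraints=[{"type": "eq", "fun": constraint, "jac": constraint_jac}],
            options={"maxiter": max_steps, "ftol": 1e-10},
        )
        pos = res.x.reshape(n, 3)
        final = AtomicConfiguration(list(config.elements), pos)
        E, _ = calc.energy_and_forces(final)
        final.energy = E
        resid = abs(_wrap_deg(dihedral_angle(pos, dihedral) - target))
        flags[g] = bool(resid <= constraint_tol_deg)
        energies[g] = E
        configs.append(final)
    rel = energies - energies.min()
    return ScanResult(
        coordinate=grid,
        energies=rel,
        converged=flags,
        absolute_energies=energies,
        configurations=configs,
    )


def bond_scan(
    calc, config: AtomicConfiguration, pair, distances
) -> ScanResult:
    """Rigid scan: atom b is translated along the a->b bond direction to each
    requested distance; all other degrees of freedom stay fixed."""
    a, b = pair
    distances = np.asarray(distances, dtype=float)
    if np.any(distances <= 0.0):
        raise ValueError("bond distances must be positive")
    direction = config.positions[b] - config.positions[a]
    r0 = np.linalg.norm(direction)
    direction = direction / r0
    energies = np.empty(len(distances))
    configs = []
    for g, d in enumerate(distances):
        c = config.copy()
        c.positions[b] = c.positions[a] + d * direction
        E, _ = calc.energy_and_forces(c)
        c.energy = E
        energies[g] = E
        configs.append(c)
    rel = energies - energies.min()
    return ScanResult(
        coordinate=distances,
        energies=rel,
        converged=np.ones(len(distances), dtype=bool),
        absolute_energies=energies,
        configurations=configs,
    )


# ---------------------------------------------------------------------------
# Langevin molecular dynamics
# ---------------------------------------------------------------------------


@dataclass
class MDResult:
    positions: np.ndarray          # (n_recorded, n_atoms, 3)
    velocities: np.ndarray         # (n_recorded, n_atoms, 3)
    potential_energies: np.ndarray
    kinetic_energies: np.ndarray
    times_fs: np.ndarray
    terminated_early: bool = False
    termination_reason: str | None = None
    termination_step: int | None = None

    @property
    def n_steps_completed(self) -> int:
        return len(self.potential_energies) - 1


def run_langevin_md(
    calc,
    config: AtomicConfiguration,
    temperature: float,
    timestep_fs: float,
    n_steps: int,
    friction_per_fs: float = 0.01,
    seed: int = 0,
    hole_energy_offset: float = 10.0,
    hole_min_distance: float | None = None,
    record_every: int = 1,
    initialize_velocities: bool = True,
) -> MDResult:
    """Langevin dynamics with the BAOAB splitting, bit-reproducible for a
    fixed seed.

    Per-step monitoring flags a "hole" in the potential -- the potential
    energy dropping more than ``hole_energy_offset`` eV below the starting
    value, any pair distance shrinking under ``hole_min_distance`` (defaults
    to the model's inner cutoff when available), or a non-finite energy or
    force -- and terminates the run flagged, the way an unstable fitted PES
    ends an MD trajectory.

    friction = 0 together with temperature = 0 reduces the scheme to velocity
    Verlet (symplectic, near-conserving).
    """
    if timestep_fs <= 0 or n_steps <= 0:
        raise ValueError("timestep and n_steps must be positive")
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    if hole_min_distance is None:
        hole_min_distance = getattr(getattr(calc, "radial", None), "r_in", 0.0)

    rng = np.random.default_rng(seed)
    masses = np.array([atomic_mass(z) for z in config.elements])[:, None]
    x = config.positions.copy()
    if initialize_velocities and temperature > 0:
        sigma = np.sqrt(KB_EV * temperature / masses * ACC_EV_PER_A_AMU_TO_A_FS2)
        v = rng.normal(size=x.shape) * sigma
        # remove net linear momentum
        v -= (masses * v).sum(axis=0) / masses.sum()
    else:
        v = np.zeros_like(x)

    dt = timestep_fs
    gamma = friction_per_fs
    if gamma > 0 and temperature > 0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt((1.0 - c1 ** 2) * KB_EV * temperature / masses
                     * ACC_EV_PER_A_AMU_TO_A_FS2)
    elif gamma > 0:
        c1, c2 = np.exp(-gamma * dt), 0.0
    else:
        c1, c2 = 1.0, 0.0

    def kinetic(v):
        return float(0.5 * (masses * v ** 2).sum() / ACC_EV_PER_A_AMU_TO_A_FS2)

    E, F = calc.energy_and_forces(AtomicConfiguration(config.elements, x))
    E_start = E
    rec_x, rec_v, rec_pe, rec_ke, rec_t = [x.copy()], [v.copy()], [E], [kinetic(v)], [0.0]
    terminated, reason, term_step = False, None, None

    def min_dist(x):
        n = x.shape[0]
        if n < 2:
            return np.inf
        d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
        return d[np.triu_indices(n, k=1)].min()

    acc = F / masses * ACC_EV_PER_A_AMU_TO_A_FS2
    for step in range(1, n_steps + 1):
        v = v + 0.5 * dt * acc                      # B
        x = x + 0.5 * dt * v                        # A
        if gamma > 0:
            v = c1 * v + c2 * rng.normal(size=v.shape)  # O
        x = x + 0.5 * dt * v                        # A
        E, F = calc.energy_and_forces(AtomicConfiguration(config.elements, x))
        if not (np.isfinite(E) and np.all(np.isfinite(F))):
            terminated, reason, term_step = True, "non-finite energy/forces", step
            break
        acc = F / masses * ACC_EV_PER_A_AMU_TO_A_FS2
        v = v + 0.5 * dt * acc                      # B
        if E < E_start - hole_energy_offset:
            terminated, reason, term_step = True, "potential-energy hole", step
        elif hole_min_distance > 0 and min_dist(x) < hole_min_distance:
            terminated, reason, term_step = True, "pair distance below inner cutoff", step
        if step % record_every == 0 or terminated or step == n_steps:
            rec_x.append(x.copy())
            rec_v.append(v.copy())
            rec_pe.append(E)
            rec_ke.append(kinetic(v))
            rec_t.append(step * dt)
        if terminated:
            break

    return MDResult(
        positions=np.array(rec_x),
        velocities=np.array(rec_v),
        potential_energies=np.array(rec_pe),
        kinetic_energies=np.array(rec_ke),
        times_fs=np.array(rec_t),
        terminated_early=terminated,
        termination_reason=reason,
        termination_step=term_step,
    )


def sample_md(
    calc,
    config: AtomicConfiguration,
    temperature: float,
    timestep_fs: float = 0.3,
    n_equilibration: int = 500,
    n_samples: int = 10,
    sample_stride: int = 200,
    friction_per_fs: float = 0.01,
    seed: int = 0,
    **kwargs,
) -> list[AtomicConfiguration]:
    """The reusable MD sampling protocol: equilibrate, then collect samples a
    fixed number of steps apart from the running trajectory."""
    n_steps = n_equilibration + n_samples * sample_stride
    result = run_langevin_md(
        calc,
        config,
        temperature,
        timestep_fs,
        n_steps,
        friction_per_fs=friction_per_fs,
        seed=seed,
        record_every=1,
        **kwargs,
    )
    out = []
    for s in range(1, n_samples + 1):
        step = n_equilibration + s * sample_stride
        if step < len(result.positions):
            c = AtomicConfiguration(list(config.elements), result.positions[step])
            c.info["md_step"] = step
            out.append(c)
    return out
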