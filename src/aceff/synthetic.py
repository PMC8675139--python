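"""Synthetic labeled datasets from analytic body-ordered reference potentials.

The fits in this package assume training data with the statistical structure
of thermally sampled molecular geometries carrying total energies and
per-atom forces.  This module generates exactly that, with no download:
fixture molecules, analytic reference potentials (Morse pairs plus harmonic
angles, plain harmonic bonds/tethers, or a *planted* linear ACE model with
known coefficients), and two sampling modes mirroring the two regimes the
fits face -- near-equilibrium Gaussian displacements and barrier-crossing
multi-temperature MD sampling.

What these datasets emulate: label self-consistency (forces are exact
gradients of the labeled energy), thermal spread of geometries, multiple
element channels, anharmonicity (Morse), torsional flexibility (the chain
fixture).  What they do not emulate: electronic-structure label physics
(charge transfer, long-range electrostatics, reactivity), so passing tests
certify the machinery, not chemical accuracy against quantum labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bbasis import BasisSelection, build_basis
from .potential import LinearACEModel
from .radial import RadialSpec, build_orthogonal_polynomials
from .structures import AtomicConfiguration

__all__ = [
    "MorseAnglePotential",
    "HarmonicPotential",
    "make_reference_potential",
    "make_planted_ace",
    "make_toy_molecules",
    "sample_configurations",
]


# ---------------------------------------------------------------------------
# analytic reference potentials
# ---------------------------------------------------------------------------


@dataclass
class MorseAnglePotential:
    """Morse bonds plus harmonic angle bends, with analytic forces.

    bonds: list of (i, j, D_e [eV], r_e [A], a [1/A]); the pair energy is
    D_e [(1 - exp(-a (r - r_e)))^2 - 1], so a bond at r = r_e contributes
    exactly -D_e.  angles: list of (i, j, k, k_theta [eV/rad^2],
    theta_0 [rad]) with j the apex; energy 0.5 k_theta (theta - theta_0)^2.
    """

    bonds: list = field(default_factory=list)
    angles: list = field(default_factory=list)
    torsions: list = field(default_factory=list)
    # torsions: (i, j, k, l, V [eV], n, gamma [rad]) -> V (1 + cos(n phi - gamma))

    def energy_and_forces(self, config: AtomicConfiguration):
        pos = config.positions
        E = 0.0
        F = np.zeros_like(pos)
        for (i, j, De, re, a) in self.bonds:
            d = pos[j] - pos[i]
            r = np.linalg.norm(d)
            ex = np.exp(-a * (r - re))
            E += De * ((1.0 - ex) ** 2 - 1.0)
            dEdr = 2.0 * De * a * (1.0 - ex) * ex
            g = dEdr * d / r
            F[i] += g
            F[j] -= g
        for (i, j, k, kt, t0) in self.angles:
            u = pos[i] - pos[j]
            v = pos[k] - pos[j]
            ru, rv = np.linalg.norm(u), np.linalg.norm(v)
            c = np.clip(np.dot(u, v) / (ru * rv), -1.0, 1.0)
            theta = np.arccos(c)
            s = np.sqrt(max(1.0 - c * c, 1e-14))
            E += 0.5 * kt * (theta - t0) ** 2
            dEdtheta = kt * (theta - t0)
            # d(theta)/d(r_i), d/d(r_k), d/d(r_j) (standard bend gradients)
            dci = (v / (ru * rv)) - c * u / ru ** 2
            dck = (u / (ru * rv)) - c * v / rv ** 2
            dti = -dci / s
            dtk = -dck / s
            dtj = -(dti + dtk)
            F[i] -= dEdtheta * dti
            F[k] -= dEdtheta * dtk
            F[j] -= dEdtheta * dtj
        for (i, j, k, l, V, nper, gamma) in self.torsions:
            b1 = pos[j] - pos[i]
            b2 = pos[k] - pos[j]
            b3 = pos[l] - pos[k]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            b = np.linalg.norm(b2)
            phi = np.arctan2(np.dot(np.cross(n1, n2), b2) / b, np.dot(n1, n2))
            E += V * (1.0 + np.cos(nper * phi - gamma))
            dEdphi = -V * nper * np.sin(nper * phi - gamma)
            dphi_i = -(b / np.dot(n1, n1)) * n1
            dphi_l = (b / np.dot(n2, n2)) * n2
            c12 = np.dot(b1, b2) / b ** 2
            c32 = np.dot(b3, b2) / b ** 2
            dphi_j = -(1.0 + c12) * dphi_i + c32 * dphi_l
            dphi_k = c12 * dphi_i - (1.0 + c32) * dphi_l
            F[i] -= dEdphi * dphi_i
            F[j] -= dEdphi * dphi_j
            F[k] -= dEdphi * dphi_k
            F[l] -= dEdphi * dphi_l
        return E, F


@dataclass
class HarmonicPotential:
    """Harmonic bonds and/or site tethers: the exactly solvable reference
    used for normal-mode and MD statistical-mechanics checks.

    bonds: (i, j, k [eV/A^2], r_e [A]) -> 0.5 k (r_ij - r_e)^2.
    tethers: (i, k [eV/A^2], site [3-vector]) -> 0.5 k |r_i - site|^2.
    """

    bonds: list = field(default_factory=list)
    tethers: list = field(default_factory=list)

    def energy_and_forces(self, config: AtomicConfiguration):
        pos = config.positions
        E = 0.0
        F = np.zeros_like(pos)
        for (i, j, k, re) in self.bonds:
            d = pos[j] - pos[i]
            r = np.linalg.norm(d)
            E += 0.5 * k * (r - re) ** 2
            g = k * (r - re) * d / r
            F[i] += g
            F[j] -= g
        for (i, k, site) in self.tethers:
            d = pos[i] - np.asarray(site, dtype=float)
            E += 0.5 * k * float(d @ d)
            F[i] -= k * d
        return E, F


class PlantedACEPotential:
    """A linear ACE model with known (planted) random coefficients: the
    backbone of exact parameter-recovery studies."""

    def __init__(self, model: LinearACEModel, seed: int):
        self.model = model
        self.seed = seed

    @property
    def radial(self):
        return self.model.radial

    def energy_and_forces(self, config: AtomicConfiguration):
        return self.model.energy_and_forces(config)


def make_planted_ace(
    elements,
    selection: BasisSelection | None = None,
    radial: RadialSpec | None = None,
    seed: int = 0,
    coefficient_scale: float = 0.1,
    one_body: dict | None = None,
    pair_n_max: int = 3,
) -> PlantedACEPotential:
    """Build a basis and draw coefficients c ~ N(0, scale/Gamma-like decay):
    each coefficient is scaled down by the total degree of its basis function
    so the planted surface is smooth."""
    if selection is None:
        selection = BasisSelection(
            elements=tuple(elements), nu_max=3, degree_caps=((1, 8), (2, 7), (3, 6))
        )
    if radial is None:
        radial = RadialSpec(r_in=0.7, r_out=4.0, n_max=selection.n_max)
    polys = build_orthogonal_polynomials(radial)
    basis = build_basis(selection, radial, polys)
    model = LinearACEModel.zeros(basis, radial, polys, pair_n_max=pair_n_max)
    rng = np.random.default_rng(seed)
    decay = []
    for _ in model.elements:
        for f in basis.functions:
            deg = sum(n + selection.w_Y * l for (_, n, l) in f.lead)
            decay.append(1.0 / (1.0 + deg))
    for _ in model.pairs:
        for n in range(1, model.pair_n_max + 1):
            decay.append(1.0 / (1.0 + n))
    model.theta = rng.normal(size=model.n_features) * coefficient_scale * np.array(decay)
    model.one_body = dict(one_body or {z: 0.0 for z in model.elements})
    return PlantedACEPotential(model, seed)


def make_reference_potential(kind: str, params: dict, seed: int = 0):
    """Factory for the reference-potential kinds."""
    if kind == "morse_pairs_plus_harmonic_angles":
        return MorseAnglePotential(
            bonds=list(params.get("bonds", [])),
            angles=list(params.get("angles", [])),
            torsions=list(params.get("torsions", [])),
        )
    if kind == "harmonic":
        return HarmonicPotential(
            bonds=list(params.get("bonds", [])), tethers=list(params.get("tethers", []))
        )
    if kind == "planted_ace":
        return make_planted_ace(seed=seed, **params)
    raise ValueError(f"unknown reference potential kind {kind!r}")


# ---------------------------------------------------------------------------
# fixture molecules
# ---------------------------------------------------------------------------


def _zigzag_chain():
    """A 15-atom flexible ether chain (C4 O backbone, H-saturated): three
    consecutive rotatable backbone bonds, echoing a druglike torsional PES."""
    # backbone: C0-C1-O2-C3-C4 zigzag in the xz-plane
    d, ang = 1.50, np.radians(111.0)
    backbone = []
    x = np.zeros(3)
    direction = 0
    for k in range(5):
        backbone.append(x.copy())
        theta = (ang - np.pi / 2.0) * (1 if direction == 0 else -1)
        step = np.array([np.cos(theta), 0.0, np.sin(theta)]) * (1.43 if k in (1, 2) else d)
        x = x + step
        direction = 1 - direction
    elements = ["C", "C", "O", "C", "C"]
    positions = list(backbone)

    def add_h(center, partners, n_h, dist=1.09):
        """Place n_h hydrogens roughly tetrahedrally away from the partners."""
        c = positions[center]
        away = np.zeros(3)
        for p in partners:
            v = c - positions[p]
            away += v / np.linalg.norm(v)
        if np.linalg.norm(away) < 1e-8:
            away = np.array([0.0, 1.0, 0.0])
        away /= np.linalg.norm(away)
        ortho = np.cross(away, [0.0, 1.0, 0.0])
        if np.linalg.norm(ortho) < 1e-8:
            ortho = np.cross(away, [1.0, 0.0, 0.0])
        ortho /= np.linalg.norm(ortho)
        third = np.cross(away, ortho)
        for h in range(n_h):
            phi = 2.0 * np.pi * h / max(n_h, 1)
            u = away * np.cos(0.68) + (ortho * np.cos(phi) + third * np.sin(phi)) * np.sin(0.68)
            elements.append("H")
            positions.append(c + dist * u / np.linalg.norm(u))

    add_h(0, [1], 3)
    add_h(1, [0, 2], 2)
    add_h(3, [2, 4], 2)
    add_h(4, [3], 3)
    config = AtomicConfiguration(elements, np.array(positions))
    config.info["dihedrals"] = {
        "alpha": (5, 0, 1, 2),   # H-C0-C1-O2
        "beta": (0, 1, 2, 3),    # C0-C1-O2-C3
        "gamma": (1, 2, 3, 4),   # C1-O2-C3-C4
        "delta": (2, 3, 4, 12),  # O2-C3-C4-H
    }
    config.info["bonds"] = (
        [(0, 1), (1, 2), (2, 3), (3, 4)]
        + [(0, 5), (0, 6), (0, 7), (1, 8), (1, 9), (3, 10), (3, 11)]
        + [(4, 12), (4, 13), (4, 14)]
    )
    return config


def make_toy_molecules() -> dict[str, AtomicConfiguration]:
    """Documented fixture geometries.

    diatomic: O-H at 0.97 A.
    triatomic: bent water-like H-O-H (0.96 A, 104.5 deg).
    ring6: benzene-like planar C6H6 (C-C 1.40 A, C-H 1.09 A).
    chain: 15-atom flexible ether chain with four named rotatable dihedrals
    (info['dihedrals']) and a bond list (info['bonds']).
    Minimum pair distance exceeds 0.7 A in every fixture.
    """
    out: dict[str, AtomicConfiguration] = {}

    dia = AtomicConfiguration(["O", "H"], np.array([[0.0, 0.0, 0.0], [0.97, 0.0, 0.0]]))
    dia.info["bonds"] = [(0, 1)]
    out["diatomic"] = dia

    theta = np.radians(104.5)
    tri = AtomicConfiguration(
        ["H", "O", "H"],
        np.array(
            [
                [0.96 * np.sin(theta / 2), 0.96 * np.cos(theta / 2), 0.0],
                [0.0, 0.0, 0.0],
                [-0.96 * np.sin(theta / 2), 0.96 * np.cos(theta / 2), 0.0],
            ]
        ),
    )
    tri.info["bonds"] = [(0, 1), (1, 2)]
    tri.info["angles"] = [(0, 1, 2)]
    out["triatomic"] = tri

    rc = 1.40 / (2.0 * np.sin(np.pi / 6.0))
    els, pos = [], []
    for k in range(6):
        phi = 2.0 * np.pi * k / 6.0
        els.append("C")
        pos.append([rc * np.cos(phi), rc * np.sin(phi), 0.0])
    for k in range(6):
        phi = 2.0 * np.pi * k / 6.0
        els.append("H")
        pos.append([(rc + 1.09) * np.cos(phi), (rc + 1.09) * np.sin(phi), 0.0])
    ring = AtomicConfiguration(els, np.array(pos))
    ring.info["bonds"] = [(k, (k + 1) % 6) for k in range(6)] + [
        (k, k + 6) for k in range(6)
    ]
    out["ring6"] = ring

    out["chain"] = _zigzag_chain()
    return out


def default_morse_reference(config: AtomicConfiguration) -> MorseAnglePotential:
    """A Morse + angle + torsion reference matched to a fixture's topology
    lists, with generic organic parameters (D_e 4 eV, a 2 /A, k_theta
    3 eV/rad^2, threefold 0.15 eV torsions minimized at the template
    geometry)."""
    from .evaluation import dihedral_angle

    bonds = []
    for (i, j) in config.info.get("bonds", []):
        re = float(np.linalg.norm(config.positions[i] - config.positions[j]))
        bonds.append((i, j, 4.0, re, 2.0))
    angles = []
    for (i, j, k) in config.info.get("angles", []):
        u = config.positions[i] - config.positions[j]
        v = config.positions[k] - config.positions[j]
        t0 = float(
            np.arccos(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
        )
        angles.append((i, j, k, 3.0, t0))
    torsions = []
    for quad in config.info.get("dihedrals", {}).values():
        phi_eq = np.radians(dihedral_angle(config.positions, quad))
        torsions.append((*quad, 0.15, 3, 3.0 * phi_eq - np.pi))
    return MorseAnglePotential(bonds=bonds, angles=angles, torsions=torsions)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def sample_configurations(
    template: AtomicConfiguration,
    reference,
    n: int,
    mode: str = "gaussian_displace",
    scale_or_temperature: float = 0.05,
    seed: int = 0,
    min_distance: float = 0.6,
    md_timestep_fs: float = 0.5,
    md_stride: int = 20,
    max_retries: int = 200,
) -> list[AtomicConfiguration]:
    """n labeled configurations from a template geometry.

    gaussian_displace: independent Gaussian perturbation of every Cartesian
    coordinate with the given standard deviation (A); draws whose minimum
    pair distance falls under ``min_distance`` are rejected and resampled
    (bounded retries).

    md_sample: seeded Langevin MD on the reference at the given temperature
    (K), subsampled at a fixed stride after a short equilibration.

    Labels (energy + forces) always come from re-evaluating the reference on
    the stored positions, so stored forces are bitwise self-consistent.
    """
    rng = np.random.default_rng(seed)
    out: list[AtomicConfiguration] = []
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode == "gaussian_displace":
        tries = 0
        while len(out) < n:
            pos = template.positions + rng.normal(
                size=template.positions.shape
            ) * scale_or_temperature
            c = AtomicConfiguration(list(template.elements), pos)
            if scale_or_temperature > 0 and c.min_distance() < min_distance:
                tries += 1
                if tries > max_retries + n:
                    raise RuntimeError("too many rejected draws; lower the scale")
                continue
            E, F = reference.energy_and_forces(c)
            c.energy, c.forces = E, F
            c.info.update({"generator": mode, "seed": seed, "scale": scale_or_temperature})
            out.append(c)
    elif mode == "md_sample":
        from .evaluation import run_langevin_md

        n_steps = 100 + n * md_stride
        traj = run_langevin_md(
            reference,
            template,
            temperature=scale_or_temperature,
            timestep_fs=md_timestep_fs,
            n_steps=n_steps,
            friction_per_fs=0.05,
            seed=seed,
            hole_energy_offset=np.inf,
            hole_min_distance=0.0,
        )
        if traj.terminated_early or len(traj.positions) < 101 + n * md_stride:
            raise RuntimeError("reference MD terminated early; lower the temperature")
        for s in range(1, n + 1):
            pos = traj.positions[100 + s * md_stride]
            c = AtomicConfiguration(list(template.elements), pos)
            E, F = reference.energy_and_forces(c)
            c.energy, c.forces = E, F
            c.info.update(
                {"generator": mode, "seed": seed, "temperature": scale_or_temperature}
            )
            out.append(c)
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    return out


def stratified_multi_temperature_sample(
    template: AtomicConfiguration,
    reference,
    n_per_temperature: int,
    temperatures=(300.0, 600.0, 1200.0),
    seed: int = 0,
    **kwargs,
) -> list[AtomicConfiguration]:
    """Equal-count sampling from seeded MD trajectories at several
    temperatures: the barrier-crossing, mixed-temperature training regime."""
    out = []
    for k, T in enumerate(temperatures):
        out.extend(
            sample_configurations(
                template,
                reference,
                n_per_temperature,
                mode="md_sample",
                scale_or_temperature=T,
                seed=seed + 1000 * k,
                **kwargs,
            )
        )
    return out
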