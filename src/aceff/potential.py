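"""The linear ACE energy model: site energies, total energy, analytic forces.

The site energy of atom i is

    E_i = E0(z_i) + sum_B c_{z_i, B} B(env_i) + sum_{pair, n} c2_{pair, n} Rp_n(r_ij)

with the invariant B-basis of :mod:`aceff.bbasis`, a small auxiliary
two-body basis built on the pair envelope (no inner cutoff, so it carries
short-range repulsion), and element-wise one-body energies E0.  The total
energy is the sum of site energies over environments built at r_out, and
forces are exact negative gradients assembled from the analytic basis
gradients, including cross-site contributions.

Internal units: Angstrom, eV, eV/A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bbasis import BasisSet, evaluate_basis, evaluate_basis_gradients
from .density import DensityIndex, project_density
from .radial import (
    OrthogonalPolynomialSet,
    RadialSpec,
    build_orthogonal_polynomials,
    evaluate_radial_basis,
)
from .structures import AtomicConfiguration, AtomicEnvironment, build_environments

__all__ = ["LinearACEModel", "element_pairs"]

ONE_BODY_STRATEGIES = ("isolated_atom", "training_average", "forces_only_shift")


def element_pairs(elements) -> list[tuple[str, str]]:
    """Unordered element pairs, deterministic order."""
    els = sorted(set(elements))
    return [(a, b) for i, a in enumerate(els) for b in els[i:]]


@dataclass
class LinearACEModel:
    """Basis set + linear coefficients + one-body energies + pair repulsion."""

    elements: tuple[str, ...]
    radial: RadialSpec
    polys: OrthogonalPolynomialSet
    pair_polys: OrthogonalPolynomialSet
    basis: BasisSet
    coefficients: np.ndarray         # (n_elements, n_basis)
    pair_coefficients: np.ndarray    # (n_pairs, pair_n_max)
    one_body: dict = field(default_factory=dict)
    one_body_strategy: str = "isolated_atom"
    energy_shift: float = 0.0        # forces-only post-fit constant

    def __post_init__(self) -> None:
        self.elements = tuple(sorted(self.elements))
        self.coefficients = np.asarray(self.coefficients, dtype=float).reshape(
            len(self.elements), len(self.basis)
        )
        self.pair_coefficients = np.asarray(
            self.pair_coefficients, dtype=float
        ).reshape(len(self.pairs), -1)
        for z in self.elements:
            self.one_body.setdefault(z, 0.0)

    # -- layout ------------------------------------------------------------

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return element_pairs(self.elements)

    @property
    def pair_n_max(self) -> int:
        return self.pair_polys.degree_max

    @property
    def index(self) -> DensityIndex:
        l_max = max((l for f in self.basis.functions for (_, _, l) in f.lead), default=0)
        return DensityIndex(self.elements, self.radial.n_max, l_max)

    @property
    def n_features(self) -> int:
        return len(self.elements) * len(self.basis) + len(self.pairs) * self.pair_n_max

    @property
    def theta(self) -> np.ndarray:
        """All linear coefficients as one flat vector (B blocks per center
        element, then pair blocks)."""
        return np.concatenate(
            [self.coefficients.reshape(-1), self.pair_coefficients.reshape(-1)]
        )

    @theta.setter
    def theta(self, value: np.ndarray) -> None:
        value = np.asarray(value, dtype=float)
        nb = len(self.elements) * len(self.basis)
        self.coefficients = value[:nb].reshape(len(self.elements), len(self.basis))
        self.pair_coefficients = value[nb:].reshape(len(self.pairs), -1)

    def _center_slice(self, z: str) -> slice:
        zi = self.elements.index(z)
        nb = len(self.basis)
        return slice(zi * nb, (zi + 1) * nb)

    def _pair_col(self, za: str, zb: str) -> int:
        key = (za, zb) if za <= zb else (zb, za)
        nb = len(self.elements) * len(self.basis)
        return nb + self.pairs.index(key) * self.pair_n_max

    def _check_elements(self, elements) -> None:
        unknown = set(elements) - set(self.elements)
        if unknown:
            raise ValueError(f"undeclared elements: {sorted(unknown)}")

    # -- features ----------------------------------------------------------

    def config_features(self, config: AtomicConfiguration):
        """(phi, dphi): the linear feature vector of the configuration and
        its position gradient, so that

            E(X) = sum_i E0(z_i) + shift + theta . phi
            F_k  = -theta . dphi[k]

        phi has shape (n_features,), dphi (n_atoms, n_features, 3).
        """
        self._check_elements(config.elements)
        index = self.index
        nfeat = self.n_features
        phi = np.zeros(nfeat)
        dphi = np.zeros((config.n_atoms, nfeat, 3))
        envs = build_environments(config, self.radial.r_out)
        for i, env in enumerate(envs):
            A = project_density(env, self.radial, self.polys, index)
            B = evaluate_basis(env, self.basis, A)
            sl = self._center_slice(env.center_element)
            phi[sl] += B
            if env.n_neighbors:
                dB = evaluate_basis_gradients(env, self.basis, A)
                for jj, j in enumerate(env.neighbor_indices):
                    dphi[j, sl, :] += dB[:, jj, :]
                    dphi[i, sl, :] -= dB[:, jj, :]
                # pair features
                disp = env.neighbor_displacements
                r = np.linalg.norm(disp, axis=1)
                u = disp / r[:, None]
                Rp, dRp = evaluate_radial_basis(r, self.radial, self.pair_polys)
                for jj, j in enumerate(env.neighbor_indices):
                    c0 = self._pair_col(env.center_element, env.neighbor_elements[jj])
                    sl2 = slice(c0, c0 + self.pair_n_max)
                    phi[sl2] += Rp[:, jj]
                    g = dRp[:, jj, None] * u[jj]
                    dphi[j, sl2, :] += g
                    dphi[i, sl2, :] -= g
        return phi, dphi

    def _energy_features_only(self, config: AtomicConfiguration) -> np.ndarray:
        self._check_elements(config.elements)
        index = self.index
        phi = np.zeros(self.n_features)
        for env in build_environments(config, self.radial.r_out):
            A = project_density(env, self.radial, self.polys, index)
            phi[self._center_slice(env.center_element)] += evaluate_basis(
                env, self.basis, A
            )
            if env.n_neighbors:
                r = np.linalg.norm(env.neighbor_displacements, axis=1)
                Rp, _ = evaluate_radial_basis(r, self.radial, self.pair_polys)
                for jj in range(env.n_neighbors):
                    c0 = self._pair_col(env.center_element, env.neighbor_elements[jj])
                    phi[c0 : c0 + self.pair_n_max] += Rp[:, jj]
        return phi

    # -- predictions -------------------------------------------------------

    def site_energy(self, env: AtomicEnvironment) -> float:
        """E_i for a single environment."""
        self._check_elements([env.center_element, *env.neighbor_elements])
        index = self.index
        A = project_density(env, self.radial, self.polys, index)
        B = evaluate_basis(env, self.basis, A)
        zi = self.elements.index(env.center_element)
        e = self.one_body[env.center_element] + float(self.coefficients[zi] @ B)
        if env.n_neighbors:
            r = np.linalg.norm(env.neighbor_displacements, axis=1)
            Rp, _ = evaluate_radial_basis(r, self.radial, self.pair_polys)
            for jj in range(env.n_neighbors):
                key = tuple(sorted((env.center_element, env.neighbor_elements[jj])))
                e += float(self.pair_coefficients[self.pairs.index(key)] @ Rp[:, jj])
        return e

    def total_energy(self, config: AtomicConfiguration) -> float:
        phi = self._energy_features_only(config)
        e0 = sum(self.one_body[z] for z in config.elements)
        return e0 + self.energy_shift + float(self.theta @ phi)

    def forces(self, config: AtomicConfiguration) -> np.ndarray:
        _, dphi = self.config_features(config)
        return -np.einsum("f,kfd->kd", self.theta, dphi)

    def energy_and_forces(self, config: AtomicConfiguration):
        phi, dphi = self.config_features(config)
        e0 = sum(self.one_body[z] for z in config.elements)
        energy = e0 + self.energy_shift + float(self.theta @ phi)
        forces = -np.einsum("f,kfd->kd", self.theta, dphi)
        return energy, forces

    # -- one-body ----------------------------------------------------------

    def set_one_body_term(self, strategy: str, values=None, dataset=None):
        """Populate the one-body energies.

        isolated_atom: per-element energies supplied in ``values``.
        training_average: mean per-atom training energy assigned to every
        element (the fitted model then has zero-mean energy).
        forces_only_shift: call *after* a force-only coefficient fit; a single
        constant shift minimizing the training energy error (the mean signed
        residual becomes exactly zero).
        """
        if strategy not in ONE_BODY_STRATEGIES:
            raise ValueError(f"unknown one-body strategy {strategy!r}")
        self.one_body_strategy = strategy
        if strategy == "isolated_atom":
            if values is None:
                raise ValueError("isolated_atom strategy requires per-element values")
            self._check_elements(values.keys())
            self.one_body = {z: float(values.get(z, 0.0)) for z in self.elements}
            self.energy_shift = 0.0
        elif strategy == "training_average":
            if not dataset:
                raise ValueError("training_average strategy requires a dataset")
            etot = sum(c.energy for c in dataset)
            ntot = sum(c.n_atoms for c in dataset)
            ebar = etot / ntot
            self.one_body = {z: ebar for z in self.elements}
            self.energy_shift = 0.0
        else:  # forces_only_shift
            if not dataset:
                raise ValueError("forces_only_shift strategy requires a dataset")
            self.one_body = {z: 0.0 for z in self.elements}
            self.energy_shift = 0.0
            residuals = [c.energy - self.total_energy(c) for c in dataset]
            self.energy_shift = float(np.mean(residuals))
        return self

    @classmethod
    def zeros(
        cls,
        basis: BasisSet,
        radial: RadialSpec,
        polys: OrthogonalPolynomialSet,
        pair_polys: OrthogonalPolynomialSet | None = None,
        pair_n_max: int = 6,
    ) -> "LinearACEModel":
        """A model skeleton with all linear coefficients zero."""
        if pair_polys is None:
            pair_polys = build_orthogonal_polynomials(
                radial, pair=True, degree_max=pair_n_max
            )
        elements = tuple(sorted(basis.elements))
        return cls(
            elements=elements,
            radial=radial,
            polys=polys,
            pair_polys=pair_polys,
            basis=basis,
            coefficients=np.zeros((len(elements), len(basis))),
            pair_coefficients=np.zeros(
                (len(element_pairs(elements)), pair_polys.degree_max)
            ),
        )
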