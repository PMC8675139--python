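"""Molecular configurations and atomic neighbor environments.

A configuration is a molecule snapshot in vacuum (free boundary conditions):
chemical elements, Cartesian positions in Angstrom, and optional total-energy
(eV) / per-atom force (eV/A) labels.  Environments are built by a brute-force
O(N^2) pair scan, which is the right tool for isolated molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["AtomicConfiguration", "AtomicEnvironment", "build_environments"]


@dataclass
class AtomicConfiguration:
    """A molecule snapshot with optional energy/force labels."""

    elements: list[str]
    positions: np.ndarray  # (n_atoms, 3), Angstrom
    energy: float | None = None        # total energy, eV
    forces: np.ndarray | None = None   # (n_atoms, 3), eV/A
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.elements), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.elements)} elements"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")
        if self.forces is not None:
            self.forces = np.ascontiguousarray(self.forces, dtype=float)
            if self.forces.shape != self.positions.shape:
                raise ValueError("forces shape does not match positions")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def copy(self) -> "AtomicConfiguration":
        return AtomicConfiguration(
            list(self.elements),
            self.positions.copy(),
            self.energy,
            None if self.forces is None else self.forces.copy(),
            dict(self.info),
        )

    def min_distance(self) -> float:
        """Smallest interatomic distance (inf for a single atom)."""
        n = self.n_atoms
        if n < 2:
            return np.inf
        d = self.positions[:, None, :] - self.positions[None, :, :]
        r = np.linalg.norm(d, axis=-1)
        return float(r[np.triu_indices(n, k=1)].min())


@dataclass
class AtomicEnvironment:
    """The neighborhood of one atom: central element plus displacement vectors
    r_ij = r_j - r_i to all neighbors within the outer cutoff."""

    center_element: str
    neighbor_elements: list[str]
    neighbor_displacements: np.ndarray  # (n_neighbors, 3), Angstrom
    neighbor_indices: np.ndarray | None = None  # indices into the parent configuration

    def __post_init__(self) -> None:
        self.neighbor_displacements = np.asarray(
            self.neighbor_displacements, dtype=float
        ).reshape(-1, 3)
        if len(self.neighbor_elements) != self.neighbor_displacements.shape[0]:
            raise ValueError("neighbor elements/displacements length mismatch")
        if self.n_neighbors:
            r = np.linalg.norm(self.neighbor_displacements, axis=1)
            if np.any(r <= 0.0):
                raise ValueError("coincident atoms in environment")

    @property
    def n_neighbors(self) -> int:
        return self.neighbor_displacements.shape[0]

    def rotated(self, rot: np.ndarray) -> "AtomicEnvironment":
        """The same environment with all displacements mapped through an
        orthogonal matrix (proper or improper)."""
        return AtomicEnvironment(
            self.center_element,
            list(self.neighbor_elements),
            self.neighbor_displacements @ np.asarray(rot).T,
            self.neighbor_indices,
        )


def build_environments(
    config: AtomicConfiguration, r_cut: float
) -> list[AtomicEnvironment]:
    """One environment per atom, brute-force pair scan at cutoff ``r_cut``."""
    pos = config.positions
    n = config.n_atoms
    envs: list[AtomicEnvironment] = []
    if n == 0:
        return envs
    diff = pos[None, :, :] - pos[:, None, :]  # diff[i, j] = r_j - r_i
    dist = np.linalg.norm(diff, axis=-1)
    for i in range(n):
        mask = (dist[i] < r_cut) & (np.arange(n) != i)
        idx = np.nonzero(mask)[0]
        envs.append(
            AtomicEnvironment(
                config.elements[i],
                [config.elements[j] for j in idx],
                diff[i, idx],
                idx,
            )
        )
    return envs


def random_environment(
    rng: np.random.Generator,
    elements: Sequence[str],
    center_element: str | None = None,
    n_neighbors: int = 6,
    r_lo: float = 0.8,
    r_hi: float = 4.5,
) -> AtomicEnvironment:
    """A random environment for basis-audit purposes: neighbors at uniform
    random distances in [r_lo, r_hi] and uniform random directions."""
    elements = list(elements)
    center = center_element or elements[int(rng.integers(len(elements)))]
    z = [elements[int(k)] for k in rng.integers(len(elements), size=n_neighbors)]
    u = rng.normal(size=(n_neighbors, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = rng.uniform(r_lo, r_hi, size=n_neighbors)
    return AtomicEnvironment(center, z, u * r[:, None])
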