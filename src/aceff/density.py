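"""One-particle basis and projection of the neighborhood density.

The neighborhood of atom i is described per element channel z by the formal
density rho_i^z = sum_{j : z_j = z} delta(r - r_ij).  Projecting it onto the
one-particle functions phi_{znlm}(r) = R_n(|r|) Y_lm(r-hat) gives the *atomic
base*

    A_{z n l m} = sum_{j : z_j = z} R_n(r_ij) Y_lm(r-hat_ij),

a single sum over neighbors.  A and its per-neighbor gradients are the only
ingredients the higher-body-order invariant basis needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .harmonics import lm_index, n_lm, real_spherical_harmonics
from .radial import OrthogonalPolynomialSet, RadialSpec, evaluate_radial_basis
from .structures import AtomicEnvironment

__all__ = [
    "DensityIndex",
    "AtomicBase",
    "evaluate_one_particle_basis",
    "project_density",
]


@dataclass(frozen=True)
class DensityIndex:
    """Flat column layout of the multi-index v = (z, n, l, m):
    column = z_block * n_max * (l_max+1)^2 + (n-1) * (l_max+1)^2 + lm_index(l, m).
    """

    elements: tuple[str, ...]
    n_max: int
    l_max: int

    @property
    def n_columns(self) -> int:
        return len(self.elements) * self.n_max * n_lm(self.l_max)

    def column(self, z: str, n: int, l: int, m: int) -> int:
        if not (1 <= n <= self.n_max):
            raise KeyError(f"radial index n={n} outside 1..{self.n_max}")
        if not (0 <= l <= self.l_max and abs(m) <= l):
            raise KeyError(f"angular index (l={l}, m={m}) invalid for l_max={self.l_max}")
        zi = self.elements.index(z)
        nlm = n_lm(self.l_max)
        return zi * self.n_max * nlm + (n - 1) * nlm + lm_index(l, m)

    def element_block(self, z: str) -> slice:
        zi = self.elements.index(z)
        w = self.n_max * n_lm(self.l_max)
        return slice(zi * w, (zi + 1) * w)


@dataclass
class AtomicBase:
    """A values (flat over the DensityIndex layout) and per-neighbor gradients
    dA/dr_j of shape (n_neighbors, n_columns, 3)."""

    index: DensityIndex
    values: np.ndarray
    gradients: np.ndarray


def evaluate_one_particle_basis(
    displacement: np.ndarray,
    element: str,
    spec: RadialSpec,
    polys: OrthogonalPolynomialSet,
    index: DensityIndex,
):
    """phi values over the full flat layout (zero outside the element channel)
    and gradients with respect to the displacement vector."""
    env = AtomicEnvironment("X", [element], np.asarray(displacement, float).reshape(1, 3))
    base = project_density(env, spec, polys, index)
    return base.values, base.gradients[0]


def project_density(
    env: AtomicEnvironment,
    spec: RadialSpec,
    polys: OrthogonalPolynomialSet,
    index: DensityIndex,
) -> AtomicBase:
    """Atomic base A and gradients for one environment.

    phi = R_n(r) Y_lm(u);  dphi = (dR_n/dr) (r_ij/r) Y_lm + R_n dY_lm.
    """
    unknown = set(env.neighbor_elements) - set(index.elements)
    if unknown:
        raise KeyError(f"undeclared elements in environment: {sorted(unknown)}")
    ncols = index.n_columns
    nlm = n_lm(index.l_max)
    nnbr = env.n_neighbors
    values = np.zeros(ncols)
    grads = np.zeros((nnbr, ncols, 3))
    if nnbr == 0:
        return AtomicBase(index, values, grads)

    disp = env.neighbor_displacements
    r = np.linalg.norm(disp, axis=1)
    u = disp / r[:, None]
    Rv, dRv = evaluate_radial_basis(r, spec, polys)       # (n_max, nnbr)
    Y, dY = real_spherical_harmonics(disp, index.l_max)   # (nnbr, nlm), (nnbr, nlm, 3)

    # phi tensor per neighbor: (nnbr, n_max, nlm)
    phi = Rv.T[:, :, None] * Y[:, None, :]
    # gradient: dR (u outer) Y + R dY -> (nnbr, n_max, nlm, 3)
    dphi = (
        dRv.T[:, :, None, None] * u[:, None, None, :] * Y[:, None, :, None]
        + Rv.T[:, :, None, None] * dY[:, None, :, :]
    )

    for zi, z in enumerate(index.elements):
        mask = np.array([e == z for e in env.neighbor_elements])
        if not mask.any():
            continue
        block = index.element_block(z)
        sel = np.nonzero(mask)[0]
        # canonical summation order: bitwise invariance under neighbor
        # permutations requires the float sum to run in a fixed order
        order = sel[np.lexsort(disp[sel].T[::-1])]
        values[block] = phi[order].sum(axis=0).reshape(-1)
        grads[sel, block, :] = dphi[sel].reshape(len(sel), index.n_max * nlm, 3)
    return AtomicBase(index, values, grads)
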