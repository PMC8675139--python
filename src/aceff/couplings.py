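"""O(3)-invariant coupling coefficients over products of real harmonics.

A product of factors carrying angular degrees (l_1 .. l_nu) admits a
rotation-invariant contraction

    B = sum_{m_1..m_nu} C_{m_1..m_nu} prod_t A_{.. l_t m_t}

iff the coefficient tensor C lies in the joint null space of the three total
rotation generators acting on the tensor product of the spin-l_t
representations (in the real-harmonic basis), and -- for full O(3) -- the
parity (-1)^(l_1+..+l_nu) is even.  Odd total l admits no invariant at all,
so parity reduces to an exact integer test.

The per-degree generator matrices are computed *exactly* (to roundoff): the
angular-momentum operator is the tangential differential operator
L_a = -(e_a x u) . grad, which maps degree-l real harmonics into their own
span; applying it via the analytic harmonic gradients at a set of sample
directions and solving the resulting interpolation system recovers the matrix
without any quadrature error.

Because the atomic-base factors commute, coefficient tensors are symmetrized
over permutations of identical factor slots and re-orthonormalized; entries
below 1e-12 are dropped (the coupling tensors are extremely sparse).
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from scipy.linalg import null_space

from .harmonics import lm_index, real_spherical_harmonics

__all__ = ["generator_matrices", "invariant_couplings"]

_SPARSIFY_TOL = 1e-12
_NULLSPACE_RCOND = 1e-8


@lru_cache(maxsize=None)
def generator_matrices(l: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The three SO(3) generator matrices on the (2l+1)-dimensional space of
    degree-l real spherical harmonics: (L_a Y)_j = sum_i G_a[i, j] Y_i."""
    dim = 2 * l + 1
    if l == 0:
        z = np.zeros((1, 1))
        return z, z.copy(), z.copy()
    rng = np.random.default_rng(20210021 + l)  # fixed: generator sampling
    npts = 2 * dim + 8
    u = rng.normal(size=(npts, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    Y, dY = real_spherical_harmonics(u, l)
    sl = slice(lm_index(l, -l), lm_index(l, l) + 1)
    M = Y[:, sl]                      # (npts, dim)
    dYl = dY[:, sl, :]                # (npts, dim, 3)
    out = []
    for a in range(3):
        e = np.zeros(3)
        e[a] = 1.0
        tang = np.cross(e[None, :], u)          # (npts, 3)
        g = -np.einsum("pk,pik->pi", tang, dYl)  # L_a Y_i at each point
        G, *_ = np.linalg.lstsq(M, g, rcond=None)
        out.append(G.T)  # columns index the source harmonic
    return tuple(out)


def _total_generator(ls: tuple[int, ...], a: int) -> np.ndarray:
    dims = [2 * l + 1 for l in ls]
    P = int(np.prod(dims))
    T = np.zeros((P, P))
    for t, l in enumerate(ls):
        G = generator_matrices(l)[a]
        op = np.array([[1.0]])
        for s, d in enumerate(dims):
            op = np.kron(op, G if s == t else np.eye(d))
        T += op
    return T


def invariant_couplings(
    ls: tuple[int, ...],
    identical_slot_groups: tuple[tuple[int, ...], ...] = (),
) -> list[np.ndarray]:
    """Orthonormal spanning set of invariant coefficient tensors for angular
    degrees ``ls``; each returned array has shape (2l_1+1, ..., 2l_nu+1).

    ``identical_slot_groups`` lists groups of factor slots whose full lead
    indices (z, n, l) coincide; coefficients are symmetrized over permutations
    within each group since the corresponding A-factors commute.
    """
    ls = tuple(int(l) for l in ls)
    if sum(ls) % 2 == 1:
        return []  # parity: no O(3) invariant for odd total degree
    dims = tuple(2 * l + 1 for l in ls)
    T = np.vstack([_total_generator(ls, a) for a in range(3)])
    ns = null_space(T, rcond=_NULLSPACE_RCOND)
    if ns.shape[1] == 0:
        return []

    # symmetrize over permutations of identical slots
    perms_per_group = [
        list(itertools.permutations(g)) for g in identical_slot_groups if len(g) > 1
    ]
    vecs = []
    for k in range(ns.shape[1]):
        tens = ns[:, k].reshape(dims)
        if perms_per_group:
            acc = np.zeros_like(tens)
            count = 0
            groups = [g for g in identical_slot_groups if len(g) > 1]
            for combo in itertools.product(*perms_per_group):
                axes = list(range(len(ls)))
                for g, perm in zip(groups, combo):
                    for src, dst in zip(g, perm):
                        axes[dst] = src
                acc += np.transpose(tens, axes)
                count += 1
            tens = acc / count
        vecs.append(tens.reshape(-1))

    V = np.array(vecs)
    # drop zero / duplicate directions, re-orthonormalize
    U, s, Vt = np.linalg.svd(V, full_matrices=False)
    keep = s > 1e-8 * (s[0] if s.size else 1.0)
    out = []
    for row in Vt[keep]:
        row = row.copy()
        row[np.abs(row) < _SPARSIFY_TOL] = 0.0
        nrm = np.linalg.norm(row)
        if nrm > 0:
            out.append((row / nrm).reshape(dims))
    return out
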