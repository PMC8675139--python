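"""Invariant (B-) basis: enumeration, symmetrization, pruning, evaluation.

Candidate basis functions are products of nu atomic-base entries
A_{z_1 n_1 l_1 m_1} .. A_{z_nu n_nu l_nu m_nu}, truncated by correlation
order nu <= nu_max and modified polynomial degree
D = sum_t n_t + w_Y l_t <= D_nu^max.  Each product tuple is canonically
sorted (the A factors commute).  O(3) symmetrization couples the m indices
of every distinct (z, n, l) lead tuple through the invariant coupling
tensors of :mod:`aceff.couplings`; linear dependencies among the resulting
functions are removed by a rank-revealing QR factorization of their
evaluation matrix on a seeded sample of random environments.

Evaluation uses the density trick: a nu-correlation costs one product of nu
pre-computed A entries per coupling element, i.e. O(1) per basis function
regardless of body order, with cost linear in the number of neighbors (spent
once, in the density projection).  ``brute_force_correlation`` keeps the
explicit ordered-neighbor-tuple sum (including self-interaction terms with
repeated neighbor indices) as an independent oracle for small environments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .couplings import invariant_couplings
from .density import AtomicBase, DensityIndex, project_density
from .radial import OrthogonalPolynomialSet, RadialSpec
from .structures import AtomicEnvironment, random_environment

__all__ = [
    "BasisSelection",
    "ProductSpec",
    "SymmetricBasisFunction",
    "BasisSet",
    "enumerate_product_specs",
    "symmetrize",
    "build_candidate_functions",
    "remove_linear_dependencies",
    "build_basis",
    "evaluate_basis",
    "evaluate_basis_gradients",
    "brute_force_correlation",
]

DEFAULT_DEGREE_CAPS = {1: 12, 2: 10, 3: 8, 4: 8}
DEFAULT_PRUNE_SEED = 2021
DEFAULT_PRUNE_TOL = 1e-10


@dataclass(frozen=True)
class BasisSelection:
    """Truncation parameters: element set, maximum correlation order nu_max,
    per-order degree caps D_nu^max, and the angular degree weight w_Y."""

    elements: tuple[str, ...]
    nu_max: int = 3
    degree_caps: tuple[tuple[int, int], ...] = ()
    w_Y: float = 2.0

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("empty element set")
        object.__setattr__(self, "elements", tuple(sorted(self.elements)))
        if self.nu_max < 1:
            raise ValueError("nu_max must be >= 1")
        caps = dict(self.degree_caps) if self.degree_caps else {}
        for nu in range(1, self.nu_max + 1):
            caps.setdefault(nu, DEFAULT_DEGREE_CAPS.get(nu, 8))
            if caps[nu] <= 0:
                raise ValueError("degree caps must be positive")
        object.__setattr__(
            self, "degree_caps", tuple(sorted((k, v) for k, v in caps.items()))
        )

    @property
    def caps(self) -> dict[int, int]:
        return dict(self.degree_caps)

    @property
    def l_max(self) -> int:
        # tightest bound: each of the other nu-1 factors contributes degree >= 1
        caps = self.caps
        return max(
            int((caps[nu] - nu) // self.w_Y) for nu in range(1, self.nu_max + 1)
        )

    @property
    def n_max(self) -> int:
        caps = self.caps
        return max(caps[nu] - (nu - 1) for nu in range(1, self.nu_max + 1))

    def to_dict(self) -> dict:
        return {
            "elements": list(self.elements),
            "nu_max": self.nu_max,
            "degree_caps": [list(x) for x in self.degree_caps],
            "w_Y": self.w_Y,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSelection":
        return cls(
            elements=tuple(d["elements"]),
            nu_max=d["nu_max"],
            degree_caps=tuple(tuple(x) for x in d["degree_caps"]),
            w_Y=d["w_Y"],
        )


def default_selection(elements, **kwargs) -> BasisSelection:
    """The truncation defaults used throughout: nu_max = 4 for at most three
    distinct elements, nu_max = 3 for four or more; w_Y = 2."""
    elements = tuple(sorted(set(elements)))
    nu_max = kwargs.pop("nu_max", 4 if len(elements) <= 3 else 3)
    return BasisSelection(elements=elements, nu_max=nu_max, **kwargs)


@dataclass(frozen=True)
class ProductSpec:
    """A canonical nu-tuple of one-particle multi-indices (z, n, l, m)."""

    indices: tuple[tuple[str, int, int, int], ...]
    w_Y: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", tuple(sorted(self.indices)))

    @property
    def nu(self) -> int:
        return len(self.indices)

    @property
    def degree(self) -> float:
        return sum(n + self.w_Y * l for (_, n, l, _) in self.indices)

    @property
    def lead(self) -> tuple[tuple[str, int, int], ...]:
        return tuple((z, n, l) for (z, n, l, _) in self.indices)


@dataclass(frozen=True)
class SymmetricBasisFunction:
    """One invariant B-function: an ordered lead tuple of (z, n, l) factors
    plus a sparse coupling over the factors' m indices."""

    lead: tuple[tuple[str, int, int], ...]
    m_tuples: tuple[tuple[int, ...], ...]
    coefficients: tuple[float, ...]

    @property
    def nu(self) -> int:
        return len(self.lead)

    @property
    def degree_terms(self) -> tuple[tuple[int, int], ...]:
        return tuple((n, l) for (_, n, l) in self.lead)

    def to_dict(self) -> dict:
        return {
            "lead": [list(x) for x in self.lead],
            "m_tuples": [list(x) for x in self.m_tuples],
            "coefficients": list(self.coefficients),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SymmetricBasisFunction":
        return cls(
            lead=tuple((z, int(n), int(l)) for z, n, l in d["lead"]),
            m_tuples=tuple(tuple(int(m) for m in t) for t in d["m_tuples"]),
            coefficients=tuple(float(c) for c in d["coefficients"]),
        )


def _factor_alphabet(selection: BasisSelection, nu: int):
    """Per-factor (z, n, l) candidates: degree n + w_Y l small enough that the
    remaining nu-1 factors (each of degree >= 1) can still fit under the cap."""
    cap = selection.caps[nu]
    budget = cap - (nu - 1)
    out = []
    for z in selection.elements:
        for n in range(1, int(budget) + 1):
            l = 0
            while n + selection.w_Y * l <= budget:
                out.append((z, n, l))
                l += 1
    return sorted(out)


def _lead_tuples(selection: BasisSelection):
    """All canonical (sorted) lead multisets per correlation order."""
    leads = []
    for nu in range(1, selection.nu_max + 1):
        cap = selection.caps[nu]
        alphabet = _factor_alphabet(selection, nu)
        for combo in itertools.combinations_with_replacement(alphabet, nu):
            deg = sum(n + selection.w_Y * l for (_, n, l) in combo)
            if deg <= cap:
                leads.append(combo)
    return leads


def enumerate_product_specs(selection: BasisSelection) -> list[ProductSpec]:
    """Exactly the canonical nu-tuples of full multi-indices (z, n, l, m)
    with nu <= nu_max and D <= D_nu^max; deterministic order, no duplicates."""
    seen = set()
    out: list[ProductSpec] = []
    for lead in _lead_tuples(selection):
        m_ranges = [range(-l, l + 1) for (_, _, l) in lead]
        for ms in itertools.product(*m_ranges):
            spec = ProductSpec(
                tuple((z, n, l, m) for (z, n, l), m in zip(lead, ms)),
                w_Y=selection.w_Y,
            )
            if spec.indices not in seen:
                seen.add(spec.indices)
                out.append(spec)
    out.sort(key=lambda s: (s.nu, s.indices))
    return out


def _slot_groups(lead) -> tuple[tuple[int, ...], ...]:
    groups: dict[tuple, list[int]] = {}
    for t, key in enumerate(lead):
        groups.setdefault(key, []).append(t)
    return tuple(tuple(v) for v in groups.values())


def symmetrize(spec: ProductSpec) -> list[SymmetricBasisFunction]:
    """All O(3)-invariant couplings over the m indices of the tuple's lead;
    empty when none exists (odd total l, or angular momenta that cannot
    couple to zero)."""
    return _symmetrize_lead(spec.lead)


def _symmetrize_lead(lead) -> list[SymmetricBasisFunction]:
    ls = tuple(l for (_, _, l) in lead)
    tensors = invariant_couplings(ls, _slot_groups(lead))
    out = []
    for tens in tensors:
        nz = np.nonzero(tens)
        coeffs = tens[nz]
        m_tuples = tuple(
            tuple(int(idx[k]) - ls[t] for t, idx in enumerate(nz))
            for k in range(len(coeffs))
        )
        out.append(
            SymmetricBasisFunction(
                lead=tuple(lead),
                m_tuples=m_tuples,
                coefficients=tuple(float(c) for c in coeffs),
            )
        )
    return out


def build_candidate_functions(selection: BasisSelection) -> list[SymmetricBasisFunction]:
    """Symmetrize every distinct lead tuple admitted by the truncation."""
    out: list[SymmetricBasisFunction] = []
    for lead in _lead_tuples(selection):
        out.extend(_symmetrize_lead(lead))
    return out


# ---------------------------------------------------------------------------
# compiled evaluation (density trick)
# ---------------------------------------------------------------------------


@dataclass
class _CompiledGroup:
    nu: int
    func_ids: np.ndarray      # (n_funcs,) global basis-function indices
    idxmat: np.ndarray        # (n_entries, nu) columns into the A vector
    coeff: np.ndarray         # (n_entries,)
    boundaries: np.ndarray    # reduceat boundaries per function


@dataclass
class BasisSet:
    """An ordered, linearly independent set of invariant basis functions,
    shared across center elements, with build provenance."""

    elements: tuple[str, ...]
    functions: list[SymmetricBasisFunction]
    provenance: dict = field(default_factory=dict)
    _compiled: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.functions)

    def compile(self, index: DensityIndex) -> list[_CompiledGroup]:
        key = (index.elements, index.n_max, index.l_max)
        if key in self._compiled:
            return self._compiled[key]
        groups: dict[int, list[int]] = {}
        for b, f in enumerate(self.functions):
            groups.setdefault(f.nu, []).append(b)
        compiled = []
        for nu in sorted(groups):
            fids, idxrows, coeffs, bounds = [], [], [], []
            pos = 0
            for b in groups[nu]:
                f = self.functions[b]
                fids.append(b)
                bounds.append(pos)
                for ms, c in zip(f.m_tuples, f.coefficients):
                    cols = [
                        index.column(z, n, l, m)
                        for (z, n, l), m in zip(f.lead, ms)
                    ]
                    idxrows.append(cols)
                    coeffs.append(c)
                    pos += 1
            compiled.append(
                _CompiledGroup(
                    nu=nu,
                    func_ids=np.array(fids, dtype=np.int64),
                    idxmat=np.array(idxrows, dtype=np.int64).reshape(-1, nu),
                    coeff=np.array(coeffs),
                    boundaries=np.array(bounds, dtype=np.int64),
                )
            )
        self._compiled[key] = compiled
        return compiled


def evaluate_basis(env: AtomicEnvironment, basis: BasisSet, A: AtomicBase) -> np.ndarray:
    """B values for one environment from a pre-computed atomic base."""
    if A.index.elements != tuple(sorted(basis.elements)):
        raise ValueError("basis/model element mismatch")
    B = np.zeros(len(basis))
    for grp in basis.compile(A.index):
        vals = A.values[grp.idxmat]              # (E, nu)
        prod = vals.prod(axis=1)
        B[grp.func_ids] = np.add.reduceat(grp.coeff * prod, grp.boundaries)
    return B


def evaluate_basis_gradients(
    env: AtomicEnvironment, basis: BasisSet, A: AtomicBase
) -> np.ndarray:
    """dB/dr_j, shape (n_basis, n_neighbors, 3), by the product rule."""
    if A.index.elements != tuple(sorted(basis.elements)):
        raise ValueError("basis/model element mismatch")
    nnbr = env.n_neighbors
    dB = np.zeros((len(basis), nnbr, 3))
    if nnbr == 0:
        return dB
    for grp in basis.compile(A.index):
        vals = A.values[grp.idxmat]              # (E, nu)
        for t in range(grp.nu):
            excl = grp.coeff.copy()
            for s in range(grp.nu):
                if s != t:
                    excl = excl * vals[:, s]
            # (nnbr, E, 3) -> per-function reduction over entries
            contrib = excl[None, :, None] * A.gradients[:, grp.idxmat[:, t], :]
            reduced = np.add.reduceat(contrib, grp.boundaries, axis=1)
            dB[grp.func_ids] += reduced.transpose(1, 0, 2)
    return dB


def brute_force_correlation(
    env: AtomicEnvironment,
    spec: ProductSpec,
    radial_spec: RadialSpec,
    polys: OrthogonalPolynomialSet,
    index: DensityIndex,
    max_neighbors: int = 8,
) -> float:
    """The explicit ordered-neighbor-tuple sum for one A-product:

        sum_{j_1..j_nu} prod_t phi_{v_t}(r_{i j_t})

    with repeated neighbor indices allowed (self-interaction terms included),
    matching the density-trick product exactly.  Independent oracle; cost
    grows as neighbors^nu, so environments are capped at ``max_neighbors``.
    """
    if env.n_neighbors > max_neighbors:
        raise ValueError("brute-force oracle restricted to small environments")
    cols = [index.column(z, n, l, m) for (z, n, l, m) in spec.indices]
    # per-neighbor one-particle values over the full flat layout
    phis = []
    for j in range(env.n_neighbors):
        sub = AtomicEnvironment(
            env.center_element,
            [env.neighbor_elements[j]],
            env.neighbor_displacements[j : j + 1],
        )
        phis.append(project_density(sub, radial_spec, polys, index).values)
    total = 0.0
    for tup in itertools.product(range(env.n_neighbors), repeat=spec.nu):
        term = 1.0
        for t, j in enumerate(tup):
            term *= phis[j][cols[t]]
        total += term
    return total


def remove_linear_dependencies(
    candidates: list[SymmetricBasisFunction],
    sample_envs: list[AtomicEnvironment],
    radial_spec: RadialSpec,
    polys: OrthogonalPolynomialSet,
    index: DensityIndex,
    tol: float = DEFAULT_PRUNE_TOL,
    provenance: dict | None = None,
) -> BasisSet:
    """Maximal linearly independent subset of the candidates, certified by a
    pivoted (rank-revealing) QR factorization of the candidate-evaluation
    matrix on the sample environments.  Requires >= 3x oversampling."""
    if len(sample_envs) < 3 * max(len(candidates), 1):
        raise ValueError(
            "need at least 3x as many sample environments as candidates"
        )
    scratch = BasisSet(elements=index.elements, functions=list(candidates))
    M = np.empty((len(sample_envs), len(candidates)))
    for i, env in enumerate(sample_envs):
        A = project_density(env, radial_spec, polys, index)
        M[i] = evaluate_basis(env, scratch, A)
    # column scaling so the rank decision is relative per function
    scale = np.linalg.norm(M, axis=0)
    scale[scale == 0.0] = 1.0
    _, Rq, piv = scipy.linalg.qr(M / scale, mode="economic", pivoting=True)
    diag = np.abs(np.diag(Rq))
    if diag.size == 0 or diag[0] == 0.0:
        keep: list[int] = []
    else:
        rank = int(np.sum(diag > tol * diag[0]))
        keep = sorted(piv[:rank])
    funcs = [candidates[k] for k in keep]
    prov = dict(provenance or {})
    prov.update({"prune_tol": tol, "n_candidates": len(candidates), "rank": len(funcs)})
    return BasisSet(elements=index.elements, functions=funcs, provenance=prov)


def build_basis(
    selection: BasisSelection,
    radial_spec: RadialSpec,
    polys: OrthogonalPolynomialSet,
    index: DensityIndex | None = None,
    seed: int = DEFAULT_PRUNE_SEED,
    tol: float = DEFAULT_PRUNE_TOL,
) -> BasisSet:
    """Enumerate, symmetrize and prune: the full basis-construction pipeline.

    Pruning environments are drawn with the documented seed; the seed and
    tolerance are recorded in the provenance so the basis identity is
    reproducible bit for bit."""
    if radial_spec.n_max < selection.n_max:
        raise ValueError(
            f"radial n_max={radial_spec.n_max} too small for the degree caps "
            f"(need {selection.n_max})"
        )
    if index is None:
        index = DensityIndex(selection.elements, radial_spec.n_max, selection.l_max)
    candidates = build_candidate_functions(selection)
    rng = np.random.default_rng(seed)
    n_env = max(3 * len(candidates), 30)
    envs = [
        random_environment(
            rng,
            selection.elements,
            n_neighbors=int(rng.integers(3, 9)),
            r_lo=max(radial_spec.r_in + 0.05, 0.3),
            r_hi=radial_spec.r_out - 0.05,
        )
        for _ in range(n_env)
    ]
    prov = {
        "selection": selection.to_dict(),
        "radial": radial_spec.to_dict(),
        "prune_seed": seed,
    }
    return remove_linear_dependencies(
        candidates, envs, radial_spec, polys, index, tol=tol, provenance=prov
    )
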