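"""Invariant basis: enumeration, symmetrization, pruning, evaluation."""

import numpy as np
import pytest
from scipy.stats import ortho_group, special_ortho_group

from aceff.bbasis import (
    BasisSelection,
    BasisSet,
    ProductSpec,
    brute_force_correlation,
    build_basis,
    enumerate_product_specs,
    evaluate_basis,
    evaluate_basis_gradients,
    remove_linear_dependencies,
    symmetrize,
)
from aceff.density import project_density
from aceff.structures import AtomicEnvironment, random_environment


def _eval(setup, basis, env):
    A = project_density(env, setup["radial"], setup["polys"], setup["index"])
    return evaluate_basis(env, basis, A)


class TestEnumeration:
    def test_nu1_hand_enumeration(self):
        # one element, D_1^max = 3, w_Y = 2: (n,l) in {(1,0),(2,0),(3,0),(1,1)},
        # all m -> 3 + 3 = 6 specs
        sel = BasisSelection(elements=("C",), nu_max=1, degree_caps=((1, 3),))
        specs = enumerate_product_specs(sel)
        assert len(specs) == 6
        nl = sorted({(s.indices[0][1], s.indices[0][2]) for s in specs})
        assert nl == [(1, 0), (1, 1), (2, 0), (3, 0)]

    def test_canonical_sorting_identifies_permuted_tuples(self):
        a = ProductSpec((("C", 1, 0, 0), ("H", 2, 1, -1)))
        b = ProductSpec((("H", 2, 1, -1), ("C", 1, 0, 0)))
        assert a == b

    def test_truncation_is_monotone_in_nu_max(self):
        caps = ((1, 5), (2, 5))
        s1 = enumerate_product_specs(
            BasisSelection(elements=("C",), nu_max=1, degree_caps=caps[:1])
        )
        s2 = enumerate_product_specs(
            BasisSelection(elements=("C",), nu_max=2, degree_caps=caps)
        )
        assert set(s1) <= set(s2)

    def test_no_duplicates_and_deterministic(self):
        sel = BasisSelection(elements=("C", "H"), nu_max=2, degree_caps=((1, 5), (2, 5)))
        a = enumerate_product_specs(sel)
        b = enumerate_product_specs(sel)
        assert a == b
        assert len(a) == len(set(a))

    def test_empty_element_set_rejected(self):
        with pytest.raises(ValueError):
            BasisSelection(elements=(), nu_max=1)


class TestSymmetrization:
    def test_nu1_l0_single_invariant(self):
        out = symmetrize(ProductSpec((("C", 2, 0, 0),)))
        assert len(out) == 1
        assert out[0].m_tuples == ((0,),)

    def test_nu1_l_positive_annihilated(self):
        # the rotational average of a single l > 0 harmonic vanishes
        for l in (1, 2, 3):
            assert symmetrize(ProductSpec((("C", 1, l, 0),))) == []

    def test_nu2_mismatched_l_empty(self):
        assert symmetrize(ProductSpec((("C", 1, 1, 0), ("C", 1, 2, 0)))) == []

    def test_nu2_matched_l_is_the_diagonal_pairing(self):
        out = symmetrize(ProductSpec((("C", 1, 2, 0), ("H", 1, 2, 0))))
        assert len(out) == 1
        f = out[0]
        # sum_m A_{l m} A'_{l m} pairing: diagonal in (m1, m2), equal weights
        assert all(m1 == m2 for (m1, m2) in f.m_tuples)
        assert np.allclose(np.abs(f.coefficients), np.abs(f.coefficients[0]))

    def test_odd_total_l_has_no_invariant(self):
        assert symmetrize(ProductSpec((("C", 1, 1, 0), ("C", 1, 1, 0), ("C", 1, 1, 0)))) == []

    def test_invariance_under_random_o3(self, small_setup, rng):
        out = symmetrize(ProductSpec((("C", 1, 1, 0), ("C", 1, 1, 0), ("C", 1, 2, 0))))
        assert out  # 1+1+2 couples to zero
        scratch = BasisSet(elements=("C", "H"), functions=out)
        env = random_environment(rng, ("C", "H"), n_neighbors=5, r_lo=0.9, r_hi=3.8)
        B0 = _eval(small_setup, scratch, env)
        for k in range(20):
            Q = ortho_group.rvs(3, random_state=k)  # includes reflections
            Bk = _eval(small_setup, scratch, env.rotated(Q))
            assert np.abs(Bk - B0).max() < 1e-10


class TestEvaluation:
    def test_permutation_invariance_bitwise(self, small_setup, rng):
        basis = small_setup["basis"]
        env = random_environment(rng, ("C", "H"), n_neighbors=7, r_lo=0.9, r_hi=3.8)
        B = _eval(small_setup, basis, env)
        for _ in range(5):
            perm = rng.permutation(env.n_neighbors)
            envp = AtomicEnvironment(
                env.center_element,
                [env.neighbor_elements[j] for j in perm],
                env.neighbor_displacements[perm],
            )
            assert np.array_equal(_eval(small_setup, basis, envp), B)

    def test_rotation_reflection_invariance(self, small_setup, rng):
        basis = small_setup["basis"]
        env = random_environment(rng, ("C", "H"), n_neighbors=6, r_lo=0.9, r_hi=3.8)
        B = _eval(small_setup, basis, env)
        for k in range(25):
            Q = ortho_group.rvs(3, random_state=100 + k)
            Bk = _eval(small_setup, basis, env.rotated(Q))
            assert np.abs(Bk - B).max() < 1e-10

    def test_empty_environment_vanishes(self, small_setup):
        env = AtomicEnvironment("C", [], np.zeros((0, 3)))
        B = _eval(small_setup, small_setup["basis"], env)
        assert np.all(B == 0.0)

    def test_element_mismatch_rejected(self, small_setup, rng):
        foreign = BasisSet(elements=("N", "O"), functions=[])
        env = random_environment(rng, ("C", "H"), n_neighbors=3)
        A = project_density(env, small_setup["radial"], small_setup["polys"],
                            small_setup["index"])
        with pytest.raises(ValueError):
            evaluate_basis(env, foreign, A)

    def test_gradients_match_finite_differences(self, small_setup, rng):
        basis = small_setup["basis"]
        env = random_environment(rng, ("C", "H"), n_neighbors=4, r_lo=1.0, r_hi=3.5)
        A = project_density(env, small_setup["radial"], small_setup["polys"],
                            small_setup["index"])
        dB = evaluate_basis_gradients(env, basis, A)
        h = 1e-6
        err = 0.0
        for j in range(env.n_neighbors):
            for d in range(3):
                dp = env.neighbor_displacements.copy()
                dp[j, d] += h
                dm = env.neighbor_displacements.copy()
                dm[j, d] -= h
                ep = AtomicEnvironment(env.center_element, env.neighbor_elements, dp)
                em = AtomicEnvironment(env.center_element, env.neighbor_elements, dm)
                fd = (_eval(small_setup, basis, ep) - _eval(small_setup, basis, em)) / (2 * h)
                err = max(err, np.abs(fd - dB[:, j, d]).max())
        assert err < 1e-6

    def test_neighbor_beyond_cutoff_has_zero_gradient(self, small_setup):
        r_out = small_setup["radial"].r_out
        env = AtomicEnvironment(
            "C", ["H", "H"], np.array([[1.2, 0.0, 0.3], [r_out + 0.5, 0.0, 0.0]])
        )
        A = project_density(env, small_setup["radial"], small_setup["polys"],
                            small_setup["index"])
        dB = evaluate_basis_gradients(env, small_setup["basis"], A)
        assert np.all(dB[:, 1, :] == 0.0)

    def test_smooth_across_outer_cutoff(self, small_setup):
        # moving one neighbor radially through r_out: B continuous with
        # continuous first derivative
        r_out = small_setup["radial"].r_out
        basis = small_setup["basis"]

        def val(r):
            env = AtomicEnvironment(
                "C", ["H", "C"], np.array([[1.1, 0.4, -0.2], [r, 0.0, 0.0]])
            )
            return _eval(small_setup, basis, env)

        h = 1e-7
        assert np.abs(val(r_out - h) - val(r_out + h)).max() < 1e-10
        dl = (val(r_out - h) - val(r_out - 3 * h)) / (2 * h)
        dr = (val(r_out + 3 * h) - val(r_out + h)) / (2 * h)
        assert np.abs(dl - dr).max() < 1e-5


class TestBruteForceOracle:
    def test_density_trick_equals_ordered_tuple_sum(self, small_setup, rng):
        sel = BasisSelection(
            elements=("C", "H"), nu_max=4, degree_caps=((1, 5), (2, 5), (3, 5), (4, 5))
        )
        specs = enumerate_product_specs(sel)
        for _ in range(12):
            env = random_environment(rng, ("C", "H"),
                                     n_neighbors=int(rng.integers(1, 7)),
                                     r_lo=0.9, r_hi=3.8)
            A = project_density(env, small_setup["radial"], small_setup["polys"],
                                small_setup["index"])
            for spec in specs[:: max(len(specs) // 25, 1)]:
                trick = np.prod(
                    [A.values[small_setup["index"].column(*v)] for v in spec.indices]
                )
                oracle = brute_force_correlation(
                    env, spec, small_setup["radial"], small_setup["polys"],
                    small_setup["index"],
                )
                assert abs(trick - oracle) < 1e-12

    def test_single_neighbor_nu2_is_phi_squared(self, small_setup):
        env = AtomicEnvironment("C", ["H"], np.array([[1.3, 0.2, 0.4]]))
        spec = ProductSpec((("H", 1, 0, 0), ("H", 2, 0, 0)))
        A = project_density(env, small_setup["radial"], small_setup["polys"],
                            small_setup["index"])
        c1 = small_setup["index"].column("H", 1, 0, 0)
        c2 = small_setup["index"].column("H", 2, 0, 0)
        oracle = brute_force_correlation(env, spec, small_setup["radial"],
                                         small_setup["polys"], small_setup["index"])
        assert oracle == pytest.approx(A.values[c1] * A.values[c2], rel=1e-14)

    def test_empty_environment_is_zero(self, small_setup):
        env = AtomicEnvironment("C", [], np.zeros((0, 3)))
        spec = ProductSpec((("H", 1, 0, 0),))
        assert brute_force_correlation(env, spec, small_setup["radial"],
                                       small_setup["polys"], small_setup["index"]) == 0.0

    def test_large_environment_refused(self, small_setup, rng):
        env = random_environment(rng, ("C",), n_neighbors=12, r_lo=1.0, r_hi=3.5)
        spec = ProductSpec((("C", 1, 0, 0),))
        with pytest.raises(ValueError):
            brute_force_correlation(env, spec, small_setup["radial"],
                                    small_setup["polys"], small_setup["index"])


class TestPruning:
    def _envs(self, rng, n):
        return [
            random_environment(rng, ("C", "H"), n_neighbors=int(rng.integers(3, 8)),
                               r_lo=0.9, r_hi=3.8)
            for _ in range(n)
        ]

    def test_exact_duplicate_removed(self, small_setup, rng):
        funcs = list(small_setup["basis"].functions[:10])
        cands = funcs + [funcs[3]]
        out = remove_linear_dependencies(
            cands, self._envs(rng, 3 * len(cands) + 5), small_setup["radial"],
            small_setup["polys"], small_setup["index"],
        )
        assert len(out) == len(funcs)

    def test_zero_function_removed(self, small_setup, rng):
        from aceff.bbasis import SymmetricBasisFunction

        zero = SymmetricBasisFunction(lead=(("C", 1, 1),), m_tuples=((0,),),
                                      coefficients=(0.0,))
        cands = list(small_setup["basis"].functions[:8]) + [zero]
        out = remove_linear_dependencies(
            cands, self._envs(rng, 3 * len(cands) + 5), small_setup["radial"],
            small_setup["polys"], small_setup["index"],
        )
        assert len(out) == 8
        assert zero not in out.functions

    def test_rank_reproducible_across_sampling_seeds(self, small_setup):
        cands = list(small_setup["basis"].functions[:20])
        ranks = []
        for seed in (11, 12):
            rng = np.random.default_rng(seed)
            out = remove_linear_dependencies(
                cands, self._envs(rng, 3 * len(cands) + 10), small_setup["radial"],
                small_setup["polys"], small_setup["index"],
            )
            ranks.append(len(out))
        assert ranks[0] == ranks[1]

    def test_insufficient_samples_rejected(self, small_setup, rng):
        cands = list(small_setup["basis"].functions[:10])
        with pytest.raises(ValueError):
            remove_linear_dependencies(
                cands, self._envs(rng, 5), small_setup["radial"],
                small_setup["polys"], small_setup["index"],
            )


def test_nu2_span_matches_power_spectrum(small_setup, rng):
    """The nu = 2 invariants span the same space as an independently coded
    SOAP-style power spectrum p_{z1 n1, z2 n2, l} = sum_m A_{z1 n1 l m} A_{z2 n2 l m}."""
    from aceff.bbasis import build_candidate_functions

    sel = BasisSelection(elements=("C", "H"), nu_max=2, degree_caps=((1, 1), (2, 7)))
    cands = [f for f in build_candidate_functions(sel) if f.nu == 2]
    scratch = BasisSet(elements=("C", "H"), functions=cands)
    envs = [
        random_environment(rng, ("C", "H"), n_neighbors=int(rng.integers(3, 8)),
                           r_lo=0.9, r_hi=3.8)
        for _ in range(4 * len(cands) + 20)
    ]
    X = np.empty((len(envs), len(cands)))
    P_cols = []
    # independent power-spectrum enumeration under the same degree cap
    pairs = []
    for z1 in ("C", "H"):
        for z2 in ("C", "H"):
            for n1 in range(1, 8):
                for n2 in range(1, 8):
                    if (z1, n1) > (z2, n2):
                        continue
                    for l in range(0, 4):
                        if n1 + n2 + 2 * 2 * l <= 7:
                            pairs.append((z1, n1, z2, n2, l))
    P = np.empty((len(envs), len(pairs)))
    for i, env in enumerate(envs):
        A = project_density(env, small_setup["radial"], small_setup["polys"],
                            small_setup["index"])
        X[i] = evaluate_basis(env, scratch, A)
        for c, (z1, n1, z2, n2, l) in enumerate(pairs):
            s = 0.0
            for m in range(-l, l + 1):
                s += (
                    A.values[small_setup["index"].column(z1, n1, l, m)]
                    * A.values[small_setup["index"].column(z2, n2, l, m)]
                )
            P[i, c] = s
    # each basis evaluation must be reproduced exactly from the power
    # spectrum and vice versa (projection residual < 1e-10)
    coef, *_ = np.linalg.lstsq(P, X, rcond=None)
    res1 = np.abs(P @ coef - X).max()
    coef2, *_ = np.linalg.lstsq(X, P, rcond=None)
    res2 = np.abs(X @ coef2 - P).max()
    assert res1 < 1e-10 and res2 < 1e-10
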