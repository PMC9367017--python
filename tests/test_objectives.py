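import numpy as np
import pytest
from scipy.linalg import expm

from erloc.mol_integrals import MOCoefficients
from erloc.objectives import (
    CholeskyERObjective,
    ERState,
    Kappa,
    StaleStateError,
    er_energy,
    er_energy_decomposition,
    er_gradient,
    er_hessian_apply,
    er_hessian_diagonal,
    exact_er_oracle,
    fb_objective,
    pair_indices,
    refresh_er_state,
)
from tests.conftest import mo_eri


def _random_rotation(n, seed, scale=0.3):
    rng = np.random.default_rng(seed)
    K = scale * rng.standard_normal((n, n))
    return expm(K - K.T)


def _rotated_occ(cache, name, basis, seed):
    _, occ, _, _ = cache.scf(name, basis)
    return MOCoefficients(occ.C @ _random_rotation(occ.n, seed), space="occupied")


class TestKappa:
    def test_round_trip_and_antisymmetry(self):
        rng = np.random.default_rng(1)
        K = rng.standard_normal((6, 6))
        K = K - K.T
        kap = Kappa.from_matrix(K)
        assert np.abs(kap.to_matrix() - K).max() < 1e-14
        assert np.abs(kap.to_matrix() + kap.to_matrix().T).max() == 0.0

    def test_rejects_non_antisymmetric(self):
        with pytest.raises(ValueError):
            Kappa.from_matrix(np.eye(3))


class TestEnergy:
    def test_single_orbital_positive(self, cache):
        _, occ, _, _ = cache.scf("water", "sto-3g")
        C1 = MOCoefficients(occ.C[:, :1])
        st = refresh_er_state(cache.chol("water", "sto-3g"), C1)
        assert er_energy(st) > 0.0
        assert er_gradient(st).shape == (1, 1)
        assert np.all(er_gradient(st) == 0.0)

    def test_matches_exact_oracle(self, cache):
        ints, occ, _, _ = cache.scf("water", "sto-3g")
        for seed in range(3):
            C = _rotated_occ(cache, "water", "sto-3g", seed)
            st = refresh_er_state(cache.chol("water", "sto-3g"), C)
            E_exact, _ = exact_er_oracle(ints, C)
            assert er_energy(st) == pytest.approx(E_exact, abs=1e-8)

    def test_sign_flip_invariance(self, cache):
        C = _rotated_occ(cache, "water", "sto-3g", 5)
        flipped = MOCoefficients(C.C * np.array([1, -1, 1, -1, 1]))
        L = cache.chol("water", "sto-3g")
        assert er_energy(refresh_er_state(L, C)) == pytest.approx(
            er_energy(refresh_er_state(L, flipped)), abs=1e-12)

    def test_stale_state_rejected(self, cache):
        _, occ, _, _ = cache.scf("water", "sto-3g")
        obj = CholeskyERObjective(cache.chol("water", "sto-3g"))
        st1 = obj.refresh(occ)
        obj.refresh(occ)
        with pytest.raises(StaleStateError):
            er_energy(st1)

    def test_cd_exact_equivalence_across_tau(self, cache):
        ints, occ, _, _ = cache.scf("water", "cc-pvdz")
        E_exact, _ = exact_er_oracle(ints, occ)
        for tau in (1e-8, 1e-6, 1e-4):
            st = refresh_er_state(cache.chol("water", "cc-pvdz", tau), occ)
            assert abs(er_energy(st) - E_exact) <= 10 * occ.n * tau


class TestDecomposition:
    def test_single_orbital_no_interorbital_terms(self, cache):
        _, occ, _, _ = cache.scf("water", "sto-3g")
        st = refresh_er_state(cache.chol("water", "sto-3g"),
                              MOCoefficients(occ.C[:, :1]))
        self_rep, coul, exch = er_energy_decomposition(st)
        assert coul == pytest.approx(0.0, abs=1e-12)
        assert exch == pytest.approx(0.0, abs=1e-12)

    def test_matches_exact_sums(self, cache):
        ints, occ, _, _ = cache.scf("water", "sto-3g")
        g = mo_eri(ints, occ)
        st = refresh_er_state(cache.chol("water", "sto-3g"), occ)
        self_rep, coul, exch = er_energy_decomposition(st)
        n = occ.n
        idx = np.arange(n)
        self_x = sum(g[p, p, p, p] for p in idx)
        coul_x = sum(g[p, p, q, q] for p in idx for q in idx if p != q)
        exch_x = sum(g[p, q, p, q] for p in idx for q in idx if p != q)
        assert self_rep == pytest.approx(self_x, abs=1e-8)
        assert coul == pytest.approx(coul_x, abs=1e-8)
        assert exch == pytest.approx(exch_x, abs=1e-8)

    @pytest.mark.parametrize("name,basis", [("water", "sto-3g"), ("ethane", "sto-3g")])
    def test_conservation_under_rotation(self, cache, name, basis):
        """Self+exchange and self+Coulomb sums are rotation invariant."""
        _, occ, _, _ = cache.scf(name, basis)
        L = cache.chol(name, basis)
        s0, c0, x0 = er_energy_decomposition(refresh_er_state(L, occ))
        for seed in (0, 1, 2):
            C = MOCoefficients(occ.C @ _random_rotation(occ.n, seed, scale=0.8))
            s1, c1, x1 = er_energy_decomposition(refresh_er_state(L, C))
            assert abs((s0 + x0) - (s1 + x1)) <= 1e-9
            assert abs((s0 + c0) - (s1 + c1)) <= 1e-9


class TestGradient:
    def test_matches_exact_analytic_form(self, cache):
        """CD gradient equals 4[(pq|pp)-(pq|qq)] from brute-force MO ERIs."""
        ints, _, _, _ = cache.scf("water", "sto-3g")
        C = _rotated_occ(cache, "water", "sto-3g", 21)
        st = refresh_er_state(cache.chol("water", "sto-3g"), C)
        _, G_exact = exact_er_oracle(ints, C)
        assert np.abs(er_gradient(st) - G_exact).max() <= 1e-8

    @pytest.mark.parametrize("name,basis,seeds", [
        ("water", "sto-3g", range(5)),
        ("ethane", "sto-3g", range(3)),
    ])
    def test_finite_difference(self, cache, name, basis, seeds):
        L = cache.chol(name, basis)
        obj = CholeskyERObjective(L)
        _, occ, _, _ = cache.scf(name, basis)
        for seed in seeds:
            C = MOCoefficients(occ.C @ _random_rotation(occ.n, seed))
            st = refresh_er_state(L, C)
            G = er_gradient(st)
            rng = np.random.default_rng(100 + seed)
            v = rng.standard_normal(occ.n * (occ.n - 1) // 2)
            v /= np.linalg.norm(v)
            K = Kappa(v, occ.n).to_matrix()
            eps = 1e-4
            fp = obj.value(MOCoefficients(C.C @ expm(eps * K)))
            fm = obj.value(MOCoefficients(C.C @ expm(-eps * K)))
            directional = float(np.sum(G[pair_indices(occ.n)] * v))
            assert abs((fp - fm) / (2 * eps) - directional) <= 1e-6


class TestHessian:
    def test_zero_kappa_gives_zero(self, cache):
        _, occ, _, _ = cache.scf("water", "sto-3g")
        st = refresh_er_state(cache.chol("water", "sto-3g"), occ)
        out = er_hessian_apply(st, Kappa.zeros(occ.n))
        assert np.abs(out).max() == 0.0

    def test_directional_derivative_of_gradient(self, cache):
        """FD of the rotated-orbital gradient equals H kappa - 1/2 [kappa, g].

        The commutator is the chart-curvature term of the exponential
        parametrization; subtracting it leaves the symmetric Hessian.
        """
        L = cache.chol("water", "sto-3g")
        _, occ, _, _ = cache.scf("water", "sto-3g")
        C = _rotated_occ(cache, "water", "sto-3g", 33)
        st = refresh_er_state(L, C)
        rng = np.random.default_rng(8)
        kap = Kappa(rng.standard_normal(10), occ.n)
        K = kap.to_matrix()
        H = er_hessian_apply(st, kap)
        A = er_gradient(st)
        eps = 1e-4
        gp = er_gradient(refresh_er_state(L, MOCoefficients(C.C @ expm(eps * K))))
        gm = er_gradient(refresh_er_state(L, MOCoefficients(C.C @ expm(-eps * K))))
        fd = (gp - gm) / (2 * eps)
        assert np.abs(fd - (H - 0.5 * (K @ A - A @ K))).max() <= 1e-5

    def test_quadratic_form_second_difference(self, cache):
        """Along a single direction the chart term vanishes identically."""
        L = cache.chol("ethane", "sto-3g")
        _, occ, _, _ = cache.scf("ethane", "sto-3g")
        obj = CholeskyERObjective(L)
        C = MOCoefficients(occ.C @ _random_rotation(occ.n, 2))
        st = refresh_er_state(L, C)
        rng = np.random.default_rng(9)
        v = rng.standard_normal(occ.n * (occ.n - 1) // 2)
        v /= np.linalg.norm(v)
        kap = Kappa(v, occ.n)
        K = kap.to_matrix()
        eps = 1e-4
        f0 = obj.value(C)
        fp = obj.value(MOCoefficients(C.C @ expm(eps * K)))
        fm = obj.value(MOCoefficients(C.C @ expm(-eps * K)))
        qform = float(v @ er_hessian_apply(st, kap)[pair_indices(occ.n)])
        assert abs((fp - 2 * f0 + fm) / eps ** 2 - qform) <= 1e-5

    def test_bilinear_form_symmetry(self, cache):
        C = _rotated_occ(cache, "water", "sto-3g", 44)
        st = refresh_er_state(cache.chol("water", "sto-3g"), C)
        iu = pair_indices(5)
        rng = np.random.default_rng(12)
        for _ in range(10):
            k1 = Kappa(rng.standard_normal(10), 5)
            k2 = Kappa(rng.standard_normal(10), 5)
            s12 = float(k1.values @ st.hessian_apply(k2)[iu])
            s21 = float(k2.values @ st.hessian_apply(k1)[iu])
            assert abs(s12 - s21) <= 1e-9 * max(1.0, abs(s12))

    def test_diagonal_equals_unit_kappa_applies(self, cache):
        C = _rotated_occ(cache, "water", "sto-3g", 55)
        st = refresh_er_state(cache.chol("water", "sto-3g"), C)
        Hd = er_hessian_diagonal(st)
        iu = pair_indices(5)
        m = len(iu[0])
        for idx, (p, q) in enumerate(zip(*iu)):
            v = np.zeros(m)
            v[idx] = 1.0
            assert abs(st.hessian_apply(Kappa(v, 5))[p, q] - Hd[p, q]) <= 1e-10

    def test_two_orbital_diagonal_second_difference(self, cache):
        _, occ, _, _ = cache.scf("water", "sto-3g")
        L = cache.chol("water", "sto-3g")
        C2 = MOCoefficients(occ.C[:, 3:5])
        obj = CholeskyERObjective(L)
        st = refresh_er_state(L, C2)
        Hd = st.hessian_diagonal_full()[1, 0]
        eps = 1e-4
        th = np.array([[0.0, -1.0], [1.0, 0.0]])
        f0 = obj.value(C2)
        fp = obj.value(MOCoefficients(C2.C @ expm(eps * th)))
        fm = obj.value(MOCoefficients(C2.C @ expm(-eps * th)))
        assert abs((fp - 2 * f0 + fm) / eps ** 2 - Hd) <= 1e-5

    def test_dimension_mismatch(self, cache):
        _, occ, _, _ = cache.scf("water", "sto-3g")
        st = refresh_er_state(cache.chol("water", "sto-3g"), occ)
        with pytest.raises(ValueError):
            st.hessian_apply(np.zeros((3, 3)))


class TestRefresh:
    def test_deterministic_rebuild(self, cache):
        _, occ, _, _ = cache.scf("water", "cc-pvdz")
        L = cache.chol("water", "cc-pvdz")
        a = refresh_er_state(L, occ)
        b = refresh_er_state(L, occ)
        assert np.array_equal(a.M, b.M)
        assert a.f_value == b.f_value

    def test_energy_from_state_equals_direct_contraction(self, cache):
        ints, occ, _, _ = cache.scf("water", "sto-3g")
        st = refresh_er_state(cache.chol("water", "sto-3g"), occ)
        g = mo_eri(ints, occ)
        assert er_energy(st) == pytest.approx(
            float(np.einsum("pppp->", g)), abs=1e-8)

    def test_congruence_two_path_state(self, cache):
        _, occ, _, _ = cache.scf("water", "sto-3g")
        L = cache.chol("water", "sto-3g")
        U = _random_rotation(occ.n, 3)
        direct = refresh_er_state(L, MOCoefficients(occ.C @ U))
        base = refresh_er_state(L, occ)
        congr = np.einsum("tp,jtu,uq->jpq", U, base.M, U)
        assert np.abs(direct.M - congr).max() <= 1e-9

    def test_projector_preserved_by_rotation(self, cache):
        ints, occ, _, _ = cache.scf("water", "cc-pvdz")
        C = _rotated_occ(cache, "water", "cc-pvdz", 17)
        D0 = occ.C @ occ.C.T
        D1 = C.C @ C.C.T
        assert np.abs(D0 - D1).max() <= 1e-10


class TestFosterBoys:
    def test_single_orbital_nonnegative_and_empty_gradient(self, cache):
        ints, occ, _, _ = cache.scf("water", "sto-3g")
        obj = fb_objective(ints)
        st = obj.refresh(MOCoefficients(occ.C[:, :1]))
        assert st.f_value >= 0.0
        assert np.all(st.gradient_full() == 0.0)

    def test_translation_invariance(self, cache):
        from erloc.mol_integrals import BasisSpec, compute_ao_integrals

        ints, occ, _, _ = cache.scf("water", "sto-3g")
        f0 = fb_objective(ints).value(occ)
        mol2 = ints.molecule.translated([5.0, 5.0, 5.0])
        ints2 = compute_ao_integrals(mol2, BasisSpec.for_molecule(mol2, "sto-3g"))
        # the same coefficients describe the rigidly shifted orbitals
        f1 = fb_objective(ints2).value(MOCoefficients(occ.C))
        assert abs(f0 - f1) <= 1e-10

    def test_finite_difference_gradient(self, cache):
        ints, occ, _, _ = cache.scf("water", "cc-pvdz")
        obj = fb_objective(ints)
        for seed in range(5):
            C = MOCoefficients(occ.C @ _random_rotation(occ.n, seed))
            st = obj.refresh(C)
            G = st.gradient_full()
            rng = np.random.default_rng(200 + seed)
            v = rng.standard_normal(occ.n * (occ.n - 1) // 2)
            v /= np.linalg.norm(v)
            K = Kappa(v, occ.n).to_matrix()
            eps = 1e-4
            fp = obj.value(MOCoefficients(C.C @ expm(eps * K)))
            fm = obj.value(MOCoefficients(C.C @ expm(-eps * K)))
            directional = float(np.sum(G[pair_indices(occ.n)] * v))
            assert abs((fp - fm) / (2 * eps) - directional) <= 1e-6
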