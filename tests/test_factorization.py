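"""SF/DF/THC factorizations, reconstruction, lambda norms, serialization."""

import numpy as np
import pytest

import fermifactor as ff
from fermifactor.errors import ArgumentError
from fermifactor.factorization import _thc_tensor, effective_one_body


def frob(x):
    return float(np.linalg.norm(x))


class TestSingleFactorization:
    def test_recovers_known_rank(self, rank3_hamiltonian):
        sf = ff.single_factorize(rank3_hamiltonian, tol=1e-10)
        assert sf.n_vectors == 3
        assert frob(ff.reconstruct_eri(sf) - rank3_hamiltonian.eri) < 1e-9

    def test_tol_zero_is_exact(self, small_hamiltonian):
        sf = ff.single_factorize(small_hamiltonian, tol=0.0)
        assert frob(ff.reconstruct_eri(sf) - small_hamiltonian.eri) < 1e-10

    def test_truncation_error_non_increasing(self, rank3_hamiltonian):
        errs = [frob(ff.reconstruct_eri(
            ff.single_factorize(rank3_hamiltonian, n_vectors=k))
            - rank3_hamiltonian.eri) for k in (1, 2, 3)]
        assert errs[0] >= errs[1] >= errs[2]

    def test_requires_exactly_one_knob(self, small_hamiltonian):
        with pytest.raises(ArgumentError):
            ff.single_factorize(small_hamiltonian)
        with pytest.raises(ArgumentError):
            ff.single_factorize(small_hamiltonian, tol=1e-8, n_vectors=2)

    def test_pivoted_cholesky_agrees_with_eig(self, rank3_hamiltonian):
        chol = ff.single_factorize(rank3_hamiltonian, tol=1e-8,
                                   method="cholesky")
        np.testing.assert_allclose(ff.reconstruct_eri(chol),
                                   rank3_hamiltonian.eri, atol=1e-8)


class TestDoubleFactorization:
    def test_leaf_tol_zero_reconstructs_leaves(self, rank3_hamiltonian):
        sf = ff.single_factorize(rank3_hamiltonian, tol=1e-10)
        df = ff.double_factorize(sf, leaf_tol=0.0)
        for fv, u, mat in zip(df.leaf_eigenvalues, df.leaf_vectors, sf.vectors):
            np.testing.assert_allclose(u @ np.diag(fv) @ u.T, mat, atol=1e-10)
        np.testing.assert_allclose(ff.reconstruct_eri(df),
                                   ff.reconstruct_eri(sf), atol=1e-10)

    def test_leaf_rank_threshold_count(self):
        leaf = np.diag([1.0, 0.5, 1e-9])
        sf = ff.SingleFactorization(vectors=np.array([leaf]),
                                    eigenvalues=np.array([1.0]))
        df = ff.double_factorize(sf, leaf_tol=1e-6)
        assert df.leaf_ranks == [2]
        assert df.avg_rank == 2.0

    def test_truncated_leaf_error_is_dropped_eigenvalue_norm(self):
        rng = np.random.default_rng(11)
        m = rng.normal(size=(5, 5))
        m = 0.5 * (m + m.T)
        f, _ = np.linalg.eigh(m)
        mags = sorted(np.abs(f))
        cut = 0.5 * (mags[1] + mags[2])  # drop the two smallest magnitudes
        sf = ff.SingleFactorization(vectors=np.array([m]),
                                    eigenvalues=np.array([1.0]))
        df = ff.double_factorize(sf, leaf_tol=cut)
        leaf = df.leaf_vectors[0] @ np.diag(df.leaf_eigenvalues[0]) @ df.leaf_vectors[0].T
        dropped = sorted(np.abs(f))[:2]
        assert abs(frob(leaf - m) - np.sqrt(np.sum(np.square(dropped)))) < 1e-10

    def test_orthonormal_leaf_vectors(self, rank3_hamiltonian):
        df = ff.double_factorize(
            ff.single_factorize(rank3_hamiltonian, tol=1e-10), leaf_tol=1e-8)
        for u in df.leaf_vectors:
            np.testing.assert_allclose(u.T @ u, np.eye(u.shape[1]), atol=1e-10)


class TestTHC:
    def test_planted_factors_recovered(self):
        rng = np.random.default_rng(42)
        n, m = 3, 2
        chi0 = rng.normal(size=(n, m))
        a = rng.normal(size=(m, m))
        eri = _thc_tensor(chi0, a @ a.T)
        h = ff.ActiveSpaceHamiltonian(n, 2, 1, 0.0, np.zeros((n, n)), eri)
        thc = ff.thc_factorize(h, rank=m, seed=1)
        assert thc.objective_trace[-1] < 1e-8
        assert frob(ff.reconstruct_eri(thc) - eri) < 1e-4

    @pytest.mark.parametrize("seed", [0, 1])
    def test_objective_descent(self, rank3_hamiltonian, seed):
        thc = ff.thc_factorize(rank3_hamiltonian, rank=3, seed=seed,
                               max_iter=200)
        diffs = np.diff(thc.objective_trace)
        assert np.all(diffs <= 1e-9 * max(1.0, thc.objective_trace[0]))

    def test_warm_started_higher_rank_is_no_worse(self, rank3_hamiltonian):
        t4 = ff.thc_factorize(rank3_hamiltonian, rank=4, seed=3)
        t5 = ff.thc_factorize(rank3_hamiltonian, rank=5, seed=3,
                              init=(t4.chi, t4.zeta))
        assert t5.objective_trace[-1] <= t4.objective_trace[-1] + 1e-12

    def test_unit_norm_columns(self, rank3_hamiltonian):
        thc = ff.thc_factorize(rank3_hamiltonian, rank=3, seed=0, max_iter=100)
        np.testing.assert_allclose(np.linalg.norm(thc.chi, axis=0), 1.0,
                                   atol=1e-10)


class TestReconstruction:
    def test_all_branches_preserve_eightfold_symmetry(self, rank3_hamiltonian):
        sf = ff.single_factorize(rank3_hamiltonian, n_vectors=2)
        df = ff.double_factorize(sf, leaf_tol=1e-2)
        thc = ff.thc_factorize(rank3_hamiltonian, rank=2, seed=0, max_iter=50)
        for f in (sf, df, thc):
            e = ff.reconstruct_eri(f)
            for perm in ((1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)):
                np.testing.assert_allclose(e, e.transpose(perm), atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_error_non_increasing_in_rank(self, seed):
        h = ff.synthesize_hamiltonian(4, 5, seed=seed)
        errs = [frob(ff.reconstruct_eri(ff.single_factorize(h, n_vectors=k))
                     - h.eri) for k in range(1, 6)]
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))


class TestLambda:
    def test_one_body_only_limit(self):
        h = ff.ActiveSpaceHamiltonian(2, 1, 1, 0.0, np.diag([-1.0, -0.5]),
                                      np.zeros((2,) * 4))
        sf = ff.SingleFactorization(vectors=np.zeros((1, 2, 2)),
                                    eigenvalues=np.zeros(1))
        lam = ff.lambda_norm(h, sf)
        assert lam.lambda_two_body == 0.0
        assert abs(lam.lambda_total - 1.5) < 1e-12

    def test_sf_arithmetic_convention(self):
        h = ff.ActiveSpaceHamiltonian(2, 1, 1, 0.0, np.zeros((2, 2)),
                                      np.zeros((2,) * 4))
        sf = ff.SingleFactorization(vectors=np.ones((1, 2, 2)),
                                    eigenvalues=np.ones(1))
        lam = ff.lambda_norm(h, sf)
        # T' picks up the ERI-independent zero here, so lambda_2 = 16/4 = 4
        assert abs(lam.lambda_two_body - 4.0) < 1e-12

    def test_df_and_sf_agree_on_diagonal_leaves(self):
        # entrywise L1 squared == eigenvalue L1 squared only for diagonal leaves
        vecs = np.array([np.diag([0.9, -0.4, 0.2]), np.diag([0.5, 0.1, 0.0])])
        h = ff.ActiveSpaceHamiltonian(
            3, 1, 1, 0.0, np.zeros((3, 3)),
            np.einsum("lpq,lrs->pqrs", vecs, vecs))
        sf = ff.SingleFactorization(vectors=vecs, eigenvalues=np.ones(2))
        df = ff.double_factorize(sf, leaf_tol=0.0)
        l_sf = ff.lambda_norm(h, sf).lambda_two_body
        l_df = ff.lambda_norm(h, df).lambda_two_body
        assert abs(l_sf - l_df) < 1e-10

    @pytest.mark.parametrize("seed", range(4))
    def test_lambda_bounds_encoded_spectral_radius(self, seed):
        """lambda >= spectral radius of the block-encoded operator H - c I
        (c = the encoding's scalar offset) over every particle sector, for
        all three conventions — checked against the FCI oracle on
        <=4-orbital instances."""
        from fermifactor.factorization import encoding_shift
        n = 3 if seed % 2 else 4
        h = ff.synthesize_hamiltonian(n, 3, seed=seed)
        sf = ff.single_factorize(h, tol=1e-10)
        df = ff.double_factorize(sf, leaf_tol=0.0)
        thc = ff.thc_factorize(h, rank=2 * n, seed=seed, max_iter=200)
        for f in (sf, df, thc):
            henc = h.copy_with_eri(ff.reconstruct_eri(f))
            c = encoding_shift(henc, f)
            radius = 0.0
            for na in range(n + 1):
                for nb in range(na + 1):
                    e = ff.exact_spectrum(henc, na, nb).energies
                    radius = max(radius, abs(e[0] - c), abs(e[-1] - c))
            lam = ff.lambda_norm(henc, f)
            assert lam.lambda_total >= radius
            assert lam.lambda_one_body >= 0 and lam.lambda_two_body >= 0

    def test_effective_one_body_definition(self, small_hamiltonian):
        h = small_hamiltonian
        t = effective_one_body(h)
        expected = (h.h1 - 0.5 * np.einsum("prrq->pq", h.eri)
                    + np.einsum("pqrr->pq", h.eri))
        np.testing.assert_allclose(t, expected, atol=1e-14)


class TestSerialization:
    def test_hdf5_roundtrip_all_methods(self, tmp_path, rank3_hamiltonian):
        sf = ff.single_factorize(rank3_hamiltonian, tol=1e-10)
        df = ff.double_factorize(sf, leaf_tol=1e-8)
        thc = ff.thc_factorize(rank3_hamiltonian, rank=3, seed=0, max_iter=50)
        for name, f in (("sf", sf), ("df", df), ("thc", thc)):
            path = tmp_path / f"{name}.h5"
            ff.save_factorization(f, path)
            back = ff.load_factorization(path)
            np.testing.assert_allclose(ff.reconstruct_eri(back),
                                       ff.reconstruct_eri(f), atol=1e-12)
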