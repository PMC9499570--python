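"""Hamiltonian container, FCIDUMP round-tripping, synthesis, and the FCI oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fermifactor as ff
from fermifactor.errors import ArgumentError, FormatError


class TestFcidump:
    def test_roundtrip_identity(self, tmp_path, rank3_hamiltonian):
        path = tmp_path / "h.fcidump"
        ff.write_fcidump(rank3_hamiltonian, path)
        back = ff.read_fcidump(path)
        assert back.n_orb == rank3_hamiltonian.n_orb
        assert back.n_alpha == rank3_hamiltonian.n_alpha
        assert back.n_beta == rank3_hamiltonian.n_beta
        assert abs(back.e_core - rank3_hamiltonian.e_core) < 1e-12
        np.testing.assert_allclose(back.h1, rank3_hamiltonian.h1, atol=1e-12)
        np.testing.assert_allclose(back.eri, rank3_hamiltonian.eri, atol=1e-12)

    def test_minimal_file(self, tmp_path):
        path = tmp_path / "min.fcidump"
        path.write_text("&FCI NORB=2,NELEC=2,MS2=0,\n&END\n0.7 1 1 1 1\n")
        h = ff.read_fcidump(path)
        assert h.eri[0, 0, 0, 0] == 0.7
        assert np.count_nonzero(h.eri) == 1
        assert np.count_nonzero(h.h1) == 0

    def test_symmetry_completion(self, tmp_path):
        path = tmp_path / "sym.fcidump"
        path.write_text("&FCI NORB=2,NELEC=2,MS2=0,\n&END\n0.3 1 2 1 1\n")
        h = ff.read_fcidump(path)
        # (12|11) populates (21|11), (11|12), (11|21) as well
        for idx in [(0, 1, 0, 0), (1, 0, 0, 0), (0, 0, 0, 1), (0, 0, 1, 0)]:
            assert h.eri[idx] == 0.3

    def test_zero_hamiltonian_writes_core_line_only(self, tmp_path):
        h = ff.ActiveSpaceHamiltonian(2, 1, 1, 1.5, np.zeros((2, 2)),
                                      np.zeros((2,) * 4))
        path = tmp_path / "zero.fcidump"
        ff.write_fcidump(h, path)
        integral_lines = [l for l in path.read_text().splitlines()
                          if l and not l.lstrip().startswith("&")
                          and "=" not in l]
        assert len(integral_lines) == 1
        assert integral_lines[0].split()[1:] == ["0"] * 4

    def test_writes_are_byte_identical(self, tmp_path, rank3_hamiltonian):
        p1, p2 = tmp_path / "a", tmp_path / "b"
        ff.write_fcidump(rank3_hamiltonian, p1)
        ff.write_fcidump(rank3_hamiltonian, p2)
        assert p1.read_bytes() == p2.read_bytes()

    @pytest.mark.parametrize("body, header", [
        ("0.1 1 1 1 1", "&FCI NELEC=2,MS2=0,\n&END"),   # missing NORB
        ("0.1 9 1 1 1", "&FCI NORB=2,NELEC=2,MS2=0,\n&END"),  # out of range
        ("0.1 1 1 1", "&FCI NORB=2,NELEC=2,MS2=0,\n&END"),    # short line
        ("0.1 1 1 1 1\n0.2 1 1 1 1",
         "&FCI NORB=2,NELEC=2,MS2=0,\n&END"),           # contradictory dup
    ])
    def test_malformed_files_raise(self, tmp_path, body, header):
        path = tmp_path / "bad.fcidump"
        path.write_text(header + "\n" + body + "\n")
        with pytest.raises(FormatError):
            ff.read_fcidump(path)


class TestSynthesize:
    def test_seeded_determinism(self):
        a = ff.synthesize_hamiltonian(4, 3, seed=7)
        b = ff.synthesize_hamiltonian(4, 3, seed=7)
        np.testing.assert_array_equal(a.eri, b.eri)
        np.testing.assert_array_equal(a.h1, b.h1)

    def test_supermatrix_rank_bounded_by_requested(self, rank3_hamiltonian):
        w = np.linalg.eigvalsh(rank3_hamiltonian.v_matrix())
        assert np.sum(w > 1e-10) <= 3

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(n_orb=st.integers(1, 6), rank=st.integers(1, 8),
           seed=st.integers(0, 2**31 - 1))
    def test_invariants_always_hold(self, n_orb, rank, seed):
        ff.synthesize_hamiltonian(n_orb, rank, seed=seed).validate()

    def test_rejects_bad_dimensions(self):
        with pytest.raises(ArgumentError):
            ff.synthesize_hamiltonian(0, 1, seed=0)
        with pytest.raises(ArgumentError):
            ff.synthesize_hamiltonian(2, 0, seed=0)


class TestExactSpectrum:
    def test_single_orbital_hubbard_atom(self):
        # one orbital, h1 = [[-t]], (11|11) = U: sector (1,1) energy -2t + U
        t, u = 0.7, 1.3
        eri = np.full((1, 1, 1, 1), u)
        h = ff.ActiveSpaceHamiltonian(1, 1, 1, 0.0, np.array([[-t]]), eri)
        res = ff.exact_spectrum(h, 1, 1)
        assert res.energies.shape == (1,)
        assert abs(res.energies[0] - (-2 * t + u)) < 1e-12

    def test_noninteracting_limit_is_orbital_sums(self):
        rng = np.random.default_rng(3)
        n = 4
        h1 = rng.normal(size=(n, n))
        h1 = 0.5 * (h1 + h1.T)
        h = ff.ActiveSpaceHamiltonian(n, 2, 1, 0.0, h1, np.zeros((n,) * 4))
        eps = np.linalg.eigvalsh(h1)
        expected = sorted(
            sum(eps[list(a)]) + sum(eps[list(b)])
            for a in itertools.combinations(range(n), 2)
            for b in itertools.combinations(range(n), 1)
        )
        np.testing.assert_allclose(ff.exact_spectrum(h, 2, 1).energies,
                                   expected, atol=1e-10)

    def test_matches_independent_fock_space_build(self, small_hamiltonian):
        """Dense Jordan-Wigner construction of the full 64x64 Fock-space
        Hamiltonian, sector-restricted, as an independent oracle."""
        h = small_hamiltonian
        n = h.n_orb
        iden, z = np.eye(2), np.diag([1.0, -1.0])
        lower = np.array([[0.0, 1.0], [0.0, 0.0]])

        def site_op(mat, site):
            out = np.array([[1.0]])
            for i in range(2 * n):
                out = np.kron(out, mat if i == site else (z if i < site else iden))
            return out

        a = [site_op(lower, i) for i in range(2 * n)]
        ad = [m.T for m in a]
        dim = 4**n
        ham = np.zeros((dim, dim))
        for p in range(n):
            for q in range(n):
                for s in (0, 1):
                    ham += h.h1[p, q] * ad[p + s * n] @ a[q + s * n]
        for p, q, r, s_ in itertools.product(range(n), repeat=4):
            for s1, s2 in itertools.product((0, 1), repeat=2):
                ham += (0.5 * h.eri[p, q, r, s_]
                        * ad[p + s1 * n] @ ad[r + s2 * n]
                        @ a[s_ + s2 * n] @ a[q + s1 * n])
        na = np.diag(sum(ad[i] @ a[i] for i in range(n)))
        nb = np.diag(sum(ad[i] @ a[i] for i in range(n, 2 * n)))
        mask = (np.abs(na - 2) < 1e-9) & (np.abs(nb - 1) < 1e-9)
        ref = np.linalg.eigvalsh(ham[np.ix_(mask, mask)])
        np.testing.assert_allclose(ff.exact_spectrum(h, 2, 1).energies,
                                   np.sort(ref), atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_invariant_under_orbital_rotation(self, seed):
        h = ff.synthesize_hamiltonian(3, 2, seed=seed)
        rng = np.random.default_rng(seed + 50)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        hrot = h.rotated(q)
        for sector in [(1, 1), (2, 1), (3, 2)]:
            np.testing.assert_allclose(
                ff.exact_spectrum(h, *sector).energies,
                ff.exact_spectrum(hrot, *sector).energies, atol=1e-8)

    def test_refuses_large_systems(self):
        h = ff.synthesize_hamiltonian(9, 2, seed=0)
        with pytest.raises(ArgumentError):
            ff.exact_spectrum(h, 4, 4)
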