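import numpy as np
import pytest

import fermifactor as ff


@pytest.fixture(scope="session")
def small_hamiltonian():
    """3-orbital rank-2 synthetic Hamiltonian used across modules."""
    h = ff.synthesize_hamiltonian(3, 2, seed=5)
    h.validate()
    return h


@pytest.fixture(scope="session")
def rank3_hamiltonian():
    """4-orbital Hamiltonian whose ERI supermatrix has Cholesky rank exactly 3."""
    h = ff.synthesize_hamiltonian(4, 3, seed=7)
    h.validate()
    return h


@pytest.fixture(scope="session")
def brillouin_hamiltonian():
    """2-orbital closed-shell fixture with a diagonal Fock matrix, so the
    second-order perturbation energy is pure doubles (no singles mixing).

    Occupied orbital 0, virtual orbital 1; orbital energies -0.4 and 0.35;
    the only coupling integral is (12|12) = 0.15, giving the closed form
    E_MP2 = 0.15^2 * (2 - 1) * 0.15 / (2 * (-0.4 - 0.35)) ... = -0.015 Ha.
    """
    n = 2
    eri = np.zeros((n,) * 4)

    def put(i, j, k, l, v):
        for (a, b) in ((i, j), (j, i)):
            for (c, d) in ((k, l), (l, k)):
                eri[a, b, c, d] = v
                eri[c, d, a, b] = v

    put(0, 0, 0, 0, 0.6)
    put(1, 1, 1, 1, 0.7)
    put(0, 0, 1, 1, 0.4)
    put(0, 1, 0, 1, 0.15)
    h1 = np.diag([-1.0, -0.3])
    h = ff.ActiveSpaceHamiltonian(n, 1, 1, 0.0, h1, eri)
    h.validate(psd_tol=10.0)  # PSD not required for this analytic fixture
    return h


@pytest.fixture(scope="session")
def scaling_family():
    """Logical-resource points for N in {6..14} at fixed filling.

    SF retains the full Cholesky rank (min(6N, N(N+1)/2) by construction), DF
    keeps full leaves, THC uses the generic rank M = round(4.7 N). Returns
    {"SF"|"DF"|"THC": {"toffoli": [(N, total)], "qubits": [(N, Q)]}}.
    """
    budget = ff.PrecisionBudget()
    out = {m: {"toffoli": [], "qubits": []} for m in ("SF", "DF", "THC")}
    for n in (6, 8, 10, 12, 14):
        rank = min(6 * n, n * (n + 1) // 2)
        h = ff.synthesize_hamiltonian(n, rank, seed=100 + n)
        sf = ff.single_factorize(h, tol=1e-8)
        df = ff.double_factorize(sf, leaf_tol=1e-8)
        thc = ff.thc_factorize(h, rank=round(4.7 * n), seed=n,
                               max_iter=300, cp_sweeps=50)
        for name, f in (("SF", sf), ("DF", df), ("THC", thc)):
            r = ff.estimate_resources(h, f, budget=budget)
            out[name]["toffoli"].append((n, r.toffoli_total))
            out[name]["qubits"].append((n, r.logical_qubits))
    return out
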