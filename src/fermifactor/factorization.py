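"""Tensor factorizations of the two-electron integrals and qubitization L1 norms.

Three compressed representations of the chemist-notation ERI tensor are
supported:

* single factorization (SF): ``(pq|rs) = sum_l L(l)_pq L(l)_rs`` with symmetric
  N x N factors obtained from the eigendecomposition (or pivoted Cholesky) of
  the N^2 x N^2 ERI supermatrix;
* double factorization (DF): each SF leaf additionally eigendecomposed,
  ``L(l) = U(l) diag(f(l, m)) U(l)^T``, with small eigenvalues dropped;
* tensor hypercontraction (THC): ``(pq|rs) ~= sum_{mu nu} chi_p^mu chi_q^mu
  zeta_{mu nu} chi_r^nu chi_s^nu`` with an N x M collocation matrix chi and a
  symmetric M x M core zeta, fitted by symmetric CP initialization followed by
  gradient-based refinement.

Each representation carries a qubitization L1 norm ("lambda"): the walk-based
phase-estimation iteration count is proportional to lambda, so compressions
that shrink lambda directly shrink runtime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from .errors import ArgumentError, DataError, NumericalError
from .hamiltonian import ActiveSpaceHamiltonian

__all__ = [
    "SingleFactorization",
    "DoubleFactorization",
    "THCFactorization",
    "LambdaReport",
    "single_factorize",
    "double_factorize",
    "thc_factorize",
    "reconstruct_eri",
    "lambda_norm",
    "effective_one_body",
    "save_factorization",
    "load_factorization",
]


@dataclass
class SingleFactorization:
    """Cholesky-style factorization: eri = sum_l vectors[l] (x) vectors[l]."""

    vectors: np.ndarray  # (L, N, N), each symmetric, Hartree^{1/2}
    eigenvalues: np.ndarray  # (L,) supermatrix weights, descending

    @property
    def n_vectors(self) -> int:
        return len(self.vectors)

    @property
    def n_orb(self) -> int:
        return self.vectors.shape[1]

    @property
    def gamma(self) -> int:
        """Stored-coefficient count: L unique-pair matrices."""
        n = self.n_orb
        return self.n_vectors * (n * (n + 1) // 2)


@dataclass
class DoubleFactorization:
    """Eigendecomposed SF leaves with per-leaf rank truncation."""

    leaf_eigenvalues: list  # f(l, m), each a 1-D array of retained eigenvalues
    leaf_vectors: list  # U(l), (N, Xi_l) orthonormal columns

    @property
    def leaf_ranks(self) -> list[int]:
        return [len(f) for f in self.leaf_eigenvalues]

    @property
    def avg_rank(self) -> float:
        ranks = self.leaf_ranks
        return float(np.mean(ranks)) if ranks else 0.0

    @property
    def n_orb(self) -> int:
        return self.leaf_vectors[0].shape[0]

    @property
    def gamma(self) -> int:
        """Eigenvalues plus rotation-column entries across all leaves."""
        n = self.n_orb
        return int(sum(xi + n * xi for xi in self.leaf_ranks))


@dataclass
class THCFactorization:
    """Tensor hypercontraction factors; chi columns unit-normalized."""

    chi: np.ndarray  # (N, M)
    zeta: np.ndarray  # (M, M) symmetric, Hartree
    objective_trace: np.ndarray = field(default_factory=lambda: np.zeros(0))
    seed: int | None = None

    @property
    def rank(self) -> int:
        return self.chi.shape[1]

    @property
    def n_orb(self) -> int:
        return self.chi.shape[0]

    @property
    def gamma(self) -> int:
        m, n = self.rank, self.n_orb
        return m * (m + 1) // 2 + n * m


@dataclass
class LambdaReport:
    """L1 norm of the Hamiltonian coefficients in a factorized encoding."""

    method: str  # "SF" | "DF" | "THC"
    lambda_one_body: float
    lambda_two_body: float

    @property
    def lambda_total(self) -> float:
        return self.lambda_one_body + self.lambda_two_body


# ---------------------------------------------------------------------------
# Single factorization
# ---------------------------------------------------------------------------

def single_factorize(
    h: ActiveSpaceHamiltonian,
    tol: float | None = None,
    n_vectors: int | None = None,
    method: str = "eig",
    psd_tol: float = 1e-8,
) -> SingleFactorization:
    """Factor the ERI supermatrix into symmetric rank-one terms.

    Exactly one of ``tol`` (Frobenius reconstruction threshold) or
    ``n_vectors`` must be given. Vectors are ordered by decreasing supermatrix
    eigenvalue; with ``tol`` the minimal prefix whose dropped-weight Frobenius
    error is <= tol is retained.

    ``method="eig"`` (default, deterministic ordering) eigendecomposes the
    supermatrix; ``method="cholesky"`` uses pivoted Cholesky (LAPACK pstrf).
    """
    if (tol is None) == (n_vectors is None):
        raise ArgumentError("give exactly one of tol / n_vectors")
    n = h.n_orb
    v = 0.5 * (h.v_matrix() + h.v_matrix().T)
    if method == "cholesky":
        c, piv, rank, _ = scipy.linalg.lapack.dpstrf(v, lower=1)
        perm = np.argsort(piv - 1)
        low = np.tril(c)[:, :rank][perm]
        vecs = [0.5 * (m + m.T) for m in low.T.reshape(rank, n, n)]
        weights = np.array([np.sum(m * m) for m in vecs])
    else:
        w, u = np.linalg.eigh(v)
        if w.min() < -psd_tol:
            raise DataError(f"ERI supermatrix not PSD (min eig {w.min():.3e})")
        order = np.argsort(w)[::-1]
        w, u = np.clip(w[order], 0.0, None), u[:, order]
        vecs = [np.sqrt(wi) * 0.5 * (ui.reshape(n, n) + ui.reshape(n, n).T)
                for wi, ui in zip(w, u.T)]
        weights = w

    if n_vectors is not None:
        if not 1 <= n_vectors <= len(vecs):
            raise ArgumentError(f"n_vectors must be in [1, {len(vecs)}]")
        keep = n_vectors
    else:
        # Frobenius error of a k-term truncation is sqrt(sum of squared
        # dropped weights) by orthogonality of the eigenvectors.
        tail = np.sqrt(np.cumsum((weights**2)[::-1])[::-1])
        keep = len(vecs)
        for k in range(len(vecs) + 1):
            err = tail[k] if k < len(vecs) else 0.0
            if err <= tol:
                keep = max(k, 1)
                break
    return SingleFactorization(
        vectors=np.array(vecs[:keep]), eigenvalues=np.asarray(weights[:keep]),
    )


def double_factorize(
    sf: SingleFactorization, leaf_tol: float = 0.0
) -> DoubleFactorization:
    """Eigendecompose each SF leaf, dropping eigenpairs with ``|f| < leaf_tol``."""
    leaf_f, leaf_u = [], []
    for mat in sf.vectors:
        f, u = np.linalg.eigh(mat)
        order = np.argsort(np.abs(f))[::-1]
        f, u = f[order], u[:, order]
        keep = np.abs(f) >= leaf_tol if leaf_tol > 0 else np.ones(len(f), bool)
        leaf_f.append(f[keep])
        leaf_u.append(u[:, keep])
    return DoubleFactorization(leaf_eigenvalues=leaf_f, leaf_vectors=leaf_u)


# ---------------------------------------------------------------------------
# THC
# ---------------------------------------------------------------------------

def _thc_tensor(chi: np.ndarray, zeta: np.ndarray) -> np.ndarray:
    pq = np.einsum("pm,qm->pqm", chi, chi)
    return np.einsum("pqm,mn,rsn->pqrs", pq, zeta, pq, optimize=True)


def _cp_als_init(
    sf: SingleFactorization, rank: int, rng: np.random.Generator,
    sweeps: int = 500, rtol: float = 1e-8,
):
    """Symmetric CP decomposition of the stacked Cholesky vectors B[l,p,q].

    Alternating least squares over the three factor matrices (A over the leaf
    index, X and Y over the orbital indices), with the orbital factors tied by
    averaging each sweep. Returns (chi, zeta) with zeta = A^T A.
    """
    b = np.asarray(sf.vectors)  # (L, N, N)
    L, n, _ = b.shape
    x = rng.normal(size=(n, rank))
    y = x.copy()
    a = rng.normal(size=(L, rank))
    bmat = b.reshape(L, n * n)
    prev = np.inf
    for _ in range(sweeps):
        # A update: b[l,pq] ~= A[l,:] @ khatri-rao(X,Y)[pq,:]^T
        kr = np.einsum("pm,qm->pqm", x, y).reshape(n * n, rank)
        a = np.linalg.lstsq(kr, bmat.T, rcond=None)[0].T
        # X update: b[p, (l q)] ~= X @ KR(A, Y)^T
        kr = np.einsum("lm,qm->lqm", a, y).reshape(L * n, rank)
        x = np.linalg.lstsq(kr, b.transpose(1, 0, 2).reshape(n, L * n).T,
                            rcond=None)[0].T
        kr = np.einsum("lm,pm->lpm", a, x).reshape(L * n, rank)
        y = np.linalg.lstsq(kr, b.transpose(2, 0, 1).reshape(n, L * n).T,
                            rcond=None)[0].T
        x = y = 0.5 * (x + y)
        approx = np.einsum("lm,pm,qm->lpq", a, x, y, optimize=True)
        obj = float(np.sum((approx - b) ** 2))
        if not np.isfinite(obj):
            raise NumericalError("CP-ALS objective is not finite")
        if prev - obj <= rtol * max(prev, 1.0):
            break
        prev = obj
    zeta = a.T @ a
    return x, 0.5 * (zeta + zeta.T)


def thc_factorize(
    h: ActiveSpaceHamiltonian,
    rank: int,
    reg_strength: float = 0.0,
    seed: int = 0,
    max_iter: int = 10_000,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    cp_sweeps: int = 500,
) -> THCFactorization:
    """Fit THC factors to ``h.eri`` at the given rank.

    Initialization is a symmetric CP decomposition of the Cholesky vectors
    (seeded ALS); refinement minimizes

        || eri - THC(chi, zeta) ||_F^2 + reg_strength * sum |zeta|

    with L-BFGS and analytic gradients (the L1 term is smoothed with a 1e-8
    Huber width when active). ``init=(chi, zeta)`` warm-starts refinement,
    e.g. from a lower-rank solution padded with an extra column. The recorded
    ``objective_trace`` is non-increasing. Deterministic in ``seed``.
    """
    if rank < 1:
        raise ArgumentError("rank must be >= 1")
    eri = h.eri
    n = h.n_orb
    if init is not None:
        chi0, zeta0 = (np.array(x, dtype=float) for x in init)
        if chi0.shape[1] < rank:  # pad warm start with small random columns
            rng = np.random.default_rng(seed)
            extra = rank - chi0.shape[1]
            chi0 = np.hstack([chi0, 1e-3 * rng.normal(size=(n, extra))])
            z = np.zeros((rank, rank))
            z[: zeta0.shape[0], : zeta0.shape[1]] = zeta0
            zeta0 = z
    else:
        rng = np.random.default_rng(seed)
        sf = single_factorize(h, tol=1e-10)
        chi0, zeta0 = _cp_als_init(sf, rank, rng, sweeps=cp_sweeps)

    eps = 1e-8  # Huber smoothing width for the L1 penalty
    tri = np.triu_indices(rank)

    def unpack(x):
        chi = x[: n * rank].reshape(n, rank)
        zeta = np.zeros((rank, rank))
        zeta[tri] = x[n * rank:]
        zeta = zeta + np.triu(zeta, 1).T
        return chi, zeta

    def pack(chi, zeta):
        return np.concatenate([chi.ravel(), zeta[tri]])

    def objective(x):
        chi, zeta = unpack(x)
        diff = _thc_tensor(chi, zeta) - eri
        f = float(np.sum(diff * diff))
        pq = np.einsum("pm,qm->pqm", chi, chi)
        gz = 2.0 * np.einsum("pqrs,pqm,rsn->mn", diff, pq, pq, optimize=True)
        gz = 0.5 * (gz + gz.T)
        k = np.einsum("mn,rn,sn->mrs", zeta, chi, chi, optimize=True)
        gchi = 8.0 * np.einsum("pqrs,qm,mrs->pm", diff, chi, k, optimize=True)
        if reg_strength > 0.0:
            az = np.sqrt(zeta * zeta + eps * eps)
            f += reg_strength * float(np.sum(az))
            gz = gz + reg_strength * zeta / az
        gzv = gz[tri] * np.where(tri[0] == tri[1], 1.0, 2.0)
        return f, np.concatenate([gchi.ravel(), gzv])

    trace = [objective(pack(chi0, zeta0))[0]]

    def callback(xk):
        trace.append(objective(xk)[0])

    res = scipy.optimize.minimize(
        objective, pack(chi0, zeta0), jac=True, method="L-BFGS-B",
        callback=callback,
        options={"maxiter": max_iter, "maxfun": max_iter, "ftol": 1e-14,
                 "gtol": 1e-12},
    )
    if not np.isfinite(res.fun):
        raise NumericalError(f"THC refinement diverged: {res.message}")
    chi, zeta = unpack(res.x)
    # L-BFGS-B line searches enforce descent, so the callback trace is
    # already non-increasing; the final iterate is appended if it improves.
    final = float(objective(res.x)[0])
    if final <= trace[-1]:
        trace.append(final)
    trace = np.asarray(trace)
    # normalize: unit-norm chi columns, scale absorbed into zeta
    norms = np.linalg.norm(chi, axis=0)
    norms[norms == 0] = 1.0
    chi = chi / norms
    zeta = zeta * np.outer(norms**2, norms**2)
    return THCFactorization(
        chi=chi, zeta=0.5 * (zeta + zeta.T), objective_trace=trace, seed=seed,
    )


# ---------------------------------------------------------------------------
# Reconstruction & lambda
# ---------------------------------------------------------------------------

def reconstruct_eri(f) -> np.ndarray:
    """Expand a factorization back to the dense chemist-notation ERI tensor."""
    if isinstance(f, SingleFactorization):
        return np.einsum("lpq,lrs->pqrs", f.vectors, f.vectors, optimize=True)
    if isinstance(f, DoubleFactorization):
        leaves = [u @ np.diag(fv) @ u.T
                  for fv, u in zip(f.leaf_eigenvalues, f.leaf_vectors)]
        leaves = np.array(leaves)
        return np.einsum("lpq,lrs->pqrs", leaves, leaves, optimize=True)
    if isinstance(f, THCFactorization):
        return _thc_tensor(f.chi, f.zeta)
    raise ArgumentError(f"unknown factorization type {type(f)!r}")


def effective_one_body(h: ActiveSpaceHamiltonian) -> np.ndarray:
    """One-body matrix absorbing the reordering terms of the qubitized encoding:

        T'_pq = h1_pq - 1/2 sum_r (pr|rq) + sum_r (pq|rr).
    """
    return (h.h1
            - 0.5 * np.einsum("prrq->pq", h.eri)
            + np.einsum("pqrr->pq", h.eri))


def encoding_shift(h: ActiveSpaceHamiltonian, f) -> float:
    """Scalar (identity) component stripped out by the qubitized encoding.

    The walk operator block-encodes H - c*I (core energy excluded). Three
    scalar pieces accumulate in c: the one-body identity component Tr(T');
    the -1/2 sum of squared factor traces released when each number-like
    factor A_l is centred to B_l = A_l - Tr(L_l); and, for the squared
    (SF/DF) constructions, a per-leaf midpoint +lambda_l^2 / 4 — each
    B_l^2 lies in [0, lambda_l^2], so the encoding represents
    B_l^2 - lambda_l^2 / 2 whose norm is half as large, which is exactly
    what makes the 1/4 prefactor of the SF/DF two-body lambda a rigorous
    block-encoding normalization:

    * SF:  c = Tr(T') - 1/2 sum_l Tr(L_l)^2 + 1/4 sum_l (sum_pq |L_pq|)^2
    * DF:  same with traces/L1s over the retained leaf eigenvalues f(l, m)
    * THC: c = Tr(T') - 1/2 sum_{mu nu} zeta_{mu nu}  (unit-norm chi columns
      give unit-trace collocation matrices; the zeta cross products are not
      sign-definite, so no midpoint term arises)

    lambda_norm upper-bounds the spectral norm of H - c*I, not of H itself.
    """
    t = effective_one_body(h)
    c = float(np.trace(t))
    if isinstance(f, SingleFactorization):
        c -= 0.5 * float(sum(np.trace(v) ** 2 for v in f.vectors))
        c += 0.25 * float(sum(np.sum(np.abs(v)) ** 2 for v in f.vectors))
    elif isinstance(f, DoubleFactorization):
        c -= 0.5 * float(sum(np.sum(fv) ** 2 for fv in f.leaf_eigenvalues))
        c += 0.25 * float(sum(np.sum(np.abs(fv)) ** 2
                              for fv in f.leaf_eigenvalues))
    elif isinstance(f, THCFactorization):
        norms = np.linalg.norm(f.chi, axis=0)
        zeta = f.zeta * np.outer(norms**2, norms**2)
        c -= 0.5 * float(np.sum(zeta))
    else:
        raise ArgumentError(f"unknown factorization type {type(f)!r}")
    return c


def lambda_norm(h: ActiveSpaceHamiltonian, f) -> LambdaReport:
    """Qubitization L1 norm of (h, factorization).

    One-body part: sum of |eigenvalues| of the effective one-body matrix T'.
    Two-body part, per representation:

    * SF:  1/4 sum_l (sum_pq |L(l)_pq|)^2
    * DF:  1/4 sum_l (sum_m |f(l, m)|)^2
    * THC: 1/2 sum_{mu nu} |zeta_{mu nu}|  (chi columns unit-norm)
    """
    t = effective_one_body(h)
    if t.shape[0] != getattr(f, "n_orb", t.shape[0]):
        raise ArgumentError("factorization dimension does not match Hamiltonian")
    lam1 = float(np.sum(np.abs(np.linalg.eigvalsh(t))))
    if isinstance(f, SingleFactorization):
        method = "SF"
        lam2 = 0.25 * float(sum(np.sum(np.abs(v)) ** 2 for v in f.vectors))
    elif isinstance(f, DoubleFactorization):
        method = "DF"
        lam2 = 0.25 * float(sum(np.sum(np.abs(fv)) ** 2
                                for fv in f.leaf_eigenvalues))
    elif isinstance(f, THCFactorization):
        method = "THC"
        norms = np.linalg.norm(f.chi, axis=0)
        zeta = f.zeta * np.outer(norms**2, norms**2) if not np.allclose(
            norms, 1.0, atol=1e-8) else f.zeta
        lam2 = 0.5 * float(np.sum(np.abs(zeta)))
    else:
        raise ArgumentError(f"unknown factorization type {type(f)!r}")
    return LambdaReport(method=method, lambda_one_body=lam1, lambda_two_body=lam2)


# ---------------------------------------------------------------------------
# HDF5 serialization (layout version 1)
# ---------------------------------------------------------------------------

_H5_VERSION = 1


def save_factorization(f, path) -> None:
    """Serialize a factorization to an HDF5 container.

    Layout (version 1): attribute ``method`` in {SF, DF, THC}; SF stores
    ``vectors``/``eigenvalues``; DF stores per-leaf ``leaf_{i}/eigenvalues``
    and ``leaf_{i}/vectors``; THC stores ``chi``/``zeta``/``objective_trace``
    plus the fit ``seed``.
    """
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["layout_version"] = _H5_VERSION
        if isinstance(f, SingleFactorization):
            fh.attrs["method"] = "SF"
            fh["vectors"] = f.vectors
            fh["eigenvalues"] = f.eigenvalues
        elif isinstance(f, DoubleFactorization):
            fh.attrs["method"] = "DF"
            fh.attrs["n_leaves"] = len(f.leaf_eigenvalues)
            for i, (fv, u) in enumerate(zip(f.leaf_eigenvalues, f.leaf_vectors)):
                g = fh.create_group(f"leaf_{i}")
                g["eigenvalues"] = fv
                g["vectors"] = u
        elif isinstance(f, THCFactorization):
            fh.attrs["method"] = "THC"
            fh["chi"] = f.chi
            fh["zeta"] = f.zeta
            fh["objective_trace"] = f.objective_trace
            if f.seed is not None:
                fh.attrs["seed"] = f.seed
        else:
            raise ArgumentError(f"unknown factorization type {type(f)!r}")


def load_factorization(path):
    """Inverse of :func:`save_factorization`."""
    import h5py

    with h5py.File(path, "r") as fh:
        method = fh.attrs["method"]
        if method == "SF":
            return SingleFactorization(
                vectors=fh["vectors"][...], eigenvalues=fh["eigenvalues"][...])
        if method == "DF":
            nl = int(fh.attrs["n_leaves"])
            return DoubleFactorization(
                leaf_eigenvalues=[fh[f"leaf_{i}/eigenvalues"][...]
                                  for i in range(nl)],
                leaf_vectors=[fh[f"leaf_{i}/vectors"][...] for i in range(nl)],
            )
        if method == "THC":
            return THCFactorization(
                chi=fh["chi"][...], zeta=fh["zeta"][...],
                objective_trace=fh["objective_trace"][...],
                seed=int(fh.attrs["seed"]) if "seed" in fh.attrs else None,
            )
    raise DataError(f"{path}: unknown factorization method {method!r}")
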