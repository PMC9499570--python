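"""Active-space Hamiltonian container, FCIDUMP I/O, synthetic generation, and a
small full-configuration-interaction (FCI) oracle.

The container holds the one-body integrals ``h1`` and the two-electron
repulsion integrals (ERIs) ``eri`` in chemist notation ``(pq|rs)`` over real
spatial orbitals, so the ERI tensor carries the 8-fold permutational symmetry

    (pq|rs) = (qp|rs) = (pq|sr) = (rs|pq).

All energies are in Hartree and orbital indices are 0-based internally;
FCIDUMP files use the format's 1-based convention.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError, DataError, FormatError

__all__ = [
    "ActiveSpaceHamiltonian",
    "SpectrumResult",
    "read_fcidump",
    "write_fcidump",
    "synthesize_hamiltonian",
    "exact_spectrum",
]

_SYM_TOL = 1e-12
_PSD_TOL = 1e-10


@dataclass
class ActiveSpaceHamiltonian:
    """Second-quantized Hamiltonian restricted to an active space.

    H = e_core + sum_pq h1[p,q] E_pq + 1/2 sum_pqrs (pq|rs) (E_pq E_rs - d_qr E_ps)

    with ``E_pq`` the spin-summed excitation operator.

    Attributes
    ----------
    n_orb : int
        Number of spatial orbitals N.
    n_alpha, n_beta : int
        Electron counts per spin channel.
    multiplicity : int
        Spin multiplicity 2S+1 of the target state (metadata only).
    e_core : float
        Scalar energy offset (frozen core + nuclear repulsion), Hartree.
    h1 : (N, N) ndarray
        Symmetric one-body integrals, Hartree.
    eri : (N, N, N, N) ndarray
        Chemist-notation two-electron integrals, Hartree.
    """

    n_orb: int
    n_alpha: int
    n_beta: int
    e_core: float
    h1: np.ndarray
    eri: np.ndarray
    multiplicity: int = field(default=1)

    def __post_init__(self):
        self.h1 = np.asarray(self.h1, dtype=float)
        self.eri = np.asarray(self.eri, dtype=float)
        if self.h1.shape != (self.n_orb, self.n_orb):
            raise ArgumentError(f"h1 shape {self.h1.shape} != ({self.n_orb},)*2")
        if self.eri.shape != (self.n_orb,) * 4:
            raise ArgumentError(f"eri shape {self.eri.shape} != ({self.n_orb},)*4")
        if not (0 <= self.n_alpha <= self.n_orb and 0 <= self.n_beta <= self.n_orb):
            raise ArgumentError("electron counts must lie in [0, n_orb]")

    def validate(self, psd_tol: float = _PSD_TOL) -> None:
        """Check symmetry and positive-semidefiniteness invariants.

        Raises :class:`DataError` on violation.
        """
        if not np.allclose(self.h1, self.h1.T, atol=_SYM_TOL, rtol=0.0):
            raise DataError("h1 is not symmetric")
        e = self.eri
        for perm in ((1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)):
            if not np.allclose(e, e.transpose(perm), atol=_SYM_TOL, rtol=0.0):
                raise DataError(f"eri violates 8-fold symmetry (perm {perm})")
        w = np.linalg.eigvalsh(self.v_matrix())
        if w.min() < -psd_tol:
            raise DataError(f"ERI supermatrix not PSD: min eigenvalue {w.min():.3e}")

    def v_matrix(self) -> np.ndarray:
        """Return the N^2 x N^2 ERI supermatrix V[(pq),(rs)] = (pq|rs)."""
        n2 = self.n_orb * self.n_orb
        return self.eri.reshape(n2, n2)

    @property
    def n_elec(self) -> int:
        return self.n_alpha + self.n_beta

    def copy_with_eri(self, eri: np.ndarray) -> "ActiveSpaceHamiltonian":
        """Same Hamiltonian with a replacement ERI tensor (e.g. reconstructed)."""
        return ActiveSpaceHamiltonian(
            n_orb=self.n_orb,
            n_alpha=self.n_alpha,
            n_beta=self.n_beta,
            e_core=self.e_core,
            h1=self.h1.copy(),
            eri=np.asarray(eri, dtype=float),
            multiplicity=self.multiplicity,
        )

    def rotated(self, u: np.ndarray) -> "ActiveSpaceHamiltonian":
        """Apply an orthogonal orbital rotation ``u`` (columns = new orbitals)."""
        h1 = u.T @ self.h1 @ u
        eri = np.einsum("pqrs,pi,qj,rk,sl->ijkl", self.eri, u, u, u, u, optimize=True)
        return ActiveSpaceHamiltonian(
            self.n_orb, self.n_alpha, self.n_beta, self.e_core, h1, eri,
            multiplicity=self.multiplicity,
        )


@dataclass
class SpectrumResult:
    """Eigenvalues of the Hamiltonian in one (n_alpha, n_beta) particle sector."""

    sector: tuple[int, int]
    energies: np.ndarray  # ascending, Hartree; excludes e_core unless requested


# ---------------------------------------------------------------------------
# FCIDUMP I/O
# ---------------------------------------------------------------------------

def _fill_eri(eri: np.ndarray, p: int, q: int, r: int, s: int, val: float) -> None:
    for (a, b, c, d) in {
        (p, q, r, s), (q, p, r, s), (p, q, s, r), (q, p, s, r),
        (r, s, p, q), (s, r, p, q), (r, s, q, p), (s, r, q, p),
    }:
        eri[a, b, c, d] = val


def read_fcidump(path) -> ActiveSpaceHamiltonian:
    """Parse an FCIDUMP file into an :class:`ActiveSpaceHamiltonian`.

    The header is a Fortran-namelist-style block ``&FCI NORB=..., NELEC=...,
    MS2=..., ... &END`` (or terminated by ``/``); integral lines are
    ``value i j k l`` with 1-based indices, chemist notation, ``(i j 0 0)``
    one-body entries and the ``(0 0 0 0)`` core energy. ORBSYM is read but
    ignored (all orbitals treated as symmetry-equivalent). Complex values are
    rejected: only real orbitals are supported.
    """
    with open(path) as fh:
        text = fh.read()

    m = re.search(r"&FCI(.*?)(?:&END|/)", text, flags=re.S | re.I)
    if m is None:
        raise FormatError(f"{path}: missing &FCI header")
    header = m.group(1)

    def header_int(name):
        hm = re.search(rf"{name}\s*=\s*(-?\d+)", header, flags=re.I)
        if hm is None:
            raise FormatError(f"{path}: header lacks {name}")
        return int(hm.group(1))

    n_orb = header_int("NORB")
    n_elec = header_int("NELEC")
    ms2 = header_int("MS2")
    if n_orb < 1:
        raise FormatError(f"{path}: NORB={n_orb} invalid")
    n_alpha = (n_elec + ms2) // 2
    n_beta = n_elec - n_alpha
    if n_alpha + n_beta != n_elec or n_beta < 0:
        raise FormatError(f"{path}: inconsistent NELEC={n_elec}, MS2={ms2}")

    h1 = np.zeros((n_orb, n_orb))
    eri = np.zeros((n_orb,) * 4)
    e_core = 0.0
    seen: dict[tuple, float] = {}

    body = text[m.end():]
    for lineno, line in enumerate(body.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise FormatError(f"{path}: malformed integral line {lineno!r}: {line!r}")
        try:
            if "(" in parts[0] or "," in parts[0]:
                raise ValueError("complex integral")
            val = float(parts[0])
            i, j, k, l = (int(x) for x in parts[1:])
        except ValueError as exc:
            raise FormatError(f"{path}: cannot parse line {line!r}") from exc
        idx = (i, j, k, l)
        for x in idx:
            if x < 0 or x > n_orb:
                raise FormatError(f"{path}: index {x} out of range 0..{n_orb}")
        key = _canonical_key(idx)
        if key in seen and abs(seen[key] - val) > 1e-10:
            raise FormatError(
                f"{path}: contradictory duplicate integral {idx}: "
                f"{seen[key]} vs {val}"
            )
        seen[key] = val
        if idx == (0, 0, 0, 0):
            e_core = val
        elif k == 0 and l == 0:
            if i == 0 or j == 0:
                raise FormatError(f"{path}: invalid one-body indices {idx}")
            h1[i - 1, j - 1] = val
            h1[j - 1, i - 1] = val
        elif 0 in idx:
            raise FormatError(f"{path}: invalid mixed zero indices {idx}")
        else:
            _fill_eri(eri, i - 1, j - 1, k - 1, l - 1, val)

    return ActiveSpaceHamiltonian(
        n_orb=n_orb, n_alpha=n_alpha, n_beta=n_beta, e_core=e_core,
        h1=h1, eri=eri, multiplicity=ms2 + 1,
    )


def _canonical_key(idx):
    i, j, k, l = idx
    a = tuple(sorted((i, j)))
    b = tuple(sorted((k, l)))
    return tuple(sorted((a, b)))


def write_fcidump(h: ActiveSpaceHamiltonian, path, threshold: float = 1e-12) -> None:
    """Write ``h`` in FCIDUMP format.

    Only symmetry-unique integrals with ``|value| > threshold`` are emitted, in
    descending index order, so two writes of the same Hamiltonian are
    byte-identical. The core energy is always written (on the all-zero line).
    """
    n = h.n_orb
    lines = [
        f" &FCI NORB={n},NELEC={h.n_elec},MS2={h.n_alpha - h.n_beta},",
        "  ORBSYM=" + ",".join(["1"] * n) + ",",
        "  ISYM=1,",
        " &END",
    ]
    # two-body: unique chemist quadruples i>=j, k>=l, (i,j)>=(k,l), 1-based
    quads = []
    for i in range(n, 0, -1):
        for j in range(i, 0, -1):
            for k in range(i, 0, -1):
                lmax = j if k == i else k
                for l in range(lmax, 0, -1):
                    quads.append((i, j, k, l))
    for (i, j, k, l) in quads:
        val = h.eri[i - 1, j - 1, k - 1, l - 1]
        if abs(val) > threshold:
            lines.append(f"{val:23.16e} {i:4d} {j:4d} {k:4d} {l:4d}")
    for i in range(n, 0, -1):
        for j in range(i, 0, -1):
            val = h.h1[i - 1, j - 1]
            if abs(val) > threshold:
                lines.append(f"{val:23.16e} {i:4d} {j:4d} {0:4d} {0:4d}")
    lines.append(f"{h.e_core:23.16e} {0:4d} {0:4d} {0:4d} {0:4d}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Synthetic Hamiltonians
# ---------------------------------------------------------------------------

def synthesize_hamiltonian(
    n_orb: int,
    cholesky_rank: int,
    seed: int,
    n_alpha: int | None = None,
    n_beta: int | None = None,
    scale: float = 1.0,
) -> ActiveSpaceHamiltonian:
    """Generate a random Hamiltonian with chemistry-like ERI structure.

    The two-electron tensor is built as an explicit rank-``cholesky_rank``
    positive-semidefinite sum

        (pq|rs) = sum_{l=1..R} L(l)_pq L(l)_rs,

    with each ``L(l)`` a random symmetric matrix, so every invariant of
    :class:`ActiveSpaceHamiltonian` holds by construction and the true
    Cholesky rank of the instance is known (at most R). ``h1`` is random
    symmetric. Electron counts default to half filling. Deterministic in
    ``seed``.
    """
    if n_orb < 1 or cholesky_rank < 1:
        raise ArgumentError("n_orb and cholesky_rank must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_orb
    # Magnitudes chosen to mimic active-space integrals: one-body O(1) Ha,
    # per-vector two-body weight decaying with l as Cholesky spectra do.
    h1 = rng.normal(scale=0.5 * scale, size=(n, n))
    h1 = 0.5 * (h1 + h1.T)
    eri = np.zeros((n,) * 4)
    vecs = []
    for l in range(cholesky_rank):
        m = rng.normal(size=(n, n))
        m = 0.5 * (m + m.T)
        m *= scale * 0.5 / (1.0 + l)  # decaying weights
        vecs.append(m)
        eri += np.einsum("pq,rs->pqrs", m, m)
    if n_alpha is None:
        n_alpha = (n + 1) // 2
    if n_beta is None:
        n_beta = n // 2
    return ActiveSpaceHamiltonian(
        n_orb=n, n_alpha=n_alpha, n_beta=n_beta,
        e_core=float(rng.normal()), h1=h1, eri=eri,
        multiplicity=abs(n_alpha - n_beta) + 1,
    )


# ---------------------------------------------------------------------------
# FCI oracle
# ---------------------------------------------------------------------------

_MAX_FCI_ORBITALS = 8


def _slater_phase(occ: tuple[int, ...], orb: int) -> int:
    """Parity (+1/-1) from moving an operator past the orbitals below ``orb``."""
    return -1 if sum(1 for o in occ if o < orb) % 2 else 1


def _excitation(det: tuple[int, ...], remove: int, create: int):
    """Apply a_create^dagger a_remove to a determinant; return (new_det, phase)."""
    if remove not in det or (create != remove and create in det):
        return None, 0
    occ = list(det)
    ph = _slater_phase(det, remove)
    occ.remove(remove)
    ph *= _slater_phase(tuple(occ), create)
    occ.append(create)
    occ.sort()
    return tuple(occ), ph


def exact_spectrum(
    h: ActiveSpaceHamiltonian,
    n_alpha: int,
    n_beta: int,
    include_core: bool = False,
) -> SpectrumResult:
    """Full CI eigenvalues in the (n_alpha, n_beta) sector by dense
    diagonalization over occupation-number determinants (Slater-Condon rules).

    Guarded to ``n_orb <= 8`` — this is a verification oracle, not a solver.
    """
    n = h.n_orb
    if n > _MAX_FCI_ORBITALS:
        raise ArgumentError(f"exact_spectrum limited to n_orb <= {_MAX_FCI_ORBITALS}")
    if not (0 <= n_alpha <= n and 0 <= n_beta <= n):
        raise ArgumentError("invalid sector")

    # spin orbitals: alpha p -> p, beta p -> n + p
    h_so = np.zeros((2 * n, 2 * n))
    h_so[:n, :n] = h.h1
    h_so[n:, n:] = h.h1

    def spatial(p):
        return p % n

    def spin(p):
        return p // n

    eri = h.eri

    def anti(p, q, r, s):
        """<pq||rs> over spin orbitals (physicist notation)."""
        out = 0.0
        if spin(p) == spin(r) and spin(q) == spin(s):
            out += eri[spatial(p), spatial(r), spatial(q), spatial(s)]
        if spin(p) == spin(s) and spin(q) == spin(r):
            out -= eri[spatial(p), spatial(s), spatial(q), spatial(r)]
        return out

    alphas = [tuple(c) for c in itertools.combinations(range(n), n_alpha)]
    betas = [tuple(sorted(n + o for o in c))
             for c in itertools.combinations(range(n), n_beta)]
    dets = [tuple(sorted(a + b)) for a in alphas for b in betas]
    index = {d: i for i, d in enumerate(dets)}
    dim = len(dets)
    ham = np.zeros((dim, dim))

    for d, di in index.items():
        occ = d
        # diagonal
        e = sum(h_so[p, p] for p in occ)
        e += 0.5 * sum(anti(p, q, p, q) for p in occ for q in occ)
        ham[di, di] = e
        # singles
        virt = [p for p in range(2 * n) if p not in occ]
        for i in occ:
            for a in virt:
                d1, ph = _excitation(d, i, a)
                if d1 is None or d1 not in index:
                    continue
                val = h_so[a, i] + sum(anti(a, q, i, q) for q in occ if q != i)
                ham[index[d1], di] += ph * val
        # doubles
        for i, j in itertools.combinations(occ, 2):
            for a, b in itertools.combinations(virt, 2):
                d1, ph1 = _excitation(d, i, a)
                if d1 is None:
                    continue
                d2, ph2 = _excitation(d1, j, b)
                if d2 is None or d2 not in index:
                    continue
                ham[index[d2], di] += ph1 * ph2 * anti(a, b, i, j)

    ham = 0.5 * (ham + ham.T)
    energies = np.linalg.eigvalsh(ham)
    if include_core:
        energies = energies + h.e_core
    return SpectrumResult(sector=(n_alpha, n_beta), energies=energies)
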