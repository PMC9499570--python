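"""Logical resources for qubitized phase estimation.

Phase estimation applies the qubitization walk operator ceil(pi * lambda /
(2 eps)) times; each application pays an itemized Toffoli cost set by the
tensor factorization backing the walk:

* a coefficient oracle realized as a table lookup (QROM) over the Gamma
  stored coefficients, using the clean-ancilla trade-off
  ``min_k ceil(D / 2^k) + b (2^k - 1)`` Toffolis for a D-entry, b-bit table
  (uncomputation costs ``min_k ceil(D / 2^k) + 2^k``);
* coefficient state preparation by alias sampling (comparator + controlled
  swap on the index register);
* controlled swaps moving the selected orbital indices into the system
  register (N/2-scale);
* for DF and THC, programmed Givens-rotation networks entering the leaf /
  collocation eigenbasis, N rotations of ``rot_bits`` bits each;
* the qubitization reflection on the index/keep registers.

The per-step cost model is the package's own; its constants are frozen in
:data:`MODEL_VERSION` and covered by regression tests so any drift is loud.
The asymptotic behaviour follows the QROM square-root trade-off, which is
what makes THC (table size O(M^2), M ~ 4.7 N) cheaper per step and leaner in
qubits than SF (table size O(L N^2)) as N grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError
from .factorization import (
    DoubleFactorization,
    SingleFactorization,
    THCFactorization,
    lambda_norm,
)
from .hamiltonian import ActiveSpaceHamiltonian

__all__ = [
    "MODEL_VERSION",
    "BitParams",
    "PrecisionBudget",
    "LogicalResources",
    "ScalingFit",
    "qrom_lookup_cost",
    "qrom_uncompute_cost",
    "pe_iterations",
    "walk_step_cost",
    "estimate_resources",
    "fit_scaling",
]

MODEL_VERSION = "fermifactor-cost-1"


@dataclass(frozen=True)
class BitParams:
    """Bit widths of the fixed-point registers in the walk-operator oracles.

    coeff_bits: keep-probability precision of alias sampling (per coefficient).
    rot_bits: rotation-angle precision of the Givens networks (DF/THC).
    """

    coeff_bits: int = 10
    rot_bits: int = 16

    def __post_init__(self):
        if self.coeff_bits < 1 or self.rot_bits < 1:
            raise ArgumentError("bit widths must be >= 1")


@dataclass(frozen=True)
class PrecisionBudget:
    """Additive split of the total energy-error budget (Hartree).

    Phase-estimation share eps_pea, coefficient-rounding share eps_qrom, and
    integral-truncation share eps_trunc must sum to at most eps_total.
    """

    eps_pea: float = 1.0e-3
    eps_qrom: float = 1.0e-3
    eps_trunc: float = 1.0e-3
    eps_total: float = 3.0e-3

    def __post_init__(self):
        parts = (self.eps_pea, self.eps_qrom, self.eps_trunc, self.eps_total)
        if any(p <= 0 for p in parts):
            raise ArgumentError("all budget shares must be positive")
        if self.eps_pea + self.eps_qrom + self.eps_trunc > self.eps_total * (1 + 1e-12):
            raise ArgumentError("budget shares exceed eps_total")


@dataclass
class LogicalResources:
    method: str
    lambda_val: float
    iterations: int
    toffoli_per_step: int
    logical_qubits: int
    bit_params: BitParams
    components: dict = field(default_factory=dict)

    @property
    def toffoli_total(self) -> int:
        return self.iterations * self.toffoli_per_step

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "lambda": self.lambda_val,
            "iterations": self.iterations,
            "toffoli_per_step": self.toffoli_per_step,
            "toffoli_total": self.toffoli_total,
            "logical_qubits": self.logical_qubits,
            "bit_params": {"coeff_bits": self.bit_params.coeff_bits,
                           "rot_bits": self.bit_params.rot_bits},
            "components": self.components,
            "cost_model": MODEL_VERSION,
        }


@dataclass
class ScalingFit:
    """Power law value ~= prefactor * N^exponent from a log-log least-squares fit."""

    exponent: float
    prefactor: float
    r_squared: float
    points: list


# ---------------------------------------------------------------------------
# QROM primitives
# ---------------------------------------------------------------------------

def qrom_lookup_cost(n_entries: int, output_bits: int) -> tuple[int, int]:
    """(Toffolis, ancilla qubits) for a clean-ancilla table lookup.

    Minimizes ceil(D / 2^k) + b (2^k - 1) over k; ancillas are the b * 2^k
    temporary output copies plus the index register.
    """
    if n_entries < 1 or output_bits < 1:
        raise ArgumentError("n_entries and output_bits must be >= 1")
    best = None
    kmax = max(1, math.ceil(math.log2(n_entries)) + 1)
    for k in range(kmax + 1):
        cost = math.ceil(n_entries / 2**k) + output_bits * (2**k - 1)
        if best is None or cost < best[0]:
            best = (cost, k)
    cost, k = best
    ancilla = output_bits * 2**k + math.ceil(math.log2(max(n_entries, 2)))
    return cost, ancilla


def qrom_uncompute_cost(n_entries: int) -> int:
    """Measurement-based uncomputation: min_k ceil(D / 2^k) + 2^k Toffolis."""
    if n_entries < 1:
        raise ArgumentError("n_entries must be >= 1")
    kmax = max(1, math.ceil(math.log2(n_entries)) + 1)
    return min(math.ceil(n_entries / 2**k) + 2**k for k in range(kmax + 1))


# ---------------------------------------------------------------------------
# Iterations
# ---------------------------------------------------------------------------

def pe_iterations(lambda_val: float, eps_pea: float) -> int:
    """Walk applications for phase estimation to accuracy eps_pea:
    ceil(pi * lambda / (2 eps))."""
    if lambda_val <= 0 or eps_pea <= 0:
        raise ArgumentError("lambda and eps must be positive")
    return max(1, math.ceil(math.pi * lambda_val / (2.0 * eps_pea)))


# ---------------------------------------------------------------------------
# Per-step cost
# ---------------------------------------------------------------------------

def _log2ceil(x: int) -> int:
    return max(1, math.ceil(math.log2(max(x, 2))))


def walk_step_cost(
    method: str,
    n_orb: int,
    rank_params,
    bit_params: BitParams = BitParams(),
) -> tuple[int, int, dict]:
    """Itemized (toffoli_per_step, logical_qubits, components) for one walk step.

    ``rank_params``: SF — retained vector count L; DF — sequence of leaf ranks
    Xi_l; THC — rank M.
    """
    n = n_orb
    if n < 1:
        raise ArgumentError("n_orb must be >= 1")
    b = bit_params
    comp: dict[str, int] = {}

    if method == "SF":
        L = int(rank_params)
        if L < 1:
            raise ArgumentError("SF needs L >= 1")
        n_pair = n * (n + 1) // 2
        data = L * n_pair  # Gamma
        idx = _log2ceil(data)
        out_bits = idx + b.coeff_bits
        prep, anc = qrom_lookup_cost(data, out_bits)
        comp["coeff_lookup"] = prep
        comp["coeff_unlookup"] = qrom_uncompute_cost(data)
        comp["alias_compare_swap"] = 2 * (b.coeff_bits + idx)
        comp["system_swaps"] = 4 * n
        comp["reflection"] = idx + b.coeff_bits + 1
        qubits = 2 * n + 2 * idx + b.coeff_bits + anc + 10

    elif method == "DF":
        ranks = [int(x) for x in rank_params]
        if not ranks or any(x < 1 for x in ranks):
            raise ArgumentError("DF needs a nonempty list of positive leaf ranks")
        L = len(ranks)
        data = sum(ranks)
        idx = _log2ceil(data)
        out_bits = idx + b.coeff_bits
        prep_o, anc_o = qrom_lookup_cost(L + 1, _log2ceil(L + 1) + b.coeff_bits)
        prep_i, anc_i = qrom_lookup_cost(data, out_bits)
        rot_lookup, anc_r = qrom_lookup_cost(data, n * b.rot_bits)
        comp["outer_prep"] = prep_o + qrom_uncompute_cost(L + 1)
        comp["coeff_lookup"] = prep_i
        comp["coeff_unlookup"] = qrom_uncompute_cost(data)
        comp["alias_compare_swap"] = 2 * (b.coeff_bits + idx)
        comp["rotation_lookup"] = rot_lookup + qrom_uncompute_cost(data)
        comp["givens_rotations"] = 4 * n * (b.rot_bits - 2)
        comp["system_swaps"] = 2 * n
        comp["reflection"] = idx + b.coeff_bits + 1
        qubits = (2 * n + 2 * idx + b.coeff_bits + n * b.rot_bits
                  + max(anc_o, anc_i, anc_r) + 10)

    elif method == "THC":
        m = int(rank_params)
        if m < 1:
            raise ArgumentError("THC needs rank M >= 1")
        data = m * (m + 1) // 2 + n  # zeta upper triangle + one-body diagonal
        idx = 2 * _log2ceil(m + 1)  # (mu, nu) register pair
        out_bits = idx + b.coeff_bits
        prep, anc = qrom_lookup_cost(data, out_bits)
        rot_lookup, anc_r = qrom_lookup_cost(m + 1, n * b.rot_bits)
        comp["coeff_lookup"] = prep
        comp["coeff_unlookup"] = qrom_uncompute_cost(data)
        comp["alias_compare_swap"] = 2 * (b.coeff_bits + idx)
        comp["rotation_lookup"] = 2 * (rot_lookup + qrom_uncompute_cost(m + 1))
        comp["givens_rotations"] = 4 * n * (b.rot_bits - 2)
        comp["system_swaps"] = 2 * n
        comp["reflection"] = idx + b.coeff_bits + 1
        qubits = (2 * n + 2 * idx + b.coeff_bits + n * b.rot_bits
                  + max(anc, anc_r) + 10)

    else:
        raise ArgumentError(f"unknown method {method!r}")

    toffoli = int(sum(comp.values()))
    return toffoli, int(qubits), comp


def _rank_params_of(f):
    if isinstance(f, SingleFactorization):
        return "SF", f.n_vectors
    if isinstance(f, DoubleFactorization):
        return "DF", f.leaf_ranks
    if isinstance(f, THCFactorization):
        return "THC", f.rank
    raise ArgumentError(f"unknown factorization type {type(f)!r}")


def estimate_resources(
    h: ActiveSpaceHamiltonian,
    f,
    budget: PrecisionBudget = PrecisionBudget(),
    bit_params: BitParams = BitParams(),
) -> LogicalResources:
    """Compose lambda -> iteration count -> per-step cost for (h, f)."""
    method, rank_params = _rank_params_of(f)
    lam = lambda_norm(h, f)
    iters = pe_iterations(lam.lambda_total, budget.eps_pea)
    toffoli, qubits, comp = walk_step_cost(method, h.n_orb, rank_params, bit_params)
    return LogicalResources(
        method=method,
        lambda_val=lam.lambda_total,
        iterations=iters,
        toffoli_per_step=toffoli,
        logical_qubits=qubits,
        bit_params=bit_params,
        components=comp,
    )


# ---------------------------------------------------------------------------
# Empirical scaling fits
# ---------------------------------------------------------------------------

def fit_scaling(points) -> ScalingFit:
    """Ordinary least squares of log(value) on log(N): value ~ prefactor * N^exp."""
    pts = [(float(n), float(v)) for n, v in points]
    if any(n <= 0 or v <= 0 for n, v in pts):
        raise ArgumentError("fit_scaling needs positive (N, value) pairs")
    xs = np.log([n for n, _ in pts])
    if len(set(xs)) < 2:
        raise ArgumentError("need >= 2 distinct abscissae")
    ys = np.log([v for _, v in pts])
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return ScalingFit(
        exponent=float(slope), prefactor=float(np.exp(intercept)),
        r_squared=max(0.0, min(1.0, r2)), points=pts,
    )
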