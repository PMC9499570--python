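"""Surface-code physical compilation of logical resource estimates.

The model has three layers:

1. A logical failure-rate fit ``p_L(d) = A (p_phys / p_th)^((d+1)/2)`` per
   logical qubit per code cycle, with A = 0.1 and threshold p_th = 1%.
2. Parametric magic-state factory models. The AutoCCZ factory is modeled as
   two rounds of 15-to-1 T-state distillation (level-1 at code distance d1,
   level-2 at d2) feeding a catalyzed CCZ assembly consuming four level-2 T
   states per output; the T15to1 factory is the same two-level distiller
   whose outputs are grouped four-per-Toffoli. Output error combines the
   35 p^3 distillation law (injection error 10 p_phys) with a topological
   term (patches x cycles x p_L at that level's distance).
3. Space/time accounting: each logical qubit occupies 2 (d+1)^2 physical
   qubits, routing adds 50% on top of data + factories, and runtime is the
   factory-bottleneck bound T x period / n_factories floored by the
   reaction-time limit T x t_reaction.

``optimize_config`` enumerates a bounded grid of (data distance, d1, d2) and
returns the feasible configuration (total failure probability <= 10%)
minimizing spacetime volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ArgumentError, InfeasibleError

__all__ = [
    "HardwareAssumptions",
    "FactoryModel",
    "SurfaceCodeConfig",
    "PhysicalEstimate",
    "GridSpec",
    "logical_error_rate",
    "make_factory",
    "evaluate_config",
    "optimize_config",
    "MODEL_CONSTANTS",
]

MODEL_CONSTANTS = {
    "A": 0.1,                 # logical error-rate prefactor
    "p_threshold": 0.01,      # surface-code threshold
    "injection_factor": 10.0,  # raw magic-state error = 10 * p_phys
    "distill_15to1": 35.0,    # output error = 35 * p_in^3
    "l1_patches": 12, "l1_cycles_per_d": 6,
    "l2_patches": 20, "l2_cycles_per_d": 6,
    "ccz_t_states": 4,        # level-2 T states consumed per CCZ
    "autoccz_period_per_d2": 5.5,
    "footprint_per_logical": lambda d: 2 * (d + 1) ** 2,
    "routing_overhead": 1.5,
    "version": "fermifactor-surface-1",
}


@dataclass(frozen=True)
class HardwareAssumptions:
    p_phys: float = 1.0e-3
    cycle_time_s: float = 1.0e-6
    reaction_time_s: float = 10.0e-6
    n_factories: int = 4

    def __post_init__(self):
        if not 0.0 < self.p_phys < 0.5:
            raise ArgumentError("p_phys must be in (0, 0.5)")
        if self.cycle_time_s <= 0 or self.reaction_time_s <= 0:
            raise ArgumentError("times must be positive")
        if self.n_factories < 1:
            raise ArgumentError("n_factories must be >= 1")


@dataclass(frozen=True)
class FactoryModel:
    kind: str  # "autoccz" | "t15to1"
    d1: int
    d2: int
    footprint: int  # physical qubits
    period_cycles: int  # cycles per output Toffoli-equivalent state
    p_out: float  # failure probability per output state

    def __post_init__(self):
        for d in (self.d1, self.d2):
            if d < 1 or d % 2 == 0:
                raise ArgumentError("code distances must be odd and positive")
        if self.footprint < 1 or self.period_cycles < 1:
            raise ArgumentError("footprint and period must be positive")
        if not 0.0 <= self.p_out < 1.0:
            raise ArgumentError("p_out must be in [0, 1)")


@dataclass(frozen=True)
class SurfaceCodeConfig:
    d_data: int
    factory: FactoryModel
    n_factories: int

    def __post_init__(self):
        if self.d_data < 1 or self.d_data % 2 == 0:
            raise ArgumentError("d_data must be odd and positive")


@dataclass(frozen=True)
class PhysicalEstimate:
    physical_qubits: int
    runtime_hours: float
    p_fail_total: float
    spacetime_volume: float  # physical qubits x seconds
    config: SurfaceCodeConfig

    def to_dict(self) -> dict:
        f = self.config.factory
        return {
            "physical_qubits": self.physical_qubits,
            "runtime_hours": self.runtime_hours,
            "p_fail_total": self.p_fail_total,
            "success_probability": 1.0 - self.p_fail_total,
            "spacetime_volume_qubit_seconds": self.spacetime_volume,
            "config": {
                "d_data": self.config.d_data,
                "n_factories": self.config.n_factories,
                "factory": {
                    "kind": f.kind, "d1": f.d1, "d2": f.d2,
                    "footprint": f.footprint,
                    "period_cycles": f.period_cycles,
                    "p_out": f.p_out,
                },
            },
            "model_constants": {k: v for k, v in MODEL_CONSTANTS.items()
                                if not callable(v)},
        }


def logical_error_rate(p_phys: float, d: int) -> float:
    """Per-logical-qubit per-cycle failure rate A (p/p_th)^((d+1)/2)."""
    if d < 1 or d % 2 == 0:
        raise ArgumentError("code distance must be odd and positive")
    if not 0.0 < p_phys < 0.5:
        raise ArgumentError("p_phys must be in (0, 0.5)")
    c = MODEL_CONSTANTS
    return c["A"] * (p_phys / c["p_threshold"]) ** ((d + 1) // 2)


def _distill_level(p_in: float, d: int, patches: int, cycles_per_d: int,
                   p_phys: float) -> float:
    c = MODEL_CONSTANTS
    topo = patches * cycles_per_d * d * logical_error_rate(p_phys, d)
    return min(1.0, c["distill_15to1"] * p_in**3 + topo)


def make_factory(kind: str, d1: int, d2: int, p_phys: float) -> FactoryModel:
    """Instantiate a factory model at distances (d1, d2) and error rate p_phys."""
    c = MODEL_CONSTANTS
    p_inj = min(0.5, c["injection_factor"] * p_phys)
    p1 = _distill_level(p_inj, d1, c["l1_patches"], c["l1_cycles_per_d"], p_phys)
    p2 = _distill_level(p1, d2, c["l2_patches"], c["l2_cycles_per_d"], p_phys)
    foot = c["footprint_per_logical"]
    if kind == "autoccz":
        footprint = 2 * c["l1_patches"] * foot(d1) + c["l2_patches"] * foot(d2)
        period = math.ceil(c["autoccz_period_per_d2"] * d2)
        p_out = min(1.0, c["ccz_t_states"] * p2)
    elif kind == "t15to1":
        footprint = c["l1_patches"] * foot(d1) + c["l2_patches"] * foot(d2)
        # four T outputs are consumed per Toffoli
        period = 4 * math.ceil(c["l2_cycles_per_d"] * d2)
        p_out = min(1.0, 4.0 * p2)
    else:
        raise ArgumentError(f"unknown factory kind {kind!r}")
    return FactoryModel(kind=kind, d1=d1, d2=d2, footprint=int(footprint),
                        period_cycles=int(period), p_out=p_out)


def evaluate_config(
    cfg: SurfaceCodeConfig,
    hw: HardwareAssumptions,
    logical_qubits: int,
    toffoli_count: float,
) -> PhysicalEstimate:
    """Deterministic space/time/failure accounting for one configuration."""
    if logical_qubits < 1 or toffoli_count < 1:
        raise ArgumentError("logical_qubits and toffoli_count must be positive")
    c = MODEL_CONSTANTS
    q, t = logical_qubits, float(toffoli_count)
    foot_data = q * c["footprint_per_logical"](cfg.d_data)
    physical_qubits = math.ceil(
        c["routing_overhead"] * (foot_data + cfg.n_factories * cfg.factory.footprint))
    factory_bound = t * cfg.factory.period_cycles * hw.cycle_time_s / cfg.n_factories
    runtime_s = max(factory_bound, t * hw.reaction_time_s)
    total_cycles = runtime_s / hw.cycle_time_s
    p_l = logical_error_rate(hw.p_phys, cfg.d_data)
    # log-domain survival product to stay accurate at p ~ 1e-15
    log_survive = (t * math.log1p(-min(cfg.factory.p_out, 1.0 - 1e-300))
                   + q * total_cycles * math.log1p(-min(p_l, 1.0 - 1e-300)))
    p_fail = -math.expm1(log_survive)
    p_fail = min(1.0, max(0.0, p_fail))
    return PhysicalEstimate(
        physical_qubits=int(physical_qubits),
        runtime_hours=runtime_s / 3600.0,
        p_fail_total=p_fail,
        spacetime_volume=physical_qubits * runtime_s,
        config=cfg,
    )


@dataclass(frozen=True)
class GridSpec:
    """Bounded search grid over odd code distances."""

    d_data: tuple = tuple(range(3, 52, 2))
    d1: tuple = tuple(range(7, 26, 2))
    d2: tuple = tuple(range(15, 42, 2))
    kinds: tuple = ("autoccz",)


def optimize_config(
    hw: HardwareAssumptions,
    logical_qubits: int,
    toffoli_count: float,
    grid: GridSpec = GridSpec(),
    max_p_fail: float = 0.1,
) -> PhysicalEstimate:
    """Exhaustively search the grid for the feasible configuration
    (p_fail_total <= max_p_fail) with least spacetime volume.

    Ties break toward fewer physical qubits, then smaller data distance.
    Raises :class:`InfeasibleError` (carrying the best failure probability
    found) when nothing in the grid is feasible.
    """
    best = None
    best_fail = None
    for kind in grid.kinds:
        for d1 in grid.d1:
            for d2 in grid.d2:
                factory = make_factory(kind, d1, d2, hw.p_phys)
                for d_data in grid.d_data:
                    cfg = SurfaceCodeConfig(
                        d_data=d_data, factory=factory,
                        n_factories=hw.n_factories)
                    est = evaluate_config(cfg, hw, logical_qubits, toffoli_count)
                    if best_fail is None or est.p_fail_total < best_fail:
                        best_fail = est.p_fail_total
                    if est.p_fail_total > max_p_fail:
                        continue
                    key = (est.spacetime_volume, est.physical_qubits,
                           est.config.d_data)
                    if best is None or key < (best.spacetime_volume,
                                              best.physical_qubits,
                                              best.config.d_data):
                        best = est
    if best is None:
        raise InfeasibleError(
            f"no configuration in grid reaches p_fail <= {max_p_fail} "
            f"(best found {best_fail:.3e})",
            best_p_fail=best_fail,
        )
    return best
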