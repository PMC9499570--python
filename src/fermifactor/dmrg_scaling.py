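"""Classical DMRG cost extrapolation and the generic-THC-rank regression.

DMRG cost is governed by the active-orbital count k and the bond dimension M:
CPU time scales as O(k^3 M^3), memory as O(k^2 M^2), and disk as O(k^3 M^2).
Given one measured cost point, those power laws extrapolate to any (k, M).

The generic THC rank is the through-origin least-squares slope of fitted THC
ranks against orbital count, giving a single rank-per-orbital multiplier
usable when no per-system rank optimization has been run.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .errors import ArgumentError

__all__ = [
    "DMRGCostPoint",
    "RankRegression",
    "dmrg_extrapolate",
    "generic_thc_rank",
    "read_cost_points",
    "round_report",
]


@dataclass(frozen=True)
class DMRGCostPoint:
    k: int  # active orbitals
    M: int  # bond dimension
    cpu_hours: float
    memory_gb: float
    disk_gb: float

    def __post_init__(self):
        if min(self.k, self.M) < 1 or min(
                self.cpu_hours, self.memory_gb, self.disk_gb) <= 0:
            raise ArgumentError("all cost-point fields must be positive")


@dataclass(frozen=True)
class RankRegression:
    multiplier: float  # THC rank per orbital
    points: tuple

    def __post_init__(self):
        if self.multiplier <= 0:
            raise ArgumentError("multiplier must be positive")


def dmrg_extrapolate(ref: DMRGCostPoint, k_new: int, m_new: int) -> DMRGCostPoint:
    """Scale a measured cost point to (k_new, m_new) by the DMRG power laws.

    No rounding is applied; use :func:`round_report` at report time.
    """
    if k_new < 1 or m_new < 1:
        raise ArgumentError("k_new and m_new must be positive")
    rk = k_new / ref.k
    rm = m_new / ref.M
    return DMRGCostPoint(
        k=k_new, M=m_new,
        cpu_hours=ref.cpu_hours * rk**3 * rm**3,
        memory_gb=ref.memory_gb * rk**2 * rm**2,
        disk_gb=ref.disk_gb * rk**3 * rm**2,
    )


def round_report(point: DMRGCostPoint) -> dict:
    """Report-time rounding: nearest integer, half away from zero."""

    def r(x):
        return int(np.floor(x + 0.5))

    return {"k": point.k, "M": point.M, "cpu_hours": r(point.cpu_hours),
            "memory_gb": r(point.memory_gb), "disk_gb": r(point.disk_gb)}


def generic_thc_rank(points) -> RankRegression:
    """Through-origin least squares of THC rank on orbital count N.

    multiplier = sum(N_i * rank_i) / sum(N_i^2), so points lying exactly on
    rank = c N recover c.
    """
    pts = tuple((float(n), float(r)) for n, r in points)
    if len(pts) < 2:
        raise ArgumentError("need >= 2 points")
    if any(n <= 0 or r <= 0 for n, r in pts):
        raise ArgumentError("points must be positive")
    ns = np.array([n for n, _ in pts])
    rs = np.array([r for _, r in pts])
    denom = float(np.sum(ns * ns))
    if denom == 0:
        raise ArgumentError("degenerate points")
    return RankRegression(multiplier=float(np.sum(ns * rs) / denom), points=pts)


def read_cost_points(path) -> list[DMRGCostPoint]:
    """Read cost points from CSV with columns k, M, cpu_hours, memory_gb, disk_gb."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(DMRGCostPoint(
                k=int(row["k"]), M=int(row["M"]),
                cpu_hours=float(row["cpu_hours"]),
                memory_gb=float(row["memory_gb"]),
                disk_gb=float(row["disk_gb"]),
            ))
    return out
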