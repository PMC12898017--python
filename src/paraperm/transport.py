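"""Ionic current and conductance from trajectories.

The ionic current under a constant axial field is obtained from the
displacement charge

    q_disp(t) = Σ_i q_i · (x_i(t) − x_i(0)) / L

(elementary charges; x unwrapped along the field axis, L the box length
along that axis). Its time slope, converted from e/ns, is the current;
conductance follows as G = I/V. A hysteresis-based ion-crossing counter
provides an independent route to the same transported charge.

Bulk conductivity normalizes conductance by conductor geometry,
σ = G·L/A, and a regression utility compares simulated against measured
conductivity sets across salts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import PA_PER_E_NS
from .errors import ConfigurationError, DomainError, InsufficientDataError
from .traj import Selection, Trajectory, axis_index


@dataclass
class DisplacementSeries:
    """Cumulative charge displacement (e, normalized by box length) vs time."""

    time_ns: np.ndarray
    q_disp_e: np.ndarray

    def __post_init__(self) -> None:
        self.time_ns = np.asarray(self.time_ns, dtype=float)
        self.q_disp_e = np.asarray(self.q_disp_e, dtype=float)
        if self.time_ns.shape != self.q_disp_e.shape:
            raise ValueError("time and charge series must align")
        if self.q_disp_e.size and abs(self.q_disp_e[0]) > 1e-12:
            raise ValueError("q_disp_e must start at 0")


@dataclass
class IVPoint:
    voltage_mV: float
    current_pA: float
    species: str = ""
    replica: str | None = None


@dataclass
class ConductanceResult:
    """Fitted conductance ± SD (pS)."""

    g_pS: float
    sd_pS: float
    method: Literal["per_voltage_mean", "origin_slope"]
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points == 1 and self.sd_pS != 0.0:
            raise ValueError("sd must be 0 for a single point")


@dataclass
class BoxGeometry:
    """Conductor geometry: axial length, cross-section and pore multiplicity."""

    length_along_field_A: float
    cross_section_A2: float
    n_parallel_pores: int = 1

    def __post_init__(self) -> None:
        if (
            self.length_along_field_A <= 0
            or self.cross_section_A2 <= 0
            or self.n_parallel_pores < 1
        ):
            raise ValueError("geometry fields must be positive")


# ---------------------------------------------------------------------------
# Displacement charge and current
# ---------------------------------------------------------------------------


def displacement_charge(
    traj: Trajectory,
    sel: Selection,
    charges: Mapping[str, float],
    axis: str | int = "x",
) -> DisplacementSeries:
    """Charge-weighted cumulative displacement along the field axis.

    The trajectory must already be unwrapped along ``axis``. Both anion
    and cation displacements contribute (with their signed charges); a
    selected ion whose species has no charge entry is an error.
    """
    ax = axis_index(axis)
    idx = sel.resolve_or_raise(traj.topology)
    q = np.empty(idx.size)
    for k, pos in enumerate(idx):
        atom = traj.topology.atoms[pos]
        if atom.species is None or atom.species not in charges:
            raise ConfigurationError(
                f"atom {atom.atom_id} (species {atom.species!r}) has no charge entry"
            )
        q[k] = charges[atom.species]
    X = traj.coords_array()[:, idx, ax]
    L = traj.frames[0].box_lengths[ax]
    qd = (X - X[0]) @ q / L
    return DisplacementSeries(time_ns=traj.times_ns, q_disp_e=qd)


def current_from_displacement(
    series: DisplacementSeries,
    fit_window: tuple[float, float] | None = None,
    method: Literal["ols", "endpoint"] = "ols",
) -> float:
    """Current (pA) from a displacement-charge series.

    ``fit_window`` is a (t_start, t_end) interval in ns; the default is
    the last 80 % of the series. ``method='ols'`` fits a least-squares
    slope within the window; ``method='endpoint'`` uses Δq/Δt over the
    window, which states exact charge conservation for the window.
    """
    t, qd = series.time_ns, series.q_disp_e
    if fit_window is None:
        fit_window = (t[0] + 0.2 * (t[-1] - t[0]), t[-1])
    lo, hi = fit_window
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 2:
        raise InsufficientDataError(
            f"fit window ({lo}, {hi}) ns contains {int(mask.sum())} samples; need >= 2"
        )
    tw, qw = t[mask], qd[mask]
    if method == "endpoint":
        slope = (qw[-1] - qw[0]) / (tw[-1] - tw[0])
    else:
        slope = np.polyfit(tw, qw, 1)[0]
    return float(slope * PA_PER_E_NS)


def count_crossings(
    traj: Trajectory,
    sel: Selection,
    axis: str | int,
    plane_lo: float,
    plane_hi: float,
) -> dict[str, int]:
    """Net signed slab crossings per species, with hysteresis.

    A +1 crossing is a continuous passage from below ``plane_lo`` to
    above ``plane_hi`` (−1 for the reverse); an ion must fully exit the
    slab before it can be recounted. Coordinates must be unwrapped along
    ``axis``; slab images repeat with the box period, so an ion that
    drifts k full box lengths records k crossings.
    """
    if plane_lo >= plane_hi:
        raise ValueError("plane_lo must be below plane_hi")
    ax = axis_index(axis)
    idx = sel.resolve_or_raise(traj.topology)
    L = traj.frames[0].box_lengths[ax]
    width = plane_hi - plane_lo
    if width >= L:
        raise ValueError("slab must be narrower than the box")
    X = traj.coords_array()[:, idx, ax]
    counts: dict[str, int] = {}
    for k, pos in enumerate(idx):
        sp = traj.topology.atoms[pos].species or ""
        y = X[:, k]
        frac = np.mod(y - plane_lo, L)
        outside = frac > width
        if not np.any(outside):
            continue
        # image index counting slabs fully below the current position
        g = np.floor((y[outside] - plane_hi) / L) + 1
        net = int(g[-1] - g[0])
        counts[sp] = counts.get(sp, 0) + net
    return counts


# ---------------------------------------------------------------------------
# Conductance
# ---------------------------------------------------------------------------


def conductance(
    points: Sequence[IVPoint],
    method: Literal["per_voltage_mean", "origin_slope"] = "per_voltage_mean",
) -> ConductanceResult:
    """Channel conductance from I–V points, as G = I/V.

    ``per_voltage_mean`` averages the per-point conductivities I/V and
    reports their SD across voltages; ``origin_slope`` fits the
    least-squares slope of a line through the origin and reports the
    slope's standard error.
    """
    V = np.array([p.voltage_mV for p in points], dtype=float)
    I = np.array([p.current_pA for p in points], dtype=float)
    nz = V != 0
    if not np.any(nz):
        raise DomainError("all voltages are zero; conductance undefined")
    V, I = V[nz], I[nz]
    n = V.size
    if method == "per_voltage_mean":
        g = I / V * 1000.0  # pA/mV = nS → pS via ×1000
        mean = float(np.mean(g))
        sd = float(np.std(g, ddof=1)) if n > 1 else 0.0
        return ConductanceResult(mean, sd, "per_voltage_mean", n)
    slope = float(np.sum(I * V) / np.sum(V * V))
    resid = I - slope * V
    if n > 1:
        se = float(np.sqrt(np.sum(resid**2) / (n - 1) / np.sum(V * V)))
    else:
        se = 0.0
    return ConductanceResult(slope * 1000.0, se * 1000.0, "origin_slope", n)


def iv_r2_through_origin(points: Sequence[IVPoint]) -> float:
    """Coefficient of determination of the through-origin I–V fit
    (uncentered: 1 − SS_res/ΣI²)."""
    V = np.array([p.voltage_mV for p in points], dtype=float)
    I = np.array([p.current_pA for p in points], dtype=float)
    slope = np.sum(I * V) / np.sum(V * V)
    ss_res = np.sum((I - slope * V) ** 2)
    ss_tot = np.sum(I**2)
    return float(1.0 - ss_res / ss_tot)


def per_pore(g_total: ConductanceResult, geom: BoxGeometry) -> ConductanceResult:
    """Single-pore conductance: total divided by the number of identical
    parallel pores in the periodic cell (SD scales identically)."""
    n = geom.n_parallel_pores
    return ConductanceResult(
        g_total.g_pS / n, g_total.sd_pS / n, g_total.method, g_total.n_points
    )


def bulk_conductivity(g: ConductanceResult, geom: BoxGeometry) -> float:
    """Intrinsic conductivity σ = G·L/A in S/m from (pS, Å, Å²)."""
    g_S = g.g_pS * 1e-12
    L_m = geom.length_along_field_A * 1e-10
    A_m2 = geom.cross_section_A2 * 1e-20
    return g_S * L_m / A_m2


def conductivity_regression(
    x: Mapping[str, float],
    y: Mapping[str, float],
    intercept: bool = False,
) -> tuple[float, float]:
    """OLS of y on x over the shared salts; returns (slope, R²).

    Without an intercept, R² is the uncentered coefficient of
    determination (1 − SS_res/Σy²).
    """
    shared = sorted(set(x) & set(y))
    if len(shared) < 3:
        raise InsufficientDataError(
            f"need >= 3 shared salts, got {len(shared)}: {shared}"
        )
    xv = np.array([x[s] for s in shared], dtype=float)
    yv = np.array([y[s] for s in shared], dtype=float)
    if intercept:
        A = np.column_stack([xv, np.ones_like(xv)])
        coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
        slope = float(coef[0])
        pred = A @ coef
        ss_tot = np.sum((yv - yv.mean()) ** 2)
    else:
        slope = float(np.sum(xv * yv) / np.sum(xv * xv))
        pred = slope * xv
        ss_tot = np.sum(yv**2)
    ss_res = np.sum((yv - pred) ** 2)
    r2 = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 1.0
    return slope, r2


def iv_table(points: Sequence[IVPoint]) -> pd.DataFrame:
    """Tidy I–V table (species, voltage_mV, current_pA, replica)."""
    return pd.DataFrame(
        [
            {
                "species": p.species,
                "voltage_mV": p.voltage_mV,
                "current_pA": p.current_pA,
                "replica": p.replica,
            }
            for p in points
        ]
    )
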