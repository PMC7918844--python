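"""Debye-Hückel free energy of the discretely charged interface.

The electrostatic interaction free energy per unit area of an ensemble of
charged disks follows from charging each disk against the potential produced
by all *other* cells,

    F/A = (1/R^2) Int_0^R dr r sigma(r) DeltaPhi_s(r),

and is reported relative to the continuum double-layer value
``F0/A = sigma0^2 lD / (2 eps_w eps0)``. Carrying out the radial integrals
mode by mode gives the closed form (with ``rho0 = r0/R``, ``lam = lD/R``,
``D`` the shared screening denominator)

    F/F0 = 1 + (1/rho0^2) [ Sum_{n=1}^{nmax} (2 J1(yn rho0)/(yn J0(yn)))^2 / D(yn)
                            - Int_0^{y_nmax} dy 2 J1(y rho0)^2 / (y D(y)) ].

The sum (cell potential) and the integral (isolated-disk self-potential)
diverge separately as the cutoff grows; only their difference at a *shared*
cutoff ``y_nmax`` is meaningful, so the two are always truncated together and
accumulated as per-mode differences. The point-charge limit is reached by
shrinking ``r0`` at proportionally growing ``nmax`` — legitimate because the
derivative of F/F0 with respect to ``r0`` vanishes at ``r0 = 0``, making the
small-``r0`` plateau flat.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import constants
from scipy.special import j1

from .basis import j1_zeros
from .cell import mode_denominator, surface_potential_cell
from .core import CellGeometry, ElectrolyteInterface, SeriesControl
from .isolated import surface_potential_isolated

__all__ = [
    "FreeEnergyResult",
    "ScaledSweepPoint",
    "free_energy_ratio",
    "free_energy_ratio_quadrature",
    "point_charge_free_energy",
    "scaled_sweep",
    "loglog_slope",
    "to_physical_units",
]


@dataclass(frozen=True)
class FreeEnergyResult:
    """Scaled free energy ``F/F0`` with the numerical diagnostics behind it."""

    ratio: float
    n_max_used: int
    r0_used: float
    R_used: float
    convergence_estimate: float

    def __post_init__(self) -> None:
        if self.convergence_estimate < 0:
            raise ValueError("convergence_estimate must be >= 0")


@dataclass(frozen=True)
class ScaledSweepPoint:
    """One point of the fs(s) sweep at fixed Debye length.

    ``s = lD^2 sigma0 / e`` is the scaled surface charge density and
    ``fs = 2 lD^3 eps_w eps0 F / (e^2 A)`` the scaled free energy;
    algebraically ``fs = (F/F0) s^2``, so the continuum reference is
    ``fs = s^2`` exactly.
    """

    s: float
    fs: float
    fs_continuum: float
    eps_ratio: float
    result: FreeEnergyResult


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(16)


def _paired_terms(rho0: float, lam: float, eta: float, n_max: int) -> np.ndarray:
    """Per-mode difference (series term minus matching integral slice).

    Mode ``n`` contributes its series term minus the integral of the
    continuum integrand over ``[y_{n-1}, y_n]`` (16-point Gauss-Legendre per
    subinterval, which resolves the slowly varying integrand on the pi-wide
    Bessel-zero spacing). Pairing keeps the large mutually cancelling pieces
    local to each mode.
    """
    table = j1_zeros(n_max)
    yn = table.zeros
    j0z = table.j0_at_zeros
    y = yn[1:]
    s_terms = (2.0 * j1(y * rho0) / (y * j0z[1:])) ** 2 / mode_denominator(y, lam, eta)
    a, b = yn[:-1], yn[1:]
    half = 0.5 * (b - a)
    pts = 0.5 * (a + b)[:, None] + half[:, None] * _GL_NODES[None, :]
    integrand = 2.0 * j1(pts * rho0) ** 2 / (pts * mode_denominator(pts, lam, eta))
    i_terms = half * (integrand @ _GL_WEIGHTS)
    return s_terms - i_terms


def free_energy_ratio(
    geom: CellGeometry,
    medium: ElectrolyteInterface,
    ctrl: SeriesControl,
) -> FreeEnergyResult:
    """Scaled free energy ``F/F0`` of charged disks in Wigner-Seitz cells.

    Evaluates the paired-truncation closed form at ``ctrl.n_max`` modes. The
    convergence estimate compares the result against the one at half the
    cutoff, normalised on the O(1) scale of the ratio.
    """
    rho0 = geom.r0_over_R
    lam = medium.lD / geom.R
    diffs = _paired_terms(rho0, lam, medium.eps_ratio, ctrl.n_max)
    ratio = 1.0 + math.fsum(diffs) / rho0**2
    n_half = max(1, ctrl.n_max // 2)
    ratio_half = 1.0 + math.fsum(diffs[:n_half]) / rho0**2
    conv = abs(ratio - ratio_half) / max(abs(ratio), 1e-3)
    return FreeEnergyResult(
        ratio=ratio,
        n_max_used=ctrl.n_max,
        r0_used=geom.r0,
        R_used=geom.R,
        convergence_estimate=conv,
    )


def free_energy_ratio_quadrature(
    geom: CellGeometry,
    medium: ElectrolyteInterface,
    ctrl: SeriesControl,
    *,
    potential: str = "delta",
    n_nodes: int = 48,
) -> float:
    """F/F0 by direct radial quadrature of ``sigma(r) * potential(r)``.

    Independent route to the same quantity: evaluates
    ``(2/rho0^2) Int_0^{rho0} dx x P(x)`` with ``P`` the difference potential
    ``DeltaPhi_s/Phi0`` (``potential="delta"``, the free energy proper) or the
    full cell potential ``Phi_s/Phi0`` (``potential="total"``, which at
    ``r0 = R`` counts the self-energy and returns exactly 1). Used as the
    cross-check for :func:`free_energy_ratio`, never as its implementation.
    """
    if potential not in ("delta", "total"):
        raise ValueError("potential must be 'delta' or 'total'")
    rho0 = geom.r0_over_R
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    x = 0.5 * rho0 * (nodes + 1.0)
    w = 0.5 * rho0 * weights
    p = np.asarray(surface_potential_cell(x, geom, medium, ctrl), dtype=float)
    if potential == "delta":
        p = p - surface_potential_isolated(x * geom.R, geom, medium)
    return float(2.0 / rho0**2 * np.sum(w * x * p))


def point_charge_free_energy(
    R: float,
    medium: ElectrolyteInterface,
    rel_tol: float = 1e-3,
    *,
    c: float = 0.05,
    n_max_factor: float = 5.0,
    max_halvings: int = 6,
) -> FreeEnergyResult:
    """F/F0 in the point-charge limit ``r0 -> 0``.

    Starts from ``r0 = c * min(R, lD)`` and halves ``r0`` until successive
    ratios agree to ``rel_tol`` on the ``max(|ratio|, 1e-3)`` scale; the
    flatness of F/F0 in ``r0`` near zero makes that outer iteration converge
    quickly. At *each* ``r0`` the mode cutoff is refined independently:
    starting from ``n_max = ceil(n_max_factor * R/r0)``, the cutoff is
    doubled until the ratio's own truncation estimate drops below a fraction
    of ``rel_tol``. The two refinements must not be coupled — the truncation
    error depends essentially on the product ``n_max * r0/R``, so halving
    ``r0`` while doubling ``n_max`` in lockstep would leave it unchanged and
    fake convergence (visible at small ``lD/R``, where many unscreened modes
    contribute). The formal ``r0 = 0`` series is never evaluated (its sum
    and integral diverge separately).
    """
    if not (rel_tol > 0):
        raise ValueError("rel_tol must be positive")
    r0 = c * min(R, medium.lD)
    n_max = int(math.ceil(n_max_factor * R / r0))
    history: list[float] = []
    for _ in range(max_halvings + 1):
        geom = CellGeometry(R=R, r0=r0)
        res = free_energy_ratio(
            geom, medium, SeriesControl(n_max=n_max, rel_tol=rel_tol, adaptive=False)
        )
        for _ in range(24):  # inner cutoff refinement at fixed r0
            if res.convergence_estimate <= 0.3 * rel_tol:
                break
            n_max *= 2
            res = free_energy_ratio(
                geom, medium, SeriesControl(n_max=n_max, rel_tol=rel_tol, adaptive=False)
            )
        else:
            raise RuntimeError(
                f"mode cutoff not converged at r0={r0}: estimate "
                f"{res.convergence_estimate:.3e} at n_max={n_max}"
            )
        history.append(res.ratio)
        if len(history) >= 2:
            conv = abs(history[-1] - history[-2]) / max(abs(history[-1]), 1e-3)
            if conv < rel_tol:
                return FreeEnergyResult(
                    ratio=res.ratio,
                    n_max_used=res.n_max_used,
                    r0_used=r0,
                    R_used=R,
                    convergence_estimate=conv,
                )
        r0 *= 0.5
        # warm-start the next cutoff search from the converged one
        n_max = max(n_max, int(math.ceil(n_max_factor * R / r0)))
    raise RuntimeError(
        f"point-charge limit not converged to rel_tol={rel_tol} after "
        f"{max_halvings} halvings; iterates: {history}"
    )


def scaled_sweep(
    s_values,
    eps_ratio: float,
    rel_tol: float = 1e-3,
) -> list[ScaledSweepPoint]:
    """Sweep the scaled free energy ``fs`` over scaled charge densities ``s``.

    One elementary charge per cell fixes ``R = e/(sigma0 pi)``, i.e.
    ``R/lD = (pi s)^(-1/2)``; each point computes the point-charge F/F0 at
    that cell size and reports ``fs = (F/F0) s^2`` next to the continuum
    reference ``s^2``.
    """
    points = []
    for s in np.atleast_1d(np.asarray(s_values, dtype=float)):
        if s <= 0:
            raise ValueError(f"s must be positive, got {s}")
        medium = ElectrolyteInterface(lD=1.0, eps_ratio=eps_ratio)
        R = (math.pi * s) ** -0.5  # in units of lD
        res = point_charge_free_energy(R, medium, rel_tol)
        points.append(
            ScaledSweepPoint(
                s=float(s),
                fs=res.ratio * s**2,
                fs_continuum=s**2,
                eps_ratio=eps_ratio,
                result=res,
            )
        )
    return points


def loglog_slope(points) -> float:
    """Least-squares slope of ``log fs`` versus ``log s``.

    Accepts a sequence of :class:`ScaledSweepPoint` or an ``(s, fs)`` pair of
    arrays; two points give the exact two-point slope.
    """
    if len(points) and isinstance(points[0], ScaledSweepPoint):
        s = np.array([p.s for p in points])
        fs = np.array([p.fs for p in points])
    else:
        s, fs = (np.asarray(a, dtype=float) for a in points)
    if s.size < 2 or np.unique(s).size != s.size:
        raise ValueError("need at least two distinct s values")
    if np.any(fs <= 0) or np.any(s <= 0):
        raise ValueError("log-log slope requires strictly positive s and fs")
    slope, _ = np.polyfit(np.log(s), np.log(fs), 1)
    return float(slope)


def to_physical_units(
    result: FreeEnergyResult,
    medium: ElectrolyteInterface,
    *,
    area: float | None = None,
    n_charges: float | None = None,
) -> dict[str, float]:
    """Convert a scaled result to J/m^2 and kBT-per-charge.

    Requires the medium's physical block. One elementary charge per cell
    fixes ``sigma0 = e / (pi R^2)`` (sign irrelevant: the free energy is
    quadratic in ``sigma0``), and ``F/A = (F/F0) sigma0^2 lD / (2 eps_w
    eps0)``. Supply ``area`` (m^2) or ``n_charges`` to also get totals.
    """
    if not medium.has_physical_block:
        raise ValueError("to_physical_units requires the medium's physical block")
    R = result.R_used
    sigma0 = constants.e / (math.pi * R**2)
    f0_per_area = sigma0**2 * medium.lD / (2.0 * medium.eps_w * constants.epsilon_0)
    f_per_area = result.ratio * f0_per_area
    cell_area = math.pi * R**2
    kT = constants.k * medium.temperature
    out = {
        "sigma0_C_per_m2": sigma0,
        "F0_per_area_J_per_m2": f0_per_area,
        "F_per_area_J_per_m2": f_per_area,
        "F_per_charge_kT": f_per_area * cell_area / kT,
    }
    if area is not None:
        out["F_total_J"] = f_per_area * area
        out["n_charges"] = area / cell_area
    elif n_charges is not None:
        out["F_total_J"] = f_per_area * cell_area * n_charges
        out["n_charges"] = n_charges
    return out
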