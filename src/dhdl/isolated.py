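"""Isolated-disk surface potential by Hankel transform, and its limits.

Removing the cell boundary (``R -> infinity`` at fixed disk) turns the
Fourier-Bessel series into a continuous Hankel transform. With ``x = r/R``,
``rho0 = r0/R``, ``lam = lD/R`` and the shared screening denominator ``D(y)``
(:func:`dhdl.cell.mode_denominator`), the scaled self-potential of one disk is

    Phi_self(r)/Phi0 = (1/rho0) Int_0^inf dy J0(y x) J1(y rho0) / D(y)

and its point-charge limit (the classic single-interface-charge potential)

    Phi_self(r)/Phi0 = (1/2) Int_0^inf dy y J0(y x) / D(y),

which for a weak lower dielectric and ``r >> lD`` reduces to a screened
Coulomb term plus the ``1/r^3`` dipole tail carried through the salt-free
medium. The integrands oscillate and decay slowly, so the semi-infinite
integral is partitioned at the zeros of the fastest-oscillating Bessel factor
and the alternating tail is summed with an Euler-type (iterated averaging)
acceleration.
"""
from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.special import hyp2f1, j0, j1, jn_zeros

from .cell import mode_denominator, surface_potential_cell
from .core import CellGeometry, ElectrolyteInterface, RadialProfile, SeriesControl

__all__ = [
    "surface_potential_isolated",
    "surface_potential_point_isolated",
    "hurd_asymptotic",
    "delta_surface_potential",
]


class QuadratureError(RuntimeError):
    """Raised when the oscillatory quadrature fails to meet its tolerance."""


def _euler_tail(terms: np.ndarray) -> tuple[float, float]:
    """Sum an (asymptotically) alternating sequence by iterated averaging.

    Builds the partial sums and repeatedly replaces them by adjacent means;
    for alternating terms with slowly varying magnitude each level gains
    roughly one digit. Returns (value, error estimate).
    """
    levels = [np.cumsum(terms)]
    while levels[-1].size > 1:
        levels.append(0.5 * (levels[-1][:-1] + levels[-1][1:]))
    value = levels[-1][-1]
    # error gauged from the last two averaging levels
    est = abs(value - levels[-2][-1]) if len(levels) > 1 else abs(value)
    return float(value), float(est)


def _zero_family(osc_scale: float, osc_order: int, n_break: int) -> np.ndarray:
    """First ``n_break`` positive zeros of ``J_osc_order(osc_scale * y)``.

    Exact zeros up front, continued with the asymptotic pi spacing beyond the
    precomputed range (only the spacing matters for the tail acceleration).
    """
    n_exact = min(n_break, 64)
    z = jn_zeros(osc_order, n_exact)
    if n_break > n_exact:
        z = np.concatenate([z, z[-1] + np.pi * np.arange(1, n_break - n_exact + 1)])
    return z / osc_scale


def _merged_breakpoints(families: list[tuple[float, int]], n_break: int) -> np.ndarray:
    """Sign-change partition for a product of oscillatory Bessel factors.

    Merging the zero sets of every factor ``J_order(scale * y)`` yields
    subintervals on which the product has a single sign, so the subinterval
    integrals alternate strictly — the property the tail acceleration needs.
    A single factor reduces to its own zeros.
    """
    zs = [ _zero_family(scale, order, n_break) for scale, order in families if scale > 0 ]
    if not zs:
        raise ValueError("need at least one oscillatory factor with positive scale")
    merged = np.sort(np.concatenate(zs))[:n_break]
    return np.concatenate(([0.0], merged))


def _oscillatory_integral(
    f,
    families: list[tuple[float, int]],
    *,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    n_direct: int = 16,
    n_tail: int = 48,
    accelerate: bool = True,
    cutoff: float | None = None,
) -> float:
    """Integrate ``f`` over ``[0, inf)`` partitioned at its sign changes.

    ``families`` lists the oscillatory Bessel factors of the integrand as
    ``(argument scale, order)`` pairs; breakpoints sit at their merged zeros.
    The first ``n_direct`` subintervals are summed as-is, the next ``n_tail``
    feed the Euler-type acceleration; the tail is deepened (up to 4x) until
    the acceleration's own error estimate meets ``max(rtol * |I|, atol)``.
    With ``accelerate=False`` the integral is simply truncated at ``cutoff``
    (residual-bound fallback used by the cross-validation tests).
    """
    if not accelerate:
        breaks = _merged_breakpoints(families, n_direct + n_tail + 1)
        y_max = cutoff if cutoff is not None else breaks[-1]
        edges = np.append(breaks[breaks < y_max], y_max)
        total = 0.0
        for a, b in zip(edges[:-1], edges[1:]):
            val, _ = quad(f, a, b, limit=200)
            total += val
        return total

    breaks = _merged_breakpoints(families, n_direct + 4 * n_tail + 1)
    pieces: list[float] = []
    est = np.inf
    total = 0.0
    n_have = 0
    for depth in (n_tail, 2 * n_tail, 4 * n_tail):
        for k in range(n_have, n_direct + depth):
            val, _ = quad(f, breaks[k], breaks[k + 1], limit=200)
            pieces.append(val)
        n_have = n_direct + depth
        head = float(np.sum(pieces[:n_direct]))
        tail, est = _euler_tail(np.asarray(pieces[n_direct:]))
        total = head + tail
        if est <= max(rtol * abs(total), atol):
            return total
    raise QuadratureError(
        f"oscillatory tail not converged: estimate {est:.3e} for value {total:.6e} "
        f"({n_have - n_direct} accelerated subintervals)"
    )


def _ws_ratio(a: float, b: float) -> float:
    """Closed form of ``Int_0^inf dy J0(a y) J1(b y) / y`` (Weber-Schafheitlin).

    A function of ``t = a/b`` alone: ``2F1(-1/2, 1/2; 1; t^2)`` for ``t <= 1``
    and ``2F1(1/2, 1/2; 2; 1/t^2) / (2t)`` for ``t >= 1`` (both ``2/pi`` at
    ``t = 1``).
    """
    t = a / b
    if t <= 1.0:
        return float(hyp2f1(-0.5, 0.5, 1.0, t * t))
    return float(hyp2f1(0.5, 0.5, 2.0, 1.0 / (t * t)) / (2.0 * t))


def surface_potential_isolated(
    r: float | np.ndarray,
    geom: CellGeometry,
    medium: ElectrolyteInterface,
    *,
    rtol: float = 1e-6,
    accelerate: bool = True,
) -> float | np.ndarray:
    """Scaled self-potential ``Phi_self(r)/Phi0`` of one isolated charged disk.

    ``r`` is a length in the same units as ``geom``; the disk keeps the
    density ``sigma0 (R/r0)^2`` of the cell problem, so the cell radius enters
    only through the scales ``Phi0`` and ``sigma_bar``. Finite for all ``r``
    and screened to zero at large ``r``.

    The slowly decaying large-``y`` part of the Hankel integrand,
    ``J0(yx) J1(y rho0) / (rho0 lam (1+eta) y)``, is split off and integrated
    in closed form (Weber-Schafheitlin); the remainder decays like ``y^-4``
    and is handled by the partitioned quadrature. This keeps the result
    accurate even when ``r`` is close to the disk edge, where the two Bessel
    frequencies beat arbitrarily slowly.
    """
    lam = medium.lD / geom.R
    rho0 = geom.r0_over_R
    eta = medium.eps_ratio
    c = lam * (1.0 + eta)

    def one(r_val: float) -> float:
        x = r_val / geom.R
        if x < 0:
            raise ValueError("r must be >= 0")

        def f(y: float) -> float:
            return (
                j0(y * x)
                * j1(y * rho0)
                / rho0
                * (1.0 / mode_denominator(y, lam, eta) - 1.0 / (c * y))
            )

        cutoff = max(400.0, (50.0 / x if x > 0 else 0.0), 50.0 / rho0, 50.0 / lam)
        remainder = _oscillatory_integral(
            f,
            [(x, 0), (rho0, 1)],
            rtol=rtol,
            accelerate=accelerate,
            cutoff=cutoff,
        )
        return remainder + _ws_ratio(x, rho0) / (rho0 * c)

    if np.isscalar(r):
        return one(float(r))
    return np.array([one(float(v)) for v in np.asarray(r, dtype=float)])


def surface_potential_point_isolated(
    r: float | np.ndarray,
    medium: ElectrolyteInterface,
    R_scale: float,
    *,
    rtol: float = 1e-6,
) -> float | np.ndarray:
    """Scaled self-potential of a single interfacial point charge.

    The ``r0 -> 0`` limit of :func:`surface_potential_isolated`; the
    potential of one point charge at a screened dielectric interface.
    ``R_scale`` fixes the reference cell radius entering ``Phi0`` and the
    condensed density (the value is proportional to ``R_scale^2``). Diverges
    as ``r -> 0``.

    The non-decaying large-``y`` part of the integrand, ``J0(yx) / (2 lam
    (1+eta))``, integrates in closed form to ``1/(2 lam (1+eta) x)``; the
    remainder decays absolutely like ``y^-5/2``.
    """
    lam = medium.lD / R_scale
    eta = medium.eps_ratio
    c = lam * (1.0 + eta)

    def one(r_val: float) -> float:
        x = r_val / R_scale
        if x <= 0:
            raise ValueError("the point-charge potential diverges at r = 0; r must be > 0")

        def f(y: float) -> float:
            return 0.5 * j0(y * x) * (y / mode_denominator(y, lam, eta) - 1.0 / c)

        remainder = _oscillatory_integral(f, [(x, 0)], rtol=rtol, n_direct=16, n_tail=48)
        return remainder + 1.0 / (2.0 * c * x)

    if np.isscalar(r):
        return one(float(r))
    return np.array([one(float(v)) for v in np.asarray(r, dtype=float)])


def hurd_asymptotic(
    r: float | np.ndarray, medium: ElectrolyteInterface, R_scale: float
) -> float | np.ndarray:
    """Screened-Coulomb + dipole asymptote of the interfacial point-charge potential.

        Phi_self(r)/Phi0 ~ (1/2)(R/lD)^2 [ (lD/r) e^(-r/lD) + (eps_l/eps_w)(lD/r)^3 ]

    valid for ``eps_l << eps_w`` and ``r >> lD``. The first term is the
    in-electrolyte screened Coulomb interaction; the second the unscreened
    dipole field (charge + counterion cloud) transmitted through the
    salt-free medium.
    """
    r = np.asarray(r, dtype=float) if not np.isscalar(r) else float(r)
    lD = medium.lD
    return (
        0.5
        * (R_scale / lD) ** 2
        * ((lD / r) * np.exp(-r / lD) + medium.eps_ratio * (lD / r) ** 3)
    )


def delta_surface_potential(
    r_over_R: np.ndarray,
    geom: CellGeometry,
    medium: ElectrolyteInterface,
    ctrl: SeriesControl = SeriesControl(),
) -> RadialProfile:
    """Difference potential ``DeltaPhi_s = Phi_s - Phi_self`` on a radial grid.

    The potential felt inside one cell from every *other* charged disk: the
    in-cell series potential minus the isolated-disk self-potential at the
    same radius. Finite everywhere, including at the charge, because the
    short-range singular parts cancel; for point charges the cancellation is
    realized at small finite ``r0``, never by subtracting two separately
    divergent evaluations.
    """
    grid = np.asarray(r_over_R, dtype=float)
    cell_vals = surface_potential_cell(grid, geom, medium, ctrl)
    self_vals = surface_potential_isolated(grid * geom.R, geom, medium)
    meta = {
        "R": geom.R,
        "r0": geom.r0,
        "lD": medium.lD,
        "eps_ratio": medium.eps_ratio,
        "n_max": ctrl.n_max,
        "rel_tol": ctrl.rel_tol,
    }
    return RadialProfile(
        r_over_R=grid,
        values=np.asarray(cell_vals) - self_vals,
        kind="potential_difference",
        meta=meta,
    )
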