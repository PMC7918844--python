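"""Fourier-Bessel series solutions inside the Wigner-Seitz cell.

A charged disk of radius ``r0`` sits at the centre of a cylindrical cell of
radius ``R`` on the plane ``z = 0`` separating an electrolyte (Debye length
``lD``, dielectric constant ``eps_w``, half-space ``z > 0``) from a salt-free
medium (``eps_l``, ``z < 0``). The potential obeys the linearized
Poisson-Boltzmann (Debye-Hückel) equation above the interface and the Laplace
equation below it, with a no-flux condition at the cell boundary ``r = R``.
Expanding in the modes ``J0(yn r/R)`` (``yn`` the zeros of J1) reduces the
problem to algebra: every interface quantity is a series over the modes with
the shared denominator

    D(yn) = sqrt((yn lD/R)^2 + 1) + (eps_l/eps_w) (lD/R) yn.

All results are scaled: charge by the cell average ``sigma0``, potential by
the continuum surface potential ``Phi0 = sigma0 lD / (eps0 eps_w)``.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.special import j0, j1

from .basis import j1_zeros, sigma_coefficients
from .core import CellGeometry, ElectrolyteInterface, RadialProfile, SeriesControl

__all__ = [
    "mode_denominator",
    "sigma_profile",
    "surface_potential_cell",
    "surface_potential_point_cell",
    "potential_field",
    "sigma_profile_result",
    "surface_potential_result",
]


def mode_denominator(
    y: np.ndarray | float, lD_over_R: float, eps_ratio: float
) -> np.ndarray | float:
    """Screening denominator ``sqrt((y lD/R)^2 + 1) + (eps_l/eps_w)(lD/R) y``.

    The first term is the Debye-Hückel decay rate of mode ``y`` in the
    electrolyte (in units of ``1/lD``); the second is the Laplace decay into
    the salt-free medium weighted by the dielectric ratio.
    """
    y = np.asarray(y, dtype=float) if not np.isscalar(y) else y
    return np.sqrt((y * lD_over_R) ** 2 + 1.0) + eps_ratio * lD_over_R * y


def _compensated_sum(terms: np.ndarray) -> np.ndarray | float:
    """Sum mode contributions in fixed order with exact (fsum) accumulation."""
    if terms.ndim == 1:
        return math.fsum(terms)
    flat = terms.reshape(terms.shape[0], -1)
    out = np.fromiter(
        (math.fsum(flat[:, k]) for k in range(flat.shape[1])),
        dtype=float,
        count=flat.shape[1],
    )
    return out.reshape(terms.shape[1:])


def _series(term_fn, ctrl: SeriesControl):
    """Partial sum over modes 1..n with optional adaptive doubling of n.

    ``term_fn(n)`` must return the stacked mode contributions ``(n, *grid)``
    for modes 1..n. Convergence is declared when a doubling changes the
    result by less than ``rel_tol`` on the O(1) scale of the scaled fields,
    i.e. ``max|delta| <= rel_tol * max(1, max|value|)``.
    """
    if not ctrl.adaptive:
        return _compensated_sum(term_fn(ctrl.n_max)), ctrl.n_max
    n = min(ctrl.n_start, ctrl.n_max)
    value = _compensated_sum(term_fn(n))
    while n < ctrl.n_max:
        n = min(2 * n, ctrl.n_max)
        new = _compensated_sum(term_fn(n))
        delta = np.max(np.abs(np.asarray(new) - np.asarray(value)))
        value = new
        if delta <= ctrl.rel_tol * max(1.0, float(np.max(np.abs(np.asarray(new))))):
            break
    return value, n


def sigma_profile(
    r_over_R: float | np.ndarray,
    geom: CellGeometry,
    ctrl: SeriesControl = SeriesControl(),
) -> float | np.ndarray:
    """Scaled surface charge density ``sigma(r)/sigma0`` from its Bessel series.

    The exact profile is the step ``(R/r0)^2`` inside the disk and 0 outside,
    taking the midpoint value at ``r = r0`` (Heaviside ``u(0) = 1/2``
    convention); the partial sum converges to that target pointwise.
    """
    x = np.asarray(r_over_R, dtype=float)

    def terms(n: int) -> np.ndarray:
        c = sigma_coefficients(geom.r0_over_R, n)[1:]
        yn = j1_zeros(n).zeros[1:]
        return c[(...,) + (None,) * x.ndim] * j0(np.multiply.outer(yn, x))

    value, _ = _series(terms, ctrl)
    return 1.0 + value if np.isscalar(r_over_R) else 1.0 + np.asarray(value)


def surface_potential_cell(
    r_over_R: float | np.ndarray,
    geom: CellGeometry,
    medium: ElectrolyteInterface,
    ctrl: SeriesControl = SeriesControl(),
) -> float | np.ndarray:
    """Scaled surface potential ``Phi_s(r)/Phi0`` of the charged disk in its cell.

    Depends only on ``r/R``, ``r0/R``, ``lD/R`` and ``eps_l/eps_w``. For the
    uniformly charged cell ``r0 = R`` every mode coefficient vanishes and the
    result is identically 1 (the continuum value), for any screening length
    and dielectric ratio.
    """
    x = np.asarray(r_over_R, dtype=float)
    lam = medium.lD / geom.R

    def terms(n: int) -> np.ndarray:
        c = sigma_coefficients(geom.r0_over_R, n)[1:]
        yn = j1_zeros(n).zeros[1:]
        w = c / mode_denominator(yn, lam, medium.eps_ratio)
        return w[(...,) + (None,) * x.ndim] * j0(np.multiply.outer(yn, x))

    value, _ = _series(terms, ctrl)
    return 1.0 + value if np.isscalar(r_over_R) else 1.0 + np.asarray(value)


def _averaged_partial_sum(terms: np.ndarray, x: float) -> float:
    """Limit of a conditionally convergent partial-sum sequence at one radius.

    The point-charge series terms oscillate like ``J0(yn x)`` with phase step
    ``pi x`` per mode, so raw partial sums at cutoff n oscillate with the
    amplitude of the n'th term (decaying only like 1/sqrt(n)). Smoothing the
    tail of the partial-sum sequence twice with a moving average spanning one
    oscillation period (``~2/x`` modes) removes the oscillation to second
    order while never reordering the terms.
    """
    partial = np.cumsum(terms)
    w = max(2, int(np.ceil(2.0 / max(x, 1e-6))))
    if partial.size < 3 * w:
        return float(partial[-1])
    seg = partial[-(3 * w):]
    kernel = np.full(w, 1.0 / w)
    for _ in range(2):
        seg = np.convolve(seg, kernel, mode="valid")
    return float(seg[-1])


def surface_potential_point_cell(
    r_over_R: float | np.ndarray,
    medium: ElectrolyteInterface,
    ctrl: SeriesControl,
    *,
    R: float | None = None,
    accelerate: bool = True,
) -> float | np.ndarray:
    """Scaled surface potential of a point charge at the cell centre.

    The ``r0 -> 0`` limit of :func:`surface_potential_cell`: each coefficient
    ``(2R/r0) J1(yn r0/R)`` tends to ``yn``, leaving

        Phi_s(r)/Phi0 = 1 + sum_n J0(yn r/R) / (J0(yn)^2 D(yn)).

    The sum converges only conditionally (and diverges at ``r = 0``, the
    location of the charge), so the caller chooses ``ctrl.n_max`` explicitly;
    no adaptive refinement is attempted. By default the oscillating tail of
    the partial sums is smoothed out (``accelerate=True``); with
    ``accelerate=False`` the raw fixed-order partial sum is returned, whose
    residual oscillation decays only like ``1/sqrt(n_max)``. ``R`` defaults
    to the Debye length as the unit of ``lD/R``; pass ``R`` to set ``lD/R``
    directly.
    """
    x = np.asarray(r_over_R, dtype=float)
    if np.any(x <= 0):
        raise ValueError(
            "the point-charge surface potential diverges at r = 0; r/R must be > 0"
        )
    lam = medium.lD / (R if R is not None else medium.lD)
    table = j1_zeros(ctrl.n_max)
    yn = table.zeros[1:]
    w = 1.0 / (table.j0_at_zeros[1:] ** 2 * mode_denominator(yn, lam, medium.eps_ratio))

    def one(x_val: float) -> float:
        terms = w * j0(yn * x_val)
        if accelerate:
            return _averaged_partial_sum(terms, x_val)
        return float(_compensated_sum(terms))

    if np.isscalar(r_over_R):
        return 1.0 + one(float(x))
    return 1.0 + np.array([one(float(v)) for v in x])


def potential_field(
    r_over_R: float | np.ndarray,
    z_over_R: float,
    geom: CellGeometry,
    medium: ElectrolyteInterface,
    ctrl: SeriesControl = SeriesControl(),
) -> float | np.ndarray:
    """Scaled potential ``Phi(r, z)/Phi0`` anywhere in the cell.

    ``z >= 0`` evaluates the Debye-Hückel branch (each mode decays with rate
    ``sqrt((yn/R)^2 + 1/lD^2)``); ``z <= 0`` the Laplace branch (rate
    ``yn/R``). Both branches share the mode amplitudes, so the potential is
    continuous across the interface.
    """
    x = np.asarray(r_over_R, dtype=float)
    lam = medium.lD / geom.R
    zeta = float(z_over_R)

    def terms(n: int) -> np.ndarray:
        c = sigma_coefficients(geom.r0_over_R, n)
        yn = j1_zeros(n).zeros
        amp = np.empty_like(c)
        amp[0] = 1.0
        amp[1:] = c[1:] / mode_denominator(yn[1:], lam, medium.eps_ratio)
        if zeta >= 0:
            decay = np.exp(-zeta * np.sqrt(yn**2 + 1.0 / lam**2))
        else:
            decay = np.exp(zeta * yn)
        w = amp * decay
        return w[(...,) + (None,) * x.ndim] * j0(np.multiply.outer(yn, x))

    value, _ = _series(terms, ctrl)
    return value if np.isscalar(r_over_R) else np.asarray(value)


def _meta(geom: CellGeometry, medium: ElectrolyteInterface | None, ctrl: SeriesControl) -> dict:
    meta = {
        "R": geom.R,
        "r0": geom.r0,
        "r0_over_R": geom.r0_over_R,
        "n_max": ctrl.n_max,
        "rel_tol": ctrl.rel_tol,
    }
    if medium is not None:
        meta.update({"lD": medium.lD, "lD_over_R": medium.lD / geom.R, "eps_ratio": medium.eps_ratio})
    return meta


def sigma_profile_result(
    r_over_R: np.ndarray, geom: CellGeometry, ctrl: SeriesControl = SeriesControl()
) -> RadialProfile:
    """Charge-density profile packaged with its parameter metadata."""
    values = sigma_profile(r_over_R, geom, ctrl)
    return RadialProfile(r_over_R=r_over_R, values=values, kind="charge", meta=_meta(geom, None, ctrl))


def surface_potential_result(
    r_over_R: np.ndarray,
    geom: CellGeometry,
    medium: ElectrolyteInterface,
    ctrl: SeriesControl = SeriesControl(),
) -> RadialProfile:
    """Surface-potential profile packaged with its parameter metadata."""
    values = surface_potential_cell(r_over_R, geom, medium, ctrl)
    return RadialProfile(
        r_over_R=r_over_R, values=values, kind="potential", meta=_meta(geom, medium, ctrl)
    )
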