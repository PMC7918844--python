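"""Bessel-function basis for the Wigner-Seitz cell expansions.

The axisymmetric cell problem expands every interface quantity in the modes
``J0(yn r/R)`` whose radial derivative vanishes at the cell boundary, i.e. the
``yn`` are the ordered zeros of ``J1`` starting with ``y0 = 0``. This module
owns the zero table (cached, bitwise reproducible) and the Fourier-Bessel
coefficients of the step-like disk charge density.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import j0, j1

__all__ = ["BesselZeroTable", "j1_zeros", "sigma_coefficients"]

#: refinement target for each root, |J1(yn)| below this is enforced
_ROOT_TOL = 1e-12


@dataclass(frozen=True)
class BesselZeroTable:
    """Ordered zeros ``y0=0 < y1 < y2 < ...`` of the Bessel function J1.

    ``j0_at_zeros`` caches ``J0(yn)``, which enters every series denominator;
    at a zero of J1 the envelope gives ``J0(yn)^2 ~ 2/(pi yn)`` for large n.
    """

    zeros: np.ndarray
    j0_at_zeros: np.ndarray

    @property
    def n_max(self) -> int:
        return self.zeros.size - 1

    def __len__(self) -> int:
        return self.zeros.size


def _mcmahon_guess(n: np.ndarray) -> np.ndarray:
    # McMahon expansion for the n'th positive zero of J1 (mu = 4 nu^2 = 4):
    # yn ~ b - 3/(8b) - 3/(128 b^3) with b = (n + 1/4) pi.
    b = (n + 0.25) * np.pi
    return b - 3.0 / (8.0 * b) - 3.0 / (128.0 * b**3)


def _j1_prime(y: np.ndarray) -> np.ndarray:
    # J1'(y) = J0(y) - J1(y)/y, regular for y > 0
    return j0(y) - j1(y) / y


@lru_cache(maxsize=64)
def _zeros_cached(n_max: int) -> tuple[np.ndarray, np.ndarray]:
    n = np.arange(1, n_max + 1, dtype=float)
    y = _mcmahon_guess(n)
    # Newton refinement; 4 iterations take the McMahon seed (already accurate
    # to ~1e-4 at n=1, better beyond) to machine precision in fixed order.
    for _ in range(4):
        y = y - j1(y) / _j1_prime(y)
    bad = np.flatnonzero(np.abs(j1(y)) > _ROOT_TOL)
    for k in bad:  # bracketed fallback; the spacing pi guarantees uniqueness
        lo = (k + 1 - 0.25) * np.pi
        hi = (k + 1 + 0.75) * np.pi
        y[k] = brentq(j1, lo, hi, xtol=1e-13)
    zeros = np.concatenate(([0.0], y))
    zeros.setflags(write=False)
    j0z = j0(zeros)
    j0z.setflags(write=False)
    return zeros, j0z


def j1_zeros(n_max: int) -> BesselZeroTable:
    """Return the table of the first ``n_max + 1`` zeros of J1, including y0 = 0.

    Deterministic and cached: repeated calls with the same ``n_max`` (and any
    smaller one, served as a view) reuse one bitwise-identical table.
    """
    if not isinstance(n_max, (int, np.integer)) or isinstance(n_max, bool):
        raise TypeError(f"n_max must be an integer, got {type(n_max).__name__}")
    if n_max < 0:
        raise ValueError(f"n_max must be >= 0, got {n_max}")
    if n_max == 0:
        return BesselZeroTable(zeros=np.zeros(1), j0_at_zeros=np.ones(1))
    # round the cache key up to a power of two so nearby requests share a table
    key = 1 << int(np.ceil(np.log2(n_max)))
    zeros, j0z = _zeros_cached(key)
    return BesselZeroTable(zeros=zeros[: n_max + 1], j0_at_zeros=j0z[: n_max + 1])


def sigma_coefficients(r0_over_R: float, n_max: int) -> np.ndarray:
    """Fourier-Bessel coefficients ``sigma_n / sigma0`` of the step charge density.

    A disk of radius ``r0`` inside a cell of radius ``R``, carrying uniform
    density ``sigma0 (R/r0)^2``, expands as
    ``sigma(r)/sigma0 = sum_n (sigma_n/sigma0) J0(yn r/R)`` with

        sigma_0/sigma0 = 1,
        sigma_n/sigma0 = (2R/r0) J1(yn r0/R) / (yn J0(yn)^2),   n >= 1.

    The point-charge case is handled analytically downstream; ``r0_over_R = 0``
    is rejected here.
    """
    if not (0 < r0_over_R <= 1):
        raise ValueError(f"r0_over_R must lie in (0, 1], got {r0_over_R}")
    coeffs = np.empty(n_max + 1)
    coeffs[0] = 1.0
    if r0_over_R == 1.0:
        # uniform cell: J1(yn) = 0 by definition of the yn, so every mode
        # coefficient vanishes identically (not merely to root tolerance)
        coeffs[1:] = 0.0
        return coeffs
    table = j1_zeros(n_max)
    if n_max >= 1:
        yn = table.zeros[1:]
        coeffs[1:] = (
            (2.0 / r0_over_R)
            * j1(yn * r0_over_R)
            / (yn * table.j0_at_zeros[1:] ** 2)
        )
    return coeffs
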