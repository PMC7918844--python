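"""Shared domain types: cell geometry, electrolyte interface, series control, profiles.

All numerical work in :mod:`dhdl` is carried out in dimensionless variables
(``r/R``, ``lD/R``, ``eps_l/eps_w``); these containers hold the dimensional
inputs and expose the reduced parameters the solvers actually consume.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
from scipy import constants

__all__ = [
    "CellGeometry",
    "ElectrolyteInterface",
    "SeriesControl",
    "RadialProfile",
    "debye_length",
]


def debye_length(eps_w: float, temperature: float, n0: float) -> float:
    """Debye screening length ``lD = sqrt(eps_w eps0 kB T / (2 e^2 n0))``.

    Parameters
    ----------
    eps_w : relative dielectric constant of the electrolyte.
    temperature : absolute temperature in K.
    n0 : bulk number density of each ion species of a 1:1 salt, in 1/m^3.
    """
    if eps_w <= 0 or temperature <= 0 or n0 <= 0:
        raise ValueError("eps_w, temperature and n0 must be positive")
    return float(
        np.sqrt(
            eps_w * constants.epsilon_0 * constants.k * temperature
            / (2.0 * constants.e**2 * n0)
        )
    )


@dataclass(frozen=True)
class CellGeometry:
    """Cylindrical Wigner-Seitz cell of radius ``R`` holding a charged disk of radius ``r0``.

    The disk carries all the charge assigned to the cell, condensed to the
    uniform density ``sigma_bar = sigma0 (R/r0)^2`` so the cell-averaged
    density is always ``sigma0``.
    """

    R: float
    r0: float

    def __post_init__(self) -> None:
        if not (self.R > 0):
            raise ValueError(f"cell radius R must be positive, got {self.R}")
        if not (0 < self.r0 <= self.R):
            raise ValueError(
                f"disk radius r0 must satisfy 0 < r0 <= R, got r0={self.r0}, R={self.R}"
            )

    @property
    def r0_over_R(self) -> float:
        return self.r0 / self.R

    @property
    def sigma_bar_over_sigma0(self) -> float:
        """In-disk charge density relative to the cell average, ``(R/r0)^2``."""
        return (self.R / self.r0) ** 2


@dataclass(frozen=True)
class ElectrolyteInterface:
    """Planar interface between a screening electrolyte and a salt-free dielectric.

    Parameters
    ----------
    lD : Debye length of the electrolyte (same length unit as the geometry).
    eps_ratio : dielectric ratio ``eps_l / eps_w`` of the salt-free medium to
        the electrolyte (>= 0; 0 switches the lower half-space off entirely).
    eps_w, temperature, n0 : optional physical block. When all three are
        supplied, ``lD`` must be consistent with the salt solution they
        describe (checked to 1e-6 relative) and dimensional output becomes
        available via :func:`dhdl.free_energy.to_physical_units`.
    """

    lD: float
    eps_ratio: float
    eps_w: float | None = None
    temperature: float | None = None
    n0: float | None = None

    def __post_init__(self) -> None:
        if not (self.lD > 0):
            raise ValueError(f"Debye length must be positive, got {self.lD}")
        if self.eps_ratio < 0:
            raise ValueError(f"eps_ratio must be >= 0, got {self.eps_ratio}")
        if self.has_physical_block:
            lD_salt = debye_length(self.eps_w, self.temperature, self.n0)
            if abs(lD_salt - self.lD) > 1e-6 * self.lD:
                raise ValueError(
                    "inconsistent physical block: salt parameters give "
                    f"lD={lD_salt:.8g} but lD={self.lD:.8g} was supplied"
                )

    @property
    def has_physical_block(self) -> bool:
        return None not in (self.eps_w, self.temperature, self.n0)

    @classmethod
    def from_salt(
        cls,
        eps_w: float,
        temperature: float,
        n0: float,
        eps_ratio: float,
    ) -> "ElectrolyteInterface":
        """Build the interface from salt-solution parameters, deriving ``lD``."""
        return cls(
            lD=debye_length(eps_w, temperature, n0),
            eps_ratio=eps_ratio,
            eps_w=eps_w,
            temperature=temperature,
            n0=n0,
        )


@dataclass(frozen=True)
class SeriesControl:
    """Truncation and convergence control for the Fourier-Bessel series.

    ``n_max`` is the hard truncation order (number of nonzero Bessel modes).
    When ``adaptive`` is set, partial sums are refined by doubling the mode
    count from ``n_start`` until the result changes by less than ``rel_tol``
    or ``n_max`` is reached; otherwise exactly ``n_max`` modes are summed.
    """

    n_max: int = 4096
    rel_tol: float = 1e-6
    adaptive: bool = True
    n_start: int = 64

    def __post_init__(self) -> None:
        if self.n_max < 1:
            raise ValueError(f"n_max must be >= 1, got {self.n_max}")
        if not (self.rel_tol > 0):
            raise ValueError(f"rel_tol must be positive, got {self.rel_tol}")
        if self.n_start < 1:
            raise ValueError(f"n_start must be >= 1, got {self.n_start}")


_PROFILE_KINDS = ("charge", "potential", "potential_difference")


@dataclass
class RadialProfile:
    """A scaled radial profile on the interface plane.

    ``values`` holds sigma(r)/sigma0, Phi_s(r)/Phi0 or DeltaPhi_s(r)/Phi0 on
    the strictly increasing grid ``r_over_R``; ``kind`` tags which. ``meta``
    records the full parameter set so written files are self-describing.
    """

    r_over_R: np.ndarray
    values: np.ndarray
    kind: str
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r_over_R = np.asarray(self.r_over_R, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in _PROFILE_KINDS:
            raise ValueError(f"kind must be one of {_PROFILE_KINDS}, got {self.kind!r}")
        if self.r_over_R.ndim != 1 or self.r_over_R.shape != self.values.shape:
            raise ValueError("r_over_R and values must be matching 1-D arrays")
        if self.r_over_R.size > 1 and not np.all(np.diff(self.r_over_R) > 0):
            raise ValueError("r_over_R grid must be strictly increasing")

    def to_csv(self, path: str | Path) -> Path:
        """Write ``(r_over_R, value, kind_tag)`` rows under a JSON metadata header."""
        path = Path(path)
        header = json.dumps(self.meta, sort_keys=True)
        with path.open("w") as fh:
            fh.write(f"# {header}\n")
            fh.write("r_over_R,value,kind_tag\n")
            for x, v in zip(self.r_over_R, self.values):
                fh.write(f"{x:.12g},{v:.12g},{self.kind}\n")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "RadialProfile":
        path = Path(path)
        with path.open() as fh:
            first = fh.readline()
            meta = json.loads(first.lstrip("# ").strip()) if first.startswith("#") else {}
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        kind = str(df["kind_tag"].iloc[0])
        return cls(
            r_over_R=df["r_over_R"].to_numpy(),
            values=df["value"].to_numpy(),
            kind=kind,
            meta=meta,
        )


def default_radial_grid(n: int = 201) -> np.ndarray:
    """Uniform evaluation grid on [0, 1] (in units of the cell radius)."""
    return np.linspace(0.0, 1.0, n)
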