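"""Named parameter scans for the standard surveys of the model.

Each preset captures one of the canonical parameter studies of the cell
model: how the surface potential responds to disk size and to cell size, how
the free-energy truncation converges, and how F/F0 and the scaled free
energy fs(s) traverse the screening and charge-density axes.
"""
from __future__ import annotations

import numpy as np

__all__ = ["PRESETS", "preset_names"]

#: disk-size scan: fixed cell and screening, shrink the charged disk
DISK_SIZE_SCAN = {
    "kind": "potential",
    "lD_over_R": 1.0,
    "eps_ratio": 1.0,
    "r0_over_R": [0.4, 0.2, 0.1, 0.05, 0.025],
}

#: cell-size scan: fixed disk (r0 = lD), grow the cell toward isolation
CELL_SIZE_SCAN = {
    "kind": "potential_vs_cell",
    "r0_over_lD": 1.0,
    "eps_ratio": 1.0,
    "R_over_lD": [1.0, 1.2, 1.5, 2.0, 4.0],
    "include_isolated": True,
}

#: truncation scan: free-energy ratio vs disk size at several mode cutoffs
TRUNCATION_SCAN = {
    "kind": "free_energy",
    "lD_over_R": 1.0,
    "eps_ratio": 1.0,
    "n_max": [10, 33, 100, 333, 1000],
    "r0_over_R": list(np.round(np.logspace(np.log10(0.01), 0.0, 25), 6)),
}

#: screening scan: point-charge F/F0 vs lD/R for several dielectric ratios
SCREENING_SCAN = {
    "kind": "free_energy_point",
    "eps_ratio": [0.0, 0.1, 0.5, 1.0, 2.0],
    "lD_over_R": list(np.round(np.logspace(-1, 1.5, 11), 6)),
}

#: charge-density scan: scaled free energy fs vs scaled density s
CHARGE_DENSITY_SCAN = {
    "kind": "sweep",
    "eps_ratio": [0.0, 0.01, 0.1, 1.0],
    "s": list(np.logspace(-4, 0, 9)),
}

PRESETS = {
    "disk-size-scan": DISK_SIZE_SCAN,
    "cell-size-scan": CELL_SIZE_SCAN,
    "truncation-scan": TRUNCATION_SCAN,
    "screening-scan": SCREENING_SCAN,
    "charge-density-scan": CHARGE_DENSITY_SCAN,
}


def preset_names() -> list[str]:
    return sorted(PRESETS)
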