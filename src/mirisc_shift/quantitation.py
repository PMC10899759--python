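"""Absolute protein copy numbers from densitometry, compartment ratios, and
scratch-assay migration rates.

A serial dilution of recombinant protein run on the same blot gives a linear
standard curve (intensity = slope * mass + intercept). Band intensity of a
fractionated lysate lane then converts to loaded mass, to molecules via the
molar mass and Avogadro's number, and to copies per cell via the lysate cell
concentration (default 10 000 cells/ul) and loaded volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.constants import Avogadro

log = logging.getLogger(__name__)

DEFAULT_CELLS_PER_UL = 10_000.0
#: literature molar mass of human AGO2 (g/mol); user-overridable, not a fit
AGO2_MOLAR_MASS = 97_000.0


@dataclass
class StandardCurve:
    slope: float       # intensity units per ng
    intercept: float
    r2: float
    mass_range_ng: tuple[float, float]


@dataclass
class CopyEstimate:
    fraction: str
    condition: str
    copies_per_cell: float
    mass_ng: float
    flag: str = "ok"   # ok | below_intercept | extrapolated


def fit_standard_curve(masses_ng, intensities) -> StandardCurve:
    """OLS line through the dilution series; >=3 distinct masses required."""
    m = np.asarray(masses_ng, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if np.unique(m).size < 3:
        raise ValueError("standard curve needs >=3 distinct masses")
    res = stats.linregress(m, y)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        mass_range_ng=(float(m.min()), float(m.max())),
    )


def copies_per_cell(
    intensity_au: float,
    curve: StandardCurve,
    cells_per_ul: float = DEFAULT_CELLS_PER_UL,
    loaded_volume_ul: float = 10.0,
    molar_mass: float = AGO2_MOLAR_MASS,
    fraction: str = "",
    condition: str = "",
) -> CopyEstimate:
    """Convert a band intensity to protein copies per cell.

    mass_ng = (intensity - intercept)/slope; copies = mass * N_A / molar
    mass / cells loaded. Intensities below the intercept clamp to zero with
    a flag; masses outside the calibrated range are flagged extrapolated.
    """
    if curve.slope <= 0:
        raise ValueError("standard curve slope must be positive")
    if cells_per_ul <= 0 or loaded_volume_ul <= 0 or molar_mass <= 0:
        raise ValueError("cells_per_ul, loaded_volume_ul and molar_mass must be positive")
    mass_ng = (intensity_au - curve.intercept) / curve.slope
    flag = "ok"
    if mass_ng < 0:
        mass_ng, flag = 0.0, "below_intercept"
    elif not curve.mass_range_ng[0] <= mass_ng <= curve.mass_range_ng[1]:
        flag = "extrapolated"
    molecules = mass_ng * 1e-9 / molar_mass * Avogadro
    n_cells = cells_per_ul * loaded_volume_ul
    return CopyEstimate(fraction, condition, molecules / n_cells, mass_ng, flag)


def compartment_ratio(nucleus: CopyEstimate, cytoplasm: CopyEstimate,
                      whole_cell: CopyEstimate | None = None) -> dict:
    """Nuclear:cytoplasmic copy ratio, with a conservation residual if the
    whole-cell estimate is supplied (reported, not enforced)."""
    if cytoplasm.copies_per_cell == 0:
        raise ValueError("cytoplasmic copies are zero; ratio undefined")
    out = dict(
        nucleus_copies=nucleus.copies_per_cell,
        cytoplasm_copies=cytoplasm.copies_per_cell,
        ratio=nucleus.copies_per_cell / cytoplasm.copies_per_cell,
    )
    if whole_cell is not None:
        total = nucleus.copies_per_cell + cytoplasm.copies_per_cell
        out["conservation_residual"] = total - whole_cell.copies_per_cell
    return out


def migration_rate(timepoints_h, widths_um) -> dict:
    """Wound-edge front speed from a scratch-assay width series.

    Per-interval speed relative to t=0: (width(0) - width(t)) / (2 t) -- the
    factor 2 because both edges advance. Negative closure clips to 0 with a
    flag.
    """
    t = np.asarray(timepoints_h, dtype=float)
    w = np.asarray(widths_um, dtype=float)
    if t.size < 2:
        raise ValueError("need >=2 timepoints")
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must strictly increase from 0")
    if (w < 0).any():
        raise ValueError("widths must be non-negative")
    closure = w[0] - w[1:]
    rates = closure / (2.0 * t[1:])
    flag = "ok"
    if (rates < 0).any():
        flag = "negative_closure" if (rates < 0).all() else "partial_negative_closure"
        rates = np.clip(rates, 0.0, None)
    return dict(
        timepoints_h=t[1:].tolist(),
        rates_um_per_h=rates.tolist(),
        mean_rate_um_per_h=float(rates.mean()),
        flag=flag,
    )
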