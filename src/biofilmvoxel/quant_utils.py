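"""Absolute quantification arithmetic: qPCR copies, standard curves, normalizations.

The absolute copy number of a DNA template follows

    copies/μl = conc(ng/μl) × N_A / (length(bp) × 1e9 × m_bp)

with Avogadro's number N_A = 6.022e23 molecules/mol and m_bp the average
molecular weight of a base pair in Daltons. The default m_bp is 650 (the
value used in the copy equation of common qPCR calculators); 660 is the
other widely quoted average and is available via the constants object — the
two conventions differ by ~1.5% and the choice is recorded with the result.

Unknown samples are quantified by interpolating their Ct on a least-squares
standard curve Ct = intercept + slope·log10(copies); amplification
efficiency = 10^(−1/slope) − 1 (slope −3.3219 = −1/log10 2 ⇔ 100%).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CopyEquationConstants",
    "QpcrStandardCurve",
    "NormalizedCount",
    "template_copies",
    "fit_standard_curve",
    "interpolate_copies",
    "normalize_per_root",
    "percent_increase",
]

AVOGADRO = 6.022e23


@dataclasses.dataclass(frozen=True)
class CopyEquationConstants:
    avogadro: float = AVOGADRO  # molecules/mol
    per_bp_mass_da: float = 650.0  # Daltons per base pair (660 also in use)
    ng_per_g: float = 1e9

    def __post_init__(self):
        if self.avogadro <= 0 or self.per_bp_mass_da <= 0 or self.ng_per_g <= 0:
            raise ValueError("all copy-equation constants must be positive")


def template_copies(
    conc_ng_per_ul: float,
    length_bp: int,
    constants: CopyEquationConstants = CopyEquationConstants(),
) -> float:
    """Copies per μl of a template of ``length_bp`` at ``conc_ng_per_ul``."""
    if length_bp < 1:
        raise ValueError(f"template length must be >= 1 bp, got {length_bp}")
    if conc_ng_per_ul < 0:
        raise ValueError("concentration must be nonnegative")
    return conc_ng_per_ul * constants.avogadro / (length_bp * constants.ng_per_g * constants.per_bp_mass_da)


@dataclasses.dataclass(frozen=True)
class QpcrStandardCurve:
    log10_copies: np.ndarray
    ct: np.ndarray
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency 10^(−1/slope) − 1 (1.0 = perfect doubling)."""
        return 10 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(points: Sequence) -> QpcrStandardCurve:
    """Least-squares line Ct = intercept + slope·log10(copies) through standards.

    ``points`` is a sequence of (copies, Ct) pairs; at least two distinct copy
    numbers are required. A non-negative slope (not a dilution series) is
    warned about, not rejected.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (copies, Ct) standard points")
    copies, ct = pts[:, 0], pts[:, 1]
    if np.any(copies <= 0):
        raise ValueError("standard copy numbers must be positive")
    x = np.log10(copies)
    if np.unique(x).size < 2:
        raise ValueError("standards must span >= 2 distinct copy numbers")
    fit = stats.linregress(x, ct)
    if fit.slope >= 0:
        warnings.warn(
            f"standard-curve slope {fit.slope:.3g} is not negative; "
            "not a valid dilution series",
            stacklevel=2,
        )
    return QpcrStandardCurve(
        log10_copies=x,
        ct=ct,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def interpolate_copies(curve: QpcrStandardCurve, ct: float) -> float:
    """Copies for a sample Ct: 10^((ct − intercept)/slope).

    Values outside the standards' Ct range are extrapolated with a warning.
    """
    if curve.slope == 0:
        raise ValueError("cannot interpolate on a zero-slope standard curve")
    lo, hi = float(curve.ct.min()), float(curve.ct.max())
    if not (lo <= ct <= hi):
        warnings.warn(
            f"Ct {ct} outside the standard range [{lo}, {hi}]; extrapolating",
            stacklevel=2,
        )
    return 10 ** ((ct - curve.intercept) / curve.slope)


@dataclasses.dataclass(frozen=True)
class NormalizedCount:
    raw: float
    root_length_mm: float
    per_mm: float


def normalize_per_root(raw: float, root_length_mm: float) -> NormalizedCount:
    """Counts (CFU or copies) per mm of root length."""
    if root_length_mm <= 0:
        raise ValueError(f"root length must be positive, got {root_length_mm}")
    return NormalizedCount(raw=raw, root_length_mm=root_length_mm, per_mm=raw / root_length_mm)


def percent_increase(treated: float, control: float) -> float:
    """100 × (treated − control)/control, rounded to one decimal.

    Intended for group medians (the reported effect-size convention here).
    """
    if control <= 0:
        raise ValueError(f"control value must be positive, got {control}")
    return round(100.0 * (treated - control) / control, 1)
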