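"""Assay arithmetic: calibration curves and the closed-form assay readout
conversions used throughout the screen.

Colorimetric assays (IAA, phosphate solubilization, ammonia) are quantified
against an ordinary least-squares standard curve ``absorbance = slope * conc
+ intercept`` fitted with a free intercept; unknowns are inverted through the
line. Percent-style readouts come straight from their defining formulas:

* dual-culture inhibition: ``100 * (C - T) / C`` with control/test mycelial
  diameters C and T,
* CAS-shuttle siderophore units: ``100 * (Ar - As) / Ar`` with reference and
  sample absorbances at 630 nm,
* seed germination: ``100 * germinated / total``,
* chlorophyll a/b (DMSO extraction, mg per g fresh weight):
  ``Chla = 11.75 A663 - 2.35 A645`` and ``Chlb = 18.61 A645 - 3.96 A663``.

Negative outputs are never clamped: they are flagged so QC reports can
surface them while the numeric value is preserved.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, DomainError
from .trait_model import Measurement

#: r-squared below which a fitted standard curve triggers a quality warning
R2_WARN_THRESHOLD = 0.98


class CalibrationQualityWarning(UserWarning):
    """Emitted when a standard curve fits with r^2 below the QC threshold."""


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted standard curve mapping absorbance to concentration."""

    slope: float
    intercept: float
    r2: float
    standards: tuple[tuple[float, float], ...]

    @property
    def usable(self) -> bool:
        return self.slope != 0


@dataclass(frozen=True)
class ConcentrationResult:
    """An inverted unknown: raw value, zero-censored companion, sign flag."""

    value: float
    censored: float
    flagged_negative: bool


@dataclass(frozen=True)
class ChlorophyllResult:
    chl_a: float
    chl_b: float
    flagged_negative: bool


def fit_standard_curve(
    standards: Sequence[tuple[float, float]]
) -> CalibrationCurve:
    """Fit ``absorbance = slope * concentration + intercept`` by OLS.

    Requires >= 3 standards with >= 2 distinct concentrations. Emits a
    :class:`CalibrationQualityWarning` when r^2 < 0.98. A perfectly linear
    design reports r^2 = 1 exactly.
    """
    if len(standards) < 3:
        raise DegenerateDesignError(
            f"need >= 3 standards, got {len(standards)}"
        )
    conc = np.asarray([s[0] for s in standards], dtype=float)
    absb = np.asarray([s[1] for s in standards], dtype=float)
    if np.unique(conc).size < 2:
        raise DegenerateDesignError(
            "all standard concentrations identical; cannot fit a line"
        )
    fit = stats.linregress(conc, absb)
    r2 = float(fit.rvalue) ** 2
    if r2 < R2_WARN_THRESHOLD:
        warnings.warn(
            f"standard curve r^2 = {r2:.4f} < {R2_WARN_THRESHOLD}",
            CalibrationQualityWarning,
            stacklevel=2,
        )
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=r2,
        standards=tuple((float(c), float(a)) for c, a in standards),
    )


def concentration_from_absorbance(
    curve: CalibrationCurve, absorbance: float
) -> ConcentrationResult:
    """Invert the fitted line: ``(absorbance - intercept) / slope``.

    Negative concentrations are flagged and reported alongside a
    censored-at-zero companion value rather than silently clamped.
    """
    if curve.slope == 0:
        raise DomainError("calibration curve has zero slope; unusable")
    value = (absorbance - curve.intercept) / curve.slope
    return ConcentrationResult(
        value=value, censored=max(value, 0.0), flagged_negative=value < 0
    )


def percent_inhibition(control_diameter: float, test_diameter: float) -> float:
    """Dual-culture percent inhibition ``100 * (C - T) / C``.

    T > C yields a negative value (growth promotion of the pathogen); that is
    allowed and left to the caller to flag.
    """
    if control_diameter <= 0:
        raise DomainError(
            f"control diameter must be > 0, got {control_diameter}"
        )
    if test_diameter < 0:
        raise DomainError(f"test diameter must be >= 0, got {test_diameter}")
    return 100.0 * (control_diameter - test_diameter) / control_diameter


def siderophore_percent(reference_abs: float, sample_abs: float) -> float:
    """CAS-shuttle siderophore units ``100 * (Ar - As) / Ar`` at 630 nm."""
    if reference_abs <= 0:
        raise DomainError(
            f"reference absorbance must be > 0, got {reference_abs}"
        )
    if sample_abs < 0:
        raise DomainError(f"sample absorbance must be >= 0, got {sample_abs}")
    return 100.0 * (reference_abs - sample_abs) / reference_abs


def germination_percent(germinated: int, total: int) -> float:
    """Seed germination rate ``100 * germinated / total``."""
    if total <= 0:
        raise DomainError(f"total seed count must be > 0, got {total}")
    if germinated < 0 or germinated > total:
        raise DomainError(
            f"germinated count must lie in [0, {total}], got {germinated}"
        )
    return 100.0 * germinated / total


def chlorophyll_ab(a663: float, a645: float) -> ChlorophyllResult:
    """Chlorophyll a and b (mg per g fresh weight) from leaf-extract
    absorbances at 663 and 645 nm; negative outputs flagged, not clamped."""
    if a663 < 0 or a645 < 0:
        raise DomainError("absorbances must be >= 0")
    chl_a = 11.75 * a663 - 2.35 * a645
    chl_b = 18.61 * a645 - 3.96 * a663
    return ChlorophyllResult(
        chl_a=chl_a, chl_b=chl_b, flagged_negative=chl_a < 0 or chl_b < 0
    )


def summarize_replicates(values: Sequence[float]) -> Measurement:
    """Mean ± SE over replicates, SE = sd / sqrt(n) with sample sd (n - 1)."""
    vals = np.asarray(values, dtype=float)
    n = vals.size
    if n < 1:
        raise DomainError("need at least one replicate")
    se = 0.0 if n == 1 else float(np.std(vals, ddof=1) / math.sqrt(n))
    return Measurement(mean=float(vals.mean()), se=se, n=int(n))
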