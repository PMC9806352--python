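"""Unit calculations for the biochemical and pharmacological assays.

Covers four plate/coagulometer readouts:

* hyaluronidase activity in turbidity reduction units (TRU) — one TRU is
  the enzyme amount reducing the hyaluronic-acid turbidity by 50%; partial
  reductions are prorated linearly, and activity is expressed per mg of
  venom per minute of incubation;
* phospholipase specific activity from a chromogenic-substrate standard
  curve (ordinary least-squares line of absorbance vs analyte nmol),
  expressed as nmol of substrate cleaved per mg per minute;
* relative haemolysis against a detergent positive control treated as
  100% activity, blank-corrected by default;
* clotting delay (absolute and fold change vs control plasma), with
  right-censoring at the coagulometer's measurement limit reported as a
  lower bound on the fold change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "AssayMeasurement",
    "StandardCurve",
    "ClottingResult",
    "ClottingDelay",
    "turbidity_reduction_units",
    "specific_activity_from_curve",
    "relative_haemolysis",
    "clotting_delay",
]


@dataclass(frozen=True)
class AssayMeasurement:
    """One assay well: absorbances plus the venom dose and incubation time.

    Which absorbances are required depends on the calculation: turbidity
    reduction needs ``a_control``, haemolysis needs ``a_blank`` and
    ``a_positive``.
    """

    a_sample: float
    venom_mass_mg: float = 1.0
    incubation_time_min: float = 1.0
    a_control: float | None = None
    a_blank: float | None = None
    a_positive: float | None = None

    def __post_init__(self) -> None:
        for name in ("a_sample", "a_control", "a_blank", "a_positive"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        if self.venom_mass_mg <= 0:
            raise ValidationError("venom_mass_mg must be > 0")
        if self.incubation_time_min <= 0:
            raise ValidationError("incubation_time_min must be > 0")


def turbidity_reduction_units(m: AssayMeasurement) -> float:
    """Hyaluronidase activity in TRU per mg per minute.

    reduction% = 100 * (A_control - A_sample) / A_control; one TRU is a
    50% reduction, prorated linearly; the TRU count is divided by venom
    mass (mg) and incubation time (min).  A sample turbidity above the
    control yields a warning and zero activity.
    """
    if m.a_control is None or m.a_control <= 0:
        raise ValidationError("turbidity assay requires a positive control absorbance")
    reduction = 100.0 * (m.a_control - m.a_sample) / m.a_control
    if reduction < 0:
        warnings.warn(
            "sample turbidity exceeds control; reporting zero activity",
            stacklevel=2,
        )
        return 0.0
    tru = reduction / 50.0
    return tru / (m.venom_mass_mg * m.incubation_time_min)


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line of absorbance against analyte amount (nmol).

    Fit with :func:`StandardCurve.fit`; ``residuals`` holds the per-point
    fit residuals (observed - fitted absorbance).
    """

    amounts_nmol: tuple
    absorbances: tuple
    slope: float
    intercept: float
    residuals: tuple

    @classmethod
    def fit(cls, points: Sequence[tuple[float, float]]) -> "StandardCurve":
        """Ordinary least squares through (amount_nmol, absorbance) pairs."""
        if len(points) < 2:
            raise ValidationError("standard curve needs at least two points")
        amounts = np.asarray([p[0] for p in points], dtype=float)
        absorb = np.asarray([p[1] for p in points], dtype=float)
        if len(np.unique(amounts)) < 2:
            raise ValidationError("standard curve needs at least two distinct amounts")
        fit = stats.linregress(amounts, absorb)
        residuals = absorb - (fit.intercept + fit.slope * amounts)
        return cls(
            amounts_nmol=tuple(amounts),
            absorbances=tuple(absorb),
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            residuals=tuple(float(r) for r in residuals),
        )

    @property
    def amount_range(self) -> tuple[float, float]:
        return (min(self.amounts_nmol), max(self.amounts_nmol))


def specific_activity_from_curve(curve: StandardCurve, m: AssayMeasurement) -> float:
    """Specific activity in nmol per mg per minute via curve inversion.

    nmol = (A_sample - intercept) / slope; activity = nmol / (mass * time).
    Extrapolation outside the fitted amount range is permitted but warned
    about, as is a negative inferred amount.
    """
    if curve.slope == 0:
        raise DegenerateDataError("standard curve has zero slope; cannot invert")
    nmol = (m.a_sample - curve.intercept) / curve.slope
    lo, hi = curve.amount_range
    if nmol < 0:
        warnings.warn(f"negative extrapolated amount ({nmol:.4g} nmol)", stacklevel=2)
    elif not lo <= nmol <= hi:
        warnings.warn(
            f"amount {nmol:.4g} nmol extrapolated beyond curve range [{lo}, {hi}]",
            stacklevel=2,
        )
    return nmol / (m.venom_mass_mg * m.incubation_time_min)


def relative_haemolysis(m: AssayMeasurement, blank_corrected: bool = True) -> float:
    """Haemolysis as percent of the positive control (100% lysis).

    percent = 100 * (A_sample - A_blank) / (A_positive - A_blank); the
    result is not clipped, so >100% or negative values are visible.
    With ``blank_corrected=False`` the blank is treated as zero.
    """
    if m.a_positive is None:
        raise ValidationError("haemolysis assay requires a positive-control absorbance")
    blank = (m.a_blank or 0.0) if blank_corrected else 0.0
    if m.a_positive <= blank:
        raise ValidationError(
            f"positive-control absorbance ({m.a_positive}) must exceed the blank ({blank})"
        )
    return 100.0 * (m.a_sample - blank) / (m.a_positive - blank)


@dataclass(frozen=True)
class ClottingResult:
    """Clotting times for one venom dose against control plasma.

    ``censored`` marks wells where no clot formed within the instrument's
    observation window (``censoring_limit_s``); ``venom_time_s`` is then
    the limit itself, a lower bound on the true time.
    """

    control_time_s: float
    venom_time_s: float
    censored: bool = False
    censoring_limit_s: float = 1800.0

    def __post_init__(self) -> None:
        if self.control_time_s <= 0:
            raise ValidationError("control_time_s must be > 0")
        if self.venom_time_s <= 0:
            raise ValidationError("venom_time_s must be > 0")
        if self.censored and self.venom_time_s < self.censoring_limit_s:
            raise ValidationError(
                "censored result requires venom_time_s >= censoring_limit_s"
            )


@dataclass(frozen=True)
class ClottingDelay:
    delay_s: float
    fold: float
    censored: bool  # True: delay and fold are lower bounds


def clotting_delay(r: ClottingResult) -> ClottingDelay:
    """Absolute delay and fold change of the clotting time vs control."""
    t = r.censoring_limit_s if r.censored else r.venom_time_s
    return ClottingDelay(
        delay_s=t - r.control_time_s,
        fold=t / r.control_time_s,
        censored=r.censored,
    )
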