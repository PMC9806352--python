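"""Gel-lane densitometry: baseline subtraction and band-area integration.

The relative-abundance statistic weights each excised band by its
densitometric proportion — the band's integrated lane intensity divided by
the total over the analysed bands.  Bands are half-open intervals
``[start, end)`` on the migration axis so that adjacent bands partition the
lane cleanly.  Baselines are valley-to-valley straight lines through the
profile values at the band edges; areas are trapezoidal integrals, which
are exact for the piecewise-linear signals a sampled profile represents.
Proportions are normalised over the analysed bands only, not the whole
lane, matching the convention under which a composition sums to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .errors import BoundsError, DegenerateDataError, ValidationError
from .io_formats import LaneProfile

__all__ = [
    "BandDefinition",
    "BandEntry",
    "BandProportionTable",
    "subtract_baseline",
    "integrate_bands",
    "proportions_from_areas",
]


@dataclass(frozen=True)
class BandDefinition:
    """One excised band: half-open interval [start, end) on the lane."""

    band_id: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"band {self.band_id!r}: start ({self.start}) must be < end ({self.end})"
            )


def _check_disjoint(bands: Iterable[BandDefinition]) -> list[BandDefinition]:
    ordered = sorted(bands, key=lambda b: b.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValidationError(
                f"bands {a.band_id!r} and {b.band_id!r} overlap "
                f"([{a.start}, {a.end}) vs [{b.start}, {b.end}))"
            )
    return ordered


@dataclass(frozen=True)
class BandEntry:
    area: float
    proportion: float


@dataclass(frozen=True)
class BandProportionTable:
    """Integrated area and lane proportion per analysed band.

    Proportions are fractions in [0, 1] summing to 1; percentages appear
    only in reports.
    """

    entries: dict[str, BandEntry]

    def __post_init__(self) -> None:
        total = sum(e.proportion for e in self.entries.values())
        if self.entries and abs(total - 1.0) > 1e-9:
            raise ValidationError(f"band proportions sum to {total!r}, not 1")
        for band_id, e in self.entries.items():
            if e.area < 0 or e.proportion < 0:
                raise ValidationError(f"band {band_id!r}: negative area/proportion")

    @property
    def proportions(self) -> dict[str, float]:
        return {k: e.proportion for k, e in self.entries.items()}

    @property
    def areas(self) -> dict[str, float]:
        return {k: e.area for k, e in self.entries.items()}


def _check_bounds(profile: LaneProfile, bands: Iterable[BandDefinition]) -> None:
    lo, hi = profile.positions[0], profile.positions[-1]
    for b in bands:
        if b.start < lo or b.end > hi:
            raise BoundsError(
                f"band {b.band_id!r} [{b.start}, {b.end}) outside lane range "
                f"[{lo}, {hi}]"
            )


def subtract_baseline(
    profile: LaneProfile, bands: Iterable[BandDefinition]
) -> LaneProfile:
    """Subtract a valley-to-valley linear baseline inside each band.

    For each band the straight line through the profile values at ``start``
    and ``end`` is subtracted from the samples falling inside the band;
    the result is clipped at zero.  Samples outside every band are left
    unchanged.
    """
    bands = _check_disjoint(bands)
    _check_bounds(profile, bands)
    x = profile.positions
    y = profile.intensities.copy()
    for b in bands:
        y_start = float(np.interp(b.start, x, profile.intensities))
        y_end = float(np.interp(b.end, x, profile.intensities))
        mask = (x >= b.start) & (x < b.end)
        if not mask.any():
            continue
        slope = (y_end - y_start) / (b.end - b.start)
        baseline = y_start + slope * (x[mask] - b.start)
        y[mask] = np.clip(y[mask] - baseline, 0.0, None)
    return LaneProfile(x, y)


def _band_area(profile: LaneProfile, band: BandDefinition) -> float:
    """Trapezoidal integral of the profile over [start, end).

    The sampled profile is treated as piecewise linear; the integral over
    the half-open interval equals the integral over the closed one, using
    interpolated values at the band edges.
    """
    x = profile.positions
    y = profile.intensities
    inner = (x > band.start) & (x < band.end)
    xs = np.concatenate(([band.start], x[inner], [band.end]))
    ys = np.concatenate((
        [np.interp(band.start, x, y)],
        y[inner],
        [np.interp(band.end, x, y)],
    ))
    return float(np.trapezoid(ys, xs))


def integrate_bands(
    profile: LaneProfile, bands: Iterable[BandDefinition]
) -> BandProportionTable:
    """Integrate each band and normalise areas into proportions.

    The caller is expected to have applied :func:`subtract_baseline` first
    (or to opt out deliberately for pre-corrected profiles).
    """
    bands = _check_disjoint(bands)
    _check_bounds(profile, bands)
    areas = {b.band_id: _band_area(profile, b) for b in bands}
    return proportions_from_areas(areas)


def proportions_from_areas(areas: Mapping[str, float]) -> BandProportionTable:
    """Normalise precomputed band areas into a proportion table.

    Entry point for band areas quantified in external gel software.
    """
    for band_id, a in areas.items():
        if a < 0:
            raise ValidationError(f"band {band_id!r}: negative area {a}")
    total = sum(areas.values())
    if not areas or total <= 0:
        raise DegenerateDataError("all band areas are zero: degenerate lane")
    entries = {k: BandEntry(area=v, proportion=v / total) for k, v in areas.items()}
    return BandProportionTable(entries)
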