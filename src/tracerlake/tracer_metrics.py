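"""Tracer statistics: per cent increase, biomagnification, trend tests.

The per cent increase of a spike channel over ambient quantifies how much the
experimental loading raised concentrations above background; the
biomagnification factor (BMF) is the log10 predator/prey concentration ratio;
phase trend tests are per-channel OLS regressions of annual values on year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .data_model import (
    AgeClass,
    CompartmentSample,
    FishObservation,
    IsotopeChannel,
    Species,
    StudyCalendar,
)
from .errors import InsufficientDataError, ValidationError

#: Dominant prey item for each predator in the biomagnification analysis.
#: Pike prey ("forage_fish") pools YOY + age-1+ yellow perch and blacknose
#: shiner, unweighted.
DEFAULT_PREY: dict[Species, str] = {
    Species.YELLOW_PERCH: "zooplankton",
    Species.NORTHERN_PIKE: "forage_fish",
    Species.LAKE_WHITEFISH: "chaoborus",
}

FORAGE_SPECIES = (Species.YELLOW_PERCH, Species.BLACKNOSE_SHINER)


@dataclass
class AnnualSeries:
    """A per-year scalar series for one compartment/species and channel."""

    label: str
    channel: IsotopeChannel | None
    points: dict[int, float] = field(default_factory=dict)
    units: str = ""

    def value(self, year: int) -> float | None:
        return self.points.get(year)

    def years(self) -> list[int]:
        return sorted(self.points)


@dataclass(frozen=True)
class TrendResult:
    slope: float
    intercept: float
    p_value: float
    n: int
    degenerate: bool = False


def percent_increase(spike_conc: float, ambient_conc: float) -> float:
    """Per cent increase of a spike channel over ambient: ``100 * spike/ambient``."""
    if ambient_conc <= 0:
        raise ValidationError(f"ambient_conc must be > 0, got {ambient_conc}")
    if spike_conc < 0:
        raise ValidationError(f"spike_conc must be >= 0, got {spike_conc}")
    return 100.0 * spike_conc / ambient_conc


def bmf(pred_conc: float, prey_conc: float) -> float:
    """Biomagnification factor: ``log10(predator / prey)`` on wet-basis MeHg.

    Undefined for non-positive concentrations; a spike censored to zero must
    be treated as a missing BMF upstream, never passed here.
    """
    if pred_conc <= 0 or prey_conc <= 0:
        raise ValidationError(
            f"bmf requires positive concentrations, got predator={pred_conc}, prey={prey_conc}"
        )
    return math.log10(pred_conc / prey_conc)


def prey_exposure_mean(
    prey_samples: Iterable[CompartmentSample],
    year: int,
    calendar: StudyCalendar,
    channel: IsotopeChannel,
) -> float | None:
    """Mean wet-basis prey concentration over the open-water season of ``year``.

    Dry-basis invertebrate records are converted with the fixed 0.15 factor.
    Returns ``None`` when no in-window sample exists (e.g. samples only from
    the previous year).
    """
    values = []
    for s in prey_samples:
        if not calendar.in_open_water(s.date, year):
            continue
        v = s.wet_conc(channel)
        if v is not None:
            values.append(v)
    if not values:
        return None
    return float(np.mean(values))


def forage_fish_mean(
    fish: Iterable[FishObservation],
    year: int,
    channel: IsotopeChannel,
) -> float | None:
    """Mean wet-basis concentration of the pooled forage-fish prey in ``year``.

    Pools YOY and age-1+ yellow perch with blacknose shiner, unweighted.
    """
    values = []
    for f in fish:
        if f.year != year or f.species not in FORAGE_SPECIES:
            continue
        if f.species is Species.YELLOW_PERCH and f.age_class is AgeClass.ADULT:
            continue
        v = f.conc_ww(channel)
        if v is not None:
            values.append(v)
    if not values:
        return None
    return float(np.mean(values))


def annual_percent_increase_fish(
    fish: Iterable[FishObservation],
    year: int,
    species: Species,
    spike_channel: IsotopeChannel = IsotopeChannel.LAKE_SPIKE,
    age_class: AgeClass | None = None,
) -> float | None:
    """Mean of individual-level spike/ambient ratios for one species-year.

    Individual ratios (not size-standardized values) are averaged, so each
    fish contributes its own relative enrichment.
    """
    ratios = []
    for f in fish:
        if f.year != year or f.species is not species:
            continue
        if age_class is not None and f.age_class is not age_class:
            continue
        amb = f.conc_dw.get(IsotopeChannel.AMBIENT)
        spk = f.conc_dw.get(spike_channel)
        if amb is None or spk is None or amb <= 0:
            continue
        ratios.append(percent_increase(spk, amb))
    if not ratios:
        return None
    return float(np.mean(ratios))


def percent_increase_series(
    spike_series: AnnualSeries,
    ambient_series: AnnualSeries,
    label: str | None = None,
) -> AnnualSeries:
    """Per-year per cent increase from a pair of annual-mean series.

    This is the ratio-of-annual-means convention used for water, sediment and
    invertebrate compartments; years missing from either input stay missing.
    """
    out = AnnualSeries(
        label=label or spike_series.label,
        channel=spike_series.channel,
        units="percent",
    )
    for year, spk in spike_series.points.items():
        amb = ambient_series.points.get(year)
        if amb is None or amb <= 0:
            continue
        out.points[year] = percent_increase(spk, amb)
    return out


def phase_trend_test(series: AnnualSeries, phase: Iterable[int]) -> TrendResult:
    """OLS regression of annual value on year within ``phase``.

    Two-sided p-value for slope = 0.  A series with zero residual variance is
    degenerate: slope is reported but the test statistic is undefined, so
    p = 1 with ``degenerate=True``.
    """
    years = [y for y in phase if series.points.get(y) is not None]
    if len(years) < 3:
        raise InsufficientDataError(
            f"phase_trend_test needs >= 3 annual values, got {len(years)}"
        )
    x = np.asarray(years, dtype=float)
    y = np.asarray([series.points[yr] for yr in years], dtype=float)
    if np.allclose(y, y.mean(), rtol=1e-12, atol=1e-300):
        # zero residual variance: the test statistic is undefined
        return TrendResult(slope=0.0, intercept=float(y.mean()), p_value=1.0, n=len(years), degenerate=True)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    if rss == 0.0:
        # perfect non-constant linear fit: p underflows to 0
        return TrendResult(slope=float(slope), intercept=float(intercept), p_value=0.0, n=len(years))
    n = len(years)
    sxx = float(((x - x.mean()) ** 2).sum())
    se = math.sqrt(rss / (n - 2) / sxx)
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return TrendResult(slope=float(slope), intercept=float(intercept), p_value=float(p), n=n)
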