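"""End-to-end orchestration of the analysis stages.

``run_full_analysis`` composes, deterministically: spike censoring against
per-sample ambient values, open-water annual means, per cent increase series,
length standardization, biomagnification series, and the population burden
decay fit with its time-to-fraction.  Stages short of data record flagged
gaps rather than failing silently; every report carries a provenance block.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .data_model import (
    AgeClass,
    CompartmentSample,
    Compartment,
    Dataset,
    DetectionPolicy,
    FishObservation,
    IsotopeChannel,
    SPIKE_CHANNELS,
    Species,
    StudyCalendar,
    censor_spike,
    open_water_annual_mean,
)
from .errors import InsufficientDataError, UndefinedResultError
from .recovery_kinetics import (
    BurdenRecord,
    DecayFit,
    fit_burden_decay,
    individual_burden_trajectories,
    population_burden_series,
    time_to_fraction,
)
from .size_standardization import (
    STANDARD_FORK_LENGTH_MM,
    StandardizedValue,
    annual_standardized_series,
    annual_standardized_weight,
)
from .tracer_metrics import (
    AnnualSeries,
    DEFAULT_PREY,
    annual_percent_increase_fish,
    bmf,
    forage_fish_mean,
    percent_increase_series,
    prey_exposure_mean,
)

log = logging.getLogger("tracerlake")

LARGE_BODIED = (Species.NORTHERN_PIKE, Species.LAKE_WHITEFISH)


@dataclass
class AnalysisConfig:
    """Knobs for the full pipeline; defaults mirror the study conventions."""

    calendar: StudyCalendar = field(default_factory=StudyCalendar)
    detection_policy: DetectionPolicy = field(default_factory=DetectionPolicy)
    standard_fl_mm: dict[Species, float] = field(
        default_factory=lambda: dict(STANDARD_FORK_LENGTH_MM)
    )
    include_white_sucker: bool = False
    decay_start_offset: float = 2.0
    decay_fraction: float = 0.5
    burden_channel: IsotopeChannel = IsotopeChannel.LAKE_SPIKE
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "calendar": {
                "addition_start": self.calendar.addition_start,
                "addition_end": self.calendar.addition_end,
                "recovery_end": self.calendar.recovery_end,
                "open_water_months": sorted(self.calendar.open_water_months),
            },
            "detection_policy": {
                "spike_dl_fraction": self.detection_policy.spike_dl_fraction,
                "substitution": self.detection_policy.substitution.value,
            },
            "standard_fl_mm": {sp.value: fl for sp, fl in self.standard_fl_mm.items()},
            "include_white_sucker": self.include_white_sucker,
            "decay_start_offset": self.decay_start_offset,
            "decay_fraction": self.decay_fraction,
            "burden_channel": self.burden_channel.value,
            "seed": self.seed,
        }


@dataclass
class AnalysisReport:
    percent_increase: list[AnnualSeries]
    standardized_conc: dict[tuple[Species, IsotopeChannel], dict[int, StandardizedValue]]
    bmf_series: list[AnnualSeries]
    burden_series: list[BurdenRecord]
    individual_trajectories: dict[str, list[BurdenRecord]]
    decay_fit: DecayFit | None
    time_to_fraction_years: float | None
    flags: list[str]
    provenance: dict


def _censor_dataset(dataset: Dataset, policy: DetectionPolicy) -> tuple[Dataset, int]:
    """Apply the spike detection limit to every record, against its own
    ambient value.  Returns the censored dataset and the count of censored
    record-channel pairs."""
    censored = 0
    samples: list[CompartmentSample] = []
    for s in dataset.samples:
        amb = s.conc.get(IsotopeChannel.AMBIENT)
        conc = dict(s.conc)
        flags: dict[IsotopeChannel, bool] = {}
        if amb is not None and amb > 0:
            for ch in SPIKE_CHANNELS:
                if ch in conc:
                    conc[ch], flags[ch] = censor_spike(conc[ch], amb, policy)
                    censored += flags[ch]
        new = dataclasses.replace(s, conc=conc)
        new.below_dl = flags
        samples.append(new)
    fish: list[FishObservation] = []
    for f in dataset.fish:
        amb = f.conc_dw.get(IsotopeChannel.AMBIENT)
        conc = dict(f.conc_dw)
        flags = {}
        if amb is not None and amb > 0:
            for ch in SPIKE_CHANNELS:
                if ch in conc:
                    conc[ch], flags[ch] = censor_spike(conc[ch], amb, policy)
                    censored += flags[ch]
        new = dataclasses.replace(f, conc_dw=conc)
        new.below_dl = flags
        fish.append(new)
    return Dataset(samples=samples, fish=fish), censored


def _compartment_annual_series(
    samples: Sequence[CompartmentSample],
    compartment: Compartment,
    channel: IsotopeChannel,
    calendar: StudyCalendar,
) -> AnnualSeries:
    series = AnnualSeries(label=compartment.value, channel=channel)
    for year in calendar.all_years:
        v = open_water_annual_mean(samples, year, calendar, channel, compartment=compartment)
        if v is not None:
            series.points[year] = v
    return series


def run_full_analysis(
    dataset: Dataset,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Run every analysis stage on a validated dataset."""
    config = config or AnalysisConfig()
    cal = config.calendar
    flags: list[str] = []

    data, n_censored = _censor_dataset(dataset, config.detection_policy)
    log.info("censoring: %d record-channel pairs below detection", n_censored)

    active_species = [sp for sp in Species if sp is not Species.WHITE_SUCKER]
    if config.include_white_sucker:
        active_species.append(Species.WHITE_SUCKER)
    fish = [f for f in data.fish if f.species in active_species]
    n_excluded = len(data.fish) - len(fish)
    if n_excluded:
        log.info("excluded %d white sucker observations", n_excluded)

    # --- per cent increase -------------------------------------------------
    pct_series: list[AnnualSeries] = []
    for comp in Compartment:
        spike = _compartment_annual_series(data.samples, comp, IsotopeChannel.LAKE_SPIKE, cal)
        ambient = _compartment_annual_series(data.samples, comp, IsotopeChannel.AMBIENT, cal)
        if spike.points and ambient.points:
            pct_series.append(percent_increase_series(spike, ambient, label=comp.value))
    for sp in active_species:
        series = AnnualSeries(label=sp.value, channel=IsotopeChannel.LAKE_SPIKE, units="percent")
        for year in cal.all_years:
            v = annual_percent_increase_fish(fish, year, sp)
            if v is not None:
                series.points[year] = v
        if series.points:
            pct_series.append(series)

    # --- length standardization -------------------------------------------
    standardized: dict[tuple[Species, IsotopeChannel], dict[int, StandardizedValue]] = {}
    for sp in LARGE_BODIED:
        for ch in (IsotopeChannel.AMBIENT, IsotopeChannel.LAKE_SPIKE):
            values = annual_standardized_series(
                fish, sp, ch, standard_fl_mm=config.standard_fl_mm.get(sp)
            )
            if values:
                standardized[(sp, ch)] = values
            else:
                flags.append(f"standardization: no usable years for {sp.value}/{ch.value}")

    # --- biomagnification --------------------------------------------------
    bmf_series: list[AnnualSeries] = []
    for sp, prey in DEFAULT_PREY.items():
        for ch in (IsotopeChannel.AMBIENT, IsotopeChannel.LAKE_SPIKE):
            series = AnnualSeries(label=f"{sp.value}_vs_{prey}", channel=ch, units="log10")
            for year in cal.all_years:
                if prey == "forage_fish":
                    prey_c = forage_fish_mean(fish, year, ch)
                else:
                    prey_samples = [
                        s for s in data.samples if s.compartment.value == prey
                    ]
                    prey_c = prey_exposure_mean(prey_samples, year, cal, ch)
                pred_c = _predator_concentration(sp, ch, year, fish, standardized)
                if prey_c is None or pred_c is None or prey_c <= 0 or pred_c <= 0:
                    continue  # censored-to-zero or missing -> missing BMF
                series.points[year] = bmf(pred_c, prey_c)
            if series.points:
                bmf_series.append(series)

    # --- recovery kinetics -------------------------------------------------
    burden_series: list[BurdenRecord] = []
    decay_fit: DecayFit | None = None
    ttf: float | None = None
    trajectories = individual_burden_trajectories(fish, cal.t0_year, config.burden_channel)
    conc_std = standardized.get((Species.NORTHERN_PIKE, config.burden_channel), {})
    weight_std = annual_standardized_weight(
        fish, Species.NORTHERN_PIKE, config.standard_fl_mm.get(Species.NORTHERN_PIKE)
    )
    conc_map = {y: v.value for y, v in conc_std.items() if v.value > 0}
    try:
        burden_series = population_burden_series(conc_map, weight_std, cal.t0_year)
        decay_fit = fit_burden_decay(burden_series, cal.t0_year, config.decay_start_offset)
        ttf = time_to_fraction(decay_fit, config.decay_fraction)
    except InsufficientDataError as exc:
        flags.append(f"recovery: insufficient data for decay fit ({exc})")
    except UndefinedResultError as exc:
        flags.append(f"recovery: time-to-fraction undefined ({exc})")

    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "n_samples": len(dataset.samples),
        "n_fish": len(dataset.fish),
        "n_censored": n_censored,
        "n_excluded_white_sucker": n_excluded,
    }
    return AnalysisReport(
        percent_increase=pct_series,
        standardized_conc=standardized,
        bmf_series=bmf_series,
        burden_series=burden_series,
        individual_trajectories=trajectories,
        decay_fit=decay_fit,
        time_to_fraction_years=ttf,
        flags=flags,
        provenance=provenance,
    )


def _predator_concentration(sp, ch, year, fish, standardized):
    """Mean (forage/perch) or length-standardized (large-bodied) predator
    concentration for the BMF numerator."""
    if sp in LARGE_BODIED:
        values = standardized.get((sp, ch), {})
        sv = values.get(year)
        return sv.value if sv is not None else None
    concs = [
        f.conc_ww(ch)
        for f in fish
        if f.species is sp and f.year == year and ch in f.conc_dw
        and (sp is not Species.YELLOW_PERCH or f.age_class is AgeClass.AGE1PLUS)
    ]
    concs = [c for c in concs if c is not None]
    if not concs:
        return None
    return sum(concs) / len(concs)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _series_frame(series_list: Sequence[AnnualSeries], metric: str) -> pd.DataFrame:
    rows = [
        {
            "year": year,
            "label": s.label,
            "channel": s.channel.value if s.channel else "",
            "metric": metric,
            "value": value,
            "units": s.units,
        }
        for s in series_list
        for year, value in sorted(s.points.items())
    ]
    return pd.DataFrame(rows, columns=["year", "label", "channel", "metric", "value", "units"])


def render_tables(report: AnalysisReport, directory: str | Path) -> dict[str, Path]:
    """Write the report as tidy CSVs plus JSON for the fit and provenance."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["percent_increase"] = directory / "percent_increase.csv"
    _series_frame(report.percent_increase, "percent_increase").to_csv(
        paths["percent_increase"], index=False
    )

    std_rows = [
        {
            "year": year,
            "species": sp.value,
            "channel": ch.value,
            "value": sv.value,
            "model": sv.model.value,
            "transform": sv.transform.value,
            "n": sv.n,
            "rss": sv.rss,
            "quality": sv.quality,
        }
        for (sp, ch), values in sorted(
            report.standardized_conc.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
        )
        for year, sv in sorted(values.items())
    ]
    paths["standardized"] = directory / "standardized_concentrations.csv"
    pd.DataFrame(
        std_rows,
        columns=["year", "species", "channel", "value", "model", "transform", "n", "rss", "quality"],
    ).to_csv(paths["standardized"], index=False)

    paths["bmf"] = directory / "bmf.csv"
    _series_frame(report.bmf_series, "bmf").to_csv(paths["bmf"], index=False)

    burden_rows = [
        {"label": r.label, "year": r.year, "burden_ng": r.burden_ng, "normalized": r.normalized}
        for r in report.burden_series
    ] + [
        {"label": r.label, "year": r.year, "burden_ng": r.burden_ng, "normalized": r.normalized}
        for recs in report.individual_trajectories.values()
        for r in recs
    ]
    paths["burden"] = directory / "burden_series.csv"
    pd.DataFrame(burden_rows, columns=["label", "year", "burden_ng", "normalized"]).to_csv(
        paths["burden"], index=False
    )

    fit = report.decay_fit
    decay = {
        "fitted": fit is not None,
        "amplitude": fit.amplitude if fit else None,
        "rate_per_year": fit.rate if fit else None,
        "r_squared": fit.r_squared if fit else None,
        "f_stat": fit.f_stat if fit else None,
        "p_value": fit.p_value if fit else None,
        "n": fit.n if fit else None,
        "start_offset": fit.start_offset if fit else None,
        "time_to_fraction_years": report.time_to_fraction_years,
        "flags": report.flags,
    }
    paths["decay"] = directory / "decay_fit.json"
    paths["decay"].write_text(json.dumps(decay, indent=2, allow_nan=True))

    paths["provenance"] = directory / "provenance.json"
    paths["provenance"].write_text(json.dumps(report.provenance, indent=2))
    return paths
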