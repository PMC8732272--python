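"""Domain types, unit/basis conversions, censoring and CSV round-trip I/O.

Every concentration in the package is indexed by an :class:`IsotopeChannel`:
the ``ambient`` background channel plus three experimentally added spike
channels distinguishable by isotopic mass.  Non-fish compartments are carried
as :class:`CompartmentSample`; fish capture events as :class:`FishObservation`
with dry-basis muscle concentrations that convert to wet basis through the
per-fish dry-weight proportion.

The CSV schemas (``samples.csv`` and ``fish.csv``) are plain UTF-8 with a
mandatory header, ISO-8601 dates, one column per channel concentration and a
decimal point.  ``write_dataset`` followed by ``read_dataset`` reproduces every
record exactly for values representable in shortest-repr floating point.
"""

from __future__ import annotations

import datetime as dt
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

#: Fixed dry-to-wet conversion factor for invertebrate tissue.
INVERTEBRATE_DW_PROPORTION = 0.15


class IsotopeChannel(str, enum.Enum):
    """The four measurement channels carried by every concentration record."""

    AMBIENT = "ambient"
    LAKE_SPIKE = "lake_spike"
    UPLAND_SPIKE = "upland_spike"
    WETLAND_SPIKE = "wetland_spike"


SPIKE_CHANNELS: tuple[IsotopeChannel, ...] = (
    IsotopeChannel.LAKE_SPIKE,
    IsotopeChannel.UPLAND_SPIKE,
    IsotopeChannel.WETLAND_SPIKE,
)


class Compartment(str, enum.Enum):
    WATER = "water"
    SEDIMENT = "sediment"
    ZOOPLANKTON = "zooplankton"
    CHAOBORUS = "chaoborus"
    CHIRONOMID = "chironomid"


INVERTEBRATE_COMPARTMENTS = (
    Compartment.ZOOPLANKTON,
    Compartment.CHAOBORUS,
    Compartment.CHIRONOMID,
)


class Basis(str, enum.Enum):
    WET = "wet"
    DRY = "dry"


class Units(str, enum.Enum):
    NG_PER_L = "ng_per_L"
    NG_PER_G = "ng_per_g"


class Species(str, enum.Enum):
    YELLOW_PERCH = "yellow_perch"
    BLACKNOSE_SHINER = "blacknose_shiner"
    LAKE_WHITEFISH = "lake_whitefish"
    NORTHERN_PIKE = "northern_pike"
    WHITE_SUCKER = "white_sucker"


class AgeClass(str, enum.Enum):
    YOY = "YOY"
    AGE1PLUS = "age1plus"
    ADULT = "adult"


class Substitution(str, enum.Enum):
    """What to report for a spike value that falls below the detection limit."""

    ZERO = "zero"
    HALF_DL = "half_dl"
    FLAG_ONLY = "flag_only"


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DetectionPolicy:
    """Spike detection limit expressed as a fraction of the ambient channel."""

    spike_dl_fraction: float = 0.005
    substitution: Substitution = Substitution.ZERO

    def __post_init__(self) -> None:
        if not 0.0 < self.spike_dl_fraction < 1.0:
            raise ValidationError(
                f"spike_dl_fraction must be in (0, 1), got {self.spike_dl_fraction}"
            )


@dataclass(frozen=True)
class StudyCalendar:
    """Addition/recovery phase bounds and the open-water sampling window.

    ``t0_year`` — the final addition year — anchors recovery time: a sample
    from calendar year ``y`` sits at ``x = y - t0_year`` years into recovery.
    """

    addition_start: int = 2001
    addition_end: int = 2007
    recovery_end: int = 2015
    open_water_months: frozenset[int] = frozenset(range(5, 11))  # May..October

    def __post_init__(self) -> None:
        if not self.addition_start <= self.addition_end < self.recovery_end:
            raise ValidationError(
                "calendar phases must be ordered and contiguous: "
                f"{self.addition_start}..{self.addition_end}..{self.recovery_end}"
            )

    @property
    def t0_year(self) -> int:
        return self.addition_end

    @property
    def addition_years(self) -> range:
        return range(self.addition_start, self.addition_end + 1)

    @property
    def recovery_years(self) -> range:
        return range(self.addition_end + 1, self.recovery_end + 1)

    @property
    def all_years(self) -> range:
        return range(self.addition_start, self.recovery_end + 1)

    def in_open_water(self, date: dt.date, year: int) -> bool:
        return date.year == year and date.month in self.open_water_months


def _check_conc(conc: Mapping[IsotopeChannel, float], label: str) -> dict[IsotopeChannel, float]:
    clean: dict[IsotopeChannel, float] = {}
    for ch, v in conc.items():
        ch = IsotopeChannel(ch)
        v = float(v)
        if not math.isfinite(v) or v < 0:
            raise ValidationError(f"{label}: concentration for {ch.value} must be finite and >= 0, got {v}")
        clean[ch] = v
    return clean


@dataclass
class CompartmentSample:
    """Dated MeHg measurement in a non-fish lake compartment."""

    compartment: Compartment
    date: dt.date
    conc: dict[IsotopeChannel, float]
    basis: Basis
    units: Units
    depth_m: float | None = None
    below_dl: dict[IsotopeChannel, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.compartment = Compartment(self.compartment)
        self.basis = Basis(self.basis)
        self.units = Units(self.units)
        self.conc = _check_conc(self.conc, self.compartment.value)
        if self.compartment is Compartment.WATER and self.units is not Units.NG_PER_L:
            raise ValidationError("water samples must be reported in ng_per_L")
        if self.compartment is not Compartment.WATER and self.units is not Units.NG_PER_G:
            raise ValidationError(f"{self.compartment.value} samples must be reported in ng_per_g")
        if self.compartment is Compartment.SEDIMENT and self.basis is not Basis.DRY:
            raise ValidationError("sediment concentrations are dry basis")

    @property
    def year(self) -> int:
        return self.date.year

    def wet_conc(self, channel: IsotopeChannel) -> float | None:
        """Wet-basis value for ``channel``; invertebrate dry inputs use the
        fixed 0.15 conversion.  Water is already a wet-phase measure.
        Sediment has no wet-basis representation here and raises."""
        if channel not in self.conc:
            return None
        if self.compartment is Compartment.SEDIMENT:
            raise ValidationError("sediment concentrations are reported dry; no wet conversion defined")
        if self.basis is Basis.WET or self.compartment is Compartment.WATER:
            return self.conc[channel]
        return dry_to_wet(self.conc[channel], INVERTEBRATE_DW_PROPORTION)


@dataclass
class FishObservation:
    """One fish capture event with per-channel dry-basis muscle MeHg."""

    species: Species
    date: dt.date
    fork_length_mm: float
    mass_g: float
    dw_proportion: float
    conc_dw: dict[IsotopeChannel, float]
    age_class: AgeClass | None = None
    fish_id: str | None = None
    age_years: int | None = None
    below_dl: dict[IsotopeChannel, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.species = Species(self.species)
        if self.age_class is not None:
            self.age_class = AgeClass(self.age_class)
        if self.fork_length_mm <= 0:
            raise ValidationError(f"fork_length_mm must be > 0, got {self.fork_length_mm}")
        if self.mass_g <= 0:
            raise ValidationError(f"mass_g must be > 0, got {self.mass_g}")
        if not 0.0 < self.dw_proportion <= 1.0:
            raise ValidationError(f"dw_proportion must be in (0, 1], got {self.dw_proportion}")
        if self.age_years is not None and self.age_years < 0:
            raise ValidationError(f"age_years must be >= 0, got {self.age_years}")
        self.conc_dw = _check_conc(self.conc_dw, self.species.value)

    @property
    def year(self) -> int:
        return self.date.year

    def conc_ww(self, channel: IsotopeChannel) -> float | None:
        """Wet-basis muscle concentration via the individual d.w. proportion."""
        if channel not in self.conc_dw:
            return None
        return dry_to_wet(self.conc_dw[channel], self.dw_proportion)


@dataclass
class Dataset:
    """A full study dataset: compartment samples plus fish observations."""

    samples: list[CompartmentSample] = field(default_factory=list)
    fish: list[FishObservation] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def dry_to_wet(conc_dw: float, dw_proportion: float) -> float:
    """Convert a dry-basis concentration to wet basis.

    ``conc_ww = conc_dw * dw_proportion``.  Invertebrates use the fixed
    :data:`INVERTEBRATE_DW_PROPORTION` factor; fish use their per-sample
    dry-weight proportion.
    """
    if not 0.0 < dw_proportion <= 1.0:
        raise ValidationError(f"dw_proportion must be in (0, 1], got {dw_proportion}")
    if conc_dw < 0:
        raise ValidationError(f"concentration must be >= 0, got {conc_dw}")
    return conc_dw * dw_proportion


def censor_spike(
    spike_conc: float,
    ambient_conc: float,
    policy: DetectionPolicy | None = None,
) -> tuple[float, bool]:
    """Apply the spike detection limit (a fraction of the paired ambient value).

    Returns ``(value, below_dl)``.  A spike below ``spike_dl_fraction x
    ambient`` is substituted according to the policy (zero by default, half
    the detection limit, or left unchanged when only flagging).  Idempotent:
    a substituted value remains below the limit and maps to itself.
    """
    policy = policy or DetectionPolicy()
    if ambient_conc <= 0:
        raise ValidationError(
            f"ambient_conc must be > 0 to evaluate the detection limit, got {ambient_conc}"
        )
    if spike_conc < 0:
        raise ValidationError(f"spike_conc must be >= 0, got {spike_conc}")
    dl = policy.spike_dl_fraction * ambient_conc
    if spike_conc >= dl:
        return spike_conc, False
    if policy.substitution is Substitution.ZERO:
        return 0.0, True
    if policy.substitution is Substitution.HALF_DL:
        return dl / 2.0, True
    return spike_conc, True  # flag_only


def open_water_annual_mean(
    samples: Iterable[CompartmentSample],
    year: int,
    calendar: StudyCalendar,
    channel: IsotopeChannel,
    compartment: Compartment | None = None,
    max_depth_m: float | None = None,
) -> float | None:
    """Unweighted mean concentration over the open-water window of ``year``.

    Samples outside the month window (or deeper than ``max_depth_m`` when a
    depth filter is requested) are excluded.  Returns ``None`` — not zero —
    when no in-window sample carries the channel.
    """
    values = []
    for s in samples:
        if compartment is not None and s.compartment is not Compartment(compartment):
            continue
        if not calendar.in_open_water(s.date, year):
            continue
        if max_depth_m is not None and s.depth_m is not None and s.depth_m > max_depth_m:
            continue
        if channel in s.conc:
            values.append(s.conc[channel])
    if not values:
        return None
    return sum(values) / len(values)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_CHANNEL_COLS = [f"conc_{ch.value}" for ch in IsotopeChannel]

SAMPLE_COLUMNS = ["compartment", "date", "depth_m", "basis", "units", *_CHANNEL_COLS]
FISH_COLUMNS = [
    "species",
    "age_class",
    "fish_id",
    "date",
    "fork_length_mm",
    "mass_g",
    "dw_proportion",
    *_CHANNEL_COLS,
    "age_years",
]

SAMPLES_FILE = "samples.csv"
FISH_FILE = "fish.csv"


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return value


def samples_to_frame(samples: Sequence[CompartmentSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        row: dict[str, object] = {
            "compartment": s.compartment.value,
            "date": s.date.isoformat(),
            "depth_m": s.depth_m,
            "basis": s.basis.value,
            "units": s.units.value,
        }
        for ch in IsotopeChannel:
            row[f"conc_{ch.value}"] = s.conc.get(ch)
        rows.append(row)
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def fish_to_frame(fish: Sequence[FishObservation]) -> pd.DataFrame:
    rows = []
    for f in fish:
        row: dict[str, object] = {
            "species": f.species.value,
            "age_class": f.age_class.value if f.age_class else None,
            "fish_id": f.fish_id,
            "date": f.date.isoformat(),
            "fork_length_mm": f.fork_length_mm,
            "mass_g": f.mass_g,
            "dw_proportion": f.dw_proportion,
            "age_years": f.age_years,
        }
        for ch in IsotopeChannel:
            row[f"conc_{ch.value}"] = f.conc_dw.get(ch)
        rows.append(row)
    return pd.DataFrame(rows, columns=FISH_COLUMNS)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")


def _parse_conc(row: pd.Series) -> dict[IsotopeChannel, float]:
    conc = {}
    for ch in IsotopeChannel:
        v = _opt(row[f"conc_{ch.value}"])
        if v is not None:
            conc[ch] = float(v)
    return conc


def frame_to_samples(df: pd.DataFrame, path: Path = Path("samples.csv")) -> list[CompartmentSample]:
    _require_columns(df, SAMPLE_COLUMNS, path)
    out: list[CompartmentSample] = []
    bad: list[tuple[int, str]] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            depth = _opt(row["depth_m"])
            out.append(
                CompartmentSample(
                    compartment=Compartment(row["compartment"]),
                    date=dt.date.fromisoformat(str(row["date"])),
                    depth_m=float(depth) if depth is not None else None,
                    basis=Basis(row["basis"]),
                    units=Units(row["units"]),
                    conc=_parse_conc(pd.Series(row)),
                )
            )
        except (ValidationError, ValueError, KeyError) as exc:
            bad.append((i, str(exc)))
    if bad:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad[:10])
        raise ValidationError(f"{path}: {len(bad)} invalid row(s): {detail}", rows=[i for i, _ in bad])
    return out


def frame_to_fish(df: pd.DataFrame, path: Path = Path("fish.csv")) -> list[FishObservation]:
    _require_columns(df, FISH_COLUMNS, path)
    out: list[FishObservation] = []
    bad: list[tuple[int, str]] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            age_class = _opt(row["age_class"])
            fish_id = _opt(row["fish_id"])
            age_years = _opt(row["age_years"])
            out.append(
                FishObservation(
                    species=Species(row["species"]),
                    age_class=AgeClass(age_class) if age_class is not None else None,
                    fish_id=str(fish_id) if fish_id is not None else None,
                    date=dt.date.fromisoformat(str(row["date"])),
                    fork_length_mm=float(row["fork_length_mm"]),
                    mass_g=float(row["mass_g"]),
                    dw_proportion=float(row["dw_proportion"]),
                    age_years=int(age_years) if age_years is not None else None,
                    conc_dw=_parse_conc(pd.Series(row)),
                )
            )
        except (ValidationError, ValueError, KeyError) as exc:
            bad.append((i, str(exc)))
    if bad:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad[:10])
        raise ValidationError(f"{path}: {len(bad)} invalid row(s): {detail}", rows=[i for i, _ in bad])
    return out


def write_dataset(dataset: Dataset, directory: str | Path) -> dict[str, Path]:
    """Write ``samples.csv`` and ``fish.csv`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": directory / SAMPLES_FILE,
        "fish": directory / FISH_FILE,
    }
    samples_to_frame(dataset.samples).to_csv(paths["samples"], index=False)
    fish_to_frame(dataset.fish).to_csv(paths["fish"], index=False)
    return paths


def read_dataset(directory: str | Path) -> Dataset:
    """Read a dataset directory written by :func:`write_dataset`.

    Either file may be absent (an empty record list results); a present file
    must carry the full schema.  Malformed rows are reported with their
    1-based data-row numbers.
    """
    directory = Path(directory)
    samples: list[CompartmentSample] = []
    fish: list[FishObservation] = []
    sp = directory / SAMPLES_FILE
    fp = directory / FISH_FILE
    if not sp.exists() and not fp.exists():
        raise SchemaError(f"{directory}: neither {SAMPLES_FILE} nor {FISH_FILE} found")
    if sp.exists():
        df = pd.read_csv(sp, dtype={"fish_id": str}, float_precision="round_trip")
        samples = frame_to_samples(df, sp)
    if fp.exists():
        df = pd.read_csv(fp, dtype={"fish_id": str}, float_precision="round_trip")
        fish = frame_to_fish(df, fp)
    return Dataset(samples=samples, fish=fish)
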