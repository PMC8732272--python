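"""Per-year length standardization of fish concentrations and weights.

Large-bodied fish MeHg varies with body size, so annual population values are
reported at a fixed standard fork length (FL): a per-year polynomial of
(optionally square-root transformed) wet-basis concentration on FL is fitted
by ordinary least squares and evaluated at the standard FL.  The same device
standardizes body weight for burden calculations.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import FishObservation, IsotopeChannel, Species
from .errors import InsufficientDataError, SingularDesignError

#: Standard fork lengths (mm): the mean FL of all sampled fish per species.
STANDARD_FORK_LENGTH_MM: dict[Species, float] = {
    Species.NORTHERN_PIKE: 475.0,
    Species.LAKE_WHITEFISH: 530.0,
}


class Model(str, enum.Enum):
    QUADRATIC = "quadratic"
    LINEAR = "linear"
    MEAN = "mean"  # fallback of last resort


class Transform(str, enum.Enum):
    NONE = "none"
    SQRT = "sqrt"


_MIN_N = {Model.QUADRATIC: 4, Model.LINEAR: 3, Model.MEAN: 1}
_DEGREE = {Model.QUADRATIC: 2, Model.LINEAR: 1, Model.MEAN: 0}


class PredictionFlooredWarning(UserWarning):
    """Raised when a negative standardized prediction is floored at zero."""


@dataclass
class LengthFit:
    """An OLS polynomial of (transformed) response on fork length."""

    model: Model
    transform: Transform
    coefficients: np.ndarray  # ascending powers of FL (mm)
    n: int
    rss: float
    species: Species | None = None
    year: int | None = None
    channel: IsotopeChannel | None = None

    def predict_raw(self, fork_length_mm: float) -> float:
        """Polynomial value on the (possibly transformed) response scale."""
        return float(np.polynomial.polynomial.polyval(fork_length_mm, self.coefficients))


def _fit_poly(x: np.ndarray, y: np.ndarray, degree: int) -> tuple[np.ndarray, float]:
    # OLS via the Vandermonde least-squares route; the tests cross-check it
    # against an explicit normal-equations solve.
    X = np.vander(x, degree + 1, increasing=True)
    if np.linalg.matrix_rank(X) < degree + 1:
        raise SingularDesignError(
            "design matrix is rank deficient (all fork lengths identical?)"
        )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def fit_length_response(
    fork_lengths_mm: Sequence[float],
    response: Sequence[float],
    model: Model | str = Model.QUADRATIC,
    transform: Transform | str = Transform.NONE,
    species: Species | None = None,
    year: int | None = None,
    channel: IsotopeChannel | None = None,
) -> LengthFit:
    """Fit (transformed) response vs. fork length for one species-year.

    The sqrt transform is applied to the response before fitting and recorded
    on the fit so prediction back-transforms by squaring.  Minimum sample
    sizes keep at least one residual degree of freedom: quadratic needs
    n >= 4, linear n >= 3.
    """
    model = Model(model)
    transform = Transform(transform)
    x = np.asarray(fork_lengths_mm, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("fork lengths and response must be 1-D and equal length")
    n = x.size
    if n < _MIN_N[model]:
        raise InsufficientDataError(
            f"{model.value} fit needs n >= {_MIN_N[model]}, got {n}"
        )
    if transform is Transform.SQRT:
        if np.any(y < 0):
            raise ValueError("sqrt transform requires non-negative response")
        y = np.sqrt(y)
    coef, rss = _fit_poly(x, y, _DEGREE[model])
    return LengthFit(
        model=model,
        transform=transform,
        coefficients=coef,
        n=n,
        rss=rss,
        species=species,
        year=year,
        channel=channel,
    )


def standardized_concentration(fit: LengthFit, standard_fl_mm: float) -> float:
    """Evaluate the fit at the standard fork length, back-transforming.

    Negative raw predictions are floored at 0 (with a warning); a sqrt-scale
    fit squares its floored prediction.
    """
    if standard_fl_mm <= 0:
        raise ValueError(f"standard_fl_mm must be > 0, got {standard_fl_mm}")
    pred = fit.predict_raw(standard_fl_mm)
    if pred < 0:
        warnings.warn(
            f"standardized prediction {pred:.4g} at FL={standard_fl_mm} floored at 0",
            PredictionFlooredWarning,
            stacklevel=2,
        )
        pred = 0.0
    if fit.transform is Transform.SQRT:
        return pred * pred
    return pred


def standardized_weight(
    fork_lengths_mm: Sequence[float],
    masses_g: Sequence[float],
    standard_fl_mm: float,
) -> float:
    """Body weight (g) at the standard FL from a quadratic FL-weight fit."""
    fit = fit_length_response(fork_lengths_mm, masses_g, Model.QUADRATIC, Transform.NONE)
    return standardized_concentration(fit, standard_fl_mm)


@dataclass
class StandardizedValue:
    year: int
    value: float
    model: Model
    transform: Transform
    n: int
    rss: float
    quality: str  # "quadratic" | "linear_fallback" | "mean_fallback"


def standardize_species_year(
    obs: Sequence[FishObservation],
    channel: IsotopeChannel,
    standard_fl_mm: float,
    transform: Transform | str = Transform.NONE,
) -> StandardizedValue:
    """Standardize one species-year with the quadratic->linear->mean ladder.

    Falls back to a lower-order model when too few fish were caught; the
    resulting quality flag records which rung was used.
    """
    transform = Transform(transform)
    obs = [o for o in obs if channel in o.conc_dw]
    if not obs:
        raise InsufficientDataError("no observations carry the requested channel")
    years = {o.year for o in obs}
    if len(years) != 1:
        raise ValueError(f"observations span multiple years: {sorted(years)}")
    (year,) = years
    x = [o.fork_length_mm for o in obs]
    y = [o.conc_ww(channel) for o in obs]
    for model, quality in (
        (Model.QUADRATIC, "quadratic"),
        (Model.LINEAR, "linear_fallback"),
    ):
        try:
            fit = fit_length_response(x, y, model, transform)
        except (InsufficientDataError, SingularDesignError):
            continue
        value = standardized_concentration(fit, standard_fl_mm)
        return StandardizedValue(year, value, model, transform, fit.n, fit.rss, quality)
    mean = float(np.mean(y))
    return StandardizedValue(
        year, mean, Model.MEAN, transform, len(obs), float(np.sum((np.asarray(y) - mean) ** 2)), "mean_fallback"
    )


def annual_standardized_series(
    obs: Sequence[FishObservation],
    species: Species,
    channel: IsotopeChannel,
    standard_fl_mm: float | None = None,
    transform: Transform | str | None = None,
) -> dict[int, StandardizedValue]:
    """Per-year standardized concentrations for one species and channel.

    Pike concentrations are sqrt-transformed before fitting unless a
    transform is given explicitly.
    """
    if standard_fl_mm is None:
        standard_fl_mm = STANDARD_FORK_LENGTH_MM[species]
    if transform is None:
        transform = Transform.SQRT if species is Species.NORTHERN_PIKE else Transform.NONE
    by_year: dict[int, list[FishObservation]] = {}
    for o in obs:
        if o.species is species:
            by_year.setdefault(o.year, []).append(o)
    out: dict[int, StandardizedValue] = {}
    for year in sorted(by_year):
        try:
            out[year] = standardize_species_year(by_year[year], channel, standard_fl_mm, transform)
        except InsufficientDataError:
            continue
    return out


def annual_standardized_weight(
    obs: Sequence[FishObservation],
    species: Species,
    standard_fl_mm: float | None = None,
) -> dict[int, float]:
    """Per-year body weight at the standard FL (quadratic FL-weight fit)."""
    if standard_fl_mm is None:
        standard_fl_mm = STANDARD_FORK_LENGTH_MM[species]
    by_year: dict[int, list[FishObservation]] = {}
    for o in obs:
        if o.species is species:
            by_year.setdefault(o.year, []).append(o)
    out: dict[int, float] = {}
    for year in sorted(by_year):
        group = by_year[year]
        try:
            out[year] = standardized_weight(
                [o.fork_length_mm for o in group], [o.mass_g for o in group], standard_fl_mm
            )
        except (InsufficientDataError, SingularDesignError):
            if len(group) >= 1:
                out[year] = float(np.mean([o.mass_g for o in group]))
    return out
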