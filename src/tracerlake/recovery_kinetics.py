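"""Body burdens, burden normalization, exponential-decay fits and half-life.

The population recovery analysis multiplies length-standardized concentration
by length-standardized body weight to obtain a per-year population body
burden, normalizes each year to the burden at the end of additions (t0), and
fits ``y = a * exp(-k x)`` to the normalized series (x in years since t0,
starting at a configurable offset into recovery).  The time at which the
fitted curve crosses a given fraction of the original burden follows
analytically as ``t = ln(a / fraction) / k``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .data_model import FishObservation, IsotopeChannel
from .errors import InsufficientDataError, UndefinedResultError, ValidationError


@dataclass(frozen=True)
class BurdenRecord:
    """Per-year body burden (ng) and its fraction of the t0 burden."""

    label: str  # fish_id or "population"
    year: int
    burden_ng: float
    normalized: float | None = None


@dataclass
class DecayFit:
    """Fitted ``y = amplitude * exp(-rate * x)`` with goodness of fit.

    ``r_squared`` is computed on the untransformed y (1 - RSS/TSS); the F
    statistic carries (1, n-2) degrees of freedom.  ``rate_se`` is the
    asymptotic standard error of the rate from the NLS covariance.
    """

    amplitude: float
    rate: float
    r_squared: float
    f_stat: float
    p_value: float
    n: int
    start_offset: float
    rate_se: float = float("nan")
    degenerate: bool = False

    def predict(self, x: float) -> float:
        return self.amplitude * math.exp(-self.rate * x)

    def rate_confidence_interval(self, level: float = 0.95) -> tuple[float, float]:
        """Wald interval for the decay rate using the t quantile on n-2 df
        (the z quantile undercovers badly at the small n typical here)."""
        if not math.isfinite(self.rate_se):
            raise UndefinedResultError("rate standard error unavailable")
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.n - 2)
        return self.rate - tcrit * self.rate_se, self.rate + tcrit * self.rate_se


class BelowThresholdAtStartWarning(UserWarning):
    """The fitted curve starts below the requested fraction (negative time)."""


def body_burden(conc_ww: float, mass_g: float) -> float:
    """Whole-body burden (ng): wet-basis concentration (ng/g) x mass (g)."""
    if mass_g <= 0:
        raise ValidationError(f"mass_g must be > 0, got {mass_g}")
    if conc_ww < 0:
        raise ValidationError(f"conc_ww must be >= 0, got {conc_ww}")
    return conc_ww * mass_g


def normalize_burden(burden_t: float, burden_t0: float) -> float:
    """Burden at time t as a fraction of the burden at t0."""
    if burden_t0 <= 0:
        raise ValidationError(f"burden_t0 must be > 0, got {burden_t0}")
    if burden_t < 0:
        raise ValidationError(f"burden_t must be >= 0, got {burden_t}")
    return burden_t / burden_t0


def population_burden_series(
    standardized_conc: Mapping[int, float],
    standardized_weight: Mapping[int, float],
    t0_year: int,
    label: str = "population",
) -> list[BurdenRecord]:
    """Per-year standardized population burden, normalized to t0.

    Years missing from either input are propagated as missing (omitted), but
    t0 itself must be present in both.
    """
    years = sorted(set(standardized_conc) & set(standardized_weight))
    if t0_year not in years:
        raise InsufficientDataError(
            f"t0 year {t0_year} absent from the overlapping series; cannot normalize"
        )
    b0 = body_burden(standardized_conc[t0_year], standardized_weight[t0_year])
    if b0 <= 0:
        raise ValidationError(f"t0 burden is {b0}; normalization undefined")
    return [
        BurdenRecord(
            label=label,
            year=y,
            burden_ng=body_burden(standardized_conc[y], standardized_weight[y]),
            normalized=normalize_burden(
                body_burden(standardized_conc[y], standardized_weight[y]), b0
            ),
        )
        for y in years
    ]


def individual_burden_trajectories(
    fish: Sequence[FishObservation],
    t0_year: int,
    channel: IsotopeChannel = IsotopeChannel.LAKE_SPIKE,
) -> dict[str, list[BurdenRecord]]:
    """Normalized burden trajectories for recaptured, tagged individuals.

    Only fish with a t0-year capture anchor a trajectory; later captures of
    the same tag are normalized to that fish's own t0 burden.  Trajectories
    never mix tags.
    """
    by_id: dict[str, list[FishObservation]] = {}
    for f in fish:
        if f.fish_id is None or channel not in f.conc_dw:
            continue
        by_id.setdefault(f.fish_id, []).append(f)
    out: dict[str, list[BurdenRecord]] = {}
    for fid, captures in by_id.items():
        captures = sorted(captures, key=lambda f: f.date)
        t0_caps = [f for f in captures if f.year == t0_year]
        if not t0_caps or len(captures) < 2:
            continue
        b0 = body_burden(t0_caps[0].conc_ww(channel), t0_caps[0].mass_g)
        if b0 <= 0:
            continue
        out[fid] = [
            BurdenRecord(
                label=fid,
                year=f.year,
                burden_ng=body_burden(f.conc_ww(channel), f.mass_g),
                normalized=normalize_burden(body_burden(f.conc_ww(channel), f.mass_g), b0),
            )
            for f in captures
        ]
    return out


def fit_exponential_decay(
    x: Sequence[float],
    y: Sequence[float],
    start_offset: float = 2.0,
) -> DecayFit:
    """Nonlinear least squares of ``y = a exp(-k x)`` on untransformed y.

    Points with ``x < start_offset`` are excluded (the fit begins a fixed
    number of years into recovery); non-positive y among the remaining points
    is excluded with a warning because the log-linear initializer requires
    positivity.  A zero-variance series is degenerate: k = 0 is reported with
    ``degenerate=True`` and no test statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    keep = x >= start_offset
    x, y = x[keep], y[keep]
    pos = y > 0
    if not np.all(pos):
        warnings.warn(
            f"excluding {int((~pos).sum())} non-positive y value(s) from decay fit",
            UserWarning,
            stacklevel=2,
        )
        x, y = x[pos], y[pos]
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"decay fit needs >= 3 usable points, got {n}")

    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0.0:
        return DecayFit(
            amplitude=float(y[0]),
            rate=0.0,
            r_squared=1.0,
            f_stat=float("nan"),
            p_value=float("nan"),
            n=n,
            start_offset=start_offset,
            degenerate=True,
        )

    # log-linear OLS initializer (exact optimum on noiseless data)
    slope, intercept = np.polyfit(x, np.log(y), 1)
    p0 = (math.exp(intercept), -slope)

    def model(xv, a, k):
        return a * np.exp(-k * xv)

    popt, pcov = optimize.curve_fit(model, x, y, p0=p0, maxfev=10000)
    a, k = float(popt[0]), float(popt[1])
    rate_se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("nan")
    resid = y - model(x, a, k)
    rss = float(resid @ resid)
    r2 = 1.0 - rss / tss
    if rss <= 0.0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (n - 2) * r2 / (1.0 - r2) if r2 < 1.0 else float("inf")
        p = float(stats.f.sf(f_stat, 1, n - 2)) if math.isfinite(f_stat) else 0.0
    return DecayFit(
        amplitude=a,
        rate=k,
        r_squared=r2,
        f_stat=f_stat,
        p_value=p,
        n=n,
        start_offset=start_offset,
        rate_se=rate_se,
    )


def fit_burden_decay(
    records: Sequence[BurdenRecord],
    t0_year: int,
    start_offset: float = 2.0,
) -> DecayFit:
    """Decay fit of normalized population burden vs. years since t0."""
    pts = [(r.year - t0_year, r.normalized) for r in records if r.normalized is not None]
    if not pts:
        raise InsufficientDataError("no normalized burden records")
    x, y = zip(*pts)
    return fit_exponential_decay(x, y, start_offset=start_offset)


def time_to_fraction(fit: DecayFit, fraction: float = 0.5) -> float:
    """Years since t0 at which the fitted curve equals ``fraction`` of the
    original (t0) burden: ``t = ln(a / fraction) / k``.

    The fraction refers to the normalized burden itself (y), not to the fitted
    value at x = 0.  A non-positive rate means no decline and the time is
    undefined; a curve already below the fraction at x = 0 yields a negative
    time, returned with a warning.
    """
    if not 0.0 < fraction:
        raise ValueError(f"fraction must be > 0, got {fraction}")
    if fit.rate <= 0 or fit.degenerate:
        raise UndefinedResultError(
            f"decay rate {fit.rate} is not positive; time to fraction undefined"
        )
    t = math.log(fit.amplitude / fraction) / fit.rate
    if t < 0:
        warnings.warn(
            f"fitted curve starts below fraction {fraction} (t = {t:.3g} yr)",
            BelowThresholdAtStartWarning,
            stacklevel=2,
        )
    return t
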