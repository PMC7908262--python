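"""Exposure estimation: lognormal fit, Monte Carlo CTE/RME, dose adjustment.

Workplace air concentrations are modelled as lognormal, the standard
distribution for occupational hygiene series.  The central tendency
estimate (CTE) and reasonable maximum estimate (RME) are defined on the
sampling distribution of the *arithmetic mean* exposure: each Monte Carlo
iteration redraws a series of the observed size from the fitted lognormal
and records its mean; the CTE is the average of those iteration means and
the RME an upper quantile (default the 95th percentile) of them.  This
parametric-bootstrap reading matches the modest RME/CTE ratios seen in
published workplace summaries (roughly 1.1-1.5), which are far too tight
to be upper percentiles of individual measurements under typical
geometric standard deviations.

Schedule adjustments convert a workplace concentration into an
average-daily (ADD-style) or lifetime-average-daily (LADD-style)
concentration by time-weighting: hours/24 x days/365 x years exposed over
years averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, NoOELError, SchemaError
from .registry import MeasurementTable


@dataclass(frozen=True)
class ExposureFactors:
    """Exposure schedule: hours/day, days/year, years exposed and the
    averaging time.  ``averaging_years`` equal to ``exposure_years`` gives
    the ADD-style weighting; setting it to a full lifetime gives LADD."""

    hours_per_day: float = 8.0
    days_per_year: float = 240.0
    exposure_years: float = 25.0
    averaging_years: float = 25.0

    def __post_init__(self) -> None:
        if not 0 < self.hours_per_day <= 24:
            raise ValueError("hours_per_day must lie in (0, 24]")
        if not 0 < self.days_per_year <= 365:
            raise ValueError("days_per_year must lie in (0, 365]")
        if self.exposure_years <= 0 or self.averaging_years <= 0:
            raise ValueError("exposure and averaging years must be positive")

    def over_lifetime(self, lifetime_years: float) -> "ExposureFactors":
        return replace(self, averaging_years=lifetime_years)


@dataclass(frozen=True)
class LognormalFit:
    gm: float  # geometric mean, mg/m3
    gsd: float  # geometric standard deviation, dimensionless
    n: int

    def __post_init__(self) -> None:
        if not self.gm > 0:
            raise ValueError("gm must be positive")
        if not self.gsd >= 1:
            raise ValueError("gsd must be >= 1")

    @property
    def arithmetic_mean(self) -> float:
        """Closed-form lognormal mean, gm * exp(ln(gsd)^2 / 2)."""
        return self.gm * float(np.exp(0.5 * np.log(self.gsd) ** 2))


@dataclass(frozen=True)
class ExposureSummary:
    """CTE/RME exposure statistics for one substance (mg/m3).

    ``n_iterations``, ``seed`` and ``rme_percentile`` record how the
    Monte Carlo was run; they are ``None`` for summaries supplied directly
    (e.g. transcribed from a published table) rather than simulated.
    """

    substance_ref: str
    cte: float
    rme: float
    n_measurements: int
    n_iterations: int | None = None
    seed: int | None = None
    rme_percentile: float | None = None

    def __post_init__(self) -> None:
        if not self.cte > 0:
            raise ValueError("cte must be positive")
        if not self.rme > 0:
            raise ValueError("rme must be positive")


def fit_lognormal(measurements: MeasurementTable) -> LognormalFit:
    """Moment fit on the log scale: gm = exp(mean log), gsd = exp(sample
    standard deviation of logs, n-1 denominator).  Requires n >= 2."""
    if measurements.n < 2:
        raise InsufficientDataError(
            f"{measurements.substance_ref}: need at least 2 measurements to fit, "
            f"got {measurements.n}"
        )
    logs = np.log(np.asarray(measurements.values, dtype=float))
    return LognormalFit(
        gm=float(np.exp(logs.mean())),
        gsd=float(np.exp(logs.std(ddof=1))),
        n=measurements.n,
    )


def monte_carlo_summary(
    measurements: MeasurementTable,
    n_iterations: int = 10_000,
    seed: int = 0,
    rme_percentile: float = 0.95,
) -> ExposureSummary:
    """Parametric-bootstrap CTE/RME of the mean exposure.

    Each iteration draws ``n`` values from the fitted lognormal and takes
    their arithmetic mean; CTE is the average of iteration means and RME
    the ``rme_percentile`` quantile.  Bit-reproducible for a given seed.
    """
    if n_iterations < 1000:
        raise ValueError("n_iterations must be at least 1000")
    if not 0.5 < rme_percentile < 1.0:
        raise ValueError("rme_percentile must lie in (0.5, 1)")
    fit = fit_lognormal(measurements)
    rng = np.random.default_rng(seed)
    draws = rng.lognormal(
        mean=np.log(fit.gm), sigma=np.log(fit.gsd), size=(n_iterations, fit.n)
    )
    means = draws.mean(axis=1)
    return ExposureSummary(
        substance_ref=measurements.substance_ref,
        cte=float(means.mean()),
        rme=float(np.quantile(means, rme_percentile)),
        n_measurements=fit.n,
        n_iterations=n_iterations,
        seed=seed,
        rme_percentile=rme_percentile,
    )


def ratio_to_oel(summary: ExposureSummary, oel: float | None) -> float:
    """RME as a percentage of the occupational exposure limit."""
    if oel is None:
        raise NoOELError(
            f"{summary.substance_ref}: no OEL available; fall back to "
            "handling-based exposure banding"
        )
    if not oel > 0:
        raise ValueError("oel must be positive")
    return 100.0 * summary.rme / oel


def adjusted_concentration(c: float, factors: ExposureFactors) -> float:
    """Schedule-weighted concentration: c x h/24 x d/365 x years ratio."""
    if c < 0:
        raise ValueError("concentration must be non-negative")
    return (
        c
        * (factors.hours_per_day / 24.0)
        * (factors.days_per_year / 365.0)
        * (factors.exposure_years / factors.averaging_years)
    )


# ---------------------------------------------------------------------------
# summaries.csv interchange (pre-summarised CTE/RME, the shape in which
# published studies report exposure)

SUMMARY_COLUMNS = ["cas", "cte_mg_m3", "rme_mg_m3", "n_measurements"]


def read_summaries(path: str) -> list[ExposureSummary]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return [
        ExposureSummary(
            substance_ref=str(rec["cas"]).strip(),
            cte=float(rec["cte_mg_m3"]),
            rme=float(rec["rme_mg_m3"]),
            n_measurements=int(rec["n_measurements"]),
        )
        for rec in df.to_dict("records")
    ]


def write_summaries(summaries: list[ExposureSummary], path: str) -> None:
    rows = [{
        "cas": s.substance_ref, "cte_mg_m3": repr(s.cte), "rme_mg_m3": repr(s.rme),
        "n_measurements": s.n_measurements,
    } for s in summaries]
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(path, index=False)
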