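"""Quantitative risk characterisation: RfC, hazard quotient, cancer risk.

The reference concentration divides a point of departure (NOAEL or
LOAEL) by uncertainty and modifying factors:

    RfC = POD / (UF x MF)

An RfC derived for continuous exposure is rescaled to the occupational
schedule (RfC_work = RfC x 24/h x 365/d, the usual continuous-to-worker
duration correction), and the hazard quotient compares the workplace
exposure level with it:

    HQ = E / RfC_work

computed at both the CTE and the RME exposure level.  For carcinogens
the excess cancer risk is the inhalation unit risk times the
lifetime-average concentration (ECR = UR x LADC).

Both metrics band onto the shared four-level scale.  HQ uses the
management criterion 1: >1 very high, 0.5-1 (closed) high, 0.1-0.5
(right-open) moderate, <0.1 low.  ECR uses the 1e-4 management
criterion: it is divided by 1e-4 and banded on the same edges, so
ECR = 1e-4 is exactly "high" just as HQ = 1 is.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import LEVELS, LEVEL_ORDER, BandTables, RunConfig
from .exposure import ExposureSummary, adjusted_concentration
from .registry import Substance, ToxicityProfile


@dataclass(frozen=True)
class QuantitativeResult:
    substance_ref: str
    rfc: float  # continuous-exposure reference concentration, mg/m3
    rfc_work: float  # occupational-schedule reference concentration, mg/m3
    hq_cte: float
    hq_rme: float
    ecr_cte: float | None = None
    ecr_rme: float | None = None
    scaled_ecr_cte: float | None = None
    scaled_ecr_rme: float | None = None
    level_cte: str = "low"
    level_rme: str = "low"
    metric_used: str = "hq"

    def __post_init__(self) -> None:
        assert self.rfc > 0 and self.rfc_work > 0
        assert self.hq_cte >= 0 and self.hq_rme >= 0
        assert self.level_cte in LEVELS and self.level_rme in LEVELS


def reference_concentration(profile: ToxicityProfile) -> float:
    """RfC (or RfD) = POD / (UF x MF)."""
    return profile.pod_value / (profile.uf * profile.mf)


def workplace_rfc(rfc: float, factors: ExposureFactors) -> float:
    """Rescale a continuous-exposure RfC to the working schedule.

    A limit protective over 24 h/day, 365 d/year is less restrictive over
    a shorter schedule, so the RfC is multiplied by 24/hours and
    365/days; a continuous schedule leaves it unchanged.
    """
    if not rfc > 0:
        raise ValueError("rfc must be positive")
    return rfc * (24.0 / factors.hours_per_day) * (365.0 / factors.days_per_year)


def hazard_quotient(e: float, rfc: float) -> float:
    """HQ = E / RfC."""
    if not rfc > 0:
        raise ValueError("rfc must be positive")
    if e < 0:
        raise ValueError("exposure level must be non-negative")
    return e / rfc


def excess_cancer_risk(unit_risk: float, lifetime_concentration: float) -> float:
    """ECR = unit risk x lifetime-average concentration."""
    if unit_risk < 0 or lifetime_concentration < 0:
        raise ValueError("unit risk and concentration must be non-negative")
    return unit_risk * lifetime_concentration


def quantitative_level(
    value: float, metric: str = "hq", bands: BandTables | None = None
) -> str:
    """Band an HQ (or an ECR, after scaling by the 1e-4 criterion) onto
    the four-level scale: <0.1 low, [0.1, 0.5) moderate, [0.5, 1] high,
    >1 very high."""
    if value < 0:
        raise ValueError("value must be non-negative")
    bands = bands or BandTables()
    if metric == "ecr":
        value = value / bands.ecr_criterion
    elif metric != "hq":
        raise ValueError(f"unknown metric {metric!r}")
    lo, mid, hi = bands.hq_edges
    # band edges are compared with a relative tolerance so a quotient that
    # is *exactly* at an edge up to float rounding (e.g. E equal to
    # RfC_work reconstructed through the schedule adjustment) lands on the
    # side the edge convention dictates
    tol = 1e-9
    if value > hi * (1 + tol):
        return "very_high"
    if value >= mid * (1 - tol):
        return "high"
    if value >= lo * (1 - tol):
        return "moderate"
    return "low"


def assess_quantitative(
    substance: Substance,
    profile: ToxicityProfile,
    summary: ExposureSummary,
    config: RunConfig | None = None,
) -> QuantitativeResult:
    """Full quantitative assessment of one substance at CTE and RME.

    HQ compares the measured workplace level directly with the
    schedule-rescaled RfC_work.  When a unit risk is available the ECR is
    additionally computed from the lifetime-average concentration; the
    classifying metric defaults to HQ and can be switched to ECR via
    ``config.classification_metric``.
    """
    config = config or RunConfig()
    factors = config.lifetime_factors()
    rfc = reference_concentration(profile)
    rfc_w = workplace_rfc(rfc, config.work_factors())
    hq_cte = hazard_quotient(summary.cte, rfc_w)
    hq_rme = hazard_quotient(summary.rme, rfc_w)

    ecr_cte = ecr_rme = scaled_cte = scaled_rme = None
    if profile.unit_risk is not None:
        ecr_cte = excess_cancer_risk(
            profile.unit_risk, adjusted_concentration(summary.cte, factors))
        ecr_rme = excess_cancer_risk(
            profile.unit_risk, adjusted_concentration(summary.rme, factors))
        scaled_cte = ecr_cte / config.bands.ecr_criterion
        scaled_rme = ecr_rme / config.bands.ecr_criterion

    metric = config.classification_metric
    if metric == "ecr" and ecr_cte is None:
        metric = "hq"  # no unit risk: ECR cannot classify this substance
    if metric == "ecr":
        level_cte = quantitative_level(ecr_cte, "ecr", config.bands)
        level_rme = quantitative_level(ecr_rme, "ecr", config.bands)
    else:
        level_cte = quantitative_level(hq_cte, "hq", config.bands)
        level_rme = quantitative_level(hq_rme, "hq", config.bands)

    result = QuantitativeResult(
        substance_ref=substance.cas,
        rfc=rfc,
        rfc_work=rfc_w,
        hq_cte=hq_cte,
        hq_rme=hq_rme,
        ecr_cte=ecr_cte,
        ecr_rme=ecr_rme,
        scaled_ecr_cte=scaled_cte,
        scaled_ecr_rme=scaled_rme,
        level_cte=level_cte,
        level_rme=level_rme,
        metric_used=metric,
    )
    if summary.rme >= summary.cte:
        assert LEVEL_ORDER[result.level_rme] >= LEVEL_ORDER[result.level_cte]
    return result
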