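"""CHARM-style qualitative (control-banding) risk assessment.

Risk is the product of an exposure class and a hazard class, each on a
1-4 scale:

    risk grade = exposure class (probability) x hazard class (severity)

Exposure class, in priority order: (1) a history of occupational disease
attributable to the substance forces the highest class; (2) otherwise
workplace measurement results banded as a percentage of the OEL
(<10% -> 1, 10-50% -> 2, 50-100% -> 3, >=100% -> 4, lower edges
inclusive); (3) otherwise a handling-amount x volatility lookup.

Hazard class, in priority order: (1) any CMR classification (category
1A, 1B or 2 on any axis) -> class 4; (2) otherwise banded by OEL (the
lower the limit, the higher the severity); (3) otherwise the maximum
class over the substance's H-phrases.

The 16 possible grades collapse onto the shared four-level scale
(1-2 low, 3-4 moderate, 5-11 high, 12-16 very high).  Moderate risk is
permissible only for non-CMR substances; high and very-high never are.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import LEVELS, BandTables, RunConfig
from .errors import InsufficientDataError, NoHazardRouteError, NoOELError
from .exposure import ExposureSummary, ratio_to_oel
from .registry import HANDLING_AMOUNTS, VOLATILITIES, Substance

#: Grades reachable as a product of two classes in 1..4.
REACHABLE_GRADES = frozenset(
    e * h for e in (1, 2, 3, 4) for h in (1, 2, 3, 4)
)  # {1, 2, 3, 4, 6, 8, 9, 12, 16}

EXPOSURE_ROUTES = ("disease", "measurement", "handling")
HAZARD_ROUTES = ("cmr", "oel", "h_phrase")


@dataclass(frozen=True)
class QualitativeResult:
    substance_ref: str
    exposure_class: int
    exposure_route: str
    hazard_class: int
    hazard_route: str
    grade: int
    level: str
    status: str  # acceptable | unacceptable

    def __post_init__(self) -> None:
        assert self.grade == self.exposure_class * self.hazard_class
        assert self.grade in REACHABLE_GRADES
        assert self.level in LEVELS


def exposure_class_from_measurement(
    ratio: float, bands: BandTables | None = None
) -> int:
    """Band an RME/OEL percentage into an exposure class (lower edges
    inclusive: a ratio exactly at an edge takes the higher class)."""
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    edges = (bands or BandTables()).exposure_ratio_edges
    cls = 1
    for edge in edges:
        if ratio >= edge:
            cls += 1
    return cls


def exposure_class_from_handling(
    amount: str | None, volatility: str | None, bands: BandTables | None = None
) -> int:
    """Fallback exposure class from the handling-amount x volatility matrix."""
    if amount is None or volatility is None:
        raise InsufficientDataError(
            "handling-based banding needs both handling_amount and volatility"
        )
    matrix = (bands or BandTables()).handling_matrix
    return matrix[HANDLING_AMOUNTS.index(amount)][VOLATILITIES.index(volatility)]


def determine_exposure_class(
    substance: Substance,
    summary: ExposureSummary | None = None,
    bands: BandTables | None = None,
) -> tuple[int, str]:
    """Apply the exposure-route priority: disease history, then
    measurements against the OEL, then handling bands."""
    if substance.disease_history:
        return 4, "disease"
    if summary is not None:
        try:
            return (
                exposure_class_from_measurement(ratio_to_oel(summary, substance.oel), bands),
                "measurement",
            )
        except NoOELError:
            pass  # measurements without an OEL cannot be banded; fall through
    return (
        exposure_class_from_handling(
            substance.handling_amount, substance.volatility, bands
        ),
        "handling",
    )


def determine_hazard_class(
    substance: Substance, bands: BandTables | None = None
) -> tuple[int, str]:
    """Apply the hazard-route priority: CMR, then OEL severity, then
    H-phrase severity."""
    bands = bands or BandTables()
    if substance.is_cmr:
        return 4, "cmr"
    if substance.oel is not None:
        cls = 4
        for edge in bands.oel_hazard_edges:
            if substance.oel > edge:
                cls -= 1
        return cls, "oel"
    known = [bands.h_phrase_classes[p] for p in substance.h_phrases
             if p in bands.h_phrase_classes]
    if known:
        return max(known), "h_phrase"
    raise NoHazardRouteError(
        f"{substance.name} ({substance.cas}): no CMR classification, no OEL "
        "and no classifiable H-phrases"
    )


def risk_grade(exposure_class: int, hazard_class: int) -> int:
    if exposure_class not in (1, 2, 3, 4) or hazard_class not in (1, 2, 3, 4):
        raise ValueError("classes must be integers 1-4")
    return exposure_class * hazard_class


def qualitative_level(grade: int, bands: BandTables | None = None) -> str:
    """Collapse a 1-16 risk grade onto the four-level scale."""
    if not 1 <= grade <= 16:
        raise ValueError(f"grade must lie in 1..16, got {grade}")
    edges = (bands or BandTables()).grade_level_edges
    idx = sum(grade >= edge for edge in edges)
    return LEVELS[idx]


def permissible_status(level: str, is_cmr: bool) -> str:
    """Moderate risk is acceptable only for non-CMR substances; high and
    very-high are never acceptable, low always is."""
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    if level in ("high", "very_high"):
        return "unacceptable"
    if level == "moderate":
        return "unacceptable" if is_cmr else "acceptable"
    return "acceptable"


def assess_qualitative(
    substance: Substance,
    summary: ExposureSummary | None = None,
    config: RunConfig | None = None,
) -> QualitativeResult:
    """Full qualitative assessment of one substance."""
    bands = (config or RunConfig()).bands
    exposure_class, exposure_route = determine_exposure_class(substance, summary, bands)
    hazard_class, hazard_route = determine_hazard_class(substance, bands)
    grade = risk_grade(exposure_class, hazard_class)
    level = qualitative_level(grade, bands)
    return QualitativeResult(
        substance_ref=substance.cas,
        exposure_class=exposure_class,
        exposure_route=exposure_route,
        hazard_class=hazard_class,
        hazard_route=hazard_route,
        grade=grade,
        level=level,
        status=permissible_status(level, substance.is_cmr),
    )
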