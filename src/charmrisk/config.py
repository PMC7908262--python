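"""Run configuration: band tables, schedule factors and simulation settings.

Every numeric constant of the banding scheme lives here rather than in the
assessment code, so a study can swap any table without touching the
pipeline:

* measurement-based exposure banding edges (percent of OEL, 10/50/100,
  lower edge inclusive);
* the handling-amount x volatility fallback matrix;
* the OEL severity table and the H-phrase severity map used when a
  substance has no CMR classification (these two tables are not part of
  the published banding rules; the shipped defaults are COSHH-essentials
  style choices and are expected to be overridden by local guidance);
* the 16-grade to 4-level mapping (grades 12-16 very high, 5-11 high,
  3-4 moderate, 1-2 low);
* hazard-quotient banding edges (0.1/0.5/1; "0.5 to 1" closed, ">1"
  open) and the 1e-4 excess-cancer-risk management criterion.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import ConfigError
from .exposure import ExposureFactors

#: The shared four-level risk scale, worst last.
LEVELS: tuple[str, ...] = ("low", "moderate", "high", "very_high")

#: Position of each level on the ordered scale (for monotonicity checks).
LEVEL_ORDER: dict[str, int] = {lv: i for i, lv in enumerate(LEVELS)}

HANDLING_AMOUNTS: tuple[str, ...] = ("small", "medium", "large")
VOLATILITIES: tuple[str, ...] = ("low", "medium", "high")

#: Default H-phrase -> hazard class map (fallback route when a substance
#: has neither a CMR classification nor an OEL).  Severity follows the
#: GHS statement semantics: CMR statements band highest, acute lethal /
#: specific-organ statements next, irritants below, narcotic or low
#: acute-toxicity statements lowest.
DEFAULT_H_PHRASE_CLASSES: dict[str, int] = {
    # carcinogenic / mutagenic / reproductive-toxic
    "H350": 4, "H340": 4, "H360": 4,
    # fatal or serious organ damage
    "H330": 4, "H300": 4, "H310": 4, "H370": 3, "H372": 3,
    # suspected CMR, toxic
    "H351": 3, "H341": 3, "H361": 3, "H331": 3, "H301": 3, "H311": 3,
    # irritation / sensitisation / harmful
    "H335": 2, "H332": 2, "H315": 2, "H319": 2, "H317": 2,
    "H302": 2, "H312": 2, "H371": 2, "H373": 2,
    # narcotic effects, low acute toxicity
    "H336": 1, "H303": 1, "H313": 1, "H333": 1,
}


def _default_handling_matrix() -> list[list[int]]:
    # rows: handling amount small/medium/large; cols: volatility low/medium/high
    return [[1, 2, 2], [2, 3, 3], [2, 3, 4]]


@dataclass
class BandTables:
    """All classification tables used by the two assessment tracks."""

    #: Measurement route: RME as percent of OEL; class k+1 at edge k (lower
    #: edge inclusive): <10 -> 1, [10,50) -> 2, [50,100) -> 3, >=100 -> 4.
    exposure_ratio_edges: tuple[float, float, float] = (10.0, 50.0, 100.0)
    #: Handling-amount x volatility fallback exposure matrix.
    handling_matrix: list[list[int]] = field(default_factory=_default_handling_matrix)
    #: OEL severity route: OEL <= edge[0] -> class 4, <= edge[1] -> 3,
    #: <= edge[2] -> 2, else 1 (lower limit means greater severity). mg/m3.
    oel_hazard_edges: tuple[float, float, float] = (0.1, 1.0, 10.0)
    #: H-phrase severity route: class is the maximum over present phrases.
    h_phrase_classes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_H_PHRASE_CLASSES)
    )
    #: 16-grade scale to four levels: grade >= edge -> at least that level.
    #: (moderate_from, high_from, very_high_from)
    grade_level_edges: tuple[int, int, int] = (3, 5, 12)
    #: Hazard-quotient banding: < edge[0] low, [edge[0], edge[1]) moderate,
    #: [edge[1], edge[2]] high, > edge[2] very high.
    hq_edges: tuple[float, float, float] = (0.1, 0.5, 1.0)
    #: Excess-cancer-risk management criterion; ECR is divided by this and
    #: then banded on the HQ scale.
    ecr_criterion: float = 1e-4

    def validate(self) -> None:
        for name in ("exposure_ratio_edges", "oel_hazard_edges", "hq_edges",
                     "grade_level_edges"):
            edges = getattr(self, name)
            if not all(a < b for a, b in zip(edges, edges[1:])):
                raise ConfigError(f"{name} must be strictly increasing: {edges}")
        if self.ecr_criterion <= 0:
            raise ConfigError("ecr_criterion must be positive")
        m = self.handling_matrix
        if len(m) != 3 or any(len(row) != 3 for row in m):
            raise ConfigError("handling_matrix must be 3x3")
        for row in m:
            if any(c not in (1, 2, 3, 4) for c in row):
                raise ConfigError("handling_matrix entries must be classes 1-4")
        # monotone in both handling amount and volatility
        for i in range(3):
            for j in range(2):
                if m[i][j] > m[i][j + 1] or m[j][i] > m[j + 1][i]:
                    raise ConfigError("handling_matrix must be monotone in both axes")
        for phrase, cls in self.h_phrase_classes.items():
            if cls not in (1, 2, 3, 4):
                raise ConfigError(f"h_phrase class for {phrase} must be 1-4")


@dataclass
class RunConfig:
    """Configuration of one assessment run.

    ``exposure_factors`` describe the occupational schedule used both for
    the daily-dose adjustment and for rescaling a continuous reference
    concentration to the workplace; ``lifetime_years`` is the averaging
    time for the lifetime (cancer-risk) dose.
    """

    mode: str = "both"  # qualitative | quantitative | both
    rme_percentile: float = 0.95
    n_iterations: int = 10_000
    seed: int = 0
    bands: BandTables = field(default_factory=BandTables)
    # occupational exposure schedule
    hours_per_day: float = 8.0
    days_per_year: float = 240.0
    exposure_years: float = 25.0
    lifetime_years: float = 75.0
    #: which metric assigns the quantitative level ("hq" or "ecr")
    classification_metric: str = "hq"
    output_format: str = "json"  # json | csv

    def validate(self) -> None:
        if self.mode not in ("qualitative", "quantitative", "both"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if not 0.5 < self.rme_percentile < 1.0:
            raise ConfigError("rme_percentile must lie in (0.5, 1)")
        if self.n_iterations < 1000:
            raise ConfigError("n_iterations must be at least 1000")
        if self.classification_metric not in ("hq", "ecr"):
            raise ConfigError(f"unknown classification metric {self.classification_metric!r}")
        if self.output_format not in ("json", "csv"):
            raise ConfigError(f"unknown output format {self.output_format!r}")
        if not (0 < self.hours_per_day <= 24):
            raise ConfigError("hours_per_day must lie in (0, 24]")
        if not (0 < self.days_per_year <= 365):
            raise ConfigError("days_per_year must lie in (0, 365]")
        if self.exposure_years <= 0 or self.lifetime_years < self.exposure_years:
            raise ConfigError("need 0 < exposure_years <= lifetime_years")
        self.bands.validate()

    def work_factors(self) -> ExposureFactors:
        """ADD-style schedule: averaging over the exposed years."""
        return ExposureFactors(
            hours_per_day=self.hours_per_day,
            days_per_year=self.days_per_year,
            exposure_years=self.exposure_years,
            averaging_years=self.exposure_years,
        )

    def lifetime_factors(self) -> ExposureFactors:
        """LADD-style schedule: averaging over a full lifetime."""
        return ExposureFactors(
            hours_per_day=self.hours_per_day,
            days_per_year=self.days_per_year,
            exposure_years=self.exposure_years,
            averaging_years=self.lifetime_years,
        )

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        # tuples -> lists for clean YAML/JSON round trips
        for key in ("exposure_ratio_edges", "oel_hazard_edges", "hq_edges",
                    "grade_level_edges"):
            d["bands"][key] = list(d["bands"][key])
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        band_data = dict(data.pop("bands", {}))
        for key in ("exposure_ratio_edges", "oel_hazard_edges", "hq_edges",
                    "grade_level_edges"):
            if key in band_data:
                band_data[key] = tuple(band_data[key])
        unknown = set(band_data) - {f.name for f in dataclasses.fields(BandTables)}
        if unknown:
            raise ConfigError(f"unknown band table keys: {sorted(unknown)}")
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(bands=BandTables(**band_data), **data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)
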