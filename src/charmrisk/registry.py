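"""Substance registry: domain types and CSV interchange.

Three plain-CSV files describe a study (all concentrations in mg/m3;
ppm data must be converted before loading):

``substances.csv``
    name, cas, carcinogenicity, mutagenicity, reproductive_toxicity,
    skin_notation, oel_mg_m3, h_phrases (semicolon-joined), disease_history,
    handling_amount, volatility
``toxicity.csv``
    cas, pod_type, pod_value_mg_m3, uf, mf, unit_risk_per_mg_m3
``measurements.csv``
    cas, value_mg_m3  (long format, one air measurement per row)
``summaries.csv``
    cas, cte_mg_m3, rme_mg_m3, n_measurements  (pre-summarised exposure,
    the shape in which published studies report CTE/RME)

CMR axes follow the EU CLP convention: category 1A (known, human
evidence), 1B (presumed, animal evidence) or 2 (suspected); an empty cell
means the axis is not classified.  A substance counts as CMR when any of
the three axes carries any category, including 2.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import RowError, SchemaError

logger = logging.getLogger(__name__)

CMR_CATEGORIES = ("1A", "1B", "2")
CAS_PATTERN = re.compile(r"^\d{2,7}-\d{2}-\d$")
HANDLING_AMOUNTS = ("small", "medium", "large")
VOLATILITIES = ("low", "medium", "high")
POD_TYPES = ("NOAEL", "LOAEL")


@dataclass
class Substance:
    """One workplace chemical and the attributes that drive its banding."""

    name: str
    cas: str
    carcinogenicity: str | None = None
    mutagenicity: str | None = None
    reproductive_toxicity: str | None = None
    skin_notation: bool = False
    oel: float | None = None  # mg/m3
    h_phrases: frozenset[str] = field(default_factory=frozenset)
    disease_history: bool = False
    handling_amount: str | None = None
    volatility: str | None = None

    def __post_init__(self) -> None:
        if not CAS_PATTERN.match(self.cas):
            raise ValueError(f"malformed CAS number {self.cas!r}")
        for axis in ("carcinogenicity", "mutagenicity", "reproductive_toxicity"):
            value = getattr(self, axis)
            if value is not None and value not in CMR_CATEGORIES:
                raise ValueError(
                    f"{axis} must be one of {CMR_CATEGORIES} or empty, got {value!r}"
                )
        if self.oel is not None and not self.oel > 0:
            raise ValueError(f"oel must be positive, got {self.oel}")
        if self.handling_amount is not None and self.handling_amount not in HANDLING_AMOUNTS:
            raise ValueError(f"handling_amount must be one of {HANDLING_AMOUNTS}")
        if self.volatility is not None and self.volatility not in VOLATILITIES:
            raise ValueError(f"volatility must be one of {VOLATILITIES}")
        self.h_phrases = frozenset(self.h_phrases)

    @property
    def is_cmr(self) -> bool:
        """True when any CMR axis carries a category (1A, 1B or 2)."""
        return any(
            getattr(self, axis) is not None
            for axis in ("carcinogenicity", "mutagenicity", "reproductive_toxicity")
        )


@dataclass
class ToxicityProfile:
    """Dose-response inputs: point of departure, uncertainty, unit risk."""

    substance_ref: str  # CAS
    pod_type: str  # NOAEL | LOAEL
    pod_value: float  # mg/m3 for inhalation
    uf: float = 100.0
    mf: float = 1.0
    unit_risk: float | None = None  # per (mg/m3); carcinogens only

    def __post_init__(self) -> None:
        if self.pod_type not in POD_TYPES:
            raise ValueError(f"pod_type must be one of {POD_TYPES}, got {self.pod_type!r}")
        if not self.pod_value > 0:
            raise ValueError("pod_value must be positive")
        if self.uf <= 0 or self.mf <= 0 or self.uf * self.mf < 1:
            raise ValueError("uncertainty and modifying factors must satisfy uf*mf >= 1")
        if self.unit_risk is not None and self.unit_risk < 0:
            raise ValueError("unit_risk must be non-negative")


@dataclass
class MeasurementTable:
    """Air-measurement series for one substance (mg/m3)."""

    substance_ref: str
    values: list[float]

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise ValueError("at least one measurement required")
        if any(v <= 0 for v in self.values):
            raise ValueError("all measurement values must be positive")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class Issue:
    """One data-quality finding from :func:`validate_registry`."""

    kind: str
    cas: str
    message: str


# ---------------------------------------------------------------------------
# CSV I/O

SUBSTANCE_COLUMNS = [
    "name", "cas", "carcinogenicity", "mutagenicity", "reproductive_toxicity",
    "skin_notation", "oel_mg_m3", "h_phrases", "disease_history",
    "handling_amount", "volatility",
]
TOXICITY_COLUMNS = ["cas", "pod_type", "pod_value_mg_m3", "uf", "mf",
                    "unit_risk_per_mg_m3"]
MEASUREMENT_COLUMNS = ["cas", "value_mg_m3"]
SUMMARY_COLUMNS = ["cas", "cte_mg_m3", "rme_mg_m3", "n_measurements"]


def _read_table(path: str, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path, extra)
    return df


def _opt(cell: str) -> str | None:
    cell = cell.strip()
    return cell or None


def _bool(cell: str) -> bool:
    return cell.strip().lower() in ("true", "1", "yes")


def _float(cell: str, what: str, row: int) -> float:
    try:
        return float(cell)
    except ValueError:
        raise RowError(f"{what} is not a number: {cell!r}", row=row) from None


def read_registry(path: str) -> list[Substance]:
    """Load ``substances.csv``; raises :class:`RowError` with the row number
    on the first invalid row and :class:`SchemaError` on missing columns."""
    df = _read_table(path, SUBSTANCE_COLUMNS)
    substances = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        oel_cell = _opt(rec["oel_mg_m3"])
        phrases = [p for p in rec["h_phrases"].split(";") if p.strip()]
        try:
            substances.append(Substance(
                name=rec["name"].strip(),
                cas=rec["cas"].strip(),
                carcinogenicity=_opt(rec["carcinogenicity"]),
                mutagenicity=_opt(rec["mutagenicity"]),
                reproductive_toxicity=_opt(rec["reproductive_toxicity"]),
                skin_notation=_bool(rec["skin_notation"]),
                oel=_float(oel_cell, "oel_mg_m3", i) if oel_cell else None,
                h_phrases=frozenset(p.strip() for p in phrases),
                disease_history=_bool(rec["disease_history"]),
                handling_amount=_opt(rec["handling_amount"]),
                volatility=_opt(rec["volatility"]),
            ))
        except ValueError as exc:
            raise RowError(str(exc), row=i) from exc
    return substances


def write_registry(substances: list[Substance], path: str) -> None:
    rows = []
    for s in substances:
        rows.append({
            "name": s.name, "cas": s.cas,
            "carcinogenicity": s.carcinogenicity or "",
            "mutagenicity": s.mutagenicity or "",
            "reproductive_toxicity": s.reproductive_toxicity or "",
            "skin_notation": str(s.skin_notation).lower(),
            "oel_mg_m3": repr(s.oel) if s.oel is not None else "",
            "h_phrases": ";".join(sorted(s.h_phrases)),
            "disease_history": str(s.disease_history).lower(),
            "handling_amount": s.handling_amount or "",
            "volatility": s.volatility or "",
        })
    pd.DataFrame(rows, columns=SUBSTANCE_COLUMNS).to_csv(path, index=False)


def read_toxicity(path: str) -> list[ToxicityProfile]:
    df = _read_table(path, TOXICITY_COLUMNS)
    profiles = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        ur_cell = _opt(rec["unit_risk_per_mg_m3"])
        try:
            profiles.append(ToxicityProfile(
                substance_ref=rec["cas"].strip(),
                pod_type=rec["pod_type"].strip(),
                pod_value=_float(rec["pod_value_mg_m3"], "pod_value_mg_m3", i),
                uf=_float(rec["uf"], "uf", i),
                mf=_float(rec["mf"], "mf", i),
                unit_risk=_float(ur_cell, "unit_risk_per_mg_m3", i) if ur_cell else None,
            ))
        except ValueError as exc:
            raise RowError(str(exc), row=i) from exc
    return profiles


def write_toxicity(profiles: list[ToxicityProfile], path: str) -> None:
    rows = [{
        "cas": p.substance_ref, "pod_type": p.pod_type,
        "pod_value_mg_m3": repr(p.pod_value), "uf": repr(p.uf), "mf": repr(p.mf),
        "unit_risk_per_mg_m3": repr(p.unit_risk) if p.unit_risk is not None else "",
    } for p in profiles]
    pd.DataFrame(rows, columns=TOXICITY_COLUMNS).to_csv(path, index=False)


def read_measurements(path: str) -> list[MeasurementTable]:
    """Load long-format measurements grouped by CAS, preserving first-seen
    order of substances.  Non-positive values are row-level errors."""
    df = _read_table(path, MEASUREMENT_COLUMNS)
    grouped: dict[str, list[float]] = {}
    for i, rec in enumerate(df.to_dict("records"), start=1):
        value = _float(rec["value_mg_m3"], "value_mg_m3", i)
        if value <= 0:
            raise RowError(f"value_mg_m3 must be positive, got {value}", row=i)
        grouped.setdefault(rec["cas"].strip(), []).append(value)
    return [MeasurementTable(cas, values) for cas, values in grouped.items()]


def write_measurements(tables: list[MeasurementTable], path: str) -> None:
    rows = [{"cas": t.substance_ref, "value_mg_m3": repr(v)}
            for t in tables for v in t.values]
    pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS).to_csv(path, index=False)


def validate_registry(
    substances: list[Substance],
    profiles: list[ToxicityProfile] | None = None,
    measurements: list[MeasurementTable] | None = None,
    require_profiles: bool = False,
) -> list[Issue]:
    """Cross-check a study's inputs; findings are data, not exceptions.

    Reports duplicate CAS numbers, substances with no hazard route at all
    (no CMR axis, no OEL, no H-phrases), toxicity profiles or measurement
    tables whose CAS resolves to no substance, and — when
    ``require_profiles`` (i.e. a quantitative track is requested) —
    substances lacking a toxicity profile.
    """
    issues: list[Issue] = []
    seen: set[str] = set()
    for s in substances:
        if s.cas in seen:
            issues.append(Issue("duplicate_cas", s.cas,
                                f"CAS {s.cas} appears more than once"))
        seen.add(s.cas)
        if not s.is_cmr and s.oel is None and not s.h_phrases:
            issues.append(Issue("no_hazard_route", s.cas,
                                f"{s.name}: no CMR axis, no OEL and no H-phrases"))
    profile_cas = {p.substance_ref for p in profiles or []}
    for ref in sorted(profile_cas - seen):
        issues.append(Issue("unresolved_reference", ref,
                            f"toxicity profile references unknown CAS {ref}"))
    for table in measurements or []:
        if table.substance_ref not in seen:
            issues.append(Issue("unresolved_reference", table.substance_ref,
                                f"measurements reference unknown CAS {table.substance_ref}"))
    if require_profiles:
        for s in substances:
            if s.cas not in profile_cas:
                issues.append(Issue("missing_toxicity_profile", s.cas,
                                    f"{s.name}: quantitative track requested "
                                    "but no toxicity profile supplied"))
    return issues
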