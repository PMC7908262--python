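"""Study-level orchestration: run both tracks, count, cross-tabulate.

``classify_study`` assesses every substance qualitatively and — where a
toxicity profile exists — quantitatively, then aggregates: per-level
counts on each track, a 4x4 cross-tabulation of qualitative level
against quantitative level at the RME, and two agreement statistics:

* ``exact`` — the fraction of substances assigned the *same* level by
  both tracks (trace of the cross-tabulation over its total);
* ``moderate_or_above_overlap`` — of the substances the qualitative
  track puts at moderate or high, the fraction the quantitative track
  also puts at moderate or high.  This is the category-count comparison
  used when contrasting control banding with quantitative assessment
  (all-CMR studies place everything at qualitative moderate/high, so
  exact agreement is dominated by the hazard class alone).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

from .config import LEVELS, RunConfig
from .errors import CharmRiskError
from .exposure import ExposureSummary, monte_carlo_summary
from .qualitative import QualitativeResult, assess_qualitative
from .quantitative import QuantitativeResult, assess_quantitative
from .registry import MeasurementTable, Substance, ToxicityProfile

logger = logging.getLogger(__name__)


@dataclass
class AgreementStats:
    exact: float
    moderate_or_above_overlap: float
    n_overlap: int  # substances at moderate/high on both tracks


@dataclass
class StudyRow:
    substance_ref: str
    name: str
    qualitative: QualitativeResult
    quantitative: QuantitativeResult | None = None


@dataclass
class StudyReport:
    per_substance: list[StudyRow]
    qualitative_counts: dict[str, int]
    quantitative_counts_cte: dict[str, int]
    quantitative_counts_rme: dict[str, int]
    crosstab_rme: dict[str, dict[str, int]]
    agreement: AgreementStats | None
    config: dict = field(default_factory=dict)


def level_counts(assignments: list[str]) -> dict[str, int]:
    """Count levels, zero-filling all four keys in scale order."""
    counts = {level: 0 for level in LEVELS}
    for level in assignments:
        if level not in counts:
            raise ValueError(f"unknown level {level!r}")
        counts[level] += 1
    return counts


def cross_tabulate(
    qual: dict[str, str], quant: dict[str, str]
) -> dict[str, dict[str, int]]:
    """4x4 contingency table of qualitative x quantitative level.

    Both maps must cover the same substances; a mismatch is an error that
    names the differing CAS numbers.
    """
    if set(qual) != set(quant):
        only_q = sorted(set(qual) - set(quant))
        only_n = sorted(set(quant) - set(qual))
        raise CharmRiskError(
            f"cross-tabulation key mismatch: only qualitative {only_q}, "
            f"only quantitative {only_n}"
        )
    table = {ql: {qn: 0 for qn in LEVELS} for ql in LEVELS}
    for cas, ql_level in qual.items():
        table[ql_level][quant[cas]] += 1
    return table


def agreement_fraction(crosstab: dict[str, dict[str, int]]) -> AgreementStats:
    """Exact per-substance agreement and the moderate-or-above overlap."""
    total = sum(sum(row.values()) for row in crosstab.values())
    if total < 1:
        raise ValueError("cross-tabulation is empty")
    trace = sum(crosstab[level][level] for level in LEVELS)
    mid = ("moderate", "high")
    qual_mid = sum(sum(crosstab[ql].values()) for ql in mid)
    both_mid = sum(crosstab[ql][qn] for ql in mid for qn in mid)
    overlap = both_mid / qual_mid if qual_mid else float("nan")
    return AgreementStats(
        exact=trace / total,
        moderate_or_above_overlap=overlap,
        n_overlap=both_mid,
    )


def _resolve_summaries(
    substances: list[Substance],
    measurements: list[MeasurementTable] | None,
    summaries: list[ExposureSummary] | None,
    config: RunConfig,
) -> dict[str, ExposureSummary]:
    """Pre-supplied summaries win; otherwise run the Monte Carlo on the
    measurement series (per-substance seeds derived from the run seed)."""
    resolved = {s.substance_ref: s for s in summaries or []}
    by_cas = {m.substance_ref: m for m in measurements or []}
    for i, substance in enumerate(substances):
        if substance.cas in resolved or substance.cas not in by_cas:
            continue
        table = by_cas[substance.cas]
        if table.n < 2:
            logger.warning("%s: only %d measurement(s); skipping Monte Carlo",
                           substance.cas, table.n)
            continue
        resolved[substance.cas] = monte_carlo_summary(
            table,
            n_iterations=config.n_iterations,
            seed=(config.seed * 1_000_003 + i) % (2**31),
            rme_percentile=config.rme_percentile,
        )
    return resolved


def classify_study(
    registry: list[Substance],
    profiles: list[ToxicityProfile] | None = None,
    measurements: list[MeasurementTable] | None = None,
    summaries: list[ExposureSummary] | None = None,
    config: RunConfig | None = None,
) -> StudyReport:
    """Assess a whole study on both tracks and aggregate the results.

    Substances without a toxicity profile receive qualitative results
    only and are excluded from the quantitative counts (logged).  The
    run is deterministic for a given configuration seed.
    """
    if not registry:
        raise CharmRiskError("registry is empty: nothing to assess")
    config = config or RunConfig()
    config.validate()
    profile_by_cas = {p.substance_ref: p for p in profiles or []}
    summary_by_cas = _resolve_summaries(registry, measurements, summaries, config)

    rows: list[StudyRow] = []
    for substance in registry:
        summary = summary_by_cas.get(substance.cas)
        qual = assess_qualitative(substance, summary, config)
        quant = None
        if config.mode in ("quantitative", "both"):
            profile = profile_by_cas.get(substance.cas)
            if profile is None or summary is None:
                logger.info(
                    "%s (%s): no %s; qualitative result only", substance.name,
                    substance.cas,
                    "toxicity profile" if profile is None else "exposure summary")
            else:
                quant = assess_quantitative(substance, profile, summary, config)
        rows.append(StudyRow(substance.cas, substance.name, qual, quant))

    qual_counts = level_counts([r.qualitative.level for r in rows])
    quant_rows = [r for r in rows if r.quantitative is not None]
    counts_cte = level_counts([r.quantitative.level_cte for r in quant_rows])
    counts_rme = level_counts([r.quantitative.level_rme for r in quant_rows])

    crosstab: dict[str, dict[str, int]] = {ql: {qn: 0 for qn in LEVELS} for ql in LEVELS}
    agreement = None
    if quant_rows:
        crosstab = cross_tabulate(
            {r.substance_ref: r.qualitative.level for r in quant_rows},
            {r.substance_ref: r.quantitative.level_rme for r in quant_rows},
        )
        agreement = agreement_fraction(crosstab)

    return StudyReport(
        per_substance=rows,
        qualitative_counts=qual_counts,
        quantitative_counts_cte=counts_cte,
        quantitative_counts_rme=counts_rme,
        crosstab_rme=crosstab,
        agreement=agreement,
        config=config.to_dict(),
    )


# ---------------------------------------------------------------------------
# serialisation

def report_to_dict(report: StudyReport) -> dict:
    return {
        "per_substance": [
            {
                "cas": row.substance_ref,
                "name": row.name,
                "qualitative": dataclasses.asdict(row.qualitative),
                "quantitative": (
                    dataclasses.asdict(row.quantitative)
                    if row.quantitative is not None else None
                ),
            }
            for row in report.per_substance
        ],
        "qualitative_counts": report.qualitative_counts,
        "quantitative_counts_cte": report.quantitative_counts_cte,
        "quantitative_counts_rme": report.quantitative_counts_rme,
        "crosstab_rme": report.crosstab_rme,
        "agreement": (
            dataclasses.asdict(report.agreement)
            if report.agreement is not None else None
        ),
        "config": report.config,
    }


def report_from_dict(data: dict) -> StudyReport:
    rows = [
        StudyRow(
            substance_ref=entry["cas"],
            name=entry["name"],
            qualitative=QualitativeResult(**entry["qualitative"]),
            quantitative=(
                QuantitativeResult(**entry["quantitative"])
                if entry["quantitative"] is not None else None
            ),
        )
        for entry in data["per_substance"]
    ]
    agreement = AgreementStats(**data["agreement"]) if data["agreement"] else None
    return StudyReport(
        per_substance=rows,
        qualitative_counts=dict(data["qualitative_counts"]),
        quantitative_counts_cte=dict(data["quantitative_counts_cte"]),
        quantitative_counts_rme=dict(data["quantitative_counts_rme"]),
        crosstab_rme={k: dict(v) for k, v in data["crosstab_rme"].items()},
        agreement=agreement,
        config=dict(data.get("config", {})),
    )


def write_report(report: StudyReport, path: str, format: str = "json") -> None:
    """Write the study report; JSON round-trips losslessly, CSV carries
    one row per substance plus a commented summary block of the counts."""
    if format == "json":
        try:
            with open(path, "w") as fh:
                json.dump(report_to_dict(report), fh, indent=2)
        except OSError as exc:
            raise CharmRiskError(f"cannot write report to {path}: {exc}") from exc
        return
    if format != "csv":
        raise ValueError(f"unknown report format {format!r}")
    header = ("cas,name,exposure_class,exposure_route,hazard_class,hazard_route,"
              "grade,qual_level,status,hq_cte,hq_rme,quant_level_cte,quant_level_rme")
    lines = [header]
    for row in report.per_substance:
        q = row.qualitative
        n = row.quantitative
        quant_cells = (
            [f"{n.hq_cte:.6g}", f"{n.hq_rme:.6g}", n.level_cte, n.level_rme]
            if n is not None else ["", "", "", ""]
        )
        name = '"' + row.name.replace('"', '""') + '"'
        lines.append(",".join(
            [row.substance_ref, name, str(q.exposure_class), q.exposure_route,
             str(q.hazard_class), q.hazard_route, str(q.grade), q.level, q.status]
            + quant_cells))
    lines.append("# summary")
    for label, counts in (
        ("qualitative", report.qualitative_counts),
        ("quantitative_cte", report.quantitative_counts_cte),
        ("quantitative_rme", report.quantitative_counts_rme),
    ):
        cells = ",".join(f"{level}={counts[level]}" for level in LEVELS)
        lines.append(f"# {label}: {cells}")
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    except OSError as exc:
        raise CharmRiskError(f"cannot write report to {path}: {exc}") from exc


def read_report(path: str) -> StudyReport:
    """Read back a JSON study report."""
    try:
        with open(path) as fh:
            return report_from_dict(json.load(fh))
    except OSError as exc:
        raise CharmRiskError(f"cannot read report from {path}: {exc}") from exc


def plot_level_counts(report: StudyReport, path: str) -> None:
    """Grouped bar chart of per-level counts on both tracks (optional
    artifact; matplotlib imported lazily)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    x = np.arange(len(LEVELS))
    width = 0.27
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(x - width, [report.qualitative_counts[lv] for lv in LEVELS],
           width, label="qualitative")
    ax.bar(x, [report.quantitative_counts_cte[lv] for lv in LEVELS],
           width, label="quantitative (CTE)")
    ax.bar(x + width, [report.quantitative_counts_rme[lv] for lv in LEVELS],
           width, label="quantitative (RME)")
    ax.set_xticks(x, [lv.replace("_", " ") for lv in LEVELS])
    ax.set_ylabel("substances")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
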