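"""Synthetic study generation.

Two kinds of studies can be generated with no external data:

* :func:`generate_study` — fully random registries, toxicity profiles
  and lognormal measurement series under a :class:`SimulationConfig`,
  for property testing and demonstration;
* :func:`generate_paper_like_study` — a reconstruction of a published
  2011 Korean survey of 36 hazardous substances requiring management,
  all CMR-classified.  Twenty substances carry their published exposure
  statistics (measurement counts, CTE/RME in mg/m3 and RME/OEL
  percentages); the remaining sixteen are named in the survey's
  quantitative results but their measurement records were not printed,
  so they are synthetic stand-ins constructed to stay strictly inside
  the lowest measurement band (RME/OEL < 10%) — study-level counts are
  therefore invariant to their details.  Only vanadium pentoxide falls
  in the 10-50% band (13.7%).

Quantitative calibration: the survey reports which hazard-quotient band
each substance occupies at the CTE and at the RME, but not the reference
concentrations behind them.  The generator inverts HQ = E / RfC_work:
for each substance it picks the HQ at RME as the midpoint of the set of
values compatible with *both* stated band memberships (the CTE band
constrains HQ_RME through the fixed CTE/RME ratio) and sets
RfC_work = RME / HQ_RME, then back-derives a NOAEL-based toxicity
profile (UF = 100, MF = 1) consistent with the schedule rescaling.  All
structural claims are asserted after construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .exposure import ExposureSummary
from .quantitative import (
    assess_quantitative,
    reference_concentration,
    workplace_rfc,
)
from .registry import (
    MeasurementTable,
    Substance,
    ToxicityProfile,
    validate_registry,
)


@dataclass
class SimulationConfig:
    """Parameters of a random synthetic study."""

    n_substances: int = 36
    cmr_fraction: float = 1.0
    gm_range: tuple[float, float] = (1e-3, 1.0)  # mg/m3, log-uniform
    gsd_range: tuple[float, float] = (1.5, 3.0)
    n_measurements_range: tuple[int, int] = (10, 100)
    oel_range: tuple[float, float] = (0.1, 50.0)  # mg/m3, log-uniform
    rfc_scale: float = 1.0  # RfC_work = OEL * rfc_scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_substances < 1:
            raise ValueError("n_substances must be >= 1")
        if not 0 <= self.cmr_fraction <= 1:
            raise ValueError("cmr_fraction must lie in [0, 1]")
        for name in ("gm_range", "gsd_range", "n_measurements_range", "oel_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be ordered, got ({lo}, {hi})")
        if self.gsd_range[0] < 1:
            raise ValueError("gsd must be >= 1")
        if self.rfc_scale <= 0:
            raise ValueError("rfc_scale must be positive")


@dataclass
class StudyBundle:
    """Everything needed to run a study end to end."""

    substances: list[Substance]
    profiles: list[ToxicityProfile]
    measurements: list[MeasurementTable]
    summaries: list[ExposureSummary] = field(default_factory=list)
    description: str = ""


# ---------------------------------------------------------------------------
# published study data
#
# Columns: name, CAS, carcinogenicity, mutagenicity, reproductive toxicity,
# skin notation, measurement count, CTE (mg/m3), RME (mg/m3), RME/OEL (%),
# HQ band at RME, HQ band at CTE.
_PRINTED = [
    ("Acrylamide", "79-06-1", "1B", "1B", "2", True,
     452, 1.56e-4, 1.95e-4, 0.7, "low", "low"),
    ("1,2,3-Trichloropropane", "96-18-4", "1B", None, "1B", True,
     55, 7.41e-1, 8.64e-1, 8.6, "very_high", "very_high"),
    ("Ethylene dichloride", "107-06-2", "1B", None, None, False,
     365, 3.82e-1, 4.55e-1, 4.6, "very_high", "very_high"),
    ("Acrylonitrile", "107-13-1", "1B", None, None, True,
     905, 3.39e-2, 4.11e-2, 2.1, "high", "high"),
    ("2-Methoxyethyl acetate", "110-49-6", None, None, "1B", True,
     871, 9.10e-2, 9.97e-2, 2.0, "very_high", "very_high"),
    ("1,2-Epoxypropane", "75-56-9", "1B", "1B", None, False,
     45, 5.17e-2, 6.62e-2, 3.3, "high", "moderate"),
    ("Perchloroethylene", "127-18-4", "1B", None, None, False,
     2317, 5.59e-1, 7.01e-1, 2.8, "very_high", "very_high"),
    ("Hydrazine", "302-01-2", "1B", None, None, True,
     233, 2.25e-4, 2.77e-4, 0.6, "low", "low"),
    ("n-Hexane", "110-54-3", None, None, "2", False,
     16754, 7.66e-1, 8.35e-1, 1.7, "low", "low"),
    ("Nitromethane", "75-52-5", "2", None, None, False,
     16, 9.93e-1, 1.28e0, 6.4, "very_high", "very_high"),
    ("N,N-Dimethylaniline", "121-69-7", "2", None, None, True,
     68, 2.27e-4, 3.36e-4, 0.0, "low", "low"),
    ("Diethanolamine", "111-42-2", "2", None, None, False,
     893, 8.60e-3, 9.65e-3, 2.1, "moderate", "moderate"),
    ("1,4-Dioxane", "123-91-1", "2", None, None, True,
     765, 2.36e-1, 2.96e-1, 1.5, "moderate", "low"),
    ("Dichloromethane", "75-09-2", "2", None, None, False,
     7629, 3.01e0, 3.61e0, 0.7, "high", "high"),
    ("Methylene bisphenyl isocyanate", "101-68-8", "2", None, None, False,
     2395, 1.03e-4, 1.86e-4, 3.7, "low", "low"),
    ("2-Butoxyethanol", "111-76-2", "2", None, None, True,
     8673, 2.59e-1, 3.13e-1, 1.6, "low", "low"),
    ("Methyl bromide", "74-83-9", None, "2", None, True,
     59, 1.63e-5, 2.34e-5, 0.0, "low", "low"),
    ("Vinyl acetate", "108-05-4", "2", None, None, False,
     2117, 3.14e-1, 3.63e-1, 3.6, "low", "low"),
    ("Vanadium pentoxide", "1314-62-1", "2", "2", "2", False,
     38, 6.17e-3, 6.86e-3, 13.7, "very_high", "very_high"),
    ("Acetaldehyde", "75-07-0", "2", None, None, False,
     43, 2.58e-2, 3.28e-2, 1.0, "low", "low"),
]

#: OELs for the two substances whose published RME/OEL ratio prints as
#: 0.0% (the division is undefined); standard Korean limits in mg/m3.
_ASSIGNED_OELS = {"121-69-7": 25.0, "74-83-9": 3.89}

# The sixteen substances named only in the quantitative results; exposure
# attributes are synthetic stand-ins.  Columns: name, CAS, OEL (mg/m3,
# typical 8-h limits), HQ band at RME, HQ band at CTE.
_STAND_INS = [
    ("Pyridine", "110-86-1", 15.0, "very_high", "high"),
    ("Cobalt and inorganic compounds", "7440-48-4", 0.02, "high", "high"),
    ("Ethyl acrylate", "140-88-5", 20.0, "moderate", "moderate"),
    ("Chlorobenzene", "108-90-7", 46.0, "moderate", "moderate"),
    ("1,1,2,2-Tetrachloroethane", "79-34-5", 6.9, "moderate", "moderate"),
    ("Tetrahydrofuran", "109-99-9", 590.0, "moderate", "moderate"),
    ("1,1,2-Trichloroethane", "79-00-5", 55.0, "moderate", "moderate"),
    ("Methyl ethyl ketone", "78-93-3", 590.0, "moderate", "moderate"),
    ("Cyclohexanone", "108-94-1", 100.0, "low", "low"),
    ("Toluene-2,4-diisocyanate", "584-84-9", 0.036, "low", "low"),
    ("Toluene-2,6-diisocyanate", "91-08-7", 0.036, "low", "low"),
    ("Methyl n-butyl ketone", "591-78-6", 20.0, "low", "low"),
    ("Aniline and homologues", "62-53-3", 7.6, "low", "low"),
    ("Hydrogen peroxide", "7722-84-1", 1.4, "low", "low"),
    ("Mercury and inorganic compounds", "7439-97-6", 0.025, "low", "low"),
    ("Titanium dioxide", "13463-67-7", 10.0, "low", "low"),
]

#: Closed inner intervals used when solving for a hazard quotient inside a
#: band; shrunk away from the edges so float arithmetic cannot spill over.
_SOLVE_BANDS = {
    "low": (0.002, 0.095),
    "moderate": (0.105, 0.495),
    "high": (0.505, 0.995),
    "very_high": (1.05, 8.0),
}


def _calibrate_hq_rme(band_rme: str, band_cte: str, cte_rme_ratio: float) -> float:
    """Midpoint HQ at RME compatible with both band memberships."""
    lo_r, hi_r = _SOLVE_BANDS[band_rme]
    lo_c, hi_c = _SOLVE_BANDS[band_cte]
    lo = max(lo_r, lo_c / cte_rme_ratio)
    hi = min(hi_r, hi_c / cte_rme_ratio)
    if lo > hi:
        raise ValueError(
            f"no HQ satisfies RME band {band_rme!r} and CTE band {band_cte!r} "
            f"at CTE/RME ratio {cte_rme_ratio:.3f}"
        )
    return (lo + hi) / 2.0


def _profile_for_target(
    cas: str,
    hq_rme: float,
    rme: float,
    config: RunConfig,
    unit_risk: float | None,
) -> ToxicityProfile:
    """Back-derive a NOAEL-based profile giving the target RfC_work."""
    rfc_work_target = rme / hq_rme
    adjustment = (24.0 / config.hours_per_day) * (365.0 / config.days_per_year)
    rfc = rfc_work_target / adjustment
    uf, mf = 100.0, 1.0
    return ToxicityProfile(
        substance_ref=cas,
        pod_type="NOAEL",
        pod_value=rfc * uf * mf,
        uf=uf,
        mf=mf,
        unit_risk=unit_risk,
    )


def generate_measurements(
    substance: Substance | str,
    gm: float,
    gsd: float,
    n: int,
    seed: int,
) -> MeasurementTable:
    """Draw ``n`` independent lognormal air measurements (mg/m3)."""
    if gm <= 0:
        raise ValueError("gm must be positive")
    if gsd < 1:
        raise ValueError("gsd must be >= 1")
    if n < 2:
        raise ValueError("need at least 2 measurements")
    cas = substance.cas if isinstance(substance, Substance) else substance
    rng = np.random.default_rng(seed)
    values = rng.lognormal(mean=np.log(gm), sigma=np.log(gsd), size=n)
    return MeasurementTable(substance_ref=cas, values=[float(v) for v in values])


def _random_cas(i: int) -> str:
    # synthetic but pattern-valid and unique per index
    return f"{10000 + i}-{10 + (i * 7) % 90:02d}-{i % 10}"


def generate_registry(
    config: SimulationConfig,
    run_config: RunConfig | None = None,
) -> tuple[list[Substance], list[ToxicityProfile]]:
    """Random registry and matching toxicity profiles.

    The first ``round(cmr_fraction * n)`` substances receive a CMR axis;
    every substance receives an OEL drawn log-uniformly from
    ``oel_range`` and a profile constructed so that
    RfC_work = OEL * rfc_scale, which makes the hazard-quotient
    distribution controllable through the exposure level alone.
    """
    run_config = run_config or RunConfig()
    rng = np.random.default_rng(config.seed)
    n_cmr = round(config.cmr_fraction * config.n_substances)
    substances, profiles = [], []
    for i in range(config.n_substances):
        axis = rng.integers(0, 3)
        category = ("1A", "1B", "2")[rng.integers(0, 3)]
        is_cmr = i < n_cmr
        oel = float(np.exp(rng.uniform(*np.log(config.oel_range))))
        substance = Substance(
            name=f"substance-{i + 1:03d}",
            cas=_random_cas(i),
            carcinogenicity=category if is_cmr and axis == 0 else None,
            mutagenicity=category if is_cmr and axis == 1 else None,
            reproductive_toxicity=category if is_cmr and axis == 2 else None,
            skin_notation=bool(rng.random() < 0.3),
            oel=oel,
            h_phrases=frozenset({"H350"} if is_cmr else {"H335"}),
            handling_amount=("small", "medium", "large")[rng.integers(0, 3)],
            volatility=("low", "medium", "high")[rng.integers(0, 3)],
        )
        substances.append(substance)
        rfc_work = oel * config.rfc_scale
        adjustment = (24.0 / run_config.hours_per_day) * (365.0 / run_config.days_per_year)
        unit_risk = (
            float(np.exp(rng.uniform(np.log(1e-5), np.log(1e-2))))
            if substance.carcinogenicity is not None else None
        )
        profiles.append(ToxicityProfile(
            substance_ref=substance.cas,
            pod_type="NOAEL",
            pod_value=(rfc_work / adjustment) * 100.0,
            uf=100.0,
            mf=1.0,
            unit_risk=unit_risk,
        ))
    assert not validate_registry(substances, profiles)
    return substances, profiles


def generate_study(
    config: SimulationConfig,
    run_config: RunConfig | None = None,
) -> StudyBundle:
    """Random full study: registry, profiles and measurement series."""
    substances, profiles = generate_registry(config, run_config)
    rng = np.random.default_rng(config.seed + 1)
    measurements = []
    for substance in substances:
        gm = float(np.exp(rng.uniform(*np.log(config.gm_range))))
        gsd = float(rng.uniform(*config.gsd_range))
        n = int(rng.integers(config.n_measurements_range[0],
                             config.n_measurements_range[1] + 1))
        measurements.append(generate_measurements(
            substance, gm, gsd, n, seed=int(rng.integers(2**31))))
    return StudyBundle(
        substances=substances,
        profiles=profiles,
        measurements=measurements,
        description=f"random study (seed={config.seed}, n={config.n_substances})",
    )


def generate_paper_like_study(
    seed: int = 0, config: RunConfig | None = None
) -> StudyBundle:
    """The reconstructed 36-substance all-CMR survey (see module docs).

    Deterministic for a given seed; the seed only affects the synthetic
    stand-ins' exposure levels and illustrative raw measurement series,
    never the published values or the band structure.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(seed)
    substances: list[Substance] = []
    summaries: list[ExposureSummary] = []
    profiles: list[ToxicityProfile] = []
    measurements: list[MeasurementTable] = []
    expected_rme: dict[str, str] = {}
    expected_cte: dict[str, str] = {}

    def _phrases(carc, muta, repro):
        phrases = set()
        if carc:
            phrases.add("H350" if carc in ("1A", "1B") else "H351")
        if muta:
            phrases.add("H340" if muta in ("1A", "1B") else "H341")
        if repro:
            phrases.add("H360" if repro in ("1A", "1B") else "H361")
        return frozenset(phrases)

    for (name, cas, carc, muta, repro, skin, n, cte, rme,
         ratio, band_rme, band_cte) in _PRINTED:
        oel = _ASSIGNED_OELS[cas] if ratio == 0.0 else rme / (ratio / 100.0)
        substances.append(Substance(
            name=name, cas=cas, carcinogenicity=carc, mutagenicity=muta,
            reproductive_toxicity=repro, skin_notation=skin, oel=oel,
            h_phrases=_phrases(carc, muta, repro),
            handling_amount=("small", "medium", "large")[rng.integers(0, 3)],
            volatility=("low", "medium", "high")[rng.integers(0, 3)],
        ))
        summaries.append(ExposureSummary(
            substance_ref=cas, cte=cte, rme=rme, n_measurements=n))
        unit_risk = (
            float(np.exp(rng.uniform(np.log(1e-4), np.log(1e-2))))
            if carc is not None else None
        )
        hq_rme = _calibrate_hq_rme(band_rme, band_cte, cte / rme)
        profiles.append(_profile_for_target(cas, hq_rme, rme, config, unit_risk))
        expected_rme[cas], expected_cte[cas] = band_rme, band_cte

    for name, cas, oel, band_rme, band_cte in _STAND_INS:
        ratio = float(rng.uniform(0.5, 8.0))  # strictly inside the <10% band
        rme = oel * ratio / 100.0
        cte = rme * float(rng.uniform(0.80, 0.92))
        substances.append(Substance(
            name=f"{name} (synthetic stand-in)", cas=cas,
            mutagenicity="2",  # keeps the carcinogen count at the printed 17
            skin_notation=False, oel=oel, h_phrases=frozenset({"H341"}),
            handling_amount=("small", "medium", "large")[rng.integers(0, 3)],
            volatility=("low", "medium", "high")[rng.integers(0, 3)],
        ))
        summaries.append(ExposureSummary(
            substance_ref=cas, cte=cte, rme=rme,
            n_measurements=int(rng.integers(20, 500))))
        hq_rme = _calibrate_hq_rme(band_rme, band_cte, cte / rme)
        profiles.append(_profile_for_target(cas, hq_rme, rme, config, None))
        expected_rme[cas], expected_cte[cas] = band_rme, band_cte

    # illustrative raw series consistent with each substance's CTE
    gsd = 1.8
    gm_correction = float(np.exp(0.5 * np.log(gsd) ** 2))
    for substance, summary in zip(substances, summaries):
        n_raw = min(summary.n_measurements, 200)
        measurements.append(generate_measurements(
            substance, gm=summary.cte / gm_correction, gsd=gsd,
            n=max(n_raw, 5), seed=int(rng.integers(2**31))))

    # -- structural postconditions (assert, don't hope) -------------------
    assert len(substances) == 36
    assert all(s.is_cmr for s in substances)
    ratios = {
        s.cas: 100.0 * summary.rme / s.oel
        for s, summary in zip(substances, summaries)
    }
    in_band = [cas for cas, r in ratios.items() if 10.0 <= r < 50.0]
    assert in_band == ["1314-62-1"], in_band  # only vanadium pentoxide
    assert all(r < 10.0 for cas, r in ratios.items() if cas != "1314-62-1")
    assert sum(p.unit_risk is not None for p in profiles) == 17
    assert not validate_registry(substances, profiles, measurements,
                                 require_profiles=True)
    summary_by_cas = {s.substance_ref: s for s in summaries}
    profile_by_cas = {p.substance_ref: p for p in profiles}
    for substance in substances:
        result = assess_quantitative(
            substance, profile_by_cas[substance.cas],
            summary_by_cas[substance.cas], config)
        assert result.level_rme == expected_rme[substance.cas], substance.name
        assert result.level_cte == expected_cte[substance.cas], substance.name
        # round trip of the calibration through Eq. 2 and the rescaling
        rfc = reference_concentration(profile_by_cas[substance.cas])
        assert np.isclose(workplace_rfc(rfc, config.work_factors()),
                          result.rfc_work)

    return StudyBundle(
        substances=substances,
        profiles=profiles,
        measurements=measurements,
        summaries=summaries,
        description=(
            "reconstructed 36-substance all-CMR survey; 20 substances with "
            "published exposure statistics, 16 synthetic stand-ins below the "
            "10% measurement band"
        ),
    )
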