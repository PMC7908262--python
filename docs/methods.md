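# Methods

## Scope and model

charmrisk implements two complementary assessments of airborne chemical
exposure in workplaces and a structured comparison between them.

The **qualitative track** is a control-banding procedure: risk grade =
exposure class × hazard class, both on 1–4 scales, with grade bands
1–2 low, 3–4 moderate, 5–11 high, 12–16 very high. Only the nine
products {1, 2, 3, 4, 6, 8, 9, 12, 16} are reachable, and the pipeline
asserts that invariant on every result. Route priority is fixed: for
exposure, disease history ≻ measurements ≻ handling bands; for hazard,
CMR status ≻ OEL severity ≻ H-phrases. "CMR" means *any* of the three
axes carries category 1A, 1B or 2 — a substance with only a suspected
(category 2) classification is still assessed at hazard class 4.

The **quantitative track** characterises risk against a reference
concentration, RfC = POD / (UF × MF), with POD a NOAEL or LOAEL in
mg/m³ for inhalation. The RfC is a continuous-exposure quantity; it is
rescaled to the working schedule multiplicatively,
RfC_work = RfC × (24 / hours_per_day) × (365 / days_per_year), which is
the identity for a continuous schedule. The hazard quotient HQ =
E / RfC_work is evaluated at both the CTE and the RME exposure level.
For carcinogens the excess cancer risk is the product form
ECR = UR × LADC, with LADC the lifetime-average concentration from the
schedule weighting below.

## Exposure statistics

Measurement series are modelled as lognormal — the standard assumption
for workplace air data — with a log-scale moment fit: gm = exp(mean of
logs), gsd = exp(sample sd of logs, n−1 denominator).

CTE and RME are defined on the **sampling distribution of the arithmetic
mean**: each Monte Carlo iteration redraws n values from the fitted
lognormal and records their mean; CTE is the average of iteration means,
RME the `rme_percentile` quantile (default 0.95) of them. The
alternative reading — RME as an upper percentile of *individual*
exposures — was rejected because it implies RME/CTE ratios of 3–10 at
typical gsd values, while published CTE/RME pairs for this kind of
survey sit at ratios of roughly 1.1–1.5, consistent only with
uncertainty about the mean. Both the percentile and the statistic are
configurable, and a degenerate series (gsd = 1) collapses the simulation
to the sample value exactly.

Schedule weighting converts a workplace concentration to an
average-daily equivalent: c × hours/24 × days/365 ×
exposure_years/averaging_years. With averaging equal to the exposure
duration this is the ADD-style concentration; with averaging over a full
lifetime it is the LADD-style concentration used for ECR. Defaults:
8 h/day, 240 days/year, 25 years exposed, 75-year lifetime — a
conventional occupational scenario; all four are configurable.

## Band tables and edge conventions

All classification constants live in `RunConfig`/`BandTables`:

| table | default | status |
|---|---|---|
| measurement exposure edges | 10 / 50 / 100 % of OEL, lower edge inclusive | published rule |
| grade → level | 3 / 5 / 12 | published rule |
| HQ edges | 0.1 / 0.5 / 1 | published rule |
| ECR criterion | 10⁻⁴ | published rule |
| handling × volatility matrix | [[1,2,2],[2,3,3],[2,3,4]] | shipped default, beyond published rules |
| OEL severity edges | 0.1 / 1 / 10 mg/m³ (lower OEL ⇒ higher class) | shipped default, beyond published rules |
| H-phrase map | CMR statements 4, acute-lethal/organ 3–4, irritant 2, narcotic 1 | shipped default, beyond published rules |

HQ edge conventions: "0.5 to 1" is closed, ">1" open, "0.1 to 0.5"
right-open, so HQ = 1 is *high*, not very high. ECR banding divides by
10⁻⁴ first and then applies the same edges, which makes the two paths
exactly equivalent under scaling (property-tested). Band-edge
comparisons carry a 10⁻⁹ relative tolerance so a quotient that equals an
edge up to float rounding (e.g. E reconstructed to equal RfC_work
through the schedule adjustment) lands on the side the convention
dictates; the tolerance is far below any difference of practical
consequence.

Monotonicity is enforced structurally: exposure class is non-decreasing
in the OEL ratio, grade and level in both classes, quantitative level in
its metric; the handling matrix is validated as monotone in both axes on
load.

## The synthetic study generator

`generate_study` draws fully random registries: OELs log-uniform,
lognormal measurement series with gm and gsd from configurable ranges,
and toxicity profiles constructed so that RfC_work = OEL × `rfc_scale`,
which makes the HQ distribution controllable through exposure alone.
This emulates the *statistical shape* of a measurement campaign — it
does not emulate censoring below detection limits, between-shift
autocorrelation, mixed exposures or task-level variation, so passing
tests demonstrate correctness of the pipeline's arithmetic and
invariants, not fidelity to any particular real workplace.

`generate_paper_like_study` reconstructs a specific published survey of
36 hazardous substances requiring management, all CMR-classified, from a
2011 national work-environment measurement campaign. Twenty substances
carry their published measurement counts, CTE/RME values and RME/OEL
percentages verbatim. OELs are recovered as RME/(ratio/100); for the
two substances whose ratio prints as 0.0% the division is undefined and
standard Korean limits (25 and 3.89 mg/m³) are assigned — both reproduce
the printed 0.0% at one decimal. The remaining sixteen substances are
named in the survey's quantitative results but their measurement records
were not published; they are **synthetic stand-ins** (labelled so in
their names) given suspected-mutagen status and exposure levels drawn
strictly inside the lowest measurement band (0.5–8% of OEL), so every
study-level count is invariant to their details. Only vanadium
pentoxide (13.7%) occupies the 10–50% band. Exactly the 17 substances
with a carcinogenicity axis receive a unit risk, matching the survey's
carcinogen count.

**Quantitative calibration.** The survey states which HQ band each
substance occupies at CTE and at RME but not the reference
concentrations behind them. The generator inverts HQ = E/RfC_work: for
each substance it solves for the HQ at RME inside the intersection of
its RME band with its CTE band mapped through the fixed CTE/RME ratio
(intervals shrunk slightly inside each edge so float arithmetic cannot
spill across a band boundary), takes the midpoint, and sets
RfC_work = RME / HQ_RME. The toxicity profile is back-derived through
the schedule rescaling with UF = 100, MF = 1 and a NOAEL-type POD. Every
structural claim — 36 substances, all CMR, one substance in the second
measurement band, 17 unit risks, zero validation issues, and the band
membership of every substance on both exposure statistics — is asserted
inside the generator, not merely hoped for.

Raw measurement series accompany the fixed summaries for illustration
(gsd 1.8, gm chosen so the series mean matches the published CTE, n
capped at 200 per substance to keep generated files small); when both
are supplied to `classify_study`, pre-computed summaries win, matching
how a published table would be used alongside partial raw data.

## Comparison statistics

Two agreement measures are reported, clearly separated because they
answer different questions. *Exact agreement* is the trace of the
qualitative × quantitative cross-tabulation over its total — per-substance
identity of levels. The *moderate-or-above overlap* divides the number
of substances at moderate/high on **both** tracks by the number at
moderate/high on the qualitative track; this category-count comparison
is the appropriate one for an all-CMR inventory, where the qualitative
track is saturated by the hazard class and exact agreement mostly
measures that saturation. On the reconstructed study the overlap is
12/36 ≈ 33%.

## Determinism and problem sizes

Every stochastic step takes an explicit seed: Monte Carlo summaries
record seed, iteration count and percentile in their output;
`classify_study` derives per-substance seeds from the run seed
(seedᵢ = (seed × 1000003 + i) mod 2³¹); generators are reproducible per
seed and the effective configuration is echoed into every report.
Default problem sizes — 10⁴ bootstrap iterations, 36-substance studies,
six-substance registries in the randomised property checks — keep a full
test run and the acceptance script in the low tens of seconds while
leaving Monte Carlo error on the CTE near 0.1%.

## Known limitations

* Concentrations are mg/m³ throughout; ppm inputs must be pre-converted
  (no molecular-weight handling).
* The handling matrix, OEL severity table and H-phrase map defaults are
  editorial choices in the COSHH-essentials style, not published rules;
  studies relying on those fallback routes should supply their own
  tables.
* The ECR path uses the linear unit-risk product form; no low-dose
  nonlinearity or route-to-route extrapolation.
* `validate_registry` checks referential integrity and hazard-route
  availability, not toxicological plausibility of the supplied values.
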