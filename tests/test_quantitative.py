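"""Quantitative track: RfC, HQ, ECR and the four-level banding."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from charmrisk import (
    ExposureFactors,
    ExposureSummary,
    RunConfig,
    Substance,
    ToxicityProfile,
    assess_quantitative,
    excess_cancer_risk,
    hazard_quotient,
    quantitative_level,
    reference_concentration,
    workplace_rfc,
)
from charmrisk.config import LEVEL_ORDER


class TestReferenceConcentration:
    @pytest.mark.parametrize(
        "pod_type, pod, uf, mf, expected",
        [("NOAEL", 10.0, 100.0, 1.0, 0.1),
         ("LOAEL", 50.0, 1000.0, 1.0, 0.05),
         ("NOAEL", 7.3, 1.0, 1.0, 7.3)],
    )
    def test_pod_over_uf_mf(self, pod_type, pod, uf, mf, expected):
        profile = ToxicityProfile("50-00-0", pod_type, pod, uf=uf, mf=mf)
        assert reference_concentration(profile) == pytest.approx(expected)

    def test_halves_when_uf_doubles(self):
        a = ToxicityProfile("50-00-0", "NOAEL", 10.0, uf=100.0)
        b = ToxicityProfile("50-00-0", "NOAEL", 10.0, uf=200.0)
        assert reference_concentration(b) == pytest.approx(
            reference_concentration(a) / 2)


class TestWorkplaceRfc:
    def test_continuous_schedule_unchanged(self):
        assert workplace_rfc(0.3, ExposureFactors(24.0, 365.0, 25.0, 25.0)) == \
            pytest.approx(0.3)

    def test_eight_hour_half_year_schedule(self):
        assert workplace_rfc(0.1, ExposureFactors(8.0, 182.5, 25.0, 25.0)) == \
            pytest.approx(0.6)

    def test_twelve_hour_full_year_schedule(self):
        assert workplace_rfc(1.0, ExposureFactors(12.0, 365.0, 25.0, 25.0)) == \
            pytest.approx(2.0)

    def test_nonpositive_rfc_rejected(self):
        with pytest.raises(ValueError):
            workplace_rfc(0.0, ExposureFactors())


class TestHazardQuotient:
    def test_unit_ratio(self):
        assert hazard_quotient(0.701, 0.701) == pytest.approx(1.0)

    def test_double(self):
        assert hazard_quotient(1.28, 0.64) == pytest.approx(2.0)

    def test_zero_exposure(self):
        assert hazard_quotient(0.0, 0.5) == 0.0

    @given(e=st.floats(0, 100), rfc=st.floats(0.01, 100))
    def test_linear_in_exposure_inverse_in_rfc(self, e, rfc):
        assert hazard_quotient(2 * e, rfc) == pytest.approx(2 * hazard_quotient(e, rfc))
        assert hazard_quotient(e, 2 * rfc) == pytest.approx(hazard_quotient(e, rfc) / 2)

    def test_zero_rfc_rejected(self):
        with pytest.raises(ValueError):
            hazard_quotient(1.0, 0.0)


class TestExcessCancerRisk:
    @pytest.mark.parametrize(
        "ur, ladc, expected",
        [(2e-3, 0.05, 1e-4), (0.0, 0.3, 0.0), (1e-3, 0.3, 3e-4)],
    )
    def test_product_form(self, ur, ladc, expected):
        assert excess_cancer_risk(ur, ladc) == pytest.approx(expected)


class TestQuantitativeLevel:
    @pytest.mark.parametrize(
        "hq, level",
        [(0.05, "low"), (0.0999, "low"),
         (0.1, "moderate"), (0.3, "moderate"), (0.4999, "moderate"),
         (0.5, "high"), (0.8, "high"), (1.0, "high"),  # "0.5 to 1" is closed
         (1.0001, "very_high"), (2.0, "very_high")],
    )
    def test_hq_band_edges(self, hq, level):
        assert quantitative_level(hq, "hq") == level

    def test_ecr_scaled_by_criterion(self):
        assert quantitative_level(1e-4, "ecr") == "high"
        assert quantitative_level(2e-4, "ecr") == "very_high"
        assert quantitative_level(5e-6, "ecr") == "low"

    @given(x=st.floats(0, 10))
    def test_ecr_and_hq_paths_agree_under_scaling(self, x):
        assert quantitative_level(x * 1e-4, "ecr") == quantitative_level(x, "hq")

    @given(a=st.floats(0, 5), b=st.floats(0, 5))
    def test_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert LEVEL_ORDER[quantitative_level(hi)] >= LEVEL_ORDER[quantitative_level(lo)]

    def test_monotone_across_edges(self):
        grid = [0.0, 0.0999, 0.1, 0.1001, 0.4999, 0.5, 0.5001, 0.999, 1.0,
                1.0001, 5.0]
        levels = [LEVEL_ORDER[quantitative_level(v)] for v in grid]
        assert levels == sorted(levels)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            quantitative_level(-0.1)


class TestAssessQuantitative:
    def _substance(self):
        return Substance(name="x", cas="50-00-0", carcinogenicity="1B", oel=1.0)

    def _profile(self, rfc_work_target, config, unit_risk=None):
        adjustment = (24.0 / config.hours_per_day) * (365.0 / config.days_per_year)
        return ToxicityProfile("50-00-0", "NOAEL",
                               pod_value=(rfc_work_target / adjustment) * 100.0,
                               uf=100.0, mf=1.0, unit_risk=unit_risk)

    def test_exposure_equal_to_rfc_work_is_high(self):
        config = RunConfig()
        summary = ExposureSummary("50-00-0", cte=0.7, rme=0.7, n_measurements=10)
        result = assess_quantitative(self._substance(),
                                     self._profile(0.7, config), summary, config)
        assert result.hq_cte == pytest.approx(1.0)
        assert result.hq_rme == pytest.approx(1.0)
        assert result.level_cte == result.level_rme == "high"

    def test_rme_level_never_below_cte_level(self):
        config = RunConfig()
        summary = ExposureSummary("50-00-0", cte=0.9, rme=1.3, n_measurements=10)
        result = assess_quantitative(self._substance(),
                                     self._profile(1.0, config), summary, config)
        # straddles the management criterion: very high at RME, high at CTE
        assert (result.level_rme, result.level_cte) == ("very_high", "high")
        assert LEVEL_ORDER[result.level_rme] >= LEVEL_ORDER[result.level_cte]

    def test_ecr_computed_and_scaled_when_unit_risk_present(self):
        config = RunConfig()
        summary = ExposureSummary("50-00-0", cte=0.5, rme=1.0, n_measurements=10)
        result = assess_quantitative(
            self._substance(), self._profile(1.0, config, unit_risk=2e-3),
            summary, config)
        # LADC = RME * 8/24 * 240/365 * 25/75; ECR = UR * LADC
        ladc = 1.0 * (8 / 24) * (240 / 365) * (25 / 75)
        assert result.ecr_rme == pytest.approx(2e-3 * ladc)
        assert result.scaled_ecr_rme == pytest.approx(result.ecr_rme / 1e-4)
        assert result.ecr_cte == pytest.approx(result.ecr_rme / 2)
        assert result.metric_used == "hq"

    def test_ecr_can_classify_when_configured(self):
        config = RunConfig(classification_metric="ecr")
        summary = ExposureSummary("50-00-0", cte=0.5, rme=1.0, n_measurements=10)
        result = assess_quantitative(
            self._substance(), self._profile(1.0, config, unit_risk=2e-3),
            summary, config)
        assert result.metric_used == "ecr"
        assert result.level_rme == quantitative_level(result.ecr_rme, "ecr")

    def test_ecr_metric_falls_back_to_hq_without_unit_risk(self):
        config = RunConfig(classification_metric="ecr")
        summary = ExposureSummary("50-00-0", cte=0.5, rme=1.0, n_measurements=10)
        result = assess_quantitative(self._substance(),
                                     self._profile(1.0, config), summary, config)
        assert result.metric_used == "hq"
        assert result.ecr_rme is None
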