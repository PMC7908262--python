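"""Control-banding track: class rules, 16-grade matrix, levels, status."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from charmrisk import (
    BandTables,
    ExposureSummary,
    InsufficientDataError,
    NoHazardRouteError,
    Substance,
    assess_qualitative,
    determine_exposure_class,
    determine_hazard_class,
    exposure_class_from_handling,
    exposure_class_from_measurement,
    permissible_status,
    qualitative_level,
    risk_grade,
)
from charmrisk.config import LEVEL_ORDER

# The published 4x4 risk matrix: rows exposure class 4..1, columns hazard
# class 4..1 (transcribed verbatim; the independent oracle for the product rule).
RISK_MATRIX = [
    [16, 12, 8, 4],
    [12, 9, 6, 3],
    [8, 6, 4, 2],
    [4, 3, 2, 1],
]


def _summary(rme, cte=None, cas="50-00-0"):
    return ExposureSummary(cas, cte=cte or rme, rme=rme, n_measurements=10)


class TestExposureClassFromMeasurement:
    @pytest.mark.parametrize(
        "ratio, expected",
        [
            (0.7, 1),     # published acrylamide row
            (12.5, 2),    # published vanadium pentoxide percentage
            (9.999, 1), (10.0, 2), (49.9, 2),  # lower edges inclusive
            (50.0, 3), (60.0, 3), (99.9, 3),
            (100.0, 4), (120.0, 4),
        ],
    )
    def test_band_edges(self, ratio, expected):
        assert exposure_class_from_measurement(ratio) == expected

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            exposure_class_from_measurement(-1.0)

    @given(lo=st.floats(0, 200), delta=st.floats(0, 200))
    def test_monotone_in_ratio(self, lo, delta):
        assert (exposure_class_from_measurement(lo + delta)
                >= exposure_class_from_measurement(lo))


class TestExposureClassFromHandling:
    @pytest.mark.parametrize(
        "amount, volatility, expected",
        [("small", "low", 1), ("large", "high", 4), ("medium", "medium", 3)],
    )
    def test_default_matrix(self, amount, volatility, expected):
        assert exposure_class_from_handling(amount, volatility) == expected

    def test_missing_band_is_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            exposure_class_from_handling("small", None)


class TestRoutePriority:
    def test_disease_history_forces_highest_class(self):
        s = Substance(name="x", cas="50-00-0", carcinogenicity="1B", oel=10.0,
                      disease_history=True)
        assert determine_exposure_class(s, _summary(0.05)) == (4, "disease")

    def test_measurement_wins_over_handling(self):
        s = Substance(name="x", cas="50-00-0", carcinogenicity="1B", oel=0.05,
                      handling_amount="large", volatility="high")
        # published vanadium pentoxide: RME/OEL = 13.7% -> class 2
        cls, route = determine_exposure_class(s, _summary(6.86e-3, 6.17e-3))
        assert (cls, route) == (2, "measurement")

    def test_handling_fallback_without_measurements(self):
        s = Substance(name="x", cas="50-00-0", carcinogenicity="1B",
                      handling_amount="large", volatility="high")
        assert determine_exposure_class(s, None) == (4, "handling")

    def test_no_route_at_all_is_an_error(self):
        s = Substance(name="x", cas="50-00-0", carcinogenicity="1B")
        with pytest.raises(InsufficientDataError):
            determine_exposure_class(s, None)


class TestHazardClass:
    def test_any_cmr_axis_is_class_4(self):
        # suspected-carcinogen-only substances still count as CMR
        s = Substance(name="nitromethane", cas="75-52-5", carcinogenicity="2")
        assert determine_hazard_class(s) == (4, "cmr")

    def test_cmr_beats_generous_oel(self):
        s = Substance(name="x", cas="50-00-0", reproductive_toxicity="2", oel=500.0)
        assert determine_hazard_class(s) == (4, "cmr")

    @pytest.mark.parametrize("oel, expected",
                             [(0.05, 4), (0.5, 3), (5.0, 2), (50.0, 1)])
    def test_oel_severity_bands(self, oel, expected):
        s = Substance(name="x", cas="50-00-0", oel=oel)
        assert determine_hazard_class(s) == (expected, "oel")

    def test_h_phrase_fallback_takes_maximum(self):
        s = Substance(name="x", cas="50-00-0", h_phrases={"H335"})
        assert determine_hazard_class(s) == (2, "h_phrase")
        s = Substance(name="x", cas="50-00-0", h_phrases={"H335", "H331"})
        assert determine_hazard_class(s) == (3, "h_phrase")

    def test_no_route_raises(self):
        with pytest.raises(NoHazardRouteError):
            determine_hazard_class(Substance(name="x", cas="50-00-0"))


class TestGradeAndLevel:
    def test_matrix_oracle_enumeration(self):
        """risk_grade over all 16 class pairs equals the published matrix."""
        for i, exposure in enumerate((4, 3, 2, 1)):
            for j, hazard in enumerate((4, 3, 2, 1)):
                assert risk_grade(exposure, hazard) == RISK_MATRIX[i][j]

    def test_reachable_grades(self):
        grades = {risk_grade(e, h) for e in (1, 2, 3, 4) for h in (1, 2, 3, 4)}
        assert grades == {1, 2, 3, 4, 6, 8, 9, 12, 16}

    @pytest.mark.parametrize(
        "grade, level",
        [(1, "low"), (2, "low"), (3, "moderate"), (4, "moderate"),
         (5, "high"), (8, "high"), (11, "high"),
         (12, "very_high"), (16, "very_high")],
    )
    def test_level_bands(self, grade, level):
        assert qualitative_level(grade) == level

    @pytest.mark.parametrize("grade", [0, 17])
    def test_out_of_range_grade(self, grade):
        with pytest.raises(ValueError):
            qualitative_level(grade)

    @given(e1=st.integers(1, 4), h1=st.integers(1, 4),
           e2=st.integers(1, 4), h2=st.integers(1, 4))
    def test_monotone_in_both_classes(self, e1, h1, e2, h2):
        if e2 >= e1 and h2 >= h1:
            g1, g2 = risk_grade(e1, h1), risk_grade(e2, h2)
            assert g2 >= g1
            assert LEVEL_ORDER[qualitative_level(g2)] >= LEVEL_ORDER[qualitative_level(g1)]


class TestPermissibleStatus:
    @pytest.mark.parametrize(
        "level, is_cmr, expected",
        [("very_high", False, "unacceptable"), ("high", False, "unacceptable"),
         ("moderate", True, "unacceptable"), ("moderate", False, "acceptable"),
         ("low", True, "acceptable"), ("low", False, "acceptable")],
    )
    def test_table(self, level, is_cmr, expected):
        assert permissible_status(level, is_cmr) == expected


class TestAssessQualitative:
    def test_vanadium_pentoxide_worked_example(self):
        s = Substance(name="Vanadium pentoxide", cas="1314-62-1",
                      carcinogenicity="2", mutagenicity="2",
                      reproductive_toxicity="2", oel=0.05)
        result = assess_qualitative(s, _summary(6.86e-3, 6.17e-3, cas="1314-62-1"))
        assert (result.exposure_class, result.hazard_class) == (2, 4)
        assert (result.grade, result.level) == (8, "high")
        assert result.status == "unacceptable"

    def test_low_exposure_cmr_substance_is_moderate(self):
        # acrylamide pattern: ratio 0.7% -> class 1, CMR hazard -> grade 4
        s = Substance(name="Acrylamide", cas="79-06-1", carcinogenicity="1B",
                      mutagenicity="1B", reproductive_toxicity="2", oel=0.03)
        result = assess_qualitative(
            s, ExposureSummary("79-06-1", cte=1.56e-4, rme=1.95e-4,
                               n_measurements=452))
        assert (result.exposure_class, result.hazard_class) == (1, 4)
        assert (result.grade, result.level) == (4, "moderate")
        assert result.status == "unacceptable"  # moderate but CMR

    def test_routes_recorded(self):
        s = Substance(name="x", cas="50-00-0", oel=5.0,
                      handling_amount="small", volatility="low")
        result = assess_qualitative(s, None)
        assert (result.exposure_route, result.hazard_route) == ("handling", "oel")

    def test_no_data_propagates_insufficiency(self):
        with pytest.raises(InsufficientDataError):
            assess_qualitative(Substance(name="x", cas="50-00-0", oel=5.0), None)


def test_band_tables_are_overridable():
    bands = BandTables(exposure_ratio_edges=(5.0, 25.0, 50.0))
    assert exposure_class_from_measurement(12.5, bands) == 2
    assert exposure_class_from_measurement(60.0, bands) == 4
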