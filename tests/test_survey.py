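import numpy as np
import pandas as pd
import pytest

from ctshield import (
    DirectionLabel,
    RatioTable,
    SurveyRecord,
    compare_methods,
    head_ratio_correlation,
    ratio_table,
    reduction_factors,
    to_one_meter,
    two_sample_t,
)
from ctshield.core import WorkloadSummary
from ctshield.reproduce import fixture_ratio_table
from ctshield.survey import survey_frame


def record(scanner, angle, net, dist, detected=True):
    return SurveyRecord(scanner, DirectionLabel(angle), net, dist, detected)


class TestToOneMeter:
    @pytest.mark.parametrize(
        "net, dist, expected",
        [
            (1.51, 235, 8.34),   # published example, within table rounding
            (10.56, 200, 42.24),
            (3.0, 100, 3.0),
        ],
    )
    def test_inverse_square_to_reference(self, net, dist, expected):
        got = to_one_meter(record("s", 0, net, dist))
        assert got == pytest.approx(expected, abs=0.005)

    def test_non_detected_rejected(self):
        with pytest.raises(ValueError, match="non-detected"):
            to_one_meter(record("s", 45, 0.0, 200, detected=False))


def toy_dose_frame():
    # two scanners; maximum direction 135° for A, 225° for B
    rows = []
    doses_a = {0: 50.0, 45: 80.0, 90: 3.0, 135: 100.0, 180: 25.0, 225: 95.0, 270: 4.0, 315: 90.0}
    doses_b = {0: 20.0, 45: 30.0, 90: 2.0, 135: 38.0, 180: 8.0, 225: 40.0, 270: 1.0, 315: 35.0}
    for sid, doses in (("A", doses_a), ("B", doses_b)):
        for ang, d in doses.items():
            rows.append({"scanner_id": sid, "angle_deg": ang, "dose_1m_mSv": d})
    return pd.DataFrame(rows)


class TestReductionFactors:
    def test_factor_is_dose_over_scanner_maximum(self):
        rf = reduction_factors(toy_dose_frame())
        assert rf.factors.loc["A", 90] == pytest.approx(0.03)
        assert rf.factors.loc["B", 180] == pytest.approx(0.2)

    def test_maximum_direction_has_factor_one(self):
        rf = reduction_factors(toy_dose_frame())
        assert rf.factors.loc["A", 135] == 1.0
        assert rf.factors.loc["B", 225] == 1.0

    def test_factors_in_unit_interval_one_max_per_scanner(self):
        rf = reduction_factors(toy_dose_frame())
        vals = rf.factors.to_numpy()
        assert ((vals > 0) & (vals <= 1)).all()
        assert ((vals == 1.0).sum(axis=1) == 1).all()

    def test_gantry_summary_pools_both_angles(self):
        rf = reduction_factors(toy_dose_frame())
        pooled = np.concatenate(
            [rf.factors[90].to_numpy(), rf.factors[270].to_numpy()]
        )
        assert rf.summary.loc["gantry", "mean"] == pytest.approx(pooled.mean())
        assert rf.summary.loc["gantry", "n"] == 4

    def test_published_cell_from_survey(self, paper_fixture):
        # CT-1 gantry 90°: 3.49 over the highest direction dose 97.47
        rf = reduction_factors(paper_fixture.doses_1m)
        assert rf.factors.loc["CT-1", 90] == pytest.approx(3.49 / 97.47, rel=1e-12)
        assert round(rf.factors.loc["CT-1", 90], 3) == 0.036

    def test_pooled_gantry_maximum_over_scanners(self, paper_fixture):
        rf = reduction_factors(paper_fixture.doses_1m)
        assert round(rf.summary.loc["gantry", "max"], 3) == 0.082
        assert round(rf.summary.loc["couch", "max"], 3) == 0.355

    def test_scanner_with_single_detection_excluded_with_warning(self):
        df = toy_dose_frame()
        extra = pd.DataFrame(
            [{"scanner_id": "C", "angle_deg": 0, "dose_1m_mSv": 5.0}]
        )
        with pytest.warns(UserWarning, match="C"):
            rf = reduction_factors(pd.concat([df, extra], ignore_index=True))
        assert "C" not in rf.factors.index


class TestRatioTable:
    def test_identical_calculated_and_measured_gives_unit_ratios(self):
        survey = toy_dose_frame()
        calc = survey.rename(columns={"dose_1m_mSv": "dose_mSv"})
        table = ratio_table(calc, survey)
        summ = table.direction_summary()
        assert np.allclose(summ["mean"], 1.0)
        assert np.allclose(summ["sd"].iloc[:-1], 0.0)  # per-direction SDs

    def test_constant_factor_two(self):
        survey = toy_dose_frame()
        calc = survey.rename(columns={"dose_1m_mSv": "dose_mSv"})
        calc["dose_mSv"] *= 2
        table = ratio_table(calc, survey)
        assert np.allclose(table.direction_summary()["mean"], 2.0)
        assert table.min_ratio() == pytest.approx(2.0)

    def test_missing_calculated_key_rejected(self):
        survey = toy_dose_frame()
        calc = survey.rename(columns={"dose_1m_mSv": "dose_mSv"}).iloc[:-1]
        with pytest.raises(KeyError, match="B"):
            ratio_table(calc, survey)

    def test_ratio_independent_of_reference_distance(self):
        # scaling calculated and measured to any common distance cancels
        survey = toy_dose_frame()
        calc = survey.rename(columns={"dose_1m_mSv": "dose_mSv"})
        calc["dose_mSv"] *= 3.7
        at_1m = ratio_table(calc, survey).points
        survey2 = survey.copy()
        survey2["dose_1m_mSv"] *= (100 / 250) ** 2
        calc2 = calc.copy()
        calc2["dose_mSv"] *= (100 / 250) ** 2
        at_250 = ratio_table(calc2, survey2).points
        assert np.allclose(at_1m["ratio"], at_250["ratio"])

    def test_non_detected_points_excluded(self, paper_fixture):
        table = fixture_ratio_table(paper_fixture)
        assert len(table.points) == 142
        assert table.underestimation().loc["all", "n_points"] == 142
        assert table.underestimation().loc["less_shielded", "n_points"] == 88

    def test_fixture_direction_zero_mean(self, paper_fixture):
        # published per-direction mean at 0° is 3.2 over 18 scanners
        summ = fixture_ratio_table(paper_fixture).direction_summary()
        assert summ.loc["0", "n"] == 18
        assert summ.loc["0", "mean"] == pytest.approx(3.2, rel=0.10)


class TestCompareMethods:
    def test_identical_tables_give_unity(self):
        pts = pd.DataFrame(
            {"scanner_id": ["A", "A"], "angle_deg": [0, 90], "ratio": [2.0, 3.0]}
        )
        out = compare_methods(RatioTable(pts), RatioTable(pts))
        assert np.allclose(out["a_over_b"], 1.0)

    def test_direction_multipliers_between_methods(self, paper_fixture):
        jdlp = fixture_ratio_table(paper_fixture, "jdlp")
        ncrp = fixture_ratio_table(paper_fixture, "ncrp-dlp")
        out = compare_methods(jdlp, ncrp)
        assert out.loc["90", "a_over_b"] == pytest.approx(0.2, rel=1e-9)
        assert out.loc["180", "a_over_b"] == pytest.approx(0.8, rel=1e-9)
        assert out.loc["45", "a_over_b"] == pytest.approx(2.0, rel=1e-9)

    def test_pooled_ncrp_over_jdlp_near_published(self, paper_fixture):
        ncrp = fixture_ratio_table(paper_fixture, "ncrp-dlp")
        jdlp = fixture_ratio_table(paper_fixture, "jdlp")
        out = compare_methods(ncrp, jdlp)
        assert out.loc["All", "a_over_b"] == pytest.approx(2.1, rel=0.10)


class TestCorrelationAndT:
    def test_pearson_matches_textbook_formula(self):
        x = np.array([0.1, 0.3, 0.4, 0.7, 0.9])
        y = np.array([2.0, 1.7, 1.9, 1.1, 0.8])
        pts = pd.DataFrame(
            {"scanner_id": [f"S{i}" for i in range(5)], "angle_deg": 0, "ratio": y}
        )
        workloads = {
            f"S{i}": WorkloadSummary(f"S{i}", xi * 100, (1 - xi) * 100)
            for i, xi in enumerate(x)
        }
        res = head_ratio_correlation(workloads, RatioTable(pts), DirectionLabel(0))
        sx, sy = x - x.mean(), y - y.mean()
        r_hand = (sx * sy).sum() / np.sqrt((sx**2).sum() * (sy**2).sum())
        assert res.r == pytest.approx(r_hand, rel=1e-9)
        assert res.n == 5

    def test_perfectly_linear_pairs_give_unit_magnitude(self):
        x = np.array([0.1, 0.2, 0.5, 0.8])
        pts = pd.DataFrame(
            {"scanner_id": [f"S{i}" for i in range(4)], "angle_deg": 0,
             "ratio": 3.0 - 2.0 * x}
        )
        workloads = {
            f"S{i}": WorkloadSummary(f"S{i}", xi * 10, (1 - xi) * 10)
            for i, xi in enumerate(x)
        }
        res = head_ratio_correlation(workloads, RatioTable(pts), DirectionLabel(0))
        assert res.abs_r == pytest.approx(1.0)

    def test_head_heavy_scanners_have_lower_calculated_ratio(self, paper_fixture):
        # strong negative association at the open 0° direction
        table = fixture_ratio_table(paper_fixture)
        res = head_ratio_correlation(
            paper_fixture.scanners, table, DirectionLabel(0)
        )
        assert res.abs_r > 0.7
        assert res.r < 0  # ratio decreases with head fraction
        assert res.p < 0.01

    def test_constant_input_rejected(self):
        pts = pd.DataFrame(
            {"scanner_id": ["A", "B", "C"], "angle_deg": 0, "ratio": [1.0, 1.0, 1.0]}
        )
        workloads = {
            s: WorkloadSummary(s, 10, 90) for s in ("A", "B", "C")
        }
        with pytest.raises(ValueError, match="constant"):
            head_ratio_correlation(workloads, RatioTable(pts), DirectionLabel(0))

    def test_t_test_identical_groups(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_t_test_matches_textbook_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0])
        t, p = two_sample_t(a, b)
        sp2 = ((a.var(ddof=1)) * 2 + (b.var(ddof=1)) * 2) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(t_hand, rel=1e-12)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])

    def test_couch_direction_scatter_per_dlp_lower_than_head_rest(self, paper_fixture):
        piv = paper_fixture.doses_1m.pivot_table(
            index="scanner_id", columns="angle_deg", values="dose_1m_mSv"
        )
        totals = {sid: w.dlp_total for sid, w in paper_fixture.scanners.items()}
        per_dlp_0 = [piv.loc[s, 0] / totals[s] for s in piv.index]
        per_dlp_180 = [piv.loc[s, 180] / totals[s] for s in piv.index]
        t, p = two_sample_t(per_dlp_180, per_dlp_0)
        assert p < 0.001
        assert t < 0  # 180° (through the patient) is lower


def test_survey_frame_round_trip():
    records = [record("A", 0, 2.0, 200), record("A", 45, 0.0, 250, detected=False)]
    df = survey_frame(records)
    assert df.loc[0, "dose_1m_mSv"] == pytest.approx(8.0)
    assert np.isnan(df.loc[1, "dose_1m_mSv"])
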