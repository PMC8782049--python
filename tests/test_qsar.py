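"""OLS calibration, diagnostics, prediction and reporting."""

import json
import math

import numpy as np
import pytest
import statsmodels.api as sm

from heteropka import (QsarModel, Step, THERMODYNAMIC_SLOPE_LIMIT,
                       build_report, calibration_pairs, external_agreement,
                       complete_external_pairs, fit, loo_residuals, predict,
                       reference_model, residual)
from heteropka.qsar import (DegenerateInputError, InsufficientDataError,
                            report_to_csv, studentized_residuals)


def random_points(seed, n=20):
    rng = np.random.default_rng(seed)
    x = rng.uniform(-1300, -900, n)
    y = -0.13 * x - 150 + rng.normal(0, 1.3, n)
    return list(zip(x, y))


class TestFit:
    def test_perfect_line(self):
        m = fit([(0, 0), (1, 1), (2, 2)])
        assert m.slope == pytest.approx(1.0, abs=1e-12)
        assert m.intercept == pytest.approx(0.0, abs=1e-12)
        assert m.r_squared == pytest.approx(1.0, abs=1e-12)
        assert m.s == pytest.approx(0.0, abs=1e-12)

    def test_line_passes_through_sample_means(self):
        pts = random_points(1)
        m = fit(pts)
        xbar = np.mean([p[0] for p in pts])
        ybar = np.mean([p[1] for p in pts])
        assert m.slope * xbar + m.intercept == pytest.approx(ybar, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_all_diagnostics_match_statsmodels(self, seed):
        pts = random_points(seed)
        m = fit(pts)
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert m.slope == pytest.approx(ref.params[1], abs=1e-9)
        assert m.intercept == pytest.approx(ref.params[0], abs=1e-9)
        assert m.slope_se == pytest.approx(ref.bse[1], abs=1e-9)
        assert m.intercept_se == pytest.approx(ref.bse[0], abs=1e-9)
        assert m.r_squared == pytest.approx(ref.rsquared, abs=1e-12)
        assert m.s == pytest.approx(math.sqrt(ref.scale), abs=1e-9)
        assert m.f_stat == pytest.approx(ref.fvalue, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_ols_identities(self, seed):
        pts = random_points(seed)
        m = fit(pts)
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        resid = y - (m.intercept + m.slope * x)
        assert abs(resid.sum()) < 1e-9 * len(pts)
        r = np.corrcoef(x, y)[0, 1]
        assert m.r_squared == pytest.approx(r * r, abs=1e-12)
        assert m.f_stat == pytest.approx(
            (m.n - 2) * m.r_squared / (1 - m.r_squared), rel=1e-12)
        # swapping the axes: product of the two slopes is R²
        swapped = fit([(b, a) for a, b in pts])
        assert m.slope * swapped.slope == pytest.approx(m.r_squared, abs=1e-9)

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            fit([(0, 0), (1, 1)])
        with pytest.raises(DegenerateInputError):
            fit([(1.0, 0), (1.0, 1), (1.0, 2)])

    def test_fitted_reference_slopes_respect_thermodynamic_limit(self, tables):
        for rows, step in ((tables.table3, Step.PKA1),
                           (tables.table4, Step.PKA2)):
            m = fit(calibration_pairs(rows), step)
            assert abs(m.slope) < THERMODYNAMIC_SLOPE_LIMIT
        assert THERMODYNAMIC_SLOPE_LIMIT == pytest.approx(0.17518, abs=5e-4)


class TestPredict:
    @pytest.mark.parametrize("step,delta_e,expected", [
        (Step.PKA1, -1216, 7.76),   # aziridine
        (Step.PKA1, -1239, 10.77),  # pyrrolidine / piperidine
        (Step.PKA1, -1166, 1.21),   # pyrazine
        (Step.PKA2, -1200, 9.78),   # uracil
        (Step.PKA2, -1159, 4.00),   # 5-nitrouracil
        (Step.PKA2, -1254, 17.39),  # flucytosine
    ])
    def test_reference_coefficients_reproduce_estimates(self, step, delta_e,
                                                        expected):
        p = predict(reference_model(step), delta_e)
        assert p.pka_value == expected
        assert p.qualitative == "numeric"

    def test_qualitative_bands(self):
        model = reference_model(Step.PKA1)
        assert predict(model, -872).qualitative == "<<0"    # oxazole
        assert predict(model, -1115).qualitative == "<0"    # isoxazole
        assert predict(model, -1166).qualitative == "numeric"

    def test_residuals(self):
        p1 = predict(reference_model(Step.PKA1), -1216)
        assert residual(p1, 8.01) == 0.25
        p2 = predict(reference_model(Step.PKA2), -1216)
        assert residual(p2, 14.4) == 2.36
        assert residual(p2, p2.pka_value) == 0.0
        assert residual(p2, None) is None
        assert residual(predict(reference_model(Step.PKA1), -872), 0.8) is None


class TestExternalAgreement:
    def test_identity_and_anticorrelation(self):
        m = external_agreement([(0, 0), (1, 1), (2, 2)])
        assert (m.slope, m.intercept) == (pytest.approx(1.0), pytest.approx(0.0))
        assert m.r_squared == pytest.approx(1.0)
        assert external_agreement([(0, 2), (1, 1), (2, 0)]).slope == \
            pytest.approx(-1.0)

    def test_reference_pairs_match_independent_oracle(self, tables):
        for step, expected_n in ((Step.PKA1, 21), (Step.PKA2, 14)):
            pairs = complete_external_pairs(tables.table1, step)
            assert len(pairs) == expected_n
            m = external_agreement(pairs, step)
            x = np.array([p[0] for p in pairs])
            y = np.array([p[1] for p in pairs])
            ref = sm.OLS(y, sm.add_constant(x)).fit()
            assert m.slope == pytest.approx(ref.params[1], abs=1e-9)
            assert m.intercept == pytest.approx(ref.params[0], abs=1e-9)


class TestReport:
    def test_reference_report_shapes(self, tables):
        report1 = build_report(
            [(r.compound_id, r.delta_e, r.exp) for r in tables.table3],
            reference_model(Step.PKA1))
        assert len(report1) == 22
        assert report1["residual"].notna().sum() == 17
        report2 = build_report(
            [(r.compound_id, r.delta_e, r.exp) for r in tables.table4],
            reference_model(Step.PKA2))
        assert len(report2) == 21
        assert report2["residual"].notna().sum() == 12

    def test_compound_without_experimental_value_gets_prediction_only(self,
                                                                      tables):
        report = build_report(
            [(r.compound_id, r.delta_e, r.exp) for r in tables.table4],
            reference_model(Step.PKA2))
        row = report.set_index("compound").loc["flucytosine"]
        assert row["calc"] == 17.39
        import pandas as pd
        assert pd.isna(row["exp"]) and pd.isna(row["residual"])

    def test_empty_dataset_gives_empty_report(self):
        report = build_report([], reference_model(Step.PKA1))
        assert len(report) == 0

    def test_report_csv_rendering(self, tmp_path, tables):
        report = build_report(
            [(r.compound_id, r.delta_e, r.exp) for r in tables.table3],
            reference_model(Step.PKA1))
        out = tmp_path / "report.csv"
        report_to_csv(report, out)
        text = out.read_text()
        assert "azauracil,-1084,-,<<0,-" in text
        assert "aziridine,-1216,8.01,7.76,0.25" in text

    def test_outlier_flagging_marks_large_studentized_residuals(self):
        pts = [(float(x), -0.13 * x - 150) for x in range(-1250, -1150, 10)]
        pts[4] = (pts[4][0], pts[4][1] + 8.0)  # one gross digression
        t = studentized_residuals(pts)
        assert abs(t[4]) > 2.5
        report = build_report(
            [(f"c{i}", x, y) for i, (x, y) in enumerate(pts)],
            fit(pts), flag_outliers=True)
        assert report["outlier_flag"].sum() == 1
        assert bool(report["outlier_flag"][4])


def test_loo_residuals_vanish_on_perfect_line():
    pts = [(float(x), 2.0 * x + 1.0) for x in range(6)]
    assert np.allclose(loo_residuals(pts), 0.0, atol=1e-9)


def test_model_json_round_trip(tmp_path):
    m = fit(random_points(3), Step.PKA2)
    path = tmp_path / "model.json"
    m.to_json(path)
    back = QsarModel.from_json(path)
    assert back == m
    assert QsarModel.from_json(m.to_json()) == m
    assert json.loads(m.to_json())["step"] == "pka2"
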