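import numpy as np
import pytest
from scipy import stats

import metaga as m
from metaga.errors import (
    DegenerateInputError,
    InsufficientDataError,
    NoInformativeTermsError,
    RankDeficientError,
)
from metaga.panel import MetabolitePanel

from oracles import ols_normal_equations


def make_cohort(panel, ga, analytes, bw=None):
    """Build a cohort directly from arrays (bypasses the generator)."""
    records = []
    for i in range(len(ga)):
        records.append(
            m.NewbornRecord(
                id=f"t{i}",
                region="sub_saharan_africa",
                site="x",
                sex="female",
                ga_ultrasound=float(ga[i]),
                birthweight=float(bw[i]) if bw is not None else 3000.0,
                collection_age=48.0,
                metabolites={a: float(v[i]) for a, v in analytes.items()},
            )
        )
    return m.Cohort(records=records, panel=panel)


CUBIC_PANEL = MetabolitePanel(
    analytes=("X", "Y"),
    squared_eligible=frozenset({"X"}),
    cubic_eligible=frozenset({"X"}),
)


class TestUnivariateScreen:
    def test_agrees_with_normal_equations_oracle(self, default_cohort):
        cohort, _ = default_cohort
        small = cohort.subset(range(400))
        frame = small.to_frame()
        y = frame["ga_ultrasound_wk"].to_numpy(float)
        for analyte in ("Alanine", "Tyrosine", "Arginine", "C3"):
            rows = m.univariate_screen(small, analyte, 0.01)
            x = frame[analyte].to_numpy(float)
            c = x.mean()
            powers = small.panel.eligible_powers(analyte)
            X = np.column_stack([np.ones_like(x)] + [(x - c) ** p for p in powers])
            _, _, pv = ols_normal_equations(X, y)
            for row, p_oracle in zip(rows, pv[1:]):
                assert row.pvalue == pytest.approx(p_oracle, abs=1e-8)

    def test_perfect_signal_passes(self):
        ga = np.linspace(30, 42, 50)
        cohort = make_cohort(CUBIC_PANEL, ga, {"X": 2 * ga + 1, "Y": np.ones(50)})
        rows = m.univariate_screen(cohort, "X", 0.01)
        linear = next(r for r in rows if r.power == 1)
        assert linear.pvalue < 1e-12 and linear.passed

    def test_constant_analyte_degenerate(self):
        ga = np.linspace(30, 42, 50)
        cohort = make_cohort(CUBIC_PANEL, ga, {"X": 2 * ga, "Y": np.ones(50)})
        with pytest.raises(DegenerateInputError):
            m.univariate_screen(cohort, "Y", 0.01)

    def test_insufficient_data(self):
        ga = np.array([38.0, 39.0, 40.0, 41.0])
        cohort = make_cohort(
            CUBIC_PANEL, ga, {"X": ga * 1.1, "Y": np.arange(4.0)}
        )
        with pytest.raises(InsufficientDataError):
            m.univariate_screen(cohort, "X", 0.01)  # 3 powers, n=4

    def test_type_one_error_rate(self):
        """Pure-noise analyte: per-term pass rate at P<0.01 is ~1%."""
        rng = np.random.default_rng(99)
        n_screens, n, passes, total = 1000, 200, 0, 0
        for _ in range(n_screens):
            ga = rng.normal(38.5, 1.8, n)
            x = rng.normal(10.0, 1.0, n)
            cohort = make_cohort(CUBIC_PANEL, ga, {"X": x, "Y": rng.normal(size=n)})
            for row in m.univariate_screen(cohort, "X", 0.01):
                total += 1
                passes += row.passed
        assert passes / total == pytest.approx(0.01, abs=0.006)


class TestSelectTerms:
    def test_cubic_excluded_when_squared_fails(self):
        """Hierarchy at entry: a cubic term cannot ride in without its square."""
        screen = [
            m.ScreenRow("X", 1, 1e-6, True),
            m.ScreenRow("X", 2, 0.5, False),
            m.ScreenRow("X", 3, 1e-6, True),
        ]
        rng = np.random.default_rng(0)
        ga = rng.normal(38.5, 1.8, 300)
        cohort = make_cohort(
            CUBIC_PANEL, ga, {"X": ga + rng.normal(0, 1, 300), "Y": rng.normal(size=300)}
        )
        spec = m.select_terms(screen, cohort, 0.05)
        assert m.Term("X", 3) not in spec.terms
        assert m.Term("X", 1) in spec.terms

    def test_single_informative_term(self):
        rng = np.random.default_rng(1)
        ga = rng.normal(38.5, 1.8, 3000)
        x = 5 + 2 * ga + rng.normal(0, 1, 3000)
        y_noise = rng.normal(size=3000)
        cohort = make_cohort(CUBIC_PANEL, ga, {"X": x, "Y": y_noise})
        screen = m.screen_all(cohort, 0.01)
        spec = m.select_terms(screen, cohort, 0.05)
        assert m.Term("X", 1) in spec.terms
        assert all(t.analyte != "Y" for t in spec.terms)

    def test_empty_candidates_error(self, default_cohort):
        cohort, _ = default_cohort
        screen = [m.ScreenRow("Alanine", 1, 0.9, False)]
        with pytest.raises(NoInformativeTermsError):
            m.select_terms(screen, cohort.subset(range(100)), 0.05)

    def test_invariant_to_record_order(self, fitted):
        build = fitted["build"]
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(build))
        shuffled = build.subset(perm.tolist())
        spec_b = m.select_terms(m.screen_all(shuffled, 0.01), shuffled, 0.05)
        assert spec_b == fitted["spec1"]

    def test_emitted_spec_satisfies_hierarchy(self, fitted):
        present = {(t.analyte, t.power) for t in fitted["spec1"].terms}
        for a, p in present:
            if p == 3:
                assert (a, 2) in present


class TestFitModel:
    def test_noiseless_recovery(self):
        """With an exactly linear analyte, the fit inverts the true mapping."""
        ga = np.linspace(28, 43, 60)
        x = 5.0 + 2.0 * ga  # => ga = (x - 5) / 2
        y_noise = np.sin(ga)  # irrelevant second analyte
        cohort = make_cohort(CUBIC_PANEL, ga, {"X": x, "Y": y_noise})
        spec = m.ModelSpec((m.Term("X", 1),))
        cs = m.fit_model(cohort, spec)
        # centered form: ga = intercept + b*(x - c) with b = 0.5
        assert cs.coefficients[m.Term("X", 1)] == pytest.approx(0.5, abs=1e-6)
        assert cs.diagnostics.residual_sd == pytest.approx(0.0, abs=1e-8)
        preds = m.predict_ga(cohort, cs)
        assert np.allclose(preds.ga_predicted, ga, atol=1e-6)

    def test_agrees_with_normal_equations_oracle(self, fitted):
        build, cs = fitted["build"], fitted["coef1"]
        frame = build.to_frame()
        y = frame["ga_ultrasound_wk"].to_numpy(float)
        terms = sorted(cs.coefficients)
        X = np.column_stack(
            [np.ones(len(frame))]
            + [
                (frame[t.analyte].to_numpy(float) - cs.centers[t.analyte]) ** t.power
                for t in terms
            ]
        )
        beta, _, pv = ols_normal_equations(X, y)
        assert cs.intercept == pytest.approx(beta[0], abs=1e-8)
        for t, b, p in zip(terms, beta[1:], pv[1:]):
            assert cs.coefficients[t] == pytest.approx(b, abs=1e-8)
            assert cs.diagnostics.pvalues[t] == pytest.approx(p, abs=1e-8)

    def test_confidence_interval_coverage(self):
        """~95% of per-term 95% CIs cover the true coefficient."""
        rng = np.random.default_rng(7)
        true_b = 0.8
        n, reps, covered = 150, 200, 0
        crit = stats.t.ppf(0.975, n - 2)
        for _ in range(reps):
            x = rng.normal(10, 2, n)
            ga = 30.0 + true_b * x + rng.normal(0, 1.5, n)
            ga = np.clip(ga, 20.5, 44.9)
            cohort = make_cohort(CUBIC_PANEL, ga, {"X": np.ones(n), "Y": x})
            cs = m.fit_model(cohort, m.ModelSpec((m.Term("Y", 1),)))
            t = m.Term("Y", 1)
            b, se = cs.coefficients[t], cs.diagnostics.stderr[t]
            covered += b - crit * se <= true_b <= b + crit * se
        assert covered / reps >= 0.93

    def test_rank_deficient_design_names_terms(self):
        ga = np.linspace(30, 42, 40)
        x = 2 * ga + 1
        cohort = make_cohort(CUBIC_PANEL, ga, {"X": x, "Y": x})  # Y aliases X
        spec = m.ModelSpec((m.Term("X", 1), m.Term("Y", 1)))
        with pytest.raises(RankDeficientError) as exc:
            m.fit_model(cohort, spec)
        assert "Y^1" in exc.value.aliased

    def test_nested_model_never_worse_in_sample(self, fitted):
        build = fitted["build"]
        r1 = m.rmse(m.predict_ga(build, fitted["coef1"]))
        r2 = m.rmse(m.predict_ga(build, fitted["coef2"]))
        assert r2 <= r1 + 1e-12


class TestPredict:
    def test_intercept_only(self, default_cohort):
        cohort, _ = default_cohort
        cs = m.CoefficientSet(intercept=40.0, coefficients={})
        preds = m.predict_ga(cohort.subset(range(10)), cs)
        assert np.all(preds.ga_predicted == 40.0)

    def test_holdout_rmse_in_designed_band(self, holdout_predictions):
        """Generator noise is designed for ~1.5-week metabolite-model RMSE."""
        p1, _ = holdout_predictions
        assert 1.4 <= m.rmse(p1) <= 1.6

    def test_missing_birthweight_excluded_for_bw_model(self, fitted):
        import dataclasses

        val = fitted["val"]
        records = list(val.records)
        records[0] = dataclasses.replace(records[0], birthweight=None)
        val2 = m.Cohort(records=records, panel=val.panel)
        p2 = m.predict_ga(val2, fitted["coef2"])
        assert p2.n_excluded == 1
        assert len(p2) == len(val2) - 1
        p1 = m.predict_ga(val2, fitted["coef1"])
        assert p1.n_excluded == 0

    def test_unknown_analyte_rejected(self, default_cohort):
        cohort, _ = default_cohort
        cs = m.CoefficientSet(
            intercept=40.0, coefficients={m.Term("NotAnAnalyte", 1): 1.0}
        )
        with pytest.raises(m.CoefficientError):
            m.predict_ga(cohort.subset(range(5)), cs)

    def test_clamp(self, default_cohort):
        cohort, _ = default_cohort
        sub = cohort.subset(range(20))
        cs = m.CoefficientSet(intercept=50.0, coefficients={})
        preds = m.predict_ga(sub, cs, clamp=(22.0, 44.0))
        assert np.all(preds.ga_predicted == 44.0)
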