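import itertools

import numpy as np
import pytest
from scipy import stats

from gaitsig import (
    GeneratorConfig,
    LINEAR,
    ONE_PHASE,
    TWO_PHASE,
    VelocityRange,
    WALKING_RANGE,
    extra_ss_f_test,
    fit_curve,
    generate_cohort,
    range_scan,
    residual_diagnostics,
    restrict_range,
    runs_test,
    select_model,
)
from gaitsig.regression import ModelForm

from conftest import table_from_xy


class TestRestrictRange:
    def test_closed_boundaries_included(self):
        table = table_from_xy([2, 3, 10, 16, 17], [50.0] * 5)
        out, report = restrict_range(table, VelocityRange(3, 16))
        assert sorted(out.data["stride_velocity_cm_s"]) == [3, 10, 16]
        assert report.n_slow_excluded == 1
        assert report.n_fast_excluded == 1

    def test_wide_range_is_identity(self, default_cohort):
        out, report = restrict_range(default_cohort, VelocityRange(0, 1e9))
        assert len(out) == len(default_cohort)
        assert report.n_slow_excluded == report.n_fast_excluded == 0

    def test_excluded_counts_match_velocity_histogram(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 25, 300)
        table = table_from_xy(v, np.full(300, 60.0))
        _, report = restrict_range(table, WALKING_RANGE)
        assert report.n_slow_excluded == int((v < 3).sum())
        assert report.n_fast_excluded == int((v > 16).sum())


class TestFitCurve:
    def test_exactly_collinear_points_fit_perfectly(self):
        v = np.linspace(3, 16, 12)
        table = table_from_xy(v, 2.0 + 0.5 * v)
        fit = fit_curve(table, "stride_length_mm", LINEAR)
        assert fit.params == pytest.approx([2.0, 0.5], abs=1e-10)
        assert fit.ss == pytest.approx(0.0, abs=1e-18)

    def test_linear_fit_matches_closed_form_ols(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(3, 16, 150)
        y = 35.0 + 2.2 * v + rng.normal(0, 3, 150)
        table = table_from_xy(v, y)
        fit = fit_curve(table, "stride_length_mm", LINEAR)
        # independent closed-form simple-regression oracle
        b1 = np.sum((v - v.mean()) * (y - y.mean())) / np.sum((v - v.mean()) ** 2)
        b0 = y.mean() - b1 * v.mean()
        ss = np.sum((y - b0 - b1 * v) ** 2)
        assert fit.params[0] == pytest.approx(b0, rel=1e-8)
        assert fit.params[1] == pytest.approx(b1, rel=1e-8)
        assert fit.ss == pytest.approx(ss, rel=1e-8)

    def test_one_phase_parameter_recovery(self, one_phase_cohort):
        # generated as Y0=30 mm, Plateau=75 mm, K=0.25 per cm/s, noise SD 3 mm
        fit = fit_curve(one_phase_cohort, "stride_length_mm", ONE_PHASE)
        truth = np.array([30.0, 75.0, 0.25])
        assert fit.converged
        assert np.all(np.abs(fit.params - truth) <= 3.0 * fit.se)

    def test_insufficient_points_rejected(self):
        table = table_from_xy([3, 8, 16], [40, 55, 70])
        with pytest.raises(ValueError, match="insufficient points"):
            fit_curve(table, "stride_length_mm", LINEAR)

    def test_insufficient_span_rejected(self):
        v = np.linspace(8, 10, 20)
        table = table_from_xy(v, 40 + 2 * v)
        with pytest.raises(ValueError, match="span"):
            fit_curve(table, "stride_length_mm", LINEAR)

    def test_log_transform_fits_log_response(self):
        rng = np.random.default_rng(11)
        v = rng.uniform(3, 16, 200)
        stance = np.exp(0.2 - 0.08 * v + rng.normal(0, 0.05, 200))
        table = table_from_xy(v, stance, parameter="stance_s")
        form = ModelForm("linear", "log")
        fit = fit_curve(table, "stance_s", form)
        assert fit.params[1] == pytest.approx(-0.08, abs=0.01)

    def test_one_phase_approaches_line_for_small_k(self):
        # As K -> 0 with (Plateau - Y0) * K fixed, the curve flattens onto
        # a straight line of that slope.
        v = np.linspace(3, 16, 50)
        y0, slope, k = 30.0, 0.5, 1e-6
        curve = ONE_PHASE.predict([y0, y0 + slope / k, k], v)
        assert np.max(np.abs(curve - (y0 + slope * v))) < 1e-4

    @pytest.mark.parametrize("form", [ONE_PHASE, TWO_PHASE], ids=["one_phase", "two_phase"])
    def test_local_optimality_probe(self, form, one_phase_cohort):
        fit = fit_curve(one_phase_cohort, "stride_length_mm", form)
        restricted, _ = restrict_range(one_phase_cohort, fit.vrange)
        v = restricted.data["stride_velocity_cm_s"].to_numpy()
        y = restricted.data["stride_length_mm"].to_numpy()
        rng = np.random.default_rng(0)
        scale = np.maximum(np.abs(fit.params), 0.01)
        for _ in range(100):
            perturbed = fit.params + rng.normal(0, 0.02, len(fit.params)) * scale
            perturbed = np.abs(perturbed)  # keep rate constants positive
            ss_pert = np.sum((y - form.predict(perturbed, v)) ** 2)
            assert fit.ss <= ss_pert + 1e-9

    def test_confidence_band_contains_fit(self, one_phase_cohort):
        fit = fit_curve(one_phase_cohort, "stride_length_mm", ONE_PHASE)
        grid = np.linspace(3, 16, 20)
        lo, hi = fit.confidence_band(grid)
        yhat = fit.predict(grid)
        assert np.all(lo <= yhat) and np.all(yhat <= hi)


class TestExtraSSFTest:
    def test_arithmetic(self):
        f, p = extra_ss_f_test(100.0, 98, 80.0, 97)
        assert f == pytest.approx(((100 - 80) / 1) / (80 / 97))
        assert f == pytest.approx(24.25)
        assert p == pytest.approx(float(stats.f.sf(24.25, 1, 97)))

    def test_no_improvement_gives_zero_f(self):
        f, p = extra_ss_f_test(50.0, 98, 50.0, 97)
        assert f == 0.0 and p == 1.0
        f, p = extra_ss_f_test(50.0, 98, 55.0, 97)
        assert f == 0.0 and p == 1.0

    def test_requires_nested_df(self):
        with pytest.raises(ValueError):
            extra_ss_f_test(10.0, 50, 9.0, 50)


class TestSelectModel:
    def test_curved_data_prefers_one_phase(self, one_phase_cohort):
        sel = select_model(one_phase_cohort, "stride_length_mm")
        assert sel.preferred.family == "one_phase"
        assert sel.steps[0].p <= 0.05  # linear rejected
        assert sel.steps[1].p > 0.05  # two_phase unnecessary

    def test_straight_line_data_prefers_linear(self, linear_cohort):
        sel = select_model(linear_cohort, "stride_length_mm")
        assert sel.preferred.family == "linear"

    def test_chain_f_matches_brute_force_from_stored_fields(self, one_phase_cohort):
        sel = select_model(one_phase_cohort, "stride_length_mm")
        for step in sel.steps:
            if step.ss1 <= step.ss2:
                assert step.F == 0.0
            else:
                brute = ((step.ss1 - step.ss2) / (step.df1 - step.df2)) / (
                    step.ss2 / step.df2
                )
                assert step.F == brute

    def test_unordered_candidates_rejected(self, linear_cohort):
        with pytest.raises(ValueError, match="increasing parameter count"):
            select_model(linear_cohort, "stride_length_mm", (ONE_PHASE, LINEAR))


class TestRangeScan:
    def test_piecewise_data_switches_to_linear_above_cutoff(self):
        # linear on [3, 16] but strongly curved below 3 cm/s
        rng = np.random.default_rng(2)
        v = np.concatenate([rng.uniform(0.5, 3, 150), rng.uniform(3, 16, 450)])
        y = np.where(v < 3, 40 + 2 * v + 14 * (3 - v) ** 2, 40 + 2 * v)
        y = y + rng.normal(0, 2.0, len(v))
        table = table_from_xy(v, y)
        report = range_scan(
            table,
            "stride_length_mm",
            lower_bounds=[0, 3],
            upper_bounds=[16],
            compute_diagnostics=False,
        )
        low = report[(report.lower == 0) & (report.upper == 16)].iloc[0]
        walk = report[(report.lower == 3) & (report.upper == 16)].iloc[0]
        assert low.preferred in ("one_phase", "two_phase")
        assert walk.preferred == "linear"

    def test_ranges_without_data_marked_skipped(self, default_cohort):
        report = range_scan(
            default_cohort,
            "stride_length_mm",
            candidates=(LINEAR,),
            lower_bounds=[3, 20],
            upper_bounds=[25],
            compute_diagnostics=False,
        )
        assert report[report.lower == 20].status.eq("skipped").all()
        assert report[report.lower == 3].status.eq("ok").all()

    def test_restricted_fit_has_smaller_per_point_ss(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(1, 25, 600)
        y = ONE_PHASE.predict([30, 80, 0.15], v) + rng.normal(0, 3, 600)
        table = table_from_xy(v, y)
        full = fit_curve(table, "stride_length_mm", LINEAR, VelocityRange(1, 25))
        walk = fit_curve(table, "stride_length_mm", LINEAR, WALKING_RANGE)
        assert walk.ss / walk.n_points <= full.ss / full.n_points


class TestResidualDiagnostics:
    @staticmethod
    def _enumerated_runs_p(n1, n2, observed_runs):
        """Exact two-sided runs p by brute-force enumeration of all
        arrangements of n1 plus and n2 minus signs."""
        counts = {}
        for pos in itertools.combinations(range(n1 + n2), n1):
            s = np.full(n1 + n2, -1)
            s[list(pos)] = 1
            r = 1 + int((np.diff(s) != 0).sum())
            counts[r] = counts.get(r, 0) + 1
        total = sum(counts.values())
        lower = sum(c for r, c in counts.items() if r <= observed_runs) / total
        upper = sum(c for r, c in counts.items() if r >= observed_runs) / total
        return min(1.0, 2.0 * min(lower, upper))

    @pytest.mark.parametrize("pattern", ["alternating", "blocked", "mixed"])
    def test_runs_test_matches_enumeration_oracle(self, pattern):
        seqs = {
            "alternating": [1, -1] * 5,
            "blocked": [1] * 5 + [-1] * 5,
            "mixed": [1, 1, -1, 1, -1, -1, -1, 1, 1, -1],
        }
        x = np.array(seqs[pattern], float)
        res = runs_test(x)
        n1, n2 = int((x > 0).sum()), int((x < 0).sum())
        assert res["p"] == pytest.approx(self._enumerated_runs_p(n1, n2, res["runs"]))

    def test_perfectly_alternating_long_sequence(self):
        x = np.array([1, -1] * 10, float)
        res = runs_test(x)
        assert res["runs"] == 20
        # maximum possible runs: strongly non-random in the two-sided sense
        assert res["p"] < 1e-3

    def test_single_sign_is_degenerate_misfit(self):
        res = runs_test(np.ones(15))
        assert res["runs"] == 1
        assert res["p"] == 0.0

    def test_gaussian_residuals_pass_normality(self):
        rng = np.random.default_rng(8)
        out = residual_diagnostics(rng.normal(0, 1, 500))
        assert out["normality_p"] > 0.05
        assert out["runs_test_p"] > 0.01

    def test_normality_refused_below_eight_residuals(self):
        out = residual_diagnostics(np.array([0.5, -0.2, 0.1, -0.4, 0.3]))
        assert out["normality_p"] is None
        assert out["runs_test_p"] is not None

    def test_fit_carries_diagnostics(self, one_phase_cohort):
        fit = fit_curve(one_phase_cohort, "stride_length_mm", ONE_PHASE)
        assert 0 <= fit.diagnostics["runs_test_p"] <= 1
        assert 0 <= fit.diagnostics["normality_p"] <= 1
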