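"""Normality screen, paired one-sided tests, CIs, power and reporting."""

import numpy as np
import pytest
from scipy import stats

from hrident.evaluation import cross_validate, records_to_frame
from hrident.identification import TransferFunctionModel
from hrident.stats_report import (
    PowerSpec,
    average_models,
    build_report,
    lilliefors_normality,
    one_sided_mean_ci,
    paired_one_sided_ttest,
    paired_ttest_power,
    required_sample_size,
)


class TestLilliefors:
    def test_type_i_error_near_alpha(self):
        """Rejection rate on normal samples calibrates to ~5%."""
        rng = np.random.default_rng(1)
        rejections = sum(
            lilliefors_normality(rng.normal(0, 1, 20))[2] for _ in range(2000)
        )
        assert 0.03 <= rejections / 2000 <= 0.07

    def test_power_against_uniform(self):
        rng = np.random.default_rng(2)
        rejections = sum(
            lilliefors_normality(rng.uniform(0, 1, 50))[2] for _ in range(200)
        )
        # far above the 5% null rate (uniform is a mild alternative at n=50)
        assert rejections / 200 > 0.2

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            lilliefors_normality(np.full(10, 3.0))

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            lilliefors_normality([1.0, 2.0, 3.0])


class TestPairedTTest:
    def test_all_zero_differences(self):
        x = np.array([1.0, 2.0, 3.0])
        t, p, md = paired_one_sided_ttest(x, x, "greater")
        assert (t, p, md) == (0.0, 0.5, 0.0)

    def test_closed_form_example(self):
        """d = (1,2,3): t = mean/SE = 2/(1/sqrt(3)) = 2*sqrt(3)."""
        x1 = np.zeros(3)
        x2 = np.array([1.0, 2.0, 3.0])
        t, p, md = paired_one_sided_ttest(x2, x1, "greater")
        assert t == pytest.approx(2 * np.sqrt(3))
        assert p == pytest.approx(stats.t.sf(2 * np.sqrt(3), 2))
        # closed form for df = 2: p = (1 - t/sqrt(2 + t^2))/2
        t_stat = 2 * np.sqrt(3)
        assert p == pytest.approx((1 - t_stat / np.sqrt(2 + t_stat**2)) / 2, rel=1e-12)
        assert md == pytest.approx(2.0)

    def test_direction_complementarity(self, rng):
        x1 = rng.normal(0, 1, 15)
        x2 = rng.normal(0.3, 1, 15)
        _, p_g, _ = paired_one_sided_ttest(x2, x1, "greater")
        _, p_l, _ = paired_one_sided_ttest(x2, x1, "less")
        assert p_g + p_l == pytest.approx(1.0)

    def test_zero_variance_nonzero_differences_rejected(self):
        x1 = np.zeros(5)
        with pytest.raises(ValueError, match="variance"):
            paired_one_sided_ttest(x1 + 2.0, x1, "greater")


class TestOneSidedCI:
    def test_duality_with_test_on_200_samples(self):
        """Bound excludes 0 exactly when the one-sided p < 0.05."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(5, 30))
            d = rng.normal(rng.normal(0, 0.3), 1.0, n)
            direction = "greater" if rng.random() < 0.5 else "less"
            _, p, _ = paired_one_sided_ttest(d, np.zeros(n), direction)
            bound, _ = one_sided_mean_ci(d, 0.95, direction)
            excludes_zero = bound > 0 if direction == "greater" else bound < 0
            assert excludes_zero == (p < 0.05)

    def test_bound_tends_to_common_value(self, rng):
        d = 4.2 + rng.normal(0, 1e-9, 30)
        bound, _ = one_sided_mean_ci(d, 0.95, "greater")
        assert bound == pytest.approx(4.2, abs=1e-8)

    def test_coverage(self):
        """[bound, inf) covers the true mean in ~95% of normal samples."""
        rng = np.random.default_rng(4)
        mu = 1.3
        hits = 0
        reps = 10_000
        for _ in range(reps):
            d = rng.normal(mu, 2.0, 12)
            bound, _ = one_sided_mean_ci(d, 0.95, "greater")
            hits += bound <= mu
        assert hits / reps == pytest.approx(0.95, abs=0.01)


class TestPower:
    def test_null_effect_gives_alpha(self):
        assert paired_ttest_power(PowerSpec(0.0, 11)) == pytest.approx(0.05, abs=1e-9)

    def test_power_increases_to_one(self):
        powers = [paired_ttest_power(PowerSpec(0.8, n)) for n in (5, 11, 50, 200)]
        assert all(a < b for a, b in zip(powers, powers[1:]))
        assert powers[-1] > 0.999

    def test_matches_monte_carlo(self):
        """d = 0.8, n = 11, one-sided alpha 0.05 vs 1e5-rep simulation."""
        rng = np.random.default_rng(5)
        n, reps = 11, 100_000
        d = rng.normal(0.8, 1.0, size=(reps, n))
        t = d.mean(1) / (d.std(1, ddof=1) / np.sqrt(n))
        mc = float(np.mean(t > stats.t.ppf(0.95, n - 1)))
        assert paired_ttest_power(PowerSpec(0.8, 11)) == pytest.approx(mc, abs=0.01)

    def test_matches_statsmodels(self):
        from statsmodels.stats.power import TTestPower

        sm = TTestPower().power(0.8, nobs=11, alpha=0.05, alternative="larger")
        assert paired_ttest_power(PowerSpec(0.8, 11)) == pytest.approx(sm, abs=1e-6)

    def test_required_sample_size_brackets_target(self):
        n = required_sample_size(0.8, 0.05, 0.8)
        assert paired_ttest_power(PowerSpec(0.8, n)) >= 0.8
        assert paired_ttest_power(PowerSpec(0.8, n - 1)) < 0.8


class TestAverageModels:
    def test_identical_models(self):
        m = TransferFunctionModel(2, 24.7, (18.6, 37.95))
        am = average_models([m, m, m])
        assert am.gain_mean == pytest.approx(24.7)
        assert am.gain_sd == 0.0
        assert am.model() == m

    def test_two_first_order_models(self):
        a = TransferFunctionModel(1, 20.0, (60.0,))
        b = TransferFunctionModel(1, 30.0, (80.0,))
        am = average_models([a, b])
        assert am.gain_mean == pytest.approx(25.0)
        assert am.tau_means == (70.0,)

    def test_mixed_orders_rejected(self):
        with pytest.raises(ValueError, match="order"):
            average_models(
                [
                    TransferFunctionModel(1, 20.0, (60.0,)),
                    TransferFunctionModel(2, 20.0, (10.0, 60.0)),
                ]
            )

    def test_zero_sd_cohort_reproduces_generator(self, prbs_input_deviation):
        """Estimating on noiseless draws recovers the population model."""
        from hrident.identification import estimate_model, simulate_response

        truth = TransferFunctionModel(2, 24.70, (18.60, 37.95))
        u = prbs_input_deviation.values
        y = simulate_response(truth, u, 5.0)
        fits = [estimate_model(2, u, y, 5.0).model for _ in range(2)]
        am = average_models(fits)
        assert am.gain_mean == pytest.approx(24.70, rel=1e-3)
        assert am.tau_means[0] == pytest.approx(18.60, rel=1e-2)
        assert am.tau_means[1] == pytest.approx(37.95, rel=1e-2)


@pytest.fixture(scope="module")
def small_run():
    from hrident.pipeline import StudyConfig, run_study

    return run_study(StudyConfig(n_participants=4, seed=2))


class TestBuildReport:
    def test_row_counts(self, small_run):
        s = small_run.report.summaries
        assert s["rmse"].n == 8  # 4 participants x 2 directions
        assert s["fit"].n == 8

    def test_report_recomputes_from_emitted_table(self, small_run):
        """Summary numbers equal recomputation from the tidy CSV frame."""
        frame = records_to_frame(small_run.validation)
        wide = frame.pivot_table(
            index=["participant", "est_session"], columns="order", values="rmse_bpm"
        )
        d = (wide[2] - wide[1]).to_numpy()
        s = small_run.report.summaries["rmse"]
        assert s.mean_difference == pytest.approx(d.mean())
        _, p, _ = paired_one_sided_ttest(wide[2].to_numpy(), wide[1].to_numpy(), "less")
        assert s.p_value == pytest.approx(p)

    def test_ci_strings_match_direction(self, small_run):
        s = small_run.report.summaries
        assert s["rmse"].ci_string().startswith("(-inf")
        assert s["fit"].ci_string().endswith("+inf)")

    def test_markdown_and_dict_render(self, small_run):
        md = small_run.report.to_markdown()
        assert "MD (95% CI)" in md
        d = small_run.report.to_dict()
        assert set(d["summaries"]) == {"rmse", "fit"}
        assert "1" in d["average_models"] and "2" in d["average_models"]

    def test_single_participant_rejected(self, small_run):
        frame = records_to_frame(small_run.validation)
        one = frame[frame["participant"] == "P01"]
        models = [r.model for r in small_run.validation]
        with pytest.raises(ValueError, match="participants"):
            build_report(one, models=models)

    def test_constant_outcome_column_propagates_error(self, small_run):
        frame = records_to_frame(small_run.validation).copy()
        frame["fit_pct"] = 50.0
        with pytest.raises(ValueError):
            build_report(frame, models=[r.model for r in small_run.validation])

    def test_normality_gate_flags_violation(self, rng):
        """Heavy-tailed differences trip the Lilliefors screen and add a
        signed-rank fallback."""
        import pandas as pd

        n = 40
        base = rng.normal(2.2, 0.3, n)
        d = rng.standard_cauchy(n) * 0.05
        frame = pd.DataFrame(
            {
                "participant": [f"P{i:02d}" for i in range(n) for _ in (1, 2)],
                "est_session": ["I"] * 2 * n,
                "val_session": ["II"] * 2 * n,
                "order": [1, 2] * n,
                "fit_pct": np.repeat(base, 2) + np.r_[
                    np.zeros(n), d + 3
                ].reshape(2, n).T.ravel(),
                "rmse_bpm": np.repeat(base, 2)
                + np.r_[np.zeros(n), rng.normal(-0.2, 0.05, n)].reshape(2, n).T.ravel(),
            }
        )
        models = [
            TransferFunctionModel(1, 25.0, (60.0,)),
            TransferFunctionModel(2, 25.0, (15.0, 40.0)),
        ] * n
        bundle = build_report(frame, models=models)
        assert not bundle.normality_ok
        assert "fit" in bundle.wilcoxon
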