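"""Model suite: scaling, mixed fits vs oracles, fallback ladder, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from symsig.errors import NumericalError
from symsig.models import (
    ModelSpec,
    RandomEffects,
    _ladder_structures,
    bootstrap_ci,
    fallback_ladder,
    fit_mixed,
    run_model_suite,
    scale_covariates,
    suite_specs,
)


class TestScaleCovariates:
    def test_hand_vector(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out, scalers = scale_covariates(df, ["x"])
        np.testing.assert_allclose(out["x_s"], [-1.0, 0.0, 1.0])
        assert scalers["x"] == (2.0, 1.0)  # sample SD (ddof=1)

    def test_outlier_vector_standardised(self):
        df = pd.DataFrame({"x": [5.0] * 9 + [50.0]})
        out, _ = scale_covariates(df, ["x"])
        assert out["x_s"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["x_s"].std(ddof=1) == pytest.approx(1.0)

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=100)})
        once, _ = scale_covariates(df, ["x"])
        twice, _ = scale_covariates(once.rename(columns={"x_s": "y"}), ["y"])
        np.testing.assert_allclose(twice["y_s"], once["x_s"], atol=1e-12)

    def test_zero_variance_named_in_error(self):
        with pytest.raises(ValueError, match="const"):
            scale_covariates(pd.DataFrame({"const": [1.0, 1.0, 1.0]}), ["const"])


def _mixed_data(n_g=12, n_per=25, sd_g=0.0, sd_e=0.5, seed=0):
    rng = np.random.default_rng(seed)
    g = np.repeat([f"g{i}" for i in range(n_g)], n_per)
    x = rng.normal(size=n_g * n_per)
    u = dict(zip(sorted(set(g)), rng.normal(scale=sd_g, size=n_g)))
    y = 1.5 + 0.7 * x + np.array([u[k] for k in g]) + rng.normal(scale=sd_e, size=len(x))
    return pd.DataFrame({"y": y, "x": x, "g": g})


class TestFitMixed:
    def test_zero_variance_random_effects_match_ols(self):
        """On noise-free data the group variance collapses to the boundary
        and the mixed estimate coincides with the closed-form OLS solution."""
        df = _mixed_data(sd_g=0.0, sd_e=1e-6)
        spec = ModelSpec("m", "y", ("x",), "gaussian", (RandomEffects("g"),))
        fit = fit_mixed(spec, df)
        X = np.column_stack([np.ones(len(df)), df.x])
        beta_ols = np.linalg.lstsq(X, df.y.to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-6)

    def test_exact_linear_response(self):
        df = pd.DataFrame({"y": np.linspace(-2, 2, 60), "x": np.linspace(-2, 2, 60)})
        spec = ModelSpec("m", "y", ("x",), "gaussian", ())
        fit = fit_mixed(spec, df)
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-10)
        assert fit.beta[1] == pytest.approx(1.0, abs=1e-10)

    def test_random_intercepts_recover_slope(self):
        df = _mixed_data(sd_g=1.0, seed=2)
        spec = ModelSpec("m", "y", ("x",), "gaussian", (RandomEffects("g"),))
        fit = fit_mixed(spec, df)
        assert fit.coef("x") == pytest.approx(0.7, abs=3 * fit.se[1])
        assert fit.converged

    def test_binomial_contingency_oracle(self):
        a, b, c, d = 30, 20, 12, 38
        y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
        x = np.concatenate([np.zeros(a + b), np.ones(c + d)])
        df = pd.DataFrame({"y": y, "x": x})
        fit = fit_mixed(ModelSpec("m", "y", ("x",), "binomial", ()), df)
        assert fit.coef("x") == pytest.approx(np.log((c * b) / (d * a)), abs=1e-6)

    def test_binary_response_declared_gaussian_rejected(self):
        df = pd.DataFrame({"y": [0.0, 1.0] * 20, "x": np.arange(40.0)})
        with pytest.raises(ValueError, match="binary"):
            fit_mixed(ModelSpec("m", "y", ("x",), "gaussian", ()), df)


class TestFallbackLadder:
    def test_structure_sequence_is_deterministic(self):
        spec = ModelSpec(
            "m", "y", ("a", "b"), "gaussian",
            (RandomEffects("item", slopes=("a", "b")), RandomEffects("p", slopes=("a",))),
        )
        labels = [lab for lab, _ in _ladder_structures(spec)]
        assert labels == [
            "maximal",
            "drop slope p:a",
            "drop slope item:b",
            "drop slope item:a",
        ]
        # last structure is intercepts-only for both factors
        last = _ladder_structures(spec)[-1][1]
        assert all(r.slopes == () for r in last.random)

    def test_well_conditioned_data_never_invokes_ladder(self):
        df = _mixed_data(sd_g=0.8, seed=3)
        spec = ModelSpec("m", "y", ("x",), "gaussian",
                         (RandomEffects("g", slopes=("x",)),))
        fit = fallback_ladder(spec, df)
        assert fit.ladder_steps == ["maximal"]
        assert fit.structure_used == "g(1+x)"

    def test_degenerate_data_hard_error(self):
        df = _mixed_data(seed=4)
        df["y"] = 3.0  # all-identical responses: no model can be estimated
        spec = ModelSpec("m", "y", ("x",), "gaussian", (RandomEffects("g"),))
        with pytest.raises(NumericalError):
            fallback_ladder(spec, df)


class TestBootstrap:
    def test_two_replicates_give_min_max_interval(self):
        df = _mixed_data(seed=5)
        fit = fit_mixed(ModelSpec("m", "y", ("x",), "gaussian", ()), df)
        bootstrap_ci(fit, n_reps=2, seed=1)
        assert (fit.ci_lower <= fit.ci_upper).all()
        # re-derive the two replicate estimates: interval is their min/max
        fit2 = fit_mixed(ModelSpec("m", "y", ("x",), "gaussian", ()), df)
        bootstrap_ci(fit2, n_reps=2, seed=1)
        np.testing.assert_array_equal(fit.ci_lower, fit2.ci_lower)

    def test_normal_theory_oracle_fixed_effects_only(self):
        """Gaussian fixed-effects model: percentile bootstrap matches
        beta +- 1.96 SE within Monte-Carlo tolerance."""
        df = _mixed_data(n_g=1, n_per=400, sd_g=0.0, seed=6)
        fit = fit_mixed(ModelSpec("m", "y", ("x",), "gaussian", ()), df)
        bootstrap_ci(fit, n_reps=600, seed=2)
        for i in range(2):
            width_norm = 2 * 1.96 * fit.se[i]
            width_boot = fit.ci_upper[i] - fit.ci_lower[i]
            assert width_boot == pytest.approx(width_norm, rel=0.15)
            assert fit.ci_lower[i] < fit.beta[i] < fit.ci_upper[i]

    def test_seed_determinism(self):
        df = _mixed_data(seed=7, sd_g=0.5)
        spec = ModelSpec("m", "y", ("x",), "gaussian", (RandomEffects("g"),))
        cis = []
        for _ in range(2):
            fit = fit_mixed(spec, df)
            bootstrap_ci(fit, n_reps=20, seed=9)
            cis.append((fit.ci_lower.copy(), fit.ci_upper.copy()))
        np.testing.assert_array_equal(cis[0][0], cis[1][0])
        np.testing.assert_array_equal(cis[0][1], cis[1][1])

    def test_ci_contains_point_estimate_mixed(self, default_study):
        sub = default_study.signals
        spec = ModelSpec("m", "insight", ("time_seen",), "gaussian",
                         (RandomEffects("item"),))
        fit = fit_mixed(spec, sub)
        bootstrap_ci(fit, n_reps=40, seed=3)
        assert (fit.ci_lower <= fit.beta).all() and (fit.beta <= fit.ci_upper).all()


class TestSuite:
    def test_thirteen_models_converge(self, default_suite):
        assert len(default_suite.fits) == 13
        assert all(f.converged for f in default_suite.fits)
        assert [f.analysis_id for f in default_suite.fits] == [
            s.analysis_id for s in suite_specs()
        ]

    def test_sign_pattern_reproduction(self, default_suite):
        """Qualitative coefficient signs at default generator settings."""
        s = default_suite
        assert s["game_logpc_turn"].coef("turn") < 0
        assert s["game_accuracy_turn"].coef("turn") > 0
        assert s["game_insight_turn"].coef("turn") < 0
        assert s["game_insight_time_turn"].coef("time") < 0
        assert s["new_insight_jd_icon_logpc"].coef("jd_mu_s") > 0
        assert s["new_accuracy_jd_icon_logpc"].coef("jd_mu_s") < 0
        assert s["old_icon_time"].coef("time") < 0
        assert s["old_familiarity_time_quad"].coef("time") > 0
        assert s["old_insight_time_icon_fam_logpc"].coef("time") < 0
        assert s["old_accuracy_time_icon_fam_logpc"].coef("familiarity_s") > 0
        assert s["old_accuracy_time_icon_fam_logpc"].coef("log_pc_s") < 0

    def test_families_match_responses(self, default_suite):
        for f in default_suite.fits:
            assert f.family == ("binomial" if f.spec.response == "accuracy" else "gaussian")

    def test_records_serialisable(self, default_suite):
        import json

        blob = json.dumps(default_suite.to_records())
        assert "game_logpc_turn" in blob
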