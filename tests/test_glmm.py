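"""Gamma log-link mixed model: oracles, invariances and inference."""

import math
import shutil
import subprocess
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rnai_memory as rm
from tests._oracles import mc_max_abs_tail


def _glm_tables(n=5, strains={"A": 1.5, "B": 3.0, "C": 5.5}):
    """Balanced half-life tables with variance components truly zero."""
    out = []
    for s in range(n):
        d = rm.SimulationDesign(
            strain_halflives=strains, sd_block=0.0, sd_rep=0.0, seed=900 + s
        )
        hl = rm.halflife_table(
            rm.group_replicates(rm.simulate_experiment(d)), rm.schedules_of(d)
        )
        out.append(hl[hl["status"] != "censored"].copy())
    return out


class TestGlmLimit:
    def test_pinned_variances_match_statsmodels_glm(self):
        """With both random terms removed the fit is a gamma log-link GLM;
        coefficients must match the IRLS oracle to 1e-6 relative."""
        import statsmodels.api as sm

        for data in _glm_tables(n=3):
            ours = rm.fit_glmm(data, rm.GlmmSpec(random=()))
            X = pd.get_dummies(data["strain"], drop_first=True, dtype=float)
            X.insert(0, "Intercept", 1.0)
            oracle = sm.GLM(
                data["value"].to_numpy(),
                X.to_numpy(),
                family=sm.families.Gamma(link=sm.families.links.Log()),
            ).fit(tol=1e-12)
            rel = np.abs(ours.beta - oracle.params) / np.abs(oracle.params)
            assert rel.max() < 1e-6
            ll = oracle.model.loglike(oracle.params, scale=1.0 / ours.dispersion)
            assert ours.loglik == pytest.approx(ll, abs=1e-6)

    def test_group_means_equal_sample_means(self):
        """Gamma log-link GLM property: fitted cell means are arithmetic
        sample means of each strain."""
        data = _glm_tables(n=1)[0]
        fit = rm.fit_glmm(data, rm.GlmmSpec(random=()))
        mm = rm.marginal_means(fit, "strain")
        for (level, _), est in zip(mm.labels, mm.estimates):
            sample = data.loc[data["strain"] == level, "value"].mean()
            assert math.exp(est) == pytest.approx(sample, rel=1e-6)

    def test_constant_response_degenerates(self):
        data = _glm_tables(n=1)[0].copy()
        data["value"] = 2.5
        fit = rm.fit_glmm(data, rm.GlmmSpec())
        assert fit.beta[0] == pytest.approx(math.log(2.5), abs=1e-6)
        assert np.allclose(fit.beta[1:], 0.0, atol=1e-6)
        assert fit.var_block < 1e-6 and fit.var_rep < 1e-6


class TestLaplaceFit:
    def test_deterministic_given_data(self, model_data):
        a = rm.fit_glmm(model_data, rm.GlmmSpec())
        b = rm.fit_glmm(model_data, rm.GlmmSpec())
        assert np.array_equal(a.beta, b.beta)
        assert a.loglik == b.loglik

    def test_adding_variance_components_never_hurts_loglik(self, model_data):
        pinned = rm.fit_glmm(model_data, rm.GlmmSpec(random=()))
        rep_only = rm.fit_glmm(model_data, rm.GlmmSpec(random=("block_replicate",)))
        full = rm.fit_glmm(model_data, rm.GlmmSpec())
        assert rep_only.loglik >= pinned.loglik - 1e-6
        assert full.loglik >= rep_only.loglik - 1e-6

    def test_scale_invariance_shifts_only_intercept(self, model_data):
        base = rm.fit_glmm(model_data, rm.GlmmSpec())
        scaled_data = model_data.copy()
        scaled_data["value"] = scaled_data["value"] * 7.0
        scaled = rm.fit_glmm(scaled_data, rm.GlmmSpec())
        assert scaled.beta[0] - base.beta[0] == pytest.approx(math.log(7.0), abs=1e-6)
        assert np.allclose(scaled.beta[1:], base.beta[1:], atol=1e-8)
        c0 = rm.tukey_contrasts(rm.marginal_means(base, "strain"))
        c1 = rm.tukey_contrasts(rm.marginal_means(scaled, "strain"))
        for a, b in zip(c0, c1):
            assert b.estimate == pytest.approx(a.estimate, abs=1e-8)

    def test_single_block_drops_block_intercept(self, model_data):
        sub = model_data[model_data["block"] == "A"]
        fit = rm.fit_glmm(sub, rm.GlmmSpec())
        assert fit.var_block is None
        assert any("single block" in n for n in fit.notes)

    def test_non_positive_response_rejected_under_gamma(self, model_data):
        bad = model_data.copy()
        bad.loc[bad.index[0], "value"] = 0.0
        with pytest.raises(rm.ParameterError, match="positive"):
            rm.fit_glmm(bad, rm.GlmmSpec())

    def test_nan_response_rejected(self, model_data):
        bad = model_data.copy()
        bad.loc[bad.index[0], "value"] = float("nan")
        with pytest.raises(rm.ValidationError, match="censored"):
            rm.fit_glmm(bad, rm.GlmmSpec())

    def test_aliased_design_rejected(self, model_data):
        data = model_data.copy()
        # a second factor perfectly aliased with strain
        data["environment"] = data["strain"].map(lambda s: f"env_{s}")
        with pytest.raises(rm.AliasingError):
            rm.fit_glmm(
                data, rm.GlmmSpec(factors=("strain", "environment"), interaction=False)
            )

    def test_gaussian_identity_family(self, model_data):
        fit = rm.fit_glmm(model_data, rm.GlmmSpec(family="gaussian_identity"))
        assert fit.converged
        # identity-scale means: intercept is the reference strain's mean
        mm = rm.marginal_means(fit, "strain")
        for (level, _), est in zip(mm.labels, mm.estimates):
            sample = model_data.loc[model_data["strain"] == level, "value"].mean()
            assert est == pytest.approx(sample, rel=0.15)

    def test_matches_glmmtmb_reference(self, model_data, tmp_path):
        """Independent cross-check against the R reference implementation
        (same Laplace approximation class)."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not on PATH; cross-check oracle unavailable")
        csv = tmp_path / "hl.csv"
        model_data.to_csv(csv, index=False)
        script = Path(__file__).parent / "glmmtmb_oracle.R"
        proc = subprocess.run(
            ["Rscript", str(script), str(csv)],
            capture_output=True, text=True, timeout=600,
        )
        assert proc.returncode == 0, proc.stderr[-2000:]
        fields = dict(
            line.split(maxsplit=1)
            for line in proc.stdout.strip().splitlines()
            if line.strip()
        )
        tmb_coef = np.array([float(x) for x in fields["coef"].split()])
        ours = rm.fit_glmm(model_data, rm.GlmmSpec())
        # contrasts agree tightly; the intercept absorbs the tiny difference
        # between profiled and fully optimized fixed effects
        assert np.allclose(ours.beta[1:], tmb_coef[1:], atol=1e-4)
        assert abs(ours.beta[0] - tmb_coef[0]) < 5e-3
        assert ours.loglik == pytest.approx(float(fields["loglik"]), abs=5e-3)
        assert ours.var_block == pytest.approx(float(fields["var_block"]), abs=1e-4)
        assert ours.var_rep == pytest.approx(float(fields["var_rep"]), abs=1e-4)
        assert ours.dispersion == pytest.approx(float(fields["shape"]), rel=0.02)


class TestTermTests:
    def test_single_coefficient_term_is_squared_z(self, model_data):
        sub = model_data[model_data["strain"].isin(["N2", "MY10"])]
        fit = rm.fit_glmm(sub, rm.GlmmSpec())
        t = rm.wald_test_term(fit, "strain")
        idx = fit.coef_names.index("strain[N2]")
        z = fit.beta[idx] / math.sqrt(fit.vcov_beta[idx, idx])
        assert t.df == 1
        assert t.stat == pytest.approx(z**2, rel=1e-10)

    def test_large_separation_is_decisive(self, fitted_model):
        t = rm.wald_test_term(fitted_model, "strain")
        assert t.df == 3
        assert t.p < 1e-6

    def test_unknown_term_rejected(self, fitted_model):
        with pytest.raises(rm.ParameterError):
            rm.wald_test_term(fitted_model, "temperature")

    def test_likelihood_ratio_agrees_in_magnitude(self, model_data):
        spec = rm.GlmmSpec()
        wald = rm.wald_test_term(rm.fit_glmm(model_data, spec), "strain")
        lr = rm.lr_test_term(model_data, spec, "strain")
        assert lr.df == wald.df
        assert lr.p < 1e-6
        with pytest.raises(rm.ParameterError):
            rm.lr_test_term(
                model_data,
                rm.GlmmSpec(factors=("strain", "environment"), interaction=True),
                "strain",
            )


class TestMarginalMeansAndContrasts:
    def test_one_factor_means_are_intercept_plus_effects(self, fitted_model):
        mm = rm.marginal_means(fitted_model, "strain")
        coef = fitted_model.coef
        for (level, _), est in zip(mm.labels, mm.estimates):
            expected = coef["Intercept"] + coef.get(f"strain[{level}]", 0.0)
            assert est == pytest.approx(expected, abs=1e-12)

    def test_two_factor_no_interaction_means_are_main_effect_predictions(self):
        envs = (
            rm.EnvironmentScenario(name="ctrl"),
            rm.EnvironmentScenario(name="hot", temperature="25C", halflife_multiplier=1.4),
        )
        d = rm.SimulationDesign(
            strain_halflives={"N2": 2.5, "JU1395": 1.5}, environments=envs, seed=77
        )
        hl = rm.halflife_table(
            rm.group_replicates(rm.simulate_experiment(d)), rm.schedules_of(d)
        )
        data = hl[hl["status"] != "censored"]
        fit = rm.fit_glmm(
            data, rm.GlmmSpec(factors=("strain", "environment"), interaction=False)
        )
        mm = rm.marginal_means(fit, "strain")
        coef = fit.coef
        env_avg = 0.5 * coef.get("environment[hot]", 0.0)
        for (level, _), est in zip(mm.labels, mm.estimates):
            expected = coef["Intercept"] + coef.get(f"strain[{level}]", 0.0) + env_avg
            assert est == pytest.approx(expected, abs=1e-12)

    def test_back_transformed_mean_tracks_strain_geometry(self, default_design, fitted_model):
        mm = rm.marginal_means(fitted_model, "strain")
        for (level, _), est in zip(mm.labels, mm.estimates):
            assert math.exp(est) == pytest.approx(
                default_design.strain_halflives[level], rel=0.25
            )

    def test_empty_interaction_cell_not_estimable(self):
        # a missing design cell cannot arise through fit_glmm (treatment
        # coding makes it an aliasing error first), so exercise the guard on
        # a fit whose observed-cell record lacks one cell
        envs = (
            rm.EnvironmentScenario(name="ctrl"),
            rm.EnvironmentScenario(name="hot", temperature="25C"),
        )
        d = rm.SimulationDesign(
            strain_halflives={"N2": 2.5, "JU1395": 1.5}, environments=envs, seed=79
        )
        hl = rm.halflife_table(
            rm.group_replicates(rm.simulate_experiment(d)), rm.schedules_of(d)
        )
        fit = rm.fit_glmm(
            hl[hl["status"] != "censored"],
            rm.GlmmSpec(factors=("strain", "environment"), interaction=True),
        )
        fit._observed_cells.discard(("N2", "hot"))
        with pytest.raises(rm.EstimabilityError, match="N2"):
            rm.marginal_means(fit, "strain")

    def test_contrast_antisymmetry_and_adjustment_monotonicity(self, fitted_model):
        mm = rm.marginal_means(fitted_model, "strain")
        results = rm.tukey_contrasts(mm)
        assert len(results) == 6
        by_pair = {(r.level_a, r.level_b): r for r in results}
        est = dict(zip([l for l, _ in mm.labels], mm.estimates))
        for (a, b), r in by_pair.items():
            assert r.estimate == pytest.approx(est[a] - est[b], abs=1e-12)
            assert r.p_adj >= r.p_raw
            assert 0.0 <= r.p_raw <= r.p_adj <= 1.0

    def test_two_level_family_unadjusted(self, model_data):
        sub = model_data[model_data["strain"].isin(["N2", "MY10"])]
        fit = rm.fit_glmm(sub, rm.GlmmSpec())
        (only,) = rm.tukey_contrasts(rm.marginal_means(fit, "strain"))
        assert only.p_adj == only.p_raw

    def test_conditioned_contrasts_stratify_by_strain(self):
        envs = (
            rm.EnvironmentScenario(name="ctrl"),
            rm.EnvironmentScenario(name="hot", temperature="25C", halflife_multiplier=1.4),
        )
        d = rm.SimulationDesign(
            strain_halflives={"N2": 2.5, "JU1395": 1.5}, environments=envs, seed=78
        )
        hl = rm.halflife_table(
            rm.group_replicates(rm.simulate_experiment(d)), rm.schedules_of(d)
        )
        data = hl[hl["status"] != "censored"]
        fit = rm.fit_glmm(
            data, rm.GlmmSpec(factors=("strain", "environment"), interaction=True)
        )
        results = rm.tukey_contrasts(rm.marginal_means(fit, "environment", by="strain"))
        assert sorted(r.stratum for r in results) == ["JU1395", "N2"]
        for r in results:  # one pair per stratum: no multiplicity penalty
            assert r.p_adj == r.p_raw

    def test_qmc_tail_probability_matches_monte_carlo(self):
        rho = 0.35
        corr = np.full((4, 4), rho) + (1 - rho) * np.eye(4)
        for t in (1.0, 2.0, 2.8):
            ours = rm.max_abs_tail_prob(t, corr)
            mc = mc_max_abs_tail(t, corr, n_draws=400_000, seed=99)
            assert ours == pytest.approx(mc, abs=4e-3)


class TestResidualDiagnostics:
    def test_residuals_bounded_and_refuse_tiny_nsim(self, fitted_model):
        diag = rm.simulate_residual_check(fitted_model, n_sim=100, seed=1)
        assert np.all((diag.residuals >= 0) & (diag.residuals <= 1))
        assert 0.5 < diag.dispersion_ratio < 2.0
        with pytest.raises(rm.ParameterError):
            rm.simulate_residual_check(fitted_model, n_sim=19, seed=1)

    def test_detects_heavy_tailed_misfit_under_gaussian(self):
        """A gaussian fit to strongly right-skewed data should be flagged by
        the uniformity test in the majority of trials."""
        flagged = 0
        for trial in range(15):
            rng = np.random.default_rng(600 + trial)
            n = 60
            data = pd.DataFrame(
                {
                    "value": np.exp(rng.normal(0.0, 1.0, size=n)),
                    "strain": np.tile(["A", "B"], n // 2),
                    "block": np.repeat(["X", "Y", "Z"], n // 3),
                    "replicate": np.tile([1, 2], n // 2),
                }
            )
            fit = rm.fit_glmm(data, rm.GlmmSpec(family="gaussian_identity"))
            flagged += rm.simulate_residual_check(fit, n_sim=150, seed=trial).ks_p < 0.05
        assert flagged > 7

    def test_simulated_response_reproducible(self, fitted_model):
        a = rm.simulate_response(fitted_model, np.random.default_rng(12))
        b = rm.simulate_response(fitted_model, np.random.default_rng(12))
        assert np.array_equal(a, b)
        assert np.all(a > 0)


class TestSingletonFilter:
    def test_drops_strains_seen_in_one_block(self, model_data):
        data = model_data.copy()
        extra = data[data["strain"] == "N2"].iloc[:3].copy()
        extra["strain"] = "QX1211"
        extra["block"] = "A"
        data = pd.concat([data, extra], ignore_index=True)
        kept, dropped = rm.filter_singleton_strains(data)
        assert dropped == ["QX1211"]
        assert set(kept["strain"]) == {"JU1171", "JU1395", "MY10", "N2"}
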