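"""Marginal maximum likelihood estimation and the Wald test."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import norm

import raschpower as rp
from raschpower.model import FitError


def brute_force_loglik(data, mu1, d, sigma2, delta, grid_points=20_001, span=8.0):
    """Dense-trapezoid integration of the marginal likelihood (oracle)."""
    theta = np.linspace(-span, span, grid_points)
    sigma = np.sqrt(sigma2)
    total = 0.0
    for i in range(data.n_patients):
        mu = mu1 + d * data.groups[i]
        p = expit(theta[:, None] - np.asarray(delta)[None, :])
        lik = np.prod(np.where(data.responses[i] == 1, p, 1 - p), axis=1)
        total += np.log(np.trapezoid(lik * norm.pdf(theta, mu, sigma), theta))
    return total


class TestMarginalLoglikelihood:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_quadrature_matches_brute_force(self, seed):
        gen = np.random.default_rng(seed)
        data = rp.ResponseData(gen.integers(0, 2, size=(4, 2)), np.array([0, 0, 1, 1]))
        delta = gen.normal(size=2)
        params = rp.RaschParams(
            d=gen.normal(scale=0.5), sigma2=float(gen.uniform(0.5, 1.5)),
            mu1=gen.normal(scale=0.3), difficulties=delta,
        )
        spec = rp.FitSpecification(situation=3, quadrature_nodes=61)
        ll = rp.marginal_loglikelihood(params, data, spec)
        assert ll == pytest.approx(
            brute_force_loglik(data, params.mu1, params.d, params.sigma2, delta), abs=1e-6
        )

    def test_pattern_probabilities_sum_to_one(self):
        # single patient, all 2^J patterns: marginal probabilities integrate to 1
        delta = np.array([-0.5, 0.2, 0.9])
        spec = rp.FitSpecification(situation=3)
        total = 0.0
        for code in range(8):
            pattern = [(code >> j) & 1 for j in range(3)]
            data = rp.ResponseData(np.array([pattern]), np.array([0]))
            params = rp.RaschParams(d=0.3, sigma2=1.2, mu1=-0.1, difficulties=delta)
            total += np.exp(rp.marginal_loglikelihood(params, data, spec))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_label_symmetry_at_null(self, small_dataset):
        data, bank = small_dataset
        spec = rp.FitSpecification(situation=2, fixed_difficulties=bank.difficulties)
        params = rp.RaschParams(d=0.0, sigma2=1.0, mu1=0.1)
        flipped = rp.ResponseData(data.responses, 1 - data.groups)
        assert rp.marginal_loglikelihood(params, data, spec) == pytest.approx(
            rp.marginal_loglikelihood(params, flipped, spec), abs=1e-12
        )

    def test_all_zero_responses_favour_lower_mu1(self):
        data = rp.ResponseData(np.zeros((8, 3), dtype=int), np.repeat([0, 1], 4))
        spec = rp.FitSpecification(situation=2, fixed_difficulties=np.zeros(3))
        lls = [
            rp.marginal_loglikelihood(rp.RaschParams(d=0.0, sigma2=1.0, mu1=m), data, spec)
            for m in (0.0, -0.5, -1.0, -2.0)
        ]
        assert np.all(np.diff(lls) > 0)

    def test_nonpositive_variance_rejected(self, small_dataset):
        data, bank = small_dataset
        spec = rp.FitSpecification(situation=2, fixed_difficulties=bank.difficulties)
        with pytest.raises(ValueError):
            rp.marginal_loglikelihood(rp.RaschParams(d=0.0, sigma2=0.0), data, spec)

    def test_location_shift_invariance(self, small_dataset):
        # adding c to every difficulty and to mu1 leaves the likelihood
        # unchanged: the constraint sum(delta) = 0 is needed in Situation 3
        data, bank = small_dataset
        spec = rp.FitSpecification(situation=3)
        base = rp.RaschParams(d=0.3, sigma2=0.9, mu1=-0.2, difficulties=bank.difficulties)
        shifted = rp.RaschParams(
            d=0.3, sigma2=0.9, mu1=-0.2 + 0.7, difficulties=bank.difficulties + 0.7
        )
        assert rp.marginal_loglikelihood(base, data, spec) == pytest.approx(
            rp.marginal_loglikelihood(shifted, data, spec), abs=1e-10
        )

    def test_quadrature_stability(self, rng):
        bank = rp.make_item_difficulties(20)
        spec = rp.latent_spec_from_effect_size(0.5)
        traits, groups = rp.simulate_latent_traits(spec, 100, rng)
        data = rp.simulate_responses(traits, groups, bank, rng)
        params = rp.RaschParams(d=0.5, sigma2=1.0, mu1=-0.25)
        lls = [
            rp.marginal_loglikelihood(
                params, data,
                rp.FitSpecification(situation=2, fixed_difficulties=bank.difficulties,
                                    quadrature_nodes=q),
            )
            for q in (41, 81)
        ]
        assert abs(lls[0] - lls[1]) < 1e-4


class TestFitSpecification:
    def test_situation_consistency_enforced(self):
        with pytest.raises(ValueError):
            rp.FitSpecification(situation=1, fixed_mu1=0.0)  # missing difficulties
        with pytest.raises(ValueError):
            rp.FitSpecification(situation=2, fixed_mu1=0.0, fixed_difficulties=np.zeros(3))
        with pytest.raises(ValueError):
            rp.FitSpecification(situation=3, fixed_difficulties=np.zeros(3))


class TestFit:
    def test_fit_is_deterministic(self, small_dataset):
        data, bank = small_dataset
        spec = rp.FitSpecification(situation=2, fixed_difficulties=bank.difficulties)
        a = rp.fit_rasch_mml(data, spec)
        b = rp.fit_rasch_mml(data, spec)
        np.testing.assert_array_equal(a.params, b.params)
        assert a.llf == b.llf and a.se_d == b.se_d

    def test_loglik_is_a_local_maximum(self, small_dataset):
        data, bank = small_dataset
        spec = rp.FitSpecification(situation=2, fixed_difficulties=bank.difficulties)
        model = rp.RaschModel(data, spec=spec)
        fit = model.fit()
        for k in range(model.k_params):
            for sign in (-1, 1):
                x = fit.params.copy()
                x[k] += sign * 1e-3
                assert model.loglike(x) <= fit.llf + 1e-9

    def test_situation1_null_recovery(self):
        # d = 0 data, mu1 and delta fixed at truth: mean d-hat near 0
        bank = rp.make_item_difficulties(5)
        spec = rp.FitSpecification(
            situation=1, fixed_mu1=0.0, fixed_difficulties=bank.difficulties
        )
        d_hats = []
        for rep in range(200):
            gen = np.random.default_rng([101, rep])
            traits, groups = rp.simulate_latent_traits(
                rp.latent_spec_from_effect_size(0.0), 100, gen
            )
            data = rp.simulate_responses(traits, groups, bank, gen)
            d_hats.append(rp.fit_rasch_mml(data, spec).d_hat)
        d_hats = np.asarray(d_hats)
        assert abs(d_hats.mean()) < 3 * d_hats.std(ddof=1) / np.sqrt(len(d_hats))

    def test_constant_item_excluded_in_situation3(self, rng):
        traits, groups = rp.simulate_latent_traits(rp.latent_spec_from_effect_size(0.5), 40, rng)
        bank = rp.make_item_difficulties(4)
        data = rp.simulate_responses(traits, groups, bank, rng)
        resp = np.column_stack([data.responses, np.ones(80, dtype=int)])
        fit = rp.RaschModel(rp.ResponseData(resp, groups)).fit()
        assert fit.excluded_items == (4,)
        assert fit.converged
        assert fit.difficulties_hat.size == 4

    def test_two_patients_per_group_required(self):
        data = rp.ResponseData(np.array([[0, 1], [1, 0], [1, 1]]), np.array([0, 0, 1]))
        with pytest.raises(ValueError):
            rp.RaschModel(data, spec=rp.FitSpecification(situation=3))

    def test_record_serialization(self, small_dataset):
        data, bank = small_dataset
        fit = rp.fit_rasch_mml(
            data, rp.FitSpecification(situation=2, fixed_difficulties=bank.difficulties)
        )
        rec = fit.to_record()
        for key in ("d_hat", "se_d", "sigma2_hat", "loglik", "converged"):
            assert key in rec
        row = pd.DataFrame([rec])
        assert row.loc[0, "d_hat"] == fit.d_hat

    def test_summary_reports_estimates(self, small_dataset):
        data, bank = small_dataset
        fit = rp.fit_rasch_mml(
            data, rp.FitSpecification(situation=2, fixed_difficulties=bank.difficulties)
        )
        text = fit.summary()
        assert "d (group)" in text and "sigma2" in text and "Converged" in text

    def test_agrees_with_independent_glmm_fit(self, tmp_path):
        # oracle: the same marginal likelihood maximised by lme4::glmer
        # (adaptive quadrature, person random intercept, items as fixed
        # effects); d, sigma and SE(d) must agree
        gen = np.random.default_rng(42)
        bank = rp.make_item_difficulties(5)
        traits, groups = rp.simulate_latent_traits(rp.latent_spec_from_effect_size(0.5), 150, gen)
        data = rp.simulate_responses(traits, groups, bank, gen)
        fit = rp.RaschModel(data).fit()

        n, J = data.responses.shape
        long = pd.DataFrame({
            "id": np.repeat(np.arange(n), J),
            "item": np.tile(np.arange(J), n),
            "group": np.repeat(data.groups, J),
            "resp": data.responses.ravel(),
        })
        csv = tmp_path / "long.csv"
        long.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv('{csv}')
            d$item <- factor(d$item)
            m <- glmer(resp ~ 0 + item + group + (1|id), data=d,
                       family=binomial, nAGQ=25)
            cat(sprintf('%.8f %.8f %.8f', fixef(m)['group'],
                sqrt(unlist(VarCorr(m))[1]),
                sqrt(vcov(m)['group','group'])))
        """))
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        d_r, sigma_r, se_r = map(float, out.stdout.split())
        assert fit.d_hat == pytest.approx(d_r, abs=2e-3)
        assert np.sqrt(fit.sigma2_hat) == pytest.approx(sigma_r, abs=2e-3)
        assert fit.se_d == pytest.approx(se_r, abs=2e-3)


class TestWaldTest:
    def _fit_with(self, d_hat, se_d):
        class Dummy:
            converged = True
        fit = rp.RaschResults.__new__(rp.RaschResults)
        fit.converged = True
        fit.d_hat = d_hat
        fit.se_d = se_d
        return fit

    def test_null_estimate_gives_p_one(self):
        res = rp.wald_test_group_effect(self._fit_with(0.0, 0.2), alpha=0.05)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_boundary_statistic_not_significant(self):
        # statistic exactly at the critical value: p = alpha, and the strict
        # inequality keeps the test non-significant
        from scipy.stats import norm
        res = rp.wald_test_group_effect(self._fit_with(norm.ppf(0.975), 1.0), alpha=0.05)
        assert res.p_value == pytest.approx(0.05, abs=1e-12)
        assert not res.significant

    def test_large_statistic_significant(self):
        res = rp.wald_test_group_effect(self._fit_with(0.5, 0.1), alpha=0.05)
        assert res.statistic == pytest.approx(5.0)
        assert res.p_value == pytest.approx(5.7e-7, rel=0.01)
        assert res.significant

    def test_nonconverged_fit_rejected(self):
        fit = self._fit_with(0.5, 0.1)
        fit.converged = False
        with pytest.raises(FitError):
            rp.wald_test_group_effect(fit, alpha=0.05)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            rp.wald_test_group_effect(self._fit_with(0.5, 0.1), alpha=1.5)
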