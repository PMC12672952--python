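"""Mixture likelihood, prior stack, EPSR diagnostics, and MCMC contracts."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from vascareless.careless import CarelessBeta
from vascareless.estimation import (
    ItemsMeta,
    McmcSpec,
    MixtureParams,
    PriorConfig,
    attentive_loglik_matrix,
    epsr,
    fit_beta_irm,
    fit_mixture,
    log_prior,
    mixture_log_likelihood,
    posterior_class_probability,
)


def toy_params(n=3, j=2, person_prob=None, m=2.0, ncare=5.0):
    rng = np.random.default_rng(0)
    return MixtureParams(
        difficulty=rng.normal(size=j),
        dispersion=rng.uniform(0, 2, size=j),
        theta=rng.normal(size=(n, 1)),
        trait_sd=np.array([1.0]),
        trait_corr=np.eye(1),
        careless=CarelessBeta(m=m, n=ncare),
        attentive_prop=0.8,
        concentration=2.0,
        person_prob=(np.full(n, 0.7) if person_prob is None
                     else np.asarray(person_prob, dtype=float)),
    )


def toy_meta(j=2):
    return ItemsMeta(wording=np.array([-1, 1][:j] if j <= 2 else [1] * j))


class TestMixtureLogLikelihood:
    def setup_method(self):
        rng = np.random.default_rng(1)
        self.y = rng.uniform(0.05, 0.95, size=(3, 2))
        self.meta = toy_meta()

    def test_degenerate_attentive(self):
        params = toy_params(person_prob=np.ones(3) - 1e-12)
        pure = attentive_loglik_matrix(
            self.y, params.difficulty, params.dispersion, params.theta, self.meta).sum()
        assert mixture_log_likelihood(self.y, params, self.meta) == pytest.approx(pure, abs=1e-6)

    def test_degenerate_careless(self):
        params = toy_params(person_prob=np.full(3, 1e-300))
        pure = stats.beta.logpdf(self.y, 2.0, 5.0).sum()
        assert mixture_log_likelihood(self.y, params, self.meta) == pytest.approx(pure, abs=1e-6)

    def test_matches_brute_force_cellwise_sum(self):
        # independent oracle: loop over cells with scipy densities
        params = toy_params(person_prob=[0.9, 0.5, 0.2])
        total = 0.0
        for i in range(3):
            for j in range(2):
                s = self.meta.wording[j]
                eta = s * params.theta[i, 0] - params.difficulty[j]
                a = np.exp(0.5 * (eta + params.dispersion[j]))
                b = np.exp(-0.5 * (eta - params.dispersion[j]))
                f_att = stats.beta.pdf(self.y[i, j], a, b)
                f_care = stats.beta.pdf(self.y[i, j], 2.0, 5.0)
                p = params.person_prob[i]
                total += np.log(p * f_att + (1 - p) * f_care)
        assert mixture_log_likelihood(self.y, params, self.meta) == pytest.approx(total, rel=1e-10)

    def test_boundary_response_rejected(self):
        y = self.y.copy()
        y[0, 0] = 1.0
        with pytest.raises(ValueError):
            mixture_log_likelihood(y, toy_params(), self.meta)


class TestLogPrior:
    def test_flat_population_proportion(self):
        # with pi_i held at 1/2 the hierarchical term is symmetric under
        # pi <-> 1-pi, so any remaining difference would come from the pi
        # prior itself; Dirichlet(1,1) is flat, hence equality
        cfg = PriorConfig()
        p1 = toy_params(person_prob=[0.5, 0.5, 0.5])
        p2 = toy_params(person_prob=[0.5, 0.5, 0.5])
        p1.attentive_prop, p2.attentive_prop = 0.3, 0.7
        assert log_prior(p1, cfg) == pytest.approx(log_prior(p2, cfg), rel=1e-12)

    def test_hierarchical_term_is_reduced_beta(self):
        cfg = PriorConfig()
        base = toy_params(person_prob=[0.5, 0.5, 0.5])
        moved = toy_params(person_prob=[0.65, 0.5, 0.5])
        a = base.concentration * base.attentive_prop
        b = base.concentration * (1 - base.attentive_prop)
        expected_delta = stats.beta.logpdf(0.65, a, b) - stats.beta.logpdf(0.5, a, b)
        assert log_prior(moved, cfg) - log_prior(base, cfg) == pytest.approx(
            expected_delta, rel=1e-9)

    @pytest.mark.parametrize("mutate", [
        lambda p: setattr(p, "trait_sd", np.array([-1.0])),
        lambda p: setattr(p, "careless", CarelessBeta.__new__(CarelessBeta)) or
                  object.__setattr__(p.careless, "m", -2.0) or
                  object.__setattr__(p.careless, "n", 1.0),
        lambda p: setattr(p, "attentive_prop", 1.5),
        lambda p: setattr(p, "concentration", 0.0),
        lambda p: setattr(p, "person_prob", np.array([0.5, 1.2, 0.5])),
    ])
    def test_out_of_support_gives_minus_inf(self, mutate):
        params = toy_params()
        mutate(params)
        assert log_prior(params, PriorConfig()) == -np.inf

    def test_finite_on_random_in_support_draws(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = toy_params()
            p.attentive_prop = rng.uniform(0.05, 0.95)
            p.concentration = rng.uniform(0.1, 20)
            p.person_prob = rng.uniform(0.05, 0.95, size=3)
            p.trait_sd = np.array([rng.uniform(0.1, 5)])
            assert np.isfinite(log_prior(p, PriorConfig()))


class TestEpsr:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((2, 5000))
        assert epsr(chains) < 1.05

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(0)
        chains = np.stack([rng.normal(0, 1, 2000), rng.normal(10, 1, 2000)])
        assert epsr(chains) > 3.0

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((3, 500))
        shuffled = chains.copy()
        for row in shuffled:
            rng.shuffle(row)
        assert epsr(chains) == pytest.approx(epsr(shuffled), rel=1e-12)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            epsr(np.random.default_rng(0).standard_normal((1, 100)))

    def test_matches_arviz_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        chains = rng.standard_normal((2, 400)) + np.array([[0.0], [0.3]])
        ours = epsr(chains, split=True)
        theirs = float(np.asarray(az.rhat(az.convert_to_dataset(chains))["x"]).ravel()[0])
        assert ours == pytest.approx(theirs, abs=0.01)

    def test_vectorized_over_parameters(self):
        rng = np.random.default_rng(3)
        chains = rng.standard_normal((2, 300, 4))
        vals = epsr(chains)
        assert vals.shape == (4,)
        for k in range(4):
            assert vals[k] == pytest.approx(epsr(chains[:, :, k]), rel=1e-12)


class TestPosteriorClassProbability:
    def test_symmetric_case(self):
        # one item, identical component densities -> posterior equals prior 1/2
        params = toy_params(n=1, j=1, person_prob=[0.5], m=1.0, ncare=1.0)
        params.difficulty = np.array([0.0])
        params.dispersion = np.array([0.0])
        params.theta = np.zeros((1, 1))
        meta = ItemsMeta(wording=np.array([1]))
        assert posterior_class_probability([0.4], params, meta) == pytest.approx(0.5, rel=1e-9)

    def test_certain_attentive(self):
        params = toy_params(person_prob=[1.0, 0.5, 0.5])
        meta = toy_meta()
        assert posterior_class_probability([0.3, 0.6], params, meta, person_index=0) == 1.0

    def test_matches_hand_bayes_rule(self):
        params = toy_params(n=1, j=1, person_prob=[0.7], m=2.0, ncare=5.0)
        params.difficulty = np.array([0.5])
        params.dispersion = np.array([1.0])
        params.theta = np.array([[0.3]])
        meta = ItemsMeta(wording=np.array([1]))
        y = 0.42
        eta = 0.3 - 0.5
        a = np.exp(0.5 * (eta + 1.0))
        b = np.exp(-0.5 * (eta - 1.0))
        f1 = stats.beta.pdf(y, a, b)
        f2 = stats.beta.pdf(y, 2, 5)
        hand = 0.7 * f1 / (0.7 * f1 + 0.3 * f2)
        assert posterior_class_probability([y], params, meta) == pytest.approx(hand, rel=1e-10)


class TestFitting:
    def test_seeded_determinism(self, small_dataset, small_meta, short_spec):
        spec = McmcSpec(chains=2, iterations=200, seed=4, thin=1)
        f1 = fit_mixture(small_dataset.responses, small_meta, spec=spec)
        f2 = fit_mixture(small_dataset.responses, small_meta, spec=spec)
        for key in f1.draws:
            np.testing.assert_array_equal(f1.draws[key], f2.draws[key])

    def test_mixture_recovers_contamination_level(self, small_dataset, small_meta, short_spec):
        fit = fit_mixture(small_dataset.responses, small_meta, spec=short_spec)
        assert 1 - float(fit.point["attentive_prop"]) == pytest.approx(
            small_dataset.condition.prop_careless, abs=0.12)

    def test_beta_irm_has_no_mixture_parameters(self, small_dataset, small_meta):
        spec = McmcSpec(chains=2, iterations=300, seed=4, thin=1)
        fit = fit_beta_irm(small_dataset.responses, small_meta, spec=spec)
        assert "person_prob" not in fit.draws
        assert {"difficulty", "dispersion", "theta", "trait_sd"} <= set(fit.draws)

    def test_posterior_summaries_shapes(self, small_dataset, small_meta):
        spec = McmcSpec(chains=2, iterations=300, seed=4, thin=3)
        fit = fit_mixture(small_dataset.responses, small_meta, spec=spec)
        kept = (300 - 150 + 2) // 3
        assert fit.draws["difficulty"].shape == (2, kept, 8)
        assert fit.point["person_prob"].shape == (120,)
        assert fit.ci95["careless_m"].shape == (2,)
        assert set(fit.epsr) and all(np.all(np.isfinite(v)) for v in fit.epsr.values())

    def test_unclamped_responses_rejected(self, small_meta, short_spec):
        y = np.full((4, 8), 0.5)
        y[0, 0] = 1.0
        with pytest.raises(ValueError):
            fit_mixture(y, small_meta, spec=short_spec)
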