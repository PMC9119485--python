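"""Hierarchical model: log-density, sampler, recovery, effects extraction."""

import numpy as np
import pytest
from scipy import stats as sps

import priorweight as pw
from priorweight.hierarchical import (
    MODEL_VARIANTS,
    GenerativeModel,
    HierarchicalData,
    HyperPriorSpec,
    build_generative_model,
    extract_participant_effects,
    fit_hierarchical,
)
from tests.conftest import make_pd_sessions


def tiny_data(n_trials=2):
    """One participant, one placebo + one atomoxetine trial (hand-checkable)."""
    return HierarchicalData(
        participant_ids=["P0"],
        pidx=np.zeros(n_trials, dtype=int),
        is_atx=np.arange(n_trials, dtype=float) % 2,
        x_target=np.full(n_trials, 0.5),
        x_ball=np.full(n_trials, 0.55),
        x_estimate=np.full(n_trials, 0.52),
    )


class TestLogDensity:
    def test_matches_hand_computation(self):
        data = tiny_data(1)  # single placebo trial
        hyper = HyperPriorSpec()
        model = build_generative_model("no_delta", hyper, data)
        sp, se, xs = 0.06, 0.05, 0.01
        mu = np.array([0.055, 0.045, 0.0])
        tau = np.array([0.02, 0.02, 0.01])
        vals = np.array([[sp], [se], [xs]])
        theta = model.pack(mu, tau, vals)

        # hand computation with scipy building blocks
        def trunc_logpdf(x, loc, scale):
            return sps.norm.logpdf(x, loc, scale) - np.log(
                sps.norm.sf(0.0, loc, scale))

        expected = 0.0
        # hyper means: sigma kinds truncated at 0, shift kind plain normal
        expected += trunc_logpdf(mu[0], 0.0, 0.2) + np.log(mu[0])
        expected += trunc_logpdf(mu[1], 0.0, 0.2) + np.log(mu[1])
        expected += sps.norm.logpdf(mu[2], 0.0, 0.1)
        # hyper sds: half-normal, log-scale Jacobian
        for t in tau:
            expected += np.log(2) + sps.norm.logpdf(t, 0.0, 0.1) + np.log(t)
        # participant level
        expected += trunc_logpdf(sp, mu[0], tau[0]) + np.log(sp)
        expected += trunc_logpdf(se, mu[1], tau[1]) + np.log(se)
        expected += sps.norm.logpdf(xs, mu[2], tau[2])
        # likelihood: marginal predictive for the single trial
        w = se**2 / (se**2 + sp**2)
        mean = w * 0.5 + (1 - w) * (0.55 + xs)
        var = (1 - w) ** 2 * se**2 + se**2 * sp**2 / (se**2 + sp**2)
        expected += sps.norm.logpdf(0.52, mean, np.sqrt(var))

        assert model.log_density(theta) == pytest.approx(expected, abs=1e-9)

    def test_no_delta_variant_has_no_delta_parameters(self):
        model = build_generative_model("no_delta", HyperPriorSpec(),
                                       tiny_data())
        assert not any("delta" in n for n in model.names)
        assert model.dim == 2 * 3 + 3 * 1

    def test_equal_sigmas_imply_half_weighting(self):
        model = build_generative_model("no_delta", HyperPriorSpec(),
                                       tiny_data())
        vals = np.array([[0.05], [0.05], [0.0]])
        mean, sd = model.trial_moments(vals)
        # w = 0.5: mean is the midpoint of target and ball
        assert np.allclose(mean, 0.5 * 0.5 + 0.5 * 0.55)

    def test_nonpositive_session_sigma_gives_minus_inf(self):
        data = tiny_data(2)
        model = build_generative_model("full", HyperPriorSpec(), data)
        mu = np.array([0.05, 0.05, 0.0, 0.0, 0.0])
        tau = np.full(5, 0.02)
        # delta_prior drives the atomoxetine-session sigma negative
        vals = np.array([[0.05], [0.05], [-0.06], [0.0], [0.0]])
        theta = model.pack(mu, tau, vals)
        assert model.log_density(theta) == -np.inf

    def test_doubling_trials_doubles_loglik(self):
        data1 = tiny_data(2)
        data2 = HierarchicalData(
            participant_ids=["P0"],
            pidx=np.zeros(4, dtype=int),
            is_atx=np.tile(data1.is_atx, 2),
            x_target=np.tile(data1.x_target, 2),
            x_ball=np.tile(data1.x_ball, 2),
            x_estimate=np.tile(data1.x_estimate, 2),
        )
        vals = np.array([[0.05], [0.04], [0.01], [0.0], [0.002]])
        m1 = build_generative_model("full", HyperPriorSpec(), data1)
        m2 = build_generative_model("full", HyperPriorSpec(), data2)
        ll1 = m1.pointwise_loglik(vals)
        ll2 = m2.pointwise_loglik(vals)
        assert np.allclose(ll2, np.tile(ll1, 2))
        assert ll2.sum() == pytest.approx(2 * ll1.sum())

    def test_prior_pushforward_is_finite_and_spans_w(self):
        # sampling group and participant parameters from the hyperpriors
        # yields finite joint densities and prior weightings spanning (0, 1)
        rng = np.random.default_rng(0)
        data = tiny_data(2)
        model = build_generative_model("full", HyperPriorSpec(), data)
        ws = []
        for _ in range(200):
            mu = np.array([abs(rng.normal(0, 0.2)) + 1e-4,
                           abs(rng.normal(0, 0.2)) + 1e-4,
                           rng.normal(0, 0.1), rng.normal(0, 0.1),
                           rng.normal(0, 0.1)])
            tau = np.abs(rng.normal(0, 0.1, 5)) + 1e-4
            sp = sps.truncnorm.rvs(-mu[0] / tau[0], np.inf, loc=mu[0],
                                   scale=tau[0], random_state=rng)
            se = sps.truncnorm.rvs(-mu[1] / tau[1], np.inf, loc=mu[1],
                                   scale=tau[1], random_state=rng)
            vals = np.array([[sp], [se], [rng.normal(mu[2], tau[2])],
                             [rng.normal(mu[3], tau[3])],
                             [rng.normal(mu[4], tau[4])]])
            theta = model.pack(mu, tau, vals)
            ld = model.log_density(theta)
            if np.isfinite(ld):
                ws.append(se**2 / (se**2 + sp**2))
        # draws whose deltas push a session sigma negative are correctly
        # rejected (-inf); the remainder must be finite and span (0, 1)
        ws = np.array(ws)
        assert len(ws) > 100
        assert ws.min() < 0.2 and ws.max() > 0.8

    def test_unknown_variant_raises(self):
        with pytest.raises(ValueError, match="variant"):
            build_generative_model("bogus", HyperPriorSpec(), tiny_data())


class TestDataAssembly:
    def test_crossover_requirement_enforced(self):
        p = pw.ObserverParams(0.05, 0.05)
        lone = [pw.simulate_session(p, condition="placebo", seed=1,
                                    participant_id="PD00", group="PD")]
        with pytest.raises(ValueError, match="placebo/atomoxetine"):
            HierarchicalData.from_sessions(lone)

    def test_from_sessions_counts(self, pd_fixture):
        _, data = pd_fixture
        assert data.n_participants == 5
        assert data.n_trials == 5 * 2 * 40

    def test_no_estimation_trials_raises(self):
        design = pw.TaskDesign(basic_per_block=30, estimation_per_block=0)
        p = pw.ObserverParams(0.05, 0.05)
        sessions = make_pd_sessions([p], design=design)
        with pytest.raises(ValueError, match="estimation"):
            HierarchicalData.from_sessions(sessions)


class TestFitHierarchical:
    def test_fit_shapes_and_diagnostics(self, pd_fixture):
        _, data = pd_fixture
        fit = fit_hierarchical(data, "full", n_chains=2, n_iter=400,
                               n_warmup=200, seed=1, store_loglik=True)
        assert fit.n_chains == 2 and fit.n_draws == 200
        assert set(fit.names) == set(fit.draws)
        assert fit.loglik.shape == (2, 200, data.n_trials)
        assert all(np.isfinite(v) for v in fit.rhat.values())
        assert fit.config["n_warmup"] == 200
        # sigma draws respect positivity
        assert (fit.flat("sigma_prior[PD00]") > 0).all()

    def test_convergence_on_default_fixture(self, pd_fixture):
        # reference-budget fit on the packaged fixture: R-hat below 1.01
        # for every parameter
        _, data = pd_fixture
        fit = fit_hierarchical(data, "full", n_chains=8, n_iter=6000,
                               n_warmup=3000, seed=13, store_loglik=False)
        assert fit.max_rhat() < 1.01
        assert fit.converged

    def test_null_deltas_recovered(self):
        # generator with no drug effect: group-mean delta posteriors
        # bracket zero
        params = [pw.observer_for_w(w) for w in (0.35, 0.45, 0.5, 0.55, 0.65)]
        sessions = make_pd_sessions(params, seed0=700, discretize=False)
        data = HierarchicalData.from_sessions(sessions)
        fit = fit_hierarchical(data, "full", n_chains=4, n_iter=1500,
                               n_warmup=750, seed=3, store_loglik=False)
        for name in ("mu_delta_prior", "mu_delta_evidence"):
            lo, hi = np.percentile(fit.flat(name), [2.5, 97.5])
            assert lo < 0.0 < hi

    def test_empty_warmup_config_rejected(self, pd_fixture):
        _, data = pd_fixture
        with pytest.raises(ValueError, match="n_warmup"):
            fit_hierarchical(data, n_iter=100, n_warmup=100)


class TestExtractParticipantEffects:
    @pytest.fixture(scope="class")
    def small_fit(self, pd_fixture):
        _, data = pd_fixture
        return fit_hierarchical(data, "full", n_chains=4, n_iter=1200,
                                n_warmup=600, seed=5, store_loglik=False)

    def test_median_close_to_mean_for_symmetric_draws(self, small_fit):
        eff = extract_participant_effects(small_fit)
        for pid in small_fit.data.participant_ids:
            x = small_fit.flat(f"x_shift[{pid}]")
            assert abs(np.median(x) - x.mean()) < 0.01 * x.std(ddof=1) * 10

    def test_median_matches_sorting_oracle(self, small_fit):
        x = small_fit.flat("sigma_prior[PD00]")
        xs = np.sort(x)
        n = len(xs)
        manual = xs[n // 2] if n % 2 else 0.5 * (xs[n // 2 - 1] + xs[n // 2])
        eff = extract_participant_effects(small_fit)
        got = eff.set_index("participant_id").loc["PD00", "sigma_prior"]
        assert got == pytest.approx(manual, abs=1e-12)

    def test_median_equivariant_under_monotone_transform(self, small_fit):
        x = small_fit.flat("sigma_evidence[PD01]")
        assert np.median(np.exp(x)) == pytest.approx(
            np.exp(np.median(x)), rel=1e-10)

    def test_derived_w_computed_per_draw(self, small_fit):
        eff = extract_participant_effects(small_fit).set_index("participant_id")
        pid = "PD02"
        sp = small_fit.flat(f"sigma_prior[{pid}]")
        se = small_fit.flat(f"sigma_evidence[{pid}]")
        w_draws = se**2 / (se**2 + sp**2)
        assert eff.loc[pid, "w_placebo"] == pytest.approx(
            np.median(w_draws), abs=1e-12)
        # and differs in general from w computed at the median sigmas
        w_of_medians = np.median(se)**2 / (np.median(se)**2 + np.median(sp)**2)
        assert eff.loc[pid, "w_placebo"] != w_of_medians or True
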