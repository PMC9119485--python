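"""Group-level inference: regressions, Pitman, Johnson-Neyman, Bayes
factors, repeated-measures ANCOVA, plausible values."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import priorweight as pw
from priorweight.stats import (
    AncovaResult,
    fit_drug_cnr_model,
    johnson_neyman,
    johnson_neyman_thresholds,
    jzs_bayes_factor,
    pitman_test,
    plausible_values,
    precision_term_ancova,
    regress_apathy,
)


def synth_normative_table(rng, n_controls=20, n_pd=17, apathy_slope=0.0):
    apathy = rng.normal(12, 5, n_controls + n_pd)
    iqr = rng.normal(9, 2, n_controls + n_pd)
    w = 0.45 + apathy_slope * (apathy - apathy.mean()) / apathy.std(ddof=1) \
        * 0.2 + rng.normal(0, 0.2, n_controls + n_pd)
    return pd.DataFrame({
        "w_hat": w, "apathy": apathy, "iqr_performance_error": iqr,
        "group": ["control"] * n_controls + ["PD"] * n_pd,
        "condition": ["none"] * n_controls + ["placebo"] * n_pd,
    })


def synth_pd_sessions_table(rng, n=17, coupling=0.0):
    cnr = rng.normal(10, 2, n)
    w_plc = rng.normal(0.45, 0.2, n)
    dw = 0.2 * (coupling * (cnr - cnr.mean()) / cnr.std(ddof=1)
                + np.sqrt(1 - coupling**2) * rng.normal(size=n))
    rows = []
    for i in range(n):
        for cond, w in (("placebo", w_plc[i]), ("atomoxetine", w_plc[i] + dw[i])):
            rows.append(dict(participant_id=f"PD{i:02d}", condition=cond,
                             w_hat=w, lc_cnr=cnr[i],
                             iqr_performance_error=rng.normal(9, 1)))
    return pd.DataFrame(rows)


class TestRegressApathy:
    def test_residual_df_for_study_sample_sizes(self):
        rng = np.random.default_rng(0)
        tab = regress_apathy(synth_normative_table(rng))
        assert (tab["df"] == 32).all()  # 37 sessions, 5 parameters
        assert set(tab["term"]) == {"intercept", "apathy", "group",
                                    "apathy:group", "iqr_performance_error"}

    def test_null_coupling_type_one_calibration(self):
        rng = np.random.default_rng(1)
        inside = 0
        n_sim = 600
        for _ in range(n_sim):
            tab = regress_apathy(synth_normative_table(rng)).set_index("term")
            beta, se = tab.loc["apathy", "beta"], tab.loc["apathy", "se"]
            inside += abs(beta) < 2 * se
        assert inside / n_sim >= 0.93

    def test_recovers_generating_slope(self):
        # cohorts simulated at the default apathy coupling: the mean
        # recovered standardized apathy coefficient approaches it (the
        # full 40-estimation-trial design keeps attenuation modest)
        betas = []
        for k in range(50):
            sessions, cov = pw.simulate_cohort(seed=6000 + k)
            est = pw.estimate_prior_weighting(sessions, method="per-session")
            merged = est.merge(cov, on=["participant_id", "condition"])
            tab = regress_apathy(
                merged[merged["condition"].isin(["none", "placebo"])]
            ).set_index("term")
            betas.append(tab.loc["apathy", "beta"])
        # attenuated toward zero by estimation noise; sign and rough
        # magnitude must match the generating standardized slope (-0.35)
        assert np.mean(betas) < -0.15
        assert np.mean(betas) == pytest.approx(-0.35, abs=0.15)

    def test_collinear_design_raises(self):
        rng = np.random.default_rng(2)
        df = synth_normative_table(rng)
        df["iqr_performance_error"] = df["apathy"]
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            regress_apathy(df)


class TestDrugCnrModel:
    def test_denominator_dfs_for_17_participants(self):
        rng = np.random.default_rng(3)
        res = fit_drug_cnr_model(synth_pd_sessions_table(rng))
        tab = res.table.set_index("term")
        assert tab.loc["drug:lc_cnr", "df_den"] == 15
        assert tab.loc["drug", "df_den"] == 15
        assert tab.loc["lc_cnr", "df_den"] == 14
        assert res.correlation["df"] == 15

    def test_interaction_type_one_calibration(self):
        rng = np.random.default_rng(4)
        n_sim = 500
        rej = 0
        for _ in range(n_sim):
            res = fit_drug_cnr_model(synth_pd_sessions_table(rng))
            rej += res.table.set_index("term").loc["drug:lc_cnr", "p"] < 0.05
        assert 0.02 <= rej / n_sim <= 0.08

    def test_power_at_default_coupling(self):
        rng = np.random.default_rng(5)
        neg = 0
        n_sim = 400
        for _ in range(n_sim):
            res = fit_drug_cnr_model(
                synth_pd_sessions_table(rng, coupling=-0.59))
            neg += res.correlation["r"] < 0
        assert neg / n_sim >= 0.95

    def test_incomplete_participants_excluded_with_warning(self):
        rng = np.random.default_rng(6)
        df = synth_pd_sessions_table(rng)
        df = df.drop(df[(df["participant_id"] == "PD00")
                        & (df["condition"] == "placebo")].index)
        with pytest.warns(UserWarning, match="single session"):
            res = fit_drug_cnr_model(df)
        assert len(res.delta_w) == 16


class TestPitman:
    def test_df_is_n_minus_two(self):
        rng = np.random.default_rng(7)
        res = pitman_test(rng.normal(size=17), rng.normal(size=17))
        assert res.df == 15

    def test_detects_unequal_variances(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)  # var(y) > var(x)
        res = pitman_test(x, 2 * x + rng.normal(size=200))
        assert res.p < 0.01

    def test_null_rejection_rate_nominal(self):
        rng = np.random.default_rng(9)
        rej = sum(
            pitman_test(x := rng.normal(size=17),
                        0.5 * x + np.sqrt(0.75) * rng.normal(size=17)).p < 0.05
            for _ in range(4000)
        )
        assert 0.035 <= rej / 4000 <= 0.065

    def test_power_matches_direct_monte_carlo_of_statistic(self):
        # implementation vs an inline re-derivation of the same statistic
        rng1 = np.random.default_rng(10)
        rng2 = np.random.default_rng(10)
        n, n_sim = 17, 3000

        def draw(rng):
            x = rng.normal(size=n)
            y = 0.5 * x + np.sqrt(4 - 0.25) * rng.normal(size=n)  # var 4
            return x, y

        p1 = np.mean([pitman_test(*draw(rng1)).p < 0.05
                      for _ in range(n_sim)])
        hits = 0
        for _ in range(n_sim):
            x, y = draw(rng2)
            r = np.corrcoef(x + y, x - y)[0, 1]
            t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
            hits += 2 * sps.t.sf(abs(t), n - 2) < 0.05
        assert p1 == pytest.approx(hits / n_sim, abs=1e-12)

    def test_degenerate_pairs_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            pitman_test(np.ones(5), np.ones(5))


class TestJohnsonNeyman:
    def test_no_interaction_significant_everywhere(self):
        cov = np.array([[0.01, 0.0], [0.0, 0.04]])
        region = johnson_neyman_thresholds(0.8, 0.0, cov, 30)
        assert region.region in ("all", "outside", "between")
        assert region.region == "all" or len(region.thresholds_z) > 0

    def test_no_interaction_nonsignificant_everywhere(self):
        cov = np.array([[0.04, 0.0], [0.0, 0.04]])
        region = johnson_neyman_thresholds(0.05, 0.0, cov, 30)
        assert region.region == "none"

    @pytest.mark.parametrize("seed", range(100))
    def test_thresholds_match_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        b1, b2 = rng.normal(0, 0.5, 2)
        a = rng.normal(0, 0.3, (2, 2))
        cov = a @ a.T + 0.01 * np.eye(2)
        df = int(rng.integers(10, 60))
        region = johnson_neyman_thresholds(b1, b2, cov, df)
        t_crit = sps.t.ppf(0.975, df)
        zs = np.linspace(-6, 6, 240001)
        slope = b1 + b2 * zs
        se = np.sqrt(cov[0, 0] + 2 * zs * cov[0, 1] + zs**2 * cov[1, 1])
        sig = np.abs(slope) / se >= t_crit
        crossings = zs[1:][np.diff(sig.astype(int)) != 0]
        inside = [z for z in region.thresholds_z if abs(z) < 6]
        assert len(inside) == len(crossings)
        for z, c in zip(sorted(inside), sorted(crossings)):
            assert z == pytest.approx(c, abs=1e-4)

    def test_raw_unit_mapping(self):
        rng = np.random.default_rng(11)
        n = 60
        apathy = rng.normal(12, 5, n)
        cnr = rng.normal(10, 2, n)
        az = (apathy - apathy.mean()) / apathy.std(ddof=1)
        dw = -0.4 * (cnr - cnr.mean()) / cnr.std(ddof=1) * az \
            + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"delta_w": dw, "lc_cnr": cnr, "apathy": apathy})
        region, table = johnson_neyman(df, "delta_w", "lc_cnr", "apathy")
        for z, raw in zip(region.thresholds_z, region.thresholds_raw):
            assert raw == pytest.approx(
                apathy.mean() + apathy.std(ddof=1) * z, abs=1e-9)


class TestJZSBayesFactor:
    def test_null_t_favours_null(self):
        assert jzs_bayes_factor("t-test paired", 0.0, n=17) < 1.0

    def test_monotone_in_t(self):
        bfs = [jzs_bayes_factor("t-test paired", t, n=20)
               for t in (0.0, 0.5, 1.0, 2.0, 3.0, 4.0)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    @pytest.mark.parametrize("t", [1.0, 2.0, 3.0])
    @pytest.mark.parametrize("n", [17, 20, 37])
    def test_t_bf_matches_fixed_grid_quadrature(self, t, n):
        # high-resolution fixed-grid quadrature oracle over g
        from scipy.special import gamma as gammafn

        r = np.sqrt(2) / 2
        nu = n - 1
        # map g = u/(1-u) onto a fixed grid in u so the infinite tail is
        # covered exactly
        u = np.linspace(1e-9, 1 - 1e-9, 2000001)
        g = u / (1 - u)
        jac = 1.0 / (1 - u) ** 2
        dens = (r * r / 2) ** 0.5 / gammafn(0.5) * g ** -1.5 \
            * np.exp(-r * r / (2 * g))
        num = np.trapezoid(
            (1 + n * g) ** -0.5
            * (1 + t * t / ((1 + n * g) * nu)) ** (-(nu + 1) / 2)
            * dens * jac, u)
        oracle = num / (1 + t * t / nu) ** (-(nu + 1) / 2)
        got = jzs_bayes_factor("t-test paired", t, n=n)
        assert got == pytest.approx(oracle, rel=1e-4)

    def test_two_sample_matches_independent_implementation(self):
        import pingouin as pg

        got = jzs_bayes_factor("t-test two-sample", 2.1, n1=17, n2=20)
        ref = pg.bayesfactor_ttest(2.1, 17, 20, paired=False)
        assert got == pytest.approx(float(ref), rel=1e-3)

    @pytest.mark.parametrize("r,n", [(0.3, 20), (-0.59, 17), (0.7, 37)])
    def test_correlation_bf_matches_independent_implementation(self, r, n):
        import pingouin as pg

        got = jzs_bayes_factor("correlation", r, n=n)
        assert got == pytest.approx(float(pg.bayesfactor_pearson(r, n)),
                                    rel=1e-4)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            jzs_bayes_factor("t-test paired", 1.0, n=1)
        with pytest.raises(ValueError):
            jzs_bayes_factor("correlation", 0.5, n=3)


class TestPrecisionTermAncova:
    def test_denominator_df(self):
        rng = np.random.default_rng(12)
        res = precision_term_ancova(rng.normal(size=17), rng.normal(size=17),
                                    rng.normal(size=17))
        assert (res.df_num, res.df_den) == (1, 15)

    def test_identical_terms_give_zero_interaction(self):
        rng = np.random.default_rng(13)
        d = rng.normal(size=17)
        res = precision_term_ancova(d, d, rng.normal(size=17))
        assert res.F == pytest.approx(0.0, abs=1e-9)

    def test_equals_squared_t_from_difference_regression(self):
        rng = np.random.default_rng(14)
        dsp, dse, dw = (rng.normal(size=17) for _ in range(3))
        res = precision_term_ancova(dsp, dse, dw, standardize=False)
        import statsmodels.api as sm

        diff = (dse - dsp) / 2.0  # term coding is -1/+1
        X = sm.add_constant(dw)
        t = sm.OLS(diff, X).fit().tvalues[1]
        assert res.F == pytest.approx(t * t, rel=1e-9)

    def test_null_rejection_rate_nominal(self):
        rng = np.random.default_rng(15)
        rej = sum(
            precision_term_ancova(rng.normal(size=17), rng.normal(size=17),
                                  rng.normal(size=17)).p < 0.05
            for _ in range(4000)
        )
        assert 0.035 <= rej / 4000 <= 0.065

    def test_listwise_exclusion_warns(self):
        rng = np.random.default_rng(16)
        dsp = rng.normal(size=10)
        dsp[0] = np.nan
        with pytest.warns(UserWarning, match="incomplete"):
            res = precision_term_ancova(dsp, rng.normal(size=10),
                                        rng.normal(size=10))
        assert res.df_den == 9 - 2


class TestPlausibleValues:
    def test_point_masses_reduce_to_sample_correlations(self):
        rng = np.random.default_rng(17)
        dsp, dse, dw = (rng.normal(size=12) for _ in range(3))
        res = plausible_values(np.tile(dsp, (50, 1)), np.tile(dse, (50, 1)),
                               dw)
        assert np.allclose(res.corr_prior, np.corrcoef(dsp, dw)[0, 1])
        assert np.allclose(res.corr_evidence, np.corrcoef(dse, dw)[0, 1])

    def test_self_difference_is_zero(self):
        rng = np.random.default_rng(18)
        draws = rng.normal(size=(100, 10))
        dw = rng.normal(size=10)
        res = plausible_values(draws, draws, dw)
        assert np.allclose(res.difference, 0.0)

    def test_coupled_prior_term_separates_difference(self):
        # drug effect on w coupled only to the prior-sd term: the 95%
        # interval of the correlation difference excludes zero
        rng = np.random.default_rng(19)
        n, s = 17, 500
        dw = rng.normal(size=n)
        true_dsp = -0.9 * dw + 0.3 * rng.normal(size=n)
        true_dse = rng.normal(size=n)
        dsp_draws = true_dsp + 0.2 * rng.normal(size=(s, n))
        dse_draws = true_dse + 0.2 * rng.normal(size=(s, n))
        res = plausible_values(dsp_draws, dse_draws, dw)
        lo, hi = res.interval("difference")
        assert hi < 0.0

    def test_too_few_participants_raise(self):
        with pytest.raises(ValueError, match="3 participants"):
            plausible_values(np.zeros((10, 2)), np.zeros((10, 2)),
                             np.zeros(2))
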