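"""Group-level inferential procedures for the crossover cohort.

Continuous predictors are z-scored (sample sd) and categorical predictors
sum-to-zero coded before model fitting, so reported coefficients are
standardized betas.  Tests are two-sided at alpha = .05 unless stated.

Mixed-model denominator degrees of freedom use the balanced-crossover
within/between decomposition (a Satterthwaite-style assignment that is
exact for complete two-session data): terms involving the drug contrast are
tested against the within-subject stratum (df = n_subjects - number of
within-stratum model terms), all other terms against the between-subject
stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special
from scipy import stats as sps

__all__ = [
    "zscore",
    "regress_apathy",
    "DrugCnrResult",
    "fit_drug_cnr_model",
    "PitmanResult",
    "pitman_test",
    "JNRegion",
    "johnson_neyman_thresholds",
    "johnson_neyman",
    "jzs_bayes_factor",
    "AncovaResult",
    "precision_term_ancova",
    "PlausibleValuesResult",
    "plausible_values",
]


def zscore(x: np.ndarray) -> np.ndarray:
    """Standardize with the sample (n-1) denominator."""
    x = np.asarray(x, dtype=float)
    return (x - x.mean()) / x.std(ddof=1)


def _ols_table(y: np.ndarray, X: np.ndarray, terms: list[str]) -> pd.DataFrame:
    import statsmodels.api as sm

    fit = sm.OLS(y, X).fit()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; check collinearity among {terms}"
        )
    return pd.DataFrame({
        "term": terms,
        "beta": fit.params,
        "se": fit.bse,
        "t": fit.tvalues,
        "df": int(fit.df_resid),
        "p": fit.pvalues,
    }).reset_index(drop=True)


def regress_apathy(data: pd.DataFrame) -> pd.DataFrame:
    """Regression of prior weighting on apathy, group, and their interaction.

    ``data`` has one row per normative session (controls plus PD on placebo)
    with columns ``w_hat``, ``apathy``, ``group`` ("PD"/"control") and
    ``iqr_performance_error`` (covariate of no interest).  Continuous
    variables are z-scored; group is coded +1 (control) / -1 (PD).
    Returns a tidy table of standardized betas, SEs, t, residual df and p.
    """
    if "condition" in data.columns:
        data = data[data["condition"].isin(["none", "placebo"])]
    w = zscore(data["w_hat"].to_numpy())
    apathy = zscore(data["apathy"].to_numpy())
    iqr = zscore(data["iqr_performance_error"].to_numpy())
    group = np.where(data["group"].to_numpy() == "control", 1.0, -1.0)
    X = np.column_stack([np.ones_like(w), apathy, group, apathy * group, iqr])
    terms = ["intercept", "apathy", "group", "apathy:group",
             "iqr_performance_error"]
    return _ols_table(w, X, terms)


@dataclass
class DrugCnrResult:
    """Output of the drug x locus coeruleus CNR mixed model.

    ``table`` holds per-term standardized betas with F tests;
    ``delta_w`` the per-participant drug effect on prior weighting (raw w
    units) with the participant's CNR; ``correlation`` the Pearson
    correlation of the two with its df and p.
    """

    table: pd.DataFrame
    delta_w: pd.DataFrame
    correlation: dict


def fit_drug_cnr_model(data: pd.DataFrame) -> DrugCnrResult:
    """Linear mixed model of prior weighting on drug condition, locus
    coeruleus CNR and their interaction.

    ``data`` has one row per PD session with columns ``participant_id``,
    ``condition`` ("placebo"/"atomoxetine"), ``w_hat``, ``lc_cnr`` and
    ``iqr_performance_error``.  The model has a random intercept per
    participant; drug is sum-to-zero coded (+1 atomoxetine / -1 placebo) and
    continuous variables z-scored.  Participants lacking both sessions are
    excluded with a warning.
    """
    import statsmodels.api as sm

    counts = data.groupby("participant_id")["condition"].nunique()
    complete = counts[counts == 2].index
    dropped = sorted(set(data["participant_id"]) - set(complete))
    if dropped:
        warnings.warn(f"excluding participants with a single session: {dropped}")
    df = data[data["participant_id"].isin(complete)].copy()
    n_subj = df["participant_id"].nunique()
    if n_subj < 3:
        raise ValueError("need at least 3 participants with both sessions")

    w = zscore(df["w_hat"].to_numpy())
    cnr = zscore(df["lc_cnr"].to_numpy())
    iqr = zscore(df["iqr_performance_error"].to_numpy())
    drug = np.where(df["condition"].to_numpy() == "atomoxetine", 1.0, -1.0)
    X = np.column_stack([np.ones_like(w), drug, cnr, drug * cnr, iqr])
    terms = ["intercept", "drug", "lc_cnr", "drug:lc_cnr",
             "iqr_performance_error"]
    model = sm.MixedLM(w, X, groups=df["participant_id"].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)

    # balanced-crossover df assignment: drug-involving terms are tested in
    # the within-subject stratum (difference regression on {1, CNR}), the
    # rest in the between-subject stratum ({1, CNR, IQR})
    df_within = n_subj - 2
    df_between = n_subj - 3
    rows = []
    for i, term in enumerate(terms):
        beta = float(fit.fe_params[i])
        se = float(fit.bse_fe[i])
        dof = df_within if "drug" in term else df_between
        t = beta / se
        F = t * t
        p = 2.0 * sps.t.sf(abs(t), dof)
        rows.append(dict(term=term, beta=beta, se=se, t=t, F=F,
                         df_num=1, df_den=dof, p=p))
    table = pd.DataFrame(rows)

    wide = df.pivot_table(index="participant_id", columns="condition",
                          values="w_hat")
    cnr_by_pid = df.groupby("participant_id")["lc_cnr"].first()
    delta_w = pd.DataFrame({
        "participant_id": wide.index,
        "delta_w": (wide["atomoxetine"] - wide["placebo"]).to_numpy(),
        "lc_cnr": cnr_by_pid.loc[wide.index].to_numpy(),
    }).reset_index(drop=True)
    r, p_r = sps.pearsonr(delta_w["delta_w"], delta_w["lc_cnr"])
    correlation = {"r": float(r), "df": n_subj - 2, "p": float(p_r)}
    return DrugCnrResult(table=table, delta_w=delta_w, correlation=correlation)


@dataclass(frozen=True)
class PitmanResult:
    t: float
    df: int
    p: float
    r: float


def pitman_test(x: np.ndarray, y: np.ndarray) -> PitmanResult:
    """Pitman-Morgan test of equality of variances for paired samples.

    Correlates the pairwise sums and differences: r = corr(x+y, x-y);
    t = r sqrt(n-2) / sqrt(1-r^2) on n-2 df, two-sided p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D paired samples")
    n = len(x)
    if n < 3:
        raise ValueError("Pitman's test requires at least 3 pairs")
    s, d = x + y, x - y
    if np.std(s) == 0.0 or np.std(d) == 0.0:
        raise ValueError("degenerate pairs: sums or differences have zero variance")
    r = float(np.corrcoef(s, d)[0, 1])
    df = n - 2
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * sps.t.sf(abs(t), df)
    return PitmanResult(t=float(t), df=df, p=float(p), r=r)


@dataclass(frozen=True)
class JNRegion:
    """Johnson-Neyman region of significance for a moderated slope.

    ``region`` is one of "all", "none", "between", "outside", "above",
    "below" (the last two arise when the boundary is linear in the
    moderator);
    ``thresholds_z`` are the moderator values (z units) where the
    conditional slope crosses the significance boundary, mapped to raw
    moderator units in ``thresholds_raw``.
    """

    region: str
    thresholds_z: tuple[float, ...]
    thresholds_raw: tuple[float, ...]
    alpha: float
    t_crit: float


def johnson_neyman_thresholds(
    b_pred: float,
    b_int: float,
    cov: np.ndarray,
    df: int,
    alpha: float = 0.05,
    moderator_mean: float = 0.0,
    moderator_sd: float = 1.0,
) -> JNRegion:
    """Solve for the moderator values where the conditional slope of the
    predictor becomes significant.

    The conditional slope at moderator value z is b_pred + b_int z with
    variance v11 + 2 z v12 + z^2 v22; setting |slope| / SE = t_crit yields a
    quadratic in z.  No real roots is reported as an empty or entire-range
    region (never an exception).
    """
    cov = np.asarray(cov, dtype=float)
    t_crit = float(sps.t.ppf(1.0 - alpha / 2.0, df))
    v11, v12, v22 = cov[0, 0], cov[0, 1], cov[1, 1]
    a = b_int**2 - t_crit**2 * v22
    b = 2.0 * (b_pred * b_int - t_crit**2 * v12)
    c = b_pred**2 - t_crit**2 * v11

    def significant(z: float) -> bool:
        slope = b_pred + b_int * z
        se = np.sqrt(v11 + 2.0 * z * v12 + z * z * v22)
        return abs(slope) / se >= t_crit

    def build(region: str, roots: tuple[float, ...]) -> JNRegion:
        raw = tuple(moderator_mean + moderator_sd * z for z in roots)
        return JNRegion(region=region, thresholds_z=roots, thresholds_raw=raw,
                        alpha=alpha, t_crit=t_crit)

    if abs(a) < 1e-300:  # no curvature: at most one crossing
        if abs(b) < 1e-300:
            return build("all" if significant(0.0) else "none", ())
        z0 = -c / b
        lo_sig, hi_sig = significant(z0 - 1.0), significant(z0 + 1.0)
        if lo_sig and hi_sig:
            return build("all", (float(z0),))
        if not lo_sig and not hi_sig:
            return build("none", (float(z0),))
        return build("above" if hi_sig else "below", (float(z0),))

    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        return build("all" if significant(0.0) else "none", ())
    r1 = (-b - np.sqrt(disc)) / (2.0 * a)
    r2 = (-b + np.sqrt(disc)) / (2.0 * a)
    z1, z2 = sorted((float(r1), float(r2)))
    mid_sig = significant((z1 + z2) / 2.0)
    return build("between" if mid_sig else "outside", (z1, z2))


def johnson_neyman(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    moderator: str,
    alpha: float = 0.05,
) -> tuple[JNRegion, pd.DataFrame]:
    """Fit outcome ~ predictor * moderator (all z-scored) and return the
    Johnson-Neyman region for the predictor's conditional slope, with
    thresholds mapped back to raw moderator units."""
    import statsmodels.api as sm

    y = zscore(data[outcome].to_numpy())
    x = zscore(data[predictor].to_numpy())
    m_raw = data[moderator].to_numpy(dtype=float)
    m = zscore(m_raw)
    X = np.column_stack([np.ones_like(y), x, m, x * m])
    terms = ["intercept", predictor, moderator, f"{predictor}:{moderator}"]
    fit = sm.OLS(y, X).fit()
    cov = np.asarray(fit.cov_params())[np.ix_([1, 3], [1, 3])]
    region = johnson_neyman_thresholds(
        float(fit.params[1]), float(fit.params[3]), cov, int(fit.df_resid),
        alpha=alpha, moderator_mean=float(m_raw.mean()),
        moderator_sd=float(m_raw.std(ddof=1)),
    )
    table = pd.DataFrame({
        "term": terms, "beta": fit.params, "se": fit.bse,
        "t": fit.tvalues, "df": int(fit.df_resid), "p": fit.pvalues,
    }).reset_index(drop=True)
    return region, table


def jzs_bayes_factor(
    kind: str,
    statistic: float,
    n: int | None = None,
    n1: int | None = None,
    n2: int | None = None,
    scale: float | None = None,
) -> float:
    """Default-prior (JZS) Bayes factor BF10 for t tests and correlations.

    For t tests the effect size carries a zero-centred Cauchy prior with
    scale sqrt(2)/2 (g integrated against its inverse-gamma mixing density);
    for correlations a stretched beta with kappa = 1, i.e. uniform on
    (-1, 1).  Marginal likelihood ratios are computed by adaptive numerical
    integration (relative tolerance 1e-6 or better).
    """
    if kind in ("t-test paired", "t-test one-sample", "t-test two-sample"):
        t = float(statistic)
        if kind == "t-test two-sample":
            if n1 is None or n2 is None:
                raise ValueError("two-sample t test needs n1 and n2")
            if min(n1, n2) < 2:
                raise ValueError("each group needs at least 2 observations")
            n_eff = n1 * n2 / (n1 + n2)
            nu = n1 + n2 - 2
        else:
            if n is None or n < 2:
                raise ValueError("paired/one-sample t test needs n >= 2")
            n_eff = float(n)
            nu = n - 1
        r = float(scale) if scale is not None else np.sqrt(2.0) / 2.0

        def integrand(g: float) -> float:
            # t likelihood under effect-size prior mixed over g, times the
            # inverse-gamma(1/2, r^2/2) density of g
            m = (1.0 + n_eff * g) ** -0.5 \
                * (1.0 + t * t / ((1.0 + n_eff * g) * nu)) ** (-(nu + 1.0) / 2.0)
            dens = (r * r / 2.0) ** 0.5 / special.gamma(0.5) \
                * g ** -1.5 * np.exp(-r * r / (2.0 * g))
            return m * dens

        num, _ = integrate.quad(integrand, 0.0, np.inf, epsabs=0.0,
                                epsrel=1e-10, limit=200)
        den = (1.0 + t * t / nu) ** (-(nu + 1.0) / 2.0)
        return float(num / den)

    if kind == "correlation":
        if n is None or n < 4:
            raise ValueError("correlation BF needs n >= 4")
        r_obs = float(statistic)
        if not -1.0 < r_obs < 1.0:
            raise ValueError("correlation statistic must lie in (-1, 1)")

        def g(rho: float) -> float:
            # rho-dependent part of the sampling density of the observed r
            return (1.0 - rho * rho) ** ((n - 1.0) / 2.0) \
                * (1.0 - rho * r_obs) ** (-(n - 1.5)) \
                * special.hyp2f1(0.5, 0.5, n - 0.5, (1.0 + rho * r_obs) / 2.0)

        num, _ = integrate.quad(lambda rho: 0.5 * g(rho), -1.0, 1.0,
                                epsabs=0.0, epsrel=1e-10, limit=200)
        return float(num / g(0.0))

    raise ValueError(f"unknown kind {kind!r}")


@dataclass(frozen=True)
class AncovaResult:
    F: float
    df_num: int
    df_den: int
    p: float


def precision_term_ancova(
    delta_sigma_prior: np.ndarray,
    delta_sigma_evidence: np.ndarray,
    delta_w: np.ndarray,
    standardize: bool = True,
) -> AncovaResult:
    """Repeated-measures ANCOVA of the two drug-effect precision terms.

    The dependent variable stacks each participant's drug effect on the
    prior sd and on the evidence sd (within-subject factor: precision term),
    with the drug effect on prior weighting as a between-subject covariate.
    The interaction F (1, n-2) tests whether the covariate relates
    differently to the two precision terms.  The two precision-term
    variables are standardized by default before the within-subject
    contrast.  Participants with any missing value are excluded listwise.
    """
    dsp = np.asarray(delta_sigma_prior, dtype=float)
    dse = np.asarray(delta_sigma_evidence, dtype=float)
    dw = np.asarray(delta_w, dtype=float)
    keep = ~(np.isnan(dsp) | np.isnan(dse) | np.isnan(dw))
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} incomplete participants")
        dsp, dse, dw = dsp[keep], dse[keep], dw[keep]
    n = len(dw)
    if n < 4:
        raise ValueError("need at least 4 complete participants")
    if standardize:
        if dsp.std(ddof=1) > 0:
            dsp = zscore(dsp)
        if dse.std(ddof=1) > 0:
            dse = zscore(dse)
    # long format: subject fixed effects + term + term:covariate; the
    # between-subject covariate main effect is absorbed by subject effects
    y = np.concatenate([dsp, dse])
    subj = np.tile(np.eye(n), (2, 1))
    term = np.concatenate([np.full(n, -1.0), np.full(n, 1.0)])
    X_full = np.column_stack([subj, term, term * np.tile(dw, 2)])
    X_red = np.column_stack([subj, term])

    def rss(X: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid)

    df_den = n - 2
    rss_full = rss(X_full)
    rss_red = rss(X_red)
    # guard against pure rounding noise when the fit is exact (e.g. the two
    # precision terms are identical)
    eps = 1e-10 * max(1.0, float(y @ y))
    if rss_full < eps:
        F = 0.0 if rss_red - rss_full < eps else np.inf
    else:
        F = max(rss_red - rss_full, 0.0) / (rss_full / df_den)
    p = float(sps.f.sf(F, 1, df_den)) if np.isfinite(F) else 0.0
    return AncovaResult(F=float(F), df_num=1, df_den=df_den, p=p)


@dataclass
class PlausibleValuesResult:
    """Distributions of plausible correlations across posterior draws.

    Each array has one entry per retained draw: the correlation of the
    drug effect on prior weighting with the drawn drug effect on the prior
    sd (``corr_prior``), with the drawn drug effect on the evidence sd
    (``corr_evidence``), and their per-draw difference.
    """

    corr_prior: np.ndarray
    corr_evidence: np.ndarray
    difference: np.ndarray

    def interval(self, which: str = "difference",
                 level: float = 0.95) -> tuple[float, float]:
        x = getattr(self, which)
        lo = (1.0 - level) / 2.0 * 100.0
        return tuple(np.percentile(x, [lo, 100.0 - lo]))


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``a`` with the vector ``b``."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean()
    denom = np.sqrt((a * a).sum(axis=1) * (b * b).sum())
    return (a @ b) / denom


def plausible_values(
    draws_delta_sigma_prior: np.ndarray,
    draws_delta_sigma_evidence: np.ndarray,
    delta_w: np.ndarray,
) -> PlausibleValuesResult:
    """Propagate posterior uncertainty into the precision-term correlations.

    For every posterior draw, correlate the participants' drawn drug effects
    on the prior and evidence sds with the observed drug effect on prior
    weighting, and form the per-draw difference of the two correlations.
    Draw matrices have shape (draws, participants), aligned across inputs.
    """
    dsp = np.atleast_2d(np.asarray(draws_delta_sigma_prior, dtype=float))
    dse = np.atleast_2d(np.asarray(draws_delta_sigma_evidence, dtype=float))
    dw = np.asarray(delta_w, dtype=float)
    if dsp.shape != dse.shape or dsp.shape[1] != len(dw):
        raise ValueError("draw matrices and delta_w are not aligned")
    if len(dw) < 3:
        raise ValueError("need at least 3 participants")
    cp = _rowwise_corr(dsp, dw)
    ce = _rowwise_corr(dse, dw)
    return PlausibleValuesResult(corr_prior=cp, corr_evidence=ce,
                                 difference=cp - ce)
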