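"""Slope-based estimation of prior weighting from estimation trials.

Under the Gaussian cue-combination model, estimation error (estimate minus
true ball position) relates to performance error (ball minus target) as

    estimation_error = -w * performance_error,

so the prior weighting w is the negative of the no-intercept regression
slope.  Errors are z-scored within each session before fitting (population
denominator), which removes the unit mismatch between option-unit estimation
errors and screen-fraction performance errors and forces the zero intercept
the model assumes.  Two estimators are provided: independent per-session
least squares (the transparent, shrinkage-free oracle) and a random-slope
mixed model pooled across sessions, mirroring the study's analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .task import TaskDesign
from .simulate import (
    ObserverParams,
    SessionData,
    _simulate_estimation_core,
)

__all__ = [
    "DegenerateSessionError",
    "zscore_session_errors",
    "session_error_pairs",
    "estimate_prior_weighting",
    "predict_estimation_quantiles",
    "observer_for_w",
    "RecoveryResult",
    "run_parameter_recovery",
]


class DegenerateSessionError(ValueError):
    """A session's error series has zero variance or too few trials."""


def session_error_pairs(session: SessionData) -> tuple[np.ndarray, np.ndarray]:
    """Raw (estimation error, performance error) pairs from a session's
    estimation trials.

    Estimation errors are in option units when responses were snapped to the
    grid, otherwise in screen fractions (continuous-response mode); the
    subsequent z-scoring makes the two conventions equivalent up to scale.
    """
    est = session.estimation_trials
    ee = est["estimation_error_options"].to_numpy(dtype=float)
    if np.isnan(ee).all():
        ee = est["estimation_error_pos"].to_numpy(dtype=float)
    pe = est["performance_error"].to_numpy(dtype=float)
    keep = ~(np.isnan(ee) | np.isnan(pe))
    return ee[keep], pe[keep]


def zscore_session_errors(
    estimation_errors: np.ndarray, performance_errors: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score the two error series within a session (population sd).

    Raises :class:`DegenerateSessionError` when either series has fewer than
    3 observations or zero variance.
    """
    ee = np.asarray(estimation_errors, dtype=float)
    pe = np.asarray(performance_errors, dtype=float)
    if len(ee) != len(pe):
        raise ValueError("error series must have equal length")
    if len(ee) < 3:
        raise DegenerateSessionError("fewer than 3 estimation trials")
    for name, v in (("estimation error", ee), ("performance error", pe)):
        if np.std(v) == 0.0:
            raise DegenerateSessionError(f"{name} series has zero variance")
    return (ee - ee.mean()) / ee.std(), (pe - pe.mean()) / pe.std()


def _per_session_fit(ee_z: np.ndarray, pe_z: np.ndarray) -> tuple[float, float]:
    """No-intercept OLS slope and SE on z-scored pairs.

    For z-scored series the slope equals the Pearson correlation.
    """
    sxx = float(np.sum(pe_z**2))
    b = float(np.sum(pe_z * ee_z)) / sxx
    resid = ee_z - b * pe_z
    dof = len(ee_z) - 1
    se = float(np.sqrt(np.sum(resid**2) / dof / sxx)) if dof > 0 else np.nan
    return b, se


def estimate_prior_weighting(
    sessions: list[SessionData], method: str = "mixed",
    standardize: bool = True,
) -> pd.DataFrame:
    """Estimate prior weighting for each session from estimation trials only.

    Parameters
    ----------
    method
        ``"per-session"`` fits independent no-intercept least squares per
        session; ``"mixed"`` fits a single random-slope model (REML, no
        intercepts, slope varying by session) and reports the per-session
        conditional slopes.  In both cases ``w_hat`` is the negative slope.
    standardize
        Z-score both error series per session before fitting (the default,
        matching the zero-intercept convention; the slope then equals the
        correlation).  ``False`` fits the raw-unit slope — only meaningful
        when both errors share a unit, but exact for noiseless data.

    Returns
    -------
    DataFrame with columns session_id, participant_id, condition, w_hat, se,
    method, n_trials, out_of_range.  Sessions with fewer than 3 usable
    estimation trials are omitted with a warning.  Estimates are not clipped
    to [0, 1]; out-of-range values are flagged instead.
    """
    if method not in ("mixed", "per-session"):
        raise ValueError("method must be 'mixed' or 'per-session'")
    rows = []
    z_data = []
    for s in sessions:
        sid = f"{s.participant_id}/{s.condition}"
        ee, pe = session_error_pairs(s)
        try:
            if standardize:
                ee_z, pe_z = zscore_session_errors(ee, pe)
            else:
                if len(ee) < 3:
                    raise DegenerateSessionError("fewer than 3 estimation trials")
                if np.std(pe) == 0.0:
                    raise DegenerateSessionError(
                        "performance error series has zero variance")
                ee_z, pe_z = ee - ee.mean(), pe - pe.mean()
        except DegenerateSessionError as err:
            warnings.warn(f"session {sid} omitted: {err}")
            continue
        z_data.append((sid, s, ee_z, pe_z))

    if method == "per-session":
        for sid, s, ee_z, pe_z in z_data:
            b, se = _per_session_fit(ee_z, pe_z)
            rows.append((sid, s.participant_id, s.condition, -b, se, len(ee_z)))
    else:
        import statsmodels.api as sm

        endog = np.concatenate([d[2] for d in z_data])
        exog = np.concatenate([d[3] for d in z_data])[:, None]
        groups = np.concatenate(
            [np.repeat(i, len(d[2])) for i, d in enumerate(z_data)]
        )
        model = sm.MixedLM(endog, exog, groups=groups, exog_re=exog)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=True)
        fe = float(fit.fe_params[0])
        fe_var = float(fit.bse_fe[0]) ** 2
        try:
            re = fit.random_effects
            re_cov = fit.random_effects_cov
        except Exception:
            # singular random-effects covariance: total shrinkage, every
            # session takes the fixed slope
            re = {i: np.zeros(1) for i in range(len(z_data))}
            re_cov = {i: np.zeros((1, 1)) for i in range(len(z_data))}
        for i, (sid, s, ee_z, pe_z) in enumerate(z_data):
            b_i = fe + float(np.asarray(re[i]).ravel()[0])
            cvar = float(np.asarray(re_cov[i]).ravel()[0])
            se_i = float(np.sqrt(max(fe_var + cvar, 0.0)))
            rows.append((sid, s.participant_id, s.condition, -b_i, se_i, len(ee_z)))

    out = pd.DataFrame(
        rows,
        columns=["session_id", "participant_id", "condition", "w_hat", "se",
                 "n_trials"],
    )
    out["method"] = method
    out["out_of_range"] = (out["w_hat"] < 0) | (out["w_hat"] > 1)
    return out


def predict_estimation_quantiles(
    w: float,
    performance_errors: np.ndarray,
    posterior_sd: float,
) -> pd.DataFrame:
    """Predicted estimation-error quantile bands for given performance errors.

    The predicted estimation error for performance error e is distributed
    N(-w e, posterior_sd^2); returns its median together with the central
    25% and 50% interval bounds per input.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    if posterior_sd < 0:
        raise ValueError("posterior_sd must be non-negative")
    pe = np.asarray(performance_errors, dtype=float)
    loc = -w * pe
    if posterior_sd == 0:
        z25 = z50 = 0.0
    else:
        z50 = sps.norm.ppf(0.75) * posterior_sd   # central 50%: [q25, q75]
        z25 = sps.norm.ppf(0.625) * posterior_sd  # central 25%: [q37.5, q62.5]
    return pd.DataFrame(
        {
            "performance_error": pe,
            "median": loc,
            "q25_lo": loc - z25,
            "q25_hi": loc + z25,
            "q50_lo": loc - z50,
            "q50_hi": loc + z50,
        }
    )


def calibrated_sigma_evidence(w: float, motor_noise_sd: float) -> float:
    """Evidence noise matching estimation-error to performance-error spread.

    The marginal estimation-error variance of the observer model is
    w^2 m^2 + sigma_e^2 (1-w)(2-w) with m the motor noise; setting
    sigma_e^2 = m^2 (1+w)/(2-w) makes it equal m^2 — the empirically
    observed near-equality of the two error spreads — so the correlation-
    based slope estimator recovers w without attenuation or inflation.
    """
    w_eff = float(np.clip(w, 1e-4, 1.0 - 1e-4))
    return float(motor_noise_sd * np.sqrt((1.0 + w_eff) / (2.0 - w_eff)))


def observer_for_w(
    w: float,
    sigma_evidence: float | None = None,
    x_shift: float = 0.0,
    motor_noise_sd: float | None = None,
) -> ObserverParams:
    """Observer whose placebo-session prior weighting equals ``w``.

    When ``sigma_evidence`` is omitted it is set by
    :func:`calibrated_sigma_evidence` (estimation-error spread matched to
    the performance-error spread); sigma_prior then follows from w, which
    is clipped to [1e-4, 1 - 1e-4] so boundary values stay representable.
    """
    w_eff = float(np.clip(w, 1e-4, 1.0 - 1e-4))
    kwargs = {}
    if motor_noise_sd is not None:
        kwargs["motor_noise_sd"] = motor_noise_sd
    m = kwargs.get("motor_noise_sd", ObserverParams(1, 1).motor_noise_sd)
    if sigma_evidence is None:
        sigma_evidence = calibrated_sigma_evidence(w_eff, m)
    sigma_prior = sigma_evidence * np.sqrt((1.0 - w_eff) / w_eff)
    return ObserverParams(
        sigma_prior=float(sigma_prior), sigma_evidence=float(sigma_evidence),
        x_shift=x_shift, **kwargs,
    )


@dataclass
class RecoveryResult:
    """Output of the parameter-recovery study.

    ``table`` has one row per generating w (median and 95% quantile interval
    of the per-session estimates); ``w_hats`` maps each generating w to the
    full vector of per-session estimates; ``median_bias`` maps it to
    median(w_hat) - w.
    """

    table: pd.DataFrame
    w_hats: dict[float, np.ndarray]

    @property
    def median_bias(self) -> dict[float, float]:
        return {
            float(r["w_generating"]): float(r["w_hat_median"] - r["w_generating"])
            for _, r in self.table.iterrows()
        }


def run_parameter_recovery(
    w_grid: list[float],
    design: TaskDesign | None = None,
    n_sims: int = 2000,
    seed: int | None = None,
    sigma_evidence: float | None = None,
    discretize: bool = True,
) -> RecoveryResult:
    """Simulate sessions at known prior weightings and re-estimate them.

    For each generating w, ``n_sims`` sessions of estimation trials are
    simulated through the observer model (grid discretisation on by default)
    and the per-session slope estimator applied; the table reports the
    median and the 2.5% / 97.5% quantiles of the estimates.
    """
    design = design or TaskDesign()
    if n_sims < 1:
        raise ValueError("n_sims must be positive")
    for w in w_grid:
        if not 0.0 <= w <= 1.0:
            raise ValueError("w_grid values must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_est = design.n_estimation
    targets = np.resize(np.asarray(design.effort_levels, dtype=float), n_est)
    rows = []
    w_hats: dict[float, np.ndarray] = {}
    for w in w_grid:
        params = observer_for_w(w, sigma_evidence=sigma_evidence)
        ests = np.empty(n_sims)
        for k in range(n_sims):
            core = _simulate_estimation_core(
                targets, params.sigma_prior, params.sigma_evidence,
                params.x_shift, params.motor_noise_sd, design, rng, discretize,
            )
            ee = core["estimation_error_options" if discretize
                      else "estimation_error_pos"]
            pe = core["ball_pos"] - targets
            ee_z, pe_z = zscore_session_errors(ee, pe)
            b, _ = _per_session_fit(ee_z, pe_z)
            ests[k] = -b
        w_hats[float(w)] = ests
        lo, med, hi = np.percentile(ests, [2.5, 50.0, 97.5])
        rows.append((w, med, lo, hi, n_sims))
    table = pd.DataFrame(
        rows,
        columns=["w_generating", "w_hat_median", "w_hat_q025", "w_hat_q975",
                 "n_sims"],
    )
    return RecoveryResult(table=table, w_hats=w_hats)
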