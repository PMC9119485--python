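"""Generative simulator of Bayesian observers, sessions, and cohorts.

Each observer combines a Gaussian prior centred on the target with Gaussian
sensory evidence centred on the (possibly shifted) final ball position, and
reports a sample from the resulting posterior, snapped to the estimation
grid.  Cohorts emulate the study's crossover design: controls complete one
session, patients complete a placebo and an atomoxetine session in
counterbalanced order, with configurable couplings between apathy and prior
weighting and between locus coeruleus contrast and the drug-induced change
in prior weighting.

The force -> ball-velocity physics is not simulated: the final ball position
is drawn directly as target + motor noise, since every analysis operates on
positions.  One relative-force unit is identified with one screen width, so
force errors in percentage points equal position errors x 100.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .task import TaskDesign, TrialSequence, build_task_design

__all__ = [
    "ObserverParams",
    "GroupHyperParams",
    "CohortConfig",
    "SessionData",
    "session_sigmas",
    "prior_weighting_from_sigmas",
    "simulate_session",
    "simulate_cohort",
    "draw_observer_params",
    "write_cohort",
    "read_cohort",
]

#: default motor noise (screen fraction): chosen so the interquartile range of
#: force error is ~9.2 percentage points (IQR of a Gaussian = 1.349 sd).
DEFAULT_MOTOR_NOISE_SD = 0.0919 / 1.349


@dataclass(frozen=True)
class ObserverParams:
    """Per-participant generative parameters (screen-fraction units).

    ``sigma_prior`` / ``sigma_evidence`` are the placebo-session standard
    deviations of the prior and sensory-evidence distributions;
    ``delta_prior`` / ``delta_evidence`` are additive atomoxetine-induced
    changes; ``x_shift`` is a constant spatial shift of the sensory evidence;
    ``motor_noise_sd`` is generator-only dispersion of the ball around the
    target.
    """

    sigma_prior: float
    sigma_evidence: float
    delta_prior: float = 0.0
    delta_evidence: float = 0.0
    x_shift: float = 0.0
    motor_noise_sd: float = DEFAULT_MOTOR_NOISE_SD

    def __post_init__(self) -> None:
        if self.sigma_prior <= 0 or self.sigma_evidence <= 0:
            raise ValueError("sigma_prior and sigma_evidence must be positive")
        if self.motor_noise_sd <= 0:
            raise ValueError("motor_noise_sd must be positive")

    def w_prior(self, condition: str = "placebo") -> float:
        """Prior weighting w = sigma_evidence^2 / (sigma_evidence^2 + sigma_prior^2)."""
        sp, se = session_sigmas(self, condition)
        return prior_weighting_from_sigmas(sp, se)


def session_sigmas(params: ObserverParams, condition: str) -> tuple[float, float]:
    """Session-specific (sigma_prior, sigma_evidence): the drug deltas apply
    only in the atomoxetine session."""
    if condition == "atomoxetine":
        sp = params.sigma_prior + params.delta_prior
        se = params.sigma_evidence + params.delta_evidence
    elif condition in ("placebo", "none"):
        sp, se = params.sigma_prior, params.sigma_evidence
    else:
        raise ValueError(f"unknown condition {condition!r}")
    if sp <= 0 or se <= 0:
        raise ValueError(
            "invalid drug configuration: session standard deviation is not positive"
        )
    return sp, se


def prior_weighting_from_sigmas(sigma_prior: float, sigma_evidence: float) -> float:
    return sigma_evidence**2 / (sigma_evidence**2 + sigma_prior**2)


def cue_combination_posterior(
    prior_mean: float,
    evidence: float,
    sigma_prior: float,
    sigma_evidence: float,
) -> tuple[float, float]:
    """Mean and sd of the Gaussian-product posterior over the hidden position.

    The posterior of the true position given one evidence sample is the
    normalised product of the prior N(prior_mean, sigma_prior^2) and the
    likelihood N(evidence, sigma_evidence^2): precision-weighted mean, and
    variance equal to the harmonic combination of the two variances.
    """
    w = prior_weighting_from_sigmas(sigma_prior, sigma_evidence)
    mean = w * prior_mean + (1.0 - w) * evidence
    sd = np.sqrt(
        sigma_evidence**2 * sigma_prior**2 / (sigma_evidence**2 + sigma_prior**2)
    )
    return float(mean), float(sd)


def marginal_predictive_sd(sigma_prior: float, sigma_evidence: float) -> float:
    """Sd of the estimate given (target, ball), marginal over the evidence
    sample: sqrt((1-w)^2 sigma_e^2 + sigma_posterior^2) = sqrt(w(2-w)) sigma_p."""
    w = prior_weighting_from_sigmas(sigma_prior, sigma_evidence)
    return float(np.sqrt(w * (2.0 - w)) * sigma_prior)


@dataclass(frozen=True)
class GroupHyperParams:
    """Group-level distributions from which participant parameters are drawn.

    sigma parameters follow positive-truncated normals; deltas and the
    evidence shift follow normals.  Units: screen fraction.  Defaults give
    placebo prior weightings centred near 0.45 with realistic spread.
    """

    mu_sigma_prior: float = 0.055
    sd_sigma_prior: float = 0.015
    mu_sigma_evidence: float = 0.050
    sd_sigma_evidence: float = 0.012
    mu_delta_prior: float = 0.0
    sd_delta_prior: float = 0.020
    mu_delta_evidence: float = 0.0
    sd_delta_evidence: float = 0.010
    mu_xshift: float = 0.0
    sd_xshift: float = 0.010

    def __post_init__(self) -> None:
        for name in ("sd_sigma_prior", "sd_sigma_evidence", "sd_delta_prior",
                     "sd_delta_evidence", "sd_xshift"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition, covariate distributions, and coupling knobs.

    ``coupling_apathy_w`` is the standardized slope linking apathy to prior
    weighting (default -0.35); ``coupling_cnr_delta`` links locus coeruleus
    CNR to the drug-induced change in prior weighting (default -0.59).
    Apathy Scale scores are rounded Gaussians clipped to the instrument
    range 0-42.
    """

    n_pd: int = 17
    n_controls: int = 20
    apathy_mean: float = 11.0
    apathy_sd: float = 5.0
    apathy_range: tuple[int, int] = (0, 42)
    lc_cnr_mean: float = 10.0
    lc_cnr_sd: float = 2.0
    coupling_apathy_w: float = -0.35
    coupling_cnr_delta: float = -0.59
    w_mean: float = 0.45
    w_sd: float = 0.18
    delta_w_sd: float = 0.20
    w_bounds: tuple[float, float] = (0.05, 0.95)
    calibrate_evidence_noise: bool = True

    def __post_init__(self) -> None:
        if self.n_pd < 0 or self.n_controls < 0:
            raise ValueError("group sizes must be non-negative")
        for c in (self.coupling_apathy_w, self.coupling_cnr_delta):
            if not np.isfinite(c) or abs(c) > 1:
                raise ValueError("couplings must be finite standardized slopes in [-1, 1]")


@dataclass
class SessionData:
    """One completed testing session: identity, condition, and trial table.

    ``trials`` has one row per trial; estimation-specific columns
    (``veridical_index``, ``chosen_index``, ``estimate_pos``,
    ``estimation_error_options``, ``estimation_error_pos``, grid geometry)
    are NaN on basic trials.
    """

    participant_id: str
    group: str                    # "PD" | "control"
    condition: str                # "placebo" | "atomoxetine" | "none"
    session_order: int            # 1 or 2
    trials: pd.DataFrame
    params: ObserverParams | None = None
    seed: int | None = None

    @property
    def estimation_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["trial_type"] == "estimation"]

    def iqr_performance_error(self) -> float:
        """Interquartile range of performance error, in percentage points."""
        pe = self.trials["performance_error"].to_numpy()
        q75, q25 = np.percentile(pe, [75, 25])
        return float((q75 - q25) * 100.0)


def _simulate_estimation_core(
    target: np.ndarray,
    sigma_prior: float,
    sigma_evidence: float,
    x_shift: float,
    motor_noise_sd: float,
    design: TaskDesign,
    rng: np.random.Generator,
    discretize: bool,
) -> dict[str, np.ndarray]:
    """Vectorised observer model for a batch of estimation trials.

    Draws the ball position, samples sensory evidence, forms the posterior
    N(x_hat, sigma_post^2) of the Gaussian cue-combination model, samples the
    reported estimate from it, and (optionally) snaps it to the veridical-
    centred response grid with ties resolved toward the lower option index.
    """
    k = len(target)
    ball = target + rng.normal(0.0, motor_noise_sd, size=k)
    s = ball + x_shift + rng.normal(0.0, sigma_evidence, size=k)
    w = prior_weighting_from_sigmas(sigma_prior, sigma_evidence)
    x_hat = w * target + (1.0 - w) * s
    post_sd = np.sqrt(
        sigma_evidence**2 * sigma_prior**2 / (sigma_evidence**2 + sigma_prior**2)
    )
    estimate = x_hat + rng.normal(0.0, post_sd, size=k)
    out = {"ball_pos": ball, "w": np.full(k, w), "post_sd": np.full(k, post_sd)}
    if not discretize:
        out.update(
            veridical_index=np.full(k, np.nan),
            chosen_index=np.full(k, np.nan),
            estimate_pos=estimate,
            estimation_error_options=np.full(k, np.nan),
            estimation_error_pos=estimate - ball,
            grid_first_centre=np.full(k, np.nan),
            grid_clamped=np.zeros(k, dtype=bool),
        )
        return out
    lo, hi = design.veridical_index_range
    vidx = rng.integers(lo, hi + 1, size=k)
    spacing = design.option_spacing
    n = design.n_response_options
    first_centre = ball + (1 - vidx) * spacing
    left_edge = first_centre - spacing / 2
    right_edge = first_centre + (n - 1) * spacing + spacing / 2
    shift = np.where(left_edge < 0, -left_edge, 0.0) + np.where(
        right_edge > 1, 1.0 - right_edge, 0.0
    )
    clamped = shift != 0.0
    first_centre = first_centre + shift
    # nearest option centre; exact midpoints resolve to the lower index
    u = (estimate - first_centre) / spacing
    chosen = np.ceil(u - 0.5).astype(int) + 1
    chosen = np.clip(chosen, 1, n)
    snapped = first_centre + (chosen - 1) * spacing
    out.update(
        veridical_index=vidx.astype(float),
        chosen_index=chosen.astype(float),
        estimate_pos=snapped,
        estimation_error_options=(chosen - vidx).astype(float),
        estimation_error_pos=snapped - ball,
        grid_first_centre=first_centre,
        grid_clamped=clamped,
    )
    return out


def simulate_session(
    params: ObserverParams,
    design: TaskDesign | None = None,
    condition: str = "none",
    seed: int | np.random.Generator | None = None,
    discretize: bool = True,
    sequence: TrialSequence | None = None,
    participant_id: str = "sim",
    group: str = "control",
    session_order: int = 1,
) -> SessionData:
    """Simulate one testing session for a single observer.

    The drug condition selects the session-specific prior and evidence
    standard deviations (deltas apply on atomoxetine only).  With
    ``discretize=False`` the raw posterior sample is reported instead of the
    nearest grid option (the continuous-response oracle mode).
    """
    if design is None:
        design = TaskDesign()
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = _sequence_for(design, rng)
    sp, se = session_sigmas(params, condition)
    df = sequence.to_frame().copy()
    df.insert(0, "index", np.arange(1, len(df) + 1))
    target = df["effort"].to_numpy(dtype=float)
    is_est = (df["trial_type"] == "estimation").to_numpy()

    # basic trials: ball position only
    ball = target + rng.normal(0.0, params.motor_noise_sd, size=len(df))
    est_cols = [
        "veridical_index", "chosen_index", "estimate_pos",
        "estimation_error_options", "estimation_error_pos", "grid_first_centre",
    ]
    for c in est_cols:
        df[c] = np.nan
    df["grid_clamped"] = False
    if is_est.any():
        core = _simulate_estimation_core(
            target[is_est], sp, se, params.x_shift, params.motor_noise_sd,
            design, rng, discretize,
        )
        ball[is_est] = core["ball_pos"]
        for c in est_cols:
            df.loc[is_est, c] = core[c]
        df.loc[is_est, "grid_clamped"] = core["grid_clamped"]
    df["target_pos"] = target
    df["ball_pos"] = ball
    df["performance_error"] = df["ball_pos"] - df["target_pos"]
    return SessionData(
        participant_id=participant_id,
        group=group,
        condition=condition,
        session_order=session_order,
        trials=df,
        params=params,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def _sequence_for(design: TaskDesign, rng: np.random.Generator) -> TrialSequence:
    cfg = {
        f.name: getattr(design, f.name)
        for f in dataclasses.fields(TaskDesign)
    }
    _, seq = build_task_design(cfg, seed=int(rng.integers(2**31)))
    return seq


def draw_observer_params(
    hyper: GroupHyperParams,
    n: int,
    seed: int | np.random.Generator | None = None,
    motor_noise_sd: float = DEFAULT_MOTOR_NOISE_SD,
) -> list[ObserverParams]:
    """Draw n observers from the group-level distributions (positive-truncated
    normals for the sigma parameters, normals for deltas and evidence shift)."""
    rng = np.random.default_rng(seed)

    def truncpos(mu, sd, size):
        a = (0.0 - mu) / sd
        return sps.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=size, random_state=rng)

    sp = truncpos(hyper.mu_sigma_prior, hyper.sd_sigma_prior, n)
    se = truncpos(hyper.mu_sigma_evidence, hyper.sd_sigma_evidence, n)
    dp = rng.normal(hyper.mu_delta_prior, hyper.sd_delta_prior, n)
    de = rng.normal(hyper.mu_delta_evidence, hyper.sd_delta_evidence, n)
    xs = rng.normal(hyper.mu_xshift, hyper.sd_xshift, n)
    # ensure the atomoxetine-session sigmas stay positive
    dp = np.maximum(dp, -0.9 * sp)
    de = np.maximum(de, -0.9 * se)
    return [
        ObserverParams(sp[i], se[i], dp[i], de[i], xs[i], motor_noise_sd)
        for i in range(n)
    ]


def _counterbalanced_orders(n: int, rng: np.random.Generator) -> list[tuple[str, str]]:
    """Drug order permuted in blocks of six (three placebo-first per block)."""
    orders: list[tuple[str, str]] = []
    remaining = n
    while remaining > 0:
        block = min(6, remaining)
        half = block // 2
        labels = [("placebo", "atomoxetine")] * (block - half) + [
            ("atomoxetine", "placebo")
        ] * half
        rng.shuffle(labels)
        orders.extend(labels)
        remaining -= block
    return orders


def simulate_cohort(
    cohort: CohortConfig | None = None,
    hyper: GroupHyperParams | None = None,
    design: TaskDesign | None = None,
    seed: int | None = None,
    discretize: bool = True,
) -> tuple[list[SessionData], pd.DataFrame]:
    """Simulate a full crossover cohort.

    Controls complete one session (condition "none"); PD participants
    complete placebo and atomoxetine sessions in counterbalanced order.
    Participant parameters are drawn from the group-level distributions and
    then adjusted so that (a) prior weighting decreases with apathy at the
    standardized slope ``coupling_apathy_w`` and (b) the drug-induced change
    in prior weighting covaries with locus coeruleus CNR at standardized
    slope ``coupling_cnr_delta``.  The covariate table records the true
    prior weighting of every session.

    All randomness flows from the master ``seed`` through per-participant
    derived streams, so any session can be reproduced in isolation.
    """
    cohort = cohort or CohortConfig()
    hyper = hyper or GroupHyperParams()
    design = design or TaskDesign()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n_total = cohort.n_pd + cohort.n_controls
    session_seeds = [int(s) for s in rng.integers(2**31, size=2 * n_total)]

    def standardized_mix(coupling: float, z: np.ndarray) -> np.ndarray:
        noise = rng.normal(size=len(z))
        return coupling * z + np.sqrt(1.0 - coupling**2) * noise

    lo_w, hi_w = cohort.w_bounds
    sessions: list[SessionData] = []
    cov_rows: list[dict] = []
    seed_ix = 0

    def make_participant(group: str, idx: int, apathy_z: float, cnr_z: float,
                         w_z: float, dw_z: float):
        apathy = int(np.clip(
            round(cohort.apathy_mean + cohort.apathy_sd * apathy_z),
            *cohort.apathy_range,
        ))
        lc_cnr = cohort.lc_cnr_mean + cohort.lc_cnr_sd * cnr_z
        base = draw_observer_params(hyper, 1, rng)[0]
        w_plc = float(np.clip(cohort.w_mean + cohort.w_sd * w_z, lo_w, hi_w))
        if cohort.calibrate_evidence_noise:
            # match the estimation-error spread to the performance-error
            # spread (as observed empirically), so slope-based w estimates
            # are neither attenuated nor inflated
            sigma_e = base.motor_noise_sd * np.sqrt((1.0 + w_plc) / (2.0 - w_plc))
        else:
            sigma_e = base.sigma_evidence
        sigma_p = sigma_e * np.sqrt((1.0 - w_plc) / w_plc)
        if group == "PD":
            dw = cohort.delta_w_sd * dw_z
            w_atx = float(np.clip(w_plc + dw, lo_w, hi_w))
            sigma_e_atx = max(sigma_e + base.delta_evidence, 0.1 * sigma_e)
            sigma_p_atx = sigma_e_atx * np.sqrt((1.0 - w_atx) / w_atx)
            params = ObserverParams(
                sigma_prior=float(sigma_p),
                sigma_evidence=float(sigma_e),
                delta_prior=float(sigma_p_atx - sigma_p),
                delta_evidence=float(sigma_e_atx - sigma_e),
                x_shift=base.x_shift,
                motor_noise_sd=base.motor_noise_sd,
            )
        else:
            w_atx = np.nan
            params = ObserverParams(
                sigma_prior=float(sigma_p), sigma_evidence=float(sigma_e),
                x_shift=base.x_shift, motor_noise_sd=base.motor_noise_sd,
            )
        return params, apathy, lc_cnr, w_plc, w_atx

    # PD participants: crossover with counterbalanced order
    apathy_z_pd = rng.normal(size=cohort.n_pd)
    cnr_z_pd = rng.normal(size=cohort.n_pd)
    w_z_pd = standardized_mix(cohort.coupling_apathy_w, apathy_z_pd)
    dw_z_pd = standardized_mix(cohort.coupling_cnr_delta, cnr_z_pd)
    orders = _counterbalanced_orders(cohort.n_pd, rng)
    for i in range(cohort.n_pd):
        pid = f"PD{i + 1:02d}"
        params, apathy, lc_cnr, w_plc, w_atx = make_participant(
            "PD", i, apathy_z_pd[i], cnr_z_pd[i], w_z_pd[i], dw_z_pd[i]
        )
        ledd = float(np.clip(rng.normal(450.0, 200.0), 0.0, None))
        updrs = int(np.clip(round(rng.normal(30.0, 10.0)), 0, 132))
        for order, condition in enumerate(orders[i], start=1):
            sess = simulate_session(
                params, design, condition, seed=session_seeds[seed_ix],
                discretize=discretize, participant_id=pid, group="PD",
                session_order=order,
            )
            seed_ix += 1
            sessions.append(sess)
            cov_rows.append(dict(
                participant_id=pid, group="PD", condition=condition,
                session_order=order, apathy=apathy, lc_cnr=lc_cnr,
                ledd=ledd, updrs_iii=updrs,
                w_true=params.w_prior(condition),
                delta_w_true=w_atx - w_plc,
                sigma_prior_true=params.sigma_prior,
                sigma_evidence_true=params.sigma_evidence,
                delta_prior_true=params.delta_prior,
                delta_evidence_true=params.delta_evidence,
                x_shift_true=params.x_shift,
                iqr_performance_error=sess.iqr_performance_error(),
            ))

    # controls: single session, no drug
    apathy_z_c = rng.normal(size=cohort.n_controls)
    cnr_z_c = rng.normal(size=cohort.n_controls)
    w_z_c = standardized_mix(cohort.coupling_apathy_w, apathy_z_c)
    for i in range(cohort.n_controls):
        pid = f"C{i + 1:02d}"
        params, apathy, lc_cnr, w_plc, _ = make_participant(
            "control", i, apathy_z_c[i], cnr_z_c[i], w_z_c[i], 0.0
        )
        sess = simulate_session(
            params, design, "none", seed=session_seeds[seed_ix],
            discretize=discretize, participant_id=pid, group="control",
            session_order=1,
        )
        seed_ix += 1
        sessions.append(sess)
        cov_rows.append(dict(
            participant_id=pid, group="control", condition="none",
            session_order=1, apathy=apathy, lc_cnr=lc_cnr,
            ledd=np.nan, updrs_iii=np.nan,
            w_true=params.w_prior("none"), delta_w_true=np.nan,
            sigma_prior_true=params.sigma_prior,
            sigma_evidence_true=params.sigma_evidence,
            delta_prior_true=0.0, delta_evidence_true=0.0,
            x_shift_true=params.x_shift,
            iqr_performance_error=sess.iqr_performance_error(),
        ))

    covariates = pd.DataFrame(cov_rows)
    return sessions, covariates


def write_cohort(
    sessions: list[SessionData],
    covariates: pd.DataFrame,
    out_dir: str | Path,
    config: dict | None = None,
) -> dict[str, str]:
    """Persist a cohort as trials.csv + covariates.csv + metadata.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for s in sessions:
        df = s.trials.copy()
        df.insert(0, "participant_id", s.participant_id)
        df.insert(1, "group", s.group)
        df.insert(2, "condition", s.condition)
        df.insert(3, "session_order", s.session_order)
        frames.append(df)
    trials = pd.concat(frames, ignore_index=True)
    trials_path = out / "trials.csv"
    cov_path = out / "covariates.csv"
    meta_path = out / "metadata.json"
    trials.to_csv(trials_path, index=False)
    covariates.to_csv(cov_path, index=False)
    meta = {
        "config": config or {},
        "session_seeds": {
            f"{s.participant_id}/{s.condition}": s.seed for s in sessions
        },
        "n_sessions": len(sessions),
    }
    meta_path.write_text(json.dumps(meta, indent=2, default=str))
    return {"trials": str(trials_path), "covariates": str(cov_path),
            "metadata": str(meta_path)}


def read_cohort(in_dir: str | Path) -> tuple[list[SessionData], pd.DataFrame]:
    """Read a cohort previously written by :func:`write_cohort`."""
    src = Path(in_dir)
    trials = pd.read_csv(src / "trials.csv")
    covariates = pd.read_csv(src / "covariates.csv")
    sessions = []
    keys = ["participant_id", "condition"]
    for (pid, cond), g in trials.groupby(keys, sort=False):
        g = g.reset_index(drop=True)
        sessions.append(SessionData(
            participant_id=str(pid),
            group=str(g["group"].iloc[0]),
            condition=str(cond),
            session_order=int(g["session_order"].iloc[0]),
            trials=g.drop(columns=["participant_id", "group", "condition",
                                   "session_order"]),
        ))
    return sessions, covariates
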