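"""MCMC diagnostics, information criteria, and posterior predictive checks.

R-hat is the rank-normalised split potential scale reduction factor
(maximum of the bulk and folded variants), implemented directly; WAIC is
computed from the pointwise log-likelihood with the variance-based
effective-parameter penalty; PSIS-LOO is delegated to arviz.  Both criteria
are reported on the deviance scale (-2 x elpd).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import logsumexp

__all__ = [
    "compute_rhat",
    "compute_ess",
    "ICResult",
    "waic_from_loglik",
    "loo_from_loglik",
    "compare_models",
    "PPCResult",
    "posterior_predictive_check",
]


def _split_chains(x: np.ndarray) -> np.ndarray:
    """Split each chain in half, doubling the chain count."""
    c, n = x.shape
    half = n // 2
    return np.concatenate([x[:, :half], x[:, n - half:]], axis=0)


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    """Fractional ranks over the pooled draws mapped through the normal
    quantile function (Blom offsets)."""
    flat = x.ravel()
    ranks = sps.rankdata(flat, method="average")
    z = sps.norm.ppf((ranks - 3.0 / 8.0) / (flat.size + 1.0 / 4.0))
    return z.reshape(x.shape)


def _basic_rhat(x: np.ndarray) -> float:
    """Classic between/within R-hat on an array of shape (chains, draws)."""
    c, n = x.shape
    chain_means = x.mean(axis=1)
    chain_vars = x.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    var_plus = (n - 1.0) / n * w + b / n
    if w == 0.0:
        return 1.0
    return float(np.sqrt(var_plus / w))


def compute_rhat(draws: np.ndarray) -> float:
    """Rank-normalised split R-hat for one parameter.

    Parameters
    ----------
    draws
        Array of shape (chains, draws), post-warmup.

    Returns the maximum of the bulk (rank-normalised) and folded
    (rank-normalised absolute deviation from the median) split R-hat,
    following the modern convergence-diagnostic recommendation.
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim != 2:
        raise ValueError("draws must have shape (chains, draws)")
    if x.shape[0] < 2:
        raise ValueError("R-hat requires at least 2 chains")
    if x.shape[1] < 4:
        raise ValueError("R-hat requires at least 4 draws per chain")
    if np.ptp(x) == 0.0:
        return 1.0
    split = _split_chains(x)
    bulk = _basic_rhat(_rank_normalize(split))
    folded = _basic_rhat(_rank_normalize(np.abs(split - np.median(split))))
    return max(bulk, folded)


def compute_ess(draws: np.ndarray) -> float:
    """Bulk effective sample size (delegated to arviz)."""
    import arviz as az

    x = np.asarray(draws, dtype=float)
    if x.ndim != 2:
        raise ValueError("draws must have shape (chains, draws)")
    return float(np.asarray(az.ess(az.convert_to_dataset(x[..., None]))["x"]).ravel()[0])


@dataclass(frozen=True)
class ICResult:
    """One information criterion on the deviance scale."""

    value: float
    se: float
    p_eff: float
    pointwise: np.ndarray
    pareto_k: np.ndarray | None = None


def waic_from_loglik(loglik: np.ndarray) -> ICResult:
    """Widely applicable information criterion from a pointwise
    log-likelihood matrix.

    ``loglik`` has shape (total draws, n observations) or (chains, draws,
    n).  WAIC_i = -2 (lppd_i - p_i) with lppd_i the log of the posterior-
    mean likelihood of observation i and p_i the posterior variance of its
    log-likelihood; the SE is sqrt(n var(WAIC_i)).
    """
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim == 3:
        ll = ll.reshape(-1, ll.shape[-1])
    s, n = ll.shape
    lppd_i = logsumexp(ll, axis=0) - np.log(s)
    p_i = ll.var(axis=0, ddof=1)
    waic_i = -2.0 * (lppd_i - p_i)
    value = float(waic_i.sum())
    se = float(np.sqrt(n * waic_i.var(ddof=1)))
    return ICResult(value=value, se=se, p_eff=float(p_i.sum()), pointwise=waic_i)


def loo_from_loglik(loglik: np.ndarray) -> ICResult:
    """PSIS leave-one-out information criterion (via arviz) on the deviance
    scale; ``loglik`` has shape (chains, draws, n)."""
    import arviz as az
    import xarray as xr

    ll = np.asarray(loglik, dtype=float)
    if ll.ndim == 2:
        ll = ll[None, ...]
    idata = az.from_dict(
        posterior={"dummy": np.zeros(ll.shape[:2])},
        log_likelihood={"obs": ll},
    )
    res = az.loo(idata, pointwise=True)
    pointwise = -2.0 * np.asarray(res.loo_i)
    return ICResult(
        value=float(-2.0 * res.elpd_loo),
        se=float(2.0 * res.se),
        p_eff=float(res.p_loo),
        pointwise=pointwise,
        pareto_k=np.asarray(res.pareto_k),
    )


def compare_models(fits: dict) -> "pd.DataFrame":
    """Information-criterion table across model variants fit to the same data.

    ``fits`` maps a variant name to a :class:`~priorweight.hierarchical.
    PosteriorSamples` with a stored pointwise log-likelihood.  Reports WAIC
    and PSIS-LOOIC (deviance scale) with standard errors, and pairwise
    differences to the best (lowest) variant with pointwise difference SEs.
    """
    import pandas as pd

    if not fits:
        raise ValueError("no fits supplied")
    ns = set()
    results = {}
    for name, fit in fits.items():
        ll = fit.loglik
        if ll is None:
            raise ValueError(f"fit {name!r} has no stored pointwise log-likelihood")
        ns.add(ll.shape[-1])
        results[name] = (waic_from_loglik(ll), loo_from_loglik(ll))
    if len(ns) != 1:
        raise ValueError("fits were computed on mismatched trial sets")
    n = ns.pop()
    best_waic = min(results, key=lambda k: results[k][0].value)
    best_loo = min(results, key=lambda k: results[k][1].value)
    rows = []
    for name, (w, l) in results.items():
        dw_i = w.pointwise - results[best_waic][0].pointwise
        dl_i = l.pointwise - results[best_loo][1].pointwise
        rows.append(dict(
            variant=name,
            waic=w.value, waic_se=w.se, p_waic=w.p_eff,
            looic=l.value, looic_se=l.se, p_loo=l.p_eff,
            d_waic=float(dw_i.sum()),
            d_waic_se=float(np.sqrt(n * dw_i.var(ddof=1))),
            d_looic=float(dl_i.sum()),
            d_looic_se=float(np.sqrt(n * dl_i.var(ddof=1))),
            pareto_k_max=float(np.max(l.pareto_k)),
        ))
    return pd.DataFrame(rows).sort_values("looic").reset_index(drop=True)


@dataclass
class PPCResult:
    """Posterior predictive check summaries.

    ``replicated`` holds simulated estimation responses (one row per used
    posterior draw, one column per estimation trial); ``residual_means`` the
    per-participant mean of observed minus replicated responses per draw.
    """

    replicated: np.ndarray        # (n_draws_used, n_trials)
    residual_means: np.ndarray    # (n_draws_used, n_participants)
    participant_ids: list
    draw_indices: np.ndarray


def posterior_predictive_check(samples, data=None, seed=None, n_draws: int = 200) -> PPCResult:
    """Simulate replicated estimation responses from the posterior.

    For each of ``n_draws`` retained posterior draws (a thinned subset, or
    every draw if fewer are available), replicated responses are drawn from
    the trial-wise predictive normal N(mean_n, sd_n) implied by that draw's
    participant parameters, and the per-participant mean residual (observed
    minus replicated) is recorded.
    """
    if data is None:
        data = samples.data
    rng = np.random.default_rng(seed)
    total = samples.n_chains * samples.n_draws
    k = min(n_draws, total)
    idx = np.linspace(0, total - 1, k).astype(int)
    means, sds = samples.predictive_params(data, idx)
    replicated = rng.normal(means, sds)
    obs = data.x_estimate
    resid = obs[None, :] - replicated
    p = len(data.participant_ids)
    counts = np.bincount(data.pidx, minlength=p)
    residual_means = np.stack(
        [np.bincount(data.pidx, weights=resid[d], minlength=p) / counts
         for d in range(k)]
    )
    return PPCResult(
        replicated=replicated,
        residual_means=residual_means,
        participant_ids=list(data.participant_ids),
        draw_indices=idx,
    )
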