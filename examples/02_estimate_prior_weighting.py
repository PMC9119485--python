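"""Estimate prior weighting from estimation trials.

Simulates one observer with a known prior weighting, then recovers it with
the slope estimator: estimation errors regressed on performance errors
(z-scored within session, no intercept) have slope -w.  The per-session and
random-slope mixed estimates are compared on a small cohort.
"""

import priorweight as pw

w_true = 0.45
observer = pw.observer_for_w(w_true)
session = pw.simulate_session(observer, condition="none", seed=2)
est = pw.estimate_prior_weighting([session], method="per-session")
row = est.iloc[0]
print(f"single session: true w = {w_true}, "
      f"estimated w = {row.w_hat:.3f} (se {row.se:.3f}, "
      f"{row.n_trials} estimation trials)")

sessions, covariates = pw.simulate_cohort(
    pw.CohortConfig(n_pd=6, n_controls=4), seed=3)
per = pw.estimate_prior_weighting(sessions, method="per-session")
mixed = pw.estimate_prior_weighting(sessions, method="mixed")
merged = per.merge(mixed, on="session_id", suffixes=("_per", "_mixed"))
print("\nper-session vs mixed (partial pooling shrinks noisy sessions):")
print(merged[["session_id", "w_hat_per", "w_hat_mixed"]]
      .round(3).to_string(index=False))
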