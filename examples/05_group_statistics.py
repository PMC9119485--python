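"""The group-level inferential battery on a simulated cohort.

Runs the apathy regression, the drug x locus-coeruleus-CNR mixed model,
the Pitman paired-variance test, the Johnson-Neyman moderation analysis,
and default-prior (JZS) Bayes factors, printing each result with its
degrees of freedom.
"""

import numpy as np

import priorweight as pw
from priorweight.stats import (
    fit_drug_cnr_model, johnson_neyman, jzs_bayes_factor, pitman_test,
    regress_apathy,
)

sessions, covariates = pw.simulate_cohort(seed=10)
est = pw.estimate_prior_weighting(sessions, method="per-session")
merged = est.merge(covariates, on=["participant_id", "condition"])

# apathy regression over the normative sessions (controls + PD placebo)
tab = regress_apathy(merged[merged["condition"].isin(["none", "placebo"])])
row = tab.set_index("term").loc["apathy"]
print(f"apathy -> w:   beta = {row.beta:+.2f}, SE {row.se:.2f}, "
      f"t({int(row.df)}) = {row.t:+.2f}, p = {row.p:.3f}")
bf = jzs_bayes_factor("t-test one-sample", row.t, n=int(row.df) + 1)
print(f"               JZS BF10 ~ {bf:.2f}")

# drug x LC CNR mixed model over the PD crossover sessions
drug = fit_drug_cnr_model(
    merged[merged["condition"].isin(["placebo", "atomoxetine"])])
inter = drug.table.set_index("term").loc["drug:lc_cnr"]
print(f"drug x LC CNR: beta = {inter.beta:+.2f}, "
      f"F(1,{int(inter.df_den)}) = {inter.F:.2f}, p = {inter.p:.3f}")
r = drug.correlation
print(f"corr(dw, CNR): r({r['df']}) = {r['r']:+.2f}, p = {r['p']:.3f}, "
      f"BF10 = {jzs_bayes_factor('correlation', r['r'], n=r['df'] + 2):.2f}")

# paired-variance test: does the drug compress between-subject spread?
wide = merged[merged["condition"].isin(["placebo", "atomoxetine"])] \
    .pivot_table(index="participant_id", columns="condition", values="w_hat")
pit = pitman_test(wide["placebo"].to_numpy(), wide["atomoxetine"].to_numpy())
print(f"Pitman:        t({pit.df}) = {pit.t:+.2f}, p = {pit.p:.3f}")

# Johnson-Neyman: for which apathy scores does CNR predict the drug effect?
jn_df = drug.delta_w.merge(
    covariates[covariates["group"] == "PD"]
    [["participant_id", "apathy"]].drop_duplicates(), on="participant_id")
region, _ = johnson_neyman(jn_df, "delta_w", "lc_cnr", "apathy")
print(f"JN region:     {region.region}, thresholds (Apathy Scale units): "
      f"{[round(t, 1) for t in region.thresholds_raw]}")
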