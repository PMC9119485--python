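"""Parameter-recovery study for the slope-based w estimator.

For each generating prior weighting on a grid, many sessions are simulated
through the observer model (responses snapped to the 12-option grid) and
re-estimated; the table reports the median and 95% quantile interval of the
estimates.  Medians hugging the identity line show the estimator is
unbiased at the study's design size of 40 estimation trials.
"""

from priorweight.weighting import run_parameter_recovery

res = run_parameter_recovery(
    [0.1, 0.3, 0.5, 0.7, 0.9], n_sims=500, seed=4)
print(res.table.round(3).to_string(index=False))
print("\nmedian bias per grid point:",
      {w: round(b, 3) for w, b in res.median_bias.items()})
print("(the interval width reflects 40-trial sampling noise, not bias)")
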