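"""Benchmark empirical variable selection against the standard baselines
with split-sample validation.

Four methods are fitted to the same synthetic dataset: the ranked nested
series (best model by AIC), the all-subsets comparator (lowest-AIC
level-best model), forward stepwise selection at P-to-enter 0.05, and the
full model.  Ten cases are then withheld at random, every method is
refitted on the remaining forty, and hold-out predictions are regressed
against the actual values: honest R² (higher = better out-of-sample fit)
and honest RSS (lower = smaller error).
"""

from revs import SyntheticSpec, compare_methods, generate_synthetic

data = generate_synthetic(
    SyntheticSpec(
        n=50, p=10, effects={0: 1.0, 3: 1.0, 6: 1.0},
        correlation="equicorrelation", rho=0.3, sigma=1.0, seed=5,
    )
)
result = compare_methods(data, holdout=10, seed=7)

frame = result.to_frame()
cols = ["k", "adj_r2", "aic", "delta_aic", "p_value",
        "honest_r2", "honest_rss"]
print(frame[cols].to_string(float_format=lambda v: f"{v:.4g}"))
print(
    "\nThe full model carries every noise predictor (delta AIC well above"
    "\n10 = essentially no support); the selected sparse models match it"
    "\nor beat it out of sample with a fraction of the parameters."
)
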