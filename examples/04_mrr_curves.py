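"""Age-specific mortality rate ratios with delta-method confidence bands.

Compares the most deprived quintile with the least deprived reference for
males, locates the age of the largest relative inequality, and shows at
which ages the 95% band excludes a ratio of 1.
"""

import warnings

import deplife as dl

warnings.simplefilter("ignore")

result = dl.run_pipeline(
    dl.PipelineConfig(simulation=dl.SimulationConfig(n_individuals=100_000, seed=1))
)

curve = result.mrr.query("sex == 'male' and quintile == 5")
print("MRR q5 vs q1, males (every 10th age):")
print(curve.iloc[::10][["age", "mrr", "ci_low", "ci_high"]]
      .round(3).to_string(index=False))

age, mrr, (lo, hi) = dl.mrr_peak(curve, age_window=(30, 90))
print(f"\nlargest relative inequality: MRR = {mrr:.2f} [{lo:.2f}; {hi:.2f}] "
      f"at age {age}")

mask = dl.significance_mask(curve)
sig_ages = mask[mask].index
print(f"CI excludes 1 at {mask.mean():.0%} of ages "
      f"(from {sig_ages.min()} to {sig_ages.max()})" if mask.any()
      else "CI never excludes 1")
print("\nUnder the proportional-hazards truth (HR = 2) the curve is flat;")
print("with real data it typically peaks in midlife and fades at old ages.")
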