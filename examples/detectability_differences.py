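"""Paired comparison of reconstruction algorithms per dose level.

Each reader contributes one detectability score per (algorithm, dose) cell;
algorithms are compared against FBP with a paired Student's t-test
(19 degrees of freedom for 20 readers), reported in percentage points.
"""

import lcdetect as lc

records, _ = lc.clean_responses(lc.simulate_trials(lc.PipelineConfig()))
table = lc.compare_all(records, reference="FBP")

print("difference in detectability vs FBP, percentage points (95% CI):")
for _, row in table.iterrows():
    print(f"  {row.algorithm:>4s} at {row.dose_mGy:4.0f} mGy: "
          f"{row.mean_diff_pp:+5.1f} p.p. "
          f"({row.ci_low_pp:+5.1f}, {row.ci_high_pp:+5.1f}), p={row.p_value:.3f}")
print("\npositive differences mean the algorithm detects low-contrast")
print("lesions better than FBP at the same dose; p-values are two-sided.")
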