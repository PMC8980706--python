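"""Simulate the 20-reader 2AFC study and look at the raw trial table.

Builds the full-factorial schedule (600 comparisons per reader), randomizes
the signal-present side and presentation order, draws responses from the
default psychometric ground truth and flags one response invalid.
"""

import lcdetect as lc

config = lc.PipelineConfig()  # the default 20-reader study, seed 20220402
records = lc.simulate_trials(config)
cleaned, log = lc.clean_responses(records)

print(f"simulated {log['n_input']} comparisons, "
      f"{log['n_excluded']} discarded, {log['n_retained']} analysed")
print(records[["reader_id", "algorithm", "dose_mGy", "lesion_type",
               "signal_side", "chosen_side", "correct"]].head(5).to_string())

cells = lc.aggregate(cleaned, ["algorithm", "dose_mGy"])
print("\ndetectability per (algorithm, dose) cell — the fraction of trials")
print("where the signal-present image was correctly chosen (0.5 = guessing):")
print(cells.pivot(index="dose_mGy", columns="algorithm",
                  values="detectability").round(3).to_string())
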