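"""Call binary vs graded expression with the dip test + Gaussian mixtures.

For each condition the dip test decides whether the log-fluorescence
distribution is bimodal; only then is a two-component mixture fitted and the
percent-positive taken as the upper-component weight.  Unimodal (graded)
conditions are gated against the unimmunized control instead.
"""

from il2field.expression import analyze_table
from il2field.synthetic import GeneratorConfig, generate_dataset

config = GeneratorConfig(events_per_condition=8000, seed=2)
events = generate_dataset(config, populations=("Th_tg",),
                          doses=(0.0, 31.0, 125.0, 500.0, 2000.0),
                          times=(14.0,), markers=("IL2", "CD25"))
summary = analyze_table(events, alpha=0.05, n_boot=200, seed=2)

cols = ["marker", "dose_ug", "call", "dip_p", "percent_positive", "mode_high"]
print(summary[cols].sort_values(["marker", "dose_ug"]).to_string(index=False,
                                                                 float_format="%.3g"))
print("\nIL-2 is called binary once enough producers exist (strong doses);")
print("CD25 is graded at every dose: its location shifts, no second mode appears.")
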