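"""Fit the producer-fraction curve phi(A) from per-dose summaries.

The percent of IL-2-secreting Th cells per dose, estimated by the mixture
stage, is fitted with a monotone Hill curve on the normalized stimulus scale
A = dose / 2000 µg.  phi feeds the spatial model: it sets how many producers
exist (binary scenario) or how fast each producer secretes (graded scenario).
"""

from il2field.doseresponse import StimulusMapping, fit_stimulus_curve
from il2field.expression import analyze_table
from il2field.synthetic import GeneratorConfig, generate_dataset

config = GeneratorConfig(events_per_condition=8000, seed=3)
events = generate_dataset(config, populations=("Th_tg",), times=(14.0,),
                          markers=("IL2",))
summary = analyze_table(events, n_boot=200, seed=3).sort_values("dose_ug")

fit = fit_stimulus_curve(summary.dose_ug, summary.percent_positive / 100,
                         StimulusMapping(), fix_floor=0.0)
c = fit.curve
print("fitted producer-fraction curve:")
print(f"  ceiling (p_max) = {c.ceiling:.3f}   (fraction of Th secreting at 2 mg)")
print(f"  half-point A50  = {c.a50:.4f}    (~{2000 * c.a50:.0f} µg antigen)")
print(f"  Hill h          = {c.h:.2f}")
print(f"  residual SS     = {fit.rss:.2e}")
print("\nphi(A) at the experimental doses:")
for d in (0, 31, 125, 500, 2000):
    print(f"  {d:>5} µg -> phi = {c.value(d / 2000):.3f}")
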