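"""Generate synthetic flow-cytometry events across antigen doses.

Builds the default single-cell event table for transgenic Th cells at 14 h
post-immunization and prints, per dose, the fraction of IL-2-secreting cells
(binary readout: the dose moves the producing fraction) and the CD25 mean
fluorescence (graded readout: the dose moves the per-cell level).
"""

import numpy as np

from il2field.synthetic import GeneratorConfig, generate_dataset

config = GeneratorConfig(events_per_condition=5000, seed=1)
events = generate_dataset(config, populations=("Th_tg",),
                          times=(14.0,), markers=("IL2", "CD25"))

print(f"{'dose (µg)':>10} {'IL-2+ (%)':>10} {'CD25 MFI':>10}")
for dose in config.dose_grid:
    il2 = events.query("marker == 'IL2' and dose_ug == @dose").fi
    cd25 = events.query("marker == 'CD25' and dose_ug == @dose").fi
    pct = 100 * np.mean(np.log10(il2) > 1.5)   # midpoint between the components
    print(f"{dose:>10.0f} {pct:>10.1f} {cd25.mean():>10.0f}")

print("\nThe IL-2-positive fraction climbs toward 75% while CD25 MFI rises")
print("continuously: binary cytokine secretion, graded receptor expression.")
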