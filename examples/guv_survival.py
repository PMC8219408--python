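"""GUV dye-release viability: normalize traces, critical times, survival.

Synthetic single-vesicle fluorescence traces (1 frame/min after peptide
arrival) emulate a population in which a quarter of the vesicles lyse
(exponential lysis times, 60 min mean) and the rest survive with only
photobleaching.  A vesicle's critical viability time is the first frame its
normalized intensity drops below 50%.
"""

import numpy as np

from memrupt import (
    normalize_traces,
    order_heatmap,
    survival_curve,
    synth_guv_traces,
    viability_table,
)

raw = synth_guv_traces(
    n=300,
    survivor_fraction=0.75,
    lysis_time_dist=("exponential", 60.0),
    rng_seed=5,
)
normalized = normalize_traces(raw)
table = viability_table(normalized)
times, surviving = survival_curve(table)

n_lysed = int(np.sum(~np.isnan(table.critical_times)))
print(f"vesicles analysed: {len(table.vesicle_ids)}; lysed: {n_lysed}")
print(f"median critical time of lysed vesicles: "
      f"{np.nanmedian(table.critical_times):.0f} min")
for t in (60, 120, 240, 360):
    idx = np.searchsorted(times, t, side="right") - 1
    print(f"survival at {t:3d} min: {surviving[idx]:.2f}")

order = order_heatmap(normalized, table)
print(f"heatmap row order (first 5, fastest lysis first): {order[:5]}")
print(
    "\nThe survival plateau near 0.75 recovers the simulated survivor"
    "\nfraction; a fully membranolytic peptide would drive survival to zero"
    "\nwithin a few hundred minutes."
)
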