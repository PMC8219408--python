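"""Classical pore energetics and the circular-vs-fractal regime criterion.

E(r) = 2 pi r gamma - pi r^2 sigma trades edge energy against released
tension: pores below r_c = gamma/sigma reseal, larger ones expand over the
barrier E* = pi gamma^2 / sigma.  When the rupture front outruns edge
relaxation (perimeter scale above L_c = sqrt(gamma/(xi nu))), the circular
shape is unreachable and fingering interfaces appear.
"""

from memrupt import (
    MembraneParams,
    classify_mode,
    critical_length,
    critical_radius,
    energy_barrier,
)

params = MembraneParams(
    sigma=1e-3,   # lateral tension, N/m
    gamma=1e-11,  # line tension, N
    xi=1e8,       # friction coefficient (model units)
    nu=1e-6,      # rupture front speed, m/s
)

r_c = critical_radius(params)
E_star = energy_barrier(params)
L_c = critical_length(params)
print(f"critical pore radius   r_c = {r_c * 1e9:.1f} nm")
print(f"nucleation barrier     E*  = {E_star:.3e} J")
print(f"critical length scale  L_c = {L_c * 1e6:.3f} um")

for L in (0.1e-6, 1e-6):
    regime = classify_mode(L, params)
    print(
        f"perimeter L = {L * 1e6:.1f} um -> {regime.mode}"
        f" (tau_p = {regime.tau_p:.2f} s)"
    )
print(
    "\nPores smaller than r_c reseal; ruptures whose perimeter exceeds L_c"
    "\ncannot maintain a circular edge and grow as fingering patterns."
)
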