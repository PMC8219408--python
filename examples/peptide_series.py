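"""Build the bienA/bienK truncation series and report masses and composition.

The template RLLRL-X-LRLLR is a minimal binary-encoded amphipathic helix:
arginines form the cationic face, leucines the hydrophobic face, and the
single mutation slot X (alanine -> bienA, lysine -> bienK) decides whether
the peptide porates bilayers or tears fractal ruptures in the upper leaflet.
"""

from memrupt import (
    TEMPLATE,
    average_mass,
    build_series,
    hydrophobic_cationic_ratio,
    monoisotopic_mass,
    wheel_projection,
)

for mutation in "AK":
    print(f"\nbien{mutation} series (C-terminally amidated, C-anchored windows)")
    print(f"{'name':<10} {'sequence':<12} {'avg mass':>9} {'mono mass':>10} {'H/C':>5}")
    for p in build_series(TEMPLATE, mutation, range(7, 12)):
        stats = hydrophobic_cationic_ratio(p)
        print(
            f"{p.name:<10} {p.residues:<12} {average_mass(p):9.1f} "
            f"{monoisotopic_mass(p):10.2f} {stats.ratio:5.2f}"
        )

# Helical wheel of the 9-mer lysine variant: 100 degrees per residue places
# the mutation inside the hydrophobic face, splitting it into two subfaces.
(p,) = build_series(TEMPLATE, "K", [9])
wheel = wheel_projection(p)
print(f"\nHelical wheel of {p.name}:")
for i, (code, angle, face) in enumerate(zip(p.residues, wheel.angles, wheel.face_labels)):
    print(f"  residue {i + 1} ({code}) at {angle:5.0f} deg  [{face}]")
print(
    "\nMasses are neutral average/monoisotopic values in Da; H/C is the"
    "\nhydrophobic (L, A) to cationic (R, K) residue ratio - above 1 for"
    "\nevery biologically active member (9-mers and longer)."
)
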