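# memrupt

Analysis machinery for a nanoscale membrane-disruption switch: ultrashort
binary-encoded amphipathic helices (arginine/leucine, template
`RLLRL-X-LRLLR`) either open circular transmembrane pores (X = Ala,
"bienA") or tear branching, fractal ruptures confined to the upper
bilayer leaflet (X = Lys, "bienK").  `memrupt` packages the quantitative
machinery needed to study that switch on synthetic or user-supplied
data:

* **`memrupt.peptides`** — construct the bienA/bienK truncation series
  (7–11-mers), neutral average/monoisotopic masses with the C-terminal
  amide correction, helical-wheel projection (100°/residue), and
  hydrophobic-to-cationic composition statistics.
* **`memrupt.energetics`** — classical pore energetics
  `E(r) = 2πrγ − πr²σ` with barrier `E* = πγ²/σ` at `r_c = γ/σ`, and the
  growth-regime criterion: ruptures of perimeter scale `L` above
  `L_c = √(γ/(ξν))` outrun edge relaxation and grow as fingering
  (Saffman–Taylor-like) interfaces instead of circles.
* **`memrupt.growth`** — seeded lattice simulators for the two
  morphologies: Eden growth (compact, pore-like) and diffusion-limited
  aggregation (fingering, fractal), plus rasterized discs and
  area/perimeter/isoperimetric statistics.
* **`memrupt.afm`** — AFM height-map analysis: line-by-line flattening
  and plane removal, defect segmentation, monolayer-vs-transmembrane
  depth classification, cross-section profiles, and box-counting fractal
  dimension (grid-aligned and sliding-box variants).
* **`memrupt.assays`** — GUV dye-release viability (trace normalization,
  50% critical viability time, right-censored survival curves, heatmap
  ordering), MIC endpoints, hemolysis percentages, and CD
  mean-residue-ellipticity conversion.
* **`memrupt.scenes`** — synthetic AFM scenes with exact ground truth
  (stamped defects, tilt, Gaussian roughness) and analytic fractal
  fixtures (Sierpinski carpet) for estimator validation.

## Worked example

Build the lysine series and check the switch-relevant numbers
(`examples/peptide_series.py` prints the full table):

```python
>>> from memrupt import build_series, average_mass, hydrophobic_cationic_ratio
>>> (p,) = build_series(mutation_residue="K", lengths=[11])
>>> p.residues, round(average_mass(p), 1)
('RLLRLKLRLLR', 1448.9)
>>> hydrophobic_cationic_ratio(p).ratio
1.2
```

The amidated 11-mer weighs 1448.9 Da (the value a MALDI-ToF "calc" mass
list reports) and keeps a hydrophobic-to-cationic ratio above 1 — the
composition regime in which the single A→K mutation, not gross
composition, decides the disruption mode.

Simulate the two rupture regimes and measure their morphology
(`examples/rupture_growth.py`):

```
compact (Eden)   area =  80000 nm^2  perimeter =  8624 nm  isoperimetric ratio =   74.0  box dimension = 1.82
fingering (DLA)  area =  80000 nm^2  perimeter = 67960 nm  isoperimetric ratio = 4594.2  box dimension = 1.57
disc             area =  79952 nm^2  perimeter =  1264 nm  isoperimetric ratio =    1.6
```

At matched area the fingering cluster carries an ~8× larger perimeter
than the compact one and a lower box-counting dimension — "large
perimeters and small areas", the signature of upper-leaflet fractal
rupture.  `examples/afm_morphometry.py` pushes such a pattern through
the full AFM pipeline (flatten → segment → classify → fractal
dimension) and recovers the half-depth monolayer class with mask IoU
1.0 at 0.1 nm noise; `examples/guv_survival.py` recovers a 0.75
survivor plateau from 300 synthetic dye-release traces.

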