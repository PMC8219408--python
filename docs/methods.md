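# Methods

This note records the models implemented in `memrupt`, the defaults and
tolerances chosen where the underlying study leaves the choice open, and
what the synthetic-data pipeline does and does not establish about real
data.

## Peptide series and masses

The series template `RLLRL-X-LRLLR` is an idealized three-turn
amphipathic helix: arginines at the `i, i+3/i+4` spacings form the
cationic face, leucines the hydrophobic face, and the single slot X
(position 6) carries the mutation — alanine (bienA) or lysine (bienK).
Truncated members are contiguous end-anchored windows of the template;
because the template is palindromic at the composition level, N- and
C-anchored windows of equal length have identical residue compositions
and therefore identical masses, and the default truncation end (`"C"`)
is a labelling convention, not a physical claim.  The mutation slot must
survive truncation; it does for every length 7–11.

Masses are neutral molecular masses: the sum of standard 4-decimal
average (or monoisotopic) residue masses plus one water
(18.0153 / 18.010565 Da), minus 0.9847 / 0.98402 Da when the C terminus
is amidated (OH → NH₂; all synthesized members are amidated).  Reported
"calc" m/z values for such peptides are conventionally compared at
±0.2 Da, which absorbs one-decimal rounding and residue-table
differences; all ten series values agree at that tolerance.  Note the
values match *neutral* amidated masses, not [M+H]⁺ — the package
reports neutral masses.

Composition statistics count L and A as hydrophobic and R and K as
cationic.  Lysine is counted cationic even when it sits in the
hydrophobic face: the ratio is a charge-classification statistic, and
under this convention every active member (9-mers and longer) has ratio
> 1.  The helical wheel uses exactly 100°/residue (360°/3.6) with no
winding correction.

## Continuum pore energetics

The bilayer is a thin elastic sheet under lateral tension σ (N/m) with
pore edge (line) tension γ (N):

    E(r) = 2πrγ − πr²σ,   E* = πγ²/σ,   r_c = γ/σ.

These identities are exact and tested at machine precision against a
brute-force grid maximization.  For growth dynamics only the derived
scalar criteria are implemented, not the full tension-gradient flow
equation (∇σ = ξv − μ∇²v): propagation time τ_p = L/ν, edge relaxation
time τ_r = (ξ/γ)·L^k, and critical perimeter scale L_c = √(γ/(ξν)),
above which the front outruns edge relaxation and fingering interfaces
appear.  The printed linear form of τ_r (k = 1) is dimensionally
inconsistent with that L_c under any single unit convention for ξ; with
k = 3 the crossing τ_p = τ_r falls exactly at L_c.  Both exponents are
exposed (default 1, as printed) and neither is asserted as canonical.
Units are caller-supplied and not auto-converted — the friction
coefficient ξ has no unambiguous published unit here, so dimensional
policing would impose an interpretation the theory does not give.  The
tie L = L_c classifies as circular (closed threshold, fixed convention).

## Rupture-growth simulators

No growth rule is available from the underlying physics (an elastic
model of upper-leaflet rupture is explicitly open); the simulators are
the minimal classical pair realizing the compact-vs-fingering
dichotomy, used as *model surrogates*:

* **compact** — Eden growth: each step occupies a uniformly random
  empty 8-neighbor perimeter site of the cluster.
* **fingering** — on-lattice DLA: walkers launch from a circle of
  radius r_cluster + 5 px, are abandoned beyond 2× the launch radius,
  take 4-neighbor steps (with long jumps while far from the cluster),
  and attach with probability `stickiness` when 8-adjacent to the
  cluster.  The walker loop is numba-compiled with an internal seeded
  RNG; one RNG stream per simulation, no global state.

Conventions: 8-connectivity for cluster membership and defect
labelling; 4-neighbor foreground/background edge count for perimeters.
The edge-count perimeter of a rasterized disc is its Manhattan length
(~8r), so the isoperimetric ratio perimeter²/(4π·area) has a floor of
4/π for a single cell and ≈ 16/π² ≈ 1.62 for large discs; the statistic
is meaningful as a *relative* compactness measure (fingering clusters
score 10²–10³× above discs of equal area).  On-lattice DLA grows with
cluster radius ≈ N^(1/1.66); lattices must be provisioned accordingly
or growth aborts with a boundary-overflow error rather than silently
truncating the pattern.

## AFM analysis

Flattening mirrors standard AFM post-processing: per scan line a
polynomial (order 0–2, default 1) is least-squares fit to *background*
pixels — those within 1.5×MAD of the line median, so defects do not
drag the fit — and subtracted; a global least-squares plane fit to the
background follows, and the background median is set to zero.  Rows
with fewer background pixels than requested fall back to median
subtraction and are flagged in metadata.  After flattening, defects are
negative heights; segmentation thresholds at −`depth_threshold`,
labels 8-connected components, and records area, edge-count perimeter
and mean depth per defect.

Depth classes quantify "half" and "full" bilayer depth: mean depth in
[0.35, 0.65]×thickness → monolayer (upper-leaflet disruption);
≥ 0.8×thickness → transmembrane; otherwise indeterminate.  The bands
are this package's quantification (configurable); the bilayer thickness
is a required user input.

### Box-counting fractal dimension

`fractal_dimension` fits −slope of log N(s) vs log s over ≥ 4 box
sizes (default: powers of two from 2 px to min-dimension/4).

* **box** — occupied cells of a grid aligned to the array origin.
* **sliding_box** — the occupied-box count averaged over all s² grid
  offsets, with each offset's grid tiling from its anchor and far-edge
  boxes truncated.  Every pixel anchors exactly one box across the
  offset ensemble, so the average equals (occupied anchors)/s².  This
  form is exact on filled rectangles and axis-aligned lines and exactly
  translation-invariant for content at least s pixels off the top/left
  edges; the grid-aligned variant can shift by ~0.1 under translation
  (grid-phase sensitivity is precisely what offset averaging removes).

Validation uses analytic fixtures: a 243×243 Sierpinski carpet
(similarity dimension log 8/log 3 ≈ 1.8928; both methods agree within
0.05 of it), the filled square (exactly 2) and a single row (exactly 1
for both methods).  `fixture_sierpinski(k)` builds the 3^k-grid carpet
with 8^k foreground cells.

For grown clusters, `cluster_fractal_dimension` crops to the foreground
bounding box and fits over five power-of-two sizes ending at (bounding
box)/4: boxes comparable to the 1-px branch width of a DLA cluster
probe the lattice cutoff (local dimension → 1), while boxes comparable
to the cluster read it as a single blob, and this window brackets the
usable scaling regime for both morphologies.  Under this protocol
20 000-particle DLA clusters measure ≈ 1.6–1.7 and Eden clusters
≈ 1.85–1.90 — the finite-time Eden boundary is rough and porous, so
compact clusters read below the asymptotic 2 at any window touching
their rim.  The regime dichotomy (compact exceeding fingering by well
over 0.15) is robust to this.

## GUV viability and endpoint assays

Traces are sampled at 1 frame/min with t = 0 at peptide arrival.
Normalization subtracts the background (per-vesicle scalar or per-time
array) and divides by the initial intensity, the mean of the first
3 samples at t ≥ 0 (configurable; the window is not defined by the
source protocol).  Vesicles with non-positive initial intensity are
excluded with a warning.  The critical viability time is the *first
sampled* time the normalized trace drops *strictly* below 0.5 — no
sub-frame interpolation, which would be spurious at 1 frame/min; a
trace touching exactly 0.5 is not counted.  Survivors are
right-censored at the last sampled time, never imputed; the survival
curve is the empirical fraction with no critical time ≤ t (direct
counting — with censoring only at the horizon this coincides with the
Kaplan–Meier estimate).  Heatmap ordering sorts ascending critical
time, censored last, ties by vesicle id.

MIC follows the broth-microdilution reading: the lowest concentration
of a strictly-descending two-fold series with no visible growth such
that all higher concentrations are also clear; growth at the top
concentration → "not reached".  Hemolysis is
100·(A_sample − A_buffer)/(A_water − A_buffer), clipped to [0, 100]
with the raw value retained.  CD conversion:
MRE = θ_mdeg/(10·l_cm·c_M·n_bonds); for amidated peptides the
C-terminal amide counts as a peptide bond (n_bonds = n_residues,
configurable to n − 1).

### Synthetic traces

`synth_guv_traces` emulates the population structure of dye-release
data: each vesicle survives with probability `survivor_fraction`
(intensity only photobleaches, default 2×10⁻⁴/min, ~7% over 6 h) or
draws a lysis time (exponential, default mean 60 min, or uniform) and
decays by a step to a residual fraction (default 0.2) or exponentially.
Baselines vary ±20% between vesicles around 100 a.u. over a constant
background of 10 a.u., with i.i.d. Gaussian noise (default SD 2 a.u.).
All draws come from one seeded generator; equal configurations give
byte-identical trace sets.

## Synthetic AFM scenes

`synth_afm` stamps defects (rasterized discs, grown clusters, or
explicit masks) at −depth_fraction × thickness into a zero background,
then adds an optional tilt plane and i.i.d. Gaussian roughness
(defaults emulate the flat-to-within-angstroms supported bilayer:
0.1 nm roughness on a 3 nm bilayer).  Edges are hard steps — no tip
convolution, for which no model is available; an optional Gaussian edge
blur exists for robustness testing.  Scan-line-correlated noise is not
simulated (the line-wise flattening path is exercised by the tilt term
instead).  Overlapping defects are rejected because their ground truth
would be ambiguous.

**What passing on synthetic scenes shows** — that flattening,
segmentation, depth classification and fractal estimation recover known
ground truth through realistic tilt and roughness levels (100% class
recovery, mask IoU ≥ 0.9 at 0.1 nm noise over 50 seeds).  **What it
does not show** — robustness to tip-shape convolution, scan-line noise,
drift between frames, or real peptide-lipid edge chemistry; and the
fractal dimensions printed for real rupture data (~1.73–1.91) are not
reproduced here, since the raw images behind them are unavailable —
estimator correctness is instead established on analytic fixtures.

## Problem sizes

Default validation sizes were chosen to make sampling error negligible
relative to the tested tolerances while keeping the suite fast on a
laptop: 20 seeds × 20 000 particles for the regime dichotomy (seed SD
of the dimension ≈ 0.01), 50 scenes at 256² for recovery, and 500
traces per survivor fraction (binomial SE ≈ 0.02 against a ±0.05
tolerance).
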