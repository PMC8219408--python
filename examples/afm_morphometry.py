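"""Analyze a synthetic AFM scene: flatten, segment, classify, estimate dimension.

A 256 x 256 supported-bilayer topograph (4 nm/px, 3 nm bilayer) carries one
half-depth fingering rupture, plus plane tilt and 0.1 nm roughness.  The
pipeline removes the background, segments defects below a depth threshold,
classifies each as monolayer (upper-leaflet) or transmembrane, and measures
the rupture's box-counting fractal dimension.
"""

from memrupt import (
    DefectSpec,
    GrowthConfig,
    SceneConfig,
    flatten,
    segment_defects,
    synth_afm,
)
from memrupt.afm import cluster_fractal_dimension

THICKNESS = 3.0  # nm
config = SceneConfig(
    lattice_size=256,
    pixel_size=4.0,
    bilayer_thickness=THICKNESS,
    defects=(
        DefectSpec(
            "fractal",
            depth_fraction=0.5,
            growth=GrowthConfig(256, 4.0, "fingering", n_cells=1500, rng_seed=21),
        ),
    ),
    noise_sd=0.1,
    tilt=(0.002, -0.001),
    rng_seed=21,
)
height_map, truth = synth_afm(config)

flat = flatten(height_map)
defects = segment_defects(flat, depth_threshold=0.25 * THICKNESS, bilayer_thickness=THICKNESS)
print(defects.records.to_string(index=False))

largest = defects.records.sort_values("area_nm2").iloc[-1]
mask = defects.labels == largest["id"]
iou = (mask & truth.masks[0]).sum() / (mask | truth.masks[0]).sum()
est = cluster_fractal_dimension(mask)
print(f"\nground-truth class: {truth.classes[0]}, recovered IoU = {iou:.3f}")
print(f"rupture box-counting dimension = {est.dimension:.2f} +/- {est.stderr:.2f}")
print(
    "\nMean depth near half the bilayer thickness marks upper-leaflet"
    "\n(monolayer) disruption; a full-depth defect would be transmembrane."
)
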