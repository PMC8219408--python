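"""Synthetic AFM scenes with ground truth, plus analytic fractal fixtures.

Emulates in-liquid AFM topographs of supported bilayers: a flat
background at height 0 carrying circular full-depth pores and/or fractal
half-depth ruptures stamped as hard negative steps, with an optional
plane tilt and i.i.d. Gaussian roughness.  Every scene returns its
ground truth (per-defect mask, depth, class) so recovery by the analysis
pipeline can be scored exactly.  Scan-line correlated noise and tip
convolution are not simulated; an optional Gaussian edge blur is
available for robustness testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy import ndimage

from .afm import HeightMap, classify_depth
from .growth import GrowthConfig, RuptureMask, grow_circular_pore, grow_pattern

__all__ = [
    "DefectSpec",
    "SceneConfig",
    "GroundTruth",
    "synth_afm",
    "fixture_sierpinski",
    "fixture_catalog",
]


@dataclass(frozen=True)
class DefectSpec:
    """One defect to stamp into a scene.

    kind: "circular" (radius_px), "fractal" (growth config), or "mask"
    (an explicit RuptureMask); depth_fraction: fraction of the bilayer
    thickness removed, in (0, 1]; position: (row, col) center in the
    scene, default scene center.
    """

    kind: str
    depth_fraction: float
    radius_px: float | None = None
    growth: GrowthConfig | None = None
    mask: RuptureMask | None = None
    position: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"circular", "fractal", "mask"}:
            raise ValueError("kind must be circular|fractal|mask")
        if not 0.0 < self.depth_fraction <= 1.0:
            raise ValueError("depth_fraction must be in (0, 1]")
        if self.kind == "circular" and not self.radius_px:
            raise ValueError("circular defect requires radius_px")
        if self.kind == "fractal" and self.growth is None:
            raise ValueError("fractal defect requires a GrowthConfig")
        if self.kind == "mask" and self.mask is None:
            raise ValueError("mask defect requires a RuptureMask")


@dataclass(frozen=True)
class SceneConfig:
    """Full description of a synthetic AFM scene."""

    lattice_size: int
    pixel_size: float
    bilayer_thickness: float
    defects: tuple[DefectSpec, ...] = ()
    noise_sd: float = 0.0
    tilt: tuple[float, float] = (0.0, 0.0)  # nm/px along (row, col)
    rng_seed: int = 0
    edge_blur_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bilayer_thickness <= 0:
            raise ValueError("bilayer_thickness must be > 0")
        object.__setattr__(self, "defects", tuple(self.defects))


@dataclass
class GroundTruth:
    """True per-defect masks, depths (nm) and classes, plus the config."""

    masks: list[np.ndarray]
    depths_nm: list[float]
    classes: list[str]
    config: SceneConfig


def _defect_mask(spec: DefectSpec, size: int) -> np.ndarray:
    """Full-scene boolean mask for one defect spec."""
    if spec.kind == "circular":
        src = grow_circular_pore(spec.radius_px, size, 1.0).grid
        return _recenter(src, size, spec.position)
    if spec.kind == "fractal":
        src = grow_pattern(spec.growth).grid
    else:
        src = spec.mask.grid
    return _recenter(src, size, spec.position)


def _recenter(src: np.ndarray, size: int, position: tuple[int, int] | None) -> np.ndarray:
    """Embed src (cropped to its foreground bounding box) centered at position."""
    rows = np.any(src, axis=1)
    cols = np.any(src, axis=0)
    r0, r1 = rows.argmax(), len(rows) - rows[::-1].argmax()
    c0, c1 = cols.argmax(), len(cols) - cols[::-1].argmax()
    crop = src[r0:r1, c0:c1]
    h, w = crop.shape
    if position is None:
        position = (size // 2, size // 2)
    top = position[0] - h // 2
    left = position[1] - w // 2
    if top < 0 or left < 0 or top + h > size or left + w > size:
        raise ValueError("defect does not fit the scene at the requested position")
    out = np.zeros((size, size), dtype=bool)
    out[top : top + h, left : left + w] = crop
    return out


def synth_afm(config: SceneConfig) -> tuple[HeightMap, GroundTruth]:
    """Render a scene and its ground truth.

    Background height 0; each defect stamped at
    -depth_fraction * bilayer_thickness; then optional edge blur, tilt
    plane, and Gaussian noise.  Overlapping defects are an error (the
    ground truth would be ambiguous).  Deterministic per seed.
    """
    size = config.lattice_size
    heights = np.zeros((size, size))
    occupancy = np.zeros((size, size), dtype=bool)
    masks, depths, classes = [], [], []
    for spec in config.defects:
        m = _defect_mask(spec, size)
        if (occupancy & m).any():
            raise ValueError("overlapping defects: ground truth would be ambiguous")
        occupancy |= m
        depth = spec.depth_fraction * config.bilayer_thickness
        heights[m] = -depth
        masks.append(m)
        depths.append(depth)
        classes.append(classify_depth(depth, config.bilayer_thickness))
    if config.edge_blur_sd > 0:
        heights = ndimage.gaussian_filter(heights, config.edge_blur_sd)
    rr, cc = np.mgrid[:size, :size]
    heights = heights + config.tilt[0] * rr + config.tilt[1] * cc
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.rng_seed)
        heights = heights + rng.normal(0.0, config.noise_sd, heights.shape)
    hm = HeightMap(heights, config.pixel_size, metadata={"synthetic": True})
    return hm, GroundTruth(masks, depths, classes, config)


def fixture_sierpinski(iterations: int, pixel_size: float = 1.0) -> RuptureMask:
    """Sierpinski carpet on a 3**iterations grid (center-third removal).

    An analytic fractal (dimension log 8 / log 3 ~ 1.8928) for validating
    the box-counting estimator.  iterations=1 is the 3x3 cell with the
    center removed; foreground count is 8**iterations.
    """
    if not 1 <= iterations <= 6:
        raise ValueError("iterations must be in 1..6")
    grid = np.ones((1, 1), dtype=bool)
    for _ in range(iterations):
        n = grid.shape[0]
        new = np.zeros((3 * n, 3 * n), dtype=bool)
        for bi in range(3):
            for bj in range(3):
                if bi == 1 and bj == 1:
                    continue
                new[bi * n : (bi + 1) * n, bj * n : (bj + 1) * n] = grid
        grid = new
    return RuptureMask(grid, pixel_size, provenance=f"sierpinski iterations={iterations}")


@dataclass(frozen=True)
class FixtureRecord:
    """A named deterministic fixture with machine-readable expectations."""

    name: str
    kind: str  # "mask" | "height_map" | "trace_set"
    build: object  # zero-argument callable
    expected: dict


def fixture_catalog() -> list[FixtureRecord]:
    """The deterministic test-fixture suite with expected values.

    Regenerating the catalog yields identical inputs (fixed seeds
    throughout).  Expected values carry their tolerances.
    """
    from .assays import synth_guv_traces

    def carpet5():
        return fixture_sierpinski(5)

    def flat128():
        return HeightMap(np.zeros((128, 128)), 4.0, metadata={"synthetic": True})

    def disc_full_depth():
        cfg = SceneConfig(
            lattice_size=128,
            pixel_size=4.0,
            bilayer_thickness=3.0,
            defects=(DefectSpec("circular", 1.0, radius_px=20),),
        )
        return synth_afm(cfg)

    def dla_half_depth():
        cfg = SceneConfig(
            lattice_size=256,
            pixel_size=4.0,
            bilayer_thickness=3.0,
            defects=(
                DefectSpec(
                    "fractal",
                    0.5,
                    growth=GrowthConfig(
                        lattice_size=256,
                        pixel_size=4.0,
                        mode="fingering",
                        n_cells=1500,
                        rng_seed=11,
                    ),
                ),
            ),
            noise_sd=0.1,
            rng_seed=11,
        )
        return synth_afm(cfg)

    def eden_mask():
        return grow_pattern(
            GrowthConfig(128, 4.0, "compact", n_cells=3000, rng_seed=3)
        )

    def guv_mixed():
        return synth_guv_traces(n=200, survivor_fraction=0.75, rng_seed=7)

    return [
        FixtureRecord(
            "carpet4",
            "mask",
            carpet5,
            # the 243x243 carpet used for estimator validation
            {"dimension": np.log(8) / np.log(3), "tol": 0.05},
        ),
        FixtureRecord("flat128", "height_map", flat128, {"n_defects": 0}),
        FixtureRecord(
            "disc_full_depth",
            "height_map",
            disc_full_depth,
            {"depth_class": "transmembrane", "depth_nm": 3.0},
        ),
        FixtureRecord(
            "dla_half_depth",
            "height_map",
            dla_half_depth,
            {"depth_class": "monolayer", "depth_nm": 1.5, "iou_min": 0.9},
        ),
        FixtureRecord(
            "eden3000", "mask", eden_mask, {"dimension_min": 1.8, "n_cells": 3000}
        ),
        FixtureRecord(
            "guv_survivors_075",
            "trace_set",
            guv_mixed,
            {"plateau": 0.75, "tol": 0.08},
        ),
    ]
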