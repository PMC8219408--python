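"""Seeded lattice simulators for rupture-growth morphologies.

The continuum picture distinguishes two regimes of membrane rupture
growth: below the critical perimeter scale the edge relaxes fast enough
to keep the energetically favoured circular shape; above it the front
outruns edge relaxation and fingering, branched interfaces develop.  The
paper-scale physics gives only the regime, not a growth rule, so this
module realizes the dichotomy with the minimal pair of classical lattice
models:

* compact mode -- Eden growth (uniform random accretion on the cluster
  perimeter), producing dense, near-circular clusters with box-counting
  dimension ~2;
* fingering mode -- diffusion-limited aggregation (random walkers
  attaching to the cluster), producing dendritic clusters with dimension
  ~1.71.

These are model surrogates for the observed morphologies, not a derived
membrane theory.  Both are deterministic given the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit

__all__ = [
    "GrowthConfig",
    "RuptureMask",
    "BoundaryOverflowError",
    "grow_pattern",
    "grow_circular_pore",
    "perimeter_area_stats",
    "save_mask",
    "load_mask",
]


class BoundaryOverflowError(RuntimeError):
    """Cluster reached the lattice boundary; rerun with a larger lattice."""


@dataclass(frozen=True)
class GrowthConfig:
    """Parameters of one growth simulation.

    lattice_size: pixels per side (square lattice), >= 64
    pixel_size: nm per pixel
    mode: "compact" (Eden) or "fingering" (DLA)
    n_cells: target foreground count
    stickiness: attachment probability per contact (fingering only), (0, 1]
    rng_seed: seed of the single RNG stream for this simulation
    launch_pad: walker launch radius = cluster radius + launch_pad (px)
    kill_factor: walkers beyond kill_factor * launch radius are relaunched
    """

    lattice_size: int
    pixel_size: float
    mode: str
    n_cells: int
    stickiness: float = 1.0
    rng_seed: int = 0
    launch_pad: float = 5.0
    kill_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.lattice_size < 64:
            raise ValueError("lattice_size must be >= 64")
        if self.mode not in {"compact", "fingering"}:
            raise ValueError("mode must be 'compact' or 'fingering'")
        if not 0.0 < self.stickiness <= 1.0:
            raise ValueError("stickiness must be in (0, 1]")
        if not 0 < self.n_cells < self.lattice_size**2 / 4:
            raise ValueError("n_cells must be in (0, lattice_size^2 / 4)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass
class RuptureMask:
    """Binary rupture footprint on a square lattice.

    Foreground marks disrupted lipid.  For simulator output the
    foreground is a single 8-connected cluster containing the lattice
    center.
    """

    grid: np.ndarray
    pixel_size: float
    provenance: object = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2D")


_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _grow_eden(config: GrowthConfig) -> np.ndarray:
    """Eden accretion: each step occupies a uniformly random perimeter site."""
    size = config.lattice_size
    rng = np.random.default_rng(config.rng_seed)
    grid = np.zeros((size, size), dtype=bool)
    c = size // 2
    grid[c, c] = True
    # perimeter = empty 8-neighbors of the cluster; list + index map for O(1)
    # uniform removal.
    perim: list[tuple[int, int]] = []
    where: dict[tuple[int, int], int] = {}

    def push(site):
        if site not in where:
            where[site] = len(perim)
            perim.append(site)

    def pop_random():
        i = int(rng.integers(len(perim)))
        site = perim[i]
        last = perim[-1]
        perim[i] = last
        where[last] = i
        perim.pop()
        del where[site]
        return site

    for dr, dc in _NEIGHBORS8:
        push((c + dr, c + dc))
    placed = 1
    while placed < config.n_cells:
        r, col = pop_random()
        grid[r, col] = True
        placed += 1
        if r <= 0 or col <= 0 or r >= size - 1 or col >= size - 1:
            raise BoundaryOverflowError(
                "Eden cluster reached the lattice boundary; use a larger lattice_size"
            )
        for dr, dc in _NEIGHBORS8:
            site = (r + dr, col + dc)
            if not grid[site]:
                push(site)
    return grid


@njit(cache=False)
def _dla_core(grid, n_cells, stickiness, seed, launch_pad, kill_factor):  # pragma: no cover
    """Lattice DLA with circle launching and far-field jumps.

    Returns 0 on success, -1 if the cluster outgrew the lattice.
    """
    np.random.seed(seed)
    size = grid.shape[0]
    c = size // 2
    grid[c, c] = 1
    placed = 1
    rmax = 0.0
    while placed < n_cells:
        r_launch = rmax + launch_pad
        r_kill = kill_factor * r_launch + 10.0
        if c + r_launch >= size - 2:
            return -1
        theta = 2.0 * math.pi * np.random.random()
        x = int(round(c + r_launch * math.cos(theta)))
        y = int(round(c + r_launch * math.sin(theta)))
        while True:
            # out of bounds or beyond kill radius: abandon this walker
            if x < 1 or y < 1 or x >= size - 1 or y >= size - 1:
                break
            dx = x - c
            dy = y - c
            d = math.sqrt(dx * dx + dy * dy)
            if d > r_kill:
                break
            # far from the cluster: take one long jump toward nowhere in
            # particular (uniform direction, length = clearance)
            gap = d - (rmax + 2.0)
            if gap > 4.0:
                phi = 2.0 * math.pi * np.random.random()
                x = int(round(x + gap * math.cos(phi)))
                y = int(round(y + gap * math.sin(phi)))
                continue
            # contact check over the 8-neighborhood
            touching = (
                grid[x - 1, y - 1] or grid[x - 1, y] or grid[x - 1, y + 1]
                or grid[x, y - 1] or grid[x, y + 1]
                or grid[x + 1, y - 1] or grid[x + 1, y] or grid[x + 1, y + 1]
            )
            if touching and np.random.random() < stickiness:
                grid[x, y] = 1
                placed += 1
                if d > rmax:
                    rmax = d
                break
            # lattice step; never onto an occupied cell
            step = np.random.randint(0, 4)
            nx, ny = x, y
            if step == 0:
                nx = x + 1
            elif step == 1:
                nx = x - 1
            elif step == 2:
                ny = y + 1
            else:
                ny = y - 1
            if 0 <= nx < size and 0 <= ny < size and grid[nx, ny]:
                continue
            x, y = nx, ny
    return 0


def _grow_dla(config: GrowthConfig) -> np.ndarray:
    grid = np.zeros((config.lattice_size, config.lattice_size), dtype=np.uint8)
    status = _dla_core(
        grid,
        config.n_cells,
        config.stickiness,
        config.rng_seed % (2**31),
        config.launch_pad,
        config.kill_factor,
    )
    if status != 0:
        raise BoundaryOverflowError(
            "DLA cluster reached the lattice boundary; use a larger lattice_size"
        )
    return grid.astype(bool)


def grow_pattern(config: GrowthConfig) -> RuptureMask:
    """Grow a rupture mask in the configured regime.

    Compact mode runs Eden growth; fingering mode runs DLA with the
    configured stickiness.  The result has exactly ``n_cells`` foreground
    cells forming one 8-connected cluster around the lattice center, and
    is identical for identical configs (seed included).
    """
    if config.mode == "compact":
        grid = _grow_eden(config)
    else:
        grid = _grow_dla(config)
    return RuptureMask(grid, config.pixel_size, provenance=config)


def grow_circular_pore(
    radius_px: float, lattice_size: int, pixel_size: float
) -> RuptureMask:
    """Rasterized disc centered on the lattice (circular-pore morphology).

    A cell is foreground iff its center lies within ``radius_px`` of the
    lattice center.
    """
    if radius_px < 0.5:
        raise ValueError("radius_px must be >= 0.5 (at least the center cell)")
    c = lattice_size // 2
    if c + radius_px >= lattice_size - 0.5 or c - radius_px < -0.5:
        raise BoundaryOverflowError("disc exceeds the lattice; use a larger lattice_size")
    rr, cc = np.ogrid[:lattice_size, :lattice_size]
    grid = (rr - c) ** 2 + (cc - c) ** 2 <= radius_px**2
    return RuptureMask(grid, pixel_size, provenance=f"disc r={radius_px}px")


def perimeter_area_stats(mask: RuptureMask) -> dict:
    """Area, edge-count perimeter, and isoperimetric ratio of a mask.

    area = foreground count * pixel_size^2 (nm^2); perimeter = number of
    4-neighbor foreground/background edges (lattice border counts as
    background) * pixel_size (nm); isoperimetric ratio =
    perimeter^2 / (4 pi area), dimensionless.  Note the edge-count
    perimeter of a rasterized disc is the Manhattan length ~8r, so even
    ideal discs have ratio ~16/pi^2 ~ 1.62; a single cell gives 4/pi.
    The ratio is a relative compactness measure: fingering clusters score
    orders of magnitude above discs of equal area.
    """
    grid = mask.grid
    n = int(grid.sum())
    if n == 0:
        raise ValueError("empty mask")
    padded = np.pad(grid, 1, mode="constant")
    edges = 0
    for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neighbor = np.roll(padded, shift, axis=(0, 1))
        edges += int(np.sum(padded & ~neighbor))
    area = n * mask.pixel_size**2
    perimeter = edges * mask.pixel_size
    return {
        "area": area,
        "perimeter": perimeter,
        "isoperimetric_ratio": perimeter**2 / (4.0 * np.pi * area),
    }


# ---------------------------------------------------------------------------
# I/O: plain-text 0/1 matrix or single-channel 0/255 TIFF, with an optional
# JSON provenance sidecar.


def save_mask(mask: RuptureMask, path, sidecar: bool = True) -> None:
    path = Path(path)
    if path.suffix in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, (mask.grid.astype(np.uint8) * 255))
    else:
        np.savetxt(path, mask.grid.astype(np.uint8), fmt="%d")
    if sidecar:
        prov = mask.provenance
        if isinstance(prov, GrowthConfig):
            prov = {k: getattr(prov, k) for k in prov.__dataclass_fields__}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"pixel_size_nm": mask.pixel_size, "provenance": str(prov)})
        )


def load_mask(path, pixel_size: float) -> RuptureMask:
    path = Path(path)
    if path.suffix in {".tif", ".tiff"}:
        import tifffile

        grid = tifffile.imread(path) > 0
    else:
        grid = np.loadtxt(path) > 0
    return RuptureMask(grid, pixel_size, provenance=str(path))
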