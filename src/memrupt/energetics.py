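"""Continuum pore energetics and rupture-regime classification.

Classical thin-sheet model of a tensed bilayer: opening a pore of radius r
relieves lateral tension sigma over its area but pays line tension gamma
along its edge,

    E(r) = 2 pi r gamma - pi r^2 sigma,

giving a nucleation barrier E* = pi gamma^2 / sigma at the critical radius
r_c = gamma / sigma.  Pores below r_c reseal; above it they expand.

The circular shape is only reached if the pore edge can relax faster than
the rupture front advances.  Comparing the front propagation time
tau_p = L / nu with an edge relaxation time tau_r = (xi / gamma) L^k over
a perimeter scale L yields a critical length L_c = sqrt(gamma / (xi nu)):
above L_c the edge response is too slow and irregular, fingering
interfaces (Saffman-Taylor-like) appear instead of circular pores.

Units are caller-supplied SI unless noted and are not auto-converted; the
module validates positivity only.  The friction coefficient xi in
particular has no unambiguous published unit convention here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MembraneParams",
    "PoreEnergyProfile",
    "RuptureRegime",
    "pore_energy",
    "energy_barrier",
    "critical_radius",
    "pore_energy_profile",
    "propagation_time",
    "relaxation_time",
    "critical_length",
    "classify_mode",
]


@dataclass(frozen=True)
class MembraneParams:
    """Mechanical parameters of the bilayer.

    sigma: lateral tension (N/m), > 0
    gamma: pore edge (line) tension (N), > 0
    xi: friction coefficient (units as supplied), > 0
    nu: rupture front speed (m/s), >= 0
    mu: membrane viscosity (Pa s); carried for completeness, unused by the
        scalar criteria
    bilayer_thickness: nm, > 0
    """

    sigma: float
    gamma: float
    xi: float = 1.0
    nu: float = 0.0
    mu: float = 0.0
    bilayer_thickness: float = 3.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.xi <= 0:
            raise ValueError("xi must be > 0")
        if self.nu < 0:
            raise ValueError("nu must be >= 0")
        if self.bilayer_thickness <= 0:
            raise ValueError("bilayer_thickness must be > 0")


@dataclass(frozen=True)
class PoreEnergyProfile:
    """E(r) sampled on a radius grid, with the analytic barrier and r_c."""

    radii: np.ndarray
    energies: np.ndarray
    E_star: float
    r_c: float


@dataclass(frozen=True)
class RuptureRegime:
    """Timescale comparison for a rupture of perimeter scale L."""

    L: float
    tau_p: float
    tau_r: float
    L_c: float
    mode: str  # "circular" | "fractal"


def pore_energy(r, params: MembraneParams):
    """Pore opening energy E(r) = 2 pi r gamma - pi r^2 sigma (J).

    Accepts scalar or array radii (m); negative radii are a domain error.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("pore radius must be >= 0")
    E = 2.0 * np.pi * r * params.gamma - np.pi * r**2 * params.sigma
    return float(E) if E.ndim == 0 else E


def energy_barrier(params: MembraneParams) -> float:
    """Nucleation barrier E* = pi gamma^2 / sigma (J)."""
    return np.pi * params.gamma**2 / params.sigma


def critical_radius(params: MembraneParams) -> float:
    """Critical pore radius r_c = gamma / sigma (m); the argmax of E(r)."""
    return params.gamma / params.sigma


def pore_energy_profile(
    params: MembraneParams, r_max: float | None = None, n: int = 1000
) -> PoreEnergyProfile:
    """Sample E(r) on [0, r_max] (default 4 r_c) together with E*, r_c."""
    r_c = critical_radius(params)
    if r_max is None:
        r_max = 4.0 * r_c
    radii = np.linspace(0.0, r_max, n)
    return PoreEnergyProfile(
        radii=radii,
        energies=pore_energy(radii, params),
        E_star=energy_barrier(params),
        r_c=r_c,
    )


def propagation_time(L: float, params: MembraneParams) -> float:
    """Front propagation time tau_p = L / nu (s)."""
    if params.nu <= 0:
        raise ValueError("nu must be > 0 (nu = 0 means the front never propagates)")
    if L < 0:
        raise ValueError("perimeter scale L must be >= 0")
    return L / params.nu


def relaxation_time(L: float, params: MembraneParams, exponent: int = 1) -> float:
    """Edge relaxation time (xi / gamma) * L**exponent (model units).

    ``exponent=1`` is the form as printed; ``exponent=3`` makes the
    tau_p = tau_r crossing fall exactly at L_c = sqrt(gamma / (xi nu)).
    The linear form is dimensionally inconsistent with that L_c under any
    single unit choice for xi, so both are exposed.
    """
    if L < 0:
        raise ValueError("perimeter scale L must be >= 0")
    return (params.xi / params.gamma) * L**exponent


def critical_length(params: MembraneParams) -> float:
    """Critical perimeter scale L_c = sqrt(gamma / (xi nu)) (m)."""
    if params.nu <= 0:
        raise ValueError("nu must be > 0 to define L_c")
    return float(np.sqrt(params.gamma / (params.xi * params.nu)))


def classify_mode(L: float, params: MembraneParams) -> RuptureRegime:
    """Classify a rupture of perimeter scale L as circular or fractal.

    Fractal iff L > L_c; the tie L = L_c is classified circular (closed
    threshold on the circular side, fixed convention).
    """
    if L < 0:
        raise ValueError("perimeter scale L must be >= 0")
    L_c = critical_length(params)
    return RuptureRegime(
        L=L,
        tau_p=propagation_time(L, params),
        tau_r=relaxation_time(L, params),
        L_c=L_c,
        mode="fractal" if L > L_c else "circular",
    )
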