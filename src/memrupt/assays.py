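"""Vesicle dye-release viability, MIC/hemolysis endpoints, and CD conversion.

GUV dye-leakage experiments watch encapsulated fluorophore intensity in
single trapped vesicles after peptide arrival (t = 0, one frame per
minute).  A vesicle is compromised at its *critical viability time*: the
first sampled time its background-subtracted, initial-normalized
intensity drops strictly below 50%.  Populations are summarized as
right-censored survival curves; membranolytic peptides drive survival to
zero within hundreds of minutes while leaflet-selective ones leave a
surviving plateau.

Also here: the MIC endpoint rule for two-fold broth dilution series, the
hemolysis percentage against a water-lysed control, and conversion of raw
CD ellipticity to mean residue ellipticity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "TraceSet",
    "ViabilityTable",
    "CDSpectrum",
    "HemolysisResult",
    "normalize_traces",
    "critical_time",
    "viability_table",
    "survival_curve",
    "order_heatmap",
    "mic_endpoint",
    "hemolysis_percent",
    "mean_residue_ellipticity",
    "synth_guv_traces",
]


@dataclass
class TraceSet:
    """Per-vesicle fluorescence intensity traces on a shared time grid.

    times: minutes since peptide arrival (t = 0 at arrival), strictly
        increasing; intensities: (n_vesicles, n_times) array; background:
        scalar or per-time array already in the same units.
    """

    times: np.ndarray
    intensities: np.ndarray
    vesicle_ids: list[str]
    background: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.intensities.shape != (len(self.vesicle_ids), len(self.times)):
            raise ValueError("intensities must be (n_vesicles, n_times)")
        if self.times[0] > 0:
            raise ValueError("t = 0 (peptide arrival) must be present or bracketed")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_min": self.times})
        for i, vid in enumerate(self.vesicle_ids):
            df[vid] = self.intensities[i]
        if np.ndim(self.background) > 0 or self.background != 0.0:
            df["background"] = np.broadcast_to(self.background, self.times.shape)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TraceSet":
        df = pd.read_csv(path)
        if "time_min" not in df.columns:
            raise ValueError("trace CSV must have a 'time_min' first column")
        background = 0.0
        cols = [c for c in df.columns if c != "time_min"]
        if "background" in cols:
            bg = df["background"].to_numpy(float)
            background = float(bg[0]) if np.allclose(bg, bg[0]) else bg
            cols.remove("background")
        return cls(
            times=df["time_min"].to_numpy(float),
            intensities=df[cols].to_numpy(float).T,
            vesicle_ids=cols,
            background=background,
        )


@dataclass
class ViabilityTable:
    """Critical viability times per vesicle; NaN marks censored survivors."""

    vesicle_ids: list[str]
    critical_times: np.ndarray
    horizon: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vesicle_id": self.vesicle_ids,
                "critical_time_min": self.critical_times,
                "censored": np.isnan(self.critical_times),
            }
        )


@dataclass
class CDSpectrum:
    """Raw CD spectrum plus the quantities needed for MRE conversion."""

    wavelengths: np.ndarray
    ellipticity_mdeg: np.ndarray
    pathlength_cm: float
    peptide_conc_M: float
    n_residues: int
    n_peptide_bonds: int

    def __post_init__(self) -> None:
        if self.pathlength_cm <= 0 or self.peptide_conc_M <= 0:
            raise ValueError("pathlength and concentration must be > 0")
        if self.n_peptide_bonds < 1:
            raise ValueError("n_peptide_bonds must be >= 1")


class HemolysisResult(NamedTuple):
    percent: float       # clipped to [0, 100]
    raw_percent: float   # unclipped


def normalize_traces(raw: TraceSet, t_init_samples: int = 3) -> TraceSet:
    """Background-subtract and scale each trace to its initial intensity.

    The initial intensity is the mean of the first ``t_init_samples``
    samples at t >= 0.  Vesicles whose initial intensity is not positive
    after background subtraction are excluded with a warning.
    """
    keep_t = raw.times >= 0
    if keep_t.sum() < 3:
        raise ValueError("need at least 3 samples at t >= 0")
    times = raw.times[keep_t]
    inten = raw.intensities[:, keep_t] - np.broadcast_to(
        raw.background, raw.times.shape
    )[keep_t]
    init = inten[:, :t_init_samples].mean(axis=1)
    valid = init > 0
    if not valid.all():
        bad = [v for v, ok in zip(raw.vesicle_ids, valid) if not ok]
        warnings.warn(
            f"excluding {len(bad)} vesicle(s) with non-positive initial intensity: {bad}"
        )
    return TraceSet(
        times=times,
        intensities=inten[valid] / init[valid, None],
        vesicle_ids=[v for v, ok in zip(raw.vesicle_ids, valid) if ok],
        background=0.0,
    )


def critical_time(trace: np.ndarray, times: np.ndarray) -> float:
    """First sampled time a normalized trace drops strictly below 0.5.

    Returns NaN (censored) if the trace never crosses; a trace touching
    exactly 0.5 does not count.  No interpolation between samples: at
    1 frame/min sampling, sub-frame interpolation would be spurious.
    """
    trace = np.asarray(trace, dtype=float)
    below = trace < 0.5
    if not below.any():
        return float("nan")
    return float(np.asarray(times)[below.argmax()])


def viability_table(normalized: TraceSet) -> ViabilityTable:
    """Critical viability time for every vesicle of a normalized TraceSet."""
    ct = np.array(
        [critical_time(tr, normalized.times) for tr in normalized.intensities]
    )
    return ViabilityTable(
        vesicle_ids=list(normalized.vesicle_ids),
        critical_times=ct,
        horizon=float(normalized.times[-1]),
    )


def survival_curve(
    table: ViabilityTable, horizon: float | None = None, grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of vesicles with no critical time <= t, as a step curve.

    Censored vesicles count as surviving through the horizon (right
    censoring; no imputation).  Returns (times, fractions); the curve
    starts at 1 and is non-increasing.
    """
    n = len(table.vesicle_ids)
    if n == 0:
        raise ValueError("empty viability table")
    if horizon is None:
        horizon = table.horizon
    if grid is None:
        events = np.unique(table.critical_times[~np.isnan(table.critical_times)])
        grid = np.concatenate([[0.0], events[events <= horizon], [horizon]])
        grid = np.unique(grid)
    ct = table.critical_times[:, None]
    with np.errstate(invalid="ignore"):
        lysed = np.nansum((ct <= grid[None, :]) & ~np.isnan(ct), axis=0)
    return grid, 1.0 - lysed / n


def order_heatmap(traces: TraceSet, table: ViabilityTable) -> list[str]:
    """Row order for trace heatmaps: ascending critical time, censored last.

    Ties (and the all-censored block) break by vesicle id, so the order
    is a deterministic function of the data.
    """
    lookup = dict(zip(table.vesicle_ids, table.critical_times))
    missing = [v for v in traces.vesicle_ids if v not in lookup]
    if missing:
        raise ValueError(f"vesicles missing from viability table: {missing}")

    def key(vid: str):
        ct = lookup[vid]
        return (1, np.inf, vid) if np.isnan(ct) else (0, ct, vid)

    return sorted(traces.vesicle_ids, key=key)


def mic_endpoint(concentrations, growth_visible) -> float | None:
    """MIC from a descending two-fold dilution series.

    The MIC is the lowest concentration with no visible growth such that
    every higher concentration also shows none.  Returns None ("not
    reached") if growth persists at the top concentration.
    """
    conc = np.asarray(concentrations, dtype=float)
    growth = np.asarray(growth_visible, dtype=bool)
    if conc.shape != growth.shape:
        raise ValueError("concentrations and growth flags must align")
    if np.any(np.diff(conc) >= 0):
        raise ValueError("concentrations must be strictly decreasing")
    if growth[0]:
        return None
    if not growth.any():
        return float(conc[-1])
    first_growth = int(growth.argmax())
    return float(conc[first_growth - 1])


def hemolysis_percent(A_sample: float, A_buffer: float, A_water: float) -> HemolysisResult:
    """Percent hemolysis against the water-lysed (100%) control.

    100 * (A_sample - A_buffer) / (A_water - A_buffer), clipped to
    [0, 100] with the raw value retained.
    """
    if A_water <= A_buffer:
        raise ValueError("A_water must exceed A_buffer (water control = 100% lysis)")
    raw = 100.0 * (A_sample - A_buffer) / (A_water - A_buffer)
    return HemolysisResult(percent=float(np.clip(raw, 0.0, 100.0)), raw_percent=raw)


def mean_residue_ellipticity(spec: CDSpectrum) -> np.ndarray:
    """MRE (deg cm^2 dmol^-1 res^-1) from raw millidegree ellipticity.

    MRE(lambda) = theta_mdeg / (10 * pathlength_cm * conc_M * n_bonds).
    For C-terminally amidated peptides the amide counts as a peptide
    bond, so n_peptide_bonds defaults to n_residues in the generator
    below (configurable to n - 1).
    """
    denom = 10.0 * spec.pathlength_cm * spec.peptide_conc_M * spec.n_peptide_bonds
    if denom == 0:
        raise ValueError("zero denominator in MRE conversion")
    return np.asarray(spec.ellipticity_mdeg, dtype=float) / denom


def synth_guv_traces(
    n: int,
    survivor_fraction: float,
    lysis_time_dist: tuple = ("exponential", 60.0),
    decay: tuple = ("step", 0.2),
    noise_sd: float = 2.0,
    bleach_rate: float = 2e-4,
    rng_seed: int = 0,
    times: np.ndarray | None = None,
    baseline: float = 100.0,
    background: float = 10.0,
) -> TraceSet:
    """Generate synthetic dye-release traces with known ground truth.

    Each vesicle is a survivor with probability ``survivor_fraction``
    (its intensity only photobleaches at ``bleach_rate`` per minute,
    plus Gaussian noise); otherwise a lysis time is drawn from
    ``lysis_time_dist`` -- ("exponential", tau_min) or ("uniform", a, b)
    -- and intensity falls per the ``decay`` model: ("step", residual
    fraction) drops instantly to the residual, ("exponential", k_per_min)
    decays from the lysis time.  Baselines vary +/-20% between vesicles;
    a constant background offset is added.  Sampling is 1 frame/min over
    0..360 min unless ``times`` is given.  Deterministic per seed.
    """
    if not 0.0 <= survivor_fraction <= 1.0:
        raise ValueError("survivor_fraction must be in [0, 1]")
    if noise_sd < 0 or bleach_rate < 0:
        raise ValueError("noise_sd and bleach_rate must be >= 0")
    rng = np.random.default_rng(rng_seed)
    if times is None:
        times = np.arange(0.0, 361.0)
    times = np.asarray(times, dtype=float)

    kind = lysis_time_dist[0]
    if kind == "exponential":
        (tau,) = lysis_time_dist[1:]
        if tau <= 0:
            raise ValueError("exponential tau must be > 0")
        draw_lysis = lambda: rng.exponential(tau)
    elif kind == "uniform":
        a, b = lysis_time_dist[1:]
        if not 0 <= a < b:
            raise ValueError("uniform bounds must satisfy 0 <= a < b")
        draw_lysis = lambda: rng.uniform(a, b)
    else:
        raise ValueError(f"unknown lysis_time_dist {kind!r}")

    dkind = decay[0]
    if dkind == "step":
        residual = decay[1] if len(decay) > 1 else 0.2
        if not 0 <= residual < 0.5:
            raise ValueError("step residual must be in [0, 0.5) to register lysis")
    elif dkind == "exponential":
        k = decay[1]
        if k <= 0:
            raise ValueError("exponential decay rate must be > 0")
    else:
        raise ValueError(f"unknown decay model {dkind!r}")

    intensities = np.empty((n, len(times)))
    for i in range(n):
        i0 = baseline * rng.uniform(0.8, 1.2)
        trace = i0 * np.exp(-bleach_rate * times)
        if rng.random() >= survivor_fraction:
            t_lysis = draw_lysis()
            post = times >= t_lysis
            if dkind == "step":
                trace[post] *= residual
            else:
                trace[post] *= np.exp(-k * (times[post] - t_lysis))
        if noise_sd > 0:
            trace = trace + rng.normal(0.0, noise_sd, size=len(times))
        intensities[i] = trace + background
    return TraceSet(
        times=times,
        intensities=intensities,
        vesicle_ids=[f"guv{i:04d}" for i in range(n)],
        background=background,
    )
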