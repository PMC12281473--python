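"""Synthetic phantoms and forward signal models.

Generates the two kinds of raw data the pipeline consumes, with known ground
truth: variable-TR saturation-recovery stacks for T1 mapping, and 4D
T1-weighted time series under a gas-challenge paradigm. Regions are simple
geometric shapes (discs, boxes) on a single-slice grid; multi-slice data is
a pass-through dimension. Noise is additive Gaussian on the magnitude image
(sd = sigma * M0 per pixel), appropriate far above the noise floor; a Rician
mode is available behind a flag.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import reference as ref
from .types import GasSchedule, PhantomScene, Region, ScalarMap, ToldSeries, VariableTRSeries

__all__ = [
    "make_brain_phantom",
    "make_tube_phantom",
    "scene_t1_map",
    "scene_m0_map",
    "make_variable_tr_series",
    "make_told_series",
    "told_response",
]


def make_brain_phantom(grid_shape: tuple = (64, 64),
                       noise_sigma: float = 0.02,
                       m0: float = 100.0) -> PhantomScene:
    """Three-region mouse-brain phantom: cortex, ventricles, caudate nucleus.

    Per-gas ground-truth T1 defaults to the published group means for each
    region; challenge kinetics default to the published carbogen rise
    parameters, with the cortex consumption rate applied to all regions
    (only the cortex rate was measured).
    """
    cy, cx = grid_shape[0] // 2, grid_shape[1] // 2
    g = min(grid_shape)
    if g < 24:
        raise ValueError(f"grid too small for the three-region layout, got {grid_shape}")
    # cortex is an annulus; the two deep structures sit inside its hole
    r_out, r_in = g // 3, g // 5
    regions = [
        Region("cortex", 1, "disc", (cy, cx, r_out, r_in),
               t1_s=dict(ref.BRAIN_T1_S["cortex"]), m0=m0,
               s_max=ref.BRAIN_KINETICS_CARBOGEN["cortex"]["s_max"],
               t_ox_min=ref.BRAIN_KINETICS_CARBOGEN["cortex"]["t_ox_min"],
               k_oc_per_min=ref.CORTEX_K_OC_PER_MIN),
        Region("ventricles", 2, "disc", (cy, cx - g // 12, g // 16),
               t1_s=dict(ref.BRAIN_T1_S["ventricles"]), m0=m0,
               s_max=ref.BRAIN_KINETICS_CARBOGEN["ventricles"]["s_max"],
               t_ox_min=ref.BRAIN_KINETICS_CARBOGEN["ventricles"]["t_ox_min"],
               k_oc_per_min=ref.CORTEX_K_OC_PER_MIN),
        Region("caudate", 3, "disc", (cy, cx + g // 10, g // 16),
               t1_s=dict(ref.BRAIN_T1_S["caudate"]), m0=m0,
               s_max=ref.BRAIN_KINETICS_CARBOGEN["caudate"]["s_max"],
               t_ox_min=ref.BRAIN_KINETICS_CARBOGEN["caudate"]["t_ox_min"],
               k_oc_per_min=ref.CORTEX_K_OC_PER_MIN),
    ]
    return PhantomScene(grid_shape=grid_shape, regions=regions, noise_sigma=noise_sigma)


def make_tube_phantom(grid_shape: tuple = (64, 64),
                      noise_sigma: float = 0.02,
                      m0: float = 100.0) -> PhantomScene:
    """Two-tube cross-section phantom: a water disc and a corn-oil disc."""
    cy, cx = grid_shape[0] // 2, grid_shape[1] // 2
    r = min(grid_shape) // 6
    regions = [
        Region("water", 1, "disc", (cy, cx - r - 2, r),
               t1_s=dict(ref.PHANTOM_T1_S["water"]), m0=m0),
        Region("corn_oil", 2, "disc", (cy, cx + r + 2, r),
               t1_s=dict(ref.PHANTOM_T1_S["corn_oil"]), m0=m0),
    ]
    return PhantomScene(grid_shape=grid_shape, regions=regions, noise_sigma=noise_sigma)


def scene_t1_map(scene: PhantomScene, gas: str) -> ScalarMap:
    """Ground-truth T1 map (s) for one gas condition; background invalid."""
    vals = np.full(scene.grid_shape, np.nan)
    for reg in scene.regions:
        if gas not in reg.t1_s:
            raise KeyError(f"region {reg.name!r} has no T1 for gas {gas!r}")
        vals[reg.mask(scene.grid_shape)] = reg.t1_s[gas]
    return ScalarMap(vals, "s")


def scene_m0_map(scene: PhantomScene, include_background: bool = False) -> ScalarMap:
    vals = np.full(scene.grid_shape, scene.background_m0 if include_background else np.nan)
    for reg in scene.regions:
        vals[reg.mask(scene.grid_shape)] = reg.m0
    return ScalarMap(vals, "intensity")


def _apply_noise(clean: np.ndarray, sd: np.ndarray, rng: np.random.Generator,
                 rician: bool) -> np.ndarray:
    if rician:
        re = clean + rng.normal(0.0, 1.0, clean.shape) * sd
        im = rng.normal(0.0, 1.0, clean.shape) * sd
        return np.hypot(re, im)
    return clean + rng.normal(0.0, 1.0, clean.shape) * sd


def make_variable_tr_series(t1_map: ScalarMap,
                            m0_map: ScalarMap,
                            tr_s: Sequence[float],
                            noise_sigma: float = 0.0,
                            seed: Optional[int] = None,
                            rician: bool = False) -> VariableTRSeries:
    """Forward-model a saturation-recovery stack: M(TR) = M0 (1 - exp(-TR/T1)).

    Noise sd is ``noise_sigma * M0`` per pixel. Pixels invalid in either
    input map yield zero signal at every TR. Identical inputs and seed give
    bit-identical output.
    """
    tr_s = np.asarray(tr_s, dtype=float)
    if tr_s.size == 0:
        raise ValueError("tr list is empty")
    if np.any(tr_s <= 0):
        raise ValueError(f"repetition times must be positive, got {tr_s[tr_s <= 0][0]}")
    if noise_sigma < 0:
        raise ValueError(f"noise sigma must be >= 0, got {noise_sigma}")
    t1 = t1_map.values
    valid = t1_map.valid & m0_map.valid
    if np.any(valid & (t1 <= 0)):
        bad = t1[valid & (t1 <= 0)][0]
        raise ValueError(f"T1 values must be positive, got {bad}")
    m0 = np.where(valid, m0_map.values, 0.0)
    t1_safe = np.where(valid, t1, 1.0)
    clean = m0[..., None] * (1.0 - np.exp(-tr_s / t1_safe[..., None]))
    rng = np.random.default_rng(seed)
    sd = noise_sigma * m0[..., None] * np.ones_like(clean)
    data = _apply_noise(clean, sd, rng, rician) if noise_sigma > 0 else clean
    return VariableTRSeries(data, tr_s, meta={"noise_sigma": noise_sigma, "seed": seed})


def told_response(t_min: np.ndarray, windows: list, s_max: float,
                  t_ox_min: float, k_oc_per_min: float) -> np.ndarray:
    """Piecewise TOLD enhancement S(t) in % for a gas-challenge paradigm.

    During each challenge window the signal relaxes exponentially toward
    ``s_max`` with time constant ``t_ox_min`` (from its level at onset,
    which is 0 for the first challenge); after each offset it decays toward
    the pre-challenge baseline (asymptote 0) at rate ``k_oc_per_min``.
    """
    t = np.atleast_1d(np.asarray(t_min, dtype=float))
    out = np.zeros_like(t)
    level = 0.0
    t_prev_off = None
    segments = []  # (t_start, kind, params)
    for t_on, t_off in windows:
        if t_prev_off is not None:
            segments.append((t_prev_off, "decay", (level, k_oc_per_min)))
            level = level * math.exp(-k_oc_per_min * (t_on - t_prev_off))
        segments.append((t_on, "rise", (level,)))
        if t_off is None:
            t_prev_off = None
            break
        level = s_max + (level - s_max) * math.exp(-(t_off - t_on) / t_ox_min)
        t_prev_off = t_off
    if t_prev_off is not None:
        segments.append((t_prev_off, "decay", (level, k_oc_per_min)))

    for i, (t0, kind, params) in enumerate(segments):
        t1 = segments[i + 1][0] if i + 1 < len(segments) else np.inf
        sel = (t >= t0) & (t < t1)
        if not sel.any():
            continue
        if kind == "rise":
            lvl0 = params[0]
            out[sel] = s_max + (lvl0 - s_max) * np.exp(-(t[sel] - t0) / t_ox_min)
        else:
            lvl0, k = params
            out[sel] = lvl0 * np.exp(-k * (t[sel] - t0))
    return out if np.ndim(t_min) else float(out[0])


def make_told_series(scene: PhantomScene,
                     schedule: GasSchedule,
                     frame_interval_s: float,
                     n_frames: int,
                     seed: Optional[int] = None,
                     noise_sigma: Optional[float] = None,
                     rician: bool = False):
    """Simulate a gas-challenge T1-weighted time series.

    Per region, intensity(t) = M0 * (1 + S(t)/100) with S(t) the piecewise
    rise/decay response; background pixels carry ``scene.background_m0`` and
    no response. Frame times follow the frame-start convention
    (t_i = i * frame_interval). Returns the series and a ground-truth
    parameter table (one row per region).
    """
    if frame_interval_s <= 0:
        raise ValueError(f"frame interval must be positive, got {frame_interval_s}")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    times = np.arange(n_frames) * frame_interval_s / 60.0
    if times[-1] > schedule.end_min + 1e-9:
        raise ValueError(
            f"schedule ends at {schedule.end_min} min but the scan runs to {times[-1]:.3f} min"
        )
    sigma = scene.noise_sigma if noise_sigma is None else noise_sigma
    if sigma < 0:
        raise ValueError(f"noise sigma must be >= 0, got {sigma}")
    windows = schedule.challenge_windows()

    clean = np.full(scene.grid_shape + (n_frames,), scene.background_m0, dtype=float)
    sd = np.full_like(clean, sigma * scene.background_m0)
    rows = []
    for reg in scene.regions:
        s = told_response(times, windows, reg.s_max, reg.t_ox_min, reg.k_oc_per_min)
        m = reg.mask(scene.grid_shape)
        clean[m, :] = reg.m0 * (1.0 + s / 100.0)
        sd[m, :] = sigma * reg.m0
        rows.append({"roi": reg.name, "label": reg.label, "m0": reg.m0,
                     "s_max": reg.s_max, "t_ox_min": reg.t_ox_min,
                     "k_ox_per_min": 1.0 / reg.t_ox_min,
                     "k_oc_per_min": reg.k_oc_per_min})
    rng = np.random.default_rng(seed)
    data = _apply_noise(clean, sd, rng, rician) if sigma > 0 else clean
    series = ToldSeries(data, times, schedule,
                        meta={"frame_interval_s": frame_interval_s,
                              "noise_sigma": sigma, "seed": seed})
    truth = pd.DataFrame(rows)
    return series, truth
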