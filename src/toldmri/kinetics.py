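"""TOLD time-course analysis: percent-enhancement curves and kinetic fits.

The TOLD signal is the percent enhancement of the T1-weighted intensity
relative to the pre-challenge baseline mean,

    dM%(t) = 100 * (M(t) - M_base) / M_base,

computed per pixel or on the ROI-mean intensity (ROI-mean first, then dM%).
The rising phase after a hyperoxic gas switch is fitted with

    S(t) = S_max * (1 - exp(-(t - onset) / T_ox)),

so T_ox is the time to reach 63.2% of the plateau S_max and k_ox = 1/T_ox is
the oxygenation rate. The post-challenge decay rate k_oc (the O2 consumption
rate) is the negative slope of ln(dM%) versus time over the first few
positive points after the gas is switched off — an operational semi-log
slope, not a metabolic CMRO2 model.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import curve_fit

from .types import DmCurve, KineticFit, ScalarMap, ToldSeries

__all__ = ["compute_dm_percent", "fit_oxygenation", "fit_consumption", "map_told"]

log = logging.getLogger(__name__)

SMAX_BOUNDS = (-100.0, 1000.0)
TOX_BOUNDS_MIN = (0.01, 100.0)


def compute_dm_percent(series: ToldSeries,
                       target: Union[np.ndarray, tuple]) -> DmCurve:
    """dM% curve for one ROI (boolean mask) or one pixel (index tuple).

    ROI mode averages intensities over the mask per frame first, then forms
    dM% of the ROI-mean trace. The baseline mean of the curve is zero by
    construction.
    """
    if isinstance(target, tuple):
        trace = series.data[target]
        source = f"pixel{target}"
    else:
        mask = np.asarray(target, dtype=bool)
        if mask.shape != series.plane_shape:
            raise ValueError(f"mask shape {mask.shape} does not match image plane {series.plane_shape}")
        if not mask.any():
            raise ValueError("ROI mask is empty")
        trace = series.data[mask].mean(axis=0)
        source = "roi"
    base = float(trace[series.baseline_frames].mean())
    if base <= 0:
        raise ValueError(f"baseline mean intensity must be positive, got {base}")
    dm = 100.0 * (trace - base) / base
    return DmCurve(series.frame_times_min.copy(), dm, source)


def _rise(t, s_max, t_ox):
    return s_max * (1.0 - np.exp(-t / t_ox))


def fit_oxygenation(curve: DmCurve, onset_min: float,
                    window_end_min: float) -> KineticFit:
    """Nonlinear least-squares fit of the exponential rise on [onset, end].

    Returns S_max (%), T_ox (min) and (as a derived property) k_ox = 1/T_ox.
    A flat window yields S_max = 0 with the convergence flag cleared.
    """
    sel = (curve.times_min >= onset_min) & (curve.times_min <= window_end_min)
    if sel.sum() < 4:
        raise ValueError(f"need at least 4 frames in [{onset_min}, {window_end_min}] min, found {int(sel.sum())}")
    t = curve.times_min[sel] - onset_min
    y = curve.dm_percent[sel]
    if np.ptp(y) < 1e-12 and abs(y).max() < 1e-9:
        return KineticFit("rise", s_max=0.0, t_ox_min=None,
                          window_min=(onset_min, window_end_min),
                          residual_norm=0.0, converged=False,
                          n_points=int(sel.sum()))
    s0 = float(y[np.argmax(np.abs(y))])
    above = np.flatnonzero(np.abs(y) >= 0.632 * abs(s0))
    t0 = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(max(t[-1] / 3, TOX_BOUNDS_MIN[0]))
    t0 = float(np.clip(t0, *TOX_BOUNDS_MIN))
    try:
        popt, _ = curve_fit(_rise, t, y, p0=[s0, t0],
                            bounds=([SMAX_BOUNDS[0], TOX_BOUNDS_MIN[0]],
                                    [SMAX_BOUNDS[1], TOX_BOUNDS_MIN[1]]),
                            xtol=1e-13, ftol=1e-13, maxfev=20000)
        converged = True
    except RuntimeError:
        popt = (s0, t0)
        converged = False
    resid = y - _rise(t, *popt)
    return KineticFit("rise", s_max=float(popt[0]), t_ox_min=float(popt[1]),
                      window_min=(onset_min, window_end_min),
                      residual_norm=float(np.linalg.norm(resid)),
                      converged=converged, n_points=int(sel.sum()))


def fit_consumption(curve: DmCurve, offset_min: float,
                    n_points: int = 5) -> KineticFit:
    """Semi-log decay slope over the first ``n_points`` positive frames
    strictly after the gas-off time; k_oc is its negative.

    Non-positive dM% values inside the window are excluded (and logged);
    at least two positive points are required.
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    after = curve.times_min > offset_min
    t_all = curve.times_min[after]
    y_all = curve.dm_percent[after]
    pos = y_all > 0
    n_excl = int((~pos[: min(len(pos), n_points)]).sum())
    t = t_all[pos][:n_points]
    y = y_all[pos][:n_points]
    if t.size < 2:
        raise ValueError(
            f"need at least 2 positive dM% values after {offset_min} min, found {t.size}")
    if n_excl:
        log.warning("fit_consumption: excluded %d non-positive dM%% value(s) in the decay window", n_excl)
    slope, intercept = np.polyfit(t, np.log(y), 1)
    resid = np.log(y) - (slope * t + intercept)
    return KineticFit("decay", k_oc_per_min=float(-slope),
                      window_min=(float(t[0]), float(t[-1])),
                      residual_norm=float(np.linalg.norm(resid)),
                      converged=True, n_points=int(t.size), n_excluded=n_excl)


def map_told(series: ToldSeries, window_base: Sequence[int],
             window_challenge: Sequence[int]) -> ScalarMap:
    """Per-pixel dM% of the challenge-window mean versus the baseline-window
    mean: a signed TOLD map (positive and negative responses both kept).
    """
    base_idx = np.asarray(window_base, dtype=int)
    chal_idx = np.asarray(window_challenge, dtype=int)
    if base_idx.size == 0 or chal_idx.size == 0:
        raise ValueError("both frame windows must be non-empty")
    n = series.data.shape[-1]
    for idx in (base_idx, chal_idx):
        if idx.min() < 0 or idx.max() >= n:
            raise ValueError(f"frame index out of range [0, {n})")
    base = series.data[..., base_idx].mean(axis=-1)
    chal = series.data[..., chal_idx].mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dm = 100.0 * (chal - base) / base
    valid = base > 0
    return ScalarMap(np.where(valid, dm, np.nan), "%", valid)
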