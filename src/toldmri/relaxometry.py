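"""T1 mapping from variable-TR saturation-recovery data, and R1/dR1 maps.

The per-pixel model is the two-parameter saturation recovery
``M(TR) = M0 * (1 - exp(-TR/T1))``; an additive-offset third parameter is
available behind a flag (off by default — with a TR ladder whose longest TR
far exceeds T1 the offset is barely identifiable at phantom SNR). Sequence
gain, TE weighting and flip-angle effects are treated as constant
multiplicative factors absorbed into M0, so fitted T1 is invariant to
global intensity scaling.

Pixels that cannot be fitted (degenerate signal, too few TRs,
non-convergence) are flagged invalid in the output map rather than raising,
so map fitting always completes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .types import ScalarMap, UnitError, VariableTRSeries

__all__ = ["T1Fit", "fit_t1_pixel", "fit_t1_map", "t1_to_r1", "delta_r1", "roi_summary"]

T1_BOUNDS_S = (0.01, 20.0)


@dataclass
class T1Fit:
    t1_s: float
    m0: float
    offset: float
    residual_norm: float
    valid: bool
    message: str = ""


def _recovery(tr, m0, t1):
    return m0 * (1.0 - np.exp(-tr / t1))


def _recovery_offset(tr, m0, t1, c):
    return m0 * (1.0 - np.exp(-tr / t1)) + c


def _initial_guess(signal: np.ndarray, tr_s: np.ndarray) -> tuple:
    # M0 from the longest TR (closest to full recovery); T1 by
    # log-linearising 1 - M/M0 over TRs that are informative (not saturated).
    m0_0 = float(signal[np.argmax(tr_s)])
    if m0_0 <= 0:
        m0_0 = max(float(np.max(signal)), 1e-6)
    frac = 1.0 - signal / m0_0
    use = (frac > 1e-6) & (frac < 0.999)
    if use.sum() >= 2:
        slope = np.polyfit(tr_s[use], np.log(frac[use]), 1)[0]
        t1_0 = -1.0 / slope if slope < 0 else 1.0
    else:
        t1_0 = float(np.median(tr_s))
    t1_0 = float(np.clip(t1_0, *T1_BOUNDS_S))
    return m0_0, t1_0


def fit_t1_pixel(signal: Sequence[float], tr_s: Sequence[float],
                 with_offset: bool = False) -> T1Fit:
    """Least-squares saturation-recovery fit for one pixel.

    Returns an invalid fit (not an exception) for degenerate input: fewer
    than three distinct TRs, constant signal, or solver failure.
    """
    signal = np.asarray(signal, dtype=float)
    tr_s = np.asarray(tr_s, dtype=float)
    if signal.shape != tr_s.shape:
        raise ValueError("signal and tr list differ in length")
    if np.any(tr_s <= 0):
        raise ValueError(f"repetition times must be positive, got {tr_s[tr_s <= 0][0]}")
    nan = float("nan")
    if np.unique(tr_s).size < 3:
        return T1Fit(nan, nan, 0.0, nan, False, "fewer than 3 distinct TRs")
    if not np.all(np.isfinite(signal)) or np.ptp(signal) == 0:
        return T1Fit(nan, nan, 0.0, nan, False, "degenerate signal")

    m0_0, t1_0 = _initial_guess(signal, tr_s)
    try:
        if with_offset:
            popt, _ = curve_fit(
                _recovery_offset, tr_s, signal, p0=[m0_0, t1_0, 0.0],
                bounds=([0.0, T1_BOUNDS_S[0], -np.inf], [np.inf, T1_BOUNDS_S[1], np.inf]),
                xtol=1e-12, ftol=1e-12, maxfev=10000)
            m0, t1, c = popt
            resid = signal - _recovery_offset(tr_s, *popt)
        else:
            popt, _ = curve_fit(
                _recovery, tr_s, signal, p0=[m0_0, t1_0],
                bounds=([0.0, T1_BOUNDS_S[0]], [np.inf, T1_BOUNDS_S[1]]),
                xtol=1e-12, ftol=1e-12, maxfev=10000)
            m0, t1 = popt
            c = 0.0
            resid = signal - _recovery(tr_s, *popt)
    except (RuntimeError, ValueError) as exc:  # non-convergence
        return T1Fit(nan, nan, 0.0, nan, False, f"fit failed: {exc}")
    if not (t1 > 0 and m0 > 0):
        return T1Fit(nan, nan, 0.0, nan, False, "non-physical solution")
    return T1Fit(float(t1), float(m0), float(c),
                 float(np.linalg.norm(resid)), True)


def fit_t1_map(series: VariableTRSeries, mask: Optional[np.ndarray] = None,
               with_offset: bool = False) -> ScalarMap:
    """Pixelwise T1 map inside a boolean mask; pixels outside are invalid."""
    plane = series.plane_shape
    if mask is None:
        mask = np.ones(plane, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != plane:
            raise ValueError(f"mask shape {mask.shape} does not match image plane {plane}")
    vals = np.full(plane, np.nan)
    valid = np.zeros(plane, dtype=bool)
    flat = series.data.reshape(-1, series.tr_s.size)
    mflat = mask.reshape(-1)
    vflat = vals.reshape(-1)
    okflat = valid.reshape(-1)
    for i in np.flatnonzero(mflat):
        fit = fit_t1_pixel(flat[i], series.tr_s, with_offset=with_offset)
        if fit.valid:
            vflat[i] = fit.t1_s
            okflat[i] = True
    return ScalarMap(vals, "s", valid)


def t1_to_r1(m: ScalarMap) -> ScalarMap:
    """Reciprocal map: T1 (s) -> R1 (1/s), or back. Zeros become invalid."""
    if m.unit not in ("s", "1/s"):
        raise UnitError(f"expected a map in 's' or '1/s', got {m.unit!r}")
    out_unit = "1/s" if m.unit == "s" else "s"
    with np.errstate(divide="ignore"):
        vals = np.where(m.values != 0, 1.0 / m.values, np.nan)
    valid = m.valid & (m.values != 0)
    return ScalarMap(vals, out_unit, valid)


def delta_r1(after: Union[ScalarMap, float], before: Union[ScalarMap, float]):
    """dR1 = R1(hyperoxia) - R1(air), elementwise on maps or on scalars."""
    if isinstance(after, ScalarMap) and isinstance(before, ScalarMap):
        if after.unit != before.unit:
            raise UnitError(f"unit mismatch: {after.unit!r} vs {before.unit!r}")
        if after.shape != before.shape:
            raise ValueError(f"shape mismatch: {after.shape} vs {before.shape}")
        return ScalarMap(after.values - before.values, after.unit,
                         after.valid & before.valid)
    if isinstance(after, ScalarMap) or isinstance(before, ScalarMap):
        raise TypeError("both inputs must be maps, or both scalars")
    return float(after) - float(before)


def roi_summary(m: ScalarMap, labels: np.ndarray,
                names: Optional[dict] = None) -> pd.DataFrame:
    """Per-ROI table (roi, n_pixels, mean, sd) over valid pixels only."""
    labels = np.asarray(labels)
    if labels.shape != m.shape:
        raise ValueError("label image shape does not match map")
    rows = []
    for lab in np.unique(labels[labels > 0]):
        sel = labels == lab
        rows.append({
            "roi": (names or {}).get(int(lab), str(int(lab))),
            "n_pixels": int((sel & m.valid).sum()),
            "mean": m.roi_mean(sel),
            "sd": m.roi_sd(sel),
        })
    return pd.DataFrame(rows, columns=["roi", "n_pixels", "mean", "sd"])
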