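"""O2 relaxivity calibration and two-compartment tissue oximetry.

The tissue longitudinal relaxation rate is modeled as a volume-weighted sum
of an aqueous and a lipid component,

    R1_tissue = VA * R1_aqueous + VL * R1_lipid,   VA + VL = 1,

with water and corn oil as the in-vitro stand-ins for the two phases. Given
reference rates of the two phases at a physiological pO2 the fractions
follow in closed form; given a gas-challenge dR1 and the phase relaxivities
r1 (slope of R1 versus pO2 or versus dissolved concentration) the tissue O2
shift is the fraction-weighted sum of per-phase quotients,

    dO2 = VA * (dR1 / r1_aqueous) + VL * (dR1 / r1_lipid),

evaluated once with per-mM relaxivities (mmol/L) and once with per-mmHg
relaxivities (mmHg equivalent).
"""

from __future__ import annotations

from typing import Union

import numpy as np

from .types import (CompartmentFractions, HenryConstant, OxygenShift,
                    Relaxivity, RelaxivityFit, ScalarMap, UnitError)

__all__ = [
    "gas_po2", "fit_relaxivity", "convert_r1_units", "reference_r1_at_po2",
    "solve_fractions", "solve_fractions_map", "estimate_delta_o2",
    "delta_o2_maps",
]


def gas_po2(o2_fraction: float, total_pressure_mmhg: float = 760.0) -> float:
    """Dry-gas O2 partial pressure: fraction times total pressure (mmHg)."""
    if not 0.0 <= o2_fraction <= 1.0:
        raise ValueError(f"O2 fraction must be in [0, 1], got {o2_fraction}")
    if total_pressure_mmhg <= 0:
        raise ValueError(f"total pressure must be positive, got {total_pressure_mmhg}")
    return o2_fraction * total_pressure_mmhg


def fit_relaxivity(r1_per_s, po2_mmhg, unit: str = "per_mmHg") -> RelaxivityFit:
    """Ordinary least-squares line through R1 versus pO2 (or concentration).

    The slope is the relaxivity r1; the intercept is R1 of the deoxygenated
    phase. Requires at least two distinct abscissa values.
    """
    y = np.asarray(r1_per_s, dtype=float)
    x = np.asarray(po2_mmhg, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("r1 and pO2 must be 1-D arrays of equal length")
    if np.unique(x).size < 2:
        raise ValueError("all pO2 values are equal: slope undefined")
    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ np.array([slope, intercept])
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RelaxivityFit(float(slope), float(intercept), unit, r2, int(x.size))


def convert_r1_units(r1_per_mmhg: float, henry: HenryConstant) -> float:
    """Re-express a per-mmHg relaxivity in per-mM units via Henry's law."""
    return r1_per_mmhg * henry.mmhg_per_mm


def reference_r1_at_po2(fit: RelaxivityFit, po2_mmhg: float) -> float:
    """Evaluate a calibration line at a reference pO2 (e.g. 40 mmHg)."""
    if fit.unit != "per_mmHg":
        raise UnitError("reference evaluation needs a per-mmHg calibration fit")
    return fit.intercept + fit.slope * po2_mmhg


def solve_fractions(r1_tissue: float, r1_aqueous_ref: float, r1_lipid_ref: float,
                    reference_po2_mmhg: float = 40.0,
                    clamp: bool = False) -> CompartmentFractions:
    """Closed-form aqueous/lipid volume fractions from the tissue R1.

    VA = (R1_lipid - R1_tissue) / (R1_lipid - R1_aqueous); VL = 1 - VA.
    In strict mode (default) a VA outside [0, 1] is rejected; with
    ``clamp=True`` it is clipped to the admissible range.
    """
    if r1_aqueous_ref == r1_lipid_ref:
        raise ValueError("reference rates are equal: fractions are undefined")
    va = (r1_lipid_ref - r1_tissue) / (r1_lipid_ref - r1_aqueous_ref)
    if not 0.0 <= va <= 1.0:
        if not clamp:
            raise ValueError(
                f"tissue R1 {r1_tissue} gives VA = {va:.4f} outside [0, 1]; "
                "it lies outside the range spanned by the reference rates")
        va = float(np.clip(va, 0.0, 1.0))
    return CompartmentFractions(float(va), float(1.0 - va),
                                reference_po2_mmhg, r1_aqueous_ref, r1_lipid_ref)


def solve_fractions_map(r1_map: ScalarMap, r1_aqueous_ref: float,
                        r1_lipid_ref: float,
                        reference_po2_mmhg: float = 40.0,
                        clamp: bool = False) -> ScalarMap:
    """Pixelwise VA map; out-of-range pixels become invalid (or clipped)."""
    if r1_map.unit != "1/s":
        raise UnitError(f"expected an R1 map in '1/s', got {r1_map.unit!r}")
    if r1_aqueous_ref == r1_lipid_ref:
        raise ValueError("reference rates are equal: fractions are undefined")
    va = (r1_lipid_ref - r1_map.values) / (r1_lipid_ref - r1_aqueous_ref)
    inside = (va >= 0.0) & (va <= 1.0)
    if clamp:
        va = np.clip(va, 0.0, 1.0)
        valid = r1_map.valid
    else:
        valid = r1_map.valid & inside
    return ScalarMap(va, "fraction", valid)


def estimate_delta_o2(delta_r1_per_s: float, fractions: CompartmentFractions,
                      r1_aqueous: Relaxivity, r1_lipid: Relaxivity) -> OxygenShift:
    """Tissue O2 shift from dR1 via the fraction-weighted two-phase quotients.

    Computed twice: with per-mM relaxivities (-> mmol/L) and with per-mmHg
    relaxivities (-> mmHg equivalent). Linear in dR1 by construction, and
    bracketed between the two single-phase quotients.
    """
    if not np.isfinite(delta_r1_per_s):
        raise ValueError("dR1 must be finite")
    va, vl = fractions.va, fractions.vl
    o2_mm = va * (delta_r1_per_s / r1_aqueous.per_mm) + vl * (delta_r1_per_s / r1_lipid.per_mm)
    o2_mmhg = va * (delta_r1_per_s / r1_aqueous.per_mmhg) + vl * (delta_r1_per_s / r1_lipid.per_mmhg)
    return OxygenShift(float(delta_r1_per_s), float(o2_mm), float(o2_mmhg),
                       fractions, r1_aqueous, r1_lipid)


def delta_o2_maps(delta_r1_map: ScalarMap, va_map: ScalarMap,
                  r1_aqueous: Relaxivity, r1_lipid: Relaxivity):
    """Pixelwise O2-shift maps (mM, mmHg) from dR1 and VA maps."""
    if delta_r1_map.unit != "1/s":
        raise UnitError(f"expected a dR1 map in '1/s', got {delta_r1_map.unit!r}")
    if va_map.unit != "fraction":
        raise UnitError(f"expected a VA map in 'fraction', got {va_map.unit!r}")
    if delta_r1_map.shape != va_map.shape:
        raise ValueError("map shapes differ")
    va = va_map.values
    vl = 1.0 - va
    dr1 = delta_r1_map.values
    valid = delta_r1_map.valid & va_map.valid
    mm = va * (dr1 / r1_aqueous.per_mm) + vl * (dr1 / r1_lipid.per_mm)
    mmhg = va * (dr1 / r1_aqueous.per_mmhg) + vl * (dr1 / r1_lipid.per_mmhg)
    return ScalarMap(mm, "mM", valid), ScalarMap(mmhg, "mmHg", valid)
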