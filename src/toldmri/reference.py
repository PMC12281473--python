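"""Reference values measured at 7 T, bundled as calibration defaults.

These are published group means for water/corn-oil tube phantoms
equilibrated with N2, air, carbogen (95% O2 + 5% CO2) or 100% O2, and for
healthy C3H mouse brain regions under the same breathing gases. They serve
two roles: ground truth for the synthetic phantoms, and default calibration
constants (relaxivities, reference relaxation rates) for the oximetry step.
They are measurements, not quantities this package can recompute.
"""

from __future__ import annotations

from .types import GasInterval, GasSchedule, HenryConstant, Relaxivity

#: dry-gas O2 fractions of the breathing gases used throughout
GAS_O2_FRACTION = {"n2": 0.0, "air": 0.21, "carbogen": 0.95, "o2": 1.0}

#: total gas pressure assumed for dry-gas pO2 (mmHg); no water-vapor correction
TOTAL_PRESSURE_MMHG = 760.0

#: normal tissue pO2 used as the reference point for compartment fractions (mmHg)
REFERENCE_PO2_MMHG = 40.0

# Tube-phantom relaxometry at 30 degC: per-gas T1 (s) and R1 (1/s) group means.
PHANTOM_T1_S = {
    "water": {"n2": 4.61, "air": 4.25, "carbogen": 2.97, "o2": 2.91},
    "corn_oil": {"n2": 0.67, "air": 0.60, "carbogen": 0.48, "o2": 0.47},
}
PHANTOM_R1_PER_S = {
    "water": {"n2": 0.22, "air": 0.24, "carbogen": 0.34, "o2": 0.34},
    "corn_oil": {"n2": 1.50, "air": 1.66, "carbogen": 2.10, "o2": 2.14},
}

# Mouse brain relaxometry: per-region, per-gas T1 (s) and R1 (1/s) group means.
# Note the R1 means are means of per-animal reciprocals, so 1/T1 of the T1
# mean does not exactly reproduce them (ventricles: 1/2.84 = 0.352 vs 0.38).
BRAIN_T1_S = {
    "cortex": {"air": 1.85, "carbogen": 1.72, "o2": 1.73},
    "ventricles": {"air": 2.84, "carbogen": 2.75, "o2": 2.79},
    "caudate": {"air": 1.70, "carbogen": 1.60, "o2": 1.62},
}
BRAIN_R1_PER_S = {
    "cortex": {"air": 0.54, "carbogen": 0.58, "o2": 0.58},
    "ventricles": {"air": 0.38, "carbogen": 0.39, "o2": 0.38},
    "caudate": {"air": 0.59, "carbogen": 0.63, "o2": 0.62},
}

# Group-mean dR1 (1/s) between each hyperoxic gas and air, per brain region.
BRAIN_DELTA_R1_PER_S = {
    "carbogen": {"cortex": 0.041, "ventricles": 0.013, "caudate": 0.037},
    "o2": {"cortex": 0.038, "ventricles": 0.007, "caudate": 0.031},
}

# TOLD kinetics under carbogen, per region: rise time constant T_ox (min)
# and plateau S_max (%), group means of the challenge experiment.
BRAIN_KINETICS_CARBOGEN = {
    "cortex": {"t_ox_min": 0.60, "s_max": 5.08},
    "ventricles": {"t_ox_min": 0.97, "s_max": 4.05},
    "caudate": {"t_ox_min": 0.66, "s_max": 3.08},
}

# Cortex kinetic indices from the dedicated 5-min-challenge experiment.
CORTEX_K_OX_PER_MIN = 1.69
CORTEX_S_MAX_PERCENT = 5.18
CORTEX_K_OC_PER_MIN = 1.55

# O2 relaxivities of the two model phases at 7 T, 30 degC, in both unit systems.
WATER_RELAXIVITY = Relaxivity(per_mmhg=1.71e-4, per_mm=0.118)
CORN_OIL_RELAXIVITY = Relaxivity(per_mmhg=8.20e-4, per_mm=0.569)

#: mmHg of O2 per mM dissolved at 30 degC; the ratio implied by the published
#: relaxivity pairs (0.118 / 1.71e-4 ~ 690), applied to both phases since O2
#: solubility in water and corn oil was found equivalent
HENRY_30C = HenryConstant(mmhg_per_mm=690.0, temperature_c=30.0,
                          note="implied by the published per-mM / per-mmHg relaxivity pair for water")

#: the 12-step repetition-time ladder used for saturation-recovery T1 mapping (ms)
TR_LADDER_MS = (15000, 8000, 5500, 4000, 3000, 2000, 1600, 1200, 800, 500, 200, 100)


def standard_challenge_schedule(baseline_min: float = 5.0,
                                challenge_min: float = 5.0,
                                recovery_min: float = 5.0,
                                gas: str = "carbogen") -> GasSchedule:
    """Air baseline, hyperoxic challenge, return to air — the kinetics paradigm."""
    t1 = baseline_min
    t2 = baseline_min + challenge_min
    t3 = t2 + recovery_min
    return GasSchedule([
        GasInterval(0.0, t1, "air", GAS_O2_FRACTION["air"], TOTAL_PRESSURE_MMHG),
        GasInterval(t1, t2, gas, GAS_O2_FRACTION[gas], TOTAL_PRESSURE_MMHG),
        GasInterval(t2, t3, "air", GAS_O2_FRACTION["air"], TOTAL_PRESSURE_MMHG),
    ])


def long_challenge_schedule(gas: str = "carbogen") -> GasSchedule:
    """Air for 5 min then the challenge gas for 16 min (the 21-min TOLD scan)."""
    return GasSchedule([
        GasInterval(0.0, 5.0, "air", GAS_O2_FRACTION["air"], TOTAL_PRESSURE_MMHG),
        GasInterval(5.0, 21.0, gas, GAS_O2_FRACTION[gas], TOTAL_PRESSURE_MMHG),
    ])
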