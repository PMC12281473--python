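"""Shared containers for TOLD-MRI analysis.

Everything downstream operates on a small set of typed containers: scalar
maps with an explicit unit tag and validity mask, image series (variable-TR
stacks for relaxometry, 4D gas-challenge time series), the gas schedule that
drives a challenge experiment, and result records for the fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: unit tags a ScalarMap may carry
VALID_UNITS = ("s", "1/s", "%", "mM", "mmHg", "fraction", "intensity")


class UnitError(ValueError):
    """Raised when an operation receives a map in the wrong unit."""


@dataclass
class ScalarMap:
    """Per-pixel scalar values with a unit tag and a validity mask.

    Invalid pixels (non-convergent fits, division by zero, out-of-range
    model solutions) are flagged in ``valid`` rather than silently zeroed;
    ROI statistics use valid pixels only.
    """

    values: np.ndarray
    unit: str
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.unit not in VALID_UNITS:
            raise UnitError(f"unknown unit tag {self.unit!r}; expected one of {VALID_UNITS}")
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ValueError("valid mask shape does not match values")
            self.valid = self.valid & np.isfinite(self.values)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def roi_mean(self, mask: np.ndarray) -> float:
        """Mean over valid pixels inside a boolean mask (NaN if none)."""
        mask = np.asarray(mask, dtype=bool)
        sel = mask & self.valid
        if not sel.any():
            return float("nan")
        return float(self.values[sel].mean())

    def roi_sd(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        sel = mask & self.valid
        if sel.sum() < 2:
            return float("nan")
        return float(self.values[sel].std(ddof=1))


@dataclass(frozen=True)
class GasInterval:
    """One contiguous breathing-gas period of the paradigm."""

    start_min: float
    end_min: float
    gas: str
    o2_fraction: float
    total_pressure_mmhg: float = 760.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.o2_fraction <= 1.0:
            raise ValueError(f"O2 fraction {self.o2_fraction} outside [0, 1] for gas {self.gas!r}")
        if self.total_pressure_mmhg <= 0:
            raise ValueError(f"total pressure must be positive, got {self.total_pressure_mmhg}")
        if self.end_min <= self.start_min:
            raise ValueError(f"interval for {self.gas!r} ends ({self.end_min}) before it starts ({self.start_min})")

    @property
    def po2_mmhg(self) -> float:
        return self.o2_fraction * self.total_pressure_mmhg


@dataclass
class GasSchedule:
    """Ordered, contiguous gas intervals covering the scan.

    Intervals are left-closed: the frame containing a gas switch belongs to
    the gas active at the frame's start time.
    """

    intervals: list

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("gas schedule is empty")
        ivs = list(self.intervals)
        for a, b in zip(ivs, ivs[1:]):
            if not math.isclose(a.end_min, b.start_min, abs_tol=1e-9):
                raise ValueError(
                    f"intervals must be contiguous: {a.gas!r} ends at {a.end_min} min "
                    f"but {b.gas!r} starts at {b.start_min} min"
                )
        self.intervals = ivs

    @property
    def start_min(self) -> float:
        return self.intervals[0].start_min

    @property
    def end_min(self) -> float:
        return self.intervals[-1].end_min

    def gas_at(self, t_min: float) -> GasInterval:
        """Interval active at time t (left-closed: switch frames take the new gas)."""
        for iv in self.intervals:
            if iv.start_min <= t_min < iv.end_min:
                return iv
        if math.isclose(t_min, self.end_min, abs_tol=1e-9):
            return self.intervals[-1]
        raise ValueError(f"time {t_min} min is outside the schedule [{self.start_min}, {self.end_min}]")

    def challenge_windows(self) -> list:
        """(onset, offset) of each challenge block, in minutes.

        The first interval defines the baseline gas; consecutive intervals
        whose O2 fraction differs from baseline are merged into one window.
        An offset of ``None`` means the challenge runs to the end of the scan.
        """
        base = self.intervals[0].o2_fraction
        windows = []
        t_on = None
        for iv in self.intervals:
            if iv.o2_fraction != base:
                if t_on is None:
                    t_on = iv.start_min
            else:
                if t_on is not None:
                    windows.append((t_on, iv.start_min))
                    t_on = None
        if t_on is not None:
            windows.append((t_on, None))
        return windows


@dataclass
class Region:
    """Labeled region of a phantom scene with its ground-truth physics.

    ``t1_s`` maps gas name -> T1 (s). ``m0`` is the equilibrium intensity
    (sequence gain and proton density absorbed into one factor).
    ``s_max`` (%), ``t_ox_min`` and ``k_oc_per_min`` drive the challenge
    response; a region with s_max == 0 is non-enhancing.
    """

    name: str
    label: int
    shape: str  # "disc" | "box"
    params: tuple  # disc: (cy, cx, r[, r_inner]); box: (y0, y1, x0, x1)
    t1_s: dict = field(default_factory=dict)
    m0: float = 100.0
    s_max: float = 0.0
    t_ox_min: float = 1.0
    k_oc_per_min: float = 1.0

    def mask(self, grid_shape: tuple) -> np.ndarray:
        yy, xx = np.mgrid[0 : grid_shape[0], 0 : grid_shape[1]]
        if self.shape == "disc":
            cy, cx, r = self.params[:3]
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            m = d2 <= r**2
            if len(self.params) == 4:  # annulus
                m &= d2 > self.params[3] ** 2
            return m
        if self.shape == "box":
            y0, y1, x0, x1 = self.params
            return (yy >= y0) & (yy < y1) & (xx >= x0) & (xx < x1)
        raise ValueError(f"unknown region shape {self.shape!r}")


@dataclass
class PhantomScene:
    """Digital phantom: a pixel grid tiled with disjoint labeled regions."""

    grid_shape: tuple = (64, 64)
    regions: list = field(default_factory=list)
    noise_sigma: float = 0.02
    background_m0: float = 50.0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError(f"noise sigma must be >= 0, got {self.noise_sigma}")
        taken = np.zeros(self.grid_shape, dtype=bool)
        for reg in self.regions:
            m = reg.mask(self.grid_shape)
            if (m & taken).any():
                raise ValueError(f"region {reg.name!r} overlaps another region")
            taken |= m
            for gas, t1 in reg.t1_s.items():
                if t1 <= 0:
                    raise ValueError(f"region {reg.name!r} has non-positive T1 {t1} for gas {gas!r}")

    def label_image(self) -> np.ndarray:
        lab = np.zeros(self.grid_shape, dtype=np.int16)
        for reg in self.regions:
            lab[reg.mask(self.grid_shape)] = reg.label
        return lab

    def region(self, name: str) -> Region:
        for reg in self.regions:
            if reg.name == name:
                return reg
        raise KeyError(name)


@dataclass
class VariableTRSeries:
    """Image stack acquired at a ladder of repetition times (saturation recovery)."""

    data: np.ndarray  # (..., n_tr), spatial axes first
    tr_s: np.ndarray  # repetition times in seconds, acquisition order
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.tr_s = np.asarray(self.tr_s, dtype=float)
        if self.data.shape[-1] != self.tr_s.size:
            raise ValueError(
                f"TR axis length {self.data.shape[-1]} does not match tr list length {self.tr_s.size}"
            )
        if np.any(self.tr_s <= 0):
            bad = self.tr_s[self.tr_s <= 0][0]
            raise ValueError(f"repetition times must be positive, got {bad}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("series intensities must be finite")

    @property
    def plane_shape(self) -> tuple:
        return self.data.shape[:-1]


@dataclass
class ToldSeries:
    """T1-weighted time series under a gas-challenge paradigm."""

    data: np.ndarray  # (..., n_frames)
    frame_times_min: np.ndarray  # frame-start times, strictly increasing
    schedule: GasSchedule
    baseline_frames: Optional[np.ndarray] = None  # indices; default = initial baseline-gas frames
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.frame_times_min = np.asarray(self.frame_times_min, dtype=float)
        if self.data.shape[-1] != self.frame_times_min.size:
            raise ValueError("frame axis length does not match frame times")
        if np.any(np.diff(self.frame_times_min) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.baseline_frames is None:
            windows = self.schedule.challenge_windows()
            t_first = windows[0][0] if windows else self.schedule.end_min
            self.baseline_frames = np.flatnonzero(self.frame_times_min < t_first)
        else:
            self.baseline_frames = np.asarray(self.baseline_frames, dtype=int)
        if self.baseline_frames.size == 0:
            raise ValueError("baseline window is empty: no frames precede the first challenge")

    @property
    def plane_shape(self) -> tuple:
        return self.data.shape[:-1]


@dataclass
class DmCurve:
    """Percent signal enhancement over time, zero-mean on the baseline window."""

    times_min: np.ndarray
    dm_percent: np.ndarray
    source: str = "roi"

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.dm_percent = np.asarray(self.dm_percent, dtype=float)
        if self.times_min.shape != self.dm_percent.shape:
            raise ValueError("times and values differ in length")


@dataclass
class KineticFit:
    """Result of a TOLD kinetic fit (exponential rise or semi-log decay).

    For a rise fit ``s_max``/``t_ox_min`` are set and ``k_ox_per_min`` is
    their exact reciprocal; for a decay fit only ``k_oc_per_min`` is set.
    """

    kind: str  # "rise" | "decay"
    s_max: Optional[float] = None
    t_ox_min: Optional[float] = None
    k_oc_per_min: Optional[float] = None
    window_min: Optional[tuple] = None
    residual_norm: float = float("nan")
    converged: bool = True
    n_points: int = 0
    n_excluded: int = 0

    @property
    def k_ox_per_min(self) -> Optional[float]:
        if self.t_ox_min is None:
            return None
        return 1.0 / self.t_ox_min


@dataclass
class RelaxivityFit:
    """Slope/intercept of an R1-versus-pO2 (or concentration) regression."""

    slope: float
    intercept: float
    unit: str  # "per_mmHg" | "per_mM"
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if self.unit not in ("per_mmHg", "per_mM"):
            raise UnitError(f"relaxivity unit must be 'per_mmHg' or 'per_mM', got {self.unit!r}")
        if not np.isfinite(self.slope):
            raise ValueError("relaxivity slope is not finite")
        if self.n < 2:
            raise ValueError("relaxivity fit needs at least two points")


@dataclass(frozen=True)
class Relaxivity:
    """One substance's O2 relaxivity in both unit systems."""

    per_mmhg: float
    per_mm: float

    def __post_init__(self) -> None:
        if self.per_mmhg <= 0 or self.per_mm <= 0:
            raise ValueError("relaxivities must be positive")


@dataclass
class CompartmentFractions:
    """Aqueous/lipid volume fractions of the tissue T1 signal (VA + VL = 1)."""

    va: float
    vl: float
    reference_po2_mmhg: float
    r1_aqueous: float
    r1_lipid: float

    def __post_init__(self) -> None:
        if not math.isclose(self.va + self.vl, 1.0, rel_tol=0, abs_tol=1e-12):
            raise ValueError(f"VA + VL must equal 1 exactly, got {self.va + self.vl}")


@dataclass
class OxygenShift:
    """Tissue O2 shift derived from one dR1 via the two-compartment model."""

    delta_r1: float
    delta_o2_mm: float
    delta_o2_mmhg: float
    fractions: CompartmentFractions
    r1_aqueous: Relaxivity
    r1_lipid: Relaxivity


@dataclass(frozen=True)
class HenryConstant:
    """Proportionality between dissolved O2 partial pressure and concentration."""

    mmhg_per_mm: float
    temperature_c: float
    note: str = ""

    def __post_init__(self) -> None:
        if self.mmhg_per_mm <= 0:
            raise ValueError("Henry constant must be positive")
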