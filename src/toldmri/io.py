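"""File I/O, experiment configuration and the end-to-end pipeline.

Images travel as NIfTI-1 with a JSON sidecar carrying what the NIfTI header
cannot (unit tags, TR ladders, gas schedules, frame times); tables are CSV
with fixed column order and full float precision so runs diff cleanly.
Re-running an identical config and seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import reference as ref
from . import __version__
from .kinetics import compute_dm_percent, fit_consumption, fit_oxygenation
from .oximetry import (estimate_delta_o2, fit_relaxivity, gas_po2,
                       reference_r1_at_po2, solve_fractions)
from .relaxometry import delta_r1, fit_t1_map, roi_summary, t1_to_r1
from .synth import (make_brain_phantom, make_told_series,
                    make_variable_tr_series, scene_m0_map, scene_t1_map)
from .types import (GasInterval, GasSchedule, Relaxivity, ScalarMap,
                    ToldSeries, VariableTRSeries)

log = logging.getLogger(__name__)

__all__ = [
    "SidecarError", "write_map", "read_map", "write_series", "read_series",
    "write_mask", "read_mask", "write_table", "read_table",
    "ExperimentConfig", "RunReport", "PipelineError", "run_pipeline",
]


class SidecarError(ValueError):
    """Malformed or incomplete JSON sidecar."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def _write_nifti(path: Path, data: np.ndarray, sidecar: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(data)
    if arr.ndim < 3:  # NIfTI wants >=3 dims; pad a singleton slice axis
        arr = arr.reshape(arr.shape + (1,) * (3 - arr.ndim))
    nib.save(nib.Nifti1Image(arr.astype(np.float64), np.eye(4)), str(path))
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def _read_nifti(path: Path, required: tuple) -> tuple:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise SidecarError(f"missing sidecar {sc_path}")
    sidecar = json.loads(sc_path.read_text())
    missing = [k for k in required if k not in sidecar]
    if missing:
        raise SidecarError(f"sidecar {sc_path} is missing keys: {missing}")
    return data, sidecar


def write_map(path: Union[str, Path], m: ScalarMap) -> None:
    """ScalarMap -> NIfTI (invalid pixels stored as NaN) + unit sidecar."""
    vals = np.where(m.valid, m.values, np.nan)
    _write_nifti(Path(path), vals, {"kind": "scalar_map", "unit": m.unit})


def read_map(path: Union[str, Path]) -> ScalarMap:
    data, sc = _read_nifti(Path(path), ("kind", "unit"))
    data = np.squeeze(data)
    return ScalarMap(data, sc["unit"], np.isfinite(data))


def _schedule_to_json(schedule: GasSchedule) -> list:
    return [dataclasses.asdict(iv) for iv in schedule.intervals]


def _schedule_from_json(items: list) -> GasSchedule:
    return GasSchedule([GasInterval(**iv) for iv in items])


def write_series(path: Union[str, Path], series: Union[VariableTRSeries, ToldSeries]) -> None:
    """Image series -> 4D NIfTI (time/TR last) + acquisition sidecar."""
    path = Path(path)
    if isinstance(series, VariableTRSeries):
        sc = {"kind": "variable_tr",
              "tr_ms": [tr * 1000.0 for tr in series.tr_s.tolist()],
              "meta": series.meta}
    elif isinstance(series, ToldSeries):
        sc = {"kind": "told",
              "frame_times_min": series.frame_times_min.tolist(),
              "baseline_frames": series.baseline_frames.tolist(),
              "gas_schedule": _schedule_to_json(series.schedule),
              "meta": series.meta}
    else:
        raise TypeError(f"cannot write {type(series).__name__}")
    _write_nifti(path, series.data, sc)


def read_series(path: Union[str, Path]) -> Union[VariableTRSeries, ToldSeries]:
    data, sc = _read_nifti(Path(path), ("kind",))
    data = np.squeeze(data)
    if sc["kind"] == "variable_tr":
        if "tr_ms" not in sc:
            raise SidecarError(f"sidecar for {path} is missing keys: ['tr_ms']")
        return VariableTRSeries(data, np.asarray(sc["tr_ms"]) / 1000.0,
                                meta=sc.get("meta", {}))
    if sc["kind"] == "told":
        missing = [k for k in ("frame_times_min", "gas_schedule", "baseline_frames") if k not in sc]
        if missing:
            raise SidecarError(f"sidecar for {path} is missing keys: {missing}")
        return ToldSeries(data, np.asarray(sc["frame_times_min"]),
                          _schedule_from_json(sc["gas_schedule"]),
                          baseline_frames=np.asarray(sc["baseline_frames"]),
                          meta=sc.get("meta", {}))
    raise SidecarError(f"unknown series kind {sc['kind']!r}")


def write_mask(path: Union[str, Path], labels: np.ndarray, names: dict) -> None:
    """Integer-labeled ROI volume (0 = background) + label-name sidecar."""
    _write_nifti(Path(path), np.asarray(labels, dtype=np.int16),
                 {"kind": "roi_mask", "labels": {str(k): v for k, v in names.items()}})


def read_mask(path: Union[str, Path]) -> tuple:
    data, sc = _read_nifti(Path(path), ("kind", "labels"))
    labels = np.squeeze(data).astype(np.int16)
    names = {int(k): v for k, v in sc["labels"].items()}
    return labels, names


def write_table(path: Union[str, Path], df: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)


# --------------------------------------------------------------------------
# experiment configuration and the full pipeline
# --------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Everything a reproducible run needs; defaults give the synthetic
    brain-challenge experiment with published calibration constants."""

    out_dir: str = "toldmri_run"
    seed: int = 0
    grid_shape: tuple = (64, 64)
    noise_sigma: float = 0.02
    tr_ms: tuple = ref.TR_LADDER_MS
    frame_interval_s: float = 20.0
    n_frames: int = 45
    schedule: Optional[GasSchedule] = None  # default: 5 min air / 5 carbogen / 5 air
    challenge_gas: str = "carbogen"
    total_pressure_mmhg: float = ref.TOTAL_PRESSURE_MMHG
    henry_mmhg_per_mm: float = ref.HENRY_30C.mmhg_per_mm
    reference_po2_mmhg: float = ref.REFERENCE_PO2_MMHG
    r1_aqueous: Relaxivity = ref.WATER_RELAXIVITY
    r1_lipid: Relaxivity = ref.CORN_OIL_RELAXIVITY
    n_decay_points: int = 5
    strict_fractions: bool = True
    with_offset: bool = False
    # paths to pre-acquired data; when None the synthetic phantom is used
    series_paths: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.schedule is None:
            self.schedule = ref.standard_challenge_schedule(gas=self.challenge_gas)
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be positive")
        if self.n_frames < 4:
            raise ValueError("need at least 4 frames")
        last = (self.n_frames - 1) * self.frame_interval_s / 60.0
        if last > self.schedule.end_min + 1e-9:
            raise ValueError(
                f"gas schedule ends at {self.schedule.end_min} min but the scan runs to {last:.2f} min")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "schedule" in d and d["schedule"] is not None:
            d["schedule"] = _schedule_from_json(d["schedule"])
        for key in ("r1_aqueous", "r1_lipid"):
            if key in d and isinstance(d[key], dict):
                d[key] = Relaxivity(**d[key])
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "tr_ms" in d:
            d["tr_ms"] = tuple(d["tr_ms"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schedule"] = _schedule_to_json(self.schedule)
        return d


@dataclass
class RunReport:
    version: str
    config: dict
    results: dict
    warnings: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if hasattr(o, "item"):  # numpy scalars
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not JSON serializable: {type(o)}")
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True,
                          default=default)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: ExperimentConfig) -> RunReport:
    """simulate -> T1 maps -> dR1 -> fractions -> dO2 -> dM% -> kinetic fits.

    Writes per-stage NIfTI/CSV outputs and a JSON report under
    ``config.out_dir`` and returns the report. Any stage failure raises
    :class:`PipelineError` naming the stage; outputs written so far are kept.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    warnings: list = []
    outputs: dict = {}
    rng = np.random.default_rng(config.seed)
    roi_gases = ("air", config.challenge_gas)

    scene = make_brain_phantom(grid_shape=config.grid_shape,
                               noise_sigma=config.noise_sigma)
    labels = scene.label_image()
    names = {r.label: r.name for r in scene.regions}
    write_mask(out / "roi_mask.nii.gz", labels, names)
    outputs["roi_mask"] = str(out / "roi_mask.nii.gz")
    tr_s = np.asarray(config.tr_ms, dtype=float) / 1000.0

    @_stage("simulate")
    def simulate():
        series = {}
        for gas in roi_gases:
            series[gas] = make_variable_tr_series(
                scene_t1_map(scene, gas), scene_m0_map(scene), tr_s,
                noise_sigma=config.noise_sigma,
                seed=int(rng.integers(2**31)))
            write_series(out / f"vartr_{gas}.nii.gz", series[gas])
        told, truth = make_told_series(scene, config.schedule,
                                       config.frame_interval_s, config.n_frames,
                                       seed=int(rng.integers(2**31)))
        write_series(out / "told.nii.gz", told)
        write_table(out / "ground_truth.csv", truth)
        return series, told

    @_stage("t1map")
    def t1map(series):
        r1_means = {}
        for gas, s in series.items():
            t1 = fit_t1_map(s, labels > 0, with_offset=config.with_offset)
            r1 = t1_to_r1(t1)
            write_map(out / f"t1_{gas}.nii.gz", t1)
            write_map(out / f"r1_{gas}.nii.gz", r1)
            n_bad = int((labels > 0).sum() - t1.valid.sum())
            if n_bad:
                warnings.append(f"t1map[{gas}]: {n_bad} non-convergent pixel(s)")
            summary = roi_summary(r1, labels, names)
            write_table(out / f"r1_roi_{gas}.csv", summary)
            r1_means[gas] = {row.roi: row.mean for row in summary.itertuples()}
        return r1_means

    @_stage("deltar1")
    def deltar1(r1_means):
        return {roi: delta_r1(r1_means[config.challenge_gas][roi], r1_means["air"][roi])
                for roi in r1_means["air"]}

    @_stage("calibration")
    def calibration():
        gases = list(ref.GAS_O2_FRACTION)
        po2 = [gas_po2(ref.GAS_O2_FRACTION[g], config.total_pressure_mmhg) for g in gases]
        fits = {}
        for phase, table in (("aqueous", ref.PHANTOM_R1_PER_S["water"]),
                             ("lipid", ref.PHANTOM_R1_PER_S["corn_oil"])):
            fit = fit_relaxivity([table[g] for g in gases], po2)
            fits[phase] = fit
            results[f"r1_{phase}_per_mmhg"] = fit.slope
        return {phase: reference_r1_at_po2(fit, config.reference_po2_mmhg)
                for phase, fit in fits.items()}

    @_stage("fractions")
    def fractions(r1_means, refs):
        fr = {}
        for roi, r1t in r1_means["air"].items():
            fr[roi] = solve_fractions(r1t, refs["aqueous"], refs["lipid"],
                                      config.reference_po2_mmhg,
                                      clamp=not config.strict_fractions)
        return fr

    @_stage("deltao2")
    def deltao2(dr1, fr):
        rows = []
        for roi in dr1:
            shift = estimate_delta_o2(dr1[roi], fr[roi],
                                      config.r1_aqueous, config.r1_lipid)
            rows.append({"roi": roi, "delta_r1": shift.delta_r1,
                         "va": fr[roi].va, "vl": fr[roi].vl,
                         "delta_o2_mM": shift.delta_o2_mm,
                         "delta_o2_mmHg": shift.delta_o2_mmhg})
        df = pd.DataFrame(rows, columns=["roi", "delta_r1", "va", "vl",
                                         "delta_o2_mM", "delta_o2_mmHg"])
        write_table(out / "oximetry.csv", df)
        outputs["oximetry"] = str(out / "oximetry.csv")
        return df

    @_stage("toldfit")
    def toldfit(told):
        t_on, t_off = config.schedule.challenge_windows()[0]
        window_end = t_off if t_off is not None else config.schedule.end_min
        rows = []
        for reg in scene.regions:
            curve = compute_dm_percent(told, labels == reg.label)
            write_table(out / f"dm_{reg.name}.csv",
                        pd.DataFrame({"time_min": curve.times_min,
                                      "dm_percent": curve.dm_percent}))
            rise = fit_oxygenation(curve, t_on, window_end)
            row = {"roi": reg.name, "s_max": rise.s_max,
                   "t_ox": rise.t_ox_min, "k_ox": rise.k_ox_per_min,
                   "k_oc": float("nan"), "converged": rise.converged}
            if t_off is not None:
                try:
                    decay = fit_consumption(curve, t_off, config.n_decay_points)
                    row["k_oc"] = decay.k_oc_per_min
                    if decay.n_excluded:
                        warnings.append(
                            f"toldfit[{reg.name}]: excluded {decay.n_excluded} non-positive decay point(s)")
                except ValueError as exc:
                    warnings.append(f"toldfit[{reg.name}]: no decay fit ({exc})")
            rows.append(row)
        df = pd.DataFrame(rows, columns=["roi", "s_max", "t_ox", "k_ox", "k_oc", "converged"])
        write_table(out / "kinetics.csv", df)
        outputs["kinetics"] = str(out / "kinetics.csv")
        return df

    series, told = simulate()
    r1_means = t1map(series)
    dr1 = deltar1(r1_means)
    refs = calibration()
    fr = fractions(r1_means, refs)
    oxi = deltao2(dr1, fr)
    kin = toldfit(told)

    results["r1_reference_aqueous"] = refs["aqueous"]
    results["r1_reference_lipid"] = refs["lipid"]
    results["roi_r1"] = r1_means
    results["roi_delta_r1"] = dr1
    results["oximetry"] = oxi.to_dict("records")
    results["kinetics"] = kin.to_dict("records")

    report = RunReport(__version__, config.to_dict(), results, warnings, outputs)
    (out / "report.json").write_text(report.to_json())
    return report
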