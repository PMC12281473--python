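# Methods

This note records the models implemented in `toldmri`, the defaults and the
design choices made where the underlying method leaves room, so that results
can be interpreted and reproduced without reading the source.

## Signal models

**Saturation recovery.** The variable-TR stack is modeled per pixel as
`M(TR) = M0·(1 − exp(−TR/T1))`. M0 lumps proton density, receive gain, TE
weighting and flip-angle effects into one multiplicative factor, which makes
the fitted T1 invariant to global intensity scaling (tested). The default
TR ladder is the 12-step sequence 15000, 8000, 5500, 4000, 3000, 2000,
1600, 1200, 800, 500, 200, 100 ms; with TR_max ≫ T1 the recovery is fully
sampled and a constant-offset third parameter is barely identifiable at the
noise levels considered, so the two-parameter model is the default and the
offset variant sits behind `with_offset=True`. Fitting is bounded
Levenberg–Marquardt (trust-region reflective via `scipy.optimize.curve_fit`)
with T1 ∈ [0.01, 20] s, M0 ≥ 0; M0 is initialised from the longest-TR
sample and T1 by log-linearising `1 − M/M0` over the informative TRs.
Degenerate pixels (constant signal, fewer than three distinct TRs,
non-convergence, non-physical solutions) are flagged invalid in the output
map instead of raising; ROI statistics use valid pixels only, so a few bad
pixels never poison a region mean.

**Two-compartment oximetry.** Tissue R1 is treated as a volume-weighted sum
of an aqueous and a lipid rate, `R1_T = V_A·R1_A + V_L·R1_L` with
`V_A + V_L = 1`; water and corn oil calibrations stand in for the two
phases. Given reference rates at a physiological pO2 the fractions follow in
closed form, `V_A = (R1_L − R1_T)/(R1_L − R1_A)`. The reference pO2
defaults to 40 mmHg (normal tissue); the reference rates default to the
calibration regressions evaluated there (0.2239 and 1.5454 s⁻¹ from the
bundled phantom tables, matching the published 0.220/1.546). A tissue R1
outside the interval spanned by the two references has no admissible
fraction; the default is to reject it (scalar mode) or mark the pixel
invalid (map mode), with clamping to [0, 1] behind a flag.

The O2 shift uses the fraction-weighted sum of per-phase quotients,
`ΔO2 = V_A·(ΔR1/r1_A) + V_L·(ΔR1/r1_L)`, evaluated once with per-mM
relaxivities (giving mmol/L) and once with per-mmHg relaxivities (giving a
mmHg equivalent). The expression admits a second algebraic reading —
`ΔR1/(V_A·r1_A + V_L·r1_L)` — that does **not** reproduce the published
worked examples (it gives 0.18 rather than 0.28 mmol/L for the cortex under
carbogen), so the quotient-sum form is the one implemented. ΔO2 is linear
in ΔR1 and bracketed between the two single-phase quotients (both tested as
properties). The mmHg form is reported as an *equivalent* derived from the
calibration units, without further physiological interpretation.

**Calibration constants.** Gas pO2 uses dry-gas fractions times 760 mmHg
(air 0.21, carbogen 0.95, O2 1.0, N2 0) with no water-vapor correction —
this convention reproduces the published corn-oil relaxivity from the
bundled R1 table. Relaxivities default to the published pairs
(water 1.71×10⁻⁴ mmHg⁻¹s⁻¹ / 0.118 mM⁻¹s⁻¹; corn oil 8.20×10⁻⁴ / 0.569).
The Henry-type conversion between the unit systems defaults to
690 mmHg per mM at 30 °C, the ratio implied by the published water pair,
and is applied to both phases on the grounds that O2 solubility in water
and corn oil was found equivalent; it is configurable
(`convert_r1_units`).

**TOLD kinetics.** ΔM%(t) = 100·(M(t) − M̄_base)/M̄_base with M̄_base the
mean over the baseline window, which defaults to every frame before the
first challenge onset. For ROI curves the ROI-mean intensity is formed per
frame first and ΔM% taken of that trace (not the mean of per-pixel ΔM%),
matching how per-ROI time courses with error bars are normally computed.
Frame times follow the frame-start convention (t_i = i·Δt); gas-switch
times come from the schedule, never inferred from the data, and the frame
containing a switch belongs to the gas active at its start (left-closed
intervals).

The rising phase is fitted with `S(t) = S_max·(1 − exp(−(t−onset)/T_ox))`
by nonlinear least squares on the frames from the challenge onset to the
gas-off time (the fit window defaults to the full challenge interval; a
plateau margin is not added). T_ox is the time to reach 63.2% of S_max and
k_ox = 1/T_ox is stored as the exact reciprocal. Initialisation: S_max from
the window extremum, T_ox from the first 63.2% crossing; bounds
S_max ∈ (−100, 1000) %, T_ox ∈ (0.01, 100) min. A flat window returns
S_max = 0 with the convergence flag cleared. The consumption rate k_oc is
the negative least-squares slope of ln ΔM% against time over the first
five positive points strictly after gas-off (n_points configurable);
non-positive values inside the window are excluded and counted. The decay
is fitted on raw ΔM% (asymptote 0, i.e. return to the pre-challenge
baseline), and k_oc is an operational index, not a CMRO2 model.

## Synthetic data

The generator emulates three acquisitions with known ground truth: a
two-tube (water/corn oil) cross-section with per-gas T1 from the bundled
phantom table; a three-region brain (cortex annulus, ventricles and caudate
discs inside it, 64×64 single slice by default, disjoint masks by
construction) with per-gas T1 and carbogen challenge kinetics from the
bundled in vivo tables; and the forward models above for both series types.
The TOLD response rises toward S_max during each challenge window and
decays exponentially toward the pre-challenge baseline after gas-off;
repeated challenges are supported (each rise starts from the current
level), though no published data constrains multi-cycle behavior. Noise is
additive Gaussian on the magnitude image with sd = sigma·M0 (default
sigma = 0.02, representative of the high-SNR regime these experiments run
in); a Rician option exists behind a flag for low-SNR studies. Identical
scene, schedule and seed give bit-identical output.

What the generator does **not** emulate: Bloch-level sequence physics
(FLASH/RARE flip-angle and TE effects are absorbed into M0), B0/B1
inhomogeneity, motion, physiological noise, partial-volume mixing at region
boundaries, or animal-to-animal variability. Passing round-trip tests
therefore demonstrates correctness of the estimators under the stated
signal models, not robustness to scanner artifacts; motion correction and
DICOM conversion are assumed to happen upstream.

## Published group means as inputs

The in vivo tables bundled in `toldmri.reference` (per-region T1/R1 under
each gas, ΔR1 group means, kinetic indices) are measurements; the package
uses them as phantom ground truth and worked-example constants but cannot
recompute them. Two printed values are known not to be exactly recoverable
from the rounded table entries: the water relaxivity (regression on the
rounded R1 means gives 1.65×10⁻⁴ vs the published 1.71×10⁻⁴, presumably
fitted on unrounded triplicates) and some secondary ΔO2 entries (e.g. the
ventricles' 0.098 mM and the 100%-O2 mmHg equivalents), which recompute to
slightly different values from the two-decimal inputs. Tests and tolerances
reflect this. Note also that the published per-region R1 means are means of
per-animal reciprocals, so 1/T1 of the published T1 mean does not equal the
published R1 mean (ventricles: 1/2.84 = 0.352 vs 0.38); fractions computed
from a fitted synthetic ventricle map therefore differ from the published
0.88, which is expected, and the published R1 means are used directly where
the published fractions are the target.

## Numerical and I/O choices

Problem sizes are chosen so the full suite runs in well under a minute:
64×64 single-slice grids, 45-frame challenge series, 20 seeds for
median-bias checks. Curve fits use xtol/ftol = 1e-12 (relaxometry) and
1e-13 (kinetics) so noiseless round trips recover ground truth to ≤1e-6
relative error. Images travel as NIfTI-1 with a JSON sidecar for what the
header cannot hold (unit tags, TR ladders in ms, gas schedules, frame
times); invalid pixels are stored as NaN and rebuilt into validity masks on
read. CSVs use fixed column order and full float precision, so identical
configs and seeds yield byte-identical outputs (tested).

## Known limitations

Only the two-compartment specialization of the multi-component relaxation
sum is implemented; no temperature-dependent solubility; no absolute pO2
mapping (shifts only); no inversion-recovery or Look-Locker T1 models; no
B1 correction; the mmHg-equivalent ΔO2 inherits the calibration conditions
(30 °C, dry gas at 760 mmHg) and should not be read as an in vivo partial
pressure without further assumptions.
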