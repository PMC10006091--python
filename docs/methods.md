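# Methods

This note records the models behind `vmatqa`, the defaults and why they were
chosen, the numerical decisions, and what the synthetic pipeline can and
cannot say about real measurements.

## Planar dose model

A planar "delivered" distribution is a weighted sum of per-leaf-pair
aperture strips. Each strip is the product of an error-function-edged
profile along leaf travel (the two leaf tips) and an error-function-edged
profile across the leaf width — equivalently a hard rectangle convolved
with an isotropic Gaussian penumbra kernel of width σ (`penumbra_mm`,
default 3 mm, a typical 6 MV 20–80% penumbra of ~4–5 mm). The MLC is a
60-pair bank with 32 inner pairs of 2.5 mm and 2 × 14 outer pairs of
5.0 mm, so the generated maps carry fluence structure at the leaf-width
scale — the scale at which the detector-sampling argument lives. The
collimator angle rotates the evaluation frame (10° by default for
VMAT-like cohorts, 0° where the leaf/row alignment itself is under test).

This generator is an acknowledged stand-in for a TPS dose calculation: no
treatment-planning system model of the delivered fluence is available, and
none is attempted. No tongue-and-groove dose, arc-time resolution or
scatter transport is modelled.

Random cohort plans (`random_field_spec`) draw smooth random tip
modulations (a 7-knot profile interpolated across pairs) inside a
120 × 140 mm field, five segments with weights in [0.5, 1.5] — enough
modulation to create steep penumbra regions without leaving the 27 × 27 cm²
detector area.

### Injectable errors

* `MU_scale` multiplies all dose (or all segment weights) by
  (1 + magnitude); the study default is +2%.
* `DLG_shift` widens every open leaf-pair aperture by the magnitude, each
  bank edge retreating magnitude/2; the study default is +1 mm. Because
  the generator maps apertures straight to fluence, this error is more
  visible here than a 1 mm dosimetric-leaf-gap change is through a real
  TPS model, where tip-rounding compensation absorbs part of it; detection
  rates on synthetic cohorts are therefore upper bounds.

### Measurement noise

Deliveries are measured with optional additive Gaussian noise (clipped at
zero). The study default is σ = 0.005 of the unit open-field fluence
(0.5%), a realistic repeatability figure for array measurements; the
generator itself defaults to σ = 0 since the source analysis states no
noise model. All randomness flows from one integer seed; the pipeline
derives one generator per stage from (seed, crc32(stage name)) so stages
stay independent and reorderable.

## Detector models

Chamber response is a uniform top-hat over the square aperture: a reading
is the mean of all dose pixels whose centres fall inside the half-open
aperture square [c − a/2, c + a/2). The half-open convention matters when
the dose grid aligns with the aperture boundary: counting both boundary
rows would spread the quadrature over a + Δx and bias edge responses low.
No lateral response tails, depth averaging, energy or angular dependence
are modelled, so the published response-overlap fill factor of the
checkerboard array (0.86 → 1.00) is *not* reproduced — only geometric
coverage is (aperture/pitch: 0.5 linear for the 10 mm-pitch array).

Coalescence unions the isocenter acquisition with the +5 mm-shifted
acquisition. Points closer than 0.1 mm are duplicates, merged by
averaging; if any duplicate pair disagrees by more than the tolerance the
coalescence *fails* with the maximum discrepancy attached — the failure
mode that affects real repeated acquisitions. Sampling frequency along a
direction is 1/(minimum centre spacing along that line), computed from the
actual (possibly coalesced) point set; the checkerboard array's along-row
frequency doubles from 0.1 to 0.2 mm⁻¹ under coalescence because the
shifted interstitial grid lands in the main-grid rows.

## Dose reconstruction

Rays diverge from a point focus at 1000 mm source-axis distance; the
detector plane is the isocenter plane (z = 0) inside the phantom. For each
voxel the measured dose and the detector-plane water-equivalent depth at
the voxel's projection onto the detector plane are obtained by scattered
linear interpolation over the measured points (matching the linear
interpolation the commercial reconstruction states), then scaled by
TPR(Z_CT)/TPR(Z_Det) and (a_Det/a_CT)².

Water-equivalent depth is geometric in-contour depth times the mean
relative electron density of the traversed material. Densities are sampled
at fixed midpoints along the ray (voxel/4 steps for single rays; 48
midpoints between the phantom front face and the voxel in the vectorised
volume pass), with nearest-voxel lookup — the defining relation averages
voxel densities, so no sub-voxel density model is warranted. The
detector-plane depths use the *same* midpoint quadrature as the voxel
pass; this keeps the homogeneous-water identity (a voxel at the detector's
own depth and distance reproduces the measured dose) exact to machine
precision rather than limited by two different depth estimators.

Voxels outside the contour are zero; in-contour voxels whose projection
falls outside the measured-point hull are zeroed and counted in a coverage
report. Single-plane geometry only: how the commercial system composites a
rotating gantry into one volume is not public, and one plane exercises the
reconstruction relations fully.

PDD → TPR uses the Mayneord-type relation
TPR(d) = PDD(d)·((SSD + d)/(SSD + d_ref))², renormalised at the reference
depth (15 mm). The analytic 6 MV default is
PDD(d) ∝ (1 − e^(−0.3 d))·e^(−0.0028 d)·inverse-square, giving
TPR(100 mm) ≈ 0.80 and a build-up peak near 15 mm. A tabulated PDD is
linearly interpolated. Note that a depth-constant PDD does **not** give a
constant TPR under this relation — a TPR of 1 at all depths corresponds to
a PDD that falls purely by inverse square (an attenuation-free beam), and
that is the case the tests exercise.

## γ analysis

For each reference point above the low-dose threshold (10% of the maximum
of the *reference* distribution), γ is the minimum over the evaluated
distribution of √(dist²/DTA² + Δdose²/ΔD²), ΔD in absolute units: a
percentage of the reference maximum (global) or of the local reference
dose (local). The evaluated distribution is linearly interpolated on a
uniform sub-grid of step DTA/10; the minimum is searched inside a radius
cap of 3 × DTA (2 mm in profile mode, per the published profile analysis).
A candidate outside the cap would need γ > 3 from the distance term alone,
so capping cannot change any pass/fail decision. Implementation: the fine
grid is padded with +∞ and each reference point gathers a precomputed
circular window of offsets, so the search is exact (no per-point
interpolation error beyond the sub-grid itself) and vectorised. Undefined
regions (outside the scattered-point hull) drop out of the minimum as +∞;
a reference point with no candidate gets γ = ∞ and fails.

The same kernel runs 2D planes, 3D voxel blocks (with a coarser sub-grid
override for desk-scale volumes) and the per-point profile mode. Pass rate
is 100 × #{γ ≤ 1}/#{above threshold}.

## SPC and process capability

Individuals-chart statistics follow the standard moving-range estimator:
m̄R = mean |x_i − x_{i−1}| (divisor n − 1), CL = x̄,
LCL = x̄ − 2.66·m̄R, computed on the first 20 in-control points; every
point of the series is then flagged against that baseline limit. Only the
lower limit is meaningful for a pass-rate capped at 100%.

Action limits: ΔA = β·√((x̄ − T)² + σ²) with β = 4, T = 100%,
LAL = T − ΔA/2, UAL = 100%. Both σ (process SD) and s (capability SD) are
estimated by the sample standard deviation (ddof = 1) of the same series —
the source distinguishes the symbols but provides a single data source;
the choice is recorded in the output metadata. C_pk = min{C_pl, C_pu} with
C_pl = (x̄ − LAL)/(6(1 − P_x)s), C_pu = (UAL − x̄)/(6 P_x s); P_x
(probability of x ≤ x̄) is the empirical proportion by default, with the
normal-theory value 0.5 selectable. For a pass-rate metric whose only real
specification is the lower action limit, C_pl is the operative index (a
process sitting tightly near 100% minimises C_pu without being in any
sense incapable); both are always reported. In the pipeline, each cohort's
capability is assessed against the LAL derived from its *SA* partner
cohort, so the coalescence process is judged inside the SA process
variability. Out-of-control points (below the LCL) are dropped once, in a
single pass, before capability — no iterative re-estimation.

Cohort comparison gates on normality (Shapiro–Wilk and a
Kolmogorov–Smirnov test against the fitted normal, both at α = 0.05) and
uses the paired t-test when both cohorts pass, the Wilcoxon signed-rank
test otherwise. IQR uses linear interpolation of order statistics (type
7); a median-of-halves ("tukey") convention is selectable and is the one
under which IQR(1..8) = 4 rather than 3.5. Table-style report rounding is
two decimals, half away from zero.

## Sensitivity and ROC

Δγ = γ_NE − γ_IE per plan; Δγ > 0 counts as detected. For ROC, the
no-error pass rates are the control group, error-injected pass rates the
test group, and a *lower* pass rate scores as more error-like (the
direction is a package convention; the source plots ROC without stating
one). The curve sweeps all thresholds of the pooled scores; the trapezoid
AUC equals U/(n₁n₂) of the Mann–Whitney statistic with ties at half
credit, and the p-value comes from the two-sided rank-sum test on the two
independent collections (a paired alternative is available). The error
cohort defaults to 8 plans, mirroring the original experiment; AUC
estimates at that size are coarse (steps of 1/64), which the study
tolerates because the effects of interest are large.

## Study pipeline and problem sizes

The default study measures a 24-plan QA cohort (20-point chart baseline
plus post-baseline monitoring) and an 8-plan error cohort, on both arrays,
both procedures, 3%/2 mm global for charting and 3%/2 mm global + local
for sensitivity; maps are generated at 1 mm, references evaluated at
2.5 mm (the grid resolution of typical clinical dose calculations). These
sizes keep a full seeded study to a few minutes on one CPU while leaving
every chart with enough points to be meaningful; all of them are config
fields. A run writes its resolved config, per-cohort series, sensitivity
records, and a summary JSON sufficient to regenerate every figure;
identical config and seed give a byte-identical summary.

## What the synthetic results do and do not show

The generator reproduces the *mechanisms* — leaf-scale fluence structure,
area-averaged sparse sampling, interpolation error, coalescence — not any
clinical cohort. Synthetic pass rates are higher and tighter than
clinical ones (no setup error, no output drift, no detector calibration
terms), so chart limits and capability indices from synthetic cohorts are
not comparable in magnitude to published clinical values; only their
*orderings* (coalescence ⇒ higher LCL/LAL, smaller ΔA; denser sampling ⇒
better D50 recovery and MU-error AUC) are the tested claims. DLG-error
detection is easier here than clinically, as noted above. The published
arithmetic that is independent of the patient data — action-limit
conversions, geometry counts, frequency doubling, control-limit
differences, flag bookkeeping — is reproduced exactly by
`scripts/acceptance.py`.

## Degenerate inputs and edge cases

Zero-penumbra fields render as exact top-hats (indicator functions). A
reference distribution with zero maximum yields an empty γ result with a
warning rather than a division by zero. A constant QA series has
LCL = CL and an undefined capability (zero spread), reported as such.
Degenerate ROC groups (no score variation) return AUC 0.5 with p = 1 and
a warning. Coalescing a map with itself at zero shift returns the map
unchanged (all points merge as duplicates). Empirical P_x is clamped to
(0, 1) by half a rank so a one-sided sample cannot zero a capability
denominator.
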