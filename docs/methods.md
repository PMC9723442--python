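# Methods

`sbrteval` evaluates pairs of stereotactic body radiotherapy (SBRT) plans for
synchronous bilateral lung lesions: a *single plan* (S) that optimizes both
targets at once, versus *double plannings* (D), where each target is planned
independently and the two dose distributions are superimposed.  The package
implements the dosimetric and radiobiological evaluation layer only — dose
grids go in, DVHs, plan-quality indices, gEUDs, constraint audits and a
paired cohort comparison come out.  It performs no dose calculation, beam
modelling, optimization or registration.

## Voxel model and geometry

Dose and structure occupancy are point samples at voxel centres; a voxel
belongs to a structure iff its centre lies inside the contour solid.  There
is no partial-volume weighting, so every volume is a voxel count times the
voxel volume and the error of any volume metric is bounded by the surface
voxel layer (about one voxel size relative to the structure diameter).
Axis order is (x, y, z), indices are 0-based, and the physical position of a
voxel is `origin + index * spacing` (mm).  All doses are total physical dose
in Gy held as float64; volumes are cc.

Plan superposition (`sum_doses`) requires exactly matching geometry
(frame id, dims, spacing, origin) and never resamples implicitly; trilinear
resampling (`resample_like`) is a separate explicit step, so a summed dose
can always be audited back to its inputs.  Trilinear interpolation is exact
for affine dose fields at interior voxel centres, which the tests exploit as
an oracle.

## DVH metrics

All point metrics are computed from raw member voxel doses, never from
histogram bins.  "Receiving x Gy" is the closed comparison `dose >= x` and
"receiving less than x Gy" is its strict complement, which makes
`V_x(cc) + V_<x(cc) = V_total` an exact identity and makes target coverage
("V100") the fraction of target voxels with `dose >= prescription`.
Dose-at-volume queries (D_x cc) sort member doses descending (ties broken by
linear voxel index), cumulate volume in voxel steps and interpolate linearly
between voxel boundaries; they are exact at integer multiples of the voxel
volume.  D_min/D_max are true voxel extrema, not percentile surrogates.
The cumulative DVH (default bin width 0.01 Gy, configurable) backs the
gEUD computation and the DVH-file-only workflow; curve-derived metrics are
accurate to one bin width and are only used when no voxel data are
available.

## Plan-quality indices

With PIV the prescription-isodose volume over the body, TV the target
volume and TV_PIV their intersection:

* coverage = 100 · TV_PIV / TV
* CI = PIV / TV_PIV
* nCI = (TV · PIV) / TV_PIV² = CI / (coverage/100)
* HI = D_max / PD, and PIDL = 100 · PD / D_max (reciprocal of HI)
* GI = V(PD/2) / V(PD) over the body (Paddick gradient index)

These are the CyberKnife/Multiplan-style conventions.  They were chosen
because the published target table this package is benchmarked against
satisfies, at its printed 2-decimal precision, both `HI = Dmax/50` in every
cell and `nCI = CI / coverage-fraction` in every row — identities that fail
for the RTOG conformity index (PIV/TV) and for D2%/D98% homogeneity
definitions.  Those alternative families are therefore deliberately not
implemented.  Two documented choices remain configurable: the GI numerator
may reference half the *maximum* dose instead of half the prescription
(`half_of="max"`), and for superimposed plans all indices are computed on
the summed dose, never per component.  GI is a property of the whole dose
distribution; when a per-target table is produced the same global value is
reported on each target row.

If no target voxel reaches the prescription dose, CI/nCI/GI are undefined
and returned as NaN with a `defined=False` flag — never extrapolated and
never an exception, so cohort tabulation can proceed.

## Fractionation-corrected gEUD

Each volume element's total dose D, delivered in `n_f` equal fractions, is
converted to its 2-Gy-per-fraction equivalent with the linear-quadratic
model,

    EQD = D · (α/β + D/n_f) / (α/β + 2),

and the structure gEUD is the power mean with volume-effect exponent a:

    gEUD = ( Σ_i v_i · EQD_i^a )^(1/a),  Σ v_i = 1.

Default parameters (a, α/β in Gy): PTV (10, 10), lung (1, 4), heart
(3, 3.7), spinal cord (20, 3), esophagus (16.67, 4.9); `n_f = 5` with a
uniform dose-per-fraction assumption (no per-fraction dose data exist in a
plan sum).  The tumor exponent is kept positive as published; a
`tumor_a_negative` switch provides the negative-exponent tumor convention
(gEUD then tracks the coldest target region).  Zero-dose elements are
floored at 10⁻⁶ Gy when a < 0 to keep the mean finite (unreachable with the
all-positive defaults).  No validated parameters exist for trachea or
bronchus; the engine refuses to compute gEUD for them rather than guess.
gEUD is computed from the 0.01 Gy differential DVH by default; a voxelwise
path exists for validation and the two agree to 0.1 % in the tests.

The headline comparison statistic is the percent reduction
`100 · (S − D) / S`, positive when the double plan delivers less.

## Constraint audit and cohort statistics

The shipped constraint table encodes the 50 Gy / 5 fraction clinical
requirements (PTV coverage ≥ 95 %, PIDL ~ 70 %; lung V5 < 60 %,
V20 < 25 %, V<12.5 Gy > 1500 cc, V<13.5 Gy > 1000 cc; heart Dmax < 38 Gy,
Dmean < 12 Gy, V32 < 15 cc; cord Dmax < 27 Gy, D0.25cc < 22 Gy,
D1.2cc < 13.5 Gy; trachea and bronchus Dmax < 40 Gy, V16.5 < 4 cc;
esophagus Dmax < 35 Gy, V19.5 < 5 cc).  All comparators are strict as
written except the ~70 % isodose-line objective, which passes within a
configurable ±10-percentage-point band.  Constraints whose structure or
metric is unavailable yield "not evaluable" results, not failures.  The
heart D15cc metric is reported but carries no limit in the table.

The paired comparison reports mean ± sample SD (n−1) per arm, the percent
reduction of means, and a classical two-sided paired t-test on the
per-patient differences (df = n−1).  All-equal differences make t undefined
and are flagged rather than reported as ±∞.  No multiple-testing correction
is applied, matching common practice in planning-comparison studies; the
report records the number of tests performed.

## Synthetic cohort

Because no patient data are distributed, a seeded generator produces
phantoms with the cohort's statistical structure: 2.5 mm isotropic voxels on
a 124×84×88 grid; ellipsoidal body, lungs and heart; tubular cord, trachea,
bronchi and esophagus; one spherical target per lung, built as a GTV sphere
plus a 5 mm isotropic margin.  The margin is applied to the solid before
rasterization (expand-then-rasterize), so the realized PTV volume tracks the
requested volume to within centre-sampling error (≲5 % at 2.5 mm for
clinical target sizes); the grid-level Euclidean margin operator
(`expand_margin`) exists for mask-level workflows and is validated
separately.  PTV volumes are drawn log-uniformly from the clinical ranges
1.67–62.31 cc (PTV1) and 4.49–26.21 cc (PTV2) — median-compatible and
right-skewed like the printed spread.  Targets are peripheral by
construction: placement rejects any candidate within 10 mm of the central
structures (airways, heart, cord, esophagus), mirroring the peripheral-lesion
cohort and keeping the falloff shell off the bronchial tree.

The dose model is phenomenological: per target a plateau of `PD · peak`
inside the PTV with a Gaussian-shell falloff `exp(−(r−R)²/2σ²)` outside,
plus a smoothly apodized low-dose body bath and optional Gaussian noise
(clipped at 0).  The two arms encode how the planning strategies differ in
practice: the single plan uses a broader falloff (σ = 4 mm) and larger bath
(4 Gy), the double plan a tighter falloff (σ = 3 mm), a smaller total bath
(2.8 Gy, split evenly between its two component plans so each is a valid
plan) and a slightly hotter plateau (peak 1.47 vs 1.42 of PD, i.e. a
prescription isodose line near 70 %).  Coverage of both PTVs at the
prescription dose is verified after generation; if below 95 % the plateau is
inflated by 5 % and generation retried a bounded number of times.  All
randomness flows through named substreams (geometry, dose, noise) derived
from the per-phantom seed, and per-patient seeds derive from a cohort master
seed, so every artifact is a pure function of spec + seed.

What this emulates — and what it does not.  The generated cohort reproduces
the clinical study's *directional* findings at its defaults: the double plan
has lower GI, lung V5/V20 and normal-tissue gEUD, and slightly higher target
Dmean/HI, and every generated plan passes the constraint table.  It does
not reproduce patient-level magnitudes (e.g. GI near 5–6, lung V5 near
38 %): those depend on real anatomy, beam geometry and the commercial
optimizer.  Between-patient variability of mediastinal doses is also
understated because the organ layout is fixed across phantoms (only the
targets vary).  Passing tests therefore demonstrate correctness of the
evaluation machinery and of the constructed contrast, not clinical
calibration.

## Numerical choices and problem sizes

Conformity/coverage ratios are computed from voxel counts before unit
conversion, so full coverage is exactly 100 %.  DVH histograms use
`searchsorted` on sorted member doses (exact counting, no binning error in
the counts).  The default study size is 10 patients — the size of the
emulated cohort — on the 124×84×88 grid (about 0.9 M voxels); the full
pipeline (generation, both arms, all metrics, audit, report) runs in well
under a minute on one CPU.  Tests use a topologically identical reduced
phantom where full resolution is not the point.

## Known limitations

* DICOM support is deliberately narrow: axis-aligned RTDOSE in Gy with
  uniform frame offsets; RTSTRUCT rasterization is centre-in-polygon per
  slice without hole subtraction.
* No average-DVH plotting, TCP/NTCP modelling, nonparametric statistics or
  multiple-testing correction.
* Lung metrics use the lungs as contoured (minus overlapping mediastinal
  structures); a lungs-minus-PTV variant can be built with the mask algebra
  but is not the default.
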