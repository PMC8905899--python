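# Methods

`biorange` quantifies what switching a proton plan's RBE weighting from the
clinical constant (cRBE, factor 1.1) to a variable, LET-driven model
(vRBE, McNamara) does to the RBE-weighted dose distribution: DVH indices,
organ-at-risk constraint compliance, and the *biological range extension*
measured through equivalent-sphere V95 volumes. Because clinical CT/plan
data are not distributable, the pipeline runs on a synthetic phantom
simulator whose study conditions mirror a two-group brain / skull-base
cohort; everything downstream of the simulator applies unchanged to any
co-registered dose + LET_d grids.

## Synthetic phantom model

**Depth-dose.** The range-energy relation is Bragg-Kleeman in water,
`R = alpha_BK * E^p` with `alpha_BK = 0.0022 cm/MeV^p`, `p = 1.77`. A proton
with residual range `u` has stopping power `S(u) = K u^(1/p - 1)`
(`K = alpha_BK^(-1/p)/p`). End-of-range depths are Gaussian with
`sigma = 1.4% of R0` — range straggling (~1.2%) plus a beam-energy-spread
allowance; with that spread an 11-peak SOBP over a 5 cm modulation meets
the <=2% plateau-ripple contract, which is how real delivery systems choose
their energy-layer spacing. The pristine depth-dose is the ensemble mean
`D(z) ∝ E[S(R - z)]`, a Bortfeld-style closed form evaluated by a
singularity-removing substitution (`u = t^(1/(1-q))` kills the integrable
`u^-q` divergence exactly) on a dense trapezoid grid.

**Depth-LET.** The dose-averaged LET is the second-moment ratio of the same
ensemble, `LET_d(z) = 0.1 * E[S^2]/E[S]` keV/um. This is what makes the
curve physically sensible: a track-averaged Bragg-Kleeman LET at 1 mm
residual range is only ~4.9 keV/um, while dose averaging over the
straggling ensemble lifts the distal edge into the observed 8-20 keV/um
band (entrance plateau ~0.6 keV/um). The curve keeps rising a few mm past
`R0` and is capped at 18 keV/um: beyond the distal edge the
primaries-only ensemble over-weights the final sub-millimetre of track, a
regime where this analytic stand-in no longer represents a transport
calculation. It is clamped at its `R0 + 5 sigma` value further out, where
the dose is below 1% of the peak.

**SOBP.** Pristine peaks with ranges spanning `[R0 - m, R0]` are weighted
by non-negative least squares against a flat plateau. The fit region stops
5% of `m` short of `R0` (the deepest peak's own distal falloff cannot be
flattened; forcing it distorts the plateau). Peak count is chosen so the
spacing stays below ~1.3 straggling sigmas. The SOBP's depth-LET curve is
the dose-weighted mix of the constituent peaks' curves.

**Geometry.** One case is a spherical water-equivalent "head" (radius 66 mm)
on a 1.5 mm isotropic lattice (96^3 default), containing a spherical PTV,
CTV = PTV eroded by 3 mm (Euclidean distance transform), a brainstem slab
3 mm distal of the PTV along +x, a smaller chiasm slab lateral along +y,
and the body mask. Fields are parallel broad beams in the axial plane
(gantry 90 deg -> +x); water-equivalent depth is the chord length from the
body surface along the ray through each voxel. Each field's range reaches
the distal PTV edge plus a 2 mm margin (with 1 mm Gaussian jitter per
field), the modulation spans the PTV diameter, and the lateral profile is a
flat top (PTV radius + 3 mm) with a 3 mm Gaussian penumbra plus a broad
(2.5 x aperture) taper that keeps each field's maximum on-axis. Plans are
normalised by one global weight factor so the median of `1.1 x D_phys` over
the PTV equals the prescription.

**Cohort conditions.** Brain-like: alpha/beta(target) 6 Gy, prescriptions
36-61.2 Gy(RBE) at 1.8-2.0 Gy(RBE)/fraction, 2-4 fields, PTV radii
17-27 mm. Skull-base-like: alpha/beta 4 Gy, 70-74 Gy(RBE) at 2.0/fraction,
2-6 fields, PTV radii 12-20 mm. One field per case is aimed so its distal
edge faces the brainstem slab; the rest alternate between the two opposing
lateral windows (60-120 and 240-300 deg), the usual clinical arrangement.
All per-case randomness (prescription, geometry, angles, jitters, optional
noise) flows from a single case seed; cohort seeds fan out from one
top-level seed.

## RBE weighting

cRBE: `D_RBE = 1.1 * D_phys`, exactly.

vRBE (McNamara): with `(a/b)_x` the tissue alpha/beta ratio and fraction
dose `d`,

    RBE_max = p0 + p1 * LET_d / (a/b)_x
    RBE_min = p2 - p3 * sqrt((a/b)_x) * LET_d
    RBE = (1/2d) * ( sqrt( (a/b)_x^2 + 4 d (a/b)_x RBE_max
                           + 4 d^2 RBE_min^2 ) - (a/b)_x )

with published fit coefficients `p0 = 0.99064`, `p1 = 0.35605`,
`p2 = 1.1012`, `p3 = 0.0038703` (injectable via `RBEModelParams`). The dose
argument is evaluated **per fraction** (`d = D_phys / n_fractions`) and the
weighted total is `n * d * RBE = D_phys * RBE` — standard isoeffect
practice; total-dose evaluation is available via `per_fraction=False`. The
`d -> 0` limit (`RBE = RBE_max`) handles zero-dose voxels. The alpha/beta
map is two-valued: the target ratio inside the PTV, 2 Gy elsewhere.
Plan-level LET_d is the dose-weighted average of per-field LET_d grids,
which is algebraically identical to event-level scoring
(`LET_d = (1/rho) * sum(dE * dE/dx) / sum(dE)`) on the pooled events; both
routes are implemented and cross-checked. RBE map statistics are restricted
to voxels above 5% of the prescription (below that the quotient is
clinically meaningless); empty filtered sets report NaN, never zero.

## DVH conventions

Cumulative (>= dose) histograms, uniform voxel-volume weighting, 0.1 Gy
default bins. `Dx` ("highest dose covering x% of the structure") is the
linearly interpolated `(100 - x)` percentile of voxel doses; it agrees with
the exhaustive nearest-rank search within one voxel-dose gap. `Dmax` is the
raw maximum voxel value (no near-max volume smoothing). V95 counts body
voxels at or above `0.95 * D_p` (whole-grid evaluation available by passing
no body mask). Constraint checks: brainstem core 54, brainstem surface 64,
chiasm 54 Gy(RBE); the whole brainstem Dmax is checked against both
brainstem limits as two rows.

## Biological range extension

`R_ext = R_vRBE - R_cRBE` with `R = (3 V95 / 4 pi)^(1/3)`. Volume-based
rather than profile-based, so it is insensitive to dose inhomogeneity and
field arrangement; a 1-D distal-profile range finder is included only as a
validation oracle for single-field cases. Negative extensions are reported,
not clamped. Group summaries are means of per-case radii/extensions, not
radii of mean volumes.

## Robustness scenarios

12 scenarios: the cartesian product of +/-3.5% HU x +/-2 mm isocenter
shifts along each axis (the product reading is the only one that yields 12
cases; the additive 8-scenario reading is available behind
`make_scenarios(additive=True)`). In the phantom, the HU perturbation maps
to a `(1 -/+ 0.035)` rescaling of each field's water-equivalent range
(HU -> relative stopping power is approximately proportional), and the
shift rigidly translates the beam-axis geometry before retracing; field
weights stay at planned values (beam output is unchanged by setup error).
All scenarios are evaluated under cRBE only, as in clinical practice. The
comparison metrics are `CTV_diffRobust = D95_cRBE - min(D95)_robust`,
`CTV_diffRBE = D95_vRBE - D95_cRBE` (CTV, D95) and
`OAR_diffRobust = max(D05)_robust - D05_cRBE`,
`OAR_diffRBE = D05_vRBE - D05_cRBE` (per OAR, D05).

## Statistics

Percentile bootstrap (default 100,000 resamples, reducible for tests with
correspondingly wider CI jitter) around the median, 2.5-97.5 percentiles.
Paired model comparisons: two-sided Wilcoxon signed-rank (scipy), zero
differences dropped, exact null for small untied samples and tie-corrected
normal approximation otherwise; fewer than 5 nonzero differences is
reported as a degenerate NaN. Pearson's r for associations; NaN at zero
variance. Raw p-values, no multiple-testing correction.

## Numerical choices

- Voxel convention: 0-based indices, axis order (x, y, z), world =
  origin + (index + 0.5) * spacing, masks half-open on voxel boundaries.
- Moment integrals: 600-node trapezoid in the substituted variable; the
  pristine-peak normalisation uses the true peak value from an internal
  dense grid so curves are independent of the caller's depth grid.
- `sigma = 0` Bragg curves are cut off sharply at `R0` and normalised over
  the supplied grid (the bare power law has no finite peak).
- NIfTI persistence: float32 grids (round trip good to ~1e-7 relative),
  uint8 masks, diagonal LPS affine; lattice metadata validated on load.
- Scenario recomputation reuses cached SOBP curves: the 12 scenarios need
  only the two HU variants of each field's depth curves.

## Problem sizes

The shipped analyses and acceptance run use 10 + 10 cases on 96^3 grids,
robustness scenarios for 3 cases per group, bootstrap calibration with
1000 replicates of n = 50 (2000 resamples each), and 1000-repeat Wilcoxon
null simulations. These sizes give stable orderings and sub-hour runtimes
on a single CPU; all of them are parameters.

## What the phantom does and does not show

The simulator reproduces the *structural* features the method relies on:
rising distal LET_d, OARs abutting the target in the distal falloff,
prescription-normalised multi-field plans, and the two alpha/beta groups.
Passing cohort tests therefore demonstrates the machinery and the model's
ordering predictions (vRBE raises target and OAR dose, more so at low
alpha/beta; V95 grows under vRBE; distal OAR RBE exceeds PTV mean RBE) —
not patient-specific magnitudes. Known gaps versus real data: homogeneous
water-equivalent anatomy (no heterogeneities, so the HU perturbation acts
on range only), primary-proton LET without secondaries (hence the 18
keV/um cap), parallel broad beams rather than scanned pencil-beam fluence
maps, axial-plane fields only, and geometric target/OAR shapes. OAR
constraint exceedances consequently come out larger than clinical values;
their direction and ranking between models are the meaningful outputs.
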