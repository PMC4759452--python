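# Methods

`luquant` models the complete quantitative imaging chain used for post-therapy
Lu-177 dosimetry: a known activity distribution is imaged by a SPECT/CT
system, reconstructed with increasing levels of physics compensation, converted
to absolute concentration through a phantom calibration, and finally turned
into organ dose through time-activity-curve fitting.  This note documents the
models, their assumptions, the tunable parameters and the deliberate
simplifications.

## Digital phantoms

**Torso phantom.**  An elliptical water cylinder (default semi-axes 19 x 13 cm;
the physical phantom's outer dimensions are configuration, not physics) holds
two ellipsoidal lungs at 0.3 g/cm^3 (volumes ~1134 and ~907 cm^3) and nine
spherical inserts of 0.4-104.4 cm^3.  Region masks are fractional-occupancy
grids from deterministic sub-voxel supersampling (default 3^3 per voxel,
automatically refined so the sampling spacing stays below ~radius/10 for
sub-voxel spheres).  Activity painting assumes every insert was filled from
one stock solution: inserts sit at exactly 30x the background concentration,
the active left lung at 1.7x, the right lung is cold, and the background
concentration is solved in closed form so the voxelized total is exactly the
configured 806 MBq.  The insert table (volumes, activities) is carried
separately as nominal metadata; painted concentrations are used as ground
truth for recovery coefficients.  Insert positions are not a printed
specification; the defaults put Q2/Q3 beside the lungs under the sternum and
the other seven on an elliptical ring in the abdomen, with an overlap check
that names colliding inserts.

**Calibration phantom.**  A 6.6 cm diameter x 15.3 cm bottle (525 cm^3) at
0.45 MBq/ml centred in a water cylinder emulating a Jaszczak body
(radius 10.8 cm).

Attenuation maps are built directly in mu at 208 keV: water 0.137 cm^-1
(configurable physical constant), lungs density-scaled to 0.3x water.  A
bilinear HU-to-mu conversion (`hu_to_mu`) is provided for CT-style inputs,
anchored at air and water with a shallower bone slope above the breakpoint.

## System model

The projector is rotation-based and parallel-beam.  Per view the volume is
resampled into a detector-aligned frame, each voxel is weighted by its
transmission along the ray to the collimator face (cumulative mu with a
half-voxel offset, i.e. attenuation to the voxel centre), each constant-depth
plane is convolved with an isotropic Gaussian whose FWHM grows linearly with
plane-to-collimator distance, and planes are summed.  Projection pixels carry
MBq-equivalents; expected counts are `dwell x sensitivity` times that.

Defaults for the medium-energy parallel-hole response are FWHM(d) = 4 mm +
0.5 mm/cm x d; the camera planar sensitivity default (10 cps/MBq) only sets
the noise level and cancels through calibration.  The non-circular orbit
follows the support function of the body ellipse plus a 2 cm margin.

Two implementation choices make the back-projector the exact numerical
adjoint of the forward projector (dot-product identity to ~1e-15, which OSEM
needs for quantitative stability):

* in-plane rotation is a sparse matrix of bilinear-interpolation weights and
  back-rotation applies its transpose;
* the per-plane blur is a circular convolution evaluated in frequency space
  with an analytically sampled Gaussian response — a symmetric operator with
  unit DC gain, so it conserves counts exactly and is self-adjoint.  Circular
  wrap-around is irrelevant in practice because the phantom never approaches
  the lateral edge of the field of view; the band-limited kernel rings
  slightly negative (~1e-5 relative) near sharp edges, which downstream code
  clips at zero.

## Monte-Carlo scatter with forced detection

The scatter term of the projections is estimated by photon-tracking Monte
Carlo accelerated in three ways: transport runs on a grid coarsened by a
factor of 2 (the "sparser matrix"); at every sampled Compton interaction the
probability of scattering into each view is computed analytically from the
Klein-Nishina distribution, attenuated along the exit path and gated by the
20 % window at 208 keV via the Compton energy-shift formula (forced
detection); and the collimator blur is applied per source-depth bin on the
coarse detector grid before trilinear upsampling (convolution-based forced
detection with 4 depth bins).  Each photon's contribution is
`(A_total/N) * 4pi * p_KN(theta) * T_exit`, which puts the estimate on the
same per-decay scale as the primary projector.

Simplifications, stated as assumptions: single scatter order by default
(higher orders available and increase the estimate), exit attenuation uses
the 208 keV mu map for all accepted energies (window-accepted scatters lose
< 10 % energy), photoabsorption is neglected (Compton dominates in water at
208 keV), and detector energy blur is not modelled.  The estimator is
validated against a dense acceptance-rejection Monte Carlo with analytic
cylinder geometry (no grids, no forced detection) on a point source in water:
the scatter-to-primary ratios agree within the Monte-Carlo and
discretisation tolerance (15 %).

The simulator uses the same engine with an independent seed and a 2x photon
budget (default 2x10^5 vs 10^5 in reconstruction), so ARS reconstruction
never inverts its own scatter realisation; a matched-model switch stores the
simulated scatter expectation for convergence tests.

## OSEM reconstruction

Standard multiplicative ordered-subset EM, 15 iterations x 16 subsets; 64
views split into 16 subsets of 4 maximally separated views, processed in
bit-reversed order.  Compensation combinations: A (attenuation only,
PSF-free projector), AR (+ collimator-detector response), ARS (+ scatter).
The scatter estimate is refreshed at the start of iterations 1 and 2 only and
frozen afterwards, and enters the forward model term only — it is never
backprojected.  No post-filtering.

The image is in counts scale ("reconstructed counts per voxel"): the forward
model is the unit-scale projector, so the uniform initial estimate
(total counts / number of voxels) is on the right order and the volumetric
sensitivity calibration later absorbs dwell, camera sensitivity and voxel
volume, as a physical calibration does.

Numerical guards (all inert on consistent data; the one-iteration fixed-point
identity holds to < 1e-6):

* epsilon = 1e-10 added to the model denominator before division;
* voxels whose relative subset sensitivity is below 1e-2 (outside the rotated
  field of view for at least one subset) are frozen at zero for the whole
  reconstruction;
* detector pixels fed only by frozen voxels are excluded from the data and
  from the sensitivity normalisation;
* the Poisson ratio is capped at 1e3.  Without the cap, A and AR
  reconstructions of data containing unmodelled scatter can diverge: once the
  air voxels collapse multiplicatively, a pixel holding a few stray scatter
  counts over an underflowed model value injects an unbounded correction
  through the far tails of the response kernel.  Well-fit pixels sit orders
  of magnitude below the cap.

## Quantification

The volumetric sensitivity `S_vol = (R_bottle / V_bottle) / C_true` is
measured per compensation combination from the bottle reconstruction, with
the bottle VOI drawn as the bottle's nominal cylinder (emulating manual
CT-based delineation).  Insert recovery is
`cRC = (R / (V * S_vol)) / C_insert` with R the VOI total and V the VOI
volume — the only reading of the defining quotient under which the estimate
is a concentration.  Quantification VOIs are binary centre-inclusion masks of
the nominal sphere (fractional masks are used only for activity painting);
this deliberately admits the partial-volume losses that the recovery
coefficient is meant to measure, and no partial-volume correction is applied.
A sub-voxel sphere degenerates to the single voxel containing its centre,
with a warning.

## Dosimetry

Organ time-activity curves at 24/48/168 h are fitted with
`y(t) = A0 exp(-lambda t)` by unweighted least squares in linear space,
initialised from the log-linear closed form (exact interpolant for two
points; with three points and no stated weighting scheme, unweighted linear
least squares is the declared choice).  Derived quantities:
`T_eff = ln2/lambda`, cumulated activity `A~ = A0/lambda` (analytic integral
over [0, inf)), and the electron self-dose `D = A~ * E_mean / m` with
`E_mean` = 147.9 keV per decay (ICRP-style tabulation for Lu-177, a config
constant) and m the organ mass, an explicit input.  Photon cross-dose is out
of scope; Lu-177 electrons carry ~96 % of the absorbed dose, so method
comparisons are reported as relative differences against the A baseline.
Non-decaying fits are flagged non-physical instead of raising; the derived
quantities then refuse to evaluate.

## Study conditions and problem sizes

The torso study runs on a cropped abdomen grid of 96 x 96 x 64 voxels at
4.8 mm (the full clinical matrix is 128 x 128 x 128; the crop covers the
lungs, the sternum inserts and the abdominal ring), 64 views x 20 s,
reconstruction 15 x 16, scatter 10^5 photons per reconstruction update and
2x10^5 in the simulator, three Poisson noise seeds per study.  The
calibration phantom runs on 64 x 64 x 48.  The synthetic kidney dosimetry
study uses a 48 x 48 x 32 grid, 32 views, 8 subsets and 5 iterations with a
long dwell — it targets the bias of the dosimetry chain, not its noise.  All
random streams derive from one master seed through named
`SeedSequence`-spawned children recorded in the run report.

## What the synthetic study does and does not show

The generator emulates the geometry, contrast, count level and acquisition
protocol of the physical measurement, and the acquisition/reconstruction
de-coupling is only partial: the scatter realisation differs between
simulator and reconstructor, but the collimator response and the attenuation
map are the same model on both sides.  A physical system adds effects that
are deliberately out of scope here — detector energy resolution, septal
penetration, imperfect CT-to-SPECT registration, CT-kernel-dependent mu maps,
deadtime.  Their common net effect is an effectively broader and less
perfectly known response, so matched-model recovery coefficients for the
smallest inserts, where resolution modelling matters most, sit above
physically measured ones.  The binary centre-inclusion VOI amplifies this
for inserts of one or two voxels: it samples the core of the recovered
profile, which response modelling restores first.  The large-insert values
and every ordering, calibration-closure and dosimetry property are
insensitive to both effects.  Passing
tests therefore validate the algorithms and their relative behaviour, not the
absolute small-sphere recovery of any particular camera.

## Known limitations

* Parallel-beam geometry only; no septal penetration, no detector energy
  resolution, no deadtime or motion.
* Scatter: single order by default, 208 keV attenuation on the exit path,
  depth-binned (not per-event) collimator blur, half-pixel alignment of the
  coarse-grid upsampling.
* The mono-exponential TAC model cannot represent uptake phases before the
  first sampling point; the cumulated activity extrapolates the fitted decay
  to t = 0.
* Registration of serial images is bypassed (frames are generated
  pre-aligned).
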