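# luquant

Quantitative Lu-177 SPECT: phantom simulation, OSEM reconstruction with
attenuation / collimator-response / Monte-Carlo-scatter compensation,
recovery-coefficient quantification and time-activity dosimetry.

## The problem

Peptide receptor radionuclide therapy with Lu-177-labelled somatostatin
analogues delivers most of its absorbed dose through beta particles, and
post-therapy SPECT/CT of the 208 keV photopeak is the standard way to
estimate that dose per organ and per lesion.  Quantification is hard:
photon attenuation, Compton scatter and the distance-dependent blur of a
medium-energy parallel-hole collimator all bias the reconstructed activity,
and small lesions lose apparent concentration to partial-volume effects.
Iterative reconstruction can compensate each effect — attenuation (A),
collimator-detector response (R), scatter (S) — and the choice of
compensation combination changes the measured concentrations and therefore
the dose a patient is recorded to have received.

`luquant` implements this measurement chain end to end on digital phantoms,
for physicists and algorithm developers who want a controlled, fully seeded
test bench:

* a voxelized torso phantom with nine spherical inserts (0.4-104.4 cm^3,
  30:1 insert-to-background concentration, 806 MBq total, lungs at
  0.3 g/cm^3) and a 525 cm^3 calibration bottle at 0.45 MBq/ml;
* a parallel-beam projector with cumulative attenuation and a Gaussian
  response whose FWHM grows with distance, built as an exactly adjoint
  forward/back pair;
* Poisson projection simulation (64 views x 20 s, 128-matrix protocol with
  4.8 mm pixels, 20 % window at 208 keV, non-circular orbit);
* Monte-Carlo scatter estimation with Klein-Nishina sampling and
  convolution-based forced detection on a coarsened grid;
* OSEM (15 iterations x 16 subsets) with selectable A / AR / ARS
  compensation, scatter refreshed during the first two iterations only and
  modelled in the forward projection only;
* volumetric-sensitivity calibration and concentration recovery
  coefficients,

      S_vol = (R_bottle / V_bottle) / C_true,
      cRC   = (R_insert / (V_insert * S_vol)) / C_insert ;

* mono-exponential time-activity fitting, y(t) = A0 exp(-lambda t), with
  T_eff = ln2/lambda, cumulated activity A~ = A0/lambda and the electron
  self-dose D = A~ * E_mean / m.

Model and parameter details are in `docs/methods.md`.

## Worked example

Fit a kidney time-activity curve sampled at 24, 48 and 168 h after infusion
and convert it to an electron self-dose:

```python
from luquant import MonoExponentialModel

res = MonoExponentialModel([24.0, 48.0, 168.0], [95.3, 81.0, 40.1],
                           source="left kidney / ARS").fit()
print(res.summary())
dose = res.dose(mass_g=162.0)
print(f"D = {dose.D_Gy:.2f} Gy")
```

prints

```
Mono-exponential TAC fit
------------------------
source        : left kidney / ARS
A0 (MBq)      : 109.3
lambda (1/h)  : 0.0060178
residual norm : 1.169
physical      : True
T_eff (h)     : 115.2
A~ (MBq h)    : 1.817e+04
D = 9.57 Gy
```

The fitted amplitude extrapolates the curve to the infusion time, the decay
constant combines physical decay and biological clearance (T_eff = 115 h),
and the dose converts the 1.8e4 MBq h of cumulated activity into energy
deposited by electrons (147.9 keV per decay) in a 162 g kidney.

The imaging side is driven the same way — for example a full phantom study:

```python
from luquant.pipeline import calibrate_sensitivities, torso_crc_study

svols = calibrate_sensitivities(seed=0)          # S_vol per A/AR/ARS
table, _ = torso_crc_study(seeds=(0, 1, 2), svols=svols, master_seed=0)
print(table.groupby(["compensation", "label"]).cRC.mean().round(3))
```

which yields the recovery-versus-size table (cRC rising from ~0.2 for the
1-cm insert on the attenuation-only images towards ~0.95 for the largest
sphere under full ARS compensation).  A thin CLI wraps the same stages:
`luquant simulate | calibrate | reconstruct | quantify | dose | run-all`.

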