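# Methods

## What the package computes

`spdri` simulates shifted position–diffuse reflectance imaging (SP-DRI) of
skin microcirculation and quantifies how well the capillary diameter can be
recovered from the SP-DRI signal when the optical properties of the skin vary
across individuals.

The chain is:

1. **Tissue model.** A voxelized volume of seven horizontal skin layers
   (stratum corneum, epidermis, papillary dermis, upper blood net dermis,
   reticular dermis, deep blood net dermis, subcutaneous tissue) with
   blood-filled structures: six capillary loops fed by a two-leg superficial
   vascular plexus. Full scale is 950 x 950 x 2000 voxels at 1 um; loops span
   depths 150–300 um, the plexus axis lies at 300 um, the plexus diameter is
   30 um, and loop diameters run over the study grid 4–14 um in 2 um steps.
2. **Optical-property variation.** Each of the 8 media (7 layers + blood)
   carries (mu_a, mu_s, g, n) at 424 nm, the oxyhaemoglobin Soret-band
   wavelength. Every scalar is perturbed independently with a Gaussian of
   30% (mu_a, mu_s) or 3% (g, n) of its base value; out-of-bounds draws are
   rejection-resampled. Analysis uses the 24-predictor reduction
   (mu_a, mu_s' = mu_s(1-g), n per medium).
3. **Photon transport.** A voxel Monte-Carlo engine (numba) with
   Henyey-Greenstein scattering, unpolarized Fresnel handling at every
   refractive-index mismatch, continuous Beer absorption, 1%-threshold
   Russian roulette (survival factor m = 10), a 20 um / NA 0.35 fiber source
   and an NA 0.25 detector on the illuminated face. Per-medium partial
   pathlengths of each detected packet are recorded, so diffuse reflectance
   is rendered by Beer's law in post-processing for any absorption map.
4. **SP-DRI and K_norm.** Two images with the source shifted by 110 px in y
   are registered to a common source frame and divided pixel-wise; the ratio
   is smoothed (Gaussian sigma 10 px), a y cross-section at x = 570 px is
   Savitzky-Golay filtered (order 5, frame 151 px), and each capillary's
   modulation area K_norm is integrated between the local maximum preceding
   and the local minimum following its position.
5. **Calibration and evaluation.** Per property set, ordinary least squares
   of K_norm on diameter yields the intercept beta0 and slope beta1.
   Out-of-bag permuted predictor importance of a bagged tree ensemble ranks
   the 24 predictors (the reduced scattering of the stratum corneum and the
   epidermis dominate both responses); a tuned ensemble (bagging or
   least-squares boosting, 500 cycles) and a closed-form surface
   `z = a1 exp(-b1 x1) + a2 exp(-b2 x2) + c` model the betas; diameters are
   predicted by inverting the line, `d = (K_norm - beta0)/beta1`, and errors
   are summarised as mean/median/SD/CV per true diameter under three
   calibration modes (ensemble, analytic surface, fixed ideal-run betas).

## Reference calibration surfaces

The package ships reference coefficient sets for the beta surfaces as
functions of the reduced scattering of the two outermost skin layers
(mm^-1):

    beta1: 1.251 exp(-0.3319 x1) + 1.046 exp(-0.6513 x2) + 0.1389
    beta0: -3.803 exp(-0.4382 x1) - 2.356 exp(-0.6406 x2) - 0.4093

They serve as the generative truth of the surrogate data generator and as
targets for the surface-fitting code. The constant terms are the asymptotes
for strongly scattering surface layers: highly scattering stratum corneum
and epidermis reflect photons before they reach the capillaries, so the
modulation (and with it beta1) decays exponentially toward a floor.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| volume dims (full / desk) | 950x950x2000 / 240x240x500 | voxels | study geometry; desk preset scales laterally by 240/950, axially by 1/4 |
| voxel size | 1 | um | vessel diameters are resolved at the micrometre level |
| loop diameters | 4–14 step 2 | um | microcirculation states under study |
| plexus diameter | 30 | um | fixed feeding vessel |
| sigma (mu_a, mu_s) | 0.30 | fraction | inter-individual spread of absorption/scattering |
| sigma (g, n) | 0.03 | fraction | these vary little across skin types |
| photons (full / desk) | 1e10 / 1e6 | packets | desk value is what one CPU core handles in minutes |
| roulette threshold, m | 0.01, 10 | — | unbiased termination below 1% launch weight |
| source core, NA | 20 um, 0.35 | — | illumination fiber |
| detector NA | 0.25 | — | single fiber of the detection bundle |
| source shift | (0, 110) px; desk (0, 28) | px | SP-DRI registration offset |
| smoothing sigma | 10 px; desk 2.53 | px | ratio-image denoising (scales with lateral extent) |
| Savitzky-Golay | order 5, frame 151; desk 39 | px | profile filter (frame scales with lateral extent) |
| cross-section column | x = 570; desk 144 | px | profile location crossing the left plexus leg's loops |
| ensemble cycles | 500 | — | stable importance/prediction |
| surface probe band | central 20–80% of min–max range | — | outlier exclusion before surface fitting |

### Placeholder optical properties

The exact base optical-property table at 424 nm is not distributed with the
package. `spdri.presets` ships configurable literature-style values
(Bashkatov/Salomatina-style magnitudes: mu_a 0.3–1.5 mm^-1 and mu_s 15–70
mm^-1 for the layers; blood mu_a 150 mm^-1 at 15 g/dl near the Soret band,
g 0.98). Every algorithm takes the property set as an input; swapping in a
measured table changes no code.

## Scaled-down study design

The full-scale study (2832 runs of 1e10 photons) is far beyond a desktop
CPU, so the desk preset makes three documented reductions:

* **Geometry** scales to 240 x 240 x 500 voxels with two capillary loops on
  one plexus leg; signal-processing constants scale with the lateral extent
  (ratios 10/950 and 151/950).
* **Mirror side/deep boundaries** replace absorbing ones in the transport:
  the reduced box otherwise loses ~70% of all photon weight through its side
  faces, which the full-scale volume would have retained. Mirroring is the
  standard way a finite compute box emulates laterally extended tissue; the
  `-z` detector face is never mirrored.
* **Diameter shells.** The capillary loops are labelled as nested shells
  (inside-4um, 4–6, ..., 12–14), all sharing dermis transport properties,
  and one detected photon set per source position is re-rendered for every
  diameter by assigning blood absorption to the shells inside the diameter.
  At 424 nm a capillary's optical contrast is dominated by oxyhaemoglobin
  absorption (mu_a ~ 150 mm^-1 versus ~0.5 mm^-1 for dermis; the mu_s'
  difference is a few mm^-1 over micrometres of path), so treating the
  capillary as an absorption perturbation is accurate, and because
  pathlength-resolved Beer rendering is exact, re-rendering introduces no
  additional approximation beyond the fixed shell scattering. The payoff is
  that photon noise is fully correlated across diameters: the diameter
  dependence of K_norm is measurable at 1e6 packets, where independent
  per-diameter runs would be dominated by shot noise.

At desk photon counts most pixels hold no photon, so the pixelwise ratio of
the two images is undefined almost everywhere. `compute_spdri` therefore
switches estimator by coverage: dense images (saturated detector, the
full-scale regime) divide pixel-wise and smooth the masked ratio with a
normalized Gaussian kernel; sparse images smooth the two intensity images
with the same kernel and divide the smoothed fields. Both estimate the same
local intensity ratio.

The desk end-to-end analysis reports the designated capillary loop (the
loop nearest the source on the instrumented leg), mirroring the full-scale
analysis which likewise reports one designated loop of the left plexus leg.
The farther loop sits at roughly twice the source distance and is
shot-noise-limited at 1e6 packets; with some seeds its modulation (or that
of the near loop) is not located at all — a desk-scale
signal-to-noise limitation, not a property of the method.

## K_norm: definition used here

The modulation statistic is defined in the originating literature as the
area enclosed by the SP-DRI signal between a local maximum and the
subsequent local minimum. This package fixes the integrand as

    K_norm = integral from y_max to y_min of ( S(y) - S(y_min) ) dy

i.e. the area between the curve and the horizontal level of the minimum,
computed with the trapezoid rule. This reading makes a triangular bump of
height h and half-width w yield exactly h*w/2, is invariant under adding a
constant to the profile, and scales linearly with the modulation amplitude —
the three properties the calibration line relies on. Extremum search is
windowed to half the inter-capillary spacing around each capillary's
apparent position (the capillary position shifted by half the source shift,
where the max–min pair is centred after registration); among candidates the
most prominent extremum wins, which keeps residual noise ripples from
masquerading as the modulation.

## Surrogate data generator

The surrogate module emulates the statistical structure the calibration
stages assume, without photon transport: property sets are drawn by the real
sampler; betas are the reference surfaces evaluated at the drawn reduced
scattering of the two outermost layers plus additive Gaussian noise; K_norm
follows the linear law plus noise. Default noise SDs (0.041 for beta1,
0.063 for beta0, 0.02 for K_norm) were calibrated once so that refitting
the surfaces on a default-sized dataset attains R^2 near 0.85 (slope) and
0.91 (intercept), the regime the analysis is designed for.

What the surrogate does *not* emulate: spatial photon noise of the
reflectance images, extremum-localisation failures (missingness), or any
coupling between predictors beyond what the property sampler produces.
Tests that pass on surrogate data therefore validate the calibration and
evaluation logic, not the transport or signal-extraction stages — those are
tested against physical limits (Fresnel reflectance, weight conservation,
an independent brute-force slab Monte Carlo) and the scaled-down end-to-end
run.

## Numerical choices

* Voxel membership is a voxel-centre test; vessel axes lie on voxel
  boundaries, so even diameters cover exactly that many voxel centres
  across (the 30 um plexus measures exactly 30 voxels).
* Capillary loops are hairpins: two vertical limb cylinders at the two
  anchor coordinates plus a horizontal connector at the turning depth; a
  loop with coincident anchors degenerates to one cylinder.
* Free paths are sampled from the scattering coefficient only; absorption
  is continuous in flight and re-applied exactly at rendering from the
  recorded per-medium pathlengths. Russian roulette uses the in-flight
  weight; the survival boost is stored per packet so re-rendering remains
  unbiased for any absorption map.
* The exponential-surface fit solves the amplitudes and constant linearly
  for fixed decay rates (variable projection) over a small decay grid, then
  polishes all five parameters with a bounded trust-region least-squares
  solver (b1, b2 > 0, analytic Jacobian, perturbed restarts). On noise-free
  surface samples the recovery is exact to ~1e-6.
* The "20–80% of the value range" probe band is read as the central band of
  the observed min–max range, not quantiles; configurable.
* Importance scores follow the out-of-bag permutation scheme: per tree, the
  MSE increase on its out-of-bag rows after permuting one predictor, with
  the mean over trees divided by its standard deviation.
* In the repeated-split evaluation the analytic surfaces are fitted to the
  training rows directly by default (`analytic_source="data"`), which makes
  the analytic mode exact when the data are noise-free;
  `analytic_source="model"` reproduces the alternative of probing the
  trained ensemble on the central-band grid and fitting the surface to its
  responses.
* Whether to pool predictions across the 30 repeats or average per-repeat
  summaries is ambiguous in the design; the default averages per-repeat
  summaries, pooling is a flag. The overall CV per method is the mean of
  the per-diameter CVs.
* Per-run seeds are derived from the master seed with a counter-based hash
  and constrained to (0, 2^31) exclusive.

## Known limitations

* Loops are axis-aligned cylinder hairpins, not curved anatomical loops.
* The engine is CPU-only and unpolarized; no time-resolved detection or
  fluorescence.
* Fresnel reflection at the volume's side and deep faces is not modelled
  (packets are absorbed or mirrored there, by configuration); only the
  illuminated face carries the external-medium interface.
* The desk preset cannot reproduce the full-scale study's quantitative R^2
  and CV tables; those depend on 1e10-photon statistics. The desk targets
  are the method's qualitative signatures: K_norm rising with diameter and
  surface-based calibration beating fixed betas.
* Blood scattering inside capillary shells is fixed to dermis values in the
  shelled (shared-photon) evaluation path; the per-diameter transport path
  (`run_pipeline`) retains full blood optics.
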