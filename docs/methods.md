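# Methods

This note documents the models and numerical choices behind `camoquant`, in
the order data flows through the pipeline: calibration → visual model →
discrimination → statistics, followed by the synthetic-data generator that
stands in for real photographs and the sizes used by the automated checks.

## Reflectance calibration

Photographs enter the pipeline as images containing grey standards of known
nominal reflectance. Per channel, the pixel-value-versus-reflectance
relation is fitted on the standards and inverted:

* **linear** (default): `R = a·p + b`. Two standards determine the map
  exactly; with more it is least squares. The default matches the
  two-standards-per-image design this pipeline targets — {4.88%, 41.73%}
  for every background type except white, which carries {41.73%, 98.24%}
  because its reflectance (85.5%) exceeds the brighter default standard.
  The pairing rule is a fixed lookup (`standards_for_background`).
* **power**: `R = a·p^g + b`, requiring ≥ 3 standards, for cameras with a
  smooth nonlinear (gamma-like) response.

The exact functional form used by existing multispectral-calibration
toolboxes is internal to those tools; the linear/power pair here is this
package's own declared model, validated on synthetic cameras with known
response (two-point inversion exact to 1e-9; gamma-2.2 recovery within
0.005 across a reflectance ramp).

Fitted maps must be strictly increasing; identical standard pixel means or
a decreasing pixel–reflectance relation raise errors rather than produce a
silently wrong calibration. Calibrated values outside [0, 1.2] are clipped
with a logged warning — noise can push flat patches past nominal — rather
than erroring. Pixel coordinates are 0-based with half-open intervals.

The midpoint-grey search used for acclimation substrates takes the target
as the arithmetic mean of the black and white paper reflectances
(0.059 and 0.855 give 0.457) and, given a monotone printed-level →
reflectance curve, returns the level nearest the target (ties to the lower
level). The iterative print-measure-refine procedure converges to this
single-pass nearest search, so that is what is implemented.

## Visual model

Calibrated channel reflectances are mapped to quantum catches of a
trichromatic avian receiver — the peafowl model with single cones SW, MW,
LW and the double cone (dbl) for achromatic vision — by a user-supplied
linear receptor × channel matrix. No published coefficient set exists for
this mapping in a form reusable here, so the matrix is configuration; the
synthetic pipeline defaults to an identity-like mapping (channels →
LW/MW/SW, dbl = channel mean) that exercises all downstream mathematics
without claiming any real camera's coefficients.

Derived metrics per record:

* luminance = q_dbl (taken directly);
* standardised catches s_i = q_i / (q_SW + q_MW + q_LW);
* colour-space coordinates x = √(1/2)·(s_LW − s_MW),
  y = √(2/3)·(s_SW − (s_LW + s_MW)/2) — the achromatic point maps to the
  origin and the three pure-catch vertices are equidistant at √(2/3);
* saturation = √(x² + y²);
* hue = s_MW − (s_LW + s_SW)/2, a signed scalar in [−1/2, 1] (not an
  angle; no wrap-around semantics). Under the sum-to-one constraint
  hue ≡ 1.5·s_MW − 0.5, an identity the tests use as a second
  implementation.

Receptor noise propagates from the reference (most abundant) cone:
e_i = √(η_ref / η_i)·e_ref. With peafowl densities SW 1.9 : MW 2.2 : LW 2.1
and e_MW = 0.06 this gives e_SW = 0.064564…, e_LW = 0.061413…. Display
convention: `printed_receptor_noise` truncates (not rounds) to 4 decimals,
giving the conventional (0.0645, 0.06, 0.0614); all computation uses full
precision. The shipped background hue references (beige 0.005, brown 0.015,
green 0.075) are measured values for labelling only, never recomputed.

## Receptor-noise-limited discrimination

Distances are the log-contrast form of the receptor-noise-limited model
(Vorobyev–Osorio with logarithmic catch contrasts, per the Siddiqi-style
modification). With Δf_i = ln(q_i^A / q_i^B):

* achromatic: ΔL = |Δf_dbl| / e_dbl, Weber fraction e_dbl = 0.2;
* chromatic (trichromat):
  ΔS² = [e_SW²(Δf_LW−Δf_MW)² + e_MW²(Δf_LW−Δf_SW)² + e_LW²(Δf_SW−Δf_MW)²]
  / [(e_SW·e_MW)² + (e_SW·e_LW)² + (e_MW·e_LW)²].

ΔS is equivalently the noise-weighted distance of Δf from the nearest
uniform shift, min_c Σ((Δf_i − c)/e_i)² — the generic n-receptor form the
test suite implements independently as an oracle (agreement to 1e-9). This
makes ΔS symmetric, zero iff the two stimuli differ only in intensity,
invariant to rescaling either stimulus, and a seminorm (triangle inequality
holds).

Detectability bands in JND units: < 1 indistinguishable; 1–3 possibly
detectable under good viewing conditions; > 3 increasingly distinguishable.
Values exactly at 1 or 3 fall in the middle band (the 1–3 range is read
inclusively; a documented tie rule, not a claim about thresholds).

Each fish is compared against the background ROI of its own image. The
background is measured once at minute 0 and reused for later time points,
mirroring the single per-image background measurement of the experimental
design.

## Statistics

Per colour metric and background treatment, the repeated-measures model is

    metric ~ time * population + length + sex + (1 | fish)

with time (minutes 0/1/8/15) and population categorical and a random
intercept per fish. Time is categorical, not a continuous trend, because
the scientific questions are per-minute contrasts. Fitting is REML via
`statsmodels` MixedLM (ML for AIC comparison).

**Transforms.** A log or sqrt response transform is selected automatically
by fitting the model under each admissible candidate and maximising the
Shapiro–Wilk W of the residuals; `log` is skipped when non-positive values
are present (JND responses may be zero) and `sqrt` when negatives are.
The choice is overridable per metric in configuration, and the run log
records transform and df method for every model.

**Degrees of freedom.** The fitting backend does not expose a Satterthwaite
approximation, so denominator df use the classical between–within
partition: within-subject effects get N − (#fish) − rank(within-varying
design columns); subject-level effects get #fish − rank(subject-level
design). On the balanced study-sized design (4 populations × 20 fish × 4
times = 320 rows) this gives the interaction test 9 and 228 df — on
balanced data the Satterthwaite solution coincides with this value. The df
method is flagged in every output.

**Contrasts.** Estimated marginal means are computed per population × time
cell on a reference grid (length at its sample mean, sexes equally
weighted). When a transform was used, means are back-transformed to the
response scale before differencing, with delta-method standard errors, so
contrast estimates read in the metric's units. Within each population all
C(4,2) = 6 time pairs form one Tukey (studentised-range) family — the
within-population family matches how time-course results are reported;
a single all-cells family is available via `family="all"` for users who
prefer the more conservative reading. Adjusted p-values are floored at the
unadjusted value.

**Model comparison.** Candidate fixed-effect structures are refitted by ML
and ranked by AIC = −2·logLik + 2k, k counting fixed effects plus the two
variance parameters. REML fits refuse to report AIC.

## Synthetic-data generator

The generator emulates the study's structure: 4 populations × 5 backgrounds
× 20 fish per cell × 4 time points, sex balanced within cells, lengths
Normal(3.5, 0.67²) cm truncated at zero, plus one background ROI row per
fish at minute 0. Backgrounds black (reflectance 0.059) and white (0.855)
use the measured paper values; the chromatic backgrounds use their measured
hues (0.005/0.015/0.075) with reflectances 0.40/0.25/0.18 chosen once as
plausible printed-substrate values (the real papers' reflectances are not
published). A background's nominal saturation defaults to the
least-saturated colour-space point consistent with its hue (closed form).

The trajectory model is the generator's own assumption — the study design
does not parameterise dynamics. Each metric relaxes exponentially toward
its background target:

    m(t) = target + (m0 − target)·(gap + (1 − gap)·e^(−k·t))
           + b_fish + ε(t)

with rate k per minute, `gap` the fraction of the initial mismatch never
closed, b_fish ~ N(0, fish_sd²) drawn once per fish and ε i.i.d.
N(0, resid_sd²). With both SDs zero the closed form is exact (tested to
1e-12 and cross-checked against numerical integration of
dm/dt = −k(m − target)). Default profiles give three fast populations
(k 1.2–1.8, the rapid first-minute regime) and one slow, incomplete changer
(k 0.25), so both observed dynamic regimes are expressible. Instantaneous
minute-0 colour responses are modelled as a background-dependent additive
shift of the starting values (default 0). Sex and length effects default to
zero but are settable so covariate recovery is testable. Within-population
variance components are free parameters, not estimates: defaults
(fish_sd = resid_sd = 0.04 for luminance, 0.004 for hue, 0.008 for
saturation) were chosen once as realistic measurement-scale noise.

Metric triples are inverted to strictly positive cone catches (hue fixes
s_MW; saturation fixes s_LW through a quadratic whose longer-wavelength
root is taken; catches floored at 1e-6; saturations below the hue's
geometric minimum are clamped to it). Rendered images are flat rectangular
patches (background, central fish, corner standards) through a monotone
camera response pixel = offset + gain·R^(1/γ), with region boxes returned
in a JSON sidecar.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: fish shape, pose and pattern; within-ROI
spatial heterogeneity; UV channels; camera spectral sensitivity and RAW
processing; stress-induced colour change; non-exponential dynamics;
heteroscedastic or non-Gaussian measurement noise. Tests validate the
computational pipeline and the inference layer's calibration, not the
biology.

## Sizes used by the automated checks

The simulation checks run at deliberately reduced sizes chosen to keep the
suite fast while leaving Monte-Carlo error small relative to the asserted
bands: null calibration of the interaction test uses 500 replicates of a
one-background, 5-fish-per-cell design (80 rows each); power against a
5-fold rate difference uses 200 such replicates; fixed-effect coverage and
bias use 500 replicates at 25 fish per cell (400 rows). Bias budgets are
expressed as 5% of the fish-level response SD. All simulations are seeded
and deterministic.

## Known limitations

* The camera → cone mapping is user configuration; no spectral-sensitivity
  modelling is attempted.
* Satterthwaite df are approximated by the between–within partition; on
  strongly unbalanced designs (missing cells, unequal fish) the two can
  diverge, and the output flags the method used.
* Hue is a signed scalar suited to the middle-versus-ends contrast; it is
  not a hue angle and saturated non-green colours with equal s_MW are not
  distinguished by it.
* The detectability bands are conventions of the discrimination literature,
  not behaviourally validated thresholds.
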