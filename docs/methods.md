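# Methods

## Forward model

The leaf is modelled as `N ≥ 1` identical absorbing plates with rough
dielectric interfaces (generalized plate model). Constituent contents are
expressed per unit leaf area: chlorophyll a+b `C_ab` and carotenoids `C_car`
in µg cm⁻², anthocyanins `C_anth` in µg cm⁻², brown pigments `C_brown`
(arbitrary units), equivalent water thickness `C_w` in cm and dry matter per
area `C_m` in g cm⁻². Bulk per-plate absorption is the coefficient-weighted
sum divided by `N`. The xanthophyll cycle enters through a convex
combination of two carotenoid end-member spectra (violaxanthin- vs
zeaxanthin-dominated, the latter red-shifted), weighted by the
de-epoxidation fraction `C_x = (Z+A)/(Z+A+V) ∈ [0,1]`. The convex form was
chosen over an additive difference-spectrum formulation because the
estimated quantity *is* a pool fraction; the mixture expresses that
directly and keeps the carotenoid absorption non-negative for any
admissible `C_x`.

Plate transmissivity under isotropic illumination is
`θ(k) = (1−k)e^(−k) + k²E₁(k)`. It is evaluated directly in double
precision with a clamp to [0,1]; the subtractive cancellation at large `k`
costs only a few of the 16 digits, which the unit tests bound below 1e-8
against an independent angular quadrature. Interface transmission uses the
closed-form cone-averaged Fresnel transmissivity `tav(α,n)` (Stern's
integral), with the plate-model conventions α = 40° for the illuminated
surface and α = 90° (isotropic) for internal interfaces. The `N`-plate
stack uses the continuous Stokes solution, with two analytic limits
substituted where the general expressions degenerate: the conservative
limit (`τ → 1`, zero absorption) and the transparent-interface limit
(`r → 0`). Non-integer `N` is handled by the continuous solution itself,
never by stacking integer plates.

## Absorption library

The coefficients of the canonical plate-model calibrations are not
redistributable data, so the package ships a *synthetic* library: Gaussian
bands at literature-plausible centers (chlorophyll 430/462/680 nm plus a
weak 600 nm shoulder; carotenoid end members 424/448/474 nm with the Z
member shifted +12.5 nm; anthocyanin 548 nm; brown pigment decaying from
the blue; a water tail rising toward 900 nm; a broad dry-matter term) and a
refractive index falling from 1.45 to 1.40 across the window. Parameter
recovery is well defined for any self-consistent library, and the library
is pluggable: `leafspec.io.read_library` loads any user-supplied CSV with
the same columns. The generator seed jitters band centers by ±0.5 nm and
amplitudes by ±2% so distinct seeds give distinct but equivalent libraries.

## Inversion

Residuals are the concatenated R and T differences on the 400–900 nm
window at 1 nm (equal weighting by default; a per-channel relative
weighting with a 0.05 floor is available). The optimizer is a trust-region
reflective least-squares solver with box bounds. The chlorophyll-to-
carotenoid ratio constraint 4.4 < chl/car < 6.4 is made exact by
optimizing ρ = C_ab/C_car as a box-bounded parameter and deriving
C_car = C_ab/ρ; a quadratic-penalty variant (final iterate projected onto
the admissible interval) is provided for comparison. Default box bounds
span published leaf ranges: N ∈ [1, 3.5], C_ab ∈ [0.1, 120] µg cm⁻²,
ρ ∈ [4.4, 6.4], C_anth ∈ [0, 40] µg cm⁻², C_x ∈ [0, 1], C_brown ∈ [0, 1],
C_w ∈ [1e-4, 0.05] cm, C_m ∈ [1e-3, 0.02] g cm⁻². Five starts are drawn
from a seeded Latin hypercube over the box; the lowest final cost wins,
ties broken by the lowest start index, making results bit-reproducible for
a fixed seed. Convergence tolerances: relative cost change 1e-10, gradient
1e-8, at most 500 residual evaluations per start. Anthocyanin estimates
below 0.5 µg cm⁻² are reported as not detectable (the green cultivar's
expected state). Spectra with R and T below 1e-3 everywhere in the window
are rejected as degenerate rather than fitted.

## Wet chemistry

The 95%-ethanol assay equations (470/649/664 nm, 1 cm pathlength) are
stored in a solvent-keyed coefficient table; only the ethanol system ships.
Concentrations below −0.01 µg mL⁻¹ invalidate a replicate; absorbances
above ~1.2 trigger a linear-range warning. The combined extract volume
defaults to 2.3 mL (initial 0.6 mL plus 0.6/0.6/0.5 mL washes) and is
configurable. Readings are converted to concentrations first and averaged
afterwards — the equations are linear, so the order is immaterial, but
read-then-average keeps per-replicate traceability.

## Fluorescence indices

QY (φPSII), Rfd and qE are ratio formulas on four trace level summaries;
extraction of levels from raw kinetics happens upstream in the instrument
protocol and is out of scope. A zero denominator flags the single affected
index as NaN instead of failing the record. The Rfd vitality classes use
1.0 as the critical threshold and ≥ 3.0 as "high photosynthetic
efficiency"; the high threshold is read as *reaching* 3.0 (both thresholds
are arguments).

## Study analysis

Area-based optical estimates are converted to dry-mass basis with
treatment-level leaf mass per area (`mg g⁻¹ = µg cm⁻² / LMA / 1000`).
Modelled-vs-measured agreement is summarized as Pearson r plus the fitted
regression line, per grouping-factor level and pooled; groups with fewer
than 3 pairs or a constant vector are flagged rather than computed.
Pooled-PFD growth effects average the two spectral treatments within each
PFD and report `100·(pooled_high − pooled_low)/pooled_high`, rounded to
integer percent — expressing the change relative to the *higher*-PFD mean
is the convention that exactly reproduces the published-style growth
percentages from a treatment-mean table. Inferential statistics (ANOVA,
post-hoc tests) are deliberately excluded; this module is descriptive.

## Synthetic data generator

The generator defines the study conditions for all tests. Truth draws are
`baseline × treatment multiplier × unit-mean lognormal scatter` with an 8%
common leaf-size factor on pigments, a 2% ratio perturbation, 3–5% scatter
on structure/water/dry matter, and anthocyanin forced to zero in the green
cultivar. Truth chl/car ratios are truncated to [4.8, 6.0] — the interior
of the laboratory band — so that *measured* (assay-noise-carrying) ratios
stay within the observed 4.4–6.4 interval. Measurement noise: 1%
multiplicative on R and T (renormalized where R+T would exceed 1, with a
5% cap on the clipping rate), 0.005 additive per absorbance reading with
each stored absorbance the mean of a reading triplicate (the bench
protocol reads the combined extract in triplicate), and 2% on fluorescence
levels. Assay absorbances are obtained by inverting the assay's linear
system from the true mass-based contents (chlorophyll a:b fixed at 3:1),
dry masses drawn uniformly on 1.6–2.8 mg. Fluorescence levels are
constructed from target QY ≈ 0.55 and Rfd/qE schedules that rise with day,
blue fraction and PFD, muted for the green cultivar at the lower PFD.

What the generator does *not* emulate: leaf development and within-leaf
heterogeneity (vein vs lamina sampling), adaxial/abaxial asymmetry,
instrument stray light, or any mismatch between the forward model and real
leaf optics. Passing recovery tests therefore demonstrate the correctness
and self-consistency of the pipeline — not that the same accuracy holds on
real leaves, where model error dominates.

## Problem sizes and determinism

The packaged checks use one 72-leaf campaign for cohort-level properties,
25 noiseless and 50 noisy spectra for recovery and constraint-satisfaction
suites, 10⁴ random parameter draws for energy conservation, and 50 seeded
campaigns for the effect-injection check at day 1 (evaluated on the stored
truth, since it probes the generator's calibration rather than the
optimizer). All randomness flows through explicit integer seeds; repeated
runs are bit-identical.

## Known limitations

- The synthetic absorption library is spectrally plausible but not a
  calibrated coefficient set; absolute retrievals on real spectra require
  loading a real library.
- Reflectance-only or transmittance-only retrieval is not supported; both
  channels are required.
- Fluorescence *emission* is not modelled — only the absorption-side
  xanthophyll term of the forward model and the index arithmetic on
  measured traces.
- Uncertainty on retrieved parameters is limited to multistart spread and
  constraint-activity flags; no formal covariance is propagated.
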