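# Methods

## Model and assumptions

### Decay chain

²²⁵Ac (T½ = 9.92 d) → ²²¹Fr (4.8 min) → ²¹⁷At (32 ms) → ²¹³Bi (45.6 min) →
{²¹³Po (3.7 µs, 97.8 %) | ²⁰⁹Tl (2.2 min, 2.2 %)} → ²⁰⁹Pb. Four alphas are
emitted per head decay: 5.8, 6.3, 7.1 MeV, then 8.4 MeV (via ²¹³Po) or
5.9 MeV (the direct ²¹³Bi alpha). All half-lives are converted to hours at
ingestion; constants live in a packaged CSV (`acdose/data/nuclides.csv`,
NuDat-style values with a reference column) so nuclear-data updates require
no code change. ²¹⁷At, ²¹³Po and ²⁰⁹Tl are treated as in instantaneous
equilibrium with their parents; ²⁰⁹Pb is carried for bookkeeping and
contributes no alpha energy.

The chain is split into two segments, each represented by the imaged
surrogate whose photopeak drives it: the **Fr segment** {²²⁵Ac, ²²¹Fr,
²¹⁷At} (19.2 MeV alpha per head decay; 218 keV photopeak) and the **Bi
segment** {²¹³Bi and daughters} (0.978·8.4 + 0.022·5.9 = 8.345 MeV; 440 keV
photopeak). Daughters within a segment share the surrogate's
time-integrated activity (transient-equilibrium assumption).

### Urine ingrowth model

The measured ²¹³Bi activity of a urine aliquot t hours after collection is
the two-member Bateman solution with short-lived intermediates collapsed:
ingrowth from the ²²⁵Ac in the sample plus decay of the ²¹³Bi present at
collection. Both amplitudes are recovered by bound-constrained nonlinear
least squares (`scipy.optimize.least_squares`, trust-region reflective,
amplitudes ≥ 0). A global scale (counter efficiency) cancels from the
amplitude *ratio*, so the Bi/Ac ratio is trustworthy even when the absolute
efficiency is unknown; absolute outputs then carry an
`absolute_scale_known=False` flag. Counting-mode series are fitted against
per-bin expected counts (efficiency × integrated decays per bin) with
Poisson weights σ = √counts; pre-calibrated activity series are fitted
unweighted against the instantaneous model. A fit ending on the
non-negativity bound is flagged, not failed. Fits require ≥ 5 points
spanning ≥ 3 ²¹³Bi half-lives (≈ 2.3 h); the generators default to 6 h,
after which the transient has decayed to ~0.4 %. The "equilibrium reached"
threshold is a convention exposed as a parameter
(`time_to_equilibrium(fraction)`); a residual transient of 0.3 % gives
≈ 6.4 h.

### Kinetics

Total VOI activities follow A(t) = A(t₀)·e^(−ln2 t/T_eff). With two scans
(the clinical situation: 24 and 48 h, patients discharged afterwards) the
fit is exact interpolation in closed form; residual and uncertainty are then
undefined rather than fabricated. With more points, unweighted (optionally
1/σ²-weighted) least squares initialised from a log-linear regression.
Non-decaying curves are rejected with a dedicated error and listed in the
run log — a negative effective half-life is never clamped.

Time-integrated activity is Ã = A(t₀)·T_eff/ln2, the integral over
t ∈ [0, ∞). Extrapolating to t = 0 treats uptake before the first scan as
instantaneous — standard self-dose practice when no earlier imaging exists,
and a documented limitation. Integration from the first scan is available
(`from_time`); the run log records the bound in force.

### Image quantification

Reconstruction, attenuation/scatter correction and PSF modelling happen
upstream; the package consumes reconstructed cps/voxel volumes. A
calibration factor per energy window — mean cps/voxel in a large VOI of a
uniformly filled cylinder (524 Bq/ml, 8.7 l) divided by the known
concentration — converts to Bq/ml. Images are post-filtered with an
isotropic Gaussian (default FWHM 30 mm; σ = FWHM/2.3548 per axis scaled by
voxel size; zero-padding conserves the total of interior-supported images to
1e-6 relative). Lesions are segmented on the *filtered* first-time-point
image at ≥ 80 % of the regional maximum, restricted to the 26-connected
component containing the maximum; ties between equal maxima are broken by
scan order with a warning. Masks are reused at the later time point, with
optional integer-voxel manual shifts. SUV statistics are read from the
filtered image by default (the unfiltered alternative is a flag): filtering
before read-out matches the segmentation input and is the assumption this
package makes where practice varies. No recovery or partial-volume
correction anywhere — reported lesion SUVs and doses are biased low for
structures comparable to the system resolution, deliberately.

### Dosimetry

MIRD self-irradiation only: D = Ã[Bq·s] × S[Gy/(Bq·s)]. The default energy
model (`alpha_local`) deposits the segment's branching-weighted alpha energy
locally, S = E_α·1.602e-13 J/MeV / mass; photons and electrons are
neglected. VOI mass is segmented volume × 1 g/ml. A user-supplied S-value
table (CSV: nuclide, mass_g, s_gy_per_bq_s, optional alpha_fraction;
log-log mass interpolation) replaces the local model when richer dose
factors are available; RBE then applies to the alpha fraction if given,
else to the whole dose with a logged warning. Under `alpha_local` the RBE
(default 5) multiplies the entire dose, since all counted energy is alpha.
The three methods: (1) whole chain on the ²¹³Bi TAC, (2) whole chain on the
²²¹Fr TAC, (3) Fr segment on the ²²¹Fr TAC + Bi segment on the ²¹³Bi TAC,
components recorded separately. Method percent differences are reported in
both conventions — symmetric (100·|a−b|/mean) and relative-to-second —
because the convention used in comparable reports is often unstated. The
78 keV window contributes SUV and half-life tables only, never dosimetry.
In the pipeline a single mass per VOI (the 440 keV segmentation; CT volume
for kidneys) is used for all three methods so that method differences
reflect kinetics, not segmentation.

### Statistics

Pearson r with the two-sided p from t = r√((n−2)/(1−r²)) on n−2 degrees of
freedom. The Wilcoxon signed-rank test is exact for n ≤ 25: zero
differences dropped (logged), ties mid-ranked, and the null distribution of
W⁺ built by a convolution equivalent to enumerating all 2ⁿ sign
assignments; p = 2·min(P(W⁺≤w), P(W⁺≥w)) capped at 1. Exactness matters at
this cohort scale: eight one-signed pairs give p = 2/256 = 0.0078125, which
approximations miss. Above n = 25, normal approximation with continuity and
tie corrections. Kidney-vs-lesion dose comparisons pair every kidney with
every lesion within a patient, in sorted order (the per-patient pair list of
such studies is not otherwise recoverable; the generator documents its
ordering). Cohort SDs use the population convention (divide by n), and the
urine-ratio change is the mean per-patient difference in percentage points;
both choices are what reproduce the conventional reporting of such cohort
tables, and the alternative (mean relative change) is also emitted.

## Synthetic data

The default scenario mirrors the study scale: 5 patients at 7.7 ± 0.2 MBq,
two scans (24/48 h), three windows, 10 kidneys (≈ 247 ml ellipsoids, ²¹³Bi
T_eff ≈ 27 h with the ²²¹Fr half-life 1.5–4.5 h shorter in *every* kidney)
and 9 lesions (≈ 14–45 ml spheres, T_eff ≈ 38 h, window-independent within
±10 %), kidney SUV ≈ 3.4 and lesion SUV ≈ 5 at 24 h, urine ratios ≈ 0.98
at 24 h drifting up by ≈ 0.1 at 48 h. Images are 128³ voxels at 4.7952 mm
by default (desk-scale runs and the test suite use 64³ with organ centres
rescaled; organ sizes are preserved), with a 14-mm system blur, 2 %
soft-tissue background, and Poisson noise applied in count space via the
window's true calibration factor and an effective counting time of 3360 s.
Urine series: 0.1-h bins over 6 h, efficiency 0.2 counts/decay. Random
streams are spawned per component (image/TAC/urine) from the master seed, so
regenerating one input leaves the others' draws unchanged.

What the phantoms do **not** emulate: collimator response and
projection-domain reconstruction noise, downscatter between the 440/218/78
keV windows, attenuation artefacts, patient motion, or intestinal uptake.
Passing tests therefore demonstrate the correctness of the analysis chain
given quantitative images of the stated statistical character — not the
accuracy of any particular scanner's quantification.

## Numerical choices

* Nonlinear fits: trust-region reflective least squares, xtol = ftol =
  gtol = 1e-14; urine starting point from the mean measured level mapped
  through the unit-amplitude model (scale-free); TAC starting point from
  log-linear regression.
* Gaussian filtering uses zero-padding (`mode="constant"`), chosen so the
  total of interior-supported images is conserved.
* Isocontour threshold is inclusive (≥); component labelling uses
  26-connectivity.
* Urine parameter covariance: Gauss–Newton (JᵀJ)⁻¹, scaled by the residual
  variance for unweighted fits (Poisson weights already carry the scale).
* Degenerate inputs raise typed errors (`acdose.errors`) rather than
  returning NaNs: non-positive half-lives, non-decaying two-point TACs,
  T_eff ≥ T_phys, empty masks, zero-variance correlations, all-zero
  difference vectors, λ_Bi ≤ λ_Ac.

## Known limitations

* Self-dose only; no photon/beta crossfire between organs, no voxel dose
  maps, no dose-dependent RBE.
* Two-point kinetics cannot detect bi-exponential washout; the uptake phase
  is absorbed into the extrapolation to t = 0.
* The `alpha_local` energy model slightly overstates the dose of small
  targets (alpha escape ignored) and understates contributions a full
  S-value set would include; supplying an S-value table restores those.
* Lesion quantification is not recovery-corrected by design.
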