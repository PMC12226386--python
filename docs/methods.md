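# Methods

This note documents the models, estimators and design choices behind
`nirtrs`, in the order the pipeline applies them, together with the
assumptions of the synthetic-experiment generator and what passing tests
do and do not establish about real recordings.

## Photon transport and TPSF fitting

**Model.** Time-domain diffuse reflectance of a homogeneous semi-infinite
medium, zero-boundary solution of the photon diffusion equation:
R(ρ,t) = (4πDc)^(−3/2) z₀ t^(−5/2) exp(−μₐct) exp(−(ρ²+z₀²)/(4Dct)), with
isotropic-source depth z₀ = 1/μₛ′. Units are mm and ns; the speed of light
in tissue is c = c₀/n with n = 1.4 by default (standard for head tissue).
The diffusion constant is D = 1/(3(μₐ+μₛ′)); the absorption-free
convention D = 1/(3μₛ′) is available through `d_convention="musp"` because
instrument vendors differ and neither convention is observable from the
fitted curve alone at these optical properties. Extrapolated-boundary and
layered models are out of scope: the pipeline treats the head as one
effective medium, which is the main physical simplification relative to
real foreheads (scalp/skull/CSF layering, curvature).

**Grids and IRF.** The default TCSPC grid is 4096 bins × 10 ps (~41 ns),
long enough to hold the diffuse tail at ρ = 30 mm. The simulated
instrument response is a 150 ps FWHM Gaussian with a small exponential
tail, normalised to unit area; real IRFs are measured, and the fitting
code consumes whatever IRF histogram accompanies the TPSF.

**Fit.** The measured counts are modelled as amplitude × (R ∗ IRF) and
fitted by least squares with per-bin Poisson weights σ² = max(counts, 1),
over a window running from 10% of the smoothed peak on the rising edge to
1% on the falling tail (a common time-resolved convention; both fractions
are configurable). The window matters: the rising edge carries scattering
information, the late tail the absorption, and the sub-1% tail adds mostly
background. The amplitude is profiled out analytically at every step — a
weighted linear solve — leaving a bounded 2-parameter trust-region problem
(μₐ ∈ [10⁻⁴, 0.5] mm⁻¹, μₛ′ ∈ [0.05, 5] mm⁻¹, default start 0.01/1.0).
This reaches the same optimum as the joint 3-parameter fit but removes the
amplitude/scattering collinearity that otherwise slows convergence.
Noiseless self-consistency is exact to machine precision; at a 10⁶-photon
budget the median relative error of both coefficients is ~0.15%.

## Hemoglobin unmixing

Absorption at the three channel wavelengths (763/802/835 nm on one probe,
762/800/837 nm on the other) is modelled as
μₐ(λ) = ln10·[ε_HbO₂(λ)C_HbO₂ + ε_Hb(λ)C_Hb] + background(λ), with
concentrations in µM, extinction coefficients in mM⁻¹mm⁻¹ and background
(water/lipid) zero by default. The embedded extinction table is a standard
compiled in-vitro hemoglobin spectrum (Prahl-lineage compilation,
750–850 nm at 10 nm spacing, converted from cm⁻¹M⁻¹ by 10⁻⁴, linearly
interpolated); the oxy and deoxy curves cross near 800 nm (isosbestic
point), which is why one of the three wavelengths sits there. Unmixing is
a joint ordinary-least-squares solve of the 3-equation, 2-unknown system.
Negative concentrations are reported, not clipped, and flagged through
`HbState.physical` — clipping would bias downstream period means. The
analysis chain depends only on the internal consistency of the table
(forward map and unmixing share it), not on its absolute accuracy.

## Block-design statistics

**Normalisation.** Each sample is divided by the mean of the 10 samples
(~33 s at 0.33 Hz) immediately preceding the first pre-task rest, giving
dimensionless change rates that are invariant to the subject's baseline
concentration. Thirteen 60 s half-open windows (3 rest, 7 task, 3 rest)
are averaged into period means; a sample on a boundary belongs to the
later window.

**RM-ANOVA.** The 2 (condition) × 13 (period) fully within-subject ANOVA
partitions sums of squares with each effect tested against its own
effect-by-subject interaction. Sphericity is handled per effect:
Greenhouse–Geisser ε from Box's formula on the orthonormal-contrast
covariance — condition-averaged period scores for the period main effect,
between-condition difference scores for the interaction (exact for a
2-level factor) — with ε clipped to [1/(k−1), 1] and applied to both df.
Mauchly's W uses the standard first-order chi-square approximation; it
degenerates (NaN) when n − 1 < k − 1, in which case only the correction is
available. The implementation reproduces pingouin's two-way within F and ε
to machine precision on random data; Mauchly p agrees to ~0.01 (pingouin
uses a refined approximation). Missing cells are a hard error: the design
is balanced by construction and imputation would silently change the error
strata.

**Paired comparisons, effect size, power.** Per-period paired t tests are
reported as simple-minus-creative (so a creative increase prints a
negative t, matching the table convention). Two Cohen's d variants exist
for paired designs and the package reports both: d_av (mean difference
over the average of the two condition SDs) is the tabled effect size, and
d_z (mean difference over the SD of the differences) is what the t
statistic implies. Post-hoc power uses the noncentral t distribution with
df = n−1 and noncentrality d·√n applied to d_av — the matched-pairs
convention that reproduces the published power columns (d = 0.74 → 0.92 at
n = 23) — and `required_n` inverts it by integer search (d = 0.5, α = 0.05,
power 0.8 → n = 34). The two-variant ambiguity is deliberate and
documented rather than silently resolved: feeding d_z to the same formula
would give different power values.

No multiplicity correction is applied across the 13 periods; the raw
per-period p-values are mirrored as the original analysis reported them.

**Nonparametrics.** VAS items are compared with a paired t only when both
conditions pass Shapiro–Wilk at α = 0.05, otherwise with the Wilcoxon
matched-pairs signed-rank test. W is reported as the sum of signed ranks
(all-positive differences over 23 pairs give 276); p is exact by sign
enumeration for n ≤ 25 without ties and a tie-corrected normal
approximation otherwise. Shapiro–Wilk is Royston's algorithm via scipy.

## Autonomic analysis

Heart rate per period is the mean of 60/interval over plausible intervals
(0.3–2.0 s) whose onset lies in the window; windows with fewer than 5
beats are flagged missing. LF/HF interpolates the interval tachogram to a
uniform 4 Hz series (cubic), detrends it, and estimates the PSD by Welch's
method (120 s segments, 50% overlap, capped at the record length); LF and
HF are trapezoid-integrated band powers over 0.04–0.15 and 0.15–0.40 Hz.
These estimator details are fixed here and exposed in configuration —
commercial HRV software does not publish its exact settings, so absolute
LF/HF values are comparable only within-pipeline. Windows must span at
least 60 s for HF-band resolution.

Outlier exclusion before correlation uses the modified z-score rule:
exclude points with |v − median| > k·MAD/0.6745, k = 3.5 — the
conventional robust screen, standing in for the unnamed commercial method
of the original chain (false-flag rate ≲1% on clean normal samples of
n ≈ 21). If the MAD degenerates to zero with spread present, the 1.5·IQR
Tukey fence is used. The correlation itself is Pearson when both margins
pass Shapiro–Wilk at α = 0.05 and Spearman (midranks) otherwise, with the
two-tailed p from t = r√(n−2)/√(1−r²) in both cases — the transform that
reproduces all reported p-values from their coefficient/n pairs. VAS
correlations pool both conditions per subject (2n points), which is what
the reported degrees of freedom imply.

## Synthetic experiment generator

The generator emulates the statistical structure the analysis assumes, at
two fidelities: concentration level (default) and photon level (TPSF
streams through the full optics chain).

- **Effect profiles.** Defaults are the study-calibrated per-period mean
  change rates and between-subject SDs for oxy and deoxy in both channels
  (creative oxy rising to ≈1.014 in the first post-task minute and ≈1.023
  by the third; simple ≈0.987–0.995; deoxy dipping to ≈0.955 mid-task).
- **Subject model.** Each subject's deviation-from-baseline profile is
  scaled by a shared gain g ~ N(1, 0.3) and perturbed by independent
  per-cell noise at the tabled SDs. The gain induces within-subject
  correlation across channels and chromophores.
- **Kinetics.** Per-period targets are approached with first-order
  kinetics (τ = 30 s, matching the gradual transitions real waveforms
  show). The 13 step levels are obtained from a 13×13 linear solve so the
  *period means* of the smoothed trace equal the targets exactly — with
  noise off the generator reproduces its configuration to machine
  precision, which is what makes calibration testable.
- **Nuisance structure.** Mayer-wave (0.1 Hz), respiratory (0.25 Hz,
  aliased by 0.33 Hz sampling) and cardiac (~1.1 Hz, aliased) sinusoids
  with random phases plus white sample noise (SD 0.005). The published group
  tables constrain only between-subject SDs, so the within-subject noise
  level is a package choice.
- **Couplings.** The full-experiment path standardises each subject's
  realized creative post-task oxy response into a z-score and feeds it to
  the cardiac and VAS generators: post-task heart rate shifts by
  −4 bpm·z against a 7 bpm between-subject SD (sample correlation ≈ −0.5,
  the magnitude the correlation analysis probes for), and the hedonic VAS
  items (enjoyment, arousal, motivation, like/dislike) load on z with
  weight 0.5 on top of their condition means; difficulty, concentration
  and lack-of-fatigue are uncoupled, their pooled correlations arising
  (or not) from condition separation alone.
- **Determinism.** All draws derive from the seed through per-(subject,
  condition) child streams, so changing one condition's profile or adding
  subjects leaves every other stream bit-identical.

**What passing tests do not show.** The generator has Gaussian noise,
stationary oscillations, no motion artifacts, no scalp-layer
contamination, no drift and no missing data; real NIR-TRS group effects
come with all of these. Tests against the generator establish that the
*analysis* is correct and calibrated under its stated assumptions — type-I
error 0.05 ± 0.01 under the null, rejection frequency matching
noncentral-t power at the realized effect size — not that a real 23-subject
study would reproduce the calibrated tables.

## Problem sizes and numerical choices

The statistical calibration suites run 5000 fast-path null replicates and
200 full-series study replicates at n = 23; optics recovery uses 20 seeded
10⁶-photon histograms. These sizes give Monte-Carlo standard errors
comfortably inside the asserted tolerances (e.g. ±0.003 on a 0.05
rejection rate). Degenerate inputs are surfaced, never patched: all-zero
TPSF windows, zero baselines, constant samples in Shapiro–Wilk, all-zero
Wilcoxon differences and rank-deficient extinction designs raise or flag
explicitly. Fit convergence uses tight tolerances (xtol = ftol = gtol =
10⁻¹⁴) with an iteration cap reported through `FitResult.converged`.

## Known limitations

- Semi-infinite homogeneous optics; no two-layer scalp/cortex separation
  even though a dual-detector probe would in principle support it.
- LF/HF is the only HRV index, and its interpretation as a sympathetic
  balance measure is itself contested; the package computes, it does not
  interpret.
- The extinction fixture's absolute values are compilation-grade; studies
  needing absolute saturation accuracy should supply their own table.
- Mauchly's test is unavailable (NaN) for 13 periods with fewer than 14
  subjects; the GG correction is applied regardless, which is the
  conservative choice.
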