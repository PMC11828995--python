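# Methods

## Signal model and band measurement

A spectrum is absorbance on a strictly ascending wavenumber grid; the
instrument convention emulated throughout is 2 cm⁻¹ resolution over
400–4000 cm⁻¹ with the phosphate ν₃ envelope normalised to ≈ 0.5
absorbance (the ATR anvil-pressure convention). All band measurements
are anchored-baseline measurements: one anchor window defines a chord
through the spectrum values at its endpoints, two windows define a line
through the mean (wavenumber, absorbance) of each window. Heights are
taken at the local extremum within ±8 cm⁻¹ of the nominal position
(±6 cm⁻¹ for the 590 cm⁻¹ valley of the splitting factor) after a light
5-point quadratic Savitzky–Golay smoothing — the smoothing suppresses
the systematic upward bias of a maximum picked over a window of noisy
points, which matters for weak bands such as Amide I in fossil bone.
Areas are trapezoidal integrals of the corrected signal with negative
excursions clipped at zero. Every index is a ratio of heights or areas
and is therefore invariant under absorbance rescaling and under linear
baselines passing through the anchors.

Index anchor windows (cm⁻¹): Amide I and the ν₃PO₄ envelope use
1590–1710 and 890–1150 single windows; C/P uses 1290–1590; Calcite/PO₄
uses 700–730; the ν₄ region (IRSF, OH/PO₄) uses the two-window baseline
640–660 / 420–470.

### Shoulder-band detection

The hydroxyl libration band (630 cm⁻¹) and the calcite ν₄ band
(712 cm⁻¹) are weak shoulders that are genuinely absent in parts of the
sequence. A shoulder is accepted only if the Savitzky–Golay second
derivative (window 7, cubic) has an interior local minimum within the
search window deeper than 3.5× the noise-propagated derivative
threshold; the convex tail of a neighbouring band has a positive second
derivative there and correctly reports absent. The noise scale is the
RMS residual of a linear detrend over the quiet 1800–2400 cm⁻¹ window.
The height is read at the derivative minimum (3-point mean). Undetected
bands yield 0 with a flag, never a missing value, so cohort tables stay
rectangular.

### Deconvolution

Each preset region is fitted as a sum of pseudo-Voigt components
(amplitude-parametrised, η·Gaussian + (1−η)·Lorentzian with shared
FWHM) plus one shared linear baseline, by bounded least squares. The
fit is deliberately constrained, as is standard practice for heavily
overlapped bone envelopes: centres move at most ±8 cm⁻¹ from the preset
positions (4× the emulated instrument resolution), each component
carries a chemically motivated width window (e.g. the 1118 cm⁻¹ acid
phosphate band 8–25 cm⁻¹, the broad 1145 cm⁻¹ component 40–110 cm⁻¹),
and η ≥ 0.3. Without these constraints the six-component ν₁,ν₃ fit is
bistable: a narrow component next to a broad one can soak up overlap
area it does not own. The optimisation is two-stage and deterministic:
a non-negative linear solve for amplitudes at the seeded shapes (centres
nudged to nearby second-derivative minima, widths at the geometric mean
of their bounds), then the full nonlinear refinement. No random
restarts.

The line-shape family is a package choice: pseudo-Voigt with a free
Gaussian fraction per component is the common denominator of commercial
curve-fitting software; nothing in the implemented indices depends on
the specific mixing value.

### Index conventions

HCP, PCP, HPO₄(1118) and HPO₄(1145) are fitted band areas divided by the
**total fitted ν₁,ν₃ envelope area** (recorded in output metadata). The
published table prints no denominator, and its values are mutually
inconsistent under any within-phosphate normalisation (the 1145 cm⁻¹
value exceeds the 1030 cm⁻¹ value in the basal unit); because the
synthetic generator is calibrated through this very pipeline, any
self-consistent convention reproduces the published numbers, and the
envelope-total convention is the one that needs no extra bookkeeping.
C/C is area(1455)/area(1410) from the carbonate ν₃ fit. The remaining
indices are height ratios. Replicate spectra are averaged at the index
level (robust to small normalisation differences between replicates).

## Lattice refinement

Bone apatite is hexagonal, so 1/d² = (4/3)(h²+hk+k²)/a² + l²/c² is
linear in (1/a², 1/c²). Indexed peak positions are converted to
observed 1/d² via Bragg's law (default wavelength Cu Kα₁ = 1.5406 Å)
and fitted by weighted linear least squares; the parameter covariance
propagates to a_sd, c_sd and the volume (delta method,
V = (√3/2)a²c). A constant 2θ zero offset can be co-refined by a nested
one-dimensional search when ≥ 6 reflections are available; it is **off
by default** because co-refining an offset that does not exist trades
substantial variance into the axes (the Monte-Carlo recovery spread
roughly triples). The default reflection set is twelve standard strong
apatite lines from (002) to (004), configurable. This is a deliberate
desk-scale stand-in for full-profile Rietveld refinement: peak positions
only, no intensities, no profile shapes, no phase fractions.

## Synthetic-data generator

The study deposited no raw spectra, so the generator *is* the study
condition. It has three outputs.

**Spectra.** Each unit is a band table (pseudo-Voigt sum). The
phosphate envelope consists of the six ν₁,ν₃ preset components with the
main band at 1026 cm⁻¹, shoulders at 1054/1086 cm⁻¹ and a broad
1145 cm⁻¹ component; the ν₄ doublet (565/603 cm⁻¹, near-Gaussian) sets
the splitting factor through its width; carbonate ν₃ (1410/1455 cm⁻¹),
ν₂ (865/872/879 cm⁻¹, with the 865 cm⁻¹ component growing up-sequence),
Amide I, and unit-specific hydroxyl (630 cm⁻¹, GII only) and calcite
(712 cm⁻¹, absent in GIIa) bands complete the table. Band tables are
**calibrated through the real pipeline**: damped multiplicative
coordinate updates drive each index to its published unit mean on the
noiseless spectrum (amplitudes for the ratio and fraction indices, ν₄
width for IRSF, ν₁,ν₃ widths plus shoulder amplitudes for the envelope
FWHM), with the envelope-width knob phased every fifth iteration to
break a limit cycle with the height ratios. Per-sample variability is
mean-one lognormal amplitude jitter per band (set from the published
relative SDs, capped at 0.35), a shared width-scale jitter per band
group, a Gaussian centre jitter on the 1086 cm⁻¹ shoulder (the envelope
FWHM is pinned by band spacing, so its spread is carried by the
position of the massif's right edge), Bernoulli presence draws for the
detection-limited bands, a quadratic baseline drift (coefficient scale
0.003 absorbance), and white noise of 3×10⁻⁴ absorbance (64-scan ATR
scale). A final population-trim pass regenerates a seeded batch and
corrects the residual biases that jitter, noise and detection
thresholds introduce relative to the noiseless calibration. The
shipped band tables (`data/unit_profiles.json`) are the output of this
procedure.

**Feature tables.** Drawn directly from per-unit censored
latent-Gaussian marginals: a single latent normal per feature produces
both the zero floor of detection-limited indices and the positive
values, with the latent moments solved (2-D root finding) so the
censored distribution reproduces the published mean and SD exactly.
This reproduces, rather than imposes, the zero-inflation the study
reports (hydroxyl detected in 23/30 basal-unit and 4/30 GIIb samples).
Within-unit correlations are solved from the pooled-covariance
decomposition: pooled covariance = between-unit covariance of the
published means + mean within-unit covariance; the residual needed to
reach each published pooled correlation is assigned to a unit-shared
within correlation, clipped to ±0.9, and the matrix repaired to the
nearest positive semi-definite correlation matrix. One printed value is
infeasible: the reported HPO₄(1118)–PCP association (+0.69) cannot
coexist with the published per-unit moments (the between-unit component
is −0.44 and the required within correlation would exceed 1); the
solver clips it and reports the achievable range. Two within-unit
correlations are imposed directly as package choices, since no pooled
values constrain them: (a, c) co-vary at +0.55 within a unit (the axes
drift coherently with channel-ion substitution), and HPO₄(1118)/
HPO₄(1145) carry ±0.45 within correlations with the c-axis in the
direction of the up-sequence trends. (a, c) are drawn jointly and the
cell volume is always computed from them, never drawn. Sample sizes
default to the study design: 30 per unit, five fossil units, 150 rows.

**Reflection lists.** Per sample, (a, c) is drawn from the unit's cell
distribution, the standard reflections are positioned by Bragg's law
and perturbed with Gaussian 2θ noise (default σ = 0.01°, a realistic
laboratory-diffractometer calibration residual).

### What the generator does and does not emulate

It emulates the published per-unit index distributions, the printed
pooled cross-index correlations, the unit-specific band presence
structure, and the lattice drift from hydroxylapatite-like toward
fluorapatite-like cells. It does **not** emulate real bone microstructure:
the large 1145 cm⁻¹ component that the published values force under a
common envelope denominator makes the synthetic envelopes fatter on the
high-wavenumber side than real bone spectra; scattering artefacts, water
vapour lines, CO₂ bands and ATR penetration-depth dispersion are absent;
and the within-unit correlation structure beyond the printed pairs is
minimal. Passing tests therefore demonstrate that the pipeline
correctly recovers known generating truth under realistic noise — not
that it would be unbiased on any particular real instrument's output.

### Known limitation: the per-sample measurement floor

The pipeline adds measurement variance of its own. For HPO₄(1118) — a
component carrying ~2% of the envelope area inside a six-band overlap —
the per-sample refit reproducibility floor is an SD of ≈ 0.005, several
times the published SDs of 0.001–0.002; unit means consequently wander
up to ≈ 4 published-SE units (≤ ~10% relative) between seeds, and the
observed spreads of the weakest bands exceed the published ones. The
end-to-end consistency tests therefore assert unbiasedness in
observed-SE units with a 12% relative cap, while the feature-table
generator (used by the statistics and classification modules) meets the
published moments directly.

## Cohort statistics

Per feature, Welch's ANOVA is used when every unit passes Shapiro–Wilk
normality at α = 0.05, Kruskal–Wallis otherwise; Levene's test
(median-centred) is recorded alongside. Pairwise comparisons are
two-sided Wilcoxon rank-sum tests with the tie-corrected normal
approximation (appropriate at n = 30 per unit), Holm-adjusted by
default (Bonferroni by flag). The correlation matrix is pooled
(all-sample) Pearson. Pruning applies the study's explicit exclusion
list first (Amide I/PO₄, IRSF, C/P, Calcite/PO₄, OH/PO₄, C/C,
FWHM(ν₃PO₄), a-axis, c-axis — "contributes little to the component
space" is not algorithmised; the audit log keeps the subjectivity
visible), then greedily removes, from any remaining pair with
|r| ≥ 0.75, the member with the larger mean absolute correlation. PCA
is an eigendecomposition of the correlation matrix with the
largest-magnitude loading of each component forced positive.

## Classification

The harness owns the protocol; fitting delegates to scikit-learn.
Defaults follow the study: stratified 70/30 split (the 150-row cohort
gives exactly 105/45 with 9 test samples per unit — the published exact
binomial intervals confirm a 45-sample test set), centring and scaling
fitted on the training partition only, 10 random hyperparameter
configurations per family (LDA has none), selection by mean Cohen's
kappa over repeated stratified 10-fold CV with 10 repeats, and an exact
Clopper–Pearson 95% interval on hold-out accuracy. Two families have no
scikit-learn equivalent and are implemented as thin estimators: mixture
discriminant analysis (per-class Gaussian mixture with tied within-class
covariance, tuned on the subclass count) and PLS-DA (PLS regression on
the one-hot indicator, argmax prediction). C5.0 decision trees are not
available in the environment's packages; CART stands in for the DTC
family. The NNET search space contains the published winning
configuration (hidden size 5, decay 0.1). Stratified folds are clamped
to the smallest class count; SVM and MLP iteration caps guard against
pathological candidates.

## Problem sizes in tests and the acceptance run

Population-level spectrum checks use one seeded 30-spectrum batch per
inspected unit; the acceptance run uses 20 seeds for the pooled
correlation and the classifier hold-out mean, 100 Monte-Carlo draws for
lattice recovery, and reduced CV repeats (2 instead of 10) during
family selection — selection is insensitive to the repeat count, and
these sizes keep a single-CPU run within a few minutes while leaving
every estimate comfortably inside its tolerance. The Monte-Carlo
lattice criterion is reported as the 95th-percentile recovery error:
the maximum over 100 draws is an extreme-value statistic whose tail
exceeds any fixed band with appreciable probability even for a correct
estimator.
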