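# bonechem

Chemometrics of bone diagenesis: ATR-FTIR band indices, apatite
unit-cell refinement and stratigraphic provenance classification.

## The problem

Buried bone recrystallises. Its nanocrystalline carbonated
hydroxylapatite loses organics, exchanges ions with pore water (F⁻ and
CO₃²⁻ in, structural OH⁻ and carbonate out or in, depending on the
geochemistry), and grows larger, more ordered crystals. Those changes
are measurable: infrared band ratios quantify crystallinity and the
carbonate/phosphate/organic balance, and powder diffraction quantifies
the lattice itself — fluoride substitution in the apatite channel
contracts the *a*-axis and the cell volume. Because each depositional
layer imposes its own burial chemistry, the combined FTIR + XRD
fingerprint of a bone can identify the stratigraphic unit it came from,
which makes it possible to recontextualise fossils that lost their
excavation context.

`bonechem` implements that full analysis chain for a Middle Pleistocene
karst sequence with five bone-bearing units (labelled GIIa, GIIb, GIIIa,
GIIIb, GIV from bottom to top), plus a modern cortical-bone reference:

* **spectra** — spectrum I/O (CSV, JCAMP-DX), anchored linear-baseline
  band measurement, Savitzky–Golay second derivatives, envelope FWHM,
  and constrained pseudo-Voigt multi-band deconvolution of the
  ν₁,ν₃(PO₄), ν₄(PO₄), ν₃(CO₃) and ν₂(CO₃) regions.
* **chemometrics** — the 11-index panel per sample:
  IRSF = (A₅₆₀+A₆₀₀)/A₅₉₀, Amide I/PO₄, C/P, C/C, Calcite/PO₄, OH/PO₄,
  FWHM(ν₃PO₄), and the deconvolved fractions HCP (1030 cm⁻¹),
  PCP (960 cm⁻¹), HPO₄ (1118 cm⁻¹), HPO₄ (1145 cm⁻¹).
* **lattice** — hexagonal cell geometry, V = (√3/2)a²c, Bragg positions,
  and weighted least-squares refinement of (a, c) from indexed
  powder-peak positions (1/d² = (4/3)(h²+hk+k²)/a² + l²/c²), with
  uncertainty propagation and an optional 2θ zero-offset.
* **synthetic** — a calibrated generator for per-unit spectra, feature
  tables and XRD peak lists: the study deposited no raw data, so band
  tables are calibrated *through the index pipeline* to reproduce the
  published per-unit means and spreads, and the cohort's within-unit
  correlations are solved so pooled cross-index correlations match the
  published values.
* **cohort_stats** — Shapiro–Wilk/Levene gating into Welch's ANOVA or
  Kruskal–Wallis, pairwise Wilcoxon rank-sum tests with Holm adjustment,
  pooled Pearson correlation matrix, greedy |r| ≥ 0.75 feature pruning,
  and PCA on the correlation matrix.
* **classification** — the supervised protocol: stratified 70/30 split,
  random hyperparameter search (10 candidates) scored by repeated-CV
  Cohen's kappa, and a full metric panel (accuracy with exact
  Clopper–Pearson 95% interval, kappa, per-class sensitivity /
  specificity / balanced accuracy) for nine model families
  (NNET, SVM, KNN, RF, DTC, LDA, MDA, PLS, NB).

## Worked example

```python
import numpy as np
from bonechem import synthetic as syn
from bonechem.chemometrics import compute_profile
from bonechem.lattice import refine_cell
from bonechem.cohort_stats import prune_correlated
from bonechem.classification import SplitSpec, stratified_split, tune_and_train, evaluate

profiles = {p.unit: p for p in syn.default_unit_profiles()}
cfg = syn.GeneratorConfig(seed=1)

# one synthetic basal-unit spectrum through the index pipeline
prof = compute_profile(syn.generate_spectra(profiles["GIIa"], cfg)[0])
print(f"IRSF={prof.irsf:.3f}  C/P={prof.c_p:.3f}  FWHM={prof.fwhm_v3po4:.1f} cm-1")
# IRSF=4.420  C/P=0.152  FWHM=65.6 cm-1

# one synthetic peak list through the lattice refinement
cell = refine_cell(syn.generate_reflection_lists(profiles["GIIa"], cfg)[0])
print(f"a={cell.a:.4f}  c={cell.c:.4f}  V={cell.volume:.1f} A^3")
# a=9.4381  c=6.8922  V=531.7 A^3

# cohort -> pruning -> tuned neural network -> hold-out metrics
cohort = syn.generate_cohort_features(cfg)          # 150 samples, 30/unit
reduced, audit = prune_correlated(cohort)           # keeps CellVolume, HCP,
                                                    # PCP, HPO4_1118, HPO4_1145
train, test = stratified_split(reduced, SplitSpec(seed=1))
ev = tune_and_train(train, "NNET", cv_repeats=2, seed=1)
rep = evaluate(ev, test)
print(f"accuracy={rep.accuracy:.3f}  kappa={rep.kappa:.3f}  "
      f"95% CI=({rep.accuracy_ci_low:.2f}, {rep.accuracy_ci_high:.2f})")
# accuracy=0.933  kappa=0.917  95% CI=(0.82, 0.99)
```

The IRSF of 4.4 and envelope FWHM of 66 cm⁻¹ mark a strongly
recrystallised fossil (modern bone sits near 3.2 and 115 cm⁻¹); the
refined cell volume of 531.7 Å³ is hydroxylapatite-like, as expected for
the basal unit before fluoride uptake contracts the lattice up-sequence.
The classifier separates the five units from the five surviving
phosphate/lattice variables with hold-out accuracy well inside the
published confidence band.

A CLI mirrors the library: `bonechem simulate|indices|lattice|stats|classify`
(see `bonechem --help`).

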