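# Methods

## NMR quantification

**Model.** All acyl chains of a seed's storage lipid are assumed esterified
to glycerol (triacylglycerols), so signal areas in the ¹H spectrum are
proportional to proton counts per chain: bis-allylic CH₂ (signal A: 4 H for
18:3, 2 H for 18:2), α-carbonyl CH₂ (B: 2 H every chain), allylic CH₂ (C:
4 H for any unsaturated chain), β-carbonyl CH₂ (D: 2 H), ω-3 terminal CH₃
(E: 3 H, 18:3 only), other terminal CH₃ (F: 3 H), the mid-chain (CH₂)ₙ
envelope (G), olefinic CH (H: 2 H per double bond), and the glycerol
backbone (4 α H and 1 β H per triacylglycerol, i.e. 2/3 + 2/3 + 1/3 H per
chain across the α1/α2/β multiplets). The four class percentages follow
from the integral ratios (see README); their raw sum is identically 100,
which the property tests exercise. Signal D is integrated and reported for
completeness although no composition equation consumes it.

**Integration.** Trapezoidal integration over configurable assignment
windows, with interpolated window-edge ordinates so rectangular test cases
are exact. Baseline modes: `none`, or `endpoint-linear` (subtract the chord
joining the interpolated edge intensities). `endpoint-linear` is the
library default because real spectra carry baseline roll; for synthetic
spectra, which have none, analyses use `none` — with crowded Lorentzian
lines the chord removes genuine tail intensity, which is a property of the
lineshape, not a bug. Negative net areas (noise) are floored at zero with a
logged warning.

**Windows.** Default centers follow the standard vegetable-oil assignment
literature (F 0.88, E 0.97, G 1.30, D 1.61, C 2.02, B 2.30, A 2.77,
glycerol 4.14/4.30/5.23, olefinic 5.35 ppm); the olefinic/glycerol-β
boundary is drawn at 5.26 ppm because the two signals overlap slightly.
All windows are configurable via TOML.

**Composition tolerance.** Raw class percentages within 2 points outside
[0, 100] (integration noise) are clipped and renormalized with a warning;
larger violations raise `InconsistentIntegralsError` rather than silently
reporting an impossible composition.

**Total lipid.** Sample and reference total integrals are each divided by
the weighed mass (mg); the ratio ×100 is the lipid mass fraction, taking
the external reference as pure oil. The window set entering the sum is
configurable (default: all eleven). The totals are not exactly
composition-independent — per-chain proton totals vary slightly between
classes (31–33 H plus the G envelope) — so quantification against a
reference of similar composition is most accurate, as with the real
method.

## Soxhlet calibration

Correction factor = arithmetic mean over accessions of
(reference method)/(NMR); missing determinations are dropped pairwise.
Factors and paired Pearson correlations are estimated from pea accessions
only; the soybean row is a held-out validation sample to which the factor
is then applied. When reproducing the published corrected table, the
published factors (3.08, 1.97, 0.85) are applied to the published NMR
means, because the published corrected cells are exact 2-dp products of
those; recomputing the factors from the rounded table itself yields
3.07/1.96/0.85. Note that a multiplicative correction cannot change the
paired Pearson r (scale invariance, property-tested), so any "correlation
after correction" must come from a pooled or regression-based statistic,
not the paired one computed here. Reported values are rounded half-up to
2 decimals at the reporting layer only.

## NIR chemometrics

Reflectance → absorbance (A = log₁₀(1/R)); wavelengths truncated to
1100–2500 nm. Pretreatments:

* **SNV** — per-spectrum centering and scaling to unit sd (ddof = 1).
* **Detrend** — per-spectrum least-squares polynomial (default degree 2,
  the usual SNV-detrend convention) fit against a [−1, 1]-scaled
  wavelength axis and subtracted.
* **First derivative** — gap-segment forward difference, default gap 4 and
  segment 4 points; the output grid is the midpoint of the two averaged
  blocks. The named treatment carries no published parameters; these
  defaults are the package's choice.
* **MSC** — OLS regression of each spectrum on a reference (training-set
  mean by default), then inversion of intercept and slope.

**PLS1 / NIPALS.** X is column-centered and y centered (no scaling); each
factor's weight vector is iterated to relative change < 1e-12 (≤ 500
iterations; with a single response NIPALS converges in one pass) and X and
y deflated. The regression vector b = W(PᵀW)⁻¹q reproduces the factor
recursion to 1e-10, which is asserted. scikit-learn's PLSRegression serves
as an independent oracle in the tests only.

**Cross-validation.** Leave-one-out; MSC references (and all model
statistics) are estimated inside each training fold so the left-out sample
never informs its own prediction. SECV uses the bias-corrected n−1
denominator (an n−1−k alternative is exposed via `secv_ddof`);
RPD = sd(y, ddof = 1)/SECV; R² is the squared Pearson correlation of
predictions with reference values. Factor count is user-specified (3–4 is
typical for this problem size); no automatic selection is claimed.

## Synthetic data

**NMR generator.** One peak per signal (Lorentzian by default — the
natural NMR lineshape — Gaussian selectable), default HWHM 0.01 ppm on a
0–6 ppm, 8192-point grid. Target window areas are
`lipid%/100 × sample mass × Σ(fraction × protons)`. Because Lorentzian
tails leak a few percent of any peak's area into adjacent windows at
realistic linewidths, peak heights are obtained by solving the 11×11
linear system built from the analytic truncated-peak areas, making each
window's net area equal its target exactly up to trapezoid discretization
(measured relative error ≲ 1e-5, comfortably within the 1e-3 contract).
For degenerate mixtures (e.g. fully saturated) the solved heights of empty
windows are tiny negatives that cancel neighbour leakage; their windows
integrate to zero. White Gaussian noise is added from a seeded substream;
identical seeds reproduce spectra bit for bit.

**NIR generator.** Beer–Lambert forward model: absorbance = lipid% × (five
C–H overtone/combination bands at 1210/1725/1765/2307/2347 nm) + a fixed
matrix background (water 1450/1940 nm, starch 2100 nm, protein 2180 nm, a
broad hump and a 0.30 AU offset). Corruptions, each from an independent
seeded substream: per-sample multiplicative factor 1 + N(0, 0.05); an
additive random polynomial baseline (degree 2, coefficient sd 0.01 AU);
white noise sd 5e-4 AU. Amplitudes were set once on physical grounds
(band absorbance ≈ 0.02 AU per % lipid over a ≈ 0.5 AU background, typical
of whole-seed reflectance at 1 nm resolution). The default dataset is 18
samples with lipid uniform in 1.3–2.6 % dry mass, mirroring a small
whole-seed calibration study.

**What the generators do not emulate.** Spinning sidebands, solvent
pre-saturation artifacts, chemical-shift drift, multiplet structure and
phase errors (NMR); instrument line-spread, wavelength miscalibration,
temperature-dependent water shifts and non-linear detector response (NIR).
Passing tests therefore demonstrate correctness of the computational
chain and its behaviour under the modelled corruptions, not instrument-
level robustness.

## Numerical choices and limitations

* Reported tables round half-up to 2 decimals; all internal math is double
  precision.
* The acyl-composition equations are scale-invariant, so normalized and
  raw integral tables give identical compositions; normalization to a
  100-sum is provided for reporting parity.
* LOOCV on n = 18 samples with ≤ 4 factors overfits optimistically by
  design of the original small-sample setting; the cross-validation
  statistics characterise the pipeline, not expected field performance.
* Cross-validation problem sizes in the test suite (18 × 1401 matrix,
  ≤ 4 factors, ≤ 3 recipes) keep the full suite to a few seconds.
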