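# Methods

This note documents the models, conventions and numerical choices behind
`rosecal`, and what the synthetic data can and cannot tell you about
performance on real oils.

## Spectra and grids

A spectrum is absorbance (AU) on a strictly monotonic wavenumber grid in
cm⁻¹. The canonical order is descending (4000 → 600 cm⁻¹), following the
mid-IR plotting convention; constructors reverse ascending input, and
all derivative code accounts for the negative grid step so d/dν is
physical. The default simulation grid runs 4000 → 600 cm⁻¹ in 2 cm⁻¹
steps (1701 points), a typical digitized point spacing for a 4 cm⁻¹
instrument resolution; it is configurable and no result in this package
depends on the exact spacing. Window bounds are inclusive on both ends
(the ranges are stated as closed intervals), and window extraction never
interpolates — it selects existing grid points.

## Synthetic-data generator

The generator emulates a spiking study: three rose-oil brands
(REO1–REO3), three brands each of palmarosa and geranium oil, one
phenylethyl-alcohol product, seven oil–adulterant pairings, and eight
levels (0, 2, 4, 8, 16, 32, 64, 100 % v/v), giving 56 samples of which
the 42 at intermediate levels are "spiked". Design enumeration is
deterministic and order-stable.

**Band model.** Each pure component is a sum of Gaussian (optionally
Lorentzian) bands parameterized by center, peak amplitude and FWHM.
Only the thirteen rose-oil band *positions* are anchored to the
characteristic absorptions of Damask-rose oil (3345, 2958, 2922, 2853,
1669, 1514, 1452, 1377, 1260, 1234, 1056, 1005, 829 cm⁻¹); every
amplitude, every width, and all adulterant bands are simulation
parameters, chosen once on chemical plausibility grounds and frozen:

* Rose-oil amplitudes span 0.10–0.60 AU with the methylene C–H
  stretches (2922/2853) and the 1056/1005 fingerprint pair strongest;
  FWHMs 19–40 cm⁻¹, reflecting the band overlap of a many-component oil.
* Palmarosa and geranium oil share rose oil's terpene-alcohol backbone
  bands at identical positions (they share major constituents —
  geraniol, citronellol), differing in amplitudes plus distinguishing
  bands: PEO a strong C=C stretch at 1672 cm⁻¹ (inside its 1700–1600
  window), GEO an ester C=O at 1724 cm⁻¹ and a C–O band at 1170 cm⁻¹
  (inside its 1218–1130 window, where rose oil is essentially flat).
* Phenylethyl alcohol is a single pure aromatic compound: sharp
  (FWHM 7–12 cm⁻¹), intense (up to 1.1 AU) monosubstituted-ring modes,
  including 746 and 700 cm⁻¹ out-of-plane bends (700 anchors its
  710–690 window), aromatic C–H near 3029 and ring modes at
  1603/1496 cm⁻¹.

The library was *designed* so that the generator reproduces the
qualitative structure the downstream analyses assume: each adulterant
has net positive contrast over rose oil inside its quantification
window (hence window absorbance strictly increasing in level), and the
pure-aromatic PEOH is far more distant from all terpene oils — under the
classification pipeline — than the terpene oils are from one another,
which is what makes its dendrogram arm separate. These are structural
requirements of the emulated study, not free observations; the test
suite asserts them.

**Variability.** Brand-to-brand differences are multiplicative lognormal
jitter per band amplitude (unit mean, CV 0.05, seeded stably per brand
name), so a given brand has one fixed spectrum per dataset. Instrument
noise is i.i.d. zero-mean Gaussian per point; `noise_sd` (default
0.003 AU) is the single-measurement noise, and stored spectra emulate
the average of three repeat measurements, so their noise standard
deviation is `noise_sd/√3`. Replicates are averaged rather than stored
because the downstream analyses only ever use averaged spectra. An
optional linear baseline can be added; the default is none.

**What the generator does not model:** ATR penetration-depth dispersion,
refractive-index (band-distortion) effects, water-vapour/CO₂ lines,
detector drift, wavelength-axis miscalibration between samples, and the
real within-brand chemical variability of essential oils. Passing tests
on synthetic data therefore validate the *pipeline* — its algebra,
conventions and robustness at realistic signal-to-noise — not
instrument-specific performance on real oils, for which genuine
calibration standards are required.

## Preprocessing

Derivatives use Savitzky–Golay local polynomial fits, default window 9
points, polynomial order 3 (common FTIR-software defaults; the analytic
checks hold to 1e-6 relative at interior points). Edge points use the
polynomial fitted near the boundary (scipy's `interp` mode). The second
derivative annihilates any linear baseline, which is the reason this
variant is used for classification. Vector normalization subtracts the
mean of the selected range and scales the centered vector to unit
Euclidean norm; it is scale-invariant and idempotent, and fails loudly
on constant input.

The pipeline order is fixed: derivative on the full grid first, then
window extraction, then normalization over the concatenated windowed
points. Differentiating after windowing would contaminate window edges
with one-sided fits; normalizing over the selected ranges matches common
FTIR-software practice. The calibration variants (raw, first, second
derivative) never normalize — normalization would discard part of the
concentration signal that calibration relies on.

## Regression

PLS1 is implemented via NIPALS with the closed-form weight extraction
(for univariate y no inner iteration is needed); deflation uses
X-loadings. PCR uses SVD of centered X with a deterministic sign
convention (largest-magnitude loading element positive). Both center X
and y per fit — and per cross-validation fold — and never variance-scale
(spectral units are homogeneous). Both reduce exactly to ordinary least
squares at full rank; if the factor count exceeds the data rank,
extraction stops early and the extra factors contribute nothing, so
PRESS plateaus rather than exploding. Rank cutoffs: residual covariance
below 1e-13 of its initial scale (PLS), singular values below 1e-12 of
the largest (PCR).

Conventions pinned by internal consistency of published tables of this
metric set: SECV = √(PRESS/n) with n the calibration-set size (here 8
levels per series); bias is reported as the *absolute* mean residual;
R² is the squared Pearson correlation of actual and leave-one-out
predicted values (a cross-validation R², not a calibration R²); the
calibration line regresses predicted on actual, which is why slopes sit
just below 1 with small positive intercepts. The factor count defaults
to 3; `select_factors` instead minimizes LOO PRESS with ties broken
toward fewer factors.

## Clustering

Ward agglomeration starts from pairwise Euclidean distances and updates
them by the Lance–Williams recurrence on squared distances; heights are
reported on the Euclidean ("Ward.D2") scale so they are comparable with
the common statistical implementations that pair Ward with plain
Euclidean input. Ties are broken by the smallest (first, second)
cluster-index pair, making dendrograms bit-reproducible. Cutting removes
the k−1 highest merges and labels clusters by smallest member index.
Newick export is ultrametric: leaves at height 0, branch length = parent
merge height − child merge height. PCA is SVD-based with the same sign
convention as PCR; explained-variance ratios are relative to total
variance.

The classification run uses all 56 design samples (the emulated study
does not enumerate which samples entered its figure, so the full design
is used and stated here), second derivative + vector normalization over
3541–3153 and 1771–663 cm⁻¹, and 3 PCA components.

## Problem sizes and determinism

The shipped analyses are deliberately small: a full calibration grid
(42 models × 8-fold LOO) takes ~0.15 s, a clustering run ~0.35 s, and
the acceptance script (40 replicate datasets, 1680 cross-validated
models) a few seconds. All randomness flows from integer seeds through
`numpy` generators; a fixed config + seed reproduces outputs
byte-for-byte.

## Known limitations

* The JCAMP-DX reader supports only the tabular `(X++(Y..Y))` AFFN
  dialect — no ASDF/DIF compression, no peak tables.
* PLS2 (multivariate response), test-set validation, uncertainty
  intervals and outlier F-tests are out of scope.
* Window selection is taken as given per adulterant; the package does
  not search for optimal quantification windows.
* Predictions are not clipped to [0, 100] % v/v; slightly negative
  predictions at the blank level are expected and informative.
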