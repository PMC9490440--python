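# Methods

## The measurement model

### FT-IR ratio extraction

Spectra are absorbance traces on a 4000–400 cm⁻¹ grid (default 1 cm⁻¹
spacing, descending acquisition order, stored ascending). Processing
follows the standard burnt-bone protocol:

1. **Baseline**: a piecewise-linear interpolant through the local minimum
   of absorbance within ±10 cm⁻¹ of each anchor. The four canonical
   anchors are 450, 800, 900 and 1200 cm⁻¹; three extras (1300, 1800,
   2200 cm⁻¹) extend coverage into the carbonyl/cyanamide region and are
   flagged as extensions in config. Beyond the outermost nodes the nearest
   segment is extended linearly. Negative residuals are clipped at zero,
   which makes the correction idempotent.
2. **Peak heights**: the maximum absorbance within ±5 cm⁻¹ of the nominal
   band center (the tolerance is per-query config); the observed position
   and shift are recorded. Valleys are window minima. Shoulders are read
   from the Savitzky–Golay-smoothed second derivative (window 11 points,
   order 3): a local curvature minimum with negative curvature inside the
   window, without a full local absorbance maximum.
3. **Ratios**: sums of numerator heights over sums of denominator heights.
   Band centers are config, not code: IRSF = (565 + 605)/valley[575–600],
   C/P = 1415/1035, BPI = 1415/605, API = 1540/605 (burnt only, because
   the type-A carbonate band overlaps amide II in unburnt bone),
   C/C = 1415/1540 (burnt only), CN/P = 2010/1035, CO/CO₃ = 1740/1415,
   N/P = 1660/1035 and APR = 1640/1035 (unburnt only), PHT = 625/610.
   A near-zero denominator (≤ 10⁻⁹ absorbance) yields not-applicable with
   a logged warning rather than an exception — calcined bone can have no
   residual organics. Height ratios are invariant under positive scaling
   of absorbance; the invariance is bit-exact for power-of-two factors and
   to ~10⁻⁹ relative otherwise (IEEE rounding in subtraction/division).
4. **Markers**: the β-TCP 1123 cm⁻¹ peak requires a strict local maximum
   with prominence above an absolute floor (default 0.005 absorbance);
   the 547 cm⁻¹ shoulder uses the shoulder criterion; the burnt-bone extra
   peak is scanned over 1080–1100 cm⁻¹. The OH–Cl band position is never
   stated in the bone literature consulted for a given instrument; the
   default (3494 cm⁻¹) is an apatite-literature value and is configurable.

### Microprobe processing

Points are oxide wt% per analyte (P₂O₅, Al₂O₃, Na₂O, SiO₂, K₂O, CaO, Cl,
MgO, SrO, FeO, MnO) with an analytical total. The two data rules are
applied in a fixed order: values strictly below their detection limit are
set to exactly 0.00 and flagged; then points whose *original* total is
below 50 wt% (mislocated beam) are removed with a QC-log entry. Retained +
removed always equals the input count. Default detection limits are
conservative placeholders (0.01 wt% for trace oxides, 0.05 for CaO/P₂O₅)
and must be replaced with per-run instrument limits for real data.

Elemental wt% = oxide wt% × n·M_el/M_oxide with IUPAC conventional atomic
weights; Cl passes through. The decision thresholds are interpreted on the
elemental scale (the published figures are labelled as elemental
potassium); an oxide-scale interpretation is switchable in config.
Summaries use the n−1 SD; SE is not emitted for n = 1 cells and CV is not
emitted for zero means.

### Statistics

- Regression on PMI uses OLS per sample by default (group-mean mode
  available; the source analysis does not state which was used). The
  stated null is directional ("does not increase"), yet significant
  negative correlations are reported as rejections, so the default
  p-value is two-sided with a one-sided option.
- PCA runs on z-scored data (correlation-matrix PCA). Loadings columns are
  unit-norm; the sign convention makes the largest-magnitude loading of
  each component positive, so results are deterministic.
- LDA is Fisher's rule with pooled covariance (scikit-learn SVD solver);
  a singular within-class scatter triggers a refit with small ridge
  shrinkage. "Confidence scores" are the Gaussian posteriors.
- MANOVA is Wilks' Λ = det(W)/det(W+B) with Rao's F approximation (exact
  for ≤ 2 features or ≤ 3 groups). The post hoc is pairwise two-group
  Hotelling T² with Holm adjustment (Bonferroni switchable) — the source
  names no specific multivariate comparison test, so a conservative
  standard choice is used. Pairs too small for a p-dimensional T²
  (n₁+n₂−p−1 ≤ 0, e.g. the N = 2 365-day group against 6 features) report
  NaN and are excluded from the adjustment rather than aborting the run.

### Decision rules

The potassium rule runs on per-specimen zone means of elemental K from the
cleaned table, burnt specimens only. Branch order: mid-cortical K below
the detection limit → *long delay (≥ 1 year)*; inner and mid-cortical both
< threshold − band → *delayed burn (≥ ~3 months)*; both ≥ 0.20 wt% →
*peri-mortem burn plausible* (this floor is an inference from the day-0
observations and is flagged as an extension in the output caveats); either
value inside threshold ± band → *borderline*; otherwise *indeterminate*
(including the conflicting case of one zone high and one low, which is
deliberately not guessed). The threshold is 0.07 wt% with a ±0.01 band —
the source prints both ±0.01 and ±0.001; the headline (abstract/
conclusion) figure is used and the discrepancy noted here. Outer-cortical
values are reported but never decisive (soil K uptake), peri-vascular
values are supporting evidence only, and every assessment carries the
burial-slows-dehydration caveat. Lowering IC/MC K can never move the
category toward a fresh-burn reading (tested property).

Temperature banding requires *both* β-TCP signals for a >700 °C claim; a
1123 cm⁻¹ peak without the 547 cm⁻¹ shoulder is reported as ambiguous, and
an OH–Cl peak supports >600 °C.

## The synthetic world

The generator emulates the published experimental design: unburnt and
burnt specimens at PMI 0/14/34/91/180/365 days with N = 10/5/5/5/5/2 per
group, four zones per specimen, five points per zone. Anchored trends
(linear between anchors):

- **K (elemental wt%)**: unburnt 0.16 → 0.06 over days 0→14, then a slow
  decline to 0.04; burnt 0.22 at day 0, 0.12 at day 14, ≤ 0.05 in IC/MC/HC
  from day 91; the outer-cortical zone depletes more slowly with a 0.12
  ceiling ("<12 wt%" in the source is read as a typo for 0.12) and an
  additive soil-uptake term (default 0.02 wt%) from day 34.
- **Na**: burnt 0.54 → 0.46 → plateau 0.45–0.48; unburnt 0.50 → 0.42 then
  stable. **Cl**: increasing with PMI in burnt bone, decreasing unburnt.
  **Mg**: stepped increase at 180/365 days. Ca, P, Fe, Al, Si, Sr, Mn are
  flat in both state and PMI; CaO/P₂O₅ levels give a Ca/P molar ratio of
  ~1.28, matching the published 1.23–1.29 zone values.
- **Noise**: additive i.i.d. Gaussian per element, truncated at zero, with
  zone multipliers OC 1.6 > HC 1.3 > IC 1.1 > MC 1.0 reproducing the
  published zone-CV ordering. Within-group variances are not published;
  the SDs are order-of-magnitude choices, fixed once.
- **Spectra**: sums of Gaussian bands (pseudo-Voigt optional; no line
  shape is published) plus optional polynomial baseline and i.i.d.
  absorbance noise (default SD 0.005). Burnt spectra carry the cyanamide
  2010 cm⁻¹ band, the 1080–1100 cm⁻¹ extra peak, a 625 cm⁻¹
  high-temperature phosphate shoulder and the OH–Cl band, with amide bands
  suppressed; unburnt spectra carry amide I/II, carbonyl, and a 547 cm⁻¹
  shoulder strengthening with PMI. The ν₄ doublet width is solved
  numerically (bisection) so the measured noiseless IRSF hits its target:
  unburnt 2.90–3.22 across days 0–180 (inside the published 2.88–3.30
  band) with the published 5.04 outlier at 365 days; burnt targets are
  non-monotone in PMI (pyre conditions dominate crystallinity) inside the
  published 37.77–57.27% fresh-uplift band, with the 365-day group
  declining 5.4% on burning. Targets sit slightly inside range edges
  because window-max peak picking under noise biases measured IRSF upward
  by ~0.01–0.05; the published sequence 91 > 0 > 180 ≈ 365 > 34 > 14 is
  not exactly satisfiable jointly with the published unburnt means and
  uplift band, so it is honoured as nearly as those constraints allow.

A green test on this world establishes that the pipeline recovers the
structure it was told to generate — directions, thresholds, orderings —
not that it reproduces the unpublished specimen measurements. The
generator does not model combustion physics, soil-chemistry transport,
spatial diffusion across the cortex, instrument drift, or ATR
penetration-depth effects, and its group means are interpolated anchors,
not fits.

## Numerical choices

- Determinism: every stochastic path is seeded; study simulation spawns
  per-specimen seeds from one master `SeedSequence`, so identical
  (design, trends, seed) gives bit-identical output.
- Duplicate wavenumbers on load collapse by mean; spectra are re-sorted
  ascending regardless of acquisition order.
- Degenerate inputs: constant columns z-score to zeros with a warning;
  a constant PMI predictor, classes with < 2 samples, and singular scatter
  matrices raise typed errors; empty tables summarise to empty frames.
- Ca/P with P₂O₅ = 0 is not-applicable (warned), CaO = 0 gives 0.
- The MANOVA type-I calibration test uses 2 features × 3 groups, where
  Rao's F is exact, so the 1000-replicate rejection rate brackets α.
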