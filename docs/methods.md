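# Methods

## Problem and scope

`dendrocarbon` reconstructs the lifetime carbon-accumulation history of
individual tropical trees from annual ring-width measurements. The
workflow is retrospective dendrochronology: several radii are measured on
a stem disc at 0.01 mm resolution, averaged into one mean tree-ring
series, cumulated into a diameter trajectory, converted to aboveground
biomass (AGB) with a height-free pantropical allometry, and converted to
carbon with a species-level carbon fraction. Annual carbon accumulation is
the first difference of the carbon stock. On top of the trajectories the
package computes lifetime-quartile carbon shares and a nonparametric
trend / change-point / growth-pattern analysis, and ships a seeded
synthetic cohort generator so the whole chain is testable without any
external data.

The emulated study population is a published cohort of 61 legally
harvested canopy trees from unmanaged Surinamese wet forest — 20 *Cedrela
odorata*, 21 *Goupia glabra*, 20 *Hymenaea courbaril*; ages 84–255 years,
final diameters 36.7–99.2 cm, 369 measured radii in total — whose raw
ring-width series were never deposited. Its printed species-level summary
(see `dendrocarbon.published`) is used only to calibrate the generator and
for an internal-consistency check; cohort-level results computed here are
properties of the synthetic population, not reproductions of the original
measurements.

## Biomass and carbon model

AGB (kg) from stem diameter D (cm), wood density ρ (g cm⁻³) and an
environmental stress factor E:

    AGB = exp(−1.803 − 0.976 E + 0.976 ln ρ + 2.673 ln D − 0.0339 [ln D]²)

- ρ defaults: *C. odorata* 0.38, *H. courbaril* 0.77, *G. glabra*
  0.72 g cm⁻³ (species-level constants, overridable per species).
- E is a site-level scalar supplied in configuration (synthetic default
  0.0). It enters only as the scaling exp(−0.976 E), so any choice rescales
  all stocks uniformly and leaves every trend, share and classification
  unchanged. Computing E from climate rasters is out of scope.
- Carbon fraction: 0.471 by default (a published mean for tropical
  angiosperms; the emulated study names no number), configurable globally
  or per species. ρ is used only inside the allometry; the carbon fraction
  alone converts biomass to carbon.
- Diameter 0 maps to AGB 0 (limit convention) so trajectories may start at
  the pith year; for D > 0 the model is evaluated exactly.
- Annual accumulation: `annual_c[1] = carbon[1]` and
  `annual_c[t] = carbon[t] − carbon[t−1]` (zero origin), which makes the
  series telescope exactly to the final stock.

No pith-offset, bark or upper-stem taper correction is applied: the
reconstruction is an under-bark basal diameter, so stocks are conservative
(biased low). Uncertainty of the allometry itself is not propagated.

## Mean series, wedge rings and diameter

Radii must be aligned at the outermost (felling-year) ring with equal ring
counts; automated cross-dating (lag search and realignment) is
deliberately not implemented — expert cross-dating is assumed done, and
`crossdate_check` only verifies pairwise coherence (Pearson correlation of
first-differenced log-widths, wedge years skipped pairwise; pairs under a
configurable threshold, default 0.3, are flagged; series under 10 rings
are flagged "too short").

A wedge (locally discontinuous) ring is encoded as width 0 and *excluded*
from that year's mean rather than averaged as zero growth — the ring
exists on the stem even where one radius misses it. A year that is zero on
every radius is a truly missing ring and keeps width 0. The emulated study
does not state its own rule; exclusion is this package's documented
choice.

Diameter: `d[t] = 2 · Σ_{i≤t} w̄[i] / 10` (mm ring widths, cm diameter).
Moving averages are centred with an odd window and a shrinking window at
the edges (no padding, no dropped years).

## Lifetime quartiles

Each lifetime of T years is split at the ceiling indices ⌈T/4⌉, ⌈T/2⌉,
⌈3T/4⌉, so every year belongs to exactly one quarter and boundary years go
to the earliest eligible quarter. Shares are percentages of the final
stock and always total 100 (to 1e-9).

## Inference toolkit

All tests are implemented from their definitions; SciPy supplies only
distribution functions and midranks.

- **Cox–Stuart trend test**: pair x_i with x_{i+⌊n/2⌋} (middle element
  dropped for odd n), discard ties, exact Binomial(m, ½) p-value
  (two-sided by default; one-sided available). Pair differences within
  1e-9 of the series scale are treated as ties so floating-point noise in
  an exactly flat trajectory cannot masquerade as trend. All-tied series
  are degenerate with p = 1.
- **Pettitt change-point test**: U_t = Σ_{i≤t} Σ_{j>t} sgn(x_i − x_j),
  K = max|U_t|, τ = argmax, with the standard approximation
  p = 2·exp(−6K²/(T³+T²)) capped at 1. No permutation option in v1.
- **Dunn's test**: joint midranks, tie-corrected variance
  N(N+1)/12 − Σ(t³−t)/(12(N−1)), two-sided normal p, optional Holm
  adjustment (default none — the common default of the test's standard
  implementations).
- **One-way ANOVA + pairwise t-tests with pooled SD** (df = N − k) and
  Holm step-down adjustment, as in classical post-hoc pairwise t-tests.
- **Pearson correlation** with the t-approximation p-value.

Cox–Stuart and Pettitt are sign/rank based, hence invariant under strictly
monotone transformations; this is property-tested.

## Growth-pattern classifier

Four lifetime patterns of annual carbon accumulation are distinguished:
sustained increase, increase with a multi-decade depression, plateau, and
rise then decline. The rule operates on the moving-average-smoothed annual
series m(t) (window 11 yr) and is checked in order:

1. *rise_then_decline* if Cox–Stuart on the second half of m is
   significantly decreasing;
2. *increase_with_depression* if the full-series trend is significantly
   increasing **and** m stays below `depression_factor` (0.8) times its
   running maximum for at least `depression_min_years` (15) consecutive
   years and later recovers above that maximum;
3. *sustained_increase* if the full-series trend is significantly
   increasing;
4. *plateau* otherwise.

All four thresholds plus α (0.05) are configuration, not constants. The
rule is invariant to positive rescaling of the series (sign-based tests,
relative depression threshold). Because smoothing induces serial
correlation, the trend test is anticonservative on smoothed noise; in
practice this costs plateau recall (noisy flat series are sometimes called
a trend) while the other three classes are recovered almost perfectly —
the recovery run in the acceptance script reports the numbers.

## Synthetic cohort generator

The generator's defaults are the emulated study's conditions: species
blocks of 20/21/20 trees with the published per-species age ranges
(84–180, 112–189, 87–255 yr) and final-diameter ranges (36.7–64.9,
40.3–75.8, 40.8–99.2 cm); 6 radii per disc (the study measured 369 radii
over 61 trees, at least four per disc); 0.01 mm measurement resolution;
wedge-ring probability 0.01 per radius-year; radial noise CV 0.05;
tree-level noise CV 0.1 with AR(1) log-persistence φ = 0.3. Archetype
mixture 60 / 20 / 10 / 10 % (sustained / depression / plateau / decline),
reflecting that the vast majority of the study's trees show a significant
positive trend while all four patterns occur. Where the study prints no
value (noise levels, mixture, radii count beyond "at least 4") the choice
is a field-typical one, fixed here once.

Design choices that matter:

- **Archetypes live in carbon space.** The patterns describe annual
  *carbon* accumulation. Because the allometry is strongly convex, even
  constant ring widths yield steeply rising accumulation; a flat or
  declining carbon pattern therefore cannot be expressed as a width
  pattern. sustained_increase is generated directly in width space
  (juvenile ramp of 15 yr, then a non-negative width drift, default
  0.004 mm/yr). plateau (constant rate), increase_with_depression
  (linear rise × flat-bottomed cosine dip, default onset at half of life,
  35 yr long, 55 % deep — chosen so the depression stays unambiguous under
  the classifier's default thresholds, mirroring the deep multi-decade
  depression of the pattern's real exemplar) and rise_then_decline
  (linear rise to a mid-life peak, then linear decline to 40 % of peak)
  are specified as annual-carbon shapes and inverted through the allometry
  (the quadratic in ln D solved on its increasing branch) to the ring
  widths that realize them.
- **Stylized early growth of inverted archetypes.** A tree whose carbon
  rate is constant from year 1 must reach several cm of diameter in its
  first years; the plateau/decline archetypes therefore have wide
  innermost rings. This is a deliberate idealization — it is what makes
  the noiseless patterns exactly classifiable — and it inflates the
  maximum (not the mean) annual diameter increment of synthetic cohorts
  relative to real stems.
- **Noise.** Multiplicative lognormal with AR(1) log-deviations at tree
  level (ring widths are positive and serially correlated), mean-one
  corrected; independent lognormal radial noise per ring; Bernoulli wedge
  rings, never on all radii of one year; widths rounded to 0.01 mm.
- **Calibration.** Base width is calibrated by bisection on the
  deterministic mean structure so the noiseless final diameter hits the
  target drawn for the tree; the realized noisy series is then rescaled
  multiplicatively to hit the target exactly. The rescale keeps every
  cohort inside its configured diameter range for every seed and does not
  distort pattern structure (all downstream tests are scale-invariant).
  Targets are drawn with a 2 % inset of the range so radial noise cannot
  push the reconstructed diameter outside the published bounds.
- **No climate forcing by default**: the emulated study found no
  relationship between its growth series and annual climate; the package
  exposes plain per-tree Pearson correlation against supplied climate
  series instead of any bespoke climate model.

What the generator does *not* emulate: competition between neighbours,
height growth, measurement-table digitization artifacts beyond rounding,
missing outer rings, and cross-dating errors. Passing recovery tests
therefore show that the analysis chain is correct and well-calibrated on
data satisfying its own assumptions — not that the classifier would reach
the same accuracy on real discs.

## Numerical choices

- RWL writer uses the 999 / 0.01 mm dialect, switching a series to the
  −9999 / 0.001 mm dialect when a width would itself encode to the stop
  marker; the reader accepts both. Reader conversion divides by 100/1000
  (correctly rounded) so decimal widths round-trip bit-exactly.
- Allometry inversion uses the closed-form quadratic root, valid
  far below the parabola's vertex (D ≈ e³⁹ cm), i.e. everywhere
  biological.
- Quartile boundaries use ceiling indices (deterministic tie-break).
- Dunn/ANOVA degenerate inputs (all values identical, groups of size < 2)
  raise or are excluded with a warning, as documented per function.
- All randomness flows from one integer seed through
  `numpy.random.default_rng`; per-tree seeds are drawn from the cohort
  stream, so runs are reproducible and exports byte-identical per seed.

## Problem sizes

The default cohort is the study-shaped 61-tree population (~9,400
tree-years), which one pipeline run processes in about a second. The
classifier-recovery analysis uses a 200-tree archetype-balanced cohort at
noise CV 0.1, φ 0.3. The Cox–Stuart size check uses 2,000 null replicates
of length 100 against the exact binomial envelope of the test's attainable
(discrete) size.

## Known limitations

- E and the carbon fraction shift all stocks multiplicatively; absolute
  carbon numbers are only as good as those two inputs.
- Pettitt's closed-form p-value is approximate and anticonservative under
  serial correlation; it is reported per tree but never gates anything.
- The classifier's plateau class has materially lower recall than the
  other three under noise (see above).
- Under-bark, buttress-free diameters make all stocks conservative.
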