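# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations behind each stage of the pipeline.

## Chamber flux estimation

Fluxes come from the ideal-gas conversion of headspace mixing ratios to mass
followed by OLS of mass on time. ppm is interpreted as µmol CH4 per mol of
headspace gas, so `ppm × M (g mol⁻¹) × PV/(RT)` is already in µg with
*R* = 0.082 L atm mol⁻¹ K⁻¹ (the two-decimal constant conventional in
chamber work; the ~0.07 % difference from the CODATA value is far below
instrument noise). The slope in µg s⁻¹ is multiplied by 3600 and divided by
the dry soil mass — the only scaling of the raw slope that yields
µg g dw⁻¹ h⁻¹. Results default to the carbon basis (× 12.011/16.043),
reported as µg C–CH4; the full-molecule basis is selectable.

Conventions and edge cases:

- Trimming keeps readings with `t > exclude_first_s` (default 100 s) and
  `t ≤ end_s` (default 600 s); at 10-s cadence that is 50 of 60 readings.
- r² of a zero-variance response is defined as 0; QC uses the strict
  inequality `r² > 0.9`, so a fit at exactly 0.9 fails.
- QC failures are flagged and retained; `cumulative_by_treatment(...,
  qc_drop=True)` excludes them from daily means. Exclusion is deliberately a
  downstream choice, not part of estimation.
- Cumulative emission is the trapezoid rule over sampling days converted to
  hours. It is the exact integral of the piecewise-linear interpolant, so
  missing days simply widen a trapezoid.

Not modelled: nonlinear (saturating) chamber feedback, leak correction, and
headspace-volume correction for added floodwater — jar volume is taken from
input metadata as-is, since whether to correct it is an experiment-design
question, not an estimation one.

## Keeling-plot source partitioning

δ values follow the standard per-mil definition against VPDB (carbon) and
VSMOW (hydrogen). For a two-member conservative mixture, δ_mix is exactly
affine in 1/C_total, so an OLS fit of δ on inverse concentration recovers the
source δ as the intercept; this holds for any background fraction, which the
test grid verifies to ≤1e−6 ‰. OLS (rather than geometric-mean or
Miller–Tans regression) is used because concentration error is negligible
relative to δ error for spectrometer data; the fitter is isolated behind
`keeling_intercept` should another estimator ever be needed.

Pathway classification is a point-in-box test on the (δ¹³C, δ²H) source pair:

| category | δ¹³C (‰) | δ²H (‰) |
|---|---|---|
| hydrogenotrophic | −110 … −60 | −250 … −170 |
| acetoclastic | −60 … −50 | −400 … −250 |
| oxidation-enriched | > −50 | > −170 (both required) |

Boxes are closed (inclusive); the shared δ¹³C = −60 ‰ edge resolves to the
hydrogenotrophic box, which is tested first. Everything else is
mixed/indeterminate, reported with signed per-axis distances to each
production box so near-misses are quantified. The oxidation thresholds
default to the upper edges of the production boxes and are configurable —
oxidative enrichment is a direction, not a sharply bounded region.

## Community summaries

- **Rarefaction** draws a multivariate hypergeometric sample (subsampling
  without replacement) to exactly 29,300 reads by default, dropping and
  reporting shallower samples. Seeded and reproducible.
- **Guild extraction** matches curated methanogen/methanotroph names
  (case-insensitive, underscores as spaces) against every rank token of the
  lineage string, so class-level names (e.g. Bathyarchaeia) match as well as
  genera. The curated lists mirror taxa with mcrABC (methanogens) or
  pmoCAB/mmoX (methanotrophs) capability; a name may belong to only one
  guild, making assignment unambiguous and extraction idempotent.
- **CLAM** pools counts per taxon within each habitat group and applies two
  one-sided exact binomial tests against the supermajority threshold
  π = 2/3. Conditioning on a taxon's pooled total *t* turns the boundary
  null (relative abundance in A exactly u = π/(1−π) times that in B) into
  `y_A ~ Binomial(t, u·m/(u·m+n))` with group totals m, n — reducing to
  Binomial(t, 2/3) for equal sampling effort. The individual test level is
  α/20 by default, following the published method's allocation of the
  nominal α = 0.05 across its 20 boundary points (`adjust_alpha=False`
  restores the plain per-test α). The coverage limit (default 10) is a
  pooled-count floor below which taxa are labelled "too rare" rather than
  dropped; a per-group variant of the rule is selectable because the
  published description is ambiguous between the two readings.

## qPCR quantification

Standard curves are OLS fits of Cq on log10 copies over ≥3 dilution levels
(default 10⁰–10⁶). Efficiency `E = 10^(−1/slope) − 1` is the universal
convention (slope −3.3219 ⇒ E = 100 %). Unknowns invert through the curve;
replicates are aggregated by averaging Cq (cycler-software convention;
averaging copies is available and, by convexity, always gives a larger
value). The copies-per-gram conversion uses only explicit parameters — the
dry-soil equivalent of one reaction's template and a free scale factor for
elution/dilution — with no hidden defaults. Replicate Cq spread above a
configurable gate (0.5 cycles) flags the estimate.

## Aligned-rank-transform ANOVA

For each effect of the full factorial model the response is aligned by
cell-mean algebra: subtract the full-cross cell mean and add back the target
effect's estimate, computed by inclusion–exclusion over unweighted marginal
means (equal cell weights, type-III style, so mildly unbalanced designs are
handled consistently). Aligned values are mid-ranked and a full-factorial
fixed-effects ANOVA on the ranks supplies the target effect's F, with
degrees of freedom `∏(levels−1)` over the effect's factors and residual
`N − ∏levels`. Balanced designs use an exact cell-mean decomposition (tested
against an independent type-III OLS fit); unbalanced designs fall back to
that OLS path. Replicate microcosms enter as independent units — no random
replicate term — matching how independently incubated jars behave.

The alignment diagnostic (every stripped effect re-estimates to 0 from the
aligned data, to ≤1e−9) is asserted in the test suite, and the null
rejection rate of each effect in a 2×2, 4-replicate design is verified to
sit in [0.03, 0.07] at α = 0.05 over 1,000 simulations. All full-cross
cells must be occupied; an empty cell raises an error naming it.

## Synthetic-data generator

The generator is first-class, tested code that produces every pipeline input
under a single seed, emulating a 3-site × 2-temperature (27/30 °C) ×
2-flooding × 4-replicate design sampled on days 0, 1, 3, 6, 9, 13, 17, 23,
30, with 1.5-L jars holding 400 g fresh soil at 30 % gravimetric moisture
(280 g dry).

- **Chamber series** follow `baseline + A·exp(−t/τ) + slope·t + ε` at 10-s
  cadence for 600 s. The stabilization transient is a single exponential
  with τ = 30 s, so it is negligible (≤ e^(−100/30) ≈ 3.6 %) beyond the
  100-s trim; readings are Gaussian-independent with sd 0.001 ppm,
  the precision class of a closed-loop laser spectrometer at this cadence.
  The ppm slope is derived from the target flux by inverting the ideal-gas
  model in the generator's own arithmetic, so estimator round-trips cross
  two independent code paths. Exact (≤1e−9) round-trips require the
  transient amplitude set to 0; with the default transient, the residual
  inside the window biases small fluxes by up to a few percent — which is
  precisely what the trimming rule is for.
- **Treatment fluxes** ramp quadratically under flooding to 5e−3
  µg C g dw⁻¹ h⁻¹ for the upland-forest wet/+3 °C jar on day 30 — the
  magnitude anchor — with smaller site scalings for the floodplains, and
  steady consumption near −2e−4 µg C g dw⁻¹ h⁻¹ when dry, attenuated ~60 %
  by warming. Replicate jars carry a fixed 15 % CV multiplier. Small dry
  fluxes at +3 °C legitimately produce r² below the QC bound at
  instrument-level noise; those estimates are flagged, as in a real
  campaign.
- **Isotope sets** are exact conservative two-member mixtures above a
  1.9-ppm atmospheric background (δ¹³C −47 ‰, δ²H −90 ‰ by default; all
  background values are config, never hard-coded in analysis code), with
  optional Gaussian δ noise. Wet jars draw production-range sources, dry
  jars enriched residues.
- **Count tables** (days 0 and 30 only) draw per-sample multinomials at
  lognormal depths from lognormal taxon abundances; a configurable fraction
  of taxa carries curated guild names at ~2.5 % joint abundance, and
  configurable specialist taxa are fold-enriched in one flooding group.
- **qPCR tables** follow the log-linear model with 0.1-cycle Cq noise over
  10⁰–10⁶-copy standards and per-jar unknowns for the four assayed genes.

What the generator does **not** emulate: temporal autocorrelation or drift
in analyzer noise, chamber leaks and pressure artifacts, isotopic
fractionation during partial oxidation (sources are drawn directly),
compositional correlation structure and sequencing error in count tables,
and qPCR inhibition or plate effects. Passing tests therefore demonstrate
correctness of the estimators under their stated assumptions — not
robustness to these real-data pathologies.

## Problem sizes

The test suite and acceptance script use: 100 simulated series for the flux
QC check; a 12-point noiseless grid for Keeling recovery and 1,000 noisy
replicates for unbiasedness; exhaustive CLAM-oracle agreement for all count
pairs with total ≤ 60; 1,000 null simulations of the 2×2 design for ART
calibration; 10,000 draws for the rarefaction expectation check. These sizes
give stable statistical verdicts (binomial/SEM tolerances are computed, not
guessed) while keeping the default run in tens of seconds.
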