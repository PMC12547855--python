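# Methods

This note documents the models, conventions and design choices behind
`rrfkit`, in the spirit of a statistical-software methods appendix: what is
computed, under which assumptions, and what the synthetic validation does and
does not establish about real instrument data.

## Isotopologue and adduct chemistry (`rrfkit.chem`)

Isotopologue distributions are computed by n-fold convolution of per-element
isotope abundance vectors and aggregated by **integer nominal mass shift**
from the monoisotopic peak. Fine structure within one nominal shift (e.g.
¹³C₂ vs ³⁴S) is summed: the quantitation-model arguments in this package
concern envelope *fractions* — how much response a monoisotopic EIC discards
— not exact-mass splitting, so nominal aggregation is the appropriate
resolution. The convolution is exact (binary-exponentiation of the element
vectors); an exhaustive multinomial enumeration oracle in the test suite
confirms per-peak agreement to 1e-12 for formulas up to 12 atoms.

Abundances are the IUPAC-CIAAW 2021 representative values, packaged as a
versioned TSV (`data/isotopes_iupac2021.tsv`) so results are independent of
the runtime environment. A pseudo-element `D` (abundance 1) models
deuterium-labeled internal standards. Pruning drops envelope peaks below a
threshold (default 1e-10, bounded above at 1e-3); the monoisotopic peak is
never pruned, and the monoisotopic *fraction* is always the exact analytic
product of lightest-isotope abundances.

Adduct labels (`[M+H]+`, `[2M+Na]+`, `[M+ACN+NH4]+`, `[M-H]-`, …) parse into
(multimer, signed element delta, signed charge). m/z arithmetic includes the
electron mass — at sub-ppm mass accuracy the electron is not negligible — so
m/z([M+H]+) − m/z([M−H]−) = 2 × proton mass exactly.

## The campaign simulator (`rrfkit.simulate`)

The simulator generates centroided feature tables with the statistical
structure that makes RRF estimation hard in practice. Per instrument
calibration ("run"):

* **Run effect.** Each compound's response is scaled by a lognormal
  multiplier `exp(σ_c (√ρ z₀ + √(1−ρ) z_c))`, where `z₀` is shared across
  compounds in the run and `ρ` (default 0.7) is the shared-variance fraction.
  Internal standards use the same `z₀` with their own, smaller dispersion —
  so ISTD correction removes part, but deliberately not all, of the run
  effect. Whole-compound multipliers reflect the fact that tuning, source
  condition and ion optics move the entire response of a compound together.
* **Adduct-ratio drift.** ESI adduct ratios are resampled per run from a
  Dirichlet distribution centered on the compound's propensity vector with
  concentration `κ·p` (default κ = 50; κ → ∞ recovers the propensities
  exactly). At the default κ the predominant adduct of a multi-adduct
  compound changes across runs, which is what breaks single-adduct EIC
  calibration. EI fragment fractions are held fixed.
* **Nonlinearity.** Expected response is `coefficient × multiplier × g(C)`
  with `g` linear (`C`), saturating (`C/(1+kC)`, ESI droplet
  saturation/competitive ionization), or overload-enhancing
  (`C·min(1+kC, 10)`, GC column/detector overload). Both curvature signs are
  generable because real dynamic-range data shows both.
* **Noise.** Each (compound, injection) draws one multiplicative lognormal
  noise factor at the configured CV (default 5 %), mean-corrected to 1. Noise
  proportional to signal is what motivates 1/x and 1/x² fit weighting.
* **Envelopes.** The total is split over species by the run's
  adduct/fragment fractions and over isotope peaks by the chem-module
  envelope of the **ion** formula, pruned at 1e-12 and *not* renormalized:
  the discarded tail is < 1e-10, keeping the per-sample intensity budget
  exact to 1e-9 while leaving the monoisotopic share analytically exact
  (this is what lets the closed-form EIC bias identity hold to 1e-9).

All randomness is keyed by (seed, role, run, compound-id, …), so output is
byte-identical for a fixed seed and a nontarget extractable simulated into an
existing run shares that run's latent draws — an NTE that *is* a calibrated
compound reproduces that compound's features exactly in the noiseless limit.

**EI fragments carry the neutral molecule's isotope envelope.** Fragment
elemental compositions are not modeled; every fragment of a GC compound uses
the parent envelope. This overstates the isotope spread of small fragments
but keeps the envelope arithmetic uniform and exactly analyzable. It is a
simulator simplification, not a claim about EI physics.

What the simulator does **not** emulate: chromatographic peak shapes and
integration, retention-time drift, coeluting interferences, carryover and
contamination, matrix suppression, and derivatization. Passing tests
demonstrate that the estimators are correct under the generative model — not
that real chromatographic data is this clean.

### Fixture parameters

Fixture constants are simulator parameters chosen once to reproduce the
qualitative phenomena, not measured values:

* `methyl_oleate_like` — 40 EI fragments with rank-i intensity ∝ i^(−0.7),
  so the base peak holds 1/Σi^(−0.7) ≈ 13.6 % of the ion current (a heavily
  fragmenting ester); `bht_like` — base-peak fraction 0.55 (minimal
  fragmentation, so single-ion bias is small).
* `dtdpp_like` — four positive-mode adducts ([M+H]+ 0.08, [M+NH4]+ 0.38,
  [M+Na]+ 0.34, [M+ACN+NH4]+ 0.20) with day-to-day drift.
* `d8_like` — C16H48O8Si8, whose Si₈ envelope puts 0.430 of the response in
  the monoisotopic peak.
* The saturating LC fixture uses k = 0.3 over levels 0.025–50 µg/mL. The
  curvature is deliberately mild: for a strongly saturating response the
  single-point RRF at the maximum (the chord from the origin) always exceeds
  any in-range fitted slope, because the chord averages the steep initial
  rise. Mild saturation over a wide range, fitted with 1/x weighting,
  reproduces the empirically observed ordering
  low-range slope > high-range slope > single point at max.
  The overloading GC fixture uses k = 0.05 (enhancement capped at 10×).
* Day-to-day dispersions (0.05–0.30 lognormal σ) bracket tight and loose
  compounds; the 0.05-vs-0.30 contrast is the condition under which
  per-compound RRF variances are demonstrably unequal (Levene p ≪ 0.05 at
  50 runs).

## Quantitation models (`rrfkit.quantify`)

TIC sums every feature in the sample record set; BPC takes the largest
single peak; EIC(single) one selected (species, isotope) peak or one
species' whole envelope; EIC(multi) the monoisotopic peak of every adduct;
ECC everything attributed to the compound. Attribution comes from the
feature table's `compound_id` — deconvolution of raw chromatograms is out of
scope, and the claims under study concern the model applied to
already-grouped ions. Set inclusion gives the invariant
ECC ≥ EIC(multi) ≥ EIC(single) and ECC ≥ BPC, with TIC ≥ ECC per sample.

The internal standard is always integrated as its full ECC regardless of the
analyte model. The ISTD response cancels between calibration and
semiquantitation, so this convention cannot bias any relative quantity; it
avoids the ambiguity of "the base peak of the ISTD" changing between runs.

## Calibration (`rrfkit.calibrate`)

Replicate injections are averaged per level before fitting; the per-level
injection RSD (sample SD / mean) is kept as a system-suitability diagnostic,
not used as a fit weight. The weighted fit minimizes Σ wᵢ(yᵢ − a − bxᵢ)² with
w ∈ {1, 1/x, 1/x²}; the intercept is always estimated (never forced through
zero). RRF(slope) = slope × C_ISTD, which makes the slope and single-point
conventions coincide for an origin-passing line. Weighted R² is computed on
weighted residuals about the weighted mean — the standard WLS definition,
stated here because conventions differ.

Acceptance: max injection RSD strictly < 0.20, weighted R² strictly > 0.95
(GC-MS, 1/x² required) or > 0.97 (LC-MS, 1/x required). Boundary values
reject. Rejections are structured (reason strings), and tightening any
criterion can only convert accepted → rejected.

Default dynamic-range segmentation, configurable: low range 0.025–1 µg/mL
(LC) or 0.025–0.250 µg/mL (GC); high range above 1 µg/mL. Range bounds are
inclusive, so the 1 µg/mL level anchors both segments.

## Population statistics (`rrfkit.popstats`)

Sample (n−1) standard deviation throughout — populations are finite samples
of an ongoing process, and a UF built from an underestimated SD would be
anti-conservative. Percentiles use linear interpolation between order
statistics. Populations default to accepted-only RRFs (a flag admits all
finite estimates). Means are compared with Welch's unequal-variance t-test
(Welch–Satterthwaite df); variances with the median-centered Levene
(Brown–Forsythe) test, the robust choice for skewed lognormal-like RRF
populations. Pairwise p-values are reported raw and labeled as such; no
multiple-testing correction is applied.

## Thresholds and semiquantitation (`rrfkit.thresholds`)

AET_initial = (DBT / devices-per-day) × (devices extracted / volume), in
µg/mL; AET_final = AET_initial / UF. The default UF strategy is
UF = 1/(1 − min(RSD, cap)) with cap 0.9 (UF ≤ 10): the reciprocal form is
the common regulatory convention tying the factor to RRF relative spread,
and it is isolated behind a strategy interface together with a
percentile-ratio alternative (mean / 16th percentile, the protective lower
tail) and a fixed constant. The reportability comparison is inclusive (≥):
a compound exactly at the threshold is reported — the protective reading.

Semiquantitation requires the NTE response and the surrogate RRF to use the
same quantitation model (a mismatch raises), and the surrogate estimate to
have passed acceptance. In the noiseless linear limit, when surrogate and
NTE differ only in isotope envelope, the single-ion monoisotopic EIC bias is
exactly m_NTE/m_surrogate − 1 (m = monoisotopic fraction of the ion
formula); this identity is verified to 1e-9 and is the analytic core of why
surrogates with mismatched envelopes (one vs two chlorines, for instance)
bias reported concentrations.

Day-of-analysis scoping: the CLI applies a surrogate RRF only to responses
from the run it was calibrated in and fails otherwise, rather than silently
borrowing another day's calibration.

## Problem sizes

The validation suite uses: 250 random formulas (≤ 12 atoms) plus worst-case
compositions for the isotope oracle; 100 random fixtures for the
weighted-fit oracle; 200 seeded one-run campaigns (6 levels × 3 injections,
5 % noise) for slope-RRF recovery; 200 seeded campaigns for the
semiquantitation bias ordering; and 50-run campaigns for population-variance
and UF/AET demonstrations. These sizes give stable pass/fail behavior for
the stated bounds (recovery ≥ 95 %, ordering ≥ 90 %) while keeping the suite
fast; the quantities themselves are recomputed, never cached.

## Known limitations

* Feature-to-compound attribution is assumed given; no deconvolution,
  library matching, or identification is performed.
* Isotopologue envelopes are nominal-mass aggregated; fine structure and
  resolution-dependent envelope truncation are not modeled.
* EI fragment envelopes inherit the parent formula (see above).
* Calibration models are linear only; quadratic or log–log response models
  and LOD/LOQ estimation are out of scope.
* The UF and AET expressions are documented conventions behind swappable
  strategies, not the only defensible forms; alternative strategies slot in
  behind `compute_uf`.
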