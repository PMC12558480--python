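# Methods

## Problem and counting model

Spontaneous-report databases like FAERS collect case reports, each with one
or more drugs (role-coded: primary suspect PS, secondary suspect SS,
concomitant C, interacting I) and one or more adverse events coded as
MedDRA Preferred Terms (PTs). Disproportionality analysis asks, per event
term, whether the term is reported *relatively* more often with the target
drug than with everything else. It detects reporting associations, not
incidence or causation: there is no exposure denominator.

The counting unit throughout is the **unique (deduplicated report, term)
pair**. Reports are partitioned into target reports (≥1 synonym-matched
drug row with role in the filter, default {PS}) and background reports
(everything else — reports whose only matching rows have a non-qualifying
role stay in the background rather than being dropped, because the
comparator is "all other reports"). For a term t:

- a = target pairs with t, b = target pairs without t,
- c = background pairs with t, d = background pairs without t.

This unit was chosen because a published PT-level table whose margins we
cross-check is mutually consistent under it (see "Validation by
reconstruction"); source analyses rarely state the unit explicitly. At SOC
level a report contributes at most one pair per SOC by default
(`mode="unique"`); a sum-of-PTs mode exists for comparison.

## Statistics

Per table (all comparisons strict; zero cells make a term's statistics
*undefined* rather than silently continuity-corrected — Haldane–Anscombe
+0.5 is an explicit opt-in):

- ROR = ad/bc with Wald CI on the log scale, SE = √(1/a+1/b+1/c+1/d).
- PRR = (a/(a+b))/(c/(c+d)), SE = √(1/a − 1/(a+b) + 1/c − 1/(c+d)).
- IC = log₂(aN/((a+b)(a+c))); IC025 = IC − 2·SE/ln 2 with the ROR's SE.
  This is the simplified (non-Bayesian) information component; a full-Bayes
  BCPNN mode with the standard unit priors is available
  (`bcpnn_ic_bayes`) but is not the default, because the simplified form is
  what published IC/IC025 pairs in this literature actually match
  (IC = log₂ EBGM exactly, e.g. log₂ 39.4 = 5.30).
- EBGM = aN/((a+b)(a+c)), the observed-to-expected relative reporting
  ratio. No gamma-mixture empirical-Bayes shrinkage is fitted (that is the
  full MGPS and is out of scope); consequently EBGM here equals 2^IC.
  EBGM05 = exp(ln EBGM − 1.645·SE): a one-sided 5th percentile. The 1.645
  quantile (not 1.96) is deliberate — published EBGM05 values in the table
  we cross-check match 1.645 (vomiting: 3.82·exp(−1.645·SE) ≈ 3.66 as
  printed; 1.96 would give 3.63). A two-sided 1.96 mode would be a
  one-line change and the constant is exposed (`stats.Z05`).
- Pearson χ² with df = 1 and *no* Yates correction — reconstruction of the
  hypocalcaemia row reproduces the printed 22855.29 within 0.01% without
  correction — with upper-tail p from scipy.
- Multiplicity: Benjamini–Hochberg step-up over the family of terms with
  a ≥ min_a at the analysed level (PT and SOC adjusted separately). The
  family choice is recorded in the output metadata header.

Signal flags: a ≥ 3 (configurable), ROR/PRR CI lower bound > 1, IC025 > 0,
EBGM05 > 1, adjusted p < 0.05. The composite flag policy is `ror_primary`
by default (ROR rule ∧ p-adj rule), with `all_four` and `any` alternatives;
a < min_a forces every flag false.

The scalar API delegates to the same vectorized float64 kernel used for
whole-table computation, so per-term and frame-level results are
bit-for-bit identical (this is asserted in the tests).

## Validation by reconstruction

Published signal tables print per-row (a, ROR + CI, PRR + CI, χ², IC +
IC025, EBGM + EBGM05) but not the background cells. Given the target
drug's total pair count a+b and any two independent statistics, the table
is recoverable: with r₁ = c/(c+d) = (a/(a+b))/PRR and s = (a+c)/N =
a/((a+b)·EBGM),

    N = (r₁(a+b) − a)/(r₁ − s),   c = r₁(N − a − b).

`reconstruct_fourfold` implements this inversion (degenerate when
PRR = EBGM; inconsistent inputs yield negative cells and are rejected).
Every other printed statistic then becomes a held-out consistency check.
The acceptance suite reconstructs three rows of a published cinacalcet
PT-level table (a+b = 47,755) and reproduces the held-out ROR, CI bound,
χ², IC, IC025 and EBGM05 within 0.5% (mostly ~0.1%). Round-trip error on
random integer tables is below 1e-10.

## Synthetic data generator

The generator emulates the *structure* of FAERS extracts, not FAERS
content. Per case: one PS drug from `baseline_drug_weights`; event count
K ~ Poisson(λ) truncated at 1; K PT draws i.i.d. from the baseline PT
weights multiplied by the PS drug's planted relative risks and
renormalized, then de-duplicated within the report; secondary drugs
(roles SS/C/I) drawn independently. A fraction of cases get one superseded
version with a strictly earlier receipt date, so the correct dedup output
is known exactly. Dates are yyyymmdd strings with configurable missing and
partial (yyyymm/yyyy) fractions; receipt dates stay full, as they largely
are in practice.

Key property: with renormalizer Z = 1 + w(R−1) the planted PT's weight
becomes w' = wR/Z and 1−w' = (1−w)/Z, so the target-vs-background odds
ratio equals R exactly in the single-draw case. The planted RR is
therefore the ROR's estimand, up to a small attenuation from within-report
de-duplication that grows with the PT's baseline weight and λ (visible in
`examples/run_synthetic_study.py` when planting on common PTs). The
analytic expected cells use the truncated-Poisson identity
E[x^K] = (e^{λx} − 1)/(e^λ − 1) for the per-report inclusion probability
1 − E[(1−w)^K], and `expected_fourfold` exposes them for tests.

Defaults emulate the motivating dataset's reporting profile: λ = 1.6
events/report (≈ 47,755/30,540 ≈ 1.56 for the target drug there), ~13%
missing sex, ~33% missing age, 50% missing event/start dates (≈ the ~52%
unknown time-to-onset), onset times log-normal(μ=4.4, σ=2.7) days
(median ≈ 81 d, IQR ≈ (13, 500) — matching an 82-day median with a wide
(8, 315) IQR), reporter and outcome mixes near the published marginals,
~90% US reports. What the generator does **not** model: drug-name free
text beyond simple dose suffixes, indication-driven confounding
(channeling), secular reporting trends, country-specific dynamics, or
correlated event clusters. Passing recovery/calibration tests therefore
demonstrates correctness of the *pipeline arithmetic and bookkeeping*
under a known model — not robustness to real FAERS messiness.

Study sizes used in the validation suite: recovery uses 100 replicates of
6,000 reports with a 50% target-drug share and uniform PT weights (1/200),
giving expected a ≈ 56/138/271 for RR 2/5/10 (≥ 50 by design); null
calibration uses one 10,000-report extract with 250 candidate PTs, all
with a ≥ 3.

## Numerical and design choices

- **Partial dates** carry explicit day/month/year precision; operations
  declare what they need. Dedup orders on zero-padded date strings (a
  coarser date in the same period sorts before a finer one; missing sorts
  minimal, so a dateless version survives only if it is the sole version).
  Time-to-onset requires day precision on both endpoints; negative
  differences are tracked separately as unknown, never clipped to zero.
- **Age normalization**: YR×1, DEC×10, MON÷12, WK÷52.18, DY÷365.25,
  HR÷8766; unusable units make age missing. Age bins are left-closed
  ([60, 75) → "60-74"), as are TTO bins.
- **Outcome percentages** use counted outcome codes (each code at most once
  per report) as the denominator — outcome tables in this literature sum
  to 100% over far fewer rows than there are reports, which identifies
  this policy; a worst-outcome-per-report alternative (DE > LT > DS > HO >
  CA > RI > OT) is selectable.
- **Quartiles** by linear interpolation (numpy default); the convention is
  not identifiable from a single published median/IQR, so it is stated in
  the TTO output header.
- **SOC exclusions** (a configurable list, defaulting to six organ classes
  whose events are commonly attributed to underlying-disease progression)
  are applied to PT-level results only; the SOC-level table is unfiltered.
  Exclusion filtering commutes with ranking (tested).
- **Determinism**: generation is a pure function of the config (seed
  included); the pipeline writes no timestamps, so identical configs give
  byte-identical outputs.

## Limitations

Disproportionality measures reporting association only; with the unshrunk
EBGM, small-count terms are noisier than under a fitted MGPS prior. The
simplified IC understates uncertainty relative to the full-Bayes posterior
for very small a (the optional Bayesian mode shrinks such terms strongly).
Stratified (age/sex/year) analyses and drug–drug interaction signals are
out of scope. Reproducing a real study's absolute counts requires the real
FAERS archive; this package validates the method, the bookkeeping, and the
internal consistency of published statistics.
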