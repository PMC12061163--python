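# Methods

## The screening problem

Complex mental health difficulties (CMHD) — persistent, disruptive
difficulties short of severe mental illness — are heavily under-coded in
primary care. A records-based caseness definition therefore captures only
a small, highly specific slice of the true cases, and most latent cases sit
in the control group. In that regime, regression struggles (the target has
almost no variance to partition) whereas mutual information, which
summarises coincidence rather than explained variance, remains usable.
`ehrscreen` ranks a large census of record-derived feature sets by their
mutual information with caseness, scaled to the caseness entropy, and
evaluates binary feature sets with imbalance-appropriate contingency
statistics under statistical disclosure control.

## Caseness phenotype

A patient is in the **study population** iff, at the index date (default
2021-12-31): age 18–70 inclusive (completed years, mid-year birthday
convention, because only birth year is stored); registered with their
practice for ≥ 1 year; with either any mental-disorder diagnosis code or a
prescription for a medication of interest inside the ten-year lookback;
and with no exclusion code (schizophrenia, bipolar disorder, dementia, or
descendants). A **case** additionally has an inclusion-list diagnosis
(personality disorder, borderline PD, dysthymia, chronic depression,
persistent depressive disorder, chronic or complex PTSD, or descendants)
at *any* time up to the index date, and a medication of interest inside
the lookback window. Exclusion dominates every other criterion.

Date windows are half-open `(index − 10 y, index]`: an event exactly ten
years before the index date does not qualify. This reading of "within ten
years prior" is a design choice, is configurable, and is exercised at the
boundary in the tests. Medication matching is case-insensitive substring
on the product name, since real dm+d-style product strings embed the
substance name.

## Code vocabulary

A miniature SNOMED-CT-like DAG (≈ 60 codes) stands in for the full
terminology: the genuine inclusion/exclusion parent concepts with a few
children, ~24 generic psychiatric leaves under a mental-disorder root,
somatic noise codes, antecedent-type (childhood adversity) and
concurrent-type (self-harm, substance misuse) findings outside the
psychiatric subtree, and an IAPT-style referral type. Descendant closure
("a parent subsumes its children") is the only hierarchy operation the
pipeline needs and is tested against a brute-force reachability oracle.
The real >500k-feature codelists cannot be reproduced at this scale; the
census here is illustrative, not exhaustive.

## Synthetic cohort generator

The generator defines the study conditions; it emulates the features of
the real setting that the screen's behaviour depends on, and nothing more.
Per patient, conditional on a latent complexity status `s` (true
prevalence 4%):

* **Demographics.** Age uniform on 16–90; 5% registered under one year
  (both feed the eligibility filters). Registration lengths are uniform up
  to the 12-year observation window.
* **Medication classes.** Antidepressant / antipsychotic /
  hypnotic-anxiolytic held with probabilities 0.075/0.005/0.02 (controls)
  vs 0.75/0.20/0.35 (latent cases). A held class is laid down as repeat
  prescription "regimes" (≈ monthly scripts; cases churn through more,
  shorter regimes) always inside the ten-year window.
* **Psychiatric coding.** Distinct generic psychiatric codes
  `G ~ NB(mean 0.09, dispersion 0.8)`, mean multiplied by the
  diagnosis-count rate ratio 12 for latent cases (negative binomial for
  the over-dispersion typical of EHR code counts), plus
  `Poisson(1.2)` *indication codes* for medicated patients — patients
  prescribed psychotropics nearly always carry mental-health codes.
  Without this coupling, the conjunction "any psychiatric code AND any
  medication" becomes an artefactually strong feature that no real
  dataset shows.
* **Inclusion coding (the under-coding model).** The probability of
  carrying an inclusion diagnosis is proportional to
  `min(G + 1, 8)` and normalised so the *marginal* equals the configured
  coding probability: 10% for latent cases, 1.1% background for controls.
  Recorded caseness is thus a dose-dependent function of coding intensity
  (the odds of meeting the definition rise with every additional recorded
  diagnosis) while `P(caseness)` keeps a closed form, which the tests
  check at n = 50,000 against the product formula
  `P(age ok) · P(reg ok) · (1 − p_excl) · Σ_s p(s) · q_s · p_med(s)`.
* **Attendance.** Monthly appointment counts Poisson (rate 0.30/month,
  ×1.5 for cases); per-appointment non-attendance probability logistic in
  latent status (base 8%, case shift +1.2 logits) with a month-level
  Gaussian random effect whose SD is doubled for cases — the simplest
  process yielding tunable non-attendance entropy.
* **Noise.** Somatic codes, unrelated prescriptions and IAPT referrals.

Defaults were fixed once, by exact enumeration of the discrete core of
this model, to reproduce the published cohort margins: observed caseness
≈ 0.3% of the total population (about one tenth of the true prevalence),
study population ≈ 13.5–14% of the total, ≈ 60% of the study population
holding a medication of interest, ≈ 2% caseness within the study
population (entropy ≈ 0.1 nats), and the distinct-psychiatric-code count
as the dominant feature. The latent status is written only to a separate
truth file.

What the generator does **not** emulate: real code co-occurrence
structure, secular trends and seasonality, practice-level variation,
deprivation and demographic confounding, informative deregistration, and
free-text. Passing tests therefore demonstrate that the pipeline recovers
planted structure of the stated kind under realistic marginals — not that
it would rank features identically on real records.

## Component features

78 component features across eight families: per-code presence indicators
(generic psychiatric and somatic; antecedent codes counted only before the
30th birthday, concurrent codes only after, mid-year convention);
per-medication and per-class presence; counts (distinct psychiatric
diagnoses — inclusion codes included, since they are mental-disorder
descendants, though the per-code indicators of caseness-defining codes
are deliberately not features; appointments in the last year;
antidepressant scripts; distinct products; IAPT referrals; aborted
antidepressant regimes); and four temporal measures of non-attendance.

**Aborted regimes.** Scripts of one product at most 90 days apart form a
regime; a regime is aborted if it spans < 84 days (12 weeks, a common
minimum adequate-treatment duration) unless it is the final regime still
open at the index date.

**Temporal entropy features** operate on calendar-month bins over the
last 4 years (48 months, from the first full month after registration):

* *Sample entropy* of monthly appointment counts, m = 2,
  r = 0.2 × SD (the standard defaults; the source analysis states none):
  −ln(A/B) over template pairs, self-matches excluded. Constant series
  with an explicit r > 0 give 0; with the SD-based default r they are
  missing.
* *Spectral entropy* of the mean-centred monthly DNA series: Shannon
  entropy of the normalised positive-frequency power spectrum, normalised
  by log of the bin count; needs ≥ 24 months and non-zero power.
* *Average quarterly entropy*: per full calendar year, the entropy of the
  quarterly DNA proportions normalised by ln 4 (an all-zero year counts
  0), averaged over years.
* *Active information*: plug-in MI between the 3-month binarised DNA
  history pattern and the following month, pooled over the 12 sliding
  windows in the final 15 months. The published footnote fixes only the
  intent ("consistency of the latest three months with the preceding
  year"); this estimator — window span, pattern length, plug-in pooling —
  is a reconstruction, as are the normalisations above, and all window
  lengths are parameters.

All entropies are in nats (consistent with reporting caseness entropy in
nats); normalised measures lie in [0, 1]. Missingness (short or
degenerate histories) propagates as NaN and is reported; binary features
are never missing.

## Families and combinations

Each family's component count is the number of member features present
(binary = 1, count ≥ 1, continuous observed and > 0). Cutpoints for
Few/Some/Many default to tertiles of the *positive* counts, computed once
over all patients before assignment (the original cutpoints were
judgement-based and unpublished; tertiles are a reproducible substitute,
overridable per family). `Many` takes precedence at the upper cutpoint so
the maximum observed count always lands in the top band; `None`/`NotNone`
are complementary, and exactly one of Few/Some/Many holds for positive
counts. All five level indicators per family are rankable feature sets in
their own right.

Combinations conjoin one selector per family from
{None, NotNone, Few, Some, Many, x}. Enumeration is lazy and
deterministic — lexicographic with the wildcard first, so wildcard-heavy
(high-support) combinations appear before fully-constrained ones — with
constant columns and exact duplicates (first occurrence kept) pruned, and
a cap (default 1,500) on emitted combinations; with pruning disabled,
exceeding the cap raises rather than truncating silently. Tightening any
wildcard can only shrink a combination's TRUE-set.

## Mutual-information estimation

Caseness entropy and all MI are computed within the study population.
Binary columns (components, family levels, combinations) and count
features with ≤ 30 distinct observed values use the exact plug-in
estimator; this bound separates genuinely discrete counts from
effectively continuous ones and is configurable — the source analysis
does not state its rule. Continuous features use the Ross
discrete–continuous k-NN estimator (k = 3): with d_i the distance to the
k-th nearest same-class neighbour and m_i the number of full-sample
points strictly inside that radius (self included),

&nbsp;&nbsp;I ≈ ψ(N) − ⟨ψ(N_y)⟩ + ψ(k) − ⟨ψ(m_i)⟩.

Ties are broken by symmetric jitter at 1e-10 of the IQR, seeded per
(feature, run) from the master seed; the reported value is the arithmetic
mean of 20 runs (per-run values retained), clamped at zero before
scaling. The implementation is 1-D-specialised (sorted arrays and
`searchsorted`) for speed and is cross-checked in the tests against
scikit-learn's `mutual_info_classif` (the reference implementation of the
same estimator), against a quadrature ground truth on a two-class
Gaussian benchmark, and against the plug-in estimator on jittered binary
data. Features whose non-missing subset leaves a class with ≤ k points
are skipped and reported. Estimates are computed on each feature's
complete cases.

Ranking sorts by scaled MI descending with lexicographic tie-break on the
feature identifier, so a fixed seed fixes the entire ranking
byte-for-byte. Constant ("non-informative") columns are excluded and
counted at every stage — component, family, combination — since the
pruning stage for the published census is not specified.

## Evaluation and disclosure control

For binary feature sets: prevalence per 1,000 records
(`1000·(TP+FP)/N`; the "per 1,000" direction is taken from the worked
values, e.g. a feature present in most records scoring ≈ 856), class
balance accuracy `½·[TP/min(TP+FN, TP+FP) + TN/min(TN+FP, TN+FN)]`, odds
ratio `(TP·TN)/(FP·FN)` (unavailable on a zero off-diagonal unless the
+0.5 continuity correction is enabled), PPV and NPV. Published counts are
redacted if ≤ 7 and otherwise rounded to the nearest ten (half-up — the
convention at half-counts is a design choice) *before* any statistic is
computed; a statistic needing a suppressed cell is unavailable, never
imputed. Raw-cell statistics can be requested and are labelled.

## Pipeline and reproducibility

`run_pipeline` chains simulate → phenotype → extract → aggregate → rank →
evaluate, writes every artifact (regenerated from scratch each run) and a
manifest with per-stage counts. A single master seed fans out to the
generator and to per-feature jitter streams; identical config + seed
yields byte-identical outputs, which the tests assert. The default
problem sizes — 2,000 patients for the end-to-end smoke test, 50,000 for
planted-signal recovery (20 seeds), 5,000 for the estimator benchmark —
were chosen as the smallest scales at which the planted effects and the
binomial bounds used in the tests are comfortably resolvable.

## Known limitations

* The generator's independence structure (conditional on latent status
  and medication) is far simpler than real records; features are
  conditionally independent given the latent state except where coupled
  by construction.
* No confounding or collider adjustment is performed anywhere — by
  design, mirroring the screening setting; odds ratios are marginal.
* The active-information and spectral/quarterly entropy estimators are
  reconstructions from one-line descriptions; alternative reconstructions
  would produce different (though correlated) rankings.
* The miniature vocabulary yields a feature census of ~1,600 sets, not
  the ~500k of a full terminology; combination enumeration is capped and
  pruned deterministically rather than exhaustively.
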