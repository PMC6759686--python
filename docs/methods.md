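# Methods

## Problem setting

Expanded newborn screening quantifies 43 dried-blood-spot metabolites by
tandem MS: 11 amino acids, 30 acylcarnitines, free carnitine (C0) and
succinylacetone (SA). Two acylcarnitine channels are compound (isobaric
species the assay cannot resolve): C4DC+C5-OH and C5DC+C6-OH. Screening
for the three acyl-CoA dehydrogenase deficiencies rests on substrate
accumulation — C4 (SCAD), C6/C8 (MCAD), C14:1 (VLCAD) — but raw cutoffs
on these channels yield PPVs of a few percent. Ratios of analytes cancel
variation shared by numerator and denominator (blood-spot quality, hematocrit,
feeding state, assay recovery), which is why ratio markers can raise PPV at
equal sensitivity. The package discovers such markers from a cohort and
benchmarks them against the routine compound criteria.

Units are treated as an opaque label carried on the panel (the routine
thresholds are printed in nmol/L); no conversion is ever applied, since
all thresholds and case values are used in their native units.

The panel's channel order is fixed and versioned because every ratio
feature index and canonical orientation derives from it. Only ~12 channels
are ever referenced by rules or selected markers; the remaining channels
carry standard non-derivatized-assay names and serve to make the
combinatorics exact (43 channels → 903 unordered pairs → 946 variates).

## Feature expansion

For channels a before b in panel order the canonical ratio is a/b;
the inverse name resolves to the same column with an inversion flag, so
users can address either form. Concentrations are floored at a
detection-limit `floor` (default 0.01 concentration units) before division
— standard limit-of-detection practice that keeps every ratio finite and
positive. The default modelling scale is the natural log: logistic
regression on heavy-tailed positive ratios is numerically fragile, and on
the log scale the inverse orientation is exactly a sign flip, which makes
selection provably orientation-invariant (verified by a test that reverses
the panel order and recovers identical channel pairs). Raw scale is
retained for threshold-based evaluation, where cutoffs live in
concentration units.

## Selection protocol

1. **Split.** The cohort is split at random into model-building and
   testing parts (default 200,000-scale model part). A stratified mode
   forces at least one case of each condition into the model part; exact
   realized sizes are reported, never assumed.
2. **Subgroups.** The model part is partitioned into `n_subgroups`
   disjoint subgroups of exact `subgroup_size` (default 20 × 10,000);
   leftovers are unused and counted in the report. At realistic
   prevalence most subgroups contain no case; such subgroups return an
   empty selection with a degenerate flag and never abort the run.
3. **Per-subgroup stepwise logistic regression** over the 946 variates
   against the binary outcome (any-ACAD by default; one-vs-rest
   per-condition mode is provided, and is the right choice when distinct
   conditions carry distinct planted signals, since an any-ACAD outcome
   legitimately rewards cross-condition ratio features).
4. **Consensus.** Features selected in ≥ `consensus_min` subgroups
   (default 2) survive — a stability-selection filter that suppresses
   subgroup-idiosyncratic noise features.
5. **Final model.** The same stepwise engine refits on the consensus set
   over the full model-building data; survivors are the marker panel.
   Each final marker is assigned to the condition whose cases show the
   largest standardized separation (|case mean − control mean| / control
   SD) on that feature.

The subgroup protocol is implemented faithfully even though a single
modern fit over the full data would be feasible: the partition-and-vote
structure **is** the method under study, and it behaves as a stability
selection.

### Stepwise engine

Forward selection enters, at each step, the candidate with the smallest
Rao efficient-score p-value evaluated at the current fit (the classic
stepwise entry statistic, computed for all candidates in one vectorized
pass); entry requires p ≤ `entry_p` (default 0.05). After each entry,
included variables are tested by penalized likelihood-ratio and removed
while the largest removal p exceeds `removal_p` (default 0.10). Ties are
broken by canonical feature order; the procedure is fully deterministic
given column order and configuration. An add/remove cycle detector stops
the loop if a model state repeats. Because the residual score of a
penalized fit is not exactly zero, the entry statistic projects the
candidate out of the fitted design (the efficient score) — without this
correction, features with large means acquire spurious signal.

With ~10–20 events against 946 candidates, unpenalized stepwise over the
full set is ill-posed, so a univariate score-test prescreen admits the
top-K candidates (default K = 50) to the search; `prescreen_k=None`
disables it for fidelity runs.

### Rare events and separation

Near-perfect markers separate completely at screening prevalence, where
maximum likelihood diverges. The default engine is therefore Firth's
bias-reduced logistic regression (Jeffreys-prior penalty
0.5·log det I(β)), implemented with modified-score Newton iterations and
step-halving; nested models are compared by penalized log-likelihood
differences, the standard practice for this estimator. Complete
separation is detected (every case's linear predictor above every
control's) and flagged, never hidden. Plain ML via statsmodels is
available as `penalty="none"`, with separated fits flagged.

## Evaluation

- **Optimal PPV at 100% sensitivity.** For a higher-is-disease marker the
  threshold is the minimum case value with inclusive comparison — the
  unique threshold guaranteeing zero false negatives; among all zero-FN
  thresholds it maximizes PPV (any higher threshold loses a case, any
  lower one only adds false positives). A brute-force search over all
  observed thresholds is kept as an independent oracle in the tests.
- **Confusion metrics** use the standard definitions; undefined ratios
  (e.g. PPV with no positive calls) carry explicit `None` flags, never a
  silent zero. Displayed PPVs are rounded half-up to one decimal; full
  precision is retained internally. One benchmark table in the source
  material prints an MCAD PPV inconsistent with its own TP/FP counts; the
  package always computes PPV = TP/(TP+FP).
- **McNemar paired test** on discordant calls b (A-only) and c (B-only):
  statistic (b−c)²/(b+c), χ² with 1 df, optional continuity correction
  (default off). Identical call sets are degenerate and rendered as "–".
  Published χ² values for such comparisons are generally not recomputable
  from marginal counts alone (the paired 2×2 is usually unpublished), so
  no equality with any published statistic is asserted.
- **Incidence strings** "1/n" use half-up rounding of total/cases, with
  thousands grouping only for n ≥ 10,000 (matching the reporting style
  that prints "1/17,606" but "1/4242").
- **Rule boundaries.** The routine criteria are applied as printed
  (strict > and <, ≥ where printed). An inclusive mode widens strict
  comparators, because a confirmed case sitting exactly on a printed
  cutoff (an MCAD case with C6 = 0.09 against "C6 > 0.09") is
  screen-positive only under inclusive comparison. Default is as-printed.
  Where two published variants of a rule's denominator channel conflict
  (C4DC+C5-OH/C8 vs /C8:1), the engine implements the criterion table's
  form (C8).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes; it
is calibrated once, before any acceptance measurement, and not revisited.

- **Healthy background:** independent per-channel log-normals (an
  optional log-scale correlation matrix is supported). Medians and
  log-SDs are set so the routine cutoffs for C4 (0.7), C8 (0.3) and C14:1
  (0.5) fall at z ≈ 3.4–3.6 — healthy exceedance ~10⁻³–10⁻⁴, i.e.
  hundreds of initial false positives per ~350,000 newborns, matching the
  scale of a real programme's funnel. Log-normality is the standard model
  for blood-spot analytes and guarantees positivity.
- **Cases:** labels are i.i.d. with condition prevalences 1/32,011
  (SCAD), 1/88,030 (MCAD), 1/70,424 (VLCAD). A case multiplies its
  condition's substrate channels by a log-normal fold around an anchor
  (SCAD: C4 ×8; MCAD: C8 ×30, C6 ×10; VLCAD: C14:1 ×23), chosen so
  simulated case values cover the confirmed cases' recorded spans (e.g.
  median case C14:1 inside 0.63–4.27). Unlisted channels follow the
  background.
- **Covariates** (sex, gestational-age band, birth-weight band, age at
  test, fetus count) follow the marginal frequencies of a large regional
  cohort (≈95% ≥37 weeks, ≈94% ≥2,500 g) and are independent of the
  analytes, consistent with the absence of significant covariate–outcome
  associations in such programmes. Missing covariates are an explicit
  "unrecorded" category, never dropped.
- **Two-stage flow:** initial positives are recalled with compliance
  0.961; the second specimen regresses toward the record's latent mean,
  log x₂ = μ + ρ(log x₁ − μ) + σ√(1−ρ²)z with ρ = 0.7 by default, so an
  upper-tail false positive tends to fall back under threshold on repeat
  (the recall attrition seen in practice, ~90% of false positives
  clearing) while a true case's elevated latent mean keeps it positive.
  ρ = 1 reproduces the first specimen exactly. Diagnostic confirmation is
  modelled as perfect (confirmed = repeat-positive with a true label);
  no diagnostic errors are simulated.
- **Planted-marker scenarios** elevate a numerator by √fold and depress a
  denominator by √fold, so the planted ratio shifts by the full fold
  while each raw channel moves only half as far on the log scale — by
  construction the ratio is the best single discriminator. This is the
  scaffolding for parameter-recovery verification.

**What passing tests do and do not show.** With independent channels and
pure substrate elevation, the Bayes-optimal single marker of the default
(non-planted) simulator is the raw substrate channel itself; the ratio
advantage observed in real data arises from correlated variation that
division cancels, which the default generator does not model (the planted
scenario models it explicitly). Recovery results on planted cohorts
therefore validate the selection machinery, not the clinical superiority
of any particular ratio. The simulator also omits assay drift, batch
effects, QC structure and participation selection.

## Problem sizes and determinism

Verification runs are scaled for a desktop: parameter recovery uses
n = 20,000 with 20 cases and 10 × 2,000 subgroups over 100 seeds per arm
(planted and null); flow conservation uses up to n = 35,000; the cutoff
oracle uses 1,000 random instances with n ≤ 500. Sizes are configuration,
not code: the same estimators run at the 200,000 × 20 × 10,000 default
scale unchanged.

All randomness flows from explicit integer seeds via
`numpy.random.default_rng`; the pipeline derives per-stage seeds from one
master seed through `numpy.random.SeedSequence`, so identical
config + seed reproduces every output bit-for-bit (manifests record
SHA-256 checksums of all stage outputs).

## Known limitations

- The stepwise variant (score entry / LR removal, Firth penalty,
  prescreen) is one defensible instantiation of "stepwise multivariate
  logistic regression"; other variants (enter, backward, plain-ML) are
  selectable but not the default path.
- Condition assignment of a final marker is a heuristic (largest
  standardized separation) and can be ambiguous for markers driven by two
  conditions; the per-condition outcome mode sidesteps this.
- The optimal-PPV criterion conditions on the observed cases (threshold
  at an observed case value); it is an in-sample benchmark, not a
  prospective cutoff with guaranteed future sensitivity.
- Screening rules are held fixed across both stages of the flow; rule
  switching between initial and repeat testing is not modelled.
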