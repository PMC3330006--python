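# Methods

## The additive value model

A committee of members appraises an intervention against a matrix of
decision criteria grouped into four clusters (quality of evidence, disease
impact, intervention, economics). Member *m* gives criterion *c* an
importance weight `w_m(c)` (integer, 1–5; 5 = greatest importance, elicited
independently of the intervention) and a score `s_m(c)` (integer, 0–3;
higher is always more favorable — the scale anchors orient 3 toward
benefit, e.g. "Substantial savings"). The member's value estimate is the
sum over active criteria of normalized weight × standardized score:

V_m = Σ_c (w_m(c) / Σ_k w_m(k)) · (s_m(c) / 3), a fraction of the maximum
attainable value in [0, 1].

Assumptions baked into this form:

- **Additivity / preferential independence.** A criterion's contribution
  depends only on its own weight and score; no interactions, no
  swing-weighting, no analytic-hierarchy elicitation.
- **Linear value in the score.** Each score step is worth the same; scores
  are treated as discrete integers and non-integer inputs are rejected.
- **Per-member normalization.** Weights are ratios within a member, so the
  estimate is invariant under positive rescaling of a member's raw weights.
  Because the weight scale starts at 1, every normalized weight is strictly
  positive and the estimate is strictly increasing in every score.

**Aggregation order.** Estimates are computed per member first and then
summarized across the panel (mean, sample SD with n − 1, min, max). This
order is what makes a between-member SD of the estimate meaningful at all;
the alternative — averaging weights and scores first and combining the
panel means — is exposed only as the fitted `pooled_estimate_` diagnostic.
For all reconstructions we attempted, population- and sample-SD
denominators round to the same 1-dp values, so the n − 1 choice is safe
either way.

**Contribution shares.** The per-criterion mean contribution (mean over
members of normalized weight × standardized score) resums exactly to the
panel mean estimate. Integer-percent shares divide the mean contribution by
the panel mean (the `per_member` option averages within-member shares
instead; default off). If the panel mean is zero, shares are flagged
undefined rather than divided. Rounding everywhere is half away from zero
(4.667 → 4.7; 55.6% → 56%), matching how committee statistics are
conventionally printed; integer shares over 14 criteria therefore sum to
100 with a slack of about ±1 in practice (the mathematical worst case is
half a point per criterion).

**Missingness.** Members with any missing weight or score on an active
criterion are dropped from the quantitative model entirely and listed in
`dropped_members_`; a normalized weight vector cannot be formed from a
partial one, and imputation would manufacture opinion. Survey tallies, by
contrast, use each item's own responder count as denominator, since
denominators legitimately vary across questionnaire items.

## Criteria configuration

The bundled default configuration is a 15-criterion matrix (3 quality of
evidence, 2 disease impact, 7 intervention, 3 economics) with stable ids
(D1–D2, I1–I7, E1–E3, Q1–Q3), of which Q1 ("Adherence to requirements of
decisionmaking body") is excluded from appraisal, leaving 14 active
criteria, plus four contextual criteria recorded as positive/negative
impacts. Contextual criteria are unbounded in number and never enter the
quantitative model. Custom sets load from YAML/JSON and are validated for
duplicate ids, unknown clusters and dangling exclusions; panel CSVs are
validated cell-by-cell against each criterion's scale with errors naming
the member and criterion.

## Economics

Incremental cost per patient is the intervention price minus the
comparator price; budget impact is that difference times the covered
population per period. Amounts are exact 2-dp decimals in a single
labelled currency (no float drift: 180.00 − 103.10 = 76.90 exactly).
Externally modelled figures such as cost per QALY are treated as given
inputs, never recomputed — no Markov modelling, discounting or
sensitivity analysis beyond linearity in population.

## Synthetic committees

The generator exists because member-level panel data underlying published
appraisals are typically not released; only per-criterion means and SDs
(printed at 1 dp) survive, and several appear only in figures.

**Exact reconstruction.** For n ≤ 12 members on a bounded integer scale,
all n-multisets are enumerated (≤ C(16,4) = 1,820 for scale width 5) and a
multiset is feasible when its mean and sample SD, rounded half away from
zero to 1 dp, equal the printed targets. Rounded- rather than exact-moment
matching is the criterion because exact printed moments are generally
unattainable with a handful of integers. Among feasible multisets the
lexicographically largest sorted-descending one is returned — an arbitrary
but deterministic tie-break. A mean-only target (SD not printed) takes the
minimum-SD feasible vector. Infeasibility is a *result*: the report ranks
the nearest achievable (mean, SD) pairs by squared distance with an
example vector each. One printed score target — mean 2.5, SD 0.3, 9
members on 0–3 — is provably infeasible (integer sums 22 and 23 give
means rounding to 2.4 and 2.6; no sum yields 2.5), and an independent
brute-force oracle in the test suite confirms the enumeration's
feasibility map over a full grid of targets.

**The fixture committee.** `fixture_published_panel()` assembles a
deterministic 9 × 14 panel: text-printed (mean, SD) targets are
reconstructed exactly; mean-only columns take the minimum-SD vector;
a column with a printed SD but figure-only mean uses the mid-scale mean 3
with that SD; fully figure-only columns get constant mid-scale fill-ins
(weight 3; score 2, the rounded midpoint of 0–3). Every column's
provenance is labelled (`text`, `nearest_feasible`, `fill_in_*`) and no
test asserts against fill-ins. Within each column the sorted-descending
values are rotated by the criterion's position so no synthetic member
holds every extreme; the true member-level pairing is unknown and any
assignment consistent with the column statistics is admissible. The
fixture is a reconstruction consistent with printed statistics — not the
study data — and its panel-level value estimate is accordingly *not* a
reproduction of the published headline estimate, which depended on the
unpublished joint distribution of weights and scores.

**Seeded sampling.** `sample_panel` draws each column independently from
a pmf on the scale whose exact mean and SD are the closest achievable to
the targets, found by SLSQP least squares over the probability simplex
(an SD target of 0 degenerates to a point mass at the rounded mean). A
column is redrawn (up to 200 times) until its rounded 1-dp sample moments
fall within a tolerance, default 0.2 — loose enough for 9-member sample
noise, tight enough to pin the first decimal. When only a mean was
printed, the pmf assumes a dispersion of 0.5 (typical of the printed SDs
on these scales) and only the mean is checked. Randomness derives from
one top-level seed with per-criterion substreams keyed by a SHA-256 hash
of kind and criterion id, so columns are reproducible independently of
criterion order. Columns are sampled independently — the generator does
not emulate between-criterion correlation, clustering of opinions within
members, or strategic response behaviour, so passing tests demonstrate
the pipeline's arithmetic and contracts, not distributional realism of
real committees.

## Numerical and formatting choices

- Rounding: half away from zero throughout; 1 dp for raw-scale statistics,
  integer percents for estimates, shares and tallies. A 4-ulp epsilon
  guards against binary representations of exact halves.
- Sample SD (n − 1) everywhere, including inside the reconstruction
  feasibility test, mirroring the model's panel statistics.
- Reports render deterministically (stable ordering, fixed formats);
  partial results appear as explicit "not computed" placeholders. CSV
  dialect is comma, UTF-8, header row, "." decimal separator.
- Problem sizes in the test suite and acceptance script mirror the
  committee setting itself: 9 members × 14 criteria, with brute-force
  oracles on panels up to 3 × 4 and multiset enumerations up to scale
  width 5 — all far below any practical resource limit.

## Known limitations

- No non-linear or interacting value models; no uncertainty propagation
  from scores to the estimate beyond the between-member SD.
- Survey tallies are purely descriptive (no tests or intervals), matching
  the committee-feedback setting they serve.
- The generator's independent columns cannot reproduce joint statistics
  (e.g. the published range of individual estimates) even when every
  marginal is matched.
- Quality-of-evidence percentages and cost-effectiveness ratios cited in
  appraisal reports are stored as given values; their derivation is out of
  scope.
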