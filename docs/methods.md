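# Methods

## The measurement problem

School-based health programs routinely invite parents to take part — family
events, take-home activity packs, online lessons — and routinely evaluate them
with surveys, dietary recalls and accelerometry. Simply counting whether a
parent "participated" conflates a parent who returned one activity pack with
one who attended every event, completed every survey wave and logged three
dietary recalls per wave. This package implements a two-index schema that
separates **breadth** from **depth** of engagement and makes both comparable
across study arms that offered different menus of activities.

## The indices

For a parent offered the activity set *A* of their cohort × school arm:

* **PPP** (Parent Participation Profile): the number of distinct activity
  types attempted, where "attempted" means nonzero frequency points.
  Standardized PPP = PPP / |A|.
* **PEI** (Parent Engagement Intensity):
  Σ_{a ∈ A} f_a · w_a, where f_a are the activity's frequency points and w_a
  its intensity factor. Standardized PEI divides by the arm maximum
  Σ_a f_a^max · w_a.

**Intensity factor** (0–5): one credit for each of — participation *not*
incentivized; required leaving home (internet-at-home activities score 0);
involved the child; took ≥ 0.5 h per episode; requested personal information.
The ≥ 0.5 h boundary is inclusive: activities listed at exactly half an hour
earn the credit. In the canonical catalog the eight factors are
3, 2, 2, 1, 2, 1, 1, 2 (family fun nights, action packs, recipes, online
nutrition course, parent survey, parent diet recalls, youth diet recalls,
accelerometry).

**Frequency points** convert raw counts through one of three rules:
per-occasion (1 point per survey wave, lesson viewed, event attended);
binned (1–3 action packs → 1 point, 4–6 → 2, 7–10 → 3; 1 recipe → 1,
2–3 → 2, 4–5 → 3); or per-timepoint binned (dietary recalls: 1 recall → 1
point, 2–3 recalls → 2 points, summed over up to three measurement waves).
Bins are validated at load time for contiguity from 1, coverage, and monotone
points — a silently mis-binned rule would corrupt every downstream index.

Every canonical activity has maximum weighting f^max · w = 6, so an arm
offering *k* activity types has max PPP = k and max PEI = 6k; the full
eight-activity arm tops out at 48 intensity points. The schema's stated
intensity range has a lower bound of 2 in its original description, but no
combination of the stated rules produces a minimum of 2 for an engaged parent
(a single online lesson yields PEI 1); this implementation applies the rules
as stated, so PEI for an engaged parent ranges from 1 upward.

**Positive deviance (PD):** a parent whose standardized index is ≥ 0.75
(boundary inclusive) is a positive deviant. The default basis is the
standardized PPP — the basis on which all the schema's PD contrasts are
tabulated — with standardized PEI available as an alternative via a
parameter.

### A note on the worked examples

The four worked examples (Schools A–D) are reproduced by
`engage.synthetic.fixture_table3`. Three reproduce the published arithmetic
exactly. In the School D example the published decomposition credits the
action packs (5 returned → 2 frequency points, intensity factor 2) with 2
intensity points rather than 2 × 2 = 4; applying the schema's own rules — the
same way the other three examples apply them — gives PEI 20 and standardized
PEI 20/48 = 41.7%, not the published 37.5%. This package scores by the rules,
so School D reports 41.7%.

## Design decisions

* **Catalogs are data, not code.** The eight activities and 31 cohort × school
  arms ship as a packaged JSON document (`engage/data/fff_catalog.json`); a
  user-defined schema with different activities, bins or arms is a different
  JSON file, no code changes. Cohort 4 fielded no school-5 arm; the catalog
  encodes exactly 31 arms and looking up the missing one raises a lookup
  error rather than inventing an empty arm.
* **Standardized sub-scores can be missing.** Program/evaluation sub-indices
  are reported per category; when an arm offers nothing in a category the
  standardized sub-score is missing (`None`/NaN), never 0 — masking the
  division by zero would fabricate a "fully disengaged" reading for an
  opportunity that never existed.
* **Fractions internally, percents at the surface.** All standardized values
  are fractions in [0, 1] in memory and in the score table; rendering to
  percent happens only in CLI output and reports.
* **Zero-intensity activities are legal but warned about** for user-defined
  catalogs, since they can never contribute to PEI; all canonical factors
  are ≥ 1.
* **Tidy participation logs.** One CSV row per parent × activity
  (× timepoint for per-timepoint activities), because activities have
  heterogeneous count structures. Rejected rows (activity not offered in the
  parent's arm, count above the declared maximum, missing timepoint) are
  returned with reasons; accepted plus rejected rows always partition the
  input. Parents present only in the outcomes table are retained with zero
  engagement; parents without an outcome row are retained for scoring only.
  The outcomes CSV accepts an optional `cohort` column so outcomes-only
  parents can be resolved to an arm for standardization.

## Statistical surface

The analysis functions mirror the evaluation plan such a study uses, and
delegate to standard implementations: Pearson correlation and the independent
two-sample t (pooled-variance by default, Welch by flag) from `scipy.stats`;
Pearson χ² of independence with expected counts and a small-expected-count
warning; an additive fixed-effects adjustment of youth BMI percentile for
school and classroom (OLS on factor codings via `statsmodels`, returning
residuals plus the grand mean — idempotent and grand-mean preserving;
classroom labels are treated as globally unique rather than nested); and a
two-timepoint split-plot (mixed) ANOVA via `pingouin.mixed_anova` for
change-by-PD-status contrasts, reporting group, time and group × time effects
with marginal means ± SE. The original analyses' covariance structure for the
repeated-measures model is not documented; the split-plot decomposition is the
closest standard construction and the test suite verifies it against the
classical sums-of-squares formulae. **No multiple-testing correction is
applied anywhere** — p-values are per-comparison, as in the analysis plan this
package operationalizes.

Degenerate inputs: two groups with zero variance return t = 0 (equal means)
or ±∞ with p → 0 (unequal), flagged with a warning rather than erroring, so
batch comparisons over many near-constant activity columns do not abort.

## The synthetic cohort generator

No study data are distributed, so the generator produces cohorts with the
*structure* the schema assumes: parents nested in the 31 arms with unequal
offerings, burden-dependent partial uptake, and a tunable dependence between
engagement and youth BMI percentile. Per parent:

1. latent engagement propensity θ ~ Beta(2, 2) drawn jointly with baseline
   BMI percentile through a Gaussian copula with normal-score correlation
   `bmi_dependence` (default −0.3; the marginal percentile is uniform on
   (1, 99), mean ≈ 50, SD ≈ 28 — close to the near-uniform percentile
   distributions such cohorts report);
2. each offered activity is attempted independently with probability
   `logistic(logit(uptake_base) + propensity_scale·θ − burden_slope·w)`,
   w the intensity factor — higher-burden activities see less uptake;
3. attempted activities get raw counts uniform over their admissible nonzero
   values (no uptake distribution is documented for the original study, so
   uniform is the maximally non-committal choice);
4. BMI percentile is carried over three waves with per-wave drift
   `time_drift` (default 0) plus Gaussian noise `bmi_sd` (default 4
   percentile points), clipped to (1, 99).

Defaults `uptake_base = 0.10`, `propensity_scale = 4.0`,
`burden_slope = 0.8` were fixed once so that on the canonical catalog roughly
55% of parents engage in at least one activity and engaged parents average
close to 40% of their offered activity types — the participation margins this
kind of program reports. Zero-engagement parents arise naturally when every
attempt fails; no special mechanism is needed.

What the generator does **not** emulate: psychosocial covariates, survey-item
content, informative missingness, within-family correlation beyond the single
latent θ, or secular BMI trends. Passing tests therefore demonstrate that the
scoring and analysis machinery is correct and that dependence of the stated
sign and ordering is recoverable — not that any particular real-world effect
size is reproduced. Because the copula targets a *rank* dependence and
engagement is a coarse discrete transform of θ, the product-moment correlation
between standardized PEI and BMI percentile is attenuated relative to
`bmi_dependence`; sign and magnitude-ordering are the promised properties,
and the test suite checks exactly those (sign recovery in ≥ 95% of 200
replicates at ≈ 500 parents with `bmi_dependence = −0.5`).

## Problem sizes and numerical choices

The test suite exercises scoring on 1,000 randomly generated records against
a brute-force enumeration oracle, the statistics against textbook-formula
oracles at 1e-10, type-I error of the t-test on 2,000 seeded null replicates,
and parameter recovery on 200 replicates of ≈ 500-parent cohorts (16 parents
per arm × 31 arms). All simulations run single-threaded from
`numpy.random.default_rng` seeds; a fixed seed reproduces every cohort
bit-exactly. Ties at the PD boundary are inclusive by definition (≥ 0.75).

## Known limitations

* The schema ignores *when* within a wave participation happened; longitudinal
  change in engagement intensity is out of scope.
* Partially completed surveys count as completed at that wave if any
  completion evidence is logged; no finer rule is documented.
* The χ² warning threshold (any expected count < 5) is advisory; no exact
  test is substituted automatically.
* With unbalanced groups the split-plot F-tests follow `pingouin`'s
  unweighted-means construction; other software may differ slightly.
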