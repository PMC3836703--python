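# Methods

## The screening problem

A microRNA (miR) that actively represses a target mRNA leaves a
quantifiable signature: negative correlation between the expression
levels of the miR and the gene. When that regulation is present in only
a subset of tumours — for example because a genomic aberration has
created or destroyed the regulatory link in part of the cohort — the
cohort-wide correlation can be near zero while a patient subgroup shows
a strong association. `mirstrat` screens every miR–gene pair for exactly
this situation and asks whether the induced patient split carries
prognostic information.

For one pair with miR vector *x* and gene vector *y* over *n* patients,
the screen seeks a partition into Group 1 (the associated patients) and
Group 2 (the complement) such that

* the Pearson correlation r₁ over Group 1 is significantly **negative**
  (p < α_corr, default 0.05),
* the correlation r₂ over Group 2 is **insignificant** (p ≥ α_corr),
* both groups contain at least `min_group_size` patients (default 10).

Pairs with such a "valid" partition are then tested for survival
separation between the two groups with the two-group log-rank statistic
(χ² = (ΣO−E)²/ΣV over distinct event times, p from χ²₁), under
family-wise Bonferroni control at α_family = 0.05 divided by the number
of valid (survival-tested) pairs. Two guards follow: the **abundance
filter** removes pairs whose groups differ in the expression *level* of
the gene or the miR (two-sided Mann–Whitney, both p ≥ α_filter = 0.05) —
a level shift means the stratification is not evidence of a
correlation-borne mechanism, since no regulation can be read off when
one participant is effectively absent from a group; and, when a
binding-site prediction table is supplied, the pair must be supported by
at least one prediction program.

## The greedy partition search

Group 1 is grown greedily from a random seed triple of patients; every
remaining patient is visited once in random order and either admitted or
left in Group 2. Two admission criteria are implemented:

* **correlation** — admit unless the candidate strictly decreases |r|
  over Group 1. This single comparison per visit makes the |r| trace
  monotone non-decreasing, which is a useful contract for testing, but
  it has a structural weakness as a search move: the sampling density of
  the correlation coefficient of three bivariate-normal points is
  f(r) ∝ (1−r²)^(−1/2), so roughly one random triple in five starts with
  |r| > 0.95. Such a start almost never accepts anyone, the group stays
  at a handful of members, and a maximiser of |r₁| across restarts
  always prefers these degenerate shards.
* **significance** (screen default) — a candidate is excluded only when
  it would weaken *both* the correlation and its significance.  Because
  |r| can only fall when n rises, this reduces to a ratchet on the
  correlation t statistic t = |r|·√((n−2)/(1−r²)), which values a
  slightly weaker coefficient over more patients exactly when the
  evidence for association grows. (Comparing t across consecutive group
  sizes is marginally stricter than comparing the p-values themselves —
  the survival function of t falls with extra degrees of freedom — but
  it is deterministic, monotone and cheap inside the scan kernel.)

Each pair is fitted with `n_restarts` independent seed triples and scan
orders (default 10) drawn from a per-pair seeded generator (derived from
the run seed and a CRC32 of the pair's identifiers, so results do not
depend on the order or subsetting of the pair universe). Among the
restart outcomes the screen prefers partitions that already satisfy the
validity criterion, the largest Group 1 first — the restart search
serves the selection criterion, and on planted-subgroup benchmarks the
largest valid group tracks the true subgroup best. If no restart is
valid, the |r₁| maximiser over size-feasible partitions is returned (it
will fail validity downstream and the pair drops out).

A single pass per restart is the default; `max_passes > 1` re-offers
previously rejected patients until no admission occurs. An
iterate-to-convergence variant with removal moves was evaluated and
rejected: with either objective it collapses to 3-point groups with
|r| = 1 (both |r| and t are unbounded there), so removal moves are not
offered.

## Follow-up analyses

**Permutation FDR.** The survival labels (time, event) are permuted
jointly across patients `n_fdr_iterations` times (default 1000); the
partitions are *not* refitted, since they depend only on expression. At
each iteration the log-rank test is recomputed for every valid pair
against its fixed partition and the pairs clearing the same Bonferroni
rule are counted. The reported bound is the add-one estimator
(1 + #{count ≥ observed}) / (iterations + 1). The per-pair recomputation
is vectorised across pairs by permuting group labels with the inverse
permutation against one pre-sorted survival layout; a brute-force
re-run per permutation is used as the oracle in the test suite.

**Sensitivity.** For one pair, the greedy scan is run from many seed
triples (sampled, or exhaustive when C(n,3) is below a cap) under a
fixed scan-order policy: one seeded base permutation with the triple's
members removed, so only the seed choice varies. The spread of |r₁|
across triples measures how much the arbitrary initialisation drives
the outcome.

**Covariate balance.** Clinical covariates are compared between the two
groups (rank-sum for numeric, χ² contingency for categorical, no
multiplicity correction — the table is descriptive) to check that a
discovered stratification is not a re-discovery of a known clinical
variable.

## Synthetic cohorts

The generator emulates a matched expression/survival cohort:

* background expression per feature: independent Gaussian, mean uniform
  on [6, 10] (log₂-like microarray levels), unit sd;
* a planted pair rewrites the gene inside a random subgroup of
  ⌊fraction·n⌉ patients as gene = μ_g + b·(mir − μ_m) + ε with
  ε ~ N(0, noise_sd²) and the negative slope b calibrated so the
  expected Pearson correlation equals `target_r`
  (b² = noise_sd²·r²/(1−r²)); the complement's gene values are redrawn
  with the matched marginal sd √(b² + noise_sd²), so the two groups are
  indistinguishable by expression level and the association is carried
  by correlation structure alone;
* survival: exponential with hazard `baseline_hazard` (default 1/500
  per day) times `hazard_ratio` for planted-subgroup members, with
  independent exponential censoring (default 1/1000 per day) — about
  two thirds of baseline patients die in view.

Default study conditions: 200 patients, a 10×10 pair universe, one
planted pair with fraction 0.5, target r = −0.8, hazard ratio 3.

What the generator does **not** emulate: inter-feature correlation,
batch effects, heteroskedastic platform noise, non-exponential hazards,
informative censoring. Tests passing on these cohorts demonstrate the
mechanics and calibration of the screen, not its behaviour under real
microarray artefacts.

### Identifiability of the planted subgroup

With marginals matched by construction, the only information about a
patient's membership is the residual of (x, y) from the planted
regression line: sd noise_sd inside the subgroup versus
√(1 + b²)·(noise at the matched marginal scale) outside. At
target r = −0.8 the likelihood-ratio classifier (a threshold on the
absolute residual) attains a Jaccard overlap with the true subgroup of
only ≈ 0.58, and any partition algorithm is bounded by it. The greedy
screen measures ≈ 0.49 mean Jaccard over 50 replicates at the default
conditions, and the resulting group mixing dilutes the effective
between-group hazard ratio from 3 to ≈ 1.4, so Bonferroni-level
survival detection of a planted r = −0.8 pair at n = 200 is rare
(sole-discovery rate 2/50 measured). Recovery becomes reliable as the
association approaches determinism: the README example (target
r = −0.98, hazard ratio 6, n = 160) yields the planted pair as the sole
discovery with log-rank p ≈ 3×10⁻⁷. This is a property of the inference
problem, not of the implementation; real cohorts in which this style of
screen succeeds presumably present much sharper within-group
associations than a noisy r = −0.8.

## Numerical choices

* Correlation significance: two-sided p from the t transform with n−2
  df; |r| = 1 maps to p = 0. Zero-variance vectors yield a flagged
  degenerate result (r = 0, p = 1), never a NaN.
* Greedy scan: running sums in double precision (the jitted kernel and
  the pure-python fallback execute identical arithmetic); the stored
  group statistics are recomputed from scratch after the scan, so a
  partition always carries exactly the statistics a fresh evaluation
  would produce. Ties in the admission comparison admit.
* Log-rank: events precede censorings at tied times (both stay in the
  risk set at that time); χ² p-values use the 1-df chi-square survival
  function without continuity correction; zero observed events or zero
  variance yield a degenerate result with p = 1.
* Sample alignment orders the common samples lexicographically, making
  every seeded computation reproducible across platforms.
* Missing expression values drop the whole feature row at load (strict
  mode fails instead): per-pair varying sample subsets would silently
  change n mid-screen. Clinical rows with missing time or vital status
  are excluded at load with a logged count.

## Known limitations

* The χ²₁ tail of the log-rank statistic is slightly anti-conservative
  for very unbalanced groups at the extreme thresholds Bonferroni
  induces (≈ 1.5×10⁻⁴ at m ≈ 330): on pure-null cohorts the fraction of
  survival permutations with at least one Bonferroni survivor measures
  ≈ 0.12 rather than ≤ 0.05. The permutation FDR itself is unaffected
  (it calibrates against the same statistic) and the end-to-end
  false-discovery rate of the full cascade on null cohorts stays at the
  nominal level once the abundance filter is applied.
* The greedy outcome retains residual dependence on the seed triple:
  the coefficient of variation of |r₁| across triples is ≈ 0.03–0.06
  for strongly planted pairs (target r = −0.9, n = 200) and ≈ 0.08–0.10
  for pure noise. The contrast is systematic but the strong-pair spread
  is not always below 5% of the mean.
* Test-suite and acceptance problem sizes (20–50 replicates, cohorts of
  60–200 patients, pair universes of 16–400) are chosen to make the
  statistical assertions sharp while keeping a full run on one CPU in
  minutes; they are the package's reference benchmarks, not limits of
  the implementation.
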