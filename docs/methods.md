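# Methods

This note documents the models, conventions and parameter choices behind
`milkswap`, in the order data flows through the pipeline.

## Intake accounting

A one-day 24-h recall is a list of (child, food, amount) lines with the
amount on an as-consumed basis, in the food's own unit: grams for foods
tabulated per 100 g, millilitres for beverages tabulated per 100 mL.
Daily intake is the exact linear combination
`Σ_lines (amount / 100) × density_per_100`; no retention factors, recipe
decomposition or rounding are applied.  Composition entries can be
re-expressed between the two bases when a g/mL density is supplied, and a
helper converts a milk-powder profile plus a label dosing (g of powder per
100 mL of drink) into an as-consumed per-100-mL profile — young-child
milks are powders in practice, while the scenarios are stated in volume
terms.

### Milk-consumer classification

Groups are mutually exclusive and exhaustive: `non_milk` when no recall
line carries a milk type; otherwise the milk type contributing the most
energy among the child's milk lines, with exact ties broken by the fixed
order YCM > cow > condensed.  Surveys report exclusive groups but rarely
an assignment rule for multi-milk consumers; the dominant-energy rule is
deterministic, order-independent and reproducible.  Only explicitly
milk-typed lines count: condensed milk hidden inside mixed dishes is not
attributed to the condensed group.

## EAR cut-point inadequacy

Inadequacy prevalence is the fraction of children whose single-day intake
falls **strictly below** the EAR cut-point for their age band (12–35,
36–47, 48–60 months).  Strict inequality follows the "below reference
value" reading; boundary ties have probability zero for continuous
intakes.  When an analysis stratum pools two reference bands (the 3–4 y
modeling stratum spans 36–47 and 48–60 months), each child is judged
against their own band's cut-point and the pooled prevalence is reported —
the only reading consistent with one prevalence column against two
reference columns.  Vitamin C is tracked in the intake vector but ships
without a default cut-point, because no published value accompanies the
analysis this package models; supply one in the reference CSV to include
it.

The energy/protein adequacy rule used by the source survey programme is
not public; `fraction_of_requirement_status` exposes a configurable
fraction-of-requirement threshold (default 0.8) and is labelled an
approximation.

## Substitution scenarios

Each scenario replaces every line of the target milk type (condensed milk
by default) with an age-appropriate replacement profile, per eating
occasion — equivalent for daily totals under linearity, but preserving
line-level structure:

- **equal volume**: replacement amount (mL) = original amount (mL);
- **isocaloric**: replacement amount = original amount ×
  `E_target / E_replacement` (kcal per 100 mL), which conserves each
  child's total daily energy exactly (the conservation is algebraic, and
  asserted to 1e-9 relative in tests).

Children without target-milk lines pass through unchanged, and
substituting a profile by itself is the identity.  If the replacement is
at least as dense as the target in every micronutrient per mL, the
equal-volume swap cannot decrease any child's micronutrient intake, so no
inadequacy prevalence can rise — a monotonicity law the test suite checks
on a random cohort.

Summary statistics per arm are the mean, sample SD (n−1 denominator; a
single observation reports SD 0), and quartiles by linear interpolation
between order statistics (`numpy.percentile(..., method="linear")`).  The
interpolation rule is pinned because published tables rarely state one.
Relative reduction is `100 × (baseline − scenario) / baseline` of the
prevalence, reported unrounded and, where an integer percent is quoted,
rounded half-up.

## Statistical layer

- **Fisher's exact test** (prevalence comparisons, scenario-vs-baseline
  and group-vs-reference-group): two-sided by the probability-mass rule —
  the p-value sums hypergeometric probabilities, margins fixed, of every
  2×2 table no more probable than the observed one.  Computed in exact
  integer arithmetic (comparing weights `C(r1,k)·C(r2,c1−k)` as Python
  integers), so there is no floating-point tie ambiguity; the doubling
  convention would give different answers and is not used.
- **Wilcoxon signed-rank** (paired baseline/scenario intakes): zero
  differences dropped, midranks for tied |differences|.  For ≤ 25
  informative pairs the two-sided p is exact over all 2^m sign
  assignments, computed by subset-sum convolution over doubled midranks
  (identical distribution to explicit enumeration, at polynomial cost) as
  `min(1, 2·min(P(W⁺≤w), P(W⁺≥w)))`; above the switch point (configurable)
  a normal approximation with tie-corrected variance and no continuity
  correction is used.
- **Chi-square** (characteristics × milk-group tables): Pearson statistic
  without continuity correction, uniformly, since the tables are larger
  than 2×2.
- **Bonferroni**: adjusted p = min(1, m·p).  For the group comparisons the
  default family is the m = 2 comparator groups (condensed, cow) per
  nutrient per age stratum; the family size is configurable and surfaced
  in the output rather than hidden.

Both exact tests are verified against independent brute-force enumeration
oracles (all 2×2 tables with N ≤ 30; all sign assignments for n ≤ 12) and
cross-checked against scipy's implementations.

## Synthetic survey generator

The generator emulates the structure of the Indonesian Individual Food
Consumption Survey 2014: ~11,020 children aged 12–60 months with sex,
urban/rural region, SES and 7-level maternal-education covariates, four
age bands with published shares, and age-band-specific milk-group
probabilities (e.g. 57.7 % YCM at 36–47 months).  SES and education
marginals are derived from published group-conditional percentages
weighted by group sizes.  Covariates are drawn independently of the milk
group; the real survey shows association between them, so analyses of
covariate–milk confounding cannot be studied on this synthetic population
(none of the pipeline's computations require it).

A child's day is emitted as one background line per nutrient pseudo-food
plus at most one milk line.  Background amounts are independent
zero-inflated log-normals per nutrient and modeling stratum — the minimal
right-skewed shape able to reproduce published quantile rows in which the
25th percentile is zero while the median is positive (vitamin D).
Nutrient–nutrient correlations are not modeled; no correlation information
is published to calibrate them, and none of the pipeline's outputs depend
on cross-nutrient dependence.  Milk volumes are log-normal per milk type.
The defaults — condensed beverage median 150 mL/day, YCM and cow's milk
200 mL/day, log-sd 0.4 — are field-plausible choices; consumed volumes are
not published for this survey.

Randomness uses one root seed with per-child substreams
(`SeedSequence(seed, spawn_key=(child_index, phase))`), so enlarging the
population appends children without reshuffling earlier ones, and every
output is byte-deterministic in (config, seed).

### Calibration

`calibrate_to_baseline` matches the generator to published baseline rows
(prevalence % plus quartiles) for one consumer group and stratum:

1. zero-inflation mass π₀ from the printed zero quantiles (P25 = 0 with
   P50 > 0 → π₀ = 0.30, the midpoint of the feasible (0.25, 0.50)
   interval; P50 = 0 → 0.55);
2. log-sd from a least-squares fit of log printed quantiles against
   zero-inflation-adjusted normal scores;
3. background log-median by bisection so that the simulated prevalence —
   background plus the milk line's contribution — hits the target on a
   fixed calibration sample (n = 20,000, seeded from the config seed).

Prevalence is monotone decreasing in the log-median, so the bisection is
deterministic and convergent; targets outside the attainable range (e.g.
a prevalence the milk contribution alone rules out) raise a calibration
failure listing every unmet target.  The stated tolerance is ±3
percentage points on prevalence at a fresh n = 5,000 (Monte-Carlo SE
≈ 0.6 pp, so the band is ~5 SE) and ±50 % of a printed quantile's value;
the parameter-recovery test draws the fresh sample from substreams the
calibrator never used.  When a calibrated stratum spans multiple
reference bands the cut-point at the stratum midpoint is used; the
motivating calibration targets the single-band 12–35 month stratum.

What passing calibration shows — and what it does not: the generator
reproduces the *marginal* one-day intake distributions near the published
cut-points for the calibrated group.  It does not reproduce usual-intake
distributions, within-person variance, nutrient correlations, covariate–
intake association, or the uncalibrated groups' distributions (only
qualitative ordering is published for those), so downstream results on
synthetic data are structural demonstrations, not re-estimates of the
survey.

## Problem sizes

The test suite runs the substitution-law cohort at 1,200 children, the
parameter-recovery check at a fresh n = 5,000, and end-to-end determinism
at n = 800; the acceptance script uses n = 5,000.  These sizes put
Monte-Carlo error well inside the stated tolerances while keeping a full
run in seconds.

## Known limitations

- Single-day recall: prevalence estimates inherit the EAR cut-point
  method's bias when applied to one-day intakes; no deattenuation.
- The bundled composition profiles (condensed-milk beverage, YCM 1+/3+,
  cow's milk) are illustrative, not manufacturer data; scenario-side
  results shift with the profile supplied.
- No survey weights, household clustering, or confounder adjustment; the
  statistical layer reproduces unweighted tests.
- Bonferroni family sizes beyond the group-comparison default are the
  caller's responsibility.
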