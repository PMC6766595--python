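# Methods

## Model

A food's carbohydrate mass is modeled as a mixture of six classes —
glucose, fructose, sucrose, maltose (anhydrous), starch, cellulose
(dietary fiber is identified with cellulose) — each carrying two
uncertain quantities:

* a **composition** C_i, the class's share of the carbohydrate mass (%),
  known through a database's (mean, standard error, n) summary; and
* a **heat of combustion** HC_i (kcal/g), known through a representative
  value and an "overall interval" [HC_il, HC_ih] that merges bibliographic
  determinations with new bomb-calorimetry measurements.

The quantity of interest is the mixture heat 0.01·Σ C_i·HC_i, kcal per g
of carbohydrate. Uncertainty is propagated by interval arithmetic realized
as an exhaustive endpoint enumeration (below), not by distributional
assumptions on the joint law of (C, HC): the intervals are treated as hard
ranges, and the propagated object is again a hard range.

## Reference stage

**Contamination correction.** A measured sample heat hc_exp (kcal/g of
whole sample) is converted to kcal per g of carbohydrate by removing the
heat attributed to the lipid and protein masses the sample carries:

    HC = (hc_exp·M_T − 9.3·M_l − 5.8·M_p) / (M_T − M_l − M_p)

with 9.3 and 5.8 kcal/g the classical heats for vegetable-source lipids
and cereal proteins. The numerator is the total measured heat minus
contaminant heats; the denominator is the carbohydrate mass — the only
dimensionally consistent arrangement of these terms. The correction is
exact when M_l = M_p = 0 and undefined (degenerate-sample error) when the
contaminants exhaust the sample.

**Hydration conversion.** X g of anhydrous substance correspond to X + w g
of the hydrated crystal (w = 18 g of bound water per formula unit), so

    HC_anh = HC_hyd·(X + w)/X + HH,

HH being the hydration heat per g of anhydrous substance. Defaults for
maltose: X = 342.30 g/mol, w = 18.00 g, HH = 0.03 kcal/g; all overridable
through `HydrationSpec`. Applied to the monohydrate representative 3.76
and interval top 3.81 this yields 3.9877 → 3.99 and 4.0404 → 4.04, the
packaged anhydrous values. The packaged anhydrous lower endpoint is 3.93;
the same conversion applied to the monohydrate lower endpoint 3.71 gives
3.9353, which rounds to 3.94 — the packaged table keeps the tabulated
3.93, and the discrepancy (one unit in the second decimal, presumably a
rounding-order artifact in the source of the constant) is noted here
rather than silently recomputed.

**Outlier screens.** Whether a new measurement is consistent with the
bibliographic record is decided by appending it to the record and running
(a) the two-sided Grubbs test at α = 0.05 — G = max|x − x̄|/s against the
critical value ((n−1)/√n)·√(t²/(n−2+t²)), t the 1 − α/(2n) Student
quantile with n−2 df — and (b) Tukey boxplot fences Q1/Q3 ∓ 1.5·IQR
(linear-interpolation quartiles). The value is consistent iff neither
screen flags it; a screen abstains below its minimum n (3 for Grubbs, 4
for the boxplot), so a single reference value can never reject. α = 0.05
and whisker 1.5 are the conventional defaults; only one outlier is
considered per Grubbs pass.

**Aggregation** of surviving replicates is the arithmetic mean; no
source-weighting scheme is applied.

## Composition intervals

From a (mean C̄, standard error se, count n) summary the single-
determination standard deviation is recovered as s = se·√n and the true
composition receives the two-sided normal tolerance interval

    C̄ ± k(n, P, γ)·s,     P = coverage = 0.90, γ = confidence = 0.90,

computed with Howe's approximation k = z_{(1+P)/2}·√(ν(1+1/n)/χ²_{1−γ,ν}),
ν = n−1, which matches published two-sided tolerance tables to ~3 decimals
for n ≥ 5 (2.535 at n = 10) and tends to z_{0.95} = 1.6449 as n → ∞.
Intervals are clamped to the physical range [0, 100]. A missing se, se = 0,
or missing/singleton n collapses the interval to the mean — the rule for
database entries backed by a single determination. A tolerance interval
(not a confidence interval) is used because the object bounded is the
composition a future sample would exhibit, not merely its mean.

Compositions arrive per 100 g of food; since the propagated heat is per g
of *carbohydrate*, each food's means are rescaled by 100/Σmeans (ses by
the same factor) so they sum to 100. The six database nutrient names map
onto the reference classes via a configurable table (maltose → anhydrous
maltose, since databases report anhydrous sugar masses; fiber →
cellulose).

## Endpoint enumeration and the global interval

For the k carbohydrate classes present in a food (absent classes are
degenerate [0, 0] intervals and drop out), every choice of one endpoint
per composition interval (2^k sets) is combined with every choice of one
endpoint per heat interval (2^k sets), giving 2^(2k) — 4,096 at k = 6 —
candidate values 0.01·Σ C_chosen·HC_chosen. The **global interval** is
[min, max] of the candidates; **HCcf** is their mean; **HCcinf** =
0.01·Σ C̄_i·HC_i uses the representative heats. The enumeration is
implemented literally as a cartesian product; because all quantities are
non-negative the extremes also have closed forms (all-low / all-high sums)
and the mean factorizes over midpoints — these serve as independent
oracles in the test suite, certifying the equivalence rather than assuming
it. Candidate count, permutation invariance, and the equivalences are
property-tested.

Foods whose global-interval length exceeds 0.32 kcal/g are dropped before
the group stage (a length exactly at the limit is kept, with a 1e−9 float
guard); the cutoff reflects that longer intervals stem from unusually
noisy composition entries and are uninformative. Reported heats are
rounded to 2 decimals only at the serialization boundary (CSV reports);
JSON reports keep full precision.

## Group generalization

Viewing a group's n intervals as a measure — the measure of a Borel set is
Σ_i |interval_i ∩ set|, total mass Σ_i length_i — the cumulative function
F(x) = measure((−∞, x])/total is piecewise linear with knots at interval
endpoints. With tail = 0.025, q_low = F⁻¹(0.025) (smallest x reaching the
tail; on a plateau, its left edge) and q_high is the symmetric quantile
from above. The group expression is

    center = midpoint(q_low, q_high) rounded to 2 decimals,
    p      = 100·(q_high − q_low)/(2·center) rounded to the nearest integer,

quoted as "center ± p%". The exact band [q_low, q_high] excludes exactly
2.5% of the length per side by construction; rounding center and p can
shift the realized exclusions by a fraction of a percent, so both realized
tail fractions are re-measured and recorded on the summary (on the
packaged vegetable table the upper tail realizes 0.0268 rather than
< 0.025 — the cost of quoting an integer p). Nearest-integer rounding is
the concretization adopted because it reproduces all three tabulated
expressions (fruits 3.88 ± 4%, vegetables 3.98 ± 5%, cereals 4.13 ± 3%)
from the packaged tables; the construction is not unique and no uniqueness
is claimed. A 10^5-point grid discretization of F is the test oracle for
the quantiles.

**Atwater comparison.** Against a benchmark A = 4.2 kcal/g the
overestimation range is

    min = 100·(A − center·(1+p))/A,   max = 100·(A − center·(1−p))/A,

rounded to integers (min can be negative when the band top exceeds A, as
for cereals). The packaged tables give maxima of 11%, 10% and 5% for
fruits, vegetables and cereals.

**Generic containment.** `generic_containment` lists foods whose global
interval escapes HCcinf ± 4% (boundary inclusive) together with the
escape distance. Counts derived from 2-decimal tabulated HCcinf values are
sensitive to boundary cases shifted by that rounding, so containment
percentages are reported as descriptive output, not asserted constants.

## Synthetic data

`simulate_composition_table` draws, per food, a true composition from a
group-specific Dirichlet on the six-class simplex, scaled to 100%.
Concentration defaults (glucose, fructose, sucrose, maltose, starch,
cellulose):

| group     | α                          | implied mixture heat |
|-----------|----------------------------|----------------------|
| fruit     | 24, 28, 20, 1, 7, 10       | ≈ 3.87 kcal/g        |
| vegetable | 18, 16, 12, 1, 18, 25      | ≈ 3.97 kcal/g        |
| cereal    | 2, 1, 2, 2, 75, 8          | ≈ 4.14 kcal/g        |

chosen so fruit profiles are free-sugar-heavy and cereal profiles
starch-dominated, qualitatively matching published food tables. Each entry
gets n ~ Uniform{3..12} determinations; the emitted se is s/√n with
s = mean·se_scale — exactly the structure the tolerance interval inverts —
and the observed mean is the truth plus N(0, s/√n) sampling noise, clipped
to [0, 100]. With probability missing_se_prob (default 0.10) an entry
loses its se and n, exercising the degenerate-interval rule. The default
se_scale = 0.005 follows from the retained foods' interval lengths: the
composition contribution to a global-interval length is ≈ 24·se_scale
kcal/g, and lengths of 0.2–0.32 kcal/g (of which ~0.15 comes from the heat
intervals) imply se_scale ≲ 0.007. The true mixture heat
0.01·Σ trueC_i·HC_i (representative heats) is emitted per food.

All randomness flows through one `numpy.random.default_rng(seed)`; no
global state. `simulate_measurements` inverts the contamination correction
to place raw replicate draws so that correcting them recovers a stated
true heat — a round-trip identity at sd = 0 and a CLT-bounded mean
otherwise.

What the generator does *not* emulate: inter-laboratory effects,
correlated errors across carbohydrates within a food, non-normal
composition noise, and carbohydrates outside the six classes. Passing
recovery tests therefore certify the pipeline's arithmetic and its
statistical plumbing, not the field accuracy of any database.

For recovery tests the heat intervals can be collapsed to their
representative values (`point_reference_table`), isolating composition
uncertainty: with se_scale = 0 every global interval then has zero width
at the true mixture heat. Group-level recovery (30 noiseless fruits, full
heat intervals) reproduces the analytic profile heat to within 0.03
kcal/g.

## Numerical choices and degenerate inputs

* Quantile inversion interpolates linearly within the crossing segment of
  the piecewise-linear cumulative; plateaus (gaps between intervals)
  resolve to the edge dictated by the smallest/largest-x definition.
* Zero total interval length (all intervals degenerate) is an error for
  the group stage; the pipeline skips such a group with a warning.
* A food whose compositions are all zero is skipped with a warning
  (no carbohydrate mass to characterize).
* The carb-basis rescale guards against float overshoot past 100%.
* Grubbs returns no outlier for zero-variance data; the boxplot flags
  nothing when IQR = 0 and all values coincide.
* Interval-length comparisons at the 0.32 cutoff carry a 1e−9 guard so
  values that are 0.32 at printed precision are kept.

## Problem sizes

The packaged per-food table (68 foods) and all desk-scale constants drive
the deterministic results; synthetic runs in the test suite use 4–40 foods
per group and up to 10^4 measurement replicates, sizes at which every
stage completes in seconds while leaving the statistical assertions
well-powered.

## Known limitations

* Per-food global intervals for the packaged 68 foods cannot be recomputed
  here: the underlying composition (mean, se, n) triples are not public.
  The packaged table is a transcription, used as the input to the group
  stage and as a structural fixture (length-limit count, HCcf−HCcinf
  agreement).
* The "center ± p%" construction is one concretization of the
  tail-exclusion rule; other (center, p) pairs satisfy the same
  constraint.
* The reference table is versioned data, not a fit; updating it requires
  re-running the reference-stage screens against a new measurement set.
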