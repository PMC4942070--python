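# Methods

## Trial model

An A+B design is specified by five integers {A, B, C, D, E} and a
de-escalation flag, applied to J ordered dose levels with true DLT
probabilities p₁ … p_J.  Each patient's outcome is an independent
Bernoulli(p at their dose); cohort DLT counts are therefore binomial.
The decision rules are:

1. Treat A patients at the current dose; observe x DLTs.
   - x ≤ C−1: escalate one level.
   - C ≤ x ≤ D: treat B more patients; observe the total y out of A+B.
     Escalate when y ≤ E, otherwise halt / de-escalate.
   - x > D: halt / de-escalate.
2. Escalation never skips levels and no dose receives more than A+B
   patients.
3. Without de-escalation, a halt at dose j declares dose j−1 the MTD
   (no MTD when j = 1).  With de-escalation, the trial walks down from
   dose j−1: a dose already holding A+B patients is declared the MTD when
   its DLT total is at most E; a dose holding only A patients is expanded
   with a fresh cohort of B and declared the MTD on the same condition;
   otherwise the walk continues, and running past dose 1 declares no MTD.
   De-escalation cohorts count toward the sample size, DLT totals and
   experimentation, and the walk never re-escalates.
4. Escalating past the top dose ends the trial with the distinct outcome
   "all doses tolerated".

Since every cohort outcome takes finitely many values, the set of
possible trials ("pathways") is finite.  `enumerate_pathways` walks the
decision tree depth-first, branching over every binomial outcome with no
pruning; a pathway's probability is the product of its cohorts' binomial
pmf terms, and the pathway probabilities sum to one (asserted to 1e-12 in
the tests).  All arithmetic is in double precision; at these cohort sizes
and depths the smallest pathway probabilities are far above underflow and
log-space accumulation is unnecessary.

## Operating characteristics

All scenario-dependent quantities are exact expectations over the pathway
distribution:

- Sample-size distribution: pathway probability aggregated by total N.
- Experimentation percentage at dose j: 100·E[nⱼ/N], the expected
  within-trial share of patients at dose j.  The alternative E[nⱼ]/E[N]
  (ratio of expectations) is a different, biased quantity that
  over-weights long trials; the test suite asserts the two disagree on
  the reference scenarios so the distinction cannot silently collapse.
- MTD recommendation: pathway probability aggregated by terminal outcome,
  with "no MTD (too toxic)" and "all doses tolerated" as separate
  categories by default.  Because the reference results treat a trial
  that escalates past the top dose as having declared the top dose its
  MTD, `mtd_distribution` offers `all_tolerated="top_dose"` (and
  `"no_mtd"`) folding conventions.
- ETL: E[p at the declared MTD | an MTD is declared], with all-tolerated
  trials declaring the top dose (this conditioning is what reproduces the
  published example values); undefined, and reported as such, when no
  pathway declares an MTD.
- EOTR: E[total DLTs / N]; mean DLTs: E[total DLTs]; DLT-rate
  distribution: pathway probability aggregated by the exact rational
  rate DLTs/N (kept as `fractions.Fraction` so 1/6 and 2/12 pool).
- Interval summaries: per-dose experimentation and recommendation
  percentages summed over true-probability bins [0,0.2], (0.2,0.4],
  (0.4,0.6], (0.6,0.8], (0.8,1]; a boundary value belongs to the lower
  bin.

Zero-probability atoms that arise from degenerate scenarios (some p
exactly 0 or 1) are dropped from the distribution supports.

## Design characteristics

The data observable at a declared MTD are limited: without de-escalation
either x ≤ C−1 DLTs out of A patients or a stage-2 total y ≤ E out of
A+B (y reachable from some stage-1 count in C..D); with de-escalation
always y ≤ E out of A+B.  For each such state the package reports the
exact Clopper-Pearson interval (beta quantiles: lower
= B⁻¹(α/2; x, n−x+1), upper = B⁻¹(1−α/2; x+1, n−x), with the degenerate
endpoints exactly 0 and 1) and, as a second method, the Wilson score
interval.  Wilson was chosen as the companion interval because it is the
standard asymptotic counterpart with good small-sample behaviour; it is
labelled in every output so users can ignore it.

The escalation probability of a dose with true DLT probability p is

    e(p) = Σ_{x≤C−1} Bin(x; A, p) + Σ_{x=C..D} Bin(x; A, p) · Σ_{y≤E−x} Bin(y; B, p)

and the tipping point is the root of e(p) = 1/2 on (0,1), found with
Brent's method at tolerance 1e-8 and reported to 3 decimals.  e is
continuous and non-increasing with e(0) = 1; when D = A and E = A+B it is
identically 1, no root exists, and the tipping point is reported as
undefined rather than an arbitrary value.

## Monte-Carlo cross-check

`abdesign.simulate` samples whole trials by drawing each cohort's DLT
count from the binomial at the current dose and applying the *same*
decision functions as the exact engine (`stage1_decision`,
`stage2_decision`, `determine_mtd`).  `estimate_ocs` returns empirical
analogues of every exact quantity with standard errors (sample SEs of
per-trial proportions and means; binomial SEs for outcome frequencies).
Randomness flows through a single explicitly passed
`numpy.random.Generator`; no global state is touched, so a fixed seed
reproduces trials exactly.

The simulator emulates precisely the idealised trial model above:
independent binary DLT outcomes, fixed true probabilities, no
intra-cohort correlation, no patient dropout, ragged cohorts or deviation
from protocol.  Agreement between simulator and enumerator therefore
validates the combinatorics and probability arithmetic, not the model's
fit to any real trial.  Cross-check tests compare every exact quantity
with its empirical estimate at a 4-standard-error tolerance, using
100,000 simulations for the reference scenario and 8,000 for randomized
design/scenario sweeps — sizes at which the suite still runs in seconds
while each z-statistic is estimated from thousands of effective samples.

## Tipping-point properties

Two structural claims are property-tested over randomized designs and
monotone scenarios: without de-escalation, whenever a dose is the single
most likely terminal outcome (more likely than either no-MTD category and
every other dose), its true DLT probability is at most the tipping point;
with de-escalation, the probability of selecting any dose with true DLT
probability above the tipping point is at most 50%.  The first claim must
be read against the full outcome distribution: the most likely *selected*
dose alone can sit above the tipping point in scenarios where most trials
end with no MTD at all (e.g. {3,3,2,2,0} with p = {0.72, 0.89}).

## Numerical and interface choices

- Rounding for display and for comparison against published tables is
  half-away-from-zero (`round_half_away`), 1 dp for percentages, 3 dp for
  probabilities and the tipping point.
- Validation rejects structural violations (C > D, D > A, E > A+B,
  non-positive cohorts, probabilities outside [0,1]) but only warns on
  legal oddities: E < C (expansion can never escalate) and non-monotone
  dose-toxicity curves.
- The CLI writes pathway tables (CSV/JSON), scenario and design OC tables,
  four bar charts (sample size, experimentation, recommendation, DLT
  rate) and a Markdown report whose numbers equal the exported CSVs under
  the same rounding; an HTML option wraps the same content.  PDF output
  and any GUI are out of scope.

## Limitations

- Only the {A, B, C, D, E} + de-escalation rule family is covered: no
  dose skipping, accelerated titration, or model-based designs.
- Confidence intervals are the usual fixed-sample intervals and are not
  adjusted for the sequential stopping rule.
- Enumeration cost grows quickly with cohort sizes, dose count and
  de-escalation; the reference scenarios enumerate in well under a second
  (91–2,314 pathways), and 6+6 designs over ten doses remain feasible but
  take noticeably longer.
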