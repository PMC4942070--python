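# abdesign

Exact operating characteristics for **A+B phase I dose-escalation
designs** (including the ubiquitous 3+3 design), computed by exhaustive
enumeration of every possible trial pathway.

## The problem

Phase I oncology trials usually find the maximum tolerated dose (MTD) of
a new drug with a rule-based A+B design: a cohort of *A* patients
receives a dose; if fewer than *C* of them have a dose-limiting toxicity
(DLT) the next cohort gets the next-higher dose, if between *C* and *D*
do, the dose is expanded with *B* more patients (escalating only when the
total DLT count is at most *E*), and otherwise the trial stops — or, when
de-escalation is permitted, steps back down through the lower doses.  The
classical 3+3 design is {A,B,C,D,E} = {3,3,1,1,1} without de-escalation.

Because every cohort outcome is a binomial draw, an A+B trial has only
finitely many possible realisations.  `abdesign` enumerates all of them
with their exact probabilities and derives, without any simulation error:

- the full sample-size distribution and its mean,
- per-dose **experimentation** percentages, defined exactly as
  100·E[nⱼ/N] over the pathway distribution (not the ratio-of-means
  approximation used by older programs),
- per-dose **MTD recommendation** percentages plus the probabilities of
  stopping with no MTD or tolerating every dose,
- the **expected toxicity level** (ETL, the true DLT probability at the
  dose declared MTD), the **expected overall toxicity rate**
  (EOTR = E[DLTs/N]), the mean DLT count, and the exact distribution of
  observed DLT rates,
- scenario-independent design properties: the terminal data states
  possible at the MTD with exact (Clopper-Pearson) and Wilson confidence
  intervals, and the design's **tipping point** — the true DLT
  probability at which escalating and not escalating are equally likely.

A seeded Monte-Carlo simulator (`abdesign.simulate`) provides an
independent cross-check of the exact engine.

## Worked example

The 3+3 design over four doses with true DLT probabilities
0.05, 0.10, 0.33, 0.60:

```python
from abdesign import (validate_design, ToxScenario, enumerate_pathways,
                      compute_scenario_ocs, tipping_point, clopper_pearson_ci)

design = validate_design(3, 3, 1, 1, 1, allow_deescalation=False)
scenario = ToxScenario([0.05, 0.10, 0.33, 0.60])
ps = enumerate_pathways(design, scenario)
ocs = compute_scenario_ocs(ps)

print(f"{len(ps)} distinct trial pathways")
for d in ocs.per_dose:
    print(f"dose {d.dose}: experimentation {d.experimentation_pct:5.1f}%   "
          f"recommended as MTD {d.recommendation_pct:5.1f}%")
print(f"P(no MTD, too toxic) = {ocs.prob_no_mtd_safety:.3f}")
print(f"ETL = {ocs.etl:.3f}   EOTR = {ocs.eotr:.3f}   E[N] = {ocs.expected_sample_size:.2f}")
print(f"tipping point = {tipping_point(design).value:.3f}")
ci = clopper_pearson_ci(1, 6, 0.95)
print(f"95% CI for 1 DLT / 6 patients at the MTD: ({ci.lower:.4f}, {ci.upper:.4f})")
```

prints

```
91 distinct trial pathways
dose 1: experimentation  29.8%   recommended as MTD   9.1%
dose 2: experimentation  30.3%   recommended as MTD  49.9%
dose 3: experimentation  29.9%   recommended as MTD  35.2%
dose 4: experimentation  10.0%   recommended as MTD   0.0%
P(no MTD, too toxic) = 0.027
ETL = 0.195   EOTR = 0.224   E[N] = 12.34
tipping point = 0.297
95% CI for 1 DLT / 6 patients at the MTD: (0.0042, 0.6412)
```

Half the trials recommend dose 2 (true toxicity only 10%), about 3% stop
with no MTD at all, 22% of patients experience a DLT on average, and the
dose declared MTD has an expected true DLT probability of 19% — well
below the 33% often assumed for the 3+3.  The tipping point of 0.297
shows why: a dose whose true toxicity exceeds 29.7% is more likely to be
stopped at than escalated from.

The same evaluation from the shell, with plots, CSV/JSON tables and a
Markdown report:

```sh
abdesign --A 3 --B 3 --C 1 --D 1 --E 1 --no-deescalate \
    --dose-probs 0.05,0.10,0.33,0.60 --out results/example1 \
    --mc-check 100000 --seed 1
```

`--mc-check` additionally prints an exact-vs-simulated comparison table
with standard errors.

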