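# nodestrat

Relative-survival stratification of lymph-node-positive (LN+) prostate
cancer cohorts by **percent nodal involvement** (%LN+ — the ratio of
pathologically positive lymph nodes to lymph nodes examined at surgery),
with **inverse Gompertz** curve fitting and **inflection-point** analysis.

## The problem

About one in ten newly diagnosed prostate cancers is node-positive at
radical prostatectomy, and this cadre is prognostically heterogeneous:
patients with few involved nodes relative to the number sampled do far
better than those with extensive involvement. Registry data (SEER-style
extracts) record all-cause follow-up only, so disease-specific prognosis is
estimated through **relative survival**: observed Kaplan–Meier survival
divided by the expected survival of a demographically matched general
population (Ederer II method against sex/race/age/calendar-year life
tables).

A cohort's relative-survival curve RS(t) is summarized by inverse
Gompertzian kinetics

```
RS(t) = 1 − b1·exp(−b2·exp(−b3·t)),        dRS/dt = −b1·b2·b3·exp(−b2·e^(−b3·t))·e^(−b3·t)
```

with t in years. The curve declines slowly at first and then drops
exponentially; the **inflection point** (IP) — the time at which dRS/dt is
most negative, in closed form `ln(b2)/b3` — marks the transition beyond
which reproducible cure under the era's treatments is unlikely. Stratifying
a LN+ cohort by %LN+ (<10%, 10–40%, ≥40%) yields well-separated
relative-survival curves whose IPs fall steeply with increasing nodal
involvement (roughly 27 → 10 → 7 years in the published SEER analysis).

This package implements the full pipeline as a tested library and CLI:

- `life_tables` — life-table container/CSV I/O and Ederer II expected survival;
- `survival` — monthly-grid Kaplan–Meier with Greenwood SEs, relative
  survival with the registry correction rules (cap at 100%, then monotone
  carry-back), Z-tests at fixed months, log-rank tests;
- `gompertz` — model evaluation, derivative, numeric IP search, and a
  two-stage (differential evolution + Nelder–Mead) least-squares fitter,
  exposed as a scikit-learn-style estimator `InverseGompertzRS`;
- `stratify` — %LN+ computation, subcohort filters, the IP-vs-cutoff scan,
  three-group %LN+ stratification and positive-node-count stratification;
- `simulate` — seeded synthetic registry cohorts whose per-stratum relative
  survival follows a known inverse Gompertz law against a supplied life
  table (real SEER extracts cannot be redistributed);
- `pipeline` / `cli` — end-to-end orchestration with deterministic,
  seed-stamped report bundles.

## Worked example

```python
import nodestrat as ns

table = ns.synthetic_life_table()                      # male general-population mortality
spec = ns.default_cohort_spec(n_per_stratum=2000, seed=0)  # true IPs 25 / 10 / 7 years
cohort = ns.generate_cohort(spec, table)               # 6000 subjects
res = ns.stratify_groups(cohort, table, seed=0, max_months=312)
print(res.summary_frame().to_string(index=False))
```

prints

```
 group    n       b1       b2       b3  ip_years  r_squared  converged
  <10% 2000 1.342310 9.523009 0.082060 27.464025   0.995005       True
10-40% 2000 0.281346 6.714440 0.211920  8.985766   0.997582       True
 >=40% 2000 0.461794 4.273659 0.211613  6.863807   0.998944       True
```

Each row is one %LN+ group: its fitted inverse Gompertz parameters, the
inflection point in years after surgery, and the goodness of fit of the
model to the estimated relative-survival curve. The recovered IPs (27.5,
9.0, 6.9 y) bracket the simulation truth (25, 10, 7 y) and are strictly
ordered — more nodal involvement, earlier loss of curability. Pairwise
Z-tests at 10 years separate all three groups (e.g. <10% vs ≥40%:
z = 13.9, p ≈ 9e-44).

The same analysis from a shell:

```bash
nodestrat simulate --out cohort.csv --lifetable-out lt.csv --seed 0
nodestrat run --cohort cohort.csv --lifetable lt.csv --out results/ --seed 0
```

## Published parameter sets

`nodestrat.PUBLISHED_FITS` carries the reference (b1, b2, b3) estimates for
the SEER LN+ radical-prostatectomy cohort, whole cohort and the
white/grade III/no-radiotherapy subcohort, one per %LN+ stratum. Evaluating
`inflection_point(b2, b3)` on them reproduces the published IPs, and
`inverse_gompertz_rs(10, ...)` on the whole-cohort ≥40% set reproduces the
published 71% 10-year relative survival.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the package's own numerics, the six stratum inflection
points (numeric minimization of the model derivative on the published
parameter sets, rounded as printed) and the 10-year relative-survival
percentage of the ≥40% group, and writes them as JSON keyed by target id.

## Documentation

See `docs/methods.md` for the statistical methods, the synthetic-data
model, numerical choices, and known limitations (in particular the
identifiability of late inflection points near the follow-up horizon).
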