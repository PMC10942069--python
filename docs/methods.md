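# Methods

## Decision problem and model structure

`trastcea` evaluates one-year adjuvant trastuzumab added to chemotherapy
(paclitaxel) against chemotherapy alone for women with HER2-positive
early-stage breast cancer in Vietnam, from a societal perspective with costs
in 2020 VND. The engine is a discrete-time Markov cohort model with six
mutually exclusive health states:

| index | state | meaning |
|---|---|---|
| 0 | `DFS` | disease-free after primary treatment |
| 1 | `DFS_CHF` | disease-free with trastuzumab-induced congestive heart failure |
| 2 | `LRR` | local-regional recurrence |
| 3 | `DFS_POST_LRR` | disease-free after a local-regional recurrence |
| 4 | `MET` | metastatic disease |
| 5 | `DEAD` | absorbing |

The cohort enters entirely in `DFS` at age 50 and is advanced in annual
cycles to age 100. Structural assumptions:

* the trastuzumab treatment effect lasts five cycles: during cycles 0–4 of
  the trastuzumab arm the annual local-regional recurrence and metastasis
  probabilities are hazard-ratio adjusted, `p' = 1 − (1 − p)^HR` (a linear
  `p·HR` variant is available behind `settings.hr_transform` for sensitivity
  work);
* cardiotoxicity (CHF) can occur only in the first cycle, with arm-specific
  probabilities (0.198 trastuzumab, 0.007 chemotherapy); CHF carries no
  excess mortality, but trastuzumab is discontinued afterwards, so patients
  in `DFS_CHF` face the untreated recurrence probabilities in both arms;
* no new recurrences arise from the disease-free states (`DFS`, `DFS_CHF`)
  from cycle 20 onward; patients already in `LRR`/`DFS_POST_LRR`/`MET` keep
  progressing, and the elevated metastasis hazard after recurrence (×3.64,
  applied through the same rate-based transform) applies in both the `LRR`
  and `DFS_POST_LRR` states;
* breast-cancer death occurs only from `MET` (annual probability 0.295);
  background mortality from the life table applies in every alive state.

Within a cycle, background death `q` is applied first and all disease-event
probabilities are scaled by `(1 − q)`; from `MET` the two causes compete
independently, `P(death) = 1 − (1 − 0.295)(1 − q)`. This keeps every row of
every transition matrix stochastic by construction; the engine additionally
asserts row sums to 1e-12 and raises a negative-remainder error (naming the
state and cycle) if a perturbed parameter set pushes a row's event
probabilities above one.

## Rewards, discounting, numerical conventions

Life years, utility-weighted life years (utilities per state, death = 0) and
annual state costs accrue on **start-of-cycle** occupancy and are discounted
by `(1 + r)^(−t)` at `r = 3%`/year for both costs and effects. One-off
first-year therapy costs enter undiscounted at cycle 0: the full one-year
trastuzumab therapy package (drug aggregate + HER2 detection + other direct
medical + direct non-medical) plus paclitaxel in the combination arm, and the
paclitaxel treatment cost in the chemotherapy arm. Because the drug-only
paclitaxel cost used in the combination arm is not published, the default
configuration counts the full paclitaxel treatment cost in both arms so that
it cancels exactly in the increment; `costs.paclitaxel_drug_only` overrides
this. A half-cycle-correction flag (average of start- and end-of-cycle
occupancy) exists but is off by default, matching a conventional annual-cycle
spreadsheet model. Simulation stops at the horizon age or when the alive
fraction falls below 1e-12; the life table returns `qx = 1` beyond its last
row, which bounds every run.

The same matrix-construction and accumulation code serves scalar runs and
the probabilistic analysis (parameters as arrays of draws, matrices of shape
`(n, 6, 6)`), so there is a single source of truth for the dynamics. An
individual-level microsimulation (`markov.microsim`) re-implements the
trajectory sampling independently and is used as an oracle: at n = 200,000
individuals the cohort engine and the microsimulation agree within three
Monte-Carlo standard errors on both arms. VND amounts are carried as exact
integers through reporting; internal model arithmetic is floating point.

## Parameters and uncertainty

All inputs live in an INI configuration (`[clinical]`, `[utilities]`,
`[costs]`, `[settings]`, `[psa]`); the bundled base case carries the
published values (hazard ratios 0.76/0.58/0.48; baseline annual recurrence
0.0294 and metastasis 0.0785; utilities 0.832/0.828/0.789/0.670/0.762;
aggregate 2020 VND costs; exchange rate 22,745 VND/US$; willingness-to-pay
thresholds 83M and 249M VND per QALY, i.e. 1× and 3× GDP per capita).

For probabilistic sensitivity analysis each parameter receives a
distribution by role — beta for probabilities and utilities, lognormal for
hazard ratios and the post-recurrence multiplier, gamma for costs — fitted by
the method of moments with `SD = (hi − lo)/3.92`, i.e. the supplied range is
read as a 95% interval. Absent a published CI (none are reprinted in the
source tables) the range defaults to ±10% of the base value; explicit CIs can
be supplied as `name_ci = lo, hi` in `[psa]`. Draws are mutually independent
across parameters (no joint correlation structure is published). Vial prices
and the sharing aggregate are not sampled: in the default `printed` costing
mode the drug-cost aggregate itself carries the price uncertainty, and
sampling both would double-count. 10,000 iterations are the default
(seconds on one CPU with the vectorised engine). The ±10%-as-95%-interval
reading and the independence assumption are design choices; both are easy to
tighten in the config when better evidence exists.

## Drug costing and the vial calculator

Trastuzumab dosing is weight-based (8 mg/kg loading, 6 mg/kg maintenance,
every 3 weeks for 52 weeks → 18 administrations at the default schedule; the
count is derived by enumerating weeks 0, 3, …, < 52, and is configurable).
Two costing conventions:

* **no sharing** — each administration opens the cheapest integer
  combination of 150/440 mg vials covering the dose (exhaustive search);
  at 52.9 kg this is one 440 mg vial per dose → 18 × 45,596,775 =
  820,741,950 VND/year;
* **sharing** — concurrent patients pool vials, so the cohort pays the exact
  annual milligrams (5,819 mg at 52.9 kg) at the best price per mg.

The published one-year drug aggregates (787,384,650 VND base case;
570,022,437 VND shared) are **not** derivable from the printed vial prices,
weight and schedule — they came from an unpublished micro-costing with
weight distributions and copayment structure. The model therefore uses the
printed aggregates as direct inputs (`drug_cost_mode = "printed"`, the
default), and the vial calculator is shipped as an independent tool and an
alternative `"computed"` mode. Note also that the published "total cost of
one-year adjuvant trastuzumab therapy" (820,835,918 VND) is the component
sum *excluding* paclitaxel (the exact sum is 820,835,916; the 2 VND
difference is print rounding), and reports here follow that convention.

## Analyses

* **ICER** — incremental cost per LY and per QALY, trastuzumab vs
  chemotherapy, with dominance classification; invariant to cohort scaling.
* **CEAC** — at each willingness-to-pay λ (grid 0–1,000M VND/QALY in 5M
  steps), the fraction of PSA draws with positive incremental net monetary
  benefit `λ·ΔQALY − Δcost`; ties go to the comparator; arm probabilities
  sum to one.
* **EVPI** — per person `E[max(0, iNMB)] − max(0, E[iNMB])`, non-negative by
  construction; the population value scales by one annual treatment cohort
  (5,052 women, the published eligible-population estimate) with no
  multi-cohort decision-lifetime discounting, since no such convention is
  published.
* **Tornado** — one-way analysis setting each parameter to its range ends
  (published CI when configured, else ±10%), recomputing the deterministic
  ICER per QALY, sorted by span. Vial-price entries pass the relative price
  change through to the drug aggregate (full pass-through). Parameter values
  that break the model are flagged, not fatal.
* **Threshold price** — bisection on a common multiplicative factor applied
  to both vial prices (preserving the current 440:150 price ratio; the
  published threshold prices imply an exact 3:1 ratio that contradicts the
  current 2.93:1 and is not explained, so the common-factor convention is
  used) and hence to the drug aggregate, until the ICER meets λ within
  0.01%. Δcost is exactly linear in the factor and ΔQALY constant, so the
  search is verified against the closed form `s* = (λe − a)/b` to 1e-6
  relative.
* **Scenario** — named parameter overrides (e.g. the vial-sharing drug
  aggregate) re-run the deterministic case, PSA and threshold analysis and
  emit a comparative report.

## Synthetic life table — what it does and does not show

The published background mortality comes from the WHO 2020 life table for
Vietnamese women, which is not redistributable. The bundled
`vietnam_2020_approx` table is generated from a Gompertz–Makeham law
`q(x) = 1 − exp(−(a + c·e^{bx}))` with `a = 0.0012`, `b = 0.11`,
`c = 9·10⁻⁶`, chosen on demographic grounds to approximate Vietnamese
female mortality around 2020 (q50 ≈ 0.0034, q70 ≈ 0.021, modal age at death
≈ 85); the final age (100) is forced to `qx = 1`. It reproduces the *shape*
of adult female mortality but not the WHO table's exact values, child
mortality, or cohort effects — so tests passing on it validate the engine
and the analysis machinery, not the original study's exact numbers.

## Known limitations and reproducibility of the published figures

With the approximate life table and the published Table-1 parameters the
deterministic ICER computed here is ≈ 1,103M VND/QALY, above the published
≈ 520M. The discrepancy is structural, not numerical: the trastuzumab arm's
discounted per-person LY here (11.38) matches the published cohort-implied
value (57,530/5,052 = 11.39) almost exactly, but the chemotherapy arm
survives longer here (10.25 vs 8.30). The original analysis states its
transition probabilities were developed separately for year 1, years 2–5 and
year 6 onward, but only single constant baselines are printed; holding the
baseline recurrence and metastasis probabilities constant for 20 years (as
implemented here) lets the two arms' cumulative metastasis risks nearly
equalise, shrinking the increment (ΔLY 1.13 vs the published 3.09).
Consequently the threshold vial-price reductions on the bundled inputs
(≈ 79% at the 3× GDP threshold) are larger than the published 54–56%. The
qualitative conclusions are unchanged and reproduced exactly: every PSA draw
falls in the upper-right quadrant, the probability of cost-effectiveness is
0% at both national thresholds, and the therapy is far from cost-effective
at its current price.

Other known gaps, inherited from the sources: the published eligible-
population product gives 5,048 vs the printed cohort of 5,052 (the exact
incidence figure used is unstated; the config carries 5,052); the published
incremental QALY (1.61) is arithmetically inconsistent with the printed
incremental cost and ICER (which imply ≈ 1.71); and several printed totals
carry ±1–2 unit rounding residues, which the tests document rather than
hide.
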