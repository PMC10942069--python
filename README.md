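# trastcea

A Markov cohort cost-effectiveness model of **one-year adjuvant trastuzumab
plus chemotherapy versus chemotherapy alone** for women with HER2-positive
early-stage breast cancer in Vietnam (societal perspective, 2020 VND). It is
aimed at health-economics analysts who want a tested, scriptable
re-implementation of this decision problem: a deterministic base case,
probabilistic sensitivity analysis (PSA), cost-effectiveness acceptability
curves (CEAC), expected value of perfect information (EVPI), one-way tornado
analysis, threshold drug-price search, and a vial-sharing scenario, all
runnable offline from a bundled parameter configuration and a synthetic life
table.

## The model

Six health states — disease-free (DFS), DFS with congestive heart failure,
local-regional recurrence (LRR), DFS after LRR, metastatic (MET), dead — are
advanced in annual cycles from age 50 to 100. Annual transition
probabilities `p` are hazard-ratio adjusted in the trastuzumab arm during the
five-year benefit window via the survival identity

    p' = 1 − (1 − p)^HR,

cardiotoxicity occurs only in the first cycle, cancer death only from MET,
and background mortality `q(age)` from a life table applies everywhere, with
disease events scaled by `(1 − q)` so rows stay stochastic. Discounted
(3 %/yr) costs, life years (LY) and quality-adjusted life years (QALY)
accrue on start-of-cycle occupancy, and the comparison is summarised by the
incremental cost-effectiveness ratio

    ICER = Δcost / ΔQALY   (and per LY),

judged against willingness-to-pay thresholds of 83M and 249M VND/QALY (1×
and 3× 2020 GDP per capita). PSA assigns beta distributions to
probabilities and utilities, lognormal to hazard ratios and gamma to costs
(method-of-moments, ranges read as 95 % intervals, ±10 % defaults), and
summarises draws as CEAC probabilities `P(λ·ΔQALY − Δcost > 0)` and EVPI
`E[max(0, iNMB)] − max(0, E[iNMB])`. See `docs/methods.md` for every
assumption, numerical convention and known limitation — in particular, the
bundled life table is a labelled Gompertz–Makeham **approximation** of the
WHO 2020 Vietnamese female table, so headline numbers differ from the
original study's (the methods note quantifies how and why).

## Worked example

```bash
trastcea run --out out/
cat out/icer.tsv
```

prints (with the bundled base case and approximate life table):

```
d_cost_vnd   d_cost_usd  d_ly     d_qaly    icer_per_ly_vnd  icer_per_ly_usd  icer_per_qaly_vnd  icer_per_qaly_usd  dominance  ...
806062701    35439       1.13081  0.730963  712816412        31339            1102741081         48483              trade-off
```

Adding trastuzumab costs an extra 806M VND (35,439 US$) per patient over a
lifetime and yields 1.13 extra LYs and 0.73 extra QALYs, i.e. about 1,103M
VND (48,483 US$) per QALY gained — a trade-off far above both national
willingness-to-pay thresholds, so the therapy is not cost-effective at the
current drug price. The same conclusion holds probabilistically:

```bash
trastcea psa --iterations 10000 --out out/   # psa_draws.tsv, ceac.tsv
```

puts 100 % of the 10,000 draws in the upper-right quadrant (costlier, more
effective) with a 0 % probability of cost-effectiveness at both thresholds.
Other subcommands: `tornado`, `threshold` (cost-effective vial prices),
`scenario --sharing` (vial-sharing), `evpi`, `drugcost` (the weight-based
vial-packing calculator) and `simulate-data` (synthetic life tables and
jittered configs). Every run writes a `manifest.json` capturing config,
seed and version; identical invocations are byte-identical.

The same machinery is available as a library:

```python
from trastcea import load_config, basecase_config_path, reference_lifetable_path
from trastcea.markov import LifeTable
from trastcea.analysis import run_deterministic, threshold_price

params = load_config(basecase_config_path())
lt = LifeTable.from_tsv(reference_lifetable_path())
trast, chemo, res = run_deterministic(params, lt)
print(round(res.icer_per_qaly_vnd))        # 1102741081
print(threshold_price(249e6, params, lt))  # vial prices meeting 3x GDP per capita
```

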