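"""Cost-effectiveness analysis: ICER, NMB, PSA, CEAC, EVPI, tornado, thresholds.

The decision compares one-year adjuvant trastuzumab plus chemotherapy
("trastuzumab" arm) against chemotherapy alone ("chemo" arm).  Incremental
quantities are trastuzumab minus chemo.  Willingness-to-pay thresholds follow
the 1x and 3x GDP-per-capita convention (83 and 249 million VND per QALY).

The probabilistic sensitivity analysis re-runs both arms on each joint
parameter draw (the same draw in both arms, so arm differences reflect only
treatment effects and arm-specific costs) with the vectorised cohort engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costing import price_reduction_percent, vnd_to_usd, year_one_cost_values
from .markov import ArmResult, LifeTable, run_cohort, run_cohort_values
from .params import ConfigError, ParameterSet, sample_psa_arrays

__all__ = [
    "ICERResult", "CEACPoint", "TornadoEntry", "ThresholdResult",
    "icer", "nmb", "run_deterministic", "run_psa_model", "ceac", "evpi",
    "tornado", "threshold_price", "scenario_run", "default_lambda_grid",
]


@dataclass(frozen=True)
class ICERResult:
    """Incremental cost-effectiveness of trastuzumab versus chemotherapy."""

    d_cost_vnd: float
    d_ly: float
    d_qaly: float
    icer_per_ly_vnd: float | None
    icer_per_qaly_vnd: float | None
    dominance: str                   # "trade-off" | "dominant" | "dominated" | "undefined"
    exchange_rate: float
    cohort_size: int

    @property
    def d_cost_usd(self) -> int:
        return vnd_to_usd(self.d_cost_vnd, self.exchange_rate)

    @property
    def icer_per_ly_usd(self) -> int | None:
        return None if self.icer_per_ly_vnd is None else vnd_to_usd(self.icer_per_ly_vnd, self.exchange_rate)

    @property
    def icer_per_qaly_usd(self) -> int | None:
        return None if self.icer_per_qaly_vnd is None else vnd_to_usd(self.icer_per_qaly_vnd, self.exchange_rate)

    @property
    def cohort_d_cost_vnd(self) -> float:
        return self.d_cost_vnd * self.cohort_size

    @property
    def cohort_d_ly(self) -> float:
        return self.d_ly * self.cohort_size

    @property
    def cohort_d_qaly(self) -> float:
        return self.d_qaly * self.cohort_size


def icer(reference: ArmResult, comparator: ArmResult,
         exchange_rate: float = 22_745.0) -> ICERResult:
    """Incremental cost-effectiveness ratio of ``reference`` over ``comparator``.

    Ratios are reported only in trade-off quadrants; one arm dominating (less
    costly and at least as effective) is flagged instead, and a zero effect
    difference with a cost difference yields an "undefined" flag, not an error.
    """
    dc = reference.cost - comparator.cost
    dly = reference.ly - comparator.ly
    dq = reference.qaly - comparator.qaly
    per_ly = per_qaly = None
    if dq == 0:
        dominance = "undefined" if dc != 0 else "trade-off"
        if dc == 0:
            per_ly = per_qaly = 0.0
    elif dc <= 0 and dq >= 0:
        dominance = "dominant"
    elif dc >= 0 and dq <= 0:
        dominance = "dominated"
    else:
        dominance = "trade-off"
        per_ly = dc / dly if dly != 0 else None
        per_qaly = dc / dq
    return ICERResult(
        d_cost_vnd=dc, d_ly=dly, d_qaly=dq,
        icer_per_ly_vnd=per_ly, icer_per_qaly_vnd=per_qaly,
        dominance=dominance, exchange_rate=exchange_rate,
        cohort_size=reference.cohort_size,
    )


def nmb(qaly, cost, lam):
    """Net monetary benefit lam * QALY - cost (works on totals or increments)."""
    if np.any(np.asarray(lam) < 0):
        raise ValueError("willingness-to-pay must be >= 0")
    return lam * np.asarray(qaly) - np.asarray(cost)


def run_deterministic(params: ParameterSet, lt: LifeTable,
                      sharing: bool = False) -> tuple[ArmResult, ArmResult, ICERResult]:
    """Base-case run of both arms plus the incremental comparison."""
    from .costing import arm_year_one_cost

    _, trast = run_cohort("trastuzumab", params, lt,
                          year_one_cost=arm_year_one_cost("trastuzumab", params, sharing))
    _, chemo = run_cohort("chemo", params, lt)
    return trast, chemo, icer(trast, chemo, params.settings.exchange_rate)


def run_psa_model(params: ParameterSet, lt: LifeTable, n: int, seed: int,
                  sharing: bool = False) -> pd.DataFrame:
    """Monte-Carlo PSA: per-draw incremental cost, QALY and LY.

    Every joint draw is applied to both arms simultaneously; the returned
    frame has one row per draw with columns ``d_cost``, ``d_qaly``, ``d_ly``
    and the per-arm discounted totals, and is reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    values = sample_psa_arrays(params, n, seed)
    settings = params.settings
    results = {}
    for arm in ("trastuzumab", "chemo"):
        y1 = year_one_cost_values(arm, values, sharing=sharing)
        _, tot = run_cohort_values(arm, values, settings, lt, y1)
        results[arm] = tot
    t, c = results["trastuzumab"], results["chemo"]
    return pd.DataFrame({
        "draw": np.arange(n),
        "d_cost": t["cost"] - c["cost"],
        "d_qaly": t["qaly"] - c["qaly"],
        "d_ly": t["ly"] - c["ly"],
        "cost_trast": t["cost"], "qaly_trast": t["qaly"],
        "cost_chemo": c["cost"], "qaly_chemo": c["qaly"],
    })


@dataclass(frozen=True)
class CEACPoint:
    """Probability each arm is cost-effective at one willingness-to-pay."""

    lam: float
    p_trastuzumab: float
    p_chemo: float


def default_lambda_grid() -> np.ndarray:
    """0 to 1,000 million VND/QALY in 5-million steps."""
    return np.arange(0.0, 1_000_000_001.0, 5_000_000.0)


def ceac(draws: pd.DataFrame, lam_grid=None) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve from PSA draws.

    At each willingness-to-pay the trastuzumab probability is the fraction of
    draws with strictly positive incremental net monetary benefit (ties go to
    the comparator); the two arm probabilities sum to one.
    """
    if len(draws) == 0:
        raise ValueError("no PSA draws supplied")
    if lam_grid is None:
        lam_grid = default_lambda_grid()
    lam_grid = np.asarray(lam_grid, dtype=float)
    if lam_grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    inmb = lam_grid[:, None] * draws["d_qaly"].to_numpy() - draws["d_cost"].to_numpy()
    p = (inmb > 0).mean(axis=1)
    return [CEACPoint(float(l), float(pi), float(1.0 - pi)) for l, pi in zip(lam_grid, p)]


def ceac_frame(points: list[CEACPoint]) -> pd.DataFrame:
    return pd.DataFrame({
        "lambda_vnd_per_qaly": [p.lam for p in points],
        "p_trastuzumab": [p.p_trastuzumab for p in points],
        "p_chemo": [p.p_chemo for p in points],
    })


def evpi(draws: pd.DataFrame, lam: float, population: int | None = None) -> dict:
    """Expected value of perfect information at willingness-to-pay ``lam``.

    Per person: E[max(0, iNMB)] - max(0, E[iNMB]); non-negative by Jensen's
    inequality and zero when one arm wins in every draw.  The population value
    scales by one annual treatment cohort.
    """
    inmb = nmb(draws["d_qaly"].to_numpy(), draws["d_cost"].to_numpy(), lam)
    per_person = float(np.mean(np.maximum(inmb, 0.0)) - max(np.mean(inmb), 0.0))
    per_person = max(per_person, 0.0)  # guard tiny negative rounding
    out = {"lambda": lam, "evpi_per_person_vnd": per_person}
    if population is not None:
        out["population"] = population
        out["evpi_population_vnd"] = per_person * population
    return out


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity of the ICER per QALY to a single parameter."""

    name: str
    low: float
    high: float
    icer_low: float | None
    icer_high: float | None
    span: float
    valid: bool = True


def _det_icer_per_qaly(params: ParameterSet, lt: LifeTable,
                       sharing: bool = False) -> float | None:
    _, _, res = run_deterministic(params, lt, sharing=sharing)
    return res.icer_per_qaly_vnd


def tornado(params: ParameterSet, lt: LifeTable,
            ranges: dict[str, tuple[float, float]] | None = None,
            sharing: bool = False) -> list[TornadoEntry]:
    """One-way sensitivity analysis over every uncertain parameter.

    Each parameter is set to its low and high value in turn (holding all
    others at base) and the deterministic ICER per QALY recomputed; entries
    are sorted by descending span.  Vial-price entries scale the drug-cost
    aggregate proportionally (full price pass-through).  A parameter value
    that breaks the model (negative remainder) flags its entry rather than
    aborting the analysis.
    """
    from .markov import NegativeRemainderError
    from .params import build_distributions

    if ranges is None:
        ranges = {name: (d.lo, d.hi) for name, d in build_distributions(params).items()}
        m = params.psa.default_rel_range
        for vial in ("p_440", "p_150"):
            base = getattr(params.costs, vial)
            ranges[vial] = (base * (1 - m), base * (1 + m))
    base_vals = params.values()

    entries = []
    for name, (lo, hi) in ranges.items():
        if not (lo <= base_vals.get(name, lo) <= hi):
            raise ValueError(f"tornado range for {name} must bracket the base value")
        icers = []
        ok = True
        for v in (lo, hi):
            try:
                if name in ("p_440", "p_150"):
                    # pass the vial price change through to the drug aggregate
                    scale = v / base_vals[name] if base_vals[name] else 1.0
                    p2 = params.with_values({name: v,
                                             "trast_drug": base_vals["trast_drug"] * scale})
                else:
                    p2 = params.with_values({name: v})
                icers.append(_det_icer_per_qaly(p2, lt, sharing=sharing))
            except (NegativeRemainderError, ConfigError, ValueError):
                icers.append(None)
                ok = False
        span = (abs(icers[1] - icers[0])
                if ok and None not in icers else 0.0)
        entries.append(TornadoEntry(name, lo, hi, icers[0], icers[1], span, ok))
    entries.sort(key=lambda e: (-e.span, e.name))
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame({
        "parameter": [e.name for e in entries],
        "low": [e.low for e in entries],
        "high": [e.high for e in entries],
        "icer_low_vnd": [e.icer_low for e in entries],
        "icer_high_vnd": [e.icer_high for e in entries],
        "span_vnd": [e.span for e in entries],
        "valid": [e.valid for e in entries],
    })


@dataclass(frozen=True)
class ThresholdResult:
    """Drug-price scale at which the ICER meets a willingness-to-pay target."""

    lam: float
    scale: float | None
    price_440_vnd: float | None
    price_150_vnd: float | None
    achieved_icer_vnd: float
    reachable: bool = True


def threshold_price(lam: float, params: ParameterSet, lt: LifeTable,
                    sharing: bool = False, rel_tol: float = 1e-4,
                    max_iter: int = 200) -> ThresholdResult:
    """Trastuzumab price making the therapy exactly cost-effective at ``lam``.

    A common multiplicative factor ``s`` scales both vial prices and hence the
    one-year drug-cost aggregate (preserving the current 440:150 price ratio);
    bisection finds ``s*`` with |ICER(s*) - lam| <= ``rel_tol`` * lam.  If even
    a free drug leaves the ICER above ``lam`` the result is flagged
    unreachable with the ICER floor reported.
    """
    from .costing import resolved_drug_cost

    base_drug = resolved_drug_cost(params, sharing=sharing)

    def icer_at(s: float) -> float:
        p2 = params.with_values({"trast_drug": base_drug * s})
        if params.settings.drug_cost_mode == "computed":
            p2 = p2.with_values({"p_440": params.costs.p_440 * s,
                                 "p_150": params.costs.p_150 * s})
        val = _det_icer_per_qaly(p2, lt)
        if val is None:
            raise ValueError("ICER undefined during threshold search")
        return val

    hi_icer = icer_at(1.0)
    if hi_icer <= lam:
        return ThresholdResult(lam, 1.0, params.costs.p_440, params.costs.p_150,
                               hi_icer, reachable=True)
    lo_icer = icer_at(0.0)
    if lo_icer > lam:
        return ThresholdResult(lam, None, None, None, lo_icer, reachable=False)

    a, b = 0.0, 1.0
    s = 0.5
    for _ in range(max_iter):
        s = 0.5 * (a + b)
        val = icer_at(s)
        if abs(val - lam) <= rel_tol * lam:
            break
        if val > lam:
            b = s
        else:
            a = s
    return ThresholdResult(
        lam=lam, scale=s,
        price_440_vnd=params.costs.p_440 * s,
        price_150_vnd=params.costs.p_150 * s,
        achieved_icer_vnd=val,
    )


@dataclass
class ScenarioReport:
    """Comparative report for a named-override scenario run."""

    overrides: dict[str, float]
    trast: ArmResult
    chemo: ArmResult
    icer: ICERResult
    therapy_cost_total_vnd: float
    drug_cost_vnd: float
    prob_cost_effective: dict[float, float] = field(default_factory=dict)
    thresholds: dict[float, ThresholdResult] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        xr = self.icer.exchange_rate
        rows = [
            ("therapy_cost_total", self.therapy_cost_total_vnd, vnd_to_usd(self.therapy_cost_total_vnd, xr)),
            ("trast_drug_cost", self.drug_cost_vnd, vnd_to_usd(self.drug_cost_vnd, xr)),
            ("icer_per_qaly", self.icer.icer_per_qaly_vnd,
             None if self.icer.icer_per_qaly_vnd is None else vnd_to_usd(self.icer.icer_per_qaly_vnd, xr)),
        ]
        for lam, p in self.prob_cost_effective.items():
            rows.append((f"p_cost_effective_at_{int(lam):d}", p, None))
        for lam, th in self.thresholds.items():
            rows.append((f"threshold_price_440_at_{int(lam):d}", th.price_440_vnd,
                         None if th.price_440_vnd is None else vnd_to_usd(th.price_440_vnd, xr)))
            rows.append((f"threshold_price_150_at_{int(lam):d}", th.price_150_vnd,
                         None if th.price_150_vnd is None else vnd_to_usd(th.price_150_vnd, xr)))
        return pd.DataFrame(rows, columns=["quantity", "vnd", "usd"])


def scenario_run(overrides: dict[str, float], params: ParameterSet, lt: LifeTable,
                 n_psa: int = 10_000, seed: int = 20240315,
                 run_psa: bool = True, run_thresholds: bool = True) -> ScenarioReport:
    """Re-run the deterministic case, PSA and threshold analysis under overrides.

    ``overrides`` substitute named clinical/utility/cost values (e.g. the
    vial-sharing drug aggregate); an unknown name raises.  Empty overrides
    reproduce the base case.
    """
    from .costing import therapy_breakdown

    p2 = params.with_values(overrides)
    trast, chemo, res = run_deterministic(p2, lt)
    report = ScenarioReport(
        overrides=dict(overrides), trast=trast, chemo=chemo, icer=res,
        therapy_cost_total_vnd=float(therapy_breakdown(p2, exclude_paclitaxel=True).total),
        drug_cost_vnd=float(p2.costs.trast_drug),
    )
    if run_psa:
        draws = run_psa_model(p2, lt, n_psa, seed)
        for lam in p2.settings.wtp_thresholds:
            inmb = nmb(draws["d_qaly"].to_numpy(), draws["d_cost"].to_numpy(), lam)
            report.prob_cost_effective[lam] = float((inmb > 0).mean())
    if run_thresholds:
        for lam in p2.settings.wtp_thresholds:
            report.thresholds[lam] = threshold_price(lam, p2, lt)
    return report
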