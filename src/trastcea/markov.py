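"""Markov cohort engine for the six-state breast-cancer model.

States (fixed order, indices 0-5): disease-free (DFS), disease-free with
trastuzumab-induced congestive heart failure (DFS_CHF), local-regional
recurrence (LRR), disease-free after local-regional recurrence
(DFS_POST_LRR), metastatic disease (MET), and DEAD (absorbing).

The cohort enters entirely disease-free at the start age and moves annually
under per-cycle transition matrices.  Model assumptions: the trastuzumab
treatment effect (hazard-ratio adjustment of recurrence and metastasis
probabilities) lasts five cycles; cardiotoxicity occurs only in the first
cycle; no new recurrences arise from disease-free states from cycle 20 on;
breast-cancer death occurs only from the metastatic state; CHF itself causes
no excess mortality; background mortality from a life table applies in every
alive state.  Within a cycle, background death is applied first and disease
events are scaled by (1 - q), keeping each row stochastic by construction.

Rewards (life years, utility-weighted life years, state costs) accrue on
start-of-cycle occupancy and are discounted at a fixed annual rate; one-off
year-one therapy costs enter undiscounted at cycle 0.

The same matrix-construction code serves scalar (deterministic) runs and
vectorised probabilistic runs, where each parameter is an array of Monte
Carlo draws.  :func:`microsim` is an independent individual-level oracle for
the cohort engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .params import ModelSettings, ParameterSet

__all__ = [
    "STATES", "DFS", "DFS_CHF", "LRR", "DFS_POST_LRR", "MET", "DEAD",
    "NegativeRemainderError", "LifeTable", "CohortTrace", "ArmResult",
    "hr_adjust", "build_matrix", "run_cohort", "run_cohort_values", "microsim",
]

STATES = ("DFS", "DFS_CHF", "LRR", "DFS_POST_LRR", "MET", "DEAD")
DFS, DFS_CHF, LRR, DFS_POST_LRR, MET, DEAD = range(6)

_OCC_TOL = 1e-12  # alive-fraction floor at which simulation stops


class NegativeRemainderError(ValueError):
    """Competing event probabilities in one row exceed 1 before the remainder."""


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause death probabilities qx indexed by integer age.

    Ages must be contiguous; lookups beyond the last tabulated age return
    qx = 1 (everyone dies), which also bounds the simulation horizon.
    """

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.ndim != 1 or ages.shape != qx.shape or len(ages) == 0:
            raise ValueError("life table needs matching 1-d age and qx columns")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("life-table ages must be contiguous and increasing by 1")
        if np.any((qx < 0) | (qx > 1)):
            raise ValueError("life-table qx values must lie in [0, 1]")

    def q_at(self, age: int) -> float:
        if age < self.ages[0]:
            raise ValueError(f"age {age} below first tabulated age {self.ages[0]}")
        if age > self.ages[-1]:
            return 1.0
        return float(self.qx[age - self.ages[0]])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path, sep=None, engine="python")
        if not {"age", "qx"} <= set(df.columns):
            raise ValueError(f"life table {path} must have columns 'age' and 'qx'")
        return cls(df["age"].to_numpy(), df["qx"].to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.ages, "qx": self.qx}).to_csv(path, sep="\t", index=False)


def hr_adjust(p, hr, transform: str = "rate"):
    """Apply a hazard ratio to an annual probability.

    The default rate-based transform 1 - (1 - p)^HR follows from a constant
    hazard within the cycle and stays in [0, 1) for any HR > 0.  The "linear"
    transform p * HR (clipped at 1) is available for sensitivity analyses.
    """
    p = np.asarray(p, dtype=float)
    hr = np.asarray(hr, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probability must be in [0, 1]")
    if np.any(hr <= 0):
        raise ValueError("hazard ratio must be strictly positive")
    if transform == "rate":
        # HR = 1 returns p bit-exactly so a null effect cancels exactly
        out = np.where(hr == 1.0, p, 1.0 - (1.0 - p) ** hr)
    elif transform == "linear":
        out = np.minimum(p * hr, 1.0)
    else:
        raise ValueError(f"unknown hr transform {transform!r}")
    return out if out.ndim else float(out)


def _matrix_from_values(arm: str, cycle: int, q: float,
                        v: Mapping[str, np.ndarray | float],
                        settings: ModelSettings) -> np.ndarray:
    """Assemble the per-cycle transition matrix, broadcasting over draws.

    ``v`` maps parameter names to scalars or equally shaped arrays; the result
    has shape ``batch + (6, 6)``.
    """
    if arm not in ("trastuzumab", "chemo"):
        raise ValueError(f"unknown arm {arm!r}")
    batch = np.broadcast(*[np.asarray(v[k]) for k in
                           ("p_lrr_base", "p_met_base", "p_death_met")]).shape
    M = np.zeros(batch + (6, 6))
    surv = 1.0 - q
    cutoff = cycle >= settings.recurrence_cutoff

    # DFS row: CHF only at cycle 0; treatment effect only in the trastuzumab
    # arm during the benefit window
    p_chf = v["p_chf_trast"] if arm == "trastuzumab" else v["p_chf_chemo"]
    chf = np.asarray(p_chf, dtype=float) if cycle == 0 else 0.0
    if cutoff:
        lrr = met = np.zeros(batch)
    elif arm == "trastuzumab" and cycle < settings.benefit_duration:
        lrr = hr_adjust(v["p_lrr_base"], v["hr_lrr"], settings.hr_transform)
        met = hr_adjust(v["p_met_base"], v["hr_met"], settings.hr_transform)
    else:
        lrr = np.asarray(v["p_lrr_base"], dtype=float)
        met = np.asarray(v["p_met_base"], dtype=float)
    events = chf + lrr + met
    if np.any(events > 1.0 + 1e-12):
        raise NegativeRemainderError(
            f"DFS events exceed 1 at cycle {cycle} ({arm}): max {np.max(events):.4f}")
    M[..., DFS, DFS_CHF] = chf * surv
    M[..., DFS, LRR] = lrr * surv
    M[..., DFS, MET] = met * surv
    M[..., DFS, DEAD] = q
    M[..., DFS, DFS] = surv * (1.0 - events)

    # DFS_CHF row: trastuzumab discontinued after CHF, so recurrence risks
    # revert to the untreated baselines in both arms
    if cutoff:
        lrr_c = met_c = np.zeros(batch)
    else:
        lrr_c = np.asarray(v["p_lrr_base"], dtype=float)
        met_c = np.asarray(v["p_met_base"], dtype=float)
    events_c = lrr_c + met_c
    if np.any(events_c > 1.0 + 1e-12):
        raise NegativeRemainderError(
            f"DFS_CHF events exceed 1 at cycle {cycle} ({arm})")
    M[..., DFS_CHF, LRR] = lrr_c * surv
    M[..., DFS_CHF, MET] = met_c * surv
    M[..., DFS_CHF, DEAD] = q
    M[..., DFS_CHF, DFS_CHF] = surv * (1.0 - events_c)

    # LRR row: patients may return to disease-free or progress; the elevated
    # metastasis risk after recurrence keeps applying beyond the cutoff
    rec = np.asarray(v["p_dfs_after_lrr"], dtype=float)
    met_hi = hr_adjust(v["p_met_base"], v["rr_met_after_lrr"], settings.hr_transform)
    events_l = rec + met_hi
    if np.any(events_l > 1.0 + 1e-12):
        raise NegativeRemainderError(f"LRR events exceed 1 at cycle {cycle} ({arm})")
    M[..., LRR, DFS_POST_LRR] = rec * surv
    M[..., LRR, MET] = met_hi * surv
    M[..., LRR, DEAD] = q
    M[..., LRR, LRR] = surv * (1.0 - events_l)

    # DFS_POST_LRR row: no second local recurrence
    if np.any(met_hi > 1.0 + 1e-12):
        raise NegativeRemainderError(f"DFS_POST_LRR events exceed 1 at cycle {cycle}")
    M[..., DFS_POST_LRR, MET] = met_hi * surv
    M[..., DFS_POST_LRR, DEAD] = q
    M[..., DFS_POST_LRR, DFS_POST_LRR] = surv * (1.0 - met_hi)

    # MET row: cancer death and background death as independent competing causes
    p_dm = np.asarray(v["p_death_met"], dtype=float)
    M[..., MET, DEAD] = 1.0 - (1.0 - p_dm) * surv
    M[..., MET, MET] = (1.0 - p_dm) * surv

    M[..., DEAD, DEAD] = 1.0
    return M


def build_matrix(arm: str, cycle: int, age: int, params: ParameterSet,
                 lt: LifeTable) -> np.ndarray:
    """6x6 transition matrix for one arm at one cycle (scalar parameters)."""
    q = lt.q_at(age)
    M = _matrix_from_values(arm, cycle, q, params.values(), params.settings)
    np.testing.assert_allclose(M.sum(axis=-1), 1.0, atol=1e-12)
    return M


@dataclass
class CohortTrace:
    """State-occupancy history: one row per cycle with per-cycle increments."""

    cycles: np.ndarray        # cycle index t = 0, 1, ...
    ages: np.ndarray          # age at start of cycle
    occupancy: np.ndarray     # (T, 6) start-of-cycle proportions
    disc_cost: np.ndarray     # per-cycle discounted increments
    disc_ly: np.ndarray
    disc_qaly: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", self.cycles)
        df["disc_cost"] = self.disc_cost
        df["disc_ly"] = self.disc_ly
        df["disc_qaly"] = self.disc_qaly
        return df


@dataclass
class ArmResult:
    """Discounted and undiscounted lifetime totals per person and per cohort."""

    arm: str
    cost: float               # discounted, per person, VND
    ly: float
    qaly: float
    cost_undisc: float
    ly_undisc: float
    qaly_undisc: float
    cohort_size: int

    @property
    def cohort_cost(self) -> float:
        return self.cost * self.cohort_size

    @property
    def cohort_ly(self) -> float:
        return self.ly * self.cohort_size

    @property
    def cohort_qaly(self) -> float:
        return self.qaly * self.cohort_size


def _utility_vector(v: Mapping[str, np.ndarray | float]) -> np.ndarray:
    return np.stack(np.broadcast_arrays(
        np.asarray(v["u_dfs"], float), np.asarray(v["u_dfs_chf"], float),
        np.asarray(v["u_lrr"], float), np.asarray(v["u_dfs_post_lrr"], float),
        np.asarray(v["u_met"], float), np.asarray(v["u_dfs"], float) * 0.0,
    ), axis=-1)


def _state_cost_vector(v: Mapping[str, np.ndarray | float]) -> np.ndarray:
    return np.stack(np.broadcast_arrays(
        np.asarray(v["c_dfs"], float), np.asarray(v["c_dfs_chf"], float),
        np.asarray(v["c_lrr"], float), np.asarray(v["c_dfs_post_lrr"], float),
        np.asarray(v["c_met"], float), np.asarray(v["c_dfs"], float) * 0.0,
    ), axis=-1)


def run_cohort_values(arm: str, values: Mapping[str, np.ndarray | float],
                      settings: ModelSettings, lt: LifeTable,
                      year_one_cost: np.ndarray | float,
                      keep_trace: bool = False):
    """Run the cohort simulation on resolved parameter values.

    ``values`` may hold scalars (deterministic run) or arrays of Monte Carlo
    draws; totals then have the draws' shape.  Returns ``(trace, totals)``
    where ``trace`` is None unless ``keep_trace`` and totals is a dict of
    arrays ``cost/ly/qaly`` plus undiscounted counterparts.
    """
    u = _utility_vector(values)
    c = _state_cost_vector(values)
    batch = u.shape[:-1]
    occ = np.zeros(batch + (6,))
    occ[..., DFS] = 1.0
    r = settings.discount_rate
    hcc = settings.half_cycle_correction

    tot = {k: np.zeros(batch) for k in
           ("cost", "ly", "qaly", "cost_undisc", "ly_undisc", "qaly_undisc")}
    tot["cost"] = tot["cost"] + np.asarray(year_one_cost, float)
    tot["cost_undisc"] = tot["cost_undisc"] + np.asarray(year_one_cost, float)

    rows = [] if keep_trace else None
    t = 0
    horizon = settings.max_age - settings.start_age
    while t <= horizon:
        age = settings.start_age + t
        alive = 1.0 - occ[..., DEAD]
        if np.max(alive) < _OCC_TOL:
            break
        q = lt.q_at(age)
        M = _matrix_from_values(arm, t, q, values, settings)
        occ_next = np.einsum("...i,...ij->...j", occ, M)

        occ_acc = 0.5 * (occ + occ_next) if hcc else occ
        disc = (1.0 + r) ** (-t)
        ly_inc = 1.0 - occ_acc[..., DEAD]
        qaly_inc = np.einsum("...i,...i->...", occ_acc, u)
        cost_inc = np.einsum("...i,...i->...", occ_acc, c)
        tot["ly"] += disc * ly_inc
        tot["qaly"] += disc * qaly_inc
        tot["cost"] += disc * cost_inc
        tot["ly_undisc"] += ly_inc
        tot["qaly_undisc"] += qaly_inc
        tot["cost_undisc"] += cost_inc
        if keep_trace:
            rows.append((t, age, occ.copy(), disc * cost_inc, disc * ly_inc, disc * qaly_inc))
        occ = occ_next
        t += 1

    trace = None
    if keep_trace:
        trace = CohortTrace(
            cycles=np.array([x[0] for x in rows]),
            ages=np.array([x[1] for x in rows]),
            occupancy=np.stack([x[2] for x in rows]),
            disc_cost=np.array([x[3] for x in rows]),
            disc_ly=np.array([x[4] for x in rows]),
            disc_qaly=np.array([x[5] for x in rows]),
        )
    return trace, tot


def run_cohort(arm: str, params: ParameterSet, lt: LifeTable,
               year_one_cost: float | None = None) -> tuple[CohortTrace, ArmResult]:
    """Deterministic cohort run for one arm; returns the trace and totals.

    ``year_one_cost`` defaults to the arm's one-off first-year therapy cost
    from the costing module.
    """
    from .costing import arm_year_one_cost

    settings = params.settings
    if year_one_cost is None:
        year_one_cost = arm_year_one_cost(arm, params)
    trace, tot = run_cohort_values(arm, params.values(), settings, lt,
                                   year_one_cost, keep_trace=True)
    result = ArmResult(
        arm=arm,
        cost=float(tot["cost"]), ly=float(tot["ly"]), qaly=float(tot["qaly"]),
        cost_undisc=float(tot["cost_undisc"]), ly_undisc=float(tot["ly_undisc"]),
        qaly_undisc=float(tot["qaly_undisc"]),
        cohort_size=settings.cohort_size,
    )
    return trace, result


@dataclass
class MicrosimResult:
    """Monte-Carlo estimate of the per-person lifetime totals with SEs."""

    arm: str
    n: int
    cost: float
    ly: float
    qaly: float
    se_cost: float
    se_ly: float
    se_qaly: float


def microsim(arm: str, params: ParameterSet, lt: LifeTable,
             n_individuals: int, seed: int,
             year_one_cost: float | None = None) -> MicrosimResult:
    """Individual-level simulation oracle for :func:`run_cohort`.

    Simulates ``n_individuals`` independent trajectories through the same
    per-cycle matrices with the same start-of-cycle reward accrual, so the
    estimator of each discounted total is unbiased for the cohort-engine
    value.  Returns means and Monte-Carlo standard errors.
    """
    from .costing import arm_year_one_cost

    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    settings = params.settings
    if settings.half_cycle_correction:
        raise NotImplementedError("microsim oracle implements start-of-cycle accrual only")
    if year_one_cost is None:
        year_one_cost = arm_year_one_cost(arm, params)
    values = params.values()
    u = _utility_vector(values)
    c = _state_cost_vector(values)
    r = settings.discount_rate
    rng = np.random.default_rng(seed)

    state = np.zeros(n_individuals, dtype=np.int8)
    cost = np.full(n_individuals, float(year_one_cost))
    ly = np.zeros(n_individuals)
    qaly = np.zeros(n_individuals)

    horizon = settings.max_age - settings.start_age
    for t in range(horizon + 1):
        alive = state != DEAD
        if not alive.any():
            break
        age = settings.start_age + t
        disc = (1.0 + r) ** (-t)
        ly[alive] += disc
        qaly += disc * u[state]
        cost += disc * c[state]
        M = _matrix_from_values(arm, t, lt.q_at(age), values, settings)
        cum = np.cumsum(M, axis=-1)
        uni = rng.random(n_individuals)
        new_state = state.copy()
        for s in np.unique(state[alive]):
            idx = np.flatnonzero(state == s)  # group by the pre-transition state
            new_state[idx] = np.searchsorted(cum[s], uni[idx], side="right").astype(np.int8)
        state = np.minimum(new_state, DEAD)

    sqn = np.sqrt(n_individuals)
    return MicrosimResult(
        arm=arm, n=n_individuals,
        cost=float(cost.mean()), ly=float(ly.mean()), qaly=float(qaly.mean()),
        se_cost=float(cost.std(ddof=1) / sqn),
        se_ly=float(ly.std(ddof=1) / sqn),
        se_qaly=float(qaly.std(ddof=1) / sqn),
    )
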