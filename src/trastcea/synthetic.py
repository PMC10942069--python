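"""Synthetic inputs: parametric life tables, jittered parameters, toy models.

The published analysis reads background mortality from the WHO 2020 life
table for Vietnamese women, which is not redistributable here.  A
Gompertz-Makeham mortality law

    h(x) = a + c * exp(b * x),    qx = 1 - exp(-h(x))

generates plausible female life tables in its place; the bundled
``vietnam_2020_approx`` fixture uses a = 0.0012, b = 0.11, c = 9e-6, chosen
to approximate Vietnamese female mortality around 2020 (q50 ~ 0.0034,
q70 ~ 0.02, modal age at death ~ 85).  It is an approximation: headline
results computed on it will differ from values computed on the true WHO
table.

The toy model (single live state, constant hazard, utility and cost) has
closed-form discounted totals and anchors the cohort engine's reward and
discounting conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .markov import LifeTable
from .params import ParameterSet

__all__ = [
    "MortalityLaw", "VIETNAM_2020_APPROX_LAW",
    "make_lifetable", "jitter_params", "make_toy_model",
]


@dataclass(frozen=True)
class MortalityLaw:
    """Gompertz-Makeham hazard: background ``a`` plus senescent ``c * e^(b*age)``."""

    a: float = 0.0012    # age-independent background hazard per year
    b: float = 0.11      # log-slope of the senescent hazard per year of age
    c: float = 9.0e-6    # senescent hazard at age 0 per year

    def __post_init__(self):
        if self.a < 0 or self.b < 0 or self.c < 0:
            raise ValueError("mortality-law parameters must be non-negative")

    def qx(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        h = self.a + self.c * np.exp(self.b * age)
        return 1.0 - np.exp(-h)


VIETNAM_2020_APPROX_LAW = MortalityLaw()


def make_lifetable(law: MortalityLaw = VIETNAM_2020_APPROX_LAW,
                   age_min: int = 0, age_max: int = 100) -> LifeTable:
    """Life table from a mortality law; the final age is forced to qx = 1."""
    if age_max <= age_min:
        raise ValueError("age_max must exceed age_min")
    ages = np.arange(age_min, age_max + 1)
    qx = law.qx(ages)
    qx[-1] = 1.0
    return LifeTable(ages, qx)


def jitter_params(params: ParameterSet, magnitude: float, seed: int) -> ParameterSet:
    """Multiply each continuous parameter by an independent factor in [1-m, 1+m].

    Probabilities and utilities are clamped back into [0, 1]; the result
    passes full parameter validation.  Used for robustness testing of the
    engine over perturbed inputs.
    """
    if not 0.0 <= magnitude <= 0.5:
        raise ValueError("magnitude must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    overrides = {}
    bounded = set(type(params.clinical)._PROBS) | \
        {f for f, _ in params.value_items() if f.startswith("u_")}
    for name, value in params.value_items():
        factor = rng.uniform(1.0 - magnitude, 1.0 + magnitude)
        v = value * factor
        if name in bounded:
            v = min(max(v, 0.0), 1.0)
        overrides[name] = v
    return params.with_values(overrides)


def make_toy_model(p: float = 0.5, u: float = 1.0, c: float = 0.0,
                   r: float = 0.0, start_age: int = 50,
                   final_age: int = 100) -> tuple[ParameterSet, LifeTable, dict]:
    """Two-state check model with closed-form discounted totals.

    Disease transitions are switched off so the cohort only moves DFS -> DEAD
    under a constant annual death probability ``p``; every live state has
    utility ``u`` and annual cost ``c``; year-one therapy costs are zero.
    With N = final_age - start_age + 1 start-of-cycle accruals the exact
    totals are geometric sums

        LY   = sum_{t=0}^{N-1} ((1-p)/(1+r))^t,
        QALY = u * LY,   cost = c * LY,

    returned in the ``analytic`` dict for oracle tests.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    params = ParameterSet()
    params.clinical = replace(
        params.clinical,
        p_lrr_base=0.0, p_met_base=0.0, p_dfs_after_lrr=0.0,
        p_chf_trast=0.0, p_chf_chemo=0.0, p_death_met=0.0,
    )
    for name in ("u_dfs", "u_lrr", "u_dfs_post_lrr", "u_dfs_chf", "u_met"):
        setattr(params.utilities, name, u)
    for name in ("trast_drug", "her2_detection", "trast_other_direct_medical",
                 "trast_direct_nonmedical", "paclitaxel_treatment",
                 "c_lrr", "c_dfs_post_lrr", "c_met", "c_dfs_chf", "c_dfs"):
        setattr(params.costs, name, 0.0)
    params.costs.c_dfs = c
    horizon = final_age - start_age
    cutoff = min(20, horizon)
    params.settings = replace(params.settings, start_age=start_age,
                              max_age=final_age, discount_rate=r,
                              recurrence_cutoff=cutoff,
                              benefit_duration=min(5, cutoff))
    params.validate()

    ages = np.arange(start_age, final_age + 1)
    qx = np.full(ages.shape, p, dtype=float)
    qx[-1] = 1.0
    lt = LifeTable(ages, qx)

    n_cycles = final_age - start_age + 1
    ratio = (1.0 - p) / (1.0 + r)
    if ratio == 1.0:
        ly = float(n_cycles)
    else:
        ly = (1.0 - ratio ** n_cycles) / (1.0 - ratio)
    analytic = {"ly": ly, "qaly": u * ly, "cost": c * ly, "n_cycles": n_cycles}
    return params, lt, analytic
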