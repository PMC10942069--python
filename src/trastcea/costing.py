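"""Therapy costing: vial-based drug costs, year-one totals, currency helpers.

Trastuzumab is dosed by body weight (8 mg/kg loading, then 6 mg/kg every
three weeks for one year) and sold in 150 mg and 440 mg vials.  Two drug-cost
conventions are implemented:

* **no sharing** -- each administration opens whole vials chosen as the
  cheapest integer combination covering the required milligrams, with the
  remainder discarded;
* **vial sharing** -- concurrent patients pool vials, so the cohort pays for
  the exact milligrams at the best available price per mg.

The model's base-case runs use the published aggregate one-year drug costs
directly (``drug_cost_mode = "printed"``), because those aggregates came from
a micro-costing exercise (weight distributions, copayments) that the vial
calculator intentionally does not emulate; the calculator is an independent
tool and an alternative ``"computed"`` mode.

All VND amounts are carried as exact integers through reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as _iproduct
from math import ceil

from .params import ParameterSet

__all__ = [
    "VialSpec", "DoseSchedule", "TherapyCostBreakdown",
    "doses_per_year", "dose_amounts_mg", "drug_cost_no_sharing",
    "drug_cost_sharing", "therapy_cost_total", "therapy_breakdown",
    "arm_year_one_cost", "vnd_to_usd", "price_reduction_percent",
]


@dataclass(frozen=True)
class VialSpec:
    """A vial size (mg) and its price (VND)."""

    size_mg: float
    price_vnd: float

    def __post_init__(self):
        if self.size_mg <= 0:
            raise ValueError("vial size must be > 0")
        if self.price_vnd < 0:
            raise ValueError("vial price must be >= 0")


@dataclass(frozen=True)
class DoseSchedule:
    """Weight-based dosing: loading dose then maintenance doses at a fixed interval."""

    loading_mg_per_kg: float = 8.0
    maintenance_mg_per_kg: float = 6.0
    interval_weeks: int = 3
    duration_weeks: int = 52

    def __post_init__(self):
        if self.loading_mg_per_kg <= 0 or self.maintenance_mg_per_kg <= 0:
            raise ValueError("doses must be > 0")
        if self.interval_weeks <= 0 or self.duration_weeks <= 0:
            raise ValueError("interval and duration must be > 0")


def default_vials(params: ParameterSet) -> tuple[VialSpec, VialSpec]:
    return (VialSpec(440.0, params.costs.p_440), VialSpec(150.0, params.costs.p_150))


def doses_per_year(schedule: DoseSchedule = DoseSchedule()) -> int:
    """Number of administrations at weeks 0, interval, 2*interval, ... < duration."""
    return len(range(0, schedule.duration_weeks, schedule.interval_weeks))


def dose_amounts_mg(weight_kg: float, schedule: DoseSchedule = DoseSchedule()) -> list[float]:
    """Per-administration milligram requirements: loading first, then maintenance."""
    if weight_kg <= 0:
        raise ValueError("weight must be > 0")
    k = doses_per_year(schedule)
    return [schedule.loading_mg_per_kg * weight_kg] + \
           [schedule.maintenance_mg_per_kg * weight_kg] * (k - 1)


def _cheapest_cover(mg: float, vials: tuple[VialSpec, ...]) -> float:
    """Cheapest integer vial combination whose total size covers ``mg``.

    Exhaustive search: each vial count ranges up to the number needed to cover
    the dose alone, which is tiny for clinical doses and two vial sizes.
    """
    bounds = [range(ceil(mg / v.size_mg) + 1) for v in vials]
    best = None
    for counts in _iproduct(*bounds):
        total_mg = sum(n * v.size_mg for n, v in zip(counts, vials))
        if total_mg >= mg:
            cost = sum(n * v.price_vnd for n, v in zip(counts, vials))
            if best is None or cost < best:
                best = cost
    return best


def drug_cost_no_sharing(weight_kg: float, schedule: DoseSchedule = DoseSchedule(),
                         vials: tuple[VialSpec, ...] | None = None,
                         params: ParameterSet | None = None) -> float:
    """Annual drug cost when partial vials are discarded (whole vials per dose)."""
    if vials is None:
        vials = default_vials(params if params is not None else ParameterSet())
    if not vials:
        raise ValueError("at least one vial specification is required")
    return sum(_cheapest_cover(mg, tuple(vials)) for mg in dose_amounts_mg(weight_kg, schedule))


def drug_cost_sharing(weight_kg: float, schedule: DoseSchedule = DoseSchedule(),
                      vials: tuple[VialSpec, ...] | None = None,
                      params: ParameterSet | None = None) -> float:
    """Annual drug cost under ideal vial sharing: exact mg at the best VND/mg."""
    if vials is None:
        vials = default_vials(params if params is not None else ParameterSet())
    if not vials:
        raise ValueError("at least one vial specification is required")
    total_mg = sum(dose_amounts_mg(weight_kg, schedule))
    per_mg = min(v.price_vnd / v.size_mg for v in vials)
    return total_mg * per_mg


@dataclass(frozen=True)
class TherapyCostBreakdown:
    """Components of the one-year adjuvant trastuzumab therapy cost (VND)."""

    drug: int
    her2_detection: int
    other_direct_medical: int
    direct_nonmedical: int
    paclitaxel: int

    @property
    def total(self) -> int:
        return (self.drug + self.her2_detection + self.other_direct_medical
                + self.direct_nonmedical + self.paclitaxel)


def therapy_cost_total(components: TherapyCostBreakdown) -> int:
    """Exact integer sum of the therapy cost components."""
    for f in ("drug", "her2_detection", "other_direct_medical",
              "direct_nonmedical", "paclitaxel"):
        if getattr(components, f) < 0:
            raise ValueError(f"component {f} must be >= 0")
    return components.total


def resolved_drug_cost(params: ParameterSet, sharing: bool = False) -> float:
    """One-year trastuzumab drug cost under the configured costing mode."""
    if params.settings.drug_cost_mode == "computed":
        fn = drug_cost_sharing if sharing else drug_cost_no_sharing
        return fn(params.settings.patient_weight, params=params)
    if sharing:
        if params.costs.trast_drug_sharing is None:
            return drug_cost_sharing(params.settings.patient_weight, params=params)
        return params.costs.trast_drug_sharing
    return params.costs.trast_drug


def therapy_breakdown(params: ParameterSet, sharing: bool = False,
                      exclude_paclitaxel: bool = False) -> TherapyCostBreakdown:
    """Year-one cost components for the trastuzumab arm.

    Paclitaxel is given concurrently during the same hospitalisations, so only
    its drug cost should add to the combination arm; absent a published
    drug-only figure the full paclitaxel treatment cost is counted in both
    arms (and cancels in the increment) unless ``paclitaxel_drug_only`` is
    configured.
    """
    c = params.costs
    pac = 0.0 if exclude_paclitaxel else (
        c.paclitaxel_drug_only if c.paclitaxel_drug_only is not None
        else c.paclitaxel_treatment)
    return TherapyCostBreakdown(
        drug=round(resolved_drug_cost(params, sharing)),
        her2_detection=round(c.her2_detection),
        other_direct_medical=round(c.trast_other_direct_medical),
        direct_nonmedical=round(c.trast_direct_nonmedical),
        paclitaxel=round(pac),
    )


def arm_year_one_cost(arm: str, params: ParameterSet, sharing: bool = False) -> float:
    """One-off first-year therapy cost entering the model at cycle 0."""
    if arm == "trastuzumab":
        return float(therapy_breakdown(params, sharing=sharing).total)
    if arm == "chemo":
        return float(params.costs.paclitaxel_treatment)
    raise ValueError(f"unknown arm {arm!r}")


def year_one_cost_values(arm: str, values, sharing: bool = False):
    """Vectorised first-year cost from resolved (possibly sampled) values."""
    pac = values.get("paclitaxel_drug_only", None)
    if pac is None:
        pac = values["paclitaxel_treatment"]
    if arm == "trastuzumab":
        drug = values["trast_drug_sharing"] if sharing else values["trast_drug"]
        return (drug + values["her2_detection"] + values["trast_other_direct_medical"]
                + values["trast_direct_nonmedical"] + pac)
    if arm == "chemo":
        return values["paclitaxel_treatment"]
    raise ValueError(f"unknown arm {arm!r}")


def vnd_to_usd(amount_vnd: float, rate: float = 22_745.0) -> int:
    """Convert VND to US$ at the configured exchange rate, rounded to units."""
    if rate <= 0:
        raise ValueError("exchange rate must be > 0")
    return int(round(amount_vnd / rate))


def price_reduction_percent(current: float, target: float) -> int:
    """Percentage reduction from a current price to a target price.

    A target above the current price signals a price increase and returns a
    negative reduction rather than raising.
    """
    if current <= 0:
        raise ValueError("current price must be > 0")
    if target < 0:
        raise ValueError("target price must be >= 0")
    return int(round(100.0 * (1.0 - target / current)))
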