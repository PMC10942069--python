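"""Model parameters, configuration I/O and probabilistic-sensitivity distributions.

The parameter set mirrors the published inputs of a decision model comparing
one-year adjuvant trastuzumab plus chemotherapy against chemotherapy alone in
HER2+ early-stage breast cancer: treatment-effect hazard ratios, annual
transition probabilities, health-state utilities, and aggregate 2020 VND costs,
together with run settings (cohort start age, discount rate, willingness-to-pay
thresholds, exchange rate, vial prices and dosing inputs).

Configuration files are INI-style with sections ``[clinical]``, ``[utilities]``,
``[costs]``, ``[settings]`` and ``[psa]``; keys match the dataclass field names
below.  For probabilistic sensitivity analysis each parameter is given a
distribution family by role -- beta for probabilities and utilities, lognormal
for hazard ratios, gamma for costs -- fitted by the method of moments with the
standard deviation taken as (hi - lo) / 3.92, i.e. the stated range is read as
a 95% interval.
"""

from __future__ import annotations

import configparser
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "ConfigError",
    "InfeasibleMomentsError",
    "ClinicalParams",
    "UtilityParams",
    "CostParams",
    "ModelSettings",
    "PSASpec",
    "ParameterSet",
    "ParamDistribution",
    "PSASample",
    "fit_beta",
    "fit_gamma",
    "fit_lognormal_hr",
    "build_distributions",
    "sample_psa_arrays",
    "sample_psa",
    "eligible_population",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    """A configuration value is missing, unknown, or out of range."""


class InfeasibleMomentsError(ValueError):
    """The requested mean/variance pair admits no beta distribution."""


# --------------------------------------------------------------------------
# parameter blocks
# --------------------------------------------------------------------------

@dataclass
class ClinicalParams:
    """Treatment-effect ratios and annual transition probabilities."""

    hr_dfs: float = 0.760        # disease-free survival HR, trastuzumab arm
    hr_lrr: float = 0.580        # local-regional recurrence HR
    hr_met: float = 0.480        # distant metastasis HR
    p_lrr_base: float = 0.0294   # annual LRR probability without trastuzumab
    p_met_base: float = 0.0785   # annual metastasis probability without trastuzumab
    p_dfs_after_lrr: float = 0.100   # annual LRR -> disease-free probability
    rr_met_after_lrr: float = 3.64   # metastasis hazard multiplier after LRR
    p_chf_trast: float = 0.198   # first-year CHF probability, trastuzumab arm
    p_chf_chemo: float = 0.007   # first-year CHF probability, chemotherapy arm
    p_death_met: float = 0.295   # annual breast-cancer death probability in metastasis

    _PROBS = (
        "p_lrr_base", "p_met_base", "p_dfs_after_lrr",
        "p_chf_trast", "p_chf_chemo", "p_death_met",
    )
    _RATIOS = ("hr_dfs", "hr_lrr", "hr_met", "rr_met_after_lrr")

    def validate(self) -> None:
        for name in self._PROBS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"clinical.{name} = {v!r} is not a probability in [0, 1]")
        for name in self._RATIOS:
            v = getattr(self, name)
            if not v > 0.0:
                raise ConfigError(f"clinical.{name} = {v!r} must be strictly positive")


@dataclass
class UtilityParams:
    """Annual utility weights per health state (death is fixed at 0)."""

    u_dfs: float = 0.832
    u_lrr: float = 0.828
    u_dfs_post_lrr: float = 0.789
    u_dfs_chf: float = 0.670
    u_met: float = 0.762

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"utilities.{f.name} = {v!r} is not in [0, 1]")


@dataclass
class CostParams:
    """Aggregate costs in 2020 VND (societal perspective).

    ``trast_drug`` is the published one-year trastuzumab drug aggregate used by
    the model; ``trast_drug_sharing`` the corresponding aggregate when vials
    are shared among concurrent patients.  ``paclitaxel_drug_only`` is the
    drug-only paclitaxel cost counted in the combination arm; when ``None`` the
    full paclitaxel treatment cost is used in both arms so it cancels in the
    increment.
    """

    trast_drug: float = 787_384_650.0
    her2_detection: float = 686_116.0
    trast_other_direct_medical: float = 27_040_970.0
    trast_direct_nonmedical: float = 5_724_180.0
    paclitaxel_treatment: float = 32_116_418.0
    paclitaxel_drug_only: float | None = None
    c_dfs: float = 1_400_846.0
    c_lrr: float = 216_688_208.0
    c_dfs_post_lrr: float = 1_400_846.0
    c_met: float = 131_065_482.0
    c_dfs_chf: float = 9_529_840.0
    p_440: float = 45_596_775.0       # Herceptin 440 mg vial price
    p_150: float = 15_550_710.0       # Herceptin 150 mg vial price
    trast_drug_sharing: float | None = 570_022_437.0

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if v < 0:
                raise ConfigError(f"costs.{f.name} = {v!r} must be non-negative")


@dataclass
class ModelSettings:
    """Run settings: cohort, horizon, discounting and costing conventions."""

    start_age: int = 50
    max_age: int = 100
    cycle_length: float = 1.0            # years per cycle
    discount_rate: float = 0.03          # applied to costs and effects
    benefit_duration: int = 5            # cycles of trastuzumab effect
    recurrence_cutoff: int = 20          # no new recurrences from this cycle on
    half_cycle_correction: bool = False
    exchange_rate: float = 22_745.0      # VND per US$
    wtp_thresholds: tuple[float, ...] = (83_000_000.0, 249_000_000.0)
    patient_weight: float = 52.9         # kg
    cohort_size: int = 5_052
    hr_transform: str = "rate"           # "rate" (1-(1-p)^HR) or "linear" (p*HR)
    drug_cost_mode: str = "printed"      # "printed" aggregate or "computed" from vials

    def validate(self) -> None:
        if self.discount_rate < 0:
            raise ConfigError(f"settings.discount_rate = {self.discount_rate!r} must be >= 0")
        if self.cycle_length <= 0:
            raise ConfigError("settings.cycle_length must be > 0")
        horizon = self.max_age - self.start_age
        if not (self.benefit_duration <= self.recurrence_cutoff <= horizon):
            raise ConfigError(
                "settings must satisfy benefit_duration <= recurrence_cutoff <= horizon; "
                f"got {self.benefit_duration} <= {self.recurrence_cutoff} <= {horizon}"
            )
        if self.patient_weight <= 0:
            raise ConfigError("settings.patient_weight must be > 0")
        if self.cohort_size < 0:
            raise ConfigError("settings.cohort_size must be >= 0")
        if self.exchange_rate <= 0:
            raise ConfigError("settings.exchange_rate must be > 0")
        if self.hr_transform not in ("rate", "linear"):
            raise ConfigError(f"settings.hr_transform = {self.hr_transform!r} unknown")
        if self.drug_cost_mode not in ("printed", "computed"):
            raise ConfigError(f"settings.drug_cost_mode = {self.drug_cost_mode!r} unknown")


@dataclass
class PSASpec:
    """Uncertainty ranges for probabilistic sensitivity analysis.

    ``default_rel_range`` applies +-fraction around the base value to every
    sampled parameter that has no explicit ``(lo, hi)`` override (e.g. a
    published 95% CI transcribed into the config).
    """

    default_rel_range: float = 0.10
    overrides: dict[str, tuple[float, float]] = field(default_factory=dict)

    def validate(self) -> None:
        if not 0.0 <= self.default_rel_range <= 1.0:
            raise ConfigError("psa.default_rel_range must be in [0, 1]")
        for name, (lo, hi) in self.overrides.items():
            if lo > hi:
                raise ConfigError(f"psa.{name} range has lo > hi: ({lo}, {hi})")


@dataclass
class ParameterSet:
    """All model inputs: clinical, utilities, costs, settings, PSA spec."""

    clinical: ClinicalParams = field(default_factory=ClinicalParams)
    utilities: UtilityParams = field(default_factory=UtilityParams)
    costs: CostParams = field(default_factory=CostParams)
    settings: ModelSettings = field(default_factory=ModelSettings)
    psa: PSASpec = field(default_factory=PSASpec)

    def validate(self) -> "ParameterSet":
        self.clinical.validate()
        self.utilities.validate()
        self.costs.validate()
        self.settings.validate()
        self.psa.validate()
        return self

    # -- flat value access ------------------------------------------------
    def value_items(self) -> Iterator[tuple[str, float]]:
        """Yield (name, value) for every continuous model parameter."""
        for block in (self.clinical, self.utilities, self.costs):
            for f in fields(block):
                if f.name.startswith("_"):
                    continue
                v = getattr(block, f.name)
                if v is not None:
                    yield f.name, float(v)

    def values(self) -> dict[str, float]:
        return dict(self.value_items())

    def with_values(self, overrides: Mapping[str, float]) -> "ParameterSet":
        """Return a copy with named clinical/utility/cost values replaced."""
        new = ParameterSet(
            clinical=replace(self.clinical),
            utilities=replace(self.utilities),
            costs=replace(self.costs),
            settings=replace(self.settings),
            psa=PSASpec(self.psa.default_rel_range, dict(self.psa.overrides)),
        )
        known = {f.name: b for b in (new.clinical, new.utilities, new.costs)
                 for f in fields(b) if not f.name.startswith("_")}
        for name, value in overrides.items():
            if name not in known:
                raise ConfigError(f"unknown parameter {name!r} in override")
            setattr(known[name], name, float(value))
        return new.validate()


# --------------------------------------------------------------------------
# distribution fitting
# --------------------------------------------------------------------------

Z95 = 3.92  # width of a 95% normal interval in standard deviations


def fit_beta(mean: float, lo: float, hi: float) -> tuple[float, float]:
    """Method-of-moments beta fit with SD = (hi - lo) / 3.92.

    Returns shape parameters (alpha, beta) whose analytic mean equals ``mean``.
    """
    if not (0.0 <= lo <= mean <= hi <= 1.0) or not lo < hi:
        raise ValueError(f"require 0 <= lo <= mean <= hi <= 1 with lo < hi; got ({mean}, {lo}, {hi})")
    sd = (hi - lo) / Z95
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"variance {var:.6g} >= mean(1-mean) = {mean * (1 - mean):.6g}; no beta has these moments"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def fit_gamma(mean: float, lo: float, hi: float) -> tuple[float, float]:
    """Method-of-moments gamma fit (shape, scale) with SD = (hi - lo) / 3.92."""
    if mean <= 0:
        raise ValueError(f"gamma mean must be positive, got {mean}")
    if not (0.0 < lo <= mean <= hi) or not lo < hi:
        raise ValueError(f"require 0 < lo <= mean <= hi with lo < hi; got ({mean}, {lo}, {hi})")
    sd = (hi - lo) / Z95
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


def fit_lognormal_hr(hr: float, lo: float, hi: float) -> tuple[float, float]:
    """Lognormal fit for a hazard ratio from its 95% CI.

    mu = ln(hr), sigma = (ln hi - ln lo) / 3.92; the fitted median is ``hr``.
    A degenerate interval (lo == hi) yields sigma = 0.
    """
    if hr <= 0 or lo <= 0 or hi <= 0:
        raise ValueError(f"hazard ratio and bounds must be positive; got ({hr}, {lo}, {hi})")
    if not lo <= hr <= hi:
        raise ValueError(f"require lo <= hr <= hi; got ({hr}, {lo}, {hi})")
    return math.log(hr), (math.log(hi) - math.log(lo)) / Z95


@dataclass(frozen=True)
class ParamDistribution:
    """One parameter's PSA distribution: family chosen by parameter role."""

    name: str
    family: str          # beta | gamma | lognormal | point
    base: float
    lo: float
    hi: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "point" or self.lo == self.hi or self.base == 0.0:
            return np.full(n, self.base)
        if self.family == "beta":
            a, b = fit_beta(self.base, self.lo, self.hi)
            return rng.beta(a, b, size=n)
        if self.family == "gamma":
            shape, scale = fit_gamma(self.base, self.lo, self.hi)
            return rng.gamma(shape, scale, size=n)
        if self.family == "lognormal":
            mu, sigma = fit_lognormal_hr(self.base, self.lo, self.hi)
            return rng.lognormal(mu, sigma, size=n)
        raise ValueError(f"unknown family {self.family!r}")


# roles drive the distribution family assignment
_BETA_PARAMS = set(ClinicalParams._PROBS) | {f.name for f in fields(UtilityParams)}
_LOGNORMAL_PARAMS = set(ClinicalParams._RATIOS)
# vial prices are inputs to the vial calculator, not model-state costs, and the
# published drug aggregate already carries the price uncertainty
_GAMMA_EXCLUDE = {"p_440", "p_150", "trast_drug_sharing"}


def build_distributions(params: ParameterSet) -> dict[str, ParamDistribution]:
    """Assign each sampled parameter its PSA distribution.

    beta for probabilities/utilities, lognormal for hazard ratios, gamma for
    costs; ranges come from explicit ``[psa]`` overrides when present, else
    +-``default_rel_range`` around the base value.
    """
    m = params.psa.default_rel_range
    dists: dict[str, ParamDistribution] = {}
    for name, base in params.value_items():
        if name in _BETA_PARAMS:
            family = "beta"
        elif name in _LOGNORMAL_PARAMS:
            family = "lognormal"
        elif name not in _GAMMA_EXCLUDE:
            family = "gamma"
        else:
            continue
        if name in params.psa.overrides:
            lo, hi = params.psa.overrides[name]
        else:
            lo, hi = base * (1.0 - m), base * (1.0 + m)
        if family == "beta":
            hi = min(hi, 1.0)
        if base == 0.0 or lo == hi:
            family = "point"
        dists[name] = ParamDistribution(name, family, base, lo, hi)
    return dists


@dataclass(frozen=True)
class PSASample:
    """One joint Monte-Carlo parameter draw."""

    index: int
    values: dict[str, float]
    seed: int


def sample_psa_arrays(params: ParameterSet, n: int, seed: int) -> dict[str, np.ndarray]:
    """Draw ``n`` independent joint parameter samples as name -> array.

    Parameters without an assigned distribution (vial prices, the sharing
    aggregate) are carried at their base value so every sample resolves to a
    complete parameter set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    dists = build_distributions(params)
    out: dict[str, np.ndarray] = {}
    for name, base in params.value_items():
        if name in dists:
            out[name] = dists[name].sample(rng, n)
        else:
            out[name] = np.full(n, base)
    return out


def sample_psa(params: ParameterSet, n: int, seed: int) -> list[PSASample]:
    """Draw ``n`` joint samples, each validated against the parameter bounds."""
    arrays = sample_psa_arrays(params, n, seed)
    samples = []
    for i in range(n):
        values = {k: float(v[i]) for k, v in arrays.items()}
        params.with_values(values)  # raises if any draw is out of range
        samples.append(PSASample(index=i, values=values, seed=seed))
    return samples


# --------------------------------------------------------------------------
# eligible population
# --------------------------------------------------------------------------

def eligible_population(
    n_patients: float,
    early_frac: float,
    her2_frac: float,
    coverage: float,
    cardiac_pass: float,
) -> int:
    """Size of the treatment-eligible cohort.

    Incident breast-cancer patients, narrowed successively to those diagnosed
    early, HER2-positive, covered by treatment access, and passing the baseline
    cardiac assessment; the product is rounded to the nearest integer.
    """
    if n_patients < 0:
        raise ValueError("n_patients must be >= 0")
    for label, f in (("early_frac", early_frac), ("her2_frac", her2_frac),
                     ("coverage", coverage), ("cardiac_pass", cardiac_pass)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{label} = {f!r} must be in [0, 1]")
    return int(round(n_patients * early_frac * her2_frac * coverage * cardiac_pass))


# --------------------------------------------------------------------------
# configuration I/O
# --------------------------------------------------------------------------

_OPTIONAL_DEFAULTS = {
    ("settings", "max_age"), ("settings", "cycle_length"),
    ("settings", "discount_rate"), ("settings", "half_cycle_correction"),
    ("settings", "hr_transform"), ("settings", "drug_cost_mode"),
    ("settings", "wtp_thresholds"),
    ("costs", "paclitaxel_drug_only"), ("costs", "trast_drug_sharing"),
}

_BOOL = {"true": True, "yes": True, "1": True, "on": True,
         "false": False, "no": False, "0": False, "off": False}


def _parse_scalar(section: str, key: str, raw: str):
    if key == "wtp_thresholds":
        try:
            return tuple(float(x) for x in raw.replace(",", " ").split())
        except ValueError:
            raise ConfigError(f"{section}.{key} = {raw!r} is not a list of numbers") from None
    if key == "half_cycle_correction":
        if raw.strip().lower() not in _BOOL:
            raise ConfigError(f"{section}.{key} = {raw!r} is not a boolean")
        return _BOOL[raw.strip().lower()]
    if key in ("hr_transform", "drug_cost_mode"):
        return raw.strip()
    if key in ("start_age", "max_age", "benefit_duration", "recurrence_cutoff", "cohort_size"):
        try:
            return int(raw.replace("_", ""))
        except ValueError:
            raise ConfigError(f"{section}.{key} = {raw!r} is not an integer") from None
    try:
        return float(raw.replace("_", ""))
    except ValueError:
        raise ConfigError(f"{section}.{key} = {raw!r} is not a number") from None


def load_config(path: str | Path) -> ParameterSet:
    """Load and validate a parameter configuration file.

    Unknown sections or keys, missing required keys and out-of-range values all
    raise :class:`ConfigError` naming the offending field.  Defaults are
    applied only to the documented optional fields (e.g. a 3%/year discount
    rate when ``discount_rate`` is omitted).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    cp = configparser.ConfigParser(inline_comment_prefixes=("#", ";"))
    cp.optionxform = str  # keys are case-sensitive field names
    try:
        cp.read(path)
    except configparser.Error as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc

    blocks = {
        "clinical": ClinicalParams(),
        "utilities": UtilityParams(),
        "costs": CostParams(),
        "settings": ModelSettings(),
    }
    psa = PSASpec()

    for section in cp.sections():
        if section == "psa":
            continue
        if section not in blocks:
            raise ConfigError(f"unknown section [{section}]")
        block = blocks[section]
        known = {f.name for f in fields(block) if not f.name.startswith("_")}
        for key, raw in cp.items(section):
            if key not in known:
                raise ConfigError(f"unknown key {section}.{key}")
            setattr(block, key, _parse_scalar(section, key, raw))

    for section, block in blocks.items():
        if section not in cp:
            raise ConfigError(f"missing section [{section}]")
        present = set(cp.options(section))
        for f in fields(block):
            if f.name.startswith("_") or f.name in present:
                continue
            if (section, f.name) not in _OPTIONAL_DEFAULTS:
                raise ConfigError(f"missing required key {section}.{f.name}")

    if "psa" in cp:
        for key, raw in cp.items("psa"):
            if key == "default_rel_range":
                psa.default_rel_range = float(raw)
            elif key.endswith("_ci"):
                lo_hi = [float(x) for x in raw.replace(",", " ").split()]
                if len(lo_hi) != 2:
                    raise ConfigError(f"psa.{key} must give two numbers (lo hi)")
                psa.overrides[key[:-3]] = (lo_hi[0], lo_hi[1])
            else:
                raise ConfigError(f"unknown key psa.{key}")

    pset = ParameterSet(
        clinical=blocks["clinical"], utilities=blocks["utilities"],
        costs=blocks["costs"], settings=blocks["settings"], psa=psa,
    )
    return pset.validate()


def _format_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, tuple):
        return ", ".join(_format_scalar(x) for x in v)
    if isinstance(v, float) and v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return repr(v) if not isinstance(v, str) else v


def save_config(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter set back to the INI format (lossless round trip)."""
    cp = configparser.ConfigParser()
    cp.optionxform = str
    for section, block in (("clinical", params.clinical), ("utilities", params.utilities),
                           ("costs", params.costs), ("settings", params.settings)):
        cp[section] = {}
        for f in fields(block):
            if f.name.startswith("_"):
                continue
            v = getattr(block, f.name)
            if v is None:
                continue
            cp[section][f.name] = _format_scalar(v)
    cp["psa"] = {"default_rel_range": repr(params.psa.default_rel_range)}
    for name, (lo, hi) in params.psa.overrides.items():
        cp["psa"][f"{name}_ci"] = f"{lo!r}, {hi!r}"
    with open(path, "w") as fh:
        cp.write(fh)
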