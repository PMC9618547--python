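"""Model parameterization: health states, costs, utilities, transitions.

The model evaluates three management strategies for infants with spinal
muscular atrophy (SMA) type I — standard of care (SOC), nusinersen, and
onasemnogene abeparvovec (AVXS-101) — over a lifetime horizon with a
monthly cycle.  This module defines the validated parameter containers,
the packaged base-case preset (2020 Australian dollars), and YAML I/O.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import yaml


class ValidationError(ValueError):
    """A model parameter violates its documented constraints."""


class SchemaError(KeyError):
    """A required key is missing or unknown in a config file."""


class HealthState(enum.IntEnum):
    """The five health states of the cohort model.

    ``NOT_SITTING`` (SMA type I, ventilation-free) is the entry state.
    ``SITTING`` and ``WALKING`` represent achieved motor milestones
    (type II / III-like prognosis); ``PAV`` is permanent assisted
    ventilation; ``DEAD`` is absorbing.
    """

    NOT_SITTING = 0
    SITTING = 1
    WALKING = 2
    PAV = 3
    DEAD = 4


#: Allowed transitions out of each state (self-transitions implicit).
ALLOWED_TRANSITIONS = {
    HealthState.NOT_SITTING: {
        HealthState.SITTING,
        HealthState.WALKING,
        HealthState.PAV,
        HealthState.DEAD,
    },
    HealthState.SITTING: {HealthState.DEAD},
    HealthState.WALKING: {HealthState.DEAD},
    HealthState.PAV: {HealthState.DEAD},
    HealthState.DEAD: set(),
}

LIVING_STATES = (
    HealthState.NOT_SITTING,
    HealthState.SITTING,
    HealthState.WALKING,
    HealthState.PAV,
)

STRATEGY_NAMES = ("SOC", "nusinersen", "AVXS-101")


def _check_prob(name: str, value: float) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must be in [0, 1], got {value}")
    return float(value)


def _check_nonneg(name: str, value: float) -> float:
    if value < 0:
        raise ValidationError(f"{name} must be non-negative, got {value}")
    return float(value)


@dataclass
class DiscountSpec:
    """Annual discount rates and the model cycle length.

    Rates are annual proportions; discount factors use annual
    compounding, ``(1 + rate) ** (-t_years)``.
    """

    annual_rate_costs: float = 0.05
    annual_rate_effects: float = 0.05
    cycle_length_months: float = 1.0

    def __post_init__(self) -> None:
        for nm in ("annual_rate_costs", "annual_rate_effects"):
            r = getattr(self, nm)
            if not 0.0 <= r < 1.0:
                raise ValidationError(f"{nm} must be in [0, 1), got {r}")
        if self.cycle_length_months <= 0:
            raise ValidationError("cycle_length_months must be positive")


@dataclass
class CostSet:
    """Per-state costs per cycle and per-strategy drug/administration costs.

    ``state_costs`` are applied once per monthly cycle.  ``admin_items``
    are the itemised administration/monitoring components charged with
    every dose; their exact sum is the per-dose administration cost.
    """

    state_costs: dict  # HealthState -> AUD per cycle
    acquisition_cost: dict  # strategy name -> AUD per dose
    admin_items: dict  # strategy name -> list of AUD components
    state_cost_intervals: dict = field(default_factory=dict)  # state -> (lo, hi)
    acquisition_intervals: dict = field(default_factory=dict)  # name -> (lo, hi)

    def __post_init__(self) -> None:
        self.state_costs = {HealthState(k): _check_nonneg(f"state cost {k}", v)
                            for k, v in self.state_costs.items()}
        self.state_costs.setdefault(HealthState.DEAD, 0.0)
        for name, v in self.acquisition_cost.items():
            _check_nonneg(f"acquisition cost {name}", v)
        for name, items in self.admin_items.items():
            for c in items:
                _check_nonneg(f"admin item of {name}", c)
        pav = self.state_costs.get(HealthState.PAV, 0.0)
        ns = self.state_costs.get(HealthState.NOT_SITTING, 0.0)
        if pav < ns:
            raise ValidationError(
                "PAV state cost must be >= NOT_SITTING state cost "
                "(constructed as NOT_SITTING plus ventilation-specific costs)")

    def admin_cost(self, strategy: str) -> float:
        return total_admin_cost(self.admin_items.get(strategy, []))

    def dose_cost(self, strategy: str) -> float:
        """Total per-dose cost: acquisition plus administration."""
        return total_dose_cost(
            self.acquisition_cost.get(strategy, 0.0), self.admin_cost(strategy))


def total_admin_cost(components: Sequence[float]) -> float:
    """Exact sum of itemised administration/monitoring costs (AUD)."""
    total = 0.0
    for c in components:
        if c < 0:
            raise ValidationError(f"administration component must be >= 0, got {c}")
        total += c
    return total


def display_round(value: float, decimals: int = 0) -> float:
    """Half-up rounding for display (published tables round .5 up)."""
    scale = 10 ** decimals
    out = math.floor(value * scale + 0.5) / scale
    return int(out) if decimals == 0 else out


def total_dose_cost(acquisition: float, admin: float) -> float:
    """Per-dose total cost: drug acquisition plus administration (AUD)."""
    _check_nonneg("acquisition", acquisition)
    _check_nonneg("admin", admin)
    return acquisition + admin


@dataclass
class UtilitySet:
    """Annual QALY weight per state, with SDs for probabilistic analysis.

    A cohort member accrues ``utility * cycle_length / 12`` QALYs per
    cycle lived in a state.  DEAD has utility 0 by construction.
    """

    utilities: dict  # HealthState -> weight in [0, 1]
    sds: dict = field(default_factory=dict)  # HealthState -> SD

    def __post_init__(self) -> None:
        self.utilities = {HealthState(k): _check_prob(f"utility {k}", v)
                          for k, v in self.utilities.items()}
        self.utilities[HealthState.DEAD] = 0.0
        self.sds = {HealthState(k): _check_nonneg(f"utility SD {k}", v)
                    for k, v in self.sds.items()}


@dataclass
class MilestoneSchedule:
    """End-of-trial milestone proportions and the window to allocate them.

    ``sitting_frac`` / ``walking_frac`` are the fractions of the initial
    cohort that reach the SITTING / WALKING milestone by the end of the
    trial follow-up window (``window_cycles`` monthly cycles).  The
    per-cycle milestone probability is solved at run time so the
    cumulative inflow matches these fractions under competing exits.
    """

    sitting_frac: float = 0.0
    walking_frac: float = 0.0
    window_cycles: int = 0
    protected: bool = False  # no death/PAV exits during the window
    allocation: str = "immediate"  # "immediate" (first cycle) or "uniform"

    def __post_init__(self) -> None:
        _check_prob("sitting_frac", self.sitting_frac)
        _check_prob("walking_frac", self.walking_frac)
        if self.sitting_frac + self.walking_frac > 1.0 + 1e-12:
            raise ValidationError("milestone fractions must sum to <= 1")
        if self.window_cycles < 0:
            raise ValidationError("window_cycles must be >= 0")
        if self.window_cycles == 0 and (self.sitting_frac or self.walking_frac):
            raise ValidationError("non-zero milestone fractions need a window")
        if self.allocation not in ("immediate", "uniform"):
            raise ValidationError(
                f"unknown milestone allocation {self.allocation!r}")


@dataclass
class TransitionSpec:
    """Monthly transition probabilities and survival models for one arm.

    The SITTING->DEAD Weibull is stored with its published parameters
    (lambda, p); ``weibull_form`` fixes how they map onto a survival
    function:

    * ``"scale_months"`` — S(t) = exp(-(lambda * t_months)**p), i.e.
      lambda is a scale rate per month (the calibrated base-case
      reading: it reproduces the published cohort results).
    * ``"rate_years"`` — S(t) = exp(-lambda * t_years**p), lambda a
      proportional-hazards rate per year**p.
    """

    ns_to_death: float
    ns_to_pav: float
    pav_to_death: float
    weibull_lambda: float
    weibull_p: float
    weibull_form: str = "scale_months"
    milestones: MilestoneSchedule = field(default_factory=MilestoneSchedule)
    intervals: dict = field(default_factory=dict)  # param name -> (lo, hi)

    def __post_init__(self) -> None:
        _check_prob("ns_to_death", self.ns_to_death)
        _check_prob("ns_to_pav", self.ns_to_pav)
        _check_prob("pav_to_death", self.pav_to_death)
        if self.ns_to_death + self.ns_to_pav > 1.0:
            raise ValidationError("NOT_SITTING outgoing probabilities exceed 1")
        if self.weibull_lambda <= 0 or self.weibull_p <= 0:
            raise ValidationError("Weibull parameters must be positive")
        if self.weibull_form not in ("scale_months", "rate_years"):
            raise ValidationError(f"unknown weibull_form {self.weibull_form!r}")

    def weibull_rate_per_yearp(self) -> float:
        """Effective rate so that S(t_years) = exp(-rate * t_years**p)."""
        if self.weibull_form == "rate_years":
            return self.weibull_lambda
        return (self.weibull_lambda * 12.0) ** self.weibull_p


@dataclass
class StrategySpec:
    """Dosing calendar and treatment-arm assignment for one strategy."""

    name: str
    loading_doses_months: tuple = ()  # explicit dose times (months)
    maintenance_start_month: Optional[float] = None
    maintenance_interval_months: Optional[float] = None
    one_off: bool = False
    dosed_states: tuple = (HealthState.NOT_SITTING, HealthState.SITTING,
                           HealthState.WALKING)

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_NAMES:
            raise ValidationError(
                f"unknown strategy {self.name!r}; expected one of {STRATEGY_NAMES}")
        if self.one_off and tuple(self.loading_doses_months) != (0.0,):
            raise ValidationError("a one-off therapy has exactly one dose at t=0")
        self.loading_doses_months = tuple(float(t) for t in self.loading_doses_months)
        self.dosed_states = tuple(HealthState(s) for s in self.dosed_states)

    def dose_times(self, horizon_months: float) -> list:
        """All scheduled dose times (months) within the horizon."""
        times = [t for t in self.loading_doses_months if t <= horizon_months]
        if self.maintenance_interval_months:
            t = self.maintenance_start_month
            while t <= horizon_months:
                times.append(t)
                t += self.maintenance_interval_months
        return times


@dataclass
class ModelSpec:
    """Complete parameterization of one model run."""

    horizon_years: float
    start_age_years: float
    discount: DiscountSpec
    costs: CostSet
    utilities: UtilitySet
    transitions: dict  # strategy name -> TransitionSpec
    strategies: list  # of StrategySpec
    lifetable: "object" = None  # survival.LifeTable; set by presets/loaders
    half_cycle_correction: bool = True

    def __post_init__(self) -> None:
        if self.horizon_years <= 0:
            raise ValidationError("horizon must be positive")
        if self.start_age_years < 0:
            raise ValidationError("start age must be >= 0")
        for s in self.strategies:
            if s.name not in self.transitions:
                raise ValidationError(f"no transition spec for strategy {s.name!r}")

    # -- convenience accessors -------------------------------------------
    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years * 12 / self.discount.cycle_length_months))

    def strategy(self, name: str) -> StrategySpec:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(name)

    def utility(self, state: HealthState) -> float:
        return self.utilities.utilities[state]

    def state_cost(self, state: HealthState) -> float:
        return self.costs.state_costs.get(state, 0.0)


# ---------------------------------------------------------------------------
# Base-case preset (2020 AUD)
# ---------------------------------------------------------------------------

NUSINERSEN_ADMIN_ITEMS = (
    77.65,   # intrathecal injection, lumbar puncture
    164.4,   # intrathecal injection, CSF drainage
    51.5,    # specialist attendance
    16.95,   # thrombocytopenia monitoring
    9.7,     # renal toxicity monitoring
    102.0,   # anaesthesia for lumbar puncture
    34.3,    # imaging (ultrasound/fluoroscopy average)
    1839.0,  # inpatient per diem
    281.0,   # inpatient anaesthesia
)

AVXS_ADMIN_ITEMS = (
    67.1,    # single-dose intravenous infusion
    15.65,   # anti-AAV9 diagnostic test
    17.7,    # laboratory monitoring
    14.53,   # prednisolone
)


def base_case_spec(lifetable=None) -> ModelSpec:
    """The packaged base-case parameter set.

    Monthly transition probabilities come from the pivotal trials
    (sham-controlled nusinersen trial, n=121; single-arm gene-therapy
    trial, n=12), ventilation survival and type II survival from the
    published literature, and costs/utilities from Australian sources,
    all in 2020 AUD.  ``lifetable`` supplies background mortality for
    the WALKING state; when omitted, a synthetic low-mortality
    population life table is used.
    """
    from . import survival, synthetic  # deferred to avoid import cycle

    if lifetable is None:
        lifetable = synthetic.synthetic_lifetable()

    costs = CostSet(
        state_costs={
            HealthState.NOT_SITTING: 23569.0,
            HealthState.SITTING: 9896.0,
            HealthState.WALKING: 6644.0,
            HealthState.PAV: 27693.0,
        },
        acquisition_cost={"nusinersen": 110000.0, "AVXS-101": 3054344.0},
        admin_items={"nusinersen": list(NUSINERSEN_ADMIN_ITEMS),
                     "AVXS-101": list(AVXS_ADMIN_ITEMS)},
        state_cost_intervals={
            HealthState.NOT_SITTING: (16498.0, 30640.0),
            HealthState.SITTING: (6927.0, 12865.0),
            HealthState.WALKING: (4651.0, 8637.0),
            HealthState.PAV: (19385.0, 36001.0),
        },
        acquisition_intervals={
            "nusinersen": (78804.0, 146349.45),
            "AVXS-101": (2138121.0, 3970796.0),
        },
    )

    utilities = UtilitySet(
        utilities={
            HealthState.NOT_SITTING: 0.104,
            HealthState.SITTING: 0.115,
            HealthState.WALKING: 0.252,
            HealthState.PAV: 0.104,
        },
        sds={
            HealthState.NOT_SITTING: 0.0278,
            HealthState.SITTING: 0.0227,
            HealthState.WALKING: 0.0332,
            HealthState.PAV: 0.0278,
        },
    )

    weibull = dict(weibull_lambda=0.0006, weibull_p=1.9613)
    prob_intervals = {
        "pav_to_death": (0.0102, 0.0190),
        "weibull_lambda": (0.0002, 0.0017),
        "weibull_p": (1.7226, 2.2331),
    }
    transitions = {
        "SOC": TransitionSpec(
            ns_to_death=0.0532, ns_to_pav=0.0625, pav_to_death=0.0146,
            **weibull,
            intervals={"ns_to_death": (0.0372, 0.0692),
                       "ns_to_pav": (0.0437, 0.0812), **prob_intervals},
        ),
        "nusinersen": TransitionSpec(
            ns_to_death=0.0184, ns_to_pav=0.0355, pav_to_death=0.0146,
            **weibull,
            milestones=MilestoneSchedule(sitting_frac=0.08, walking_frac=0.0,
                                         window_cycles=13),
            intervals={"ns_to_death": (0.0129, 0.0239),
                       "ns_to_pav": (0.0248, 0.0461), **prob_intervals},
        ),
        "AVXS-101": TransitionSpec(
            ns_to_death=0.0184, ns_to_pav=0.0355, pav_to_death=0.0146,
            **weibull,
            milestones=MilestoneSchedule(sitting_frac=9.0 / 12.0,
                                         walking_frac=2.0 / 12.0,
                                         window_cycles=24, protected=True),
            intervals={"ns_to_death": (0.0129, 0.0239),
                       "ns_to_pav": (0.0248, 0.0461), **prob_intervals},
        ),
    }

    strategies = [
        StrategySpec(name="SOC"),
        StrategySpec(
            name="nusinersen",
            loading_doses_months=(0.0, 0.5, 1.0, 2.0),
            maintenance_start_month=6.0,
            maintenance_interval_months=4.0,
            dosed_states=(HealthState.NOT_SITTING, HealthState.SITTING,
                          HealthState.WALKING),
        ),
        StrategySpec(name="AVXS-101", loading_doses_months=(0.0,), one_off=True),
    ]

    return ModelSpec(
        horizon_years=100.0,
        start_age_years=0.0,
        discount=DiscountSpec(),
        costs=costs,
        utilities=utilities,
        transitions=transitions,
        strategies=strategies,
        lifetable=lifetable,
    )


# ---------------------------------------------------------------------------
# YAML serialization
# ---------------------------------------------------------------------------

_REQUIRED_TOP_KEYS = ("horizon_years", "start_age_years", "discount", "costs",
                      "utilities", "transitions", "strategies", "lifetable")


def spec_to_dict(spec: ModelSpec) -> dict:
    """Plain-dict form of a ModelSpec (enum keys become state names)."""
    def states_to_names(d):
        return {HealthState(k).name: v for k, v in d.items()}

    return {
        "horizon_years": spec.horizon_years,
        "start_age_years": spec.start_age_years,
        "half_cycle_correction": spec.half_cycle_correction,
        "discount": asdict(spec.discount),
        "costs": {
            "state_costs": states_to_names(spec.costs.state_costs),
            "acquisition_cost": dict(spec.costs.acquisition_cost),
            "admin_items": {k: list(v) for k, v in spec.costs.admin_items.items()},
            "state_cost_intervals": {
                HealthState(k).name: list(v)
                for k, v in spec.costs.state_cost_intervals.items()},
            "acquisition_intervals": {
                k: list(v) for k, v in spec.costs.acquisition_intervals.items()},
        },
        "utilities": {
            "utilities": states_to_names(spec.utilities.utilities),
            "sds": states_to_names(spec.utilities.sds),
        },
        "transitions": {
            name: {
                "ns_to_death": t.ns_to_death,
                "ns_to_pav": t.ns_to_pav,
                "pav_to_death": t.pav_to_death,
                "weibull_lambda": t.weibull_lambda,
                "weibull_p": t.weibull_p,
                "weibull_form": t.weibull_form,
                "milestones": asdict(t.milestones),
                "intervals": {k: list(v) for k, v in t.intervals.items()},
            }
            for name, t in spec.transitions.items()
        },
        "strategies": [
            {
                "name": s.name,
                "loading_doses_months": list(s.loading_doses_months),
                "maintenance_start_month": s.maintenance_start_month,
                "maintenance_interval_months": s.maintenance_interval_months,
                "one_off": s.one_off,
                "dosed_states": [HealthState(x).name for x in s.dosed_states],
            }
            for s in spec.strategies
        ],
        "lifetable": {
            "ages": [float(a) for a in spec.lifetable.ages],
            "annual_qx": [float(q) for q in spec.lifetable.annual_qx],
        },
    }


def spec_from_dict(data: dict) -> ModelSpec:
    from .survival import LifeTable

    for key in _REQUIRED_TOP_KEYS:
        if key not in data:
            raise SchemaError(f"missing required config key: {key!r}")

    def names_to_states(d):
        return {HealthState[k]: v for k, v in d.items()}

    c = data["costs"]
    costs = CostSet(
        state_costs=names_to_states(c["state_costs"]),
        acquisition_cost=dict(c.get("acquisition_cost", {})),
        admin_items={k: list(v) for k, v in c.get("admin_items", {}).items()},
        state_cost_intervals={HealthState[k]: tuple(v)
                              for k, v in c.get("state_cost_intervals", {}).items()},
        acquisition_intervals={k: tuple(v)
                               for k, v in c.get("acquisition_intervals", {}).items()},
    )
    u = data["utilities"]
    utilities = UtilitySet(utilities=names_to_states(u["utilities"]),
                           sds=names_to_states(u.get("sds", {})))
    transitions = {}
    for name, t in data["transitions"].items():
        if name not in STRATEGY_NAMES:
            raise ValidationError(f"unknown strategy name {name!r}")
        m = t.get("milestones", {})
        transitions[name] = TransitionSpec(
            ns_to_death=t["ns_to_death"], ns_to_pav=t["ns_to_pav"],
            pav_to_death=t["pav_to_death"],
            weibull_lambda=t["weibull_lambda"], weibull_p=t["weibull_p"],
            weibull_form=t.get("weibull_form", "scale_months"),
            milestones=MilestoneSchedule(**m) if m else MilestoneSchedule(),
            intervals={k: tuple(v) for k, v in t.get("intervals", {}).items()},
        )
    strategies = [
        StrategySpec(
            name=s["name"],
            loading_doses_months=tuple(s.get("loading_doses_months", ())),
            maintenance_start_month=s.get("maintenance_start_month"),
            maintenance_interval_months=s.get("maintenance_interval_months"),
            one_off=s.get("one_off", False),
            dosed_states=tuple(HealthState[x] for x in s.get(
                "dosed_states", ("NOT_SITTING", "SITTING", "WALKING"))),
        )
        for s in data["strategies"]
    ]
    lt = data["lifetable"]
    lifetable = LifeTable(ages=lt["ages"], annual_qx=lt["annual_qx"])
    return ModelSpec(
        horizon_years=data["horizon_years"],
        start_age_years=data["start_age_years"],
        discount=DiscountSpec(**data["discount"]),
        costs=costs,
        utilities=utilities,
        transitions=transitions,
        strategies=strategies,
        lifetable=lifetable,
        half_cycle_correction=data.get("half_cycle_correction", True),
    )


def save_model_spec(spec: ModelSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def load_model_spec(path) -> ModelSpec:
    """Load and fully validate a model configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError("config file did not parse to a mapping")
    return spec_from_dict(data)
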