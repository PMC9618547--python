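"""Monthly-cycle five-state cohort simulation with discounting.

For each strategy the engine builds per-cycle transition probabilities
(constant trial-derived monthly probabilities for the NOT_SITTING and
PAV exits, a Weibull survival model for SITTING, the population life
table for WALKING, and a solved milestone schedule during the trial
window), propagates the cohort over the horizon, and accumulates
discounted costs and QALYs with a trapezoidal half-cycle correction.
Drug costs follow each strategy's dosing calendar.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .config import HealthState, ModelSpec, StrategySpec, TransitionSpec
from .survival import cycle_probability, lifetable_monthly_prob, weibull_survival

NS, SIT, WALK, PAV, DEAD = (HealthState.NOT_SITTING, HealthState.SITTING,
                            HealthState.WALKING, HealthState.PAV, HealthState.DEAD)


class ModelError(RuntimeError):
    """The model specification produced an invalid transition structure."""


@dataclass
class Trace:
    """Cycle-by-cycle state occupancy for one strategy.

    ``occupancy`` has shape (n_cycles + 1, 5): row k is the cohort
    distribution at the start of cycle k (row 0 is the initial state).
    """

    occupancy: np.ndarray
    cycle_length_months: float = 1.0

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def times_years(self) -> np.ndarray:
        return np.arange(self.occupancy.shape[0]) * self.cycle_length_months / 12.0

    def validate(self, atol: float = 1e-12) -> None:
        occ = self.occupancy
        if np.any(occ < -atol) or np.any(occ > 1 + atol):
            raise ModelError("occupancy outside [0, 1]")
        if np.any(np.abs(occ.sum(axis=1) - 1.0) > 1e-9):
            raise ModelError("occupancy rows do not sum to 1")
        if np.any(np.diff(occ[:, DEAD]) < -atol):
            raise ModelError("DEAD occupancy must be non-decreasing")

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.occupancy,
                          columns=[s.name for s in HealthState])
        df.insert(0, "cycle", np.arange(len(df)))
        df.insert(1, "time_years", self.times_years())
        return df


@dataclass
class StrategyOutcome:
    """Discounted totals and per-cycle audit streams for one strategy."""

    strategy: str
    cost: float
    qalys: float
    life_years: float
    state_cost: float
    drug_cost: float
    cycle_costs: np.ndarray = field(repr=False, default=None)
    cycle_qalys: np.ndarray = field(repr=False, default=None)


def discount_factor(annual_rate: float, t_years) -> np.ndarray:
    """Annual-compound discount factor ``(1 + r) ** (-t)``."""
    return (1.0 + annual_rate) ** (-np.asarray(t_years, dtype=float))


def solve_milestone_prob(target_frac: float, window: int,
                         competing_exit: float) -> float:
    """Per-cycle milestone probability delivering a cumulative inflow.

    Finds q such that, starting from a full cohort, applying the
    milestone exit q alongside the competing per-cycle exit probability
    for ``window`` cycles moves exactly ``target_frac`` of the initial
    cohort to the milestone state:

        sum_{c=0}^{W-1} q * prod_{j<c} (1 - competing - q) = target_frac

    With no competing exits this reduces to ``1 - (1-f)^(1/W)``.
    """
    if target_frac <= 0:
        return 0.0
    if window <= 0:
        raise ValueError("milestone fractions require a positive window")

    def cum_inflow(q):
        occ, moved = 1.0, 0.0
        stay = 1.0 - competing_exit - q
        if stay < 0:
            return 2.0  # infeasible; push the solver back
        for _ in range(window):
            moved += q * occ
            occ *= stay
        return moved

    hi = 1.0 - competing_exit
    if cum_inflow(hi * (1 - 1e-12)) < target_frac:
        raise ModelError(
            f"milestone fraction {target_frac} unreachable in {window} cycles "
            f"with competing exit {competing_exit}")
    return float(optimize.brentq(
        lambda q: cum_inflow(q) - target_frac, 0.0, hi * (1 - 1e-12),
        xtol=1e-14))


def _milestone_probs(tr: TransitionSpec):
    """Per-cycle (sitting, walking) milestone probabilities in-window.

    Under "immediate" allocation the full milestone fractions move in
    the first cycle; under "uniform" a constant per-cycle probability
    is solved so the cumulative inflow over the window matches them.
    """
    m = tr.milestones
    total = m.sitting_frac + m.walking_frac
    if total == 0 or m.window_cycles == 0:
        return 0.0, 0.0
    if m.allocation == "immediate":
        q_total = total
    else:
        competing = 0.0 if m.protected else tr.ns_to_death + tr.ns_to_pav
        q_total = solve_milestone_prob(total, m.window_cycles, competing)
    return (q_total * m.sitting_frac / total, q_total * m.walking_frac / total)


def _percycle_probs(spec: ModelSpec, tr: TransitionSpec):
    """Precompute per-cycle transition probability arrays.

    Returns dict of length-n arrays: NOT_SITTING exits (death, pav,
    sitting, walking), SITTING death (age-dependent Weibull), WALKING
    death (life table), PAV death.
    """
    n = spec.n_cycles
    dt = spec.discount.cycle_length_months / 12.0
    lam, p = tr.weibull_rate_per_yearp(), tr.weibull_p
    m = tr.milestones
    in_window = np.arange(n) < m.window_cycles
    q_sit, q_walk = _milestone_probs(tr)
    if m.allocation == "immediate":
        milestone_cycles = np.arange(n) < min(1, m.window_cycles)
    else:
        milestone_cycles = in_window

    ns_death = np.full(n, tr.ns_to_death)
    ns_pav = np.full(n, tr.ns_to_pav)
    if m.protected:
        ns_death[in_window] = 0.0
        ns_pav[in_window] = 0.0
    ns_sit = np.where(milestone_cycles, q_sit, 0.0)
    ns_walk = np.where(milestone_cycles, q_walk, 0.0)

    t0 = spec.start_age_years + np.arange(n) * dt
    surv = weibull_survival(t0, lam, p)
    surv_next = weibull_survival(t0 + dt, lam, p)
    sit_death = 1.0 - surv_next / surv

    ages = spec.start_age_years + np.arange(n) * dt
    walk_death = np.array([lifetable_monthly_prob(spec.lifetable, a)
                           for a in ages])
    pav_death = np.full(n, tr.pav_to_death)

    for name, arr in (("NOT_SITTING", ns_death + ns_pav + ns_sit + ns_walk),
                      ("SITTING", sit_death), ("WALKING", walk_death),
                      ("PAV", pav_death)):
        bad = np.where(arr > 1.0 + 1e-12)[0]
        if len(bad):
            raise ModelError(
                f"outgoing probabilities from {name} exceed 1 at cycle {bad[0]}")
    return {"ns_death": ns_death, "ns_pav": ns_pav, "ns_sit": ns_sit,
            "ns_walk": ns_walk, "sit_death": sit_death,
            "walk_death": walk_death, "pav_death": pav_death}


def transition_matrix(spec: ModelSpec, strategy: StrategySpec,
                      cycle: int) -> np.ndarray:
    """Row-stochastic 5x5 transition matrix for one cycle."""
    if not 0 <= cycle < spec.n_cycles:
        raise ModelError(f"cycle {cycle} outside horizon")
    pr = _percycle_probs(spec, spec.transitions[strategy.name])
    k = cycle
    M = np.zeros((5, 5))
    M[NS, DEAD] = pr["ns_death"][k]
    M[NS, PAV] = pr["ns_pav"][k]
    M[NS, SIT] = pr["ns_sit"][k]
    M[NS, WALK] = pr["ns_walk"][k]
    M[NS, NS] = 1.0 - M[NS, 1:].sum()
    M[SIT, DEAD] = pr["sit_death"][k]
    M[SIT, SIT] = 1.0 - M[SIT, DEAD]
    M[WALK, DEAD] = pr["walk_death"][k]
    M[WALK, WALK] = 1.0 - M[WALK, DEAD]
    M[PAV, DEAD] = pr["pav_death"][k]
    M[PAV, PAV] = 1.0 - M[PAV, DEAD]
    M[DEAD, DEAD] = 1.0
    return M


def run_cohort(spec: ModelSpec, strategy: StrategySpec) -> Trace:
    """Propagate the full cohort from NOT_SITTING over the horizon."""
    pr = _percycle_probs(spec, spec.transitions[strategy.name])
    n = spec.n_cycles
    occ = np.zeros((n + 1, 5))
    occ[0, NS] = 1.0
    ns = sit = walk = pav = dead = 0.0
    ns = 1.0
    ns_death, ns_pav, ns_sit, ns_walk = (pr["ns_death"], pr["ns_pav"],
                                         pr["ns_sit"], pr["ns_walk"])
    sit_death, walk_death, pav_death = (pr["sit_death"], pr["walk_death"],
                                        pr["pav_death"])
    for k in range(n):
        d_ns = ns_death[k]; p_ns = ns_pav[k]; s_ns = ns_sit[k]; w_ns = ns_walk[k]
        sd = sit_death[k]; wd = walk_death[k]; pd_ = pav_death[k]
        new_dead = dead + ns * d_ns + sit * sd + walk * wd + pav * pd_
        new_sit = sit * (1.0 - sd) + ns * s_ns
        new_walk = walk * (1.0 - wd) + ns * w_ns
        new_pav = pav * (1.0 - pd_) + ns * p_ns
        new_ns = ns * (1.0 - d_ns - p_ns - s_ns - w_ns)
        ns, sit, walk, pav, dead = new_ns, new_sit, new_walk, new_pav, new_dead
        occ[k + 1] = (ns, sit, walk, pav, dead)
    return Trace(occupancy=occ,
                 cycle_length_months=spec.discount.cycle_length_months)


def dosing_costs(trace: Trace, strategy: StrategySpec, spec: ModelSpec) -> float:
    """Discounted drug cost over the strategy's dosing calendar.

    Each dose charges the per-dose total (acquisition + administration)
    times the proportion of the cohort in a dosed state at the dose
    time, discounted to time 0.  A one-off therapy charges exactly one
    undiscounted full-cohort dose at t=0.
    """
    dose_cost = spec.costs.dose_cost(strategy.name)
    if dose_cost == 0:
        return 0.0
    horizon_months = spec.horizon_years * 12.0
    r = spec.discount.annual_rate_costs
    occ = trace.occupancy
    dosed = [int(s) for s in strategy.dosed_states]
    for t in strategy.loading_doses_months:
        if t > horizon_months:
            warnings.warn(f"dose at month {t} beyond horizon; ignored",
                          stacklevel=2)
    total = 0.0
    for t in strategy.dose_times(horizon_months):
        k = int(math.floor(t / spec.discount.cycle_length_months))
        k = min(k, occ.shape[0] - 1)
        on_treatment = float(occ[k, dosed].sum())
        total += dose_cost * on_treatment * (1.0 + r) ** (-(t / 12.0))
    return total


def accumulate_outcomes(trace: Trace, spec: ModelSpec,
                        strategy: StrategySpec) -> StrategyOutcome:
    """Discounted cost/QALY totals with trapezoidal half-cycle correction.

    Per cycle, state membership is the average of start- and
    end-of-cycle occupancy; state costs apply per cycle, utilities as
    annual weights scaled by cycle length; both streams discount at
    mid-cycle time.
    """
    if trace.n_cycles != spec.n_cycles:
        raise ModelError("trace and spec horizons differ")
    occ = trace.occupancy
    if spec.half_cycle_correction:
        membership = 0.5 * (occ[:-1] + occ[1:])
    else:
        membership = occ[:-1]
    dt_years = spec.discount.cycle_length_months / 12.0
    t_mid = (np.arange(spec.n_cycles) + 0.5) * dt_years
    disc_c = discount_factor(spec.discount.annual_rate_costs, t_mid)
    disc_e = discount_factor(spec.discount.annual_rate_effects, t_mid)

    state_costs = np.array([spec.state_cost(s) for s in HealthState])
    utilities = np.array([spec.utility(s) for s in HealthState])
    alive = np.ones(5)
    alive[DEAD] = 0.0

    cycle_cost = membership @ state_costs
    cycle_qaly = membership @ utilities * dt_years
    life_years = float((membership @ alive).sum() * dt_years)

    state_cost = float(cycle_cost @ disc_c)
    qalys = float(cycle_qaly @ disc_e)
    drug = dosing_costs(trace, strategy, spec)
    return StrategyOutcome(
        strategy=strategy.name,
        cost=state_cost + drug,
        qalys=qalys,
        life_years=life_years,
        state_cost=state_cost,
        drug_cost=drug,
        cycle_costs=cycle_cost * disc_c,
        cycle_qalys=cycle_qaly * disc_e,
    )


def run_strategy(spec: ModelSpec, name: str) -> StrategyOutcome:
    """Convenience: run one strategy end to end."""
    strat = spec.strategy(name)
    trace = run_cohort(spec, strat)
    return accumulate_outcomes(trace, spec, strat)


def run_all(spec: ModelSpec) -> dict:
    """Run every strategy in the spec; returns {name: StrategyOutcome}."""
    return {s.name: run_strategy(spec, s.name) for s in spec.strategies}
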