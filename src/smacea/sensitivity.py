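"""Deterministic and probabilistic sensitivity analysis.

One-way sensitivity analysis (OWSA) perturbs each parameter +/-30% of
its mean and records the ICER at both ends (tornado ordering by range).
Probabilistic sensitivity analysis (PSA) samples costs from gamma
distributions and utilities/probabilities from beta distributions —
utilities from their published mean/SD by method of moments, costs and
probabilities from their published min/max interpreted as a central 95%
interval fitted with the mean constrained.  Every iteration applies one
shared parameter draw to all three strategies, preserving the
correlation between arms induced by shared parameters.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import HealthState, ModelSpec
from .cea import icer, nmb
from .markov import run_all

LIVING = (HealthState.NOT_SITTING, HealthState.SITTING,
          HealthState.WALKING, HealthState.PAV)


# ---------------------------------------------------------------------------
# Distribution parameterisation
# ---------------------------------------------------------------------------

def beta_from_mean_sd(mean: float, sd: float):
    """Method-of-moments beta parameters (alpha, beta) from mean and SD."""
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must be strictly inside (0, 1)")
    if sd <= 0:
        raise ValueError("sd must be positive")
    if sd * sd >= mean * (1.0 - mean):
        raise ValueError(
            f"infeasible moments: sd^2={sd*sd:.4g} >= mean(1-mean)="
            f"{mean*(1-mean):.4g}")
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    return mean * nu, (1.0 - mean) * nu


def _fit_mean_constrained(mean, lo, hi, q_lo, q_hi, concentration_to_q):
    """Solve a 1-D concentration so the 2.5%/97.5% quantiles match [lo, hi]
    in least squares, holding the distribution mean at ``mean``."""
    def objective(log_nu):
        ql, qh = concentration_to_q(math.exp(log_nu))
        return (ql - lo) ** 2 + (qh - hi) ** 2

    res = optimize.minimize_scalar(objective, bounds=(-5, 15), method="bounded",
                                   options={"xatol": 1e-10})
    return math.exp(res.x)


def gamma_from_mean_interval(mean: float, lo: float, hi: float):
    """Gamma (shape, scale) with the given mean and ~95% interval [lo, hi].

    The shape is solved by least squares on the 2.5% and 97.5%
    quantiles with the mean held fixed (scale = mean/shape).  A
    degenerate interval (lo == hi == mean) denotes a fixed parameter
    and returns None.
    """
    if lo == hi == mean:
        return None
    if not 0 < lo < mean < hi:
        raise ValueError(f"need 0 < lo < mean < hi, got {lo}, {mean}, {hi}")

    def q_of(shape):
        scale = mean / shape
        return (stats.gamma.ppf(0.025, shape, scale=scale),
                stats.gamma.ppf(0.975, shape, scale=scale))

    shape = _fit_mean_constrained(mean, lo, hi, 0.025, 0.975, q_of)
    return shape, mean / shape


def beta_from_mean_interval(mean: float, lo: float, hi: float):
    """Beta (alpha, beta) with the given mean and ~95% interval [lo, hi]."""
    if lo == hi == mean:
        return None
    if not 0 < lo < mean < hi < 1:
        raise ValueError(f"need 0 < lo < mean < hi < 1, got {lo}, {mean}, {hi}")

    def q_of(nu):
        a, b = mean * nu, (1 - mean) * nu
        return stats.beta.ppf(0.025, a, b), stats.beta.ppf(0.975, a, b)

    nu = _fit_mean_constrained(mean, lo, hi, 0.025, 0.975, q_of)
    return mean * nu, (1 - mean) * nu


# ---------------------------------------------------------------------------
# Parameter registry: named accessors into a ModelSpec
# ---------------------------------------------------------------------------

@dataclass
class Parameter:
    """A named scalar model input with get/set accessors and PSA metadata."""

    name: str
    getter: Callable[[ModelSpec], float]
    setter: Callable[[ModelSpec, float], None]
    dist: str = "fixed"  # gamma | beta | fixed
    sd: Optional[float] = None
    interval: Optional[tuple] = None
    cap: Optional[float] = None  # hard upper bound (e.g. 1 for probabilities)


def _state_cost_param(state):
    return Parameter(
        name=f"cost_{state.name.lower()}",
        getter=lambda s, st=state: s.costs.state_costs[st],
        setter=lambda s, v, st=state: s.costs.state_costs.__setitem__(st, v),
        dist="gamma",
    )


def _utility_param(state, shared_with=()):
    def setter(s, v, st=state, extra=shared_with):
        s.utilities.utilities[st] = v
        for other in extra:
            s.utilities.utilities[other] = v

    return Parameter(
        name=f"utility_{state.name.lower()}",
        getter=lambda s, st=state: s.utilities.utilities[st],
        setter=setter, dist="beta", cap=1.0,
    )


def _acq_param(strategy):
    key = strategy.replace("-", "_").lower()
    return Parameter(
        name=f"price_{key}",
        getter=lambda s, n=strategy: s.costs.acquisition_cost[n],
        setter=lambda s, v, n=strategy: s.costs.acquisition_cost.__setitem__(n, v),
        dist="gamma",
    )


def _transition_param(field_name, arms, label):
    def getter(s):
        return getattr(s.transitions[arms[0]], field_name)

    def setter(s, v):
        for a in arms:
            setattr(s.transitions[a], field_name, v)

    return Parameter(name=label, getter=getter, setter=setter,
                     dist="beta", cap=1.0)


def default_parameters(spec: ModelSpec,
                       shared_ns_pav_utility: bool = True):
    """The perturbable parameter set mirroring the published input table.

    NOT_SITTING and PAV utilities are identical in the base case and
    are sampled/varied as one shared parameter by default.
    """
    params = []
    for strat in ("nusinersen", "AVXS-101"):
        if strat in spec.costs.acquisition_cost:
            p = _acq_param(strat)
            p.interval = spec.costs.acquisition_intervals.get(strat)
            params.append(p)
    for st in LIVING:
        p = _state_cost_param(st)
        p.interval = spec.costs.state_cost_intervals.get(st)
        params.append(p)

    shared = (HealthState.PAV,) if shared_ns_pav_utility else ()
    params.append(_utility_param(HealthState.NOT_SITTING, shared_with=shared))
    params.append(_utility_param(HealthState.SITTING))
    params.append(_utility_param(HealthState.WALKING))
    if not shared_ns_pav_utility:
        params.append(_utility_param(HealthState.PAV))
    for p in params:
        if p.name.startswith("utility_"):
            st = HealthState[p.name.split("_", 1)[1].upper()]
            p.sd = spec.utilities.sds.get(st)

    arm_params = [
        ("ns_to_death", ("SOC",), "p_death_soc"),
        ("ns_to_death", ("nusinersen", "AVXS-101"), "p_death_treatment"),
        ("ns_to_pav", ("SOC",), "p_pav_soc"),
        ("ns_to_pav", ("nusinersen", "AVXS-101"), "p_pav_treatment"),
        ("pav_to_death", ("SOC", "nusinersen", "AVXS-101"), "p_pav_death"),
    ]
    for field_name, arms, label in arm_params:
        arms = tuple(a for a in arms if a in spec.transitions)
        p = _transition_param(field_name, arms, label)
        p.interval = spec.transitions[arms[0]].intervals.get(field_name)
        params.append(p)

    # Weibull parameters for SITTING survival: positive, gamma-sampled
    for field_name, label in (("weibull_lambda", "weibull_lambda"),
                              ("weibull_p", "weibull_p")):
        def getter(s, f=field_name):
            return getattr(next(iter(s.transitions.values())), f)

        def setter(s, v, f=field_name):
            for t in s.transitions.values():
                setattr(t, f, v)

        p = Parameter(name=label, getter=getter, setter=setter, dist="gamma")
        iv = next(iter(spec.transitions.values())).intervals.get(field_name)
        if iv is not None:
            p.interval = (min(iv), max(iv))
        params.append(p)
    return params


# ---------------------------------------------------------------------------
# One-way sensitivity analysis
# ---------------------------------------------------------------------------

def owsa(spec: ModelSpec, parameters: Optional[Sequence[Parameter]] = None,
         span: float = 0.30,
         comparisons: Sequence[tuple] = (("AVXS-101", "SOC"),)) -> pd.DataFrame:
    """Tornado table: ICER at each parameter's -span/+span perturbation.

    Each parameter is varied one at a time around its base value with
    all others fixed; utilities (and any probability) are capped at
    their natural bounds after perturbation, with the clip recorded.
    Output is sorted by descending ICER range for the first comparison.
    """
    if parameters is None:
        parameters = default_parameters(spec)
    rows = []
    for p in parameters:
        base = p.getter(spec)
        entry = {"parameter": p.name, "base_value": base}
        for direction, mult in (("low", 1.0 - span), ("high", 1.0 + span)):
            value = base * mult
            clipped = False
            if p.cap is not None and value > p.cap:
                value, clipped = p.cap, True
            s = copy.deepcopy(spec)
            p.setter(s, value)
            outcomes = run_all(s)
            for a, b in comparisons:
                entry[f"icer_{a}_vs_{b}_{direction}"] = icer(
                    outcomes[a], outcomes[b])
            entry[f"value_{direction}"] = value
            entry[f"clipped_{direction}"] = clipped
        rows.append(entry)
    df = pd.DataFrame(rows)
    a, b = comparisons[0]
    lo, hi = f"icer_{a}_vs_{b}_low", f"icer_{a}_vs_{b}_high"
    num = df[[lo, hi]].apply(pd.to_numeric, errors="coerce")
    df["icer_range"] = (num[hi] - num[lo]).abs()
    return df.sort_values("icer_range", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSAConfig:
    """Iteration count, seed and the per-parameter distribution set."""

    n_iterations: int = 5000
    seed: int = 0
    shared_ns_pav_utility: bool = True

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")


@dataclass
class PSAResult:
    """Sampled parameter draws and per-strategy (cost, QALY) per iteration."""

    draws: pd.DataFrame
    outcomes: dict  # strategy -> DataFrame with cost/qalys columns
    seed: int

    @property
    def n(self) -> int:
        return len(self.draws)


def _sampler_for(p: Parameter, base: float):
    """Build a draw function rng -> value for one parameter, or None if fixed."""
    if p.dist == "fixed":
        return None
    if p.dist == "beta":
        if p.sd is not None:
            a, b = beta_from_mean_sd(base, p.sd)
        elif p.interval is not None:
            fitted = beta_from_mean_interval(base, *p.interval)
            if fitted is None:
                return None
            a, b = fitted
        else:
            return None
        return lambda rng: rng.beta(a, b)
    if p.dist == "gamma":
        if p.interval is None:
            return None
        fitted = gamma_from_mean_interval(base, *p.interval)
        if fitted is None:
            return None
        shape, scale = fitted
        return lambda rng: rng.gamma(shape, scale)
    raise ValueError(f"unknown distribution {p.dist!r}")


def run_psa(spec: ModelSpec, cfg: PSAConfig) -> PSAResult:
    """Monte-Carlo parameter uncertainty analysis over all strategies.

    Per iteration every non-fixed parameter is drawn once and the same
    sampled specification is run for each strategy.  Reproducible under
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    params = default_parameters(
        spec, shared_ns_pav_utility=cfg.shared_ns_pav_utility)
    samplers = []
    for p in params:
        s = _sampler_for(p, p.getter(spec))
        if s is not None:
            samplers.append((p, s))

    names = [p.name for p, _ in samplers]
    strategy_names = [s.name for s in spec.strategies]
    draw_rows = np.empty((cfg.n_iterations, len(samplers)))
    out = {name: np.empty((cfg.n_iterations, 2)) for name in strategy_names}
    work = copy.deepcopy(spec)
    for i in range(cfg.n_iterations):
        for j, (p, sampler) in enumerate(samplers):
            v = sampler(rng)
            if p.cap is not None:
                v = min(v, p.cap)
            draw_rows[i, j] = v
            p.setter(work, v)
        outcomes = run_all(work)
        for name in strategy_names:
            out[name][i] = (outcomes[name].cost, outcomes[name].qalys)

    draws = pd.DataFrame(draw_rows, columns=names)
    draws.insert(0, "iteration", np.arange(cfg.n_iterations))
    outcomes_df = {
        name: pd.DataFrame(out[name], columns=["cost", "qalys"])
        for name in strategy_names}
    return PSAResult(draws=draws, outcomes=outcomes_df, seed=cfg.seed)


def ce_plane(result: PSAResult, strategy: str, comparator: str) -> pd.DataFrame:
    """Incremental (dQALY, dCost) scatter for the CE plane."""
    a, b = result.outcomes[strategy], result.outcomes[comparator]
    return pd.DataFrame({
        "delta_qalys": a["qalys"] - b["qalys"],
        "delta_cost": a["cost"] - b["cost"],
    })


def ceac(result: PSAResult, wtp_grid: Sequence[float],
         comparison: Optional[tuple] = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve(s).

    Pairwise mode (``comparison=(a, b)``): the fraction of iterations
    with positive incremental net monetary benefit of a over b at each
    willingness-to-pay.  All-vs-all mode (``comparison=None``): the
    fraction of iterations in which each strategy has the highest net
    monetary benefit; the probabilities sum to 1 at every threshold.
    """
    wtp_grid = list(wtp_grid)
    if not wtp_grid:
        raise ValueError("empty willingness-to-pay grid")
    rows = []
    if comparison is not None:
        a, b = comparison
        dq = (result.outcomes[a]["qalys"] - result.outcomes[b]["qalys"]).to_numpy()
        dc = (result.outcomes[a]["cost"] - result.outcomes[b]["cost"]).to_numpy()
        for w in wtp_grid:
            rows.append({"wtp": w,
                         "probability": float(np.mean(w * dq - dc > 0))})
        return pd.DataFrame(rows)
    names = list(result.outcomes)
    q = np.column_stack([result.outcomes[n]["qalys"] for n in names])
    c = np.column_stack([result.outcomes[n]["cost"] for n in names])
    for w in wtp_grid:
        nmb_matrix = w * q - c
        best = np.argmax(nmb_matrix, axis=1)
        row = {"wtp": w}
        for j, n in enumerate(names):
            row[n] = float(np.mean(best == j))
        rows.append(row)
    return pd.DataFrame(rows)
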