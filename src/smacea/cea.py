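"""Incremental cost-effectiveness analysis and threshold pricing.

ICERs are computed from unrounded discounted totals; display rounding
(whole dollars, three-decimal QALYs) happens only in the reporting
layer.  The threshold analysis exploits the affine relation between the
one-off acquisition price and the ICER: a one-off full-cohort dose at
t=0 enters the incremental cost with slope exactly 1, so the price
making the ICER equal a willingness-to-pay threshold has a closed form,
verified by re-running the model at the solved price.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .config import ModelSpec
from .markov import StrategyOutcome, run_all, run_strategy

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"  # equal effects: report cost difference only


@dataclass
class Comparison:
    """One pairwise incremental comparison (a vs b)."""

    a: str
    b: str
    delta_cost: float
    delta_qalys: float
    icer: Union[float, str]


@dataclass
class CEResult:
    """Per-strategy outcomes plus pairwise incremental comparisons."""

    outcomes: dict  # name -> StrategyOutcome
    comparisons: list = field(default_factory=list)  # of Comparison

    def comparison(self, a: str, b: str) -> Comparison:
        for c in self.comparisons:
            if (c.a, c.b) == (a, b):
                return c
        raise KeyError((a, b))

    def to_frame(self):
        import pandas as pd

        rows = []
        for c in self.comparisons:
            oa, ob = self.outcomes[c.a], self.outcomes[c.b]
            rows.append({
                "comparison": f"{c.a} vs {c.b}",
                "cost_a": oa.cost, "qaly_a": oa.qalys,
                "cost_b": ob.cost, "qaly_b": ob.qalys,
                "delta_cost": c.delta_cost, "delta_qalys": c.delta_qalys,
                "icer": c.icer,
            })
        return pd.DataFrame(rows)


def icer(a: StrategyOutcome, b: StrategyOutcome,
         tol: float = 1e-12) -> Union[float, str]:
    """Incremental cost-effectiveness ratio of a versus b (AUD/QALY).

    Returns ``"dominant"`` when a is cheaper and more effective,
    ``"dominated"`` when costlier and less effective, and
    ``"undefined"`` when the QALY difference is zero.
    """
    dc = a.cost - b.cost
    de = a.qalys - b.qalys
    if abs(de) <= tol:
        return UNDEFINED
    if dc < 0 and de > 0:
        return DOMINANT
    if dc > 0 and de < 0:
        return DOMINATED
    return dc / de


def nmb(outcome: StrategyOutcome, wtp: float) -> float:
    """Net monetary benefit: ``wtp * QALYs - cost``."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * outcome.qalys - outcome.cost


def compare_all(spec: ModelSpec,
                pairs: Optional[Sequence[tuple]] = None) -> CEResult:
    """Run every strategy and build the pairwise comparison table."""
    outcomes = run_all(spec)
    if pairs is None:
        pairs = [("nusinersen", "SOC"), ("AVXS-101", "SOC"),
                 ("AVXS-101", "nusinersen")]
        pairs = [(a, b) for a, b in pairs if a in outcomes and b in outcomes]
    comps = []
    for a, b in pairs:
        oa, ob = outcomes[a], outcomes[b]
        comps.append(Comparison(a=a, b=b,
                                delta_cost=oa.cost - ob.cost,
                                delta_qalys=oa.qalys - ob.qalys,
                                icer=icer(oa, ob)))
    return CEResult(outcomes=outcomes, comparisons=comps)


def frontier(result: CEResult):
    """Cost-effectiveness frontier over the strategies in a result.

    Strategies are ordered by QALYs; strictly dominated options (more
    costly, fewer QALYs than another) and extendedly dominated options
    (higher sequential ICER than the next stronger option) are flagged.
    Returns a list of dicts with strategy, status and sequential ICER.
    """
    items = sorted(result.outcomes.values(), key=lambda o: (o.qalys, o.cost))
    status = {o.strategy: "on_frontier" for o in items}
    for o in items:
        for other in items:
            if (other.qalys > o.qalys and other.cost < o.cost) or (
                    other.qalys >= o.qalys and other.cost < o.cost):
                status[o.strategy] = "dominated"
    active = [o for o in items if status[o.strategy] == "on_frontier"]
    # extended dominance: remove options whose sequential ICER exceeds the next
    changed = True
    while changed and len(active) > 2:
        changed = False
        for i in range(1, len(active) - 1):
            lo, mid, hi = active[i - 1], active[i], active[i + 1]
            icer_lo = (mid.cost - lo.cost) / (mid.qalys - lo.qalys)
            icer_hi = (hi.cost - mid.cost) / (hi.qalys - mid.qalys)
            if icer_lo > icer_hi:
                status[mid.strategy] = "extendedly_dominated"
                active.pop(i)
                changed = True
                break
    out = []
    prev = None
    for o in items:
        seq_icer = None
        if status[o.strategy] == "on_frontier":
            if prev is not None:
                seq_icer = (o.cost - prev.cost) / (o.qalys - prev.qalys)
            prev = o
        out.append({"strategy": o.strategy, "cost": o.cost, "qalys": o.qalys,
                    "status": status[o.strategy], "sequential_icer": seq_icer})
    return out


def with_acquisition_price(spec: ModelSpec, strategy: str,
                           price: float) -> ModelSpec:
    """Copy of the spec with one strategy's acquisition price replaced."""
    new = copy.deepcopy(spec)
    new.costs.acquisition_cost[strategy] = float(price)
    return new


def threshold_price(spec: ModelSpec, wtp: float, strategy: str = "AVXS-101",
                    comparator: str = "SOC", verify_tol: float = 1e-6,
                    allow_negative: bool = False) -> Optional[float]:
    """One-off acquisition price at which the ICER equals the WTP.

    Closed form: with the acquisition charged once, undiscounted, to
    the full cohort at t=0, ``price* = wtp * dE - (other costs of the
    strategy - comparator cost)``.  The solution is verified by
    re-running the model at price*; returns None when no non-negative
    price is cost-effective at the given WTP (or the raw, possibly
    negative, closed-form value when ``allow_negative`` is set).
    """
    base = compare_all(spec, pairs=[(strategy, comparator)])
    comp = base.comparison(strategy, comparator)
    if comp.delta_qalys <= 0:
        raise ValueError("threshold price requires a positive QALY gain")
    base_price = spec.costs.acquisition_cost[strategy]
    nonacq_delta = comp.delta_cost - base_price  # slope-1 affine relation
    price = wtp * comp.delta_qalys - nonacq_delta
    if price < 0:
        return price if allow_negative else None
    check = compare_all(with_acquisition_price(spec, strategy, price),
                        pairs=[(strategy, comparator)])
    achieved = check.comparison(strategy, comparator).icer
    if not isinstance(achieved, float) or abs(achieved - wtp) / wtp > verify_tol:
        raise RuntimeError(
            f"threshold verification failed: ICER at price* is {achieved}")
    return price


def threshold_curve(spec: ModelSpec, wtp_grid: Sequence[float], **kw):
    """Threshold price over a WTP grid (None where no price works)."""
    import pandas as pd

    rows = [{"wtp": w, "threshold_price": threshold_price(spec, w, **kw)}
            for w in wtp_grid]
    return pd.DataFrame(rows)
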