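"""Synthetic inputs: trial-like censored survival data, published-figure
Kaplan-Meier curves with risk tables, and a population life table.

The real model inputs (trial survival curves, the national life table)
are not redistributable, so every input the pipeline needs is generated
here.  The trial presets mirror the structure of the pivotal studies: a
sham-controlled antisense-oligonucleotide trial (80 treated / 41
control, 13-month follow-up) and a small single-arm gene-therapy trial
(12 infants, 24-month follow-up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .survival import LifeTable
from .reconstruct import KMCurve, RiskTable, km_estimator


@dataclass
class TrialScenario:
    """Design of a simulated right-censored survival trial.

    Each arm draws event times from a constant-hazard (``weibull_p=1``)
    or Weibull model (time unit: months) and is administratively
    censored at ``followup_months``.
    """

    arm_sizes: dict  # arm name -> n
    monthly_hazards: dict  # arm name -> hazard (scale-rate if Weibull)
    followup_months: float
    weibull_p: dict = field(default_factory=dict)  # arm name -> shape (default 1)
    seed: int = 0

    def __post_init__(self) -> None:
        for arm, n in self.arm_sizes.items():
            if n < 1:
                raise ValueError(f"arm {arm!r} must have >= 1 subject")
        for arm, h in self.monthly_hazards.items():
            if h < 0:
                raise ValueError(f"arm {arm!r} hazard must be >= 0")
        if self.followup_months <= 0:
            raise ValueError("follow-up must be positive")


def endear_like(seed: int = 0) -> TrialScenario:
    """Sham-controlled trial structure: 80 treated / 41 control, 13 months.

    Monthly hazards are the continuous-time equivalents of the
    base-case monthly death probabilities (control 0.0532, treated
    0.0184): ``h = -log(1 - q)``.
    """
    return TrialScenario(
        arm_sizes={"treatment": 80, "control": 41},
        monthly_hazards={"treatment": -math.log(1 - 0.0184),
                         "control": -math.log(1 - 0.0532)},
        followup_months=13.0,
        seed=seed,
    )


def cl101_like(seed: int = 0) -> TrialScenario:
    """Single-arm gene-therapy trial structure: 12 infants, 24 months.

    The observed trial had no deaths; a tiny non-zero hazard keeps the
    fixture usable for estimators that require events.
    """
    return TrialScenario(
        arm_sizes={"treatment": 12},
        monthly_hazards={"treatment": 0.002},
        followup_months=24.0,
        seed=seed,
    )


def simulate_trial(scenario: TrialScenario):
    """Draw per-arm event-level records (time, event) for a scenario.

    Returns ``{arm: (times, events)}`` with administrative censoring at
    the end of follow-up.  Reproducible under ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    out = {}
    for arm in scenario.arm_sizes:
        n = scenario.arm_sizes[arm]
        h = scenario.monthly_hazards[arm]
        p = scenario.weibull_p.get(arm, 1.0)
        if h == 0:
            raw = np.full(n, np.inf)
        else:
            # S(t) = exp(-h t^p)  =>  T = (E/h)^(1/p), E ~ Exp(1)
            raw = (rng.exponential(1.0, size=n) / h) ** (1.0 / p)
        events = raw <= scenario.followup_months
        times = np.minimum(raw, scenario.followup_months)
        out[arm] = (times, events.astype(int))
    return out


def publish_km(times, events, landmark_times: Sequence[float],
               noise: float = 0.0, seed: int = 0):
    """Emulate a published figure: KM step coordinates plus a risk table.

    ``noise`` adds uniform(-noise, +noise) digitisation error to the
    survival coordinates (truncated to [0, 1]); downstream
    reconstruction monotonises.  Numbers at risk count subjects still
    under observation at each landmark.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    curve = km_estimator(times, events)
    s = np.array(curve.survival, dtype=float)
    if noise > 0:
        rng = np.random.default_rng(seed)
        jitter = rng.uniform(-noise, noise, size=len(s))
        jitter[0] = 0.0  # the anchor (0, 1) is exact
        s = np.clip(s + jitter, 0.0, 1.0)
    noisy = KMCurve(times=curve.times, survival=s, monotonise=True)
    landmarks = sorted(set(float(t) for t in landmark_times) | {0.0})
    n_at_risk = [int(np.sum(times >= t)) for t in landmarks]
    risk = RiskTable(times=landmarks, n_at_risk=n_at_risk)
    return noisy, risk


def synthetic_lifetable(a: float = 1e-4, b: float = 2.5e-5, c: float = 1.1,
                        max_age: int = 110) -> LifeTable:
    """Synthetic population life table from a Gompertz-Makeham hazard.

    ``q_x = 1 - exp(-(a + b * c**x))`` per year of age.  The default
    preset gives negligible infant/childhood mortality (q_0 ~ 1.2e-4,
    cumulative mortality to age 20 under 1%) and realistic old-age
    mortality, standing in for a modern national life table.
    """
    if a < 0 or b < 0:
        raise ValueError("a and b must be non-negative")
    if c <= 1:
        raise ValueError("c must exceed 1")
    ages = np.arange(0, max_age + 1, dtype=float)
    hazard = a + b * np.power(c, ages)
    qx = 1.0 - np.exp(-hazard)
    if np.any(qx >= 1.0):
        raise ValueError("hazard explodes before max_age; reduce b, c or max_age")
    return LifeTable(ages=ages, annual_qx=qx)
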