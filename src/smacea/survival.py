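"""Parametric survival models, hazard/probability conversions, life tables.

Per-cycle transition probabilities for the cohort model are derived from
fitted or published survival functions via the conditional-probability
identity ``q = 1 - S(t0 + dt) / S(t0)``.  The module implements maximum
likelihood fitting with right censoring for five standard families
(exponential, Weibull, Gompertz, log-normal, log-logistic), AIC/BIC
model selection, and Cox-Snell residual diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats


class FitError(RuntimeError):
    """Survival model could not be fitted (degenerate data or no convergence)."""


# ---------------------------------------------------------------------------
# Parametric families
# ---------------------------------------------------------------------------

FAMILIES = ("exponential", "weibull", "gompertz", "lognormal", "loglogistic")

# Parameterizations (all times > 0):
#   exponential: S(t) = exp(-rate * t)
#   weibull:     S(t) = exp(-lam * t**p)
#   gompertz:    h(t) = rate * exp(shape * t); S(t) = exp(-rate/shape * (e^{shape t}-1))
#   lognormal:   log T ~ Normal(mu, sigma)
#   loglogistic: S(t) = 1 / (1 + (t/alpha)**beta)


def weibull_survival(t, lam: float, p: float):
    """Weibull survival ``S(t) = exp(-lam * t**p)``, time in years."""
    if lam <= 0 or p <= 0:
        raise ValueError("Weibull parameters must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = np.exp(-lam * np.power(t, p))
    return float(out) if out.ndim == 0 else out


def survival_function(family: str, params: Sequence[float]):
    """Return a vectorised S(t) callable for the given family."""
    params = tuple(float(x) for x in params)
    if family == "exponential":
        (rate,) = params
        return lambda t: np.exp(-rate * np.asarray(t, dtype=float))
    if family == "weibull":
        lam, p = params
        return lambda t: np.exp(-lam * np.power(np.asarray(t, dtype=float), p))
    if family == "gompertz":
        shape, rate = params
        if abs(shape) < 1e-12:
            return lambda t: np.exp(-rate * np.asarray(t, dtype=float))
        return lambda t: np.exp(
            -rate / shape * (np.expm1(shape * np.asarray(t, dtype=float))))
    if family == "lognormal":
        mu, sigma = params
        return lambda t: stats.norm.sf(
            (np.log(np.maximum(np.asarray(t, dtype=float), 1e-300)) - mu) / sigma)
    if family == "loglogistic":
        alpha, beta = params
        return lambda t: 1.0 / (1.0 + np.power(
            np.asarray(t, dtype=float) / alpha, beta))
    raise ValueError(f"unknown family {family!r}")


def _log_hazard(family: str, params, t):
    """log h(t) for event contributions to the censored log-likelihood."""
    t = np.asarray(t, dtype=float)
    if family == "exponential":
        (rate,) = params
        return np.full_like(t, math.log(rate))
    if family == "weibull":
        lam, p = params
        return math.log(lam * p) + (p - 1.0) * np.log(t)
    if family == "gompertz":
        shape, rate = params
        return math.log(rate) + shape * t
    if family == "lognormal":
        mu, sigma = params
        z = (np.log(t) - mu) / sigma
        logpdf = stats.norm.logpdf(z) - np.log(t * sigma)
        return logpdf - stats.norm.logsf(z)
    if family == "loglogistic":
        alpha, beta = params
        x = np.power(t / alpha, beta)
        return math.log(beta / alpha) + (beta - 1.0) * np.log(t / alpha) - np.log1p(x)
    raise ValueError(f"unknown family {family!r}")


def _log_cumhazard_neg(family: str, params, t):
    """-H(t) = log S(t), computed stably."""
    t = np.asarray(t, dtype=float)
    if family == "exponential":
        (rate,) = params
        return -rate * t
    if family == "weibull":
        lam, p = params
        return -lam * np.power(t, p)
    if family == "gompertz":
        shape, rate = params
        if abs(shape) < 1e-12:
            return -rate * t
        return -rate / shape * np.expm1(shape * t)
    if family == "lognormal":
        mu, sigma = params
        return stats.norm.logsf((np.log(t) - mu) / sigma)
    if family == "loglogistic":
        alpha, beta = params
        return -np.log1p(np.power(t / alpha, beta))
    raise ValueError(f"unknown family {family!r}")


_N_PARAMS = {"exponential": 1, "weibull": 2, "gompertz": 2,
             "lognormal": 2, "loglogistic": 2}


@dataclass
class ParametricFit:
    """A fitted parametric survival model with information criteria."""

    family: str
    params: tuple
    loglik: float
    n: int
    n_events: int
    converged: bool = True

    @property
    def k(self) -> int:
        return _N_PARAMS[self.family]

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    @property
    def bic(self) -> float:
        return self.k * math.log(self.n) - 2 * self.loglik

    def survival(self, t):
        return survival_function(self.family, self.params)(t)


def _loglik(family, params, times, events):
    lh = _log_hazard(family, params, times[events])
    ls_all = _log_cumhazard_neg(family, params, times)
    ll = float(np.sum(lh) + np.sum(ls_all))
    return ll if np.isfinite(ll) else -np.inf


def _initial_params(family, times, events):
    """Method-of-moments / crude starting values on the native scale."""
    t_mean = float(np.mean(times))
    rate0 = max(events.sum(), 1) / float(np.sum(times))
    if family == "exponential":
        return (rate0,)
    if family == "weibull":
        return (rate0, 1.0)
    if family == "gompertz":
        return (0.01, rate0)
    if family == "lognormal":
        lt = np.log(times[events]) if events.any() else np.log(times)
        return (float(np.mean(lt)), max(float(np.std(lt)), 0.1))
    if family == "loglogistic":
        return (t_mean, 1.0)
    raise ValueError(family)


def fit_parametric(times, events, family: str) -> ParametricFit:
    """Maximum-likelihood fit of a parametric family to censored data.

    ``times`` are positive observation times; ``events`` is 1 for an
    observed event, 0 for right censoring.  Parameters are optimised on
    an unconstrained (log, except the Gompertz shape) scale.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times <= 0):
        raise ValueError("observation times must be positive")
    n_events = int(events.sum())
    if n_events < 2:
        raise FitError(
            f"need at least 2 events to fit a parametric model, got {n_events}")

    if family == "gompertz":
        # shape unconstrained, rate > 0
        def to_native(x):
            return (x[0], math.exp(x[1]))

        def to_opt(p):
            return np.array([p[0], math.log(p[1])])
    else:
        def to_native(x):
            return tuple(math.exp(v) for v in x)

        def to_opt(p):
            return np.log(np.asarray(p, dtype=float))

    x0 = to_opt(_initial_params(family, times, events))

    def nll(x):
        return -_loglik(family, to_native(x), times, events)

    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-8,
                                     "maxiter": 20000, "maxfev": 20000})
    ll = -res.fun
    if not np.isfinite(ll):
        raise FitError(f"{family} fit did not converge (non-finite likelihood)")
    return ParametricFit(family=family, params=tuple(to_native(res.x)),
                         loglik=ll, n=len(times), n_events=n_events,
                         converged=bool(res.success))


def fit_all_families(times, events, families=FAMILIES):
    """Fit every requested family; failed fits are dropped, not silent."""
    fits, failures = [], {}
    for fam in families:
        try:
            fits.append(fit_parametric(times, events, fam))
        except FitError as exc:  # pragma: no cover - data dependent
            failures[fam] = str(exc)
    return fits, failures


def select_best(fits: Sequence[ParametricFit]) -> ParametricFit:
    """Best fit by AIC, ties by BIC, then by fewest parameters."""
    converged = [f for f in fits if f.converged]
    if not converged:
        raise FitError("no converged fits to select from")
    return min(converged, key=lambda f: (f.aic, f.bic, f.k))


def selection_report(fits: Sequence[ParametricFit]):
    """Tabular selection report (family, k, loglik, AIC, BIC)."""
    import pandas as pd

    rows = [{"family": f.family, "k": f.k, "loglik": f.loglik,
             "aic": f.aic, "bic": f.bic, "converged": f.converged}
            for f in fits]
    return pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)


def coxsnell_residuals(fit: ParametricFit, times, events):
    """Cox-Snell residuals ``r_i = -log S_fit(t_i)`` with censor flags.

    Under a correctly specified model the residuals behave as a
    censored sample from the unit exponential: the Kaplan-Meier-based
    cumulative hazard of the residuals lies on the 45-degree line.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    r = -_log_cumhazard_neg(fit.family, fit.params, times)
    return np.asarray(r, dtype=float), events


# ---------------------------------------------------------------------------
# Probability conversions
# ---------------------------------------------------------------------------

def cycle_probability(survival_fn, t0: float, delta: float) -> float:
    """Probability of the event in ``(t0, t0+delta]`` given alive at ``t0``.

    ``q = 1 - S(t0 + delta) / S(t0)``.  For a constant hazard h this is
    ``1 - exp(-h*delta)`` independent of ``t0``.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    s0 = float(survival_fn(t0))
    if s0 <= 0:
        raise ZeroDivisionError(
            f"degenerate cohort: S({t0}) = 0, conditional probability undefined")
    q = 1.0 - float(survival_fn(t0 + delta)) / s0
    return min(max(q, 0.0), 1.0)


def rescale_probability(prob: float, d1: float, d2: float) -> float:
    """Convert a probability over interval ``d1`` to interval ``d2``.

    Assumes a constant hazard within the interval:
    ``1 - (1 - prob) ** (d2 / d1)``.  A probability of exactly 1 stays 1.
    """
    if not 0.0 <= prob <= 1.0:
        raise ValueError("prob must be in [0, 1]")
    if d1 <= 0 or d2 <= 0:
        raise ValueError("intervals must be positive")
    if prob == 1.0:
        return 1.0
    return 1.0 - (1.0 - prob) ** (d2 / d1)


# ---------------------------------------------------------------------------
# Life tables
# ---------------------------------------------------------------------------

@dataclass
class LifeTable:
    """Annual mortality probabilities q_x by integer age.

    Lookup uses ``floor(age)``; ages beyond the last row fall back to
    the last row (an open-ended terminal age group).
    """

    ages: Sequence[float]
    annual_qx: Sequence[float]

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.annual_qx = np.asarray(self.annual_qx, dtype=float)
        if len(self.ages) == 0:
            raise ValueError("life table is empty")
        if len(self.ages) != len(self.annual_qx):
            raise ValueError("ages and annual_qx must have equal length")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any((self.annual_qx < 0) | (self.annual_qx > 1)):
            raise ValueError("q_x must be in [0, 1]")

    def annual_prob(self, age: float) -> float:
        if age < 0:
            raise ValueError("age must be >= 0")
        idx = int(np.searchsorted(self.ages, math.floor(age), side="right")) - 1
        idx = max(0, min(idx, len(self.ages) - 1))
        return float(self.annual_qx[idx])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"age": self.ages, "annual_qx": self.annual_qx})

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(ages=df.iloc[:, 0].to_numpy(), annual_qx=df.iloc[:, 1].to_numpy())


def lifetable_monthly_prob(lt: LifeTable, age: float) -> float:
    """Monthly death probability at ``age`` from annual life-table q_x."""
    return rescale_probability(lt.annual_prob(age), 1.0, 1.0 / 12.0)
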