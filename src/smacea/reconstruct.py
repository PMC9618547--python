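"""Pseudo individual-patient data from published Kaplan-Meier curves.

Published survival figures report only the step coordinates of the KM
estimate and, usually, numbers at risk at a few landmark times.  The
reconstruction algorithm of Guyot and colleagues inverts the
product-limit calculation interval by interval: within each risk-table
interval it iteratively allocates censoring times (spread uniformly) so
that the implied number at risk at the start of the next interval
matches the published one, and recovers event counts from the survival
drops.  The result is an event-level (time, event-indicator) data set
whose KM estimate closely reproduces the published curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


@dataclass
class KMCurve:
    """Digitised KM step coordinates starting at (0, 1)."""

    times: Sequence[float]
    survival: Sequence[float]
    monotonise: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if t.shape != s.shape or t.ndim != 1 or len(t) == 0:
            raise ValueError("times and survival must be equal-length 1-D arrays")
        if t[0] != 0.0 or abs(s[0] - 1.0) > 1e-9:
            # prepend the mandatory anchor if absent
            t = np.concatenate([[0.0], t])
            s = np.concatenate([[1.0], s])
        if np.any(np.diff(t) < 0):
            raise ValueError("curve times must be non-decreasing")
        if np.any((s < 0) | (s > 1)):
            raise ValueError("survival must lie in [0, 1]")
        if np.any(np.diff(s) > 0):
            if self.monotonise:
                warnings.warn("digitised survival not monotone; applying "
                              "cumulative minimum", stacklevel=2)
                s = np.minimum.accumulate(s)
            else:
                raise ValueError("survival must be non-increasing "
                                 "(pass monotonise=True for digitised input)")
        self.times = t
        self.survival = s

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, "survival": self.survival})


@dataclass
class RiskTable:
    """Numbers at risk at landmark times; first landmark must be 0."""

    times: Sequence[float]
    n_at_risk: Sequence[int]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.n_at_risk, dtype=int)
        if t.shape != n.shape or len(t) == 0:
            raise ValueError("times and counts must be equal-length")
        if t[0] != 0.0:
            raise ValueError("risk table must start at time 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if np.any(n < 0) or np.any(np.diff(n) > 0):
            raise ValueError("numbers at risk must be non-negative and non-increasing")
        self.times = t
        self.n_at_risk = n


def km_estimator(times, events) -> KMCurve:
    """Product-limit (Kaplan-Meier) estimate as step coordinates.

    Ties at equal times are handled events-before-censorings, the
    standard convention.  Backed by lifelines.
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("need at least one record")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    return KMCurve(times=t, survival=s)


def reconstruct_ipd(curve: KMCurve, risk: RiskTable,
                    total_events: Optional[int] = None):
    """Reconstruct pseudo-IPD from a published KM curve and risk table.

    Returns ``(times, events)`` arrays with one record per subject
    initially at risk.  Events are placed at the digitised step times;
    censoring within each risk-table interval is spread uniformly, with
    counts solved iteratively so the implied number at risk matches the
    published value at the start of the next interval.  If
    ``total_events`` is given, event counts in the final interval are
    adjusted toward it.
    """
    tk = np.asarray(curve.times, dtype=float)
    sk = np.asarray(curve.survival, dtype=float)
    t_risk = np.asarray(risk.times, dtype=float)
    n_risk = np.asarray(risk.n_at_risk, dtype=int)
    if tk[-1] > t_risk[-1] and len(t_risk) > 1:
        # risk table must cover the curve; an open final interval is allowed
        # only when the table has a single (t=0) row
        t_risk = np.append(t_risk, tk[-1] + 1e-9)
        n_risk = np.append(n_risk, 0)  # sentinel: unconstrained final interval
        unconstrained_tail = True
    else:
        unconstrained_tail = False

    n_int = len(t_risk) if len(t_risk) == 1 else len(t_risk) - 1
    # interval i covers [t_risk[i], t_risk[i+1]); a single-row table yields
    # one open interval covering the whole curve
    lower, upper = [], []
    for i in range(n_int):
        lo = t_risk[i]
        hi = t_risk[i + 1] if i + 1 < len(t_risk) else np.inf
        idx = np.where((tk >= lo) & (tk < hi))[0]
        lower.append(idx[0] if len(idx) else None)
        upper.append(idx[-1] if len(idx) else None)

    K = len(tk)
    d = np.zeros(K)  # events at each step time
    c = np.zeros(K)  # censorings allocated "at" each step (spread later)
    cens_times_all = []
    n_hat = float(n_risk[0])
    s_prev_interval_end = 1.0

    # running KM product up to (not including) step k
    s_run = np.ones(K + 1)

    for i in range(n_int):
        lo_i, up_i = lower[i], upper[i]
        last_constrained = (i + 1 < len(n_risk)) and not (
            unconstrained_tail and i == n_int - 1)
        target_next = float(n_risk[i + 1]) if i + 1 < len(n_risk) else None
        if lo_i is None:
            # no digitised steps in the interval: censor down to the target
            if target_next is not None and not (unconstrained_tail and i == n_int - 1):
                n_cens = int(round(n_hat - target_next))
                if n_cens > 0:
                    span = t_risk[i + 1] - t_risk[i]
                    cens_times_all.extend(
                        t_risk[i] + span * (np.arange(1, n_cens + 1)) / (n_cens + 1))
                    n_hat -= n_cens
            continue

        steps = list(range(lo_i, up_i + 1))
        interval_end = t_risk[i + 1] if i + 1 < len(t_risk) else tk[-1]

        def allocate(n_cens_guess):
            """Walk the interval with a censoring count; return implied
            end-of-interval at-risk and per-step events.

            Event counts use cumulative rounding: the running real-valued
            event total implied by the survival drops is rounded once per
            step, so rounding errors do not accumulate across steps.
            """
            n_cur = n_hat
            s_cur = s_prev_interval_end
            dloc = np.zeros(len(steps))
            d_real_cum = 0.0
            d_int_cum = 0
            # censor times uniform over the interval
            if n_cens_guess > 0:
                ct = t_risk[i] + (interval_end - t_risk[i]) * (
                    np.arange(1, n_cens_guess + 1)) / (n_cens_guess + 1)
            else:
                ct = np.array([])
            for j, k in enumerate(steps):
                # censorings occurring before this step time leave the risk set
                n_c_before = np.sum((ct >= (tk[steps[j - 1]] if j else t_risk[i])) &
                                    (ct < tk[k])) if len(ct) else 0
                n_cur -= n_c_before
                if s_cur > 0 and n_cur > 0:
                    d_real_cum += n_cur * (1.0 - sk[k] / s_cur)
                    dj = int(round(d_real_cum)) - d_int_cum
                else:
                    dj = 0
                dj = int(min(max(dj, 0), n_cur))
                d_int_cum += dj
                dloc[j] = dj
                if n_cur > 0:
                    s_cur *= 1.0 - dj / n_cur
                n_cur -= dj
            # censorings after the last step but inside the interval
            n_c_tail = np.sum(ct >= tk[steps[-1]]) if len(ct) else 0
            n_cur -= n_c_tail
            return n_cur, dloc, ct, s_cur

        if last_constrained and target_next is not None:
            # iterate on the censoring count until the implied at-risk matches
            guess = int(round(n_hat - target_next - max(
                0.0, n_hat * (1.0 - (sk[up_i] / max(s_prev_interval_end, 1e-12))))))
            guess = max(guess, 0)
            best = None
            seen = set()
            for _ in range(200):
                guess = int(min(max(guess, 0), n_hat))
                n_end, dloc, ct, s_end = allocate(guess)
                err = n_end - target_next
                if best is None or abs(err) < abs(best[0]):
                    best = (err, guess, dloc, ct, s_end, n_end)
                if err == 0 or guess in seen:
                    break
                seen.add(guess)
                guess += int(err)
            _, guess, dloc, ct, s_end, n_end = best
        else:
            # final (unconstrained) interval: no censoring unless total_events
            n_end, dloc, ct, s_end = allocate(0)

        for j, k in enumerate(steps):
            d[k] += dloc[j]
        cens_times_all.extend(ct.tolist())
        n_hat = n_end
        s_prev_interval_end = s_end

    # optional correction toward a known total event count
    if total_events is not None:
        diff = int(total_events - d.sum())
        if diff != 0 and K > 1:
            k_last = int(np.nonzero(d)[0][-1]) if d.any() else K - 1
            d[k_last] = max(d[k_last] + diff, 0)

    # assemble records: events at step times, censorings at allocated times,
    # remaining subjects censored at the last observed time
    times_out, events_out = [], []
    for k in range(K):
        times_out.extend([tk[k]] * int(d[k]))
        events_out.extend([1] * int(d[k]))
    times_out.extend(cens_times_all)
    events_out.extend([0] * len(cens_times_all))
    n_remaining = int(n_risk[0]) - len(times_out)
    if n_remaining > 0:
        times_out.extend([tk[-1]] * n_remaining)
        events_out.extend([0] * n_remaining)
    elif n_remaining < 0:  # numerical over-allocation; trim censorings
        for _ in range(-n_remaining):
            idx = max(i for i, e in enumerate(events_out) if e == 0)
            times_out.pop(idx)
            events_out.pop(idx)
    order = np.argsort(times_out, kind="stable")
    return (np.asarray(times_out, dtype=float)[order],
            np.asarray(events_out, dtype=int)[order])
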