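"""Kaplan-Meier step curves and exponential tail completion.

A combination's survival experience is summarised by the Kaplan-Meier
product-limit estimate up to a horizon ``tau`` and an exponential tail
``exp(-lambda * t)`` beyond it, with ``lambda = -log(S(tau)) / tau`` so the
completed curve is continuous at ``tau``.  The right-continuous convention
``S(t) = P(T > t)`` is used throughout: evaluation at a jump returns the
post-jump value, matching the identity ``P(T1 > T2) = E[S1(T2)]`` exploited
by the dissimilarity module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

__all__ = [
    "StepSurvivalCurve",
    "CompletedCurve",
    "ExponentialCurve",
    "kaplan_meier",
    "complete_with_tail",
    "global_tau",
]


@dataclass(frozen=True)
class StepSurvivalCurve:
    """Right-continuous Kaplan-Meier step function.

    Attributes
    ----------
    times : ndarray
        Distinct event times, ascending (times with at least one event).
    surv : ndarray
        Survival value immediately after each event time.
    at_risk : ndarray
        Number at risk just before each event time.
    events : ndarray
        Number of events at each event time.
    max_observed : float
        Largest observed time, event or censoring; the KM estimate is
        defined on [0, max_observed].
    n : int
        Sample size.
    """

    times: np.ndarray
    surv: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    max_observed: float
    n: int

    def survival(self, t):
        """S(t) with the right-continuous (post-jump) convention."""
        idx = np.searchsorted(self.times, t, side="right")
        vals = np.concatenate(([1.0], self.surv))
        return vals[idx]

    def survival_left(self, t):
        """Left limit S(t-)."""
        idx = np.searchsorted(self.times, t, side="left")
        vals = np.concatenate(([1.0], self.surv))
        return vals[idx]

    def jumps(self):
        """Jump times and (positive) jump masses of the failure law 1 - S."""
        vals = np.concatenate(([1.0], self.surv))
        return self.times, vals[:-1] - vals[1:]


@dataclass(frozen=True)
class CompletedCurve:
    """Step curve on [0, tau] continued by an exponential tail.

    The tail is ``exp(-lam * t)`` for ``t > tau`` with
    ``lam = -log(S(tau)) / tau``, hence continuous at ``tau``.  A curve that
    has dropped to zero by ``tau`` carries no tail mass; ``lam`` is flagged
    infinite and the tail is identically zero.
    """

    base: StepSurvivalCurve
    tau: float
    lam: float
    s_tau: float

    @property
    def zero_tail(self) -> bool:
        return self.s_tau == 0.0

    def survival(self, t):
        t = np.asarray(t, dtype=float)
        body = self.base.survival(np.minimum(t, self.tau))
        if self.zero_tail:
            tail = np.zeros_like(t, dtype=float)
        else:
            tail = np.exp(-self.lam * t)
        out = np.where(t <= self.tau, body, tail)
        return out if out.ndim else float(out)

    def survival_mid(self, t):
        """Tie-corrected evaluation: mean of left limit and value.

        Only differs from ``survival`` at the atoms of the step part; used
        so that ties in failure time across two curves get half credit.
        """
        t = np.asarray(t, dtype=float)
        right = self.survival(t)
        left = np.where(t <= self.tau, self.base.survival_left(np.minimum(t, self.tau)), right)
        out = 0.5 * (left + right)
        return out if out.ndim else float(out)

    def body_jumps(self):
        """Atoms of the failure law restricted to (0, tau]."""
        u, m = self.base.jumps()
        keep = u <= self.tau
        return u[keep], m[keep]


@dataclass(frozen=True)
class ExponentialCurve:
    """Analytic exponential survival curve ``S(t) = exp(-rate * t)``.

    Provides the same interface as :class:`CompletedCurve` for closed-form
    checks: its tail rate equals ``rate`` for any ``tau`` since
    ``-log(S(tau))/tau = rate``.  The body is continuous (no atoms).
    """

    rate: float
    tau: float

    @property
    def lam(self) -> float:
        return self.rate

    @property
    def s_tau(self) -> float:
        return math.exp(-self.rate * self.tau)

    @property
    def zero_tail(self) -> bool:
        return False

    def survival(self, t):
        out = np.exp(-self.rate * np.asarray(t, dtype=float))
        return out if out.ndim else float(out)

    survival_mid = survival

    def body_jumps(self):
        return np.empty(0), np.empty(0)


def kaplan_meier(times, events) -> StepSurvivalCurve:
    """Product-limit estimate of the survival function.

    Parameters
    ----------
    times, events : array-like
        Observed times (months, >= 0) and event indicators
        (1 = cause-specific death, 0 = censored).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("kaplan_meier: empty input")
    if times.shape != events.shape:
        raise ValueError("kaplan_meier: times and events must have equal length")
    if np.any(times < 0) or not np.all(np.isfinite(times)):
        raise ValueError("kaplan_meier: times must be finite and non-negative")
    if not np.all(np.isin(events, (0, 1))):
        raise ValueError("kaplan_meier: events must be 0/1")

    kmf = KaplanMeierFitter().fit(times, events)
    table = kmf.event_table
    ev_rows = table[table["observed"] > 0]
    ev_times = ev_rows.index.to_numpy(dtype=float)
    sf = kmf.survival_function_["KM_estimate"]
    surv = sf.loc[ev_rows.index].to_numpy(dtype=float)
    return StepSurvivalCurve(
        times=ev_times,
        surv=surv,
        at_risk=ev_rows["at_risk"].to_numpy(dtype=int),
        events=ev_rows["observed"].to_numpy(dtype=int),
        max_observed=float(times.max()),
        n=int(times.size),
    )


def complete_with_tail(curve: StepSurvivalCurve, tau: float) -> CompletedCurve:
    """Attach the exponential tail ``exp(-lam t)``, ``lam = -log S(tau)/tau``."""
    if not 0 < tau <= curve.max_observed:
        raise ValueError(
            f"tau={tau} outside (0, {curve.max_observed}]: KM estimate undefined there"
        )
    s_tau = float(curve.survival(tau))
    if s_tau == 0.0:
        lam = math.inf
    elif s_tau == 1.0:
        lam = 0.0
    else:
        lam = -math.log(s_tau) / tau
    return CompletedCurve(base=curve, tau=float(tau), lam=lam, s_tau=s_tau)


def global_tau(curves) -> float:
    """Largest time at which every curve's KM estimate is still defined.

    The minimum over curves of each curve's largest observed time; used as
    the common completion start for a whole analysis.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("global_tau: need at least one curve")
    return float(min(c.max_observed for c in curves))
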