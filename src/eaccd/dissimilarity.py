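"""Mann-Whitney effect size on tail-completed survival curves.

The Mann-Whitney parameter P(T1 > T2) — the probability a random subject
from population 1 outlives one from population 2 — is estimated from two
tail-completed Kaplan-Meier curves as D_e(tau1, tau2) = A + B + C:

* ``A = -int_0^{min(tau1,tau2)} S1(t) dS2(t)``  (Lebesgue-Stieltjes, the
  step part of curve 2),
* ``B`` covers the horizon gap: ``-int_{tau1}^{tau2} exp(-lam1 t) dS2(t)``
  when tau1 < tau2, 0 when equal, and
  ``int_{tau2}^{tau1} S1(t) lam2 exp(-lam2 t) dt`` when tau1 > tau2,
* ``C = lam2/(lam1+lam2) * exp(-(lam1+lam2) max(tau1,tau2))`` — the mass of
  both exponential tails.

The initial dissimilarity between two combinations is |D_e - 0.5|, which
lies in [0, 0.5] and vanishes for identical survival experiences.

Ties in failure time across the two curves get half credit: whenever the
step part of curve 1 is evaluated at an atom of curve 2, the mean of its
left limit and value is used.  This makes D_e(c1, c2) + D_e(c2, c1) = 1
hold exactly and D_e(c, c) = 0.5 on the nose; with distinct jump times it
reduces to the plain Stieltjes sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import CompletedCurve, ExponentialCurve, complete_with_tail, global_tau, kaplan_meier

__all__ = [
    "MWEffectEstimate",
    "DissimilarityMatrix",
    "mw_effect",
    "initial_dissimilarity",
    "initial_matrix",
]


@dataclass(frozen=True)
class MWEffectEstimate:
    a_term: float
    b_term: float
    c_term: float
    tau1: float
    tau2: float

    @property
    def estimate(self) -> float:
        return self.a_term + self.b_term + self.c_term


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric dissimilarity matrix over ordered combination keys."""

    keys: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "keys", tuple(self.keys))
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.keys):
            raise ValueError("matrix shape must match number of keys")
        if not np.array_equal(v, v.T):
            raise ValueError("matrix must be exactly symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("dissimilarities must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def m(self) -> int:
        return len(self.keys)

    def to_csv(self, path):
        df = pd.DataFrame(self.values, index=list(self.keys), columns=list(self.keys))
        df.to_csv(path, float_format="%.17g", index_label="key")

    @classmethod
    def from_csv(cls, path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        v = df.to_numpy(dtype=float)
        v = 0.5 * (v + v.T)  # guard against asymmetric decimal rounding
        np.fill_diagonal(v, 0.0)
        return cls(keys=tuple(str(k) for k in df.index), values=v)


def _exp_exp_failure_integral(lam1: float, lam2: float, a: float, b: float) -> float:
    """``int_a^b exp(-lam1 t) lam2 exp(-lam2 t) dt`` (both tails exponential)."""
    if lam2 == 0.0 or b <= a:
        return 0.0
    s = lam1 + lam2
    if s == 0.0:
        return 0.0
    return lam2 / s * (math.exp(-s * a) - math.exp(-s * b))


def _step_against_exp_density(curve: CompletedCurve, lam2: float, a: float, b: float) -> float:
    """``int_a^b S1(t) lam2 exp(-lam2 t) dt`` with S1 the step body of ``curve``.

    Exact piecewise integration: S1 is constant between its event times, so
    each segment contributes ``s * (exp(-lam2 lo) - exp(-lam2 hi))``.
    """
    if lam2 == 0.0 or not math.isfinite(lam2) or b <= a:
        return 0.0
    u, _ = curve.body_jumps()
    cuts = np.concatenate(([a], u[(u > a) & (u < b)], [b]))
    s_vals = curve.survival(cuts[:-1])  # right-continuous value on each segment
    seg = np.exp(-lam2 * cuts[:-1]) - np.exp(-lam2 * cuts[1:])
    return float(np.sum(np.asarray(s_vals) * seg))


def mw_effect(c1, c2) -> MWEffectEstimate:
    """Estimate P(T1 > T2) from two completed curves.

    Accepts :class:`CompletedCurve` or the analytic
    :class:`~eaccd.curves.ExponentialCurve`; with exact exponentials the
    terms telescope to ``lam2 / (lam1 + lam2)`` for any tau.
    """
    tau1, tau2 = float(c1.tau), float(c2.tau)
    tau_min, tau_max = min(tau1, tau2), max(tau1, tau2)

    # --- A: step/body part of curve 2 on (0, tau_min] against S1
    if isinstance(c2, ExponentialCurve):
        if isinstance(c1, ExponentialCurve):
            a_term = _exp_exp_failure_integral(c1.rate, c2.rate, 0.0, tau_min)
        else:
            a_term = _step_against_exp_density(c1, c2.rate, 0.0, tau_min)
    else:
        u, m = c2.body_jumps()
        keep = u <= tau_min
        u, m = u[keep], m[keep]
        a_term = float(np.sum(np.asarray(c1.survival_mid(u)) * m)) if u.size else 0.0

    # --- B: the horizon gap (tau_min, tau_max]
    b_term = 0.0
    if tau1 < tau2:
        # tail of curve 1 against the body of curve 2
        lam1 = c1.lam
        if c1.zero_tail:
            b_term = 0.0
        elif isinstance(c2, ExponentialCurve):
            b_term = _exp_exp_failure_integral(lam1, c2.rate, tau1, tau2)
        else:
            u, m = c2.body_jumps()
            keep = (u > tau1) & (u <= tau2)
            u, m = u[keep], m[keep]
            b_term = float(np.sum(np.exp(-lam1 * u) * m)) if u.size else 0.0
    elif tau1 > tau2:
        # body of curve 1 against the exponential tail density of curve 2
        if c2.zero_tail:
            b_term = 0.0
        elif isinstance(c1, ExponentialCurve):
            b_term = _exp_exp_failure_integral(c1.rate, c2.lam, tau2, tau1)
        else:
            b_term = _step_against_exp_density(c1, c2.lam, tau2, tau1)

    # --- C: both exponential tails beyond tau_max
    if c1.zero_tail or c2.zero_tail:
        c_term = 0.0
    else:
        lam1, lam2 = c1.lam, c2.lam
        s = lam1 + lam2
        if s == 0.0:  # no events by tau in either arm: equal-rates limit
            c_term = 0.5
        else:
            c_term = lam2 / s * math.exp(-s * tau_max)

    return MWEffectEstimate(a_term=a_term, b_term=b_term, c_term=c_term, tau1=tau1, tau2=tau2)


def initial_dissimilarity(c1, c2) -> float:
    """|D_e - 0.5|: distance of the Mann-Whitney estimate from no-effect."""
    return abs(mw_effect(c1, c2).estimate - 0.5)


def combination_curves(cohort, tau: float | None = None):
    """Completed KM curve per combination, at a common completion start.

    Returns ``(keys, curves, tau)`` with ``tau`` the analysis-wide minimum
    of per-combination largest observed times unless overridden.
    """
    keys = cohort.combination_keys
    base = {}
    for key, grp in cohort.data.groupby("combination", sort=True):
        base[key] = kaplan_meier(grp["time"].to_numpy(), grp["event"].to_numpy())
    if tau is None:
        tau = global_tau(base.values())
    curves = {k: complete_with_tail(base[k], tau) for k in keys}
    return keys, curves, float(tau)


def initial_matrix(cohort, tau: float | None = None) -> DissimilarityMatrix:
    """Pairwise initial dissimilarities between a cohort's combinations.

    All curves are completed from the same tau (the largest time at which
    every combination's KM estimate is still defined, unless overridden).
    """
    keys, curves, tau = combination_curves(cohort, tau)
    m = len(keys)
    if m < 2:
        raise ValueError("need at least 2 combinations")
    vals = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d = initial_dissimilarity(curves[keys[i]], curves[keys[j]])
            vals[i, j] = vals[j, i] = d
    return DissimilarityMatrix(keys=keys, values=vals)
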