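"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library code paths they check: grid
Lebesgue-Stieltjes integration for the effect-size terms, exhaustive
enumeration for PAM and minimax linkage, and a pure-python pair scan for
Harrell's C.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from eaccd.curves import complete_with_tail, kaplan_meier


# ---------------------------------------------------------------------------
# random censored samples and completed curves


def random_curve(rng, n=40, rate=0.02, censor=0.3, tau=None):
    """A completed KM curve from a random censored exponential sample."""
    t_event = rng.exponential(1.0 / rate, size=n)
    t_cens = np.where(rng.random(n) < censor, rng.uniform(0, 120, size=n), 150.0)
    times = np.minimum(t_event, t_cens)
    events = (t_event <= t_cens).astype(int)
    curve = kaplan_meier(times, events)
    if tau is None:
        tau = curve.max_observed
    return complete_with_tail(curve, min(tau, curve.max_observed))


def random_curve_pair(rng, tau_equal=True):
    c1 = random_curve(rng, n=int(rng.integers(15, 60)), rate=rng.uniform(0.005, 0.05))
    c2 = random_curve(rng, n=int(rng.integers(15, 60)), rate=rng.uniform(0.005, 0.05))
    tau = min(c1.base.max_observed, c2.base.max_observed)
    if tau_equal:
        return (
            complete_with_tail(c1.base, tau),
            complete_with_tail(c2.base, tau),
        )
    tau1 = rng.uniform(0.3, 1.0) * c1.base.max_observed
    tau2 = rng.uniform(0.3, 1.0) * c2.base.max_observed
    return complete_with_tail(c1.base, tau1), complete_with_tail(c2.base, tau2)


# ---------------------------------------------------------------------------
# grid Lebesgue-Stieltjes oracle for the effect-size terms


def grid_effect_terms(c1, c2, step=1e-4):
    """A, B, C by dense-grid numerical integration of the completed curves.

    A: grid Stieltjes sum of S1 against the failure law of curve 2 on
    (0, tau_min]; B likewise on the horizon gap using the relevant tail;
    C by numerically integrating both exponential tails far past tau_max.
    """
    tau1, tau2 = c1.tau, c2.tau
    tau_min, tau_max = min(tau1, tau2), max(tau1, tau2)

    def stieltjes(f, lo, hi, curve):
        if hi <= lo:
            return 0.0
        grid = np.arange(lo, hi + step, step)
        grid[-1] = hi
        s = np.asarray(curve.survival(grid))
        masses = s[:-1] - s[1:]
        return float(np.sum(f(grid[1:]) * masses))

    a = stieltjes(lambda t: np.asarray(c1.survival(t)), 0.0, tau_min, c2)
    if tau1 < tau2:
        b = stieltjes(lambda t: np.exp(-c1.lam * t), tau1, tau2, c2)
    elif tau1 > tau2:
        if c2.zero_tail:
            b = 0.0
        else:
            grid = np.arange(tau2, tau1 + step, step)
            grid[-1] = tau1
            mid = 0.5 * (grid[:-1] + grid[1:])
            dens = c2.lam * np.exp(-c2.lam * mid)
            b = float(np.sum(np.asarray(c1.survival(mid)) * dens * np.diff(grid)))
    else:
        b = 0.0
    if c1.zero_tail or c2.zero_tail:
        c = 0.0
    else:
        lam1, lam2 = c1.lam, c2.lam
        if lam1 + lam2 == 0:
            c = 0.5
        else:
            horizon = tau_max + 30.0 / max(lam1 + lam2, 1e-3)
            grid = np.linspace(tau_max, horizon, 200_000)
            mid = 0.5 * (grid[:-1] + grid[1:])
            c = float(
                np.sum(np.exp(-lam1 * mid) * lam2 * np.exp(-lam2 * mid) * np.diff(grid))
            )
    return a, b, c


# ---------------------------------------------------------------------------
# exhaustive PAM oracle


def pam_exhaustive(dist, k):
    """Globally optimal k-medoids objective by enumerating medoid sets."""
    m = dist.shape[0]
    best = np.inf
    for medoids in itertools.combinations(range(m), k):
        obj = dist[:, medoids].min(axis=1).sum()
        best = min(best, obj)
    return float(best)


# ---------------------------------------------------------------------------
# brute-force minimax linkage oracle


def minimax_brute(dist):
    """Re-derivation of minimax linkage that rescans every cluster pair and
    every candidate prototype at each step (no caching, no shortcuts)."""
    m = dist.shape[0]
    active = {i: (i,) for i in range(m)}
    merges = []
    for step in range(m - 1):
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            members = tuple(sorted(active[a] + active[b]))
            radius, proto = min(
                (max(dist[p, q] for q in members), p) for p in members
            )
            cand = (radius, (a, b), proto, members)
            if best is None or (cand[0], cand[1]) < (best[0], best[1]):
                best = cand
        radius, (a, b), proto, members = best
        del active[a], active[b]
        active[m + step] = members
        merges.append((a, b, radius, proto, members))
    return merges


# ---------------------------------------------------------------------------
# pure-python Harrell C oracle


def harrell_brute(times, events, scores):
    conc = 0.0
    perm = 0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j or times[i] >= times[j] or events[i] != 1:
                continue
            perm += 1
            if scores[i] > scores[j]:
                conc += 1.0
            elif scores[i] == scores[j]:
                conc += 0.5
    if perm == 0:
        return None
    return conc / perm


@pytest.fixture(scope="session")
def standard_cohort():
    from eaccd.simulate import standard_fixture

    return standard_fixture()
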