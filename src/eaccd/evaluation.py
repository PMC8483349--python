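"""Validation statistics for fitted grouping systems.

Adjacent prognostic groups are compared with a univariate two-group Cox
proportional-hazards fit (Newton iteration on the partial likelihood,
Breslow tie handling by default since registry months produce heavy ties;
Efron behind a flag) and the logrank test.  Two grouping systems on the
same cases are compared head-to-head by the difference of their Harrell
C-indices with a correlated-U-statistic variance (jackknife available as a
cross-check), a contingency table, mid-rank Spearman correlation, and
risk-category distributions per factor level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "GroupComparison",
    "CComparison",
    "two_group_cox",
    "adjacent_cox",
    "compare_c",
    "cross_tabulate",
    "spearman_midrank",
    "risk_category_distribution",
]


@dataclass(frozen=True)
class GroupComparison:
    group_low: int
    group_high: int
    hazard_ratio: float
    ci_low: float
    ci_high: float
    wald_p: float
    logrank_p: float
    estimable: bool = True


@dataclass(frozen=True)
class CComparison:
    c_a: float
    c_b: float
    ci_low: float
    ci_high: float
    p_value: float
    se: float
    degenerate: bool = False

    @property
    def difference(self) -> float:
        return self.c_a - self.c_b


def _cox_score_info(beta, t_ev, d, d1, n0, n1, ties="breslow"):
    """Score and information of the two-group partial likelihood.

    Arrays are per distinct event time: total events ``d``, events in the
    x=1 arm ``d1``, at-risk counts ``n0``/``n1``.
    """
    eb = math.exp(beta)
    if ties == "breslow":
        denom = n0 + n1 * eb
        mu = n1 * eb / denom
        u = float(np.sum(d1 - d * mu))
        info = float(np.sum(d * mu * (1 - mu)))
        return u, info
    # Efron: average the tied events out of the risk set
    u = 0.0
    info = 0.0
    for dt, d1t, n0t, n1t in zip(d, d1, n0, n1):
        r = n0t + n1t * eb
        de = (dt - d1t) + d1t * eb
        for j in range(int(dt)):
            denom = r - (j / dt) * de
            num = n1t * eb - (j / dt) * d1t * eb
            mu = num / denom
            u += -mu
            info += mu - mu * mu
        u += d1t
    return float(u), float(info)


def two_group_cox(times, events, x, ties: str = "breslow", tol: float = 1e-8, max_iter: int = 100):
    """Univariate Cox PH fit for a binary covariate.

    Returns ``(beta, se)``; raises ``ValueError`` when the hazard ratio is
    inestimable (no events, or monotone likelihood).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=int)
    ev_times = np.unique(times[events == 1])
    if ev_times.size == 0:
        raise ValueError("no events: hazard ratio inestimable")
    d = np.zeros(ev_times.size)
    d1 = np.zeros(ev_times.size)
    n0 = np.zeros(ev_times.size)
    n1 = np.zeros(ev_times.size)
    for i, t in enumerate(ev_times):
        at_ev = (times == t) & (events == 1)
        d[i] = at_ev.sum()
        d1[i] = (at_ev & (x == 1)).sum()
        at_risk = times >= t
        n1[i] = (at_risk & (x == 1)).sum()
        n0[i] = (at_risk & (x == 0)).sum()
    if d1.sum() == 0 or d1.sum() == d.sum():
        # all events in one arm at every time: beta diverges
        raise ValueError("monotone partial likelihood: hazard ratio inestimable")

    beta = 0.0
    for _ in range(max_iter):
        u, info = _cox_score_info(beta, ev_times, d, d1, n0, n1, ties)
        if info <= 0:
            raise ValueError("non-positive information: hazard ratio inestimable")
        step = u / info
        beta += step
        if abs(beta) > 30:
            raise ValueError("diverging estimate: hazard ratio inestimable")
        if abs(u) < tol:
            break
    else:
        raise ValueError("Cox Newton iteration did not converge")
    _, info = _cox_score_info(beta, ev_times, d, d1, n0, n1, ties)
    return beta, 1.0 / math.sqrt(info)


def adjacent_cox(times, events, groups, ties: str = "breslow", alpha: float = 0.05):
    """Cox HR + logrank p for every adjacent group pair (g+1 vs g).

    The covariate is 1 for the higher-numbered (higher-risk) group, so
    HR > 1 means the ordering is respected.  Inestimable pairs are flagged
    rather than raised.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups, dtype=int)
    levels = np.sort(np.unique(groups))
    if levels.size < 2:
        raise ValueError("need at least 2 groups")
    z = stats.norm.ppf(1 - alpha / 2)
    out = []
    for g_low, g_high in zip(levels[:-1], levels[1:]):
        sel = np.isin(groups, (g_low, g_high))
        t, e = times[sel], events[sel]
        x = (groups[sel] == g_high).astype(int)
        lr = logrank_test(t[x == 0], t[x == 1], event_observed_A=e[x == 0], event_observed_B=e[x == 1])
        try:
            beta, se = two_group_cox(t, e, x, ties=ties)
            wald_p = 2 * stats.norm.sf(abs(beta / se))
            out.append(
                GroupComparison(
                    group_low=int(g_low),
                    group_high=int(g_high),
                    hazard_ratio=math.exp(beta),
                    ci_low=math.exp(beta - z * se),
                    ci_high=math.exp(beta + z * se),
                    wald_p=float(wald_p),
                    logrank_p=float(lr.p_value),
                )
            )
        except ValueError:
            out.append(
                GroupComparison(
                    group_low=int(g_low),
                    group_high=int(g_high),
                    hazard_ratio=float("nan"),
                    ci_low=float("nan"),
                    ci_high=float("nan"),
                    wald_p=float("nan"),
                    logrank_p=float(lr.p_value),
                    estimable=False,
                )
            )
    return out


def comparison_table(comparisons) -> pd.DataFrame:
    """Adjacent-pair report with columns
    groups_compared, hr, hr_lo, hr_hi, hr_p, logrank_p."""
    return pd.DataFrame(
        {
            "groups_compared": [f"{c.group_high} vs {c.group_low}" for c in comparisons],
            "hr": [c.hazard_ratio for c in comparisons],
            "hr_lo": [c.ci_low for c in comparisons],
            "hr_hi": [c.ci_high for c in comparisons],
            "hr_p": [c.wald_p for c in comparisons],
            "logrank_p": [c.logrank_p for c in comparisons],
        }
    )


def _pair_kernels(times, events, scores):
    """Full n x n permissibility and concordance kernel matrices."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    s = np.asarray(scores, dtype=float)
    earlier = t[:, None] < t[None, :]
    perm = (earlier & (e[:, None] == 1)) | (earlier.T & (e[None, :] == 1))
    higher = s[:, None] > s[None, :]
    tie = s[:, None] == s[None, :]
    # concordant when the earlier time carries the higher score
    conc = np.where(earlier, higher, higher.T).astype(float)
    conc = np.where(tie, 0.5, conc)
    h = perm * conc
    return perm.astype(float), h


def compare_c(times, events, scores_a, scores_b, alpha: float = 0.05, method: str = "ustat") -> CComparison:
    """Test the difference of two correlated Harrell C-indices.

    Both score vectors are evaluated on the same cases, so the two
    concordance estimates share their permissible pairs and are correlated.
    The variance of the difference is estimated from the Hajek projection
    of the ratio-of-U-statistics form (``method="ustat"``), or by
    leave-one-out jackknife (``method="jackknife"``); a normal
    approximation gives the CI and two-sided p.
    """
    times = np.asarray(times, dtype=float)
    n = times.size
    perm, h_a = _pair_kernels(times, events, scores_a)
    _, h_b = _pair_kernels(times, events, scores_b)
    s_perm = perm.sum()
    if s_perm == 0:
        raise ValueError("no permissible pairs: concordance undefined")
    c_a = h_a.sum() / s_perm
    c_b = h_b.sum() / s_perm
    diff = c_a - c_b

    if method == "ustat":
        q_i = perm.sum(axis=1) / (n - 1)
        g_a = h_a.sum(axis=1) / (n - 1) - c_a * q_i
        g_b = h_b.sum(axis=1) / (n - 1) - c_b * q_i
        q_bar = s_perm / (n * (n - 1))
        phi = 2.0 * (g_a - g_b) / q_bar
        var = float(np.var(phi, ddof=1)) / n
    elif method == "jackknife":
        row_perm = perm.sum(axis=1)
        row_a = h_a.sum(axis=1)
        row_b = h_b.sum(axis=1)
        den_i = s_perm - 2 * row_perm
        if np.any(den_i <= 0):
            raise ValueError("jackknife undefined: a case carries all permissible pairs")
        d_i = (h_a.sum() - 2 * row_a) / den_i - (h_b.sum() - 2 * row_b) / den_i
        var = float((n - 1) / n * np.sum((d_i - d_i.mean()) ** 2))
    else:
        raise ValueError(f"unknown method {method!r}")

    se = math.sqrt(max(var, 0.0))
    if se == 0.0:
        if diff == 0.0:
            return CComparison(c_a=c_a, c_b=c_b, ci_low=0.0, ci_high=0.0, p_value=1.0, se=0.0)
        return CComparison(
            c_a=c_a, c_b=c_b, ci_low=diff, ci_high=diff, p_value=0.0, se=0.0, degenerate=True
        )
    z = stats.norm.ppf(1 - alpha / 2)
    p = 2 * stats.norm.sf(abs(diff) / se)
    return CComparison(
        c_a=float(c_a),
        c_b=float(c_b),
        ci_low=float(diff - z * se),
        ci_high=float(diff + z * se),
        p_value=float(p),
        se=se,
    )


def cross_tabulate(groups_a, groups_b, margins: bool = True) -> pd.DataFrame:
    """Contingency table of two case-level assignments with totals."""
    a = pd.Series(groups_a, name="a")
    b = pd.Series(groups_b, name="b")
    if len(a) != len(b):
        raise ValueError("assignments must cover the same cases")
    return pd.crosstab(a, b, margins=margins, margins_name="Total")


def spearman_midrank(groups_a, groups_b) -> float:
    """Tie-corrected Spearman correlation (Pearson on mid-ranks)."""
    a = np.asarray(groups_a, dtype=float)
    b = np.asarray(groups_b, dtype=float)
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        raise ValueError("constant assignment: rank correlation undefined")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def risk_category_distribution(groups, factor_frame: pd.DataFrame, category_map) -> pd.DataFrame:
    """Distribution of each factor level's cases over risk categories.

    ``category_map`` maps category name -> iterable of group numbers and
    must partition the observed group numbers.  Rows (factor, level) hold
    proportions summing to 1, category columns in map order.
    """
    groups = np.asarray(groups, dtype=int)
    observed = set(int(g) for g in np.unique(groups))
    covered: set = set()
    for name, gs in category_map.items():
        gs = set(int(g) for g in gs)
        if covered & gs:
            raise ValueError(f"category {name!r} overlaps another category")
        covered |= gs
    if not observed <= covered:
        raise ValueError(f"groups {sorted(observed - covered)} not covered by the category map")

    cat = pd.Series(index=range(len(groups)), dtype=object)
    for name, gs in category_map.items():
        cat[np.isin(groups, list(gs))] = name
    rows = []
    for factor in factor_frame.columns:
        lv = factor_frame[factor].astype(str)
        for level in sorted(lv.unique()):
            sel = (lv == level).to_numpy()
            counts = cat[sel].value_counts()
            total = counts.sum()
            row = {"factor": factor, "level": level}
            for name in category_map:
                row[name] = counts.get(name, 0) / total
            rows.append(row)
    return pd.DataFrame(rows).set_index(["factor", "level"])
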