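"""Prognostic-group selection: Harrell's C, the C-index curve, the knee
rule for the number of groups, risk ordering, and the assignment rule.

The dendrogram is cut at each k, clusters are renumbered so that group 1
has the best pooled 5-year survival ("risk of mortality increases with the
group number"), and Harrell's concordance between the ordinal group number
and observed survival is plotted against k.  The optimal n* is the knee of
that curve — the point of diminishing returns — found as the k whose point
lies farthest (perpendicular distance) from the chord joining the curve's
endpoints; an explicit override lets the analyst explore around the knee.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import kaplan_meier
from .dissimilarity import DissimilarityMatrix, combination_curves
from .ensemble import EnsembleSpec, learned_matrix
from .linkage import Dendrogram, cut, minimax_linkage

__all__ = [
    "ConcordanceUndefinedError",
    "CIndexCurve",
    "PrognosticSystem",
    "harrell_c",
    "order_groups",
    "c_index_curve",
    "knee",
    "build_system",
    "apply_system",
]

DEFAULT_HORIZON = 60.0  # months: groups are ordered by 5-year survival


class ConcordanceUndefinedError(ValueError):
    """No permissible pairs: the concordance index is undefined."""


def harrell_c(times, events, scores) -> float:
    """Harrell's concordance index for right-censored data.

    ``scores`` are risk scores: higher score should mean shorter survival.
    Permissible pairs have distinct observed times with the earlier time an
    event; a pair is concordant when the earlier time has the strictly
    higher score, and score ties count 1/2.

    Raises
    ------
    ConcordanceUndefinedError
        If there are no permissible pairs.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if not times.shape == events.shape == scores.shape:
        raise ValueError("times, events, scores must have equal length")

    # factorize scores; counting is O(k * n log n) for k distinct values
    uniq, ranks = np.unique(scores, return_inverse=True)
    k = len(uniq)
    ev_mask = events == 1
    ev_t = times[ev_mask]
    ev_r = ranks[ev_mask]
    if ev_t.size == 0:
        raise ConcordanceUndefinedError("no events: no permissible pairs")

    n_later = np.searchsorted(np.sort(times), ev_t, side="right")
    total_later = times.size - n_later  # subjects with strictly larger time
    if k <= 256 or k * times.size <= 5_000_000:
        later_by_rank = np.empty((k, ev_t.size))
        for g in range(k):
            tg = np.sort(times[ranks == g])
            later_by_rank[g] = tg.size - np.searchsorted(tg, ev_t, side="right")
        cum = np.cumsum(later_by_rank, axis=0)
        later_lower = np.where(ev_r > 0, cum[np.maximum(ev_r - 1, 0), np.arange(ev_t.size)], 0.0)
        later_equal = later_by_rank[ev_r, np.arange(ev_t.size)]
    else:  # many distinct scores: chunked O(n^2) scan
        later_lower = np.zeros(ev_t.size)
        later_equal = np.zeros(ev_t.size)
        for start in range(0, ev_t.size, 512):
            sl = slice(start, start + 512)
            later = times[None, :] > ev_t[sl, None]
            later_lower[sl] = (later & (ranks[None, :] < ev_r[sl, None])).sum(axis=1)
            later_equal[sl] = (later & (ranks[None, :] == ev_r[sl, None])).sum(axis=1)

    permissible = float(total_later.sum())
    if permissible == 0:
        raise ConcordanceUndefinedError("no permissible pairs")
    concordant = float(later_lower.sum()) + 0.5 * float(later_equal.sum())
    return concordant / permissible


def _km_survival_at(times, events, horizon: float) -> float:
    curve = kaplan_meier(times, events)
    return float(curve.survival(min(horizon, curve.max_observed)))


def order_groups(labels, times, events, horizon: float = DEFAULT_HORIZON):
    """Rank clusters into ordinal groups 1..k by decreasing pooled KM
    survival at ``horizon`` months; ties by decreasing mean observed time.

    Returns ``(group_numbers, mapping)`` where ``group_numbers`` is the
    per-case ordinal (1 = lowest risk) and ``mapping`` maps each input
    cluster label to its group number.
    """
    labels = np.asarray(labels)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    stats = []
    for lab in np.unique(labels):
        sel = labels == lab
        s = _km_survival_at(times[sel], events[sel], horizon)
        stats.append((-s, -float(times[sel].mean()), lab))
    stats.sort()
    mapping = {lab: g + 1 for g, (_, _, lab) in enumerate(stats)}
    groups = np.array([mapping[lab] for lab in labels], dtype=int)
    return groups, mapping


@dataclass(frozen=True)
class CIndexCurve:
    ks: tuple
    c_values: tuple

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.ks, "c_index": self.c_values})


def c_index_curve(
    dendrogram: Dendrogram,
    case_keys,
    times,
    events,
    k_cap: int | None = None,
    horizon: float = DEFAULT_HORIZON,
) -> CIndexCurve:
    """Training concordance of the cut-and-ordered grouping for each k.

    ``C(1) = 0.5`` by convention (a single group predicts nothing).
    """
    m = dendrogram.m
    k_cap = min(m, 30) if k_cap is None else min(k_cap, m)
    key_index = {key: i for i, key in enumerate(dendrogram.keys)}
    leaf = np.array([key_index[k] for k in case_keys])
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)

    ks, cs = [], []
    for k in range(1, k_cap + 1):
        if k == 1:
            ks.append(1)
            cs.append(0.5)
            continue
        labels = cut(dendrogram, k)
        groups, _ = order_groups(labels[leaf], times, events, horizon)
        ks.append(k)
        cs.append(harrell_c(times, events, groups))
    return CIndexCurve(ks=tuple(ks), c_values=tuple(cs))


def knee(curve: CIndexCurve, override: int | None = None) -> int:
    """Knee of the C-index curve: the k whose point is farthest
    (perpendicular distance) from the chord joining the first and last
    points.  Ties go to the smallest k; a flat curve returns 1 with a
    warning; ``override`` replaces the automatic choice.
    """
    if override is not None:
        if override not in curve.ks:
            raise ValueError(f"override k={override} not on the curve")
        return int(override)
    ks = np.asarray(curve.ks, dtype=float)
    cs = np.asarray(curve.c_values, dtype=float)
    if len(ks) < 3:
        return int(ks[np.argmax(cs)])
    x0, y0, x1, y1 = ks[0], cs[0], ks[-1], cs[-1]
    dx, dy = x1 - x0, y1 - y0
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (ks - x0) - dx * (cs - y0)) / norm
    if np.allclose(dist, 0.0):
        warnings.warn("flat C-index curve: no knee, returning k=1", stacklevel=2)
        return 1
    return int(ks[int(np.argmax(dist))])  # argmax: first maximum = smallest k


@dataclass
class PrognosticSystem:
    """A fitted ordered grouping of factor-level combinations.

    ``assignment`` maps combination key -> group number (1 = lowest risk);
    ``group_summaries`` carries per-group size, events and survival at the
    ordering horizon; all intermediates are retained.
    """

    factor_subset: tuple
    tau: float
    n_star: int
    assignment: dict
    group_summaries: pd.DataFrame
    c_index: float
    curve: CIndexCurve
    dendrogram: Dendrogram
    initial: DissimilarityMatrix
    learned: DissimilarityMatrix
    horizon: float = DEFAULT_HORIZON

    def to_json(self) -> str:
        """Canonical (hash-stable) text serialization."""

        def native(obj):
            if hasattr(obj, "item"):
                return obj.item()
            raise TypeError(f"not serializable: {type(obj)}")

        payload = {
            "factor_subset": list(self.factor_subset),
            "tau": self.tau,
            "horizon": self.horizon,
            "n_star": self.n_star,
            "c_index": self.c_index,
            "assignment": {k: int(v) for k, v in sorted(self.assignment.items())},
            "group_summaries": self.group_summaries.to_dict(orient="list"),
            "c_index_curve": {"k": list(self.curve.ks), "c_index": list(self.curve.c_values)},
            "dendrogram": {
                "keys": list(self.dendrogram.keys),
                "merges": [
                    [mg.left, mg.right, mg.height, mg.prototype, list(mg.members)]
                    for mg in self.dendrogram.merges
                ],
                "has_inversions": self.dendrogram.has_inversions,
            },
            "initial_matrix": {"keys": list(self.initial.keys), "values": self.initial.values.tolist()},
            "learned_matrix": {"keys": list(self.learned.keys), "values": self.learned.values.tolist()},
        }
        return json.dumps(payload, sort_keys=True, indent=1, default=native)

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "PrognosticSystem":
        from .linkage import Merge

        p = json.loads(text)
        merges = tuple(
            Merge(left=a, right=b, height=h, prototype=pr, members=tuple(mem))
            for a, b, h, pr, mem in p["dendrogram"]["merges"]
        )
        dend = Dendrogram(
            keys=tuple(p["dendrogram"]["keys"]),
            merges=merges,
            has_inversions=p["dendrogram"]["has_inversions"],
        )
        return cls(
            factor_subset=tuple(p["factor_subset"]),
            tau=p["tau"],
            n_star=p["n_star"],
            assignment={k: int(v) for k, v in p["assignment"].items()},
            group_summaries=pd.DataFrame(p["group_summaries"]),
            c_index=p["c_index"],
            curve=CIndexCurve(ks=tuple(p["c_index_curve"]["k"]), c_values=tuple(p["c_index_curve"]["c_index"])),
            dendrogram=dend,
            initial=DissimilarityMatrix(
                keys=tuple(p["initial_matrix"]["keys"]), values=np.array(p["initial_matrix"]["values"])
            ),
            learned=DissimilarityMatrix(
                keys=tuple(p["learned_matrix"]["keys"]), values=np.array(p["learned_matrix"]["values"])
            ),
            horizon=p["horizon"],
        )

    @classmethod
    def load(cls, path) -> "PrognosticSystem":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _group_summaries(times, events, groups, horizon: float) -> pd.DataFrame:
    rows = []
    for g in np.unique(groups):
        sel = groups == g
        rows.append(
            {
                "group": int(g),
                "n": int(sel.sum()),
                "events": int(events[sel].sum()),
                "survival_at_horizon": _km_survival_at(times[sel], events[sel], horizon),
            }
        )
    return pd.DataFrame(rows)


def build_system(
    cohort,
    k_cap: int | None = None,
    n_star: int | None = None,
    ensemble: EnsembleSpec = EnsembleSpec(),
    horizon: float = DEFAULT_HORIZON,
    tau: float | None = None,
) -> PrognosticSystem:
    """End-to-end fit on a filtered training cohort.

    initial dissimilarities -> PAM ensemble -> minimax linkage ->
    C-index curve -> knee (or ``n_star`` override) -> cut -> risk ordering.
    """
    times = cohort.data["time"].to_numpy(dtype=float)
    events = cohort.data["event"].to_numpy(dtype=int)
    case_keys = cohort.data["combination"].to_numpy()

    keys, curves, tau = combination_curves(cohort, tau)
    m = len(keys)
    if m < 2:
        raise ValueError("need at least 2 combinations to build a system")
    vals = np.zeros((m, m))
    from .dissimilarity import initial_dissimilarity

    for i in range(m):
        for j in range(i + 1, m):
            d = initial_dissimilarity(curves[keys[i]], curves[keys[j]])
            vals[i, j] = vals[j, i] = d
    initial = DissimilarityMatrix(keys=keys, values=vals)

    learned = learned_matrix(initial, ensemble) if m >= 3 else initial
    dend = minimax_linkage(learned)
    curve = c_index_curve(dend, case_keys, times, events, k_cap=k_cap, horizon=horizon)
    n = knee(curve, override=n_star)
    n = max(n, 1)
    labels = cut(dend, n)
    key_index = {key: i for i, key in enumerate(dend.keys)}
    leaf = np.array([key_index[k] for k in case_keys])
    groups, mapping = order_groups(labels[leaf], times, events, horizon)
    assignment = {key: int(mapping[labels[key_index[key]]]) for key in keys}
    c_at_n = dict(zip(curve.ks, curve.c_values)).get(n)
    if c_at_n is None:
        c_at_n = harrell_c(times, events, groups)
    return PrognosticSystem(
        factor_subset=tuple(cohort.factor_subset),
        tau=tau,
        n_star=int(n),
        assignment=assignment,
        group_summaries=_group_summaries(times, events, groups, horizon),
        c_index=float(c_at_n),
        curve=curve,
        dendrogram=dend,
        initial=initial,
        learned=learned,
        horizon=horizon,
    )


def apply_system(system: PrognosticSystem, cohort_or_df):
    """Attach the fitted group numbers to new cases by combination key.

    Cases whose combination is unknown to the system are excluded and
    counted.  Returns ``(frame, n_excluded)`` where ``frame`` is the case
    table restricted to classifiable cases with a ``group`` column.
    """
    df = cohort_or_df.data if hasattr(cohort_or_df, "data") else cohort_or_df
    known = df["combination"].isin(system.assignment)
    n_excluded = int((~known).sum())
    out = df[known].reset_index(drop=True).copy()
    if out.empty:
        raise ValueError("no case maps to a combination known to the system")
    out["group"] = out["combination"].map(system.assignment).astype(int)
    return out, n_excluded
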