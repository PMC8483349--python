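"""Plot helpers: per-group KM curves, the C-index curve, and the annotated
dendrogram.  All helpers draw on a provided Axes or create one, and return
the Axes so callers can restyle."""

from __future__ import annotations

import numpy as np

from .curves import kaplan_meier


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_group_survival(frame, horizon: float = 60.0, ax=None):
    """Step KM curves per prognostic group with survival-at-horizon labels."""
    ax = _get_ax(ax)
    for g in sorted(frame["group"].unique()):
        sub = frame[frame["group"] == g]
        curve = kaplan_meier(sub["time"].to_numpy(), sub["event"].to_numpy())
        ts = np.concatenate(([0.0], curve.times, [curve.max_observed]))
        ss = np.concatenate(([1.0], curve.surv, [curve.surv[-1] if curve.surv.size else 1.0]))
        s_h = curve.survival(min(horizon, curve.max_observed))
        ax.step(ts, ss, where="post", label=f"group {g} ({100 * s_h:.1f}%)")
    ax.set_xlabel("months")
    ax.set_ylabel("survival")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize="small")
    return ax


def plot_c_index_curve(curve, n_star: int | None = None, ax=None):
    ax = _get_ax(ax)
    ax.plot(curve.ks, curve.c_values, marker="o", ms=3)
    if n_star is not None:
        c = dict(zip(curve.ks, curve.c_values)).get(n_star)
        if c is not None:
            ax.axvline(n_star, ls="--", color="grey")
            ax.annotate(f"n*={n_star}", (n_star, c), textcoords="offset points", xytext=(4, -10))
    ax.set_xlabel("number of groups")
    ax.set_ylabel("C-index")
    return ax


def plot_dendrogram(system, cohort=None, horizon: float = 60.0, ax=None):
    """Dendrogram with per-leaf survival-at-horizon annotations."""
    from scipy.cluster import hierarchy

    ax = _get_ax(ax)
    dend = system.dendrogram
    labels = list(dend.keys)
    if cohort is not None:
        ann = {}
        for key, grp in cohort.data.groupby("combination"):
            curve = kaplan_meier(grp["time"].to_numpy(), grp["event"].to_numpy())
            ann[key] = 100 * float(curve.survival(min(horizon, curve.max_observed)))
        labels = [f"{k} ({ann.get(k, float('nan')):.0f}%)" for k in labels]
    hierarchy.dendrogram(
        dend.linkage_matrix(), labels=labels, ax=ax, leaf_rotation=90, leaf_font_size=7
    )
    ax.set_ylabel("minimax radius")
    return ax
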