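"""Model/Results interface for building ordered prognostic grouping systems.

``PrognosticGroupModel`` is constructed from a case-level survival table
(a cohort or a DataFrame plus a factor scheme); ``fit()`` runs the whole
pipeline — Mann-Whitney initial dissimilarities on tail-completed KM
curves, PAM-ensemble dissimilarity learning, minimax-linkage clustering,
C-index knee selection — and returns a ``PrognosticGroupResults`` carrying
the fitted system, its diagnostics, and a ``summary()`` table.  Validation
(adjacent-group Cox/logrank, temporal application, head-to-head comparison
with an alternative staging) hangs off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evaluation
from .cohort import Cohort, FactorScheme, build_combinations, filter_rare
from .ensemble import EnsembleSpec
from .selection import (
    DEFAULT_HORIZON,
    PrognosticSystem,
    apply_system,
    build_system,
    harrell_c,
)

__all__ = ["PrognosticGroupModel", "PrognosticGroupResults"]


class PrognosticGroupModel:
    """Ordered prognostic grouping of factor-level combinations.

    Parameters
    ----------
    cohort : Cohort
        Case-level survival data with combination keys over the factors to
        be modelled (apply :func:`~eaccd.cohort.build_combinations` first to
        study a factor subset).
    min_count : int
        Combinations with fewer cases are removed before fitting
        (default 25).

    Examples
    --------
    >>> from eaccd.simulate import standard_fixture
    >>> cohort, truth = standard_fixture()
    >>> res = PrognosticGroupModel(cohort).fit()
    >>> res.n_star  # doctest: +SKIP
    4
    """

    def __init__(self, cohort: Cohort, min_count: int = 25):
        self.cohort, self.rare_report = filter_rare(cohort, min_count)
        self.min_count = min_count

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        scheme: FactorScheme,
        factors=None,
        min_count: int = 25,
    ) -> "PrognosticGroupModel":
        """Build from a raw case table (columns: time, event, factors, year)."""
        cohort = Cohort(scheme=scheme, data=data.copy())
        if factors is not None:
            cohort = build_combinations(cohort, factors)
        return cls(cohort, min_count=min_count)

    def fit(
        self,
        k_cap: int | None = None,
        n_star: int | None = None,
        ensemble: EnsembleSpec = EnsembleSpec(),
        horizon: float = DEFAULT_HORIZON,
        tau: float | None = None,
    ) -> "PrognosticGroupResults":
        """Run the four-step pipeline and select n* (knee or override)."""
        system = build_system(
            self.cohort,
            k_cap=k_cap,
            n_star=n_star,
            ensemble=ensemble,
            horizon=horizon,
            tau=tau,
        )
        return PrognosticGroupResults(self, system)


class PrognosticGroupResults:
    """Fitted prognostic system with diagnostics.

    Attributes
    ----------
    system : PrognosticSystem
        The assignment rule and all retained intermediates.
    n_star, c_index, tau : scalars
        Number of groups, training concordance at n*, completion start.
    """

    def __init__(self, model: PrognosticGroupModel, system: PrognosticSystem):
        self.model = model
        self.system = system

    # -- convenient scalar views ------------------------------------------
    @property
    def n_star(self) -> int:
        return self.system.n_star

    @property
    def c_index(self) -> float:
        return self.system.c_index

    @property
    def tau(self) -> float:
        return self.system.tau

    @property
    def assignment(self) -> dict:
        return dict(self.system.assignment)

    @property
    def c_index_curve(self) -> pd.DataFrame:
        return self.system.curve.as_frame()

    @property
    def group_summaries(self) -> pd.DataFrame:
        return self.system.group_summaries

    @property
    def dendrogram(self):
        return self.system.dendrogram

    # -- application and validation ---------------------------------------
    def apply(self, cohort_or_df):
        """Group numbers for new cases; unknown combinations are excluded.

        Returns ``(frame_with_group, n_excluded)``.
        """
        return apply_system(self.system, cohort_or_df)

    def groups(self) -> np.ndarray:
        """Per-case training group numbers."""
        frame, _ = self.apply(self.model.cohort)
        return frame["group"].to_numpy()

    def validate(self, cohort_or_df=None):
        """Stratification + accuracy report (internal if no data given).

        Returns a dict with the adjacent-pair Cox/logrank table
        (columns groups_compared, hr, hr_lo, hr_hi, hr_p, logrank_p), the
        C-index on the supplied cases, per-group KM summaries, and the
        exclusion count.
        """
        target = self.model.cohort if cohort_or_df is None else cohort_or_df
        frame, n_excluded = self.apply(target)
        t = frame["time"].to_numpy(dtype=float)
        e = frame["event"].to_numpy(dtype=int)
        g = frame["group"].to_numpy(dtype=int)
        comparisons = evaluation.adjacent_cox(t, e, g)
        from .selection import _group_summaries

        return {
            "table": evaluation.comparison_table(comparisons),
            "comparisons": comparisons,
            "c_index": harrell_c(t, e, g),
            "group_summaries": _group_summaries(t, e, g, self.system.horizon),
            "n_excluded": n_excluded,
        }

    def compare_with(self, alternative_groups, cohort_or_df=None):
        """Head-to-head comparison with an alternative case-level grouping.

        Returns a dict with the correlated C-index test, the contingency
        table, and the mid-rank Spearman correlation.
        """
        target = self.model.cohort if cohort_or_df is None else cohort_or_df
        frame, _ = self.apply(target)
        alt = np.asarray(alternative_groups)
        if len(alt) != len(frame):
            raise ValueError("alternative grouping must cover the classifiable cases")
        t = frame["time"].to_numpy(dtype=float)
        e = frame["event"].to_numpy(dtype=int)
        g = frame["group"].to_numpy(dtype=int)
        return {
            "c_test": evaluation.compare_c(t, e, g, alt),
            "contingency": evaluation.cross_tabulate(alt, g),
            "spearman_rho": evaluation.spearman_midrank(g, alt),
        }

    def risk_categories(self, category_map=None) -> pd.DataFrame:
        """Per-factor-level distribution over pooled risk categories.

        Default map splits the groups into low / medium / high thirds.
        """
        if category_map is None:
            gs = sorted(set(self.system.assignment.values()))
            k = len(gs)
            category_map = {
                "low": gs[: max(1, k // 3)],
                "medium": gs[max(1, k // 3) : max(2, 2 * k // 3)],
                "high": gs[max(2, 2 * k // 3) :],
            }
        frame, _ = self.apply(self.model.cohort)
        factors = list(self.model.cohort.factor_subset)
        return evaluation.risk_category_distribution(
            frame["group"].to_numpy(), frame[factors], category_map
        )

    # -- presentation -------------------------------------------------------
    def summary(self) -> str:
        sys = self.system
        lines = [
            "Prognostic grouping system",
            "=" * 52,
            f"Factors:              {', '.join(sys.factor_subset)}",
            f"Combinations:         {len(sys.assignment)}",
            f"Cases (training):     {len(self.model.cohort)}",
            f"Completion start tau: {sys.tau:.6g} months",
            f"Groups (n*):          {sys.n_star}",
            f"Training C-index:     {sys.c_index:.4f}",
            "",
            "Group summaries (ordering horizon "
            f"{sys.horizon:g} months):",
            sys.group_summaries.to_string(index=False),
        ]
        return "\n".join(lines)

    def save(self, path):
        self.system.save(path)

    # -- plots ---------------------------------------------------------------
    def plot_c_index_curve(self, ax=None):
        from .plotting import plot_c_index_curve

        return plot_c_index_curve(self.system.curve, self.n_star, ax=ax)

    def plot_survival(self, cohort_or_df=None, ax=None):
        from .plotting import plot_group_survival

        target = self.model.cohort if cohort_or_df is None else cohort_or_df
        frame, _ = self.apply(target)
        return plot_group_survival(frame, horizon=self.system.horizon, ax=ax)

    def plot_dendrogram(self, ax=None):
        from .plotting import plot_dendrogram

        return plot_dendrogram(self.system, self.model.cohort, ax=ax)
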