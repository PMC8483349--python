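"""Case-level cohort handling: factor schemes, combinations, filters, splits.

A *combination* is the subset of cases sharing one level of every studied
factor, keyed by the concatenated level codes in scheme order (the registry
style ``T1aN0M0A0S1``).  Rare combinations are removed before modelling and
a purely year-based temporal split separates training from validation
cases; validation cases whose combination does not survive the training
filter are excluded and counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FactorScheme",
    "CaseRecord",
    "Combination",
    "Cohort",
    "read_cohort",
    "build_combinations",
    "filter_rare",
    "temporal_split",
]

DEFAULT_MIN_COUNT = 25


@dataclass(frozen=True)
class FactorScheme:
    """Ordered prognostic factors with their admissible level codes.

    Parameters
    ----------
    factors : tuple of str
        Factor names in key order.
    levels : mapping
        Per factor, the ordered admissible level codes.
    recodes : mapping, optional
        Per factor, a numeric recode ``{"breaks": [...], "labels": [...]}``
        mapping a numeric column into level codes via right-closed bins
        ``(-inf, b1], (b1, b2], ..., (bk, inf)`` — e.g. an age cutoff of 70
        sends 70 to the younger level and 71 to the older one.
    separator : str
        Separator between level codes in combination keys (default none,
        matching the registry style).
    """

    factors: tuple
    levels: Mapping[str, tuple]
    recodes: Mapping[str, Mapping] = field(default_factory=dict)
    separator: str = ""

    def __post_init__(self):
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(self, "levels", {f: tuple(v) for f, v in self.levels.items()})
        if len(set(self.factors)) != len(self.factors):
            raise ValueError("factor names must be unique")
        for f in self.factors:
            if f not in self.levels:
                raise ValueError(f"no levels declared for factor {f!r}")
            lv = self.levels[f]
            if len(set(lv)) != len(lv):
                raise ValueError(f"duplicate level codes for factor {f!r}")
        for f, rc in self.recodes.items():
            breaks = list(rc["breaks"])
            if sorted(breaks) != breaks:
                raise ValueError(f"recode breaks for {f!r} must be increasing")
            if len(rc["labels"]) != len(breaks) + 1:
                raise ValueError(f"recode for {f!r} needs len(breaks)+1 labels")

    def key(self, row: Mapping, factors: Sequence[str] | None = None) -> str:
        factors = self.factors if factors is None else tuple(factors)
        return self.separator.join(str(row[f]) for f in factors)

    def recode_value(self, factor: str, value) -> str:
        rc = self.recodes[factor]
        breaks, labels = rc["breaks"], rc["labels"]
        i = int(np.searchsorted(np.asarray(breaks, dtype=float), float(value), side="left"))
        return labels[i]

    @classmethod
    def from_config(cls, path) -> "FactorScheme":
        """Load a scheme from a YAML config (factors, levels, recodes)."""
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            factors=tuple(cfg["factors"]),
            levels={f: tuple(v) for f, v in cfg["levels"].items()},
            recodes=cfg.get("recodes", {}) or {},
            separator=cfg.get("separator", ""),
        )


@dataclass(frozen=True)
class CaseRecord:
    time: float
    event: int
    levels: Mapping[str, str]
    combination_key: str
    cohort_year: int | None = None


@dataclass(frozen=True)
class Combination:
    key: str
    levels: Mapping[str, str]
    case_count: int


@dataclass
class Cohort:
    """A factor scheme plus its case table.

    ``data`` holds one row per case with columns ``time``, ``event``, one
    column per factor, optionally ``year``, and the derived ``combination``
    key over ``factor_subset``.
    """

    scheme: FactorScheme
    data: pd.DataFrame
    factor_subset: tuple = ()

    def __post_init__(self):
        if not self.factor_subset:
            self.factor_subset = self.scheme.factors
        self.factor_subset = tuple(self.factor_subset)
        if "combination" not in self.data.columns:
            self._rekey()

    def _rekey(self):
        sep = self.scheme.separator
        parts = [self.data[f].astype(str) for f in self.factor_subset]
        key = parts[0].str.cat(parts[1:], sep=sep) if len(parts) > 1 else parts[0].copy()
        self.data = self.data.assign(combination=key)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def combinations(self) -> list[Combination]:
        out = []
        for key, grp in self.data.groupby("combination", sort=True):
            lv = {f: str(grp.iloc[0][f]) for f in self.factor_subset}
            out.append(Combination(key=str(key), levels=lv, case_count=len(grp)))
        return out

    @property
    def combination_keys(self) -> tuple:
        return tuple(sorted(self.data["combination"].unique()))

    def records(self) -> Iterator[CaseRecord]:
        year = "year" in self.data.columns
        for _, row in self.data.iterrows():
            yield CaseRecord(
                time=float(row["time"]),
                event=int(row["event"]),
                levels={f: str(row[f]) for f in self.factor_subset},
                combination_key=str(row["combination"]),
                cohort_year=int(row["year"]) if year and pd.notna(row["year"]) else None,
            )

    def summary(self) -> pd.DataFrame:
        """Per-combination counts, events, and mean follow-up."""
        g = self.data.groupby("combination", sort=True)
        return pd.DataFrame(
            {
                "n": g.size(),
                "events": g["event"].sum().astype(int),
                "mean_time": g["time"].mean(),
            }
        ).reset_index()

    def write(self, path):
        cols = ["time", "event", *self.scheme.factors]
        if "year" in self.data.columns:
            cols.append("year")
        self.data[cols].to_csv(path, index=False)


def read_cohort(path, scheme: FactorScheme, column_map: Mapping[str, str] | None = None):
    """Read a delimited case table into a :class:`Cohort`.

    Rows with a missing or inadmissible factor level are dropped (complete
    cases only) and the drop count is returned alongside the cohort.
    CSV/TSV dialect is chosen by extension.

    Parameters
    ----------
    column_map : mapping, optional
        Maps logical names (``time``, ``event``, ``year``, factor names) to
        file column names; identity where omitted.

    Returns
    -------
    (Cohort, int)
        The cohort and the number of dropped rows.
    """
    column_map = dict(column_map or {})
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    raw = pd.read_csv(path, sep=sep)

    def col(name):
        c = column_map.get(name, name)
        if c not in raw.columns:
            raise ValueError(f"mapped column {c!r} (for {name!r}) not in file")
        return c

    df = pd.DataFrame()
    try:
        df["time"] = pd.to_numeric(raw[col("time")], errors="raise")
        df["event"] = pd.to_numeric(raw[col("event")], errors="raise").astype(int)
    except (ValueError, TypeError) as exc:
        bad_t = pd.to_numeric(raw[col("time")], errors="coerce")
        bad_e = pd.to_numeric(raw[col("event")], errors="coerce")
        bad = bad_t.isna() | bad_e.isna()
        rows = list(raw.index[bad][:5])
        raise ValueError(f"unparseable time/event at rows {rows}") from exc
    if (df["time"] < 0).any() or not np.isfinite(df["time"]).all():
        rows = list(df.index[(df["time"] < 0) | ~np.isfinite(df["time"])][:5])
        raise ValueError(f"negative or non-finite time at rows {rows}")
    if not df["event"].isin((0, 1)).all():
        rows = list(df.index[~df["event"].isin((0, 1))][:5])
        raise ValueError(f"event not 0/1 at rows {rows}")

    ycol = column_map.get("year", "year")
    if ycol in raw.columns:
        df["year"] = pd.to_numeric(raw[ycol], errors="coerce")

    valid = pd.Series(True, index=raw.index)
    for f in scheme.factors:
        c = col(f)
        if f in scheme.recodes:
            num = pd.to_numeric(raw[c], errors="coerce")
            lv = pd.Series(
                [scheme.recode_value(f, v) if pd.notna(v) else None for v in num],
                index=raw.index,
                dtype=object,
            )
        else:
            lv = raw[c].astype(object).where(raw[c].notna(), None)
            lv = lv.map(lambda v: str(v).strip() if v is not None and str(v).strip() else None)
        ok = lv.map(lambda v: v in scheme.levels[f] if v is not None else False)
        valid &= ok
        df[f] = lv
    dropped = int((~valid).sum())
    df = df[valid.to_numpy()].reset_index(drop=True)
    return Cohort(scheme=scheme, data=df), dropped


def build_combinations(cohort: Cohort, factor_subset: Sequence[str]) -> Cohort:
    """Recompute combination keys over a subset of the scheme's factors.

    Collapsing to fewer factors pools cases: keys are the level codes of
    only the retained factors, joined in scheme order.
    """
    subset = tuple(f for f in cohort.scheme.factors if f in set(factor_subset))
    if not subset:
        raise ValueError("factor subset must be non-empty")
    if set(factor_subset) - set(cohort.scheme.factors):
        raise ValueError(f"unknown factors: {set(factor_subset) - set(cohort.scheme.factors)}")
    df = cohort.data.drop(columns=["combination"], errors="ignore").copy()
    return Cohort(scheme=cohort.scheme, data=df, factor_subset=subset)


def filter_rare(cohort: Cohort, min_count: int = DEFAULT_MIN_COUNT):
    """Remove combinations with fewer than ``min_count`` cases.

    Returns the filtered cohort and a report DataFrame of removed
    combination keys with their counts.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = cohort.data["combination"].value_counts()
    rare = counts[counts < min_count]
    report = pd.DataFrame({"combination": rare.index, "n": rare.to_numpy()}).sort_values(
        "combination"
    ).reset_index(drop=True)
    keep = ~cohort.data["combination"].isin(set(rare.index))
    if not keep.any():
        raise ValueError("filter_rare removed every combination")
    out = Cohort(
        scheme=cohort.scheme,
        data=cohort.data[keep].reset_index(drop=True),
        factor_subset=cohort.factor_subset,
    )
    return out, report


def temporal_split(cohort: Cohort, cutoff_year: int, min_count: int = DEFAULT_MIN_COUNT):
    """Year-based split into training (< cutoff) and validation (= cutoff).

    The rare-combination filter is applied to the training side only;
    validation keeps only cases whose combination exists in the filtered
    training set (others cannot be classified and are excluded).

    Returns
    -------
    (train, validation, report)
        ``report`` is a dict with ``rare_removed`` (DataFrame),
        ``validation_excluded`` (int), ``excluded_keys`` (list), and the
        case counts making the partition exact:
        ``len(train) + len(validation) + report["excluded_total"]`` equals
        the input size.
    """
    if "year" not in cohort.data.columns:
        raise ValueError("temporal_split requires a year column")
    years = cohort.data["year"]
    train_df = cohort.data[years < cutoff_year].reset_index(drop=True)
    val_df = cohort.data[years == cutoff_year].reset_index(drop=True)
    n_out_of_range = int(len(cohort.data) - len(train_df) - len(val_df))
    if val_df.empty:
        warnings.warn("temporal_split: empty validation set", stacklevel=2)
    train = Cohort(scheme=cohort.scheme, data=train_df, factor_subset=cohort.factor_subset)
    n_train_before = len(train)
    train, rare_report = filter_rare(train, min_count)
    n_rare_cases = n_train_before - len(train)
    keys = set(train.data["combination"].unique())
    in_train = val_df["combination"].isin(keys)
    excluded_keys = sorted(val_df.loc[~in_train, "combination"].unique())
    n_excluded = int((~in_train).sum())
    validation = Cohort(
        scheme=cohort.scheme,
        data=val_df[in_train].reset_index(drop=True),
        factor_subset=cohort.factor_subset,
    )
    report = {
        "rare_removed": rare_report,
        "rare_cases_removed": n_rare_cases,
        "validation_excluded": n_excluded,
        "excluded_keys": excluded_keys,
        "year_out_of_range": n_out_of_range,
        "excluded_total": n_rare_cases + n_excluded + n_out_of_range,
    }
    return train, validation, report
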