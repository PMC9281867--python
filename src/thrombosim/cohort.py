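"""Cohort container, CSV interchange and cohort-level statistics.

The cohort CSV is one row per donor:

    donor_id,group,sex,genotype_20210,FII_pct,FV_pct,FVII_pct,FVIII_pct,
    FIX_pct,FX_pct,AT_pct,TF_pM,TFPI_U_per_mL

Statistical conventions follow the study design: control-group normal
ranges are mean +/- 2 SD, group comparisons use an unpaired t-test
(pooled-variance by default, Welch optional), categorical comparisons a
Pearson chi-squared test, and factor/drug-effect associations Pearson
correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scheme import MEASURED_FACTORS
from .units import FactorPanel, PanelError

__all__ = [
    "CohortTable",
    "COHORT_COLUMNS",
    "normal_range",
    "compare_groups",
    "compare_groups_from_stats",
    "compare_categorical",
    "carriage_frequency",
    "assign_tertiles",
    "tertile_stratify",
    "heatmap_matrix",
    "correlate_factors_with_effects",
]

_FACTOR_COLUMNS = {
    "FII": "FII_pct",
    "FV": "FV_pct",
    "FVII": "FVII_pct",
    "FVIII": "FVIII_pct",
    "FIX": "FIX_pct",
    "FX": "FX_pct",
    "AT": "AT_pct",
    "TF": "TF_pM",
    "TFPI": "TFPI_U_per_mL",
}

COHORT_COLUMNS = ["donor_id", "group", "sex", "genotype_20210"] + [
    _FACTOR_COLUMNS[f] for f in MEASURED_FACTORS
]

TERTILE_LABELS = ("low", "medium", "high")


class CohortTable:
    """An ordered collection of :class:`FactorPanel` with unique donor ids."""

    def __init__(self, panels: Sequence[FactorPanel]) -> None:
        self.panels = list(panels)
        ids = [p.donor_id for p in self.panels]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelError(f"duplicate donor_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.panels)

    def __iter__(self):
        return iter(self.panels)

    def __getitem__(self, donor_id: str) -> FactorPanel:
        for p in self.panels:
            if p.donor_id == donor_id:
                return p
        raise KeyError(donor_id)

    def subset(self, group: str | None = None, sex: str | None = None) -> "CohortTable":
        panels = [
            p
            for p in self.panels
            if (group is None or p.group == group) and (sex is None or p.sex == sex)
        ]
        return CohortTable(panels)

    def counts(self) -> pd.DataFrame:
        df = self.to_dataframe()
        return df.groupby(["group", "sex"], observed=True).size().unstack(fill_value=0)

    def levels(self, factor: str, group: str | None = None, sex: str | None = None) -> np.ndarray:
        return np.array([p[factor] for p in self.subset(group, sex)])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.panels:
            row = {
                "donor_id": p.donor_id,
                "group": p.group,
                "sex": p.sex,
                "genotype_20210": p.genotype_20210,
            }
            for f, col in _FACTOR_COLUMNS.items():
                row[col] = p[f]
            rows.append(row)
        return pd.DataFrame(rows, columns=COHORT_COLUMNS)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CohortTable":
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise PanelError(f"cohort table missing column(s) {missing}")
        panels = []
        for _, row in df.iterrows():
            panels.append(
                FactorPanel(
                    donor_id=str(row["donor_id"]),
                    group=str(row["group"]),
                    sex=str(row["sex"]),
                    genotype_20210=str(row["genotype_20210"]),
                    levels={f: float(row[col]) for f, col in _FACTOR_COLUMNS.items()},
                )
            )
        return cls(panels)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        return cls.from_dataframe(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Statistics

def normal_range(values: Iterable[float]) -> tuple[float, float]:
    """Control-population normal range: mean +/- 2 sample SD."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("normal range needs at least two values")
    m = x.mean()
    sd = x.std(ddof=1)
    return (m - 2.0 * sd, m + 2.0 * sd)


def compare_groups(
    a: Iterable[float], b: Iterable[float], equal_var: bool = True
) -> tuple[float, float]:
    """Unpaired two-sample t-test; returns (t, two-sided p)."""
    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two values")
    if x.std() == 0 and y.std() == 0 and x.mean() == y.mean():
        return (0.0, 1.0)
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    return (float(t), float(p))


def compare_groups_from_stats(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float,
    equal_var: bool = True,
) -> tuple[float, float]:
    """t-test from summary statistics (n, mean, SD per group)."""
    t, p = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var
    )
    return (float(t), float(p))


def compare_categorical(
    table: Sequence[Sequence[float]], correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-squared test on a contingency table of counts."""
    arr = np.asarray(table, dtype=float)
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("contingency table must hold nonnegative integer counts")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    res = sps.chi2_contingency(arr, correction=correction)
    return (float(res.statistic), float(res.pvalue))


def carriage_frequency(carriers: int, n: int) -> float:
    """Allele/genotype carriage as a percentage of the group."""
    if n <= 0:
        raise ValueError("group size must be positive")
    if not 0 <= carriers <= n:
        raise ValueError("carriers must lie in [0, n]")
    return 100.0 * carriers / n


# ---------------------------------------------------------------------------
# Tertile stratification and the heatmap export

def assign_tertiles(values: pd.Series) -> pd.Series:
    """Rank-based tertiles (low/medium/high), deterministic under ties.

    Donors are sorted by value then id; sizes differ by at most one, with
    any remainder going to the lower tertiles.
    """
    values = values.astype(float)
    if values.size < 3:
        raise ValueError("tertiles need at least three donors")
    order = sorted(values.index, key=lambda i: (values[i], str(i)))
    n = len(order)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    labels = {}
    pos = 0
    for label, size in zip(TERTILE_LABELS, sizes):
        for i in order[pos : pos + size]:
            labels[i] = label
        pos += size
    out = pd.Series([labels[i] for i in values.index], index=values.index)
    return out


def tertile_stratify(
    summaries: pd.DataFrame,
    key: str = "peak_FIIa",
    cohort: CohortTable | None = None,
) -> pd.DataFrame:
    """Assign each donor a thrombin-generation tertile (and factor tertiles).

    ``summaries`` is indexed by donor_id with the stratification key as a
    column.  When a cohort is supplied, each measured factor's raw level is
    tertiled the same way and returned alongside.
    """
    if key not in summaries.columns:
        raise KeyError(f"stratification key {key!r} not in summaries")
    vals = summaries[key].astype(float)
    finite = vals[np.isfinite(vals)]
    if finite.size < 3:
        raise ValueError("need at least three donors with a finite key")
    if finite.nunique() == 1:
        out = pd.DataFrame(index=vals.index)
        out["tertile"] = "degenerate"
        return out
    out = pd.DataFrame(index=vals.index)
    out["tertile"] = assign_tertiles(finite).reindex(vals.index)
    if cohort is not None:
        df = cohort.to_dataframe().set_index("donor_id").loc[vals.index]
        for f, col in _FACTOR_COLUMNS.items():
            out[f"{f}_tertile"] = assign_tertiles(df[col])
    return out


def heatmap_matrix(
    cohort: CohortTable,
    assignment: pd.DataFrame,
    drug_effects: pd.DataFrame | None = None,
    key: str = "peak_FIIa",
    summaries: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Donor-by-factor tertile matrix with annotation columns.

    Rows are donors sorted deterministically by (thrombin tertile, key
    value, donor_id); columns are the nine factor tertiles plus sex, group
    and, when available, per-drug percent effects on peak thrombin and time
    to peak.  This is the data behind the stratification heatmap; rendering
    is left to the caller.
    """
    df = cohort.to_dataframe().set_index("donor_id")
    if "tertile" not in assignment.columns:
        raise KeyError("assignment must carry a 'tertile' column")
    out = assignment.copy()
    missing = [i for i in out.index if i not in df.index]
    if missing:
        raise KeyError(f"assignment covers unknown donors: {missing[:3]}")
    for f, col in _FACTOR_COLUMNS.items():
        if f"{f}_tertile" not in out.columns:
            out[f"{f}_tertile"] = assign_tertiles(df.loc[out.index, col])
    out["sex"] = df.loc[out.index, "sex"]
    out["group"] = df.loc[out.index, "group"]
    if drug_effects is not None:
        wide = drug_effects.pivot_table(
            index="donor_id",
            columns="drug",
            values=["pct_peak_reduction", "pct_time_to_peak_change"],
        )
        wide.columns = [f"{drug}_{metric}" for metric, drug in wide.columns]
        out = out.join(wide.reindex(out.index))
    rank = {label: i for i, label in enumerate(TERTILE_LABELS + ("degenerate",))}
    sort_key = (
        summaries[key].reindex(out.index).astype(float)
        if summaries is not None and key in summaries
        else pd.Series(0.0, index=out.index)
    )
    out = out.assign(_rank=[rank[t] for t in out["tertile"]], _key=sort_key)
    out = out.sort_values(["_rank", "_key", "donor_id"], kind="mergesort").drop(
        columns=["_rank", "_key"]
    )
    return out


def correlate_factors_with_effects(
    cohort: CohortTable,
    drug_effects: pd.DataFrame,
    endpoint: str = "pct_peak_reduction",
) -> pd.DataFrame:
    """Pearson correlation of each measured factor with each drug's effect.

    ``drug_effects`` needs columns donor_id, drug and the endpoint.  Rows
    with a zero-variance factor are flagged undefined rather than dropped.
    """
    if endpoint not in drug_effects.columns:
        raise KeyError(f"endpoint {endpoint!r} not in drug effects")
    df = cohort.to_dataframe().set_index("donor_id")
    rows = []
    for drug, sub in drug_effects.groupby("drug"):
        sub = sub.set_index("donor_id")
        ids = [i for i in sub.index if i in df.index]
        y = sub.loc[ids, endpoint].astype(float)
        for f, col in _FACTOR_COLUMNS.items():
            x = df.loc[ids, col].astype(float)
            mask = np.isfinite(x) & np.isfinite(y)
            n = int(mask.sum())
            if n < 3 or x[mask].nunique() == 1 or y[mask].nunique() == 1:
                rows.append(
                    dict(factor=f, drug=drug, endpoint=endpoint, r=math.nan,
                         p=math.nan, n=n, defined=False)
                )
                continue
            r, p = sps.pearsonr(x[mask], y[mask])
            rows.append(
                dict(factor=f, drug=drug, endpoint=endpoint, r=float(r),
                     p=float(p), n=n, defined=True)
            )
    return pd.DataFrame(rows)
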