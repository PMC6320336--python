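"""Categorical association of egg clusters with life-history predictors.

Non-binary predictors are binned into three categories (lay date: 4-day
half-open intervals from the season start; laying order: early = eggs 1 and
3, middle = 5 and 7, late = 9, 11 and 13; clutch size: small = 8-10,
average = 11-12, large = 13-15); binary predictors pass through. Each
predictor is tested against the egg clusters with a functional chi-square
test — an asymmetric contingency-table statistic that asks whether the
column variable is a (noisy) function of the row variable — with
Benjamini-Hochberg FDR across the predictor battery. Fisher's exact test
handles 2x2 questions such as whether extra-pair eggs are confined to first
laying positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .infer import benjamini_hochberg

logger = logging.getLogger(__name__)

__all__ = [
    "CategorizationScheme",
    "LAYING_ORDER_SCHEME",
    "CLUTCH_SIZE_SCHEME",
    "lay_date_scheme",
    "categorize",
    "functional_chisq",
    "fisher_exact",
    "egg_cluster_association",
]


@dataclass
class CategorizationScheme:
    """Maps raw values of one variable onto category labels."""

    variable: str
    mapping: Mapping  # value -> label; disjoint by construction
    passthrough: bool = False

    def label(self, value):
        if self.passthrough:
            return value
        if value not in self.mapping:
            raise KeyError(value)
        return self.mapping[value]


LAYING_ORDER_SCHEME = CategorizationScheme(
    "laying_order",
    {1: "early", 3: "early", 5: "middle", 7: "middle",
     9: "late", 11: "late", 13: "late"},
)
CLUTCH_SIZE_SCHEME = CategorizationScheme(
    "clutch_size",
    {**{v: "small" for v in (8, 9, 10)},
     **{v: "average" for v in (11, 12)},
     **{v: "large" for v in (13, 14, 15)}},
)


def lay_date_scheme(season_start: int = 0, width: int = 4,
                    n_bins: int = 3) -> CategorizationScheme:
    """Half-open ``width``-day bins from the season start."""
    labels = ["early", "middle", "late"][:n_bins] + [
        f"bin{i}" for i in range(3, n_bins)]

    class _DateMap(dict):
        def __contains__(self, value):
            k = (value - season_start) // width
            return 0 <= k < n_bins

        def __getitem__(self, value):
            k = (value - season_start) // width
            if not 0 <= k < n_bins:
                raise KeyError(value)
            return labels[int(k)]

    return CategorizationScheme("lay_date", _DateMap())


def categorize(values: Sequence, scheme: CategorizationScheme) -> np.ndarray:
    """Apply a categorization scheme, erroring on uncovered values."""
    out = []
    uncovered = []
    for v in values:
        try:
            out.append(scheme.label(v))
        except KeyError:
            uncovered.append(v)
    if uncovered:
        raise ValueError(
            f"value(s) not covered by the {scheme.variable} scheme: "
            f"{sorted(set(uncovered))}")
    return np.asarray(out)


@dataclass
class FunctionalChisqResult:
    statistic: float
    df: int
    p_asymptotic: float
    p_permutation: float | None = None


def _fc_statistic(table: np.ndarray) -> float:
    """FC = sum_ij (n_ij - n_i./c)^2 / (n_i./c) - sum_j (n_.j - n/c)^2 / (n/c)."""
    t = table.astype(float)
    r, c = t.shape
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = t.sum()
    e_row = row / c
    first = np.sum((t - e_row[:, None]) ** 2 / e_row[:, None])
    e_col = n / c
    second = np.sum((col - e_col) ** 2 / e_col)
    return float(first - second)


def functional_chisq(table, n_perm: int = 10_000, seed: int = 0,
                     permutation: bool = True) -> FunctionalChisqResult:
    """Functional chi-square test: are the columns a function of the rows?

    Asymptotic reference: chi-square with (r-1)(c-1) degrees of freedom. The
    permutation p (optional) shuffles the column variable across
    observations, which preserves both margins, and is reported alongside
    the asymptotic value.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need an r x c table with r >= 2 and c >= 2")
    if np.any(t.sum(axis=1) == 0):
        raise ValueError("empty row in contingency table")
    r, c = t.shape
    fc = _fc_statistic(t)
    df = (r - 1) * (c - 1)
    p_asym = float(stats.chi2.sf(fc, df))
    p_perm = None
    if permutation:
        rng = np.random.default_rng(seed)
        rows = np.repeat(np.arange(r), t.sum(axis=1).astype(int))
        cols = np.repeat(np.arange(c), t.sum(axis=0).astype(int))
        n = len(rows)
        count = 0
        for _ in range(n_perm):
            perm_cols = cols[rng.permutation(n)]
            pt = np.zeros((r, c))
            np.add.at(pt, (rows, perm_cols), 1.0)
            if _fc_statistic(pt) >= fc - 1e-12:
                count += 1
        p_perm = (1 + count) / (1 + n_perm)
    return FunctionalChisqResult(statistic=fc, df=df, p_asymptotic=p_asym,
                                 p_permutation=p_perm)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (probability-ordering rule)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        logger.warning("empty margin in 2x2 table; p = 1")
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


PREDICTOR_SCHEMES = {
    "clutch_size": CLUTCH_SIZE_SCHEME,
    "laying_order": LAYING_ORDER_SCHEME,
    "female_age": CategorizationScheme("female_age", {}, passthrough=True),
    "embryo_sex": CategorizationScheme("embryo_sex", {}, passthrough=True),
    "paternity": CategorizationScheme("paternity", {}, passthrough=True),
}


def egg_cluster_association(egg_clusters: pd.Series, predictors: pd.DataFrame,
                            season_start: int | None = None,
                            n_perm: int = 10_000, seed: int = 0
                            ) -> pd.DataFrame:
    """Functional chi-square of each life-history predictor on egg clusters.

    One test per predictor (clutch size, lay date, laying order, female age,
    embryo sex, paternity); predictors are categorised first; BH-FDR across
    the battery. Constant predictors are excluded with a warning. Eggs with
    unknown paternity are dropped from the paternity test only.
    """
    clusters = egg_clusters.astype(int)
    rows = []
    for name in predictors.columns:
        vals = predictors[name]
        cl = clusters
        if name == "paternity":
            keep = vals.isin(["within-pair", "extra-pair"])
            vals, cl = vals[keep], clusters[keep]
        if name == "lay_date":
            start = (season_start if season_start is not None
                     else int(vals.min()))
            cats = categorize(vals, lay_date_scheme(season_start=start))
        elif name in PREDICTOR_SCHEMES:
            cats = categorize(vals, PREDICTOR_SCHEMES[name])
        else:
            cats = np.asarray(vals)
        if len(pd.unique(cats)) < 2:
            logger.warning("predictor %s is constant; excluded", name)
            rows.append({"predictor": name, "statistic": np.nan, "df": 0,
                         "p_asym": np.nan, "p_perm": np.nan})
            continue
        tab = pd.crosstab(pd.Series(cats, index=vals.index), cl)
        res = functional_chisq(tab.to_numpy(), n_perm=n_perm, seed=seed)
        rows.append({"predictor": name, "statistic": res.statistic,
                     "df": res.df, "p_asym": res.p_asymptotic,
                     "p_perm": res.p_permutation})
    out = pd.DataFrame(rows)
    ok = out["p_asym"].notna()
    out["p_fdr"] = np.nan
    if ok.any():
        out.loc[ok, "p_fdr"] = benjamini_hochberg(out.loc[ok, "p_asym"])
    return out
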