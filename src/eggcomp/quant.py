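"""Label-free quantitation: filters, normalisation, imputation, concentrations.

Stages mirror a label-free MS workflow on egg compartments:

1. a protein counts as *identified* in a sample when at least two technical
   replicate runs gave a positive intensity;
2. a protein is *quantitated* (kept) when it is identified in at least half
   of the samples of at least one biological group;
3. intensities are normalised to the total MS signal of each
   (sample, replicate) run;
4. missing values are drawn from a uniform distribution bounded by the run's
   minimum observed normalised intensity and its 1% quantile (low-abundance
   imputation for missing-not-at-random dropout);
5. normalised shares are converted to concentrations (mg per g wet
   compartment) using the compartment's total protein assay and weight;
6. replicate-level concentrations are summarised per sample, absorbing MS
   batch offsets with a batch random intercept.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from math import ceil
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "filter_identified",
    "filter_quantitated",
    "normalize_total_signal",
    "impute_missing",
    "estimate_concentration",
    "summarize_replicates",
    "quantify",
]

_KEY = ["protein_id", "sample_id", "replicate_id"]


def _check_keys(table: pd.DataFrame) -> None:
    if table.duplicated(_KEY).any():
        dup = table[table.duplicated(_KEY)].iloc[0]
        raise ValueError(
            f"duplicate (protein, sample, replicate) key: "
            f"{tuple(dup[k] for k in _KEY)}")


def filter_identified(table: pd.DataFrame) -> pd.DataFrame:
    """Flag (protein, sample) pairs identified in >= 2 replicate runs.

    A replicate counts as positive when its intensity is present and > 0;
    missing (NaN) and zero intensities do not count. Samples with a single
    replicate can never satisfy the criterion and are logged.
    """
    _check_keys(table)
    n_reps = table.groupby("sample_id")["replicate_id"].nunique()
    singles = n_reps[n_reps < 2]
    if len(singles):
        logger.warning(
            "%d sample(s) have a single replicate and cannot meet the "
            "two-replicate identification criterion: %s",
            len(singles), ", ".join(map(str, singles.index[:10])))
    positive = table["intensity"].notna() & (table["intensity"] > 0)
    flags = (positive.groupby([table["protein_id"], table["sample_id"]])
             .sum().ge(2).rename("identified").reset_index())
    return flags


def filter_quantitated(flags: pd.DataFrame,
                       group_labels: Mapping[str, str]) -> set[str]:
    """Keep proteins identified in >= half the samples of some group.

    ``group_labels`` maps every sample to its biological group; the
    denominator of "half the samples" is the full group size, whether or not
    the protein was measured there.
    """
    samples = pd.Series(dict(group_labels), name="group")
    if samples.empty:
        raise ValueError("no group labels given")
    group_sizes = samples.value_counts()
    if (group_sizes < 1).any():
        raise ValueError("empty biological group")
    missing = set(flags["sample_id"]) - set(samples.index)
    if missing:
        raise ValueError(f"samples without a group label: {sorted(missing)[:5]}")

    f = flags.merge(samples.rename_axis("sample_id").reset_index(),
                    on="sample_id")
    hits = (f[f["identified"]]
            .groupby(["protein_id", "group"])["sample_id"].nunique()
            .rename("n_identified").reset_index())
    hits["needed"] = hits["group"].map(lambda g: ceil(group_sizes[g] / 2))
    kept = set(hits.loc[hits["n_identified"] >= hits["needed"], "protein_id"])
    return kept


def normalize_total_signal(table: pd.DataFrame) -> pd.DataFrame:
    """Divide every intensity by the total signal of its (sample, replicate) run."""
    _check_keys(table)
    out = table.copy()
    totals = out.groupby(["sample_id", "replicate_id"])["intensity"].transform(
        lambda s: s.sum(skipna=True))
    bad = out.loc[totals <= 0, ["sample_id", "replicate_id"]].drop_duplicates()
    if len(bad):
        first = bad.iloc[0]
        raise ValueError(
            f"zero total MS signal for sample {first['sample_id']!r} "
            f"replicate {first['replicate_id']!r}")
    out["intensity"] = out["intensity"] / totals
    out.attrs["stage"] = "normalized"
    return out


def _run_rng(seed: int, sample_id: str, replicate_id) -> np.random.Generator:
    # independent stream per run so adding proteins elsewhere leaves draws alone
    tag = zlib.crc32(f"{sample_id}\t{replicate_id}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def impute_missing(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Replace missing normalised intensities by bounded-uniform draws.

    Bounds per (sample, replicate) run: [minimum observed value, 1% quantile
    of observed values] (interpolated quantile). Deterministic for a fixed
    seed and invariant to protein input order.
    """
    out = table.copy()
    filled = []
    for (sid, rid), grp in out.groupby(["sample_id", "replicate_id"],
                                       sort=True):
        obs = grp["intensity"].dropna()
        miss_idx = grp.index[grp["intensity"].isna()]
        if len(miss_idx) == 0:
            continue
        if obs.empty:
            raise ValueError(
                f"no observed values in sample {sid!r} replicate {rid!r}; "
                "imputation bounds undefined")
        lo = float(obs.min())
        hi = float(np.quantile(obs.to_numpy(), 0.01))
        rng = _run_rng(seed, sid, rid)
        # draw in the sorted-protein order for input-order invariance
        order = grp.loc[miss_idx, "protein_id"].sort_values().index
        out.loc[order, "intensity"] = rng.uniform(lo, hi, size=len(order))
        filled.append(len(order))
    out.attrs["stage"] = "imputed"
    return out


def estimate_concentration(table: pd.DataFrame,
                           protein_totals: Mapping[str, float],
                           compartment_weights: Mapping[str, float]
                           ) -> pd.DataFrame:
    """Convert normalised shares to mg protein per g wet compartment.

    concentration = share x total protein (mg) / compartment weight (g).
    Shares are renormalised within each (sample, replicate) run so that the
    summed concentrations reproduce the measured total exactly even after
    imputation added a little mass.
    """
    out = table.copy()
    for sid in out["sample_id"].unique():
        if sid not in protein_totals:
            raise ValueError(f"no total protein value for sample {sid!r}")
        if sid not in compartment_weights:
            raise ValueError(f"no compartment weight for sample {sid!r}")
    run_sum = out.groupby(["sample_id", "replicate_id"])["intensity"].transform("sum")
    share = out["intensity"] / run_sum
    totals = out["sample_id"].map(dict(protein_totals))
    weights = out["sample_id"].map(dict(compartment_weights))
    out["concentration"] = share * totals / weights
    out = out.drop(columns=["intensity"])
    return out


def summarize_replicates(conc: pd.DataFrame, method: str = "lmm"
                         ) -> pd.DataFrame:
    """Per-sample protein abundance from replicate-level concentrations.

    With more than one MS batch, each protein's per-sample abundance is the
    sample fixed-effect estimate from a Gaussian mixed model with batch as
    random intercept; with a single batch (or ``method='mean'``) this
    collapses to the replicate mean. Model failures fall back to the mean
    and are logged.
    """
    import statsmodels.api as sm

    keep_cols = [c for c in ("compartment",) if c in conc.columns]
    rows = []
    for pid, grp in conc.groupby("protein_id", sort=True):
        extras = {c: grp[c].iloc[0] for c in keep_cols}
        n_batches = grp["batch_id"].nunique() if "batch_id" in grp else 1
        if method == "mean" or n_batches < 2:
            est = grp.groupby("sample_id")["concentration"].mean()
        else:
            try:
                dummies = pd.get_dummies(grp["sample_id"], dtype=float)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.MixedLM(grp["concentration"].to_numpy(),
                                     dummies.to_numpy(),
                                     groups=grp["batch_id"].to_numpy()
                                     ).fit(reml=True)
                est = pd.Series(fit.fe_params, index=dummies.columns)
            except Exception as exc:  # singular fits on degenerate proteins
                logger.warning("batch model failed for %s (%s); "
                               "falling back to replicate mean", pid, exc)
                est = grp.groupby("sample_id")["concentration"].mean()
        for sid, val in est.items():
            rows.append({"protein_id": pid, **extras,
                         "sample_id": sid, "concentration": float(val)})
    return pd.DataFrame(rows)


def quantify(table: pd.DataFrame,
             protein_totals: Mapping[str, float],
             compartment_weights: Mapping[str, float],
             group_labels: Mapping[str, str] | None = None,
             seed: int = 0,
             summarize: str = "lmm") -> dict:
    """Run the full quantitation chain on one compartment's intensity table.

    Returns a dict with the identification flags, kept protein set, the
    replicate-level and per-sample concentration tables.
    """
    flags = filter_identified(table)
    if group_labels is None:
        group_labels = {s: "all" for s in table["sample_id"].unique()}
    kept = filter_quantitated(flags, group_labels)
    sub = table[table["protein_id"].isin(kept)].reset_index(drop=True)
    normalized = normalize_total_signal(sub)
    imputed = impute_missing(normalized, seed=seed)
    conc = estimate_concentration(imputed, protein_totals, compartment_weights)
    per_sample = summarize_replicates(conc, method=summarize)
    return {"flags": flags, "kept": kept, "replicate_concentrations": conc,
            "sample_concentrations": per_sample}
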