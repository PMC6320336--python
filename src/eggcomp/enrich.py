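"""Monte-Carlo enrichment of protein clusters in functional categories.

For each (cluster, FunCat term) pair, the observed number of member proteins
carrying the term is compared with its null distribution obtained by
randomly permuting proteins across the fixed cluster-size partition
(10,000 cycles by default). A cluster is enriched in a term when the
observed count strictly exceeds the 95% quantile of the null distribution.
Multi-function proteins contribute to every term they carry; no multiplicity
control is applied across the (cluster, term) grid, which the result table
records in its metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EnrichmentResult", "funcat_enrichment"]


@dataclass
class EnrichmentResult:
    cluster: int
    term: str
    observed: int
    null_q95: float
    n_sim: int
    enriched: bool
    p_emp: float


def funcat_enrichment(assignment: pd.DataFrame, annotation: pd.DataFrame,
                      n_sim: int = 10_000, level: float = 0.95,
                      seed: int = 0) -> pd.DataFrame:
    """Permutation test of term frequency within clusters.

    ``assignment``: columns (protein_id, cluster); ``annotation``: columns
    (protein_id, term_id). Every simulation keeps the cluster sizes fixed and
    permutes the proteins; the permutation stream is keyed on sorted protein
    ids so results are invariant to input order. The empirical p is
    (1 + #{null >= observed}) / (1 + n_sim), the enriched flag uses the
    strict observed > q95 rule.
    """
    assign = (assignment[["protein_id", "cluster"]]
              .drop_duplicates().sort_values("protein_id")
              .reset_index(drop=True))
    if assign["protein_id"].duplicated().any():
        raise ValueError("protein assigned to more than one cluster")
    proteins = assign["protein_id"].to_numpy()
    clusters = np.sort(assign["cluster"].unique())
    terms = np.sort(annotation["term_id"].unique())
    unannotated = set(proteins) - set(annotation["protein_id"])
    if unannotated:
        raise ValueError(
            f"clustered protein(s) without annotation: {sorted(unannotated)[:5]}")

    n_p, n_t = len(proteins), len(terms)
    t_index = {t: j for j, t in enumerate(terms)}
    p_index = {p: i for i, p in enumerate(proteins)}
    carries = np.zeros((n_p, n_t), dtype=np.float32)
    for pid, tid in annotation[["protein_id", "term_id"]].itertuples(index=False):
        if pid in p_index:
            carries[p_index[pid], t_index[tid]] = 1.0

    cl_index = {c: j for j, c in enumerate(clusters)}
    member = np.array([cl_index[c] for c in assign["cluster"]])
    sizes = np.bincount(member, minlength=len(clusters))
    # observed term counts per cluster
    observed = np.zeros((len(clusters), n_t))
    for j in range(len(clusters)):
        observed[j] = carries[member == j].sum(axis=0)

    # null: permute proteins over the fixed partition; proteins are laid out
    # cluster-block-wise after each shuffle and counted with reduceat
    rng = np.random.default_rng(seed)
    order = np.argsort(member, kind="stable")
    bounds = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    null = np.empty((n_sim, len(clusters), n_t), dtype=np.float32)
    block = 500  # keep the permuted tensor small
    for start in range(0, n_sim, block):
        b = min(block, n_sim - start)
        perms = np.argsort(rng.random((b, n_p)), axis=1)
        shuffled = carries[perms]  # (b, n_p, n_t)
        null[start:start + b] = np.add.reduceat(shuffled, bounds, axis=1)

    q95 = np.quantile(null, level, axis=0)
    ge = (null >= observed[None]).sum(axis=0)
    p_emp = (1.0 + ge) / (1.0 + n_sim)

    rows = []
    for j, c in enumerate(clusters):
        for t in terms:
            jt = t_index[t]
            rows.append({
                "cluster": c,
                "term": t,
                "observed": int(observed[j, jt]),
                "null_q95": float(q95[j, jt]),
                "n_sim": n_sim,
                "enriched": bool(observed[j, jt] > q95[j, jt]),
                "p_emp": float(p_emp[j, jt]),
            })
    out = pd.DataFrame(rows)
    out.attrs["multiplicity_control"] = "none"
    return out
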