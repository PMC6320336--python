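"""Affinity propagation clustering of proteins, carotenoids and eggs.

Exemplar-based clustering by iterative exchange of two messages between
items: the responsibility r(i,k), how well suited item k is as exemplar for
item i relative to other candidates, and the availability a(i,k), the
accumulated evidence that k should serve as an exemplar. The preference
(diagonal of the similarity matrix) controls how many exemplars emerge; it
is set to the q-quantile of the off-diagonal similarities, with q=0 (the
minimum) giving a conservative cluster count. Similarities between proteins
(or eggs) are pairwise Pearson correlations between log-transformed
concentration profiles (or standardised feature vectors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "APResult",
    "build_similarity",
    "run_ap",
    "summarize_clusters",
    "cluster_eggs",
    "exhaustive_exemplars",
    "net_similarity",
]


@dataclass
class SimilarityMatrix:
    s: np.ndarray
    items: list[str]
    provenance: str = "feature-correlation"

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if self.s.ndim != 2 or self.s.shape[0] != self.s.shape[1]:
            raise ValueError("similarity matrix must be square")
        off = ~np.eye(len(self.s), dtype=bool)
        if not np.all(np.isfinite(self.s[off])):
            raise ValueError("non-finite off-diagonal similarity")


@dataclass
class APResult:
    items: list[str]
    exemplar_idx: np.ndarray  # exemplar index per item
    labels: np.ndarray  # cluster labels 1..K
    n_clusters: int
    responsibility: np.ndarray
    availability: np.ndarray
    iterations: int
    converged: bool
    net_similarity: float

    def members(self, label: int) -> list[str]:
        return [it for it, l in zip(self.items, self.labels) if l == label]

    def assignments(self) -> pd.DataFrame:
        ex = set(np.unique(self.exemplar_idx))
        return pd.DataFrame({
            "item_id": self.items,
            "cluster": self.labels,
            "exemplar": [i in ex and self.exemplar_idx[i] == i
                         for i in range(len(self.items))],
        })


def build_similarity(profiles: pd.DataFrame,
                     provenance: str = "pearson-on-log-concentration"
                     ) -> SimilarityMatrix:
    """Pairwise Pearson correlations between item profiles.

    ``profiles`` has one row per item (e.g. protein) and one column per
    observation (e.g. egg); items with zero variance are rejected by name.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 items")
    if profiles.shape[1] < 3:
        raise ValueError("need >= 3 observations per item")
    arr = profiles.to_numpy(float)
    sd = arr.std(axis=1)
    if np.any(sd == 0):
        bad = list(profiles.index[sd == 0])
        raise ValueError(f"zero-variance item(s): {bad}")
    s = np.corrcoef(arr)
    return SimilarityMatrix(s=s, items=list(map(str, profiles.index)),
                            provenance=provenance)


def net_similarity(s: np.ndarray, exemplars: np.ndarray,
                   assignment: np.ndarray) -> float:
    """Sum of similarities to assigned exemplars, preferences included."""
    total = 0.0
    ex = set(int(e) for e in np.unique(exemplars))
    for i, k in enumerate(assignment):
        total += s[i, k]  # i==k adds the preference s(k,k)
    return float(total)


def exhaustive_exemplars(s: np.ndarray) -> tuple[np.ndarray, float]:
    """Best exemplar subset by brute force (oracle for small n).

    Scans all non-empty subsets; each non-exemplar joins its most similar
    exemplar. Returns the optimal assignment vector and its net similarity.
    """
    n = len(s)
    if n > 16:
        raise ValueError("exhaustive search is for small instances only")
    best, best_val = None, -np.inf
    for mask in range(1, 1 << n):
        ex = [k for k in range(n) if mask >> k & 1]
        assign = np.array([k if k in ex
                           else ex[int(np.argmax(s[k, ex]))] for k in range(n)])
        val = net_similarity(s, np.array(ex), assign)
        if val > best_val:
            best, best_val = assign, val
    return best, best_val


def run_ap(sim: SimilarityMatrix | np.ndarray, q: float = 0.0,
           damping: float = 0.9, max_iter: int = 1000, conv_iter: int = 100,
           seed: int = 0) -> APResult:
    """Affinity propagation on a similarity matrix.

    Preferences (the diagonal) are set to the q-quantile of the off-diagonal
    similarities (q=0: minimum). Messages are damped by ``damping``; the run
    stops once the exemplar set has been stable for ``conv_iter`` sweeps.
    A seeded symmetric jitter of relative size <= 1e-12 breaks exact ties.
    """
    if isinstance(sim, SimilarityMatrix):
        s = sim.s.copy()
        items = list(sim.items)
    else:
        s = np.asarray(sim, dtype=float).copy()
        items = [str(i) for i in range(len(s))]
    n = len(s)
    if n == 0:
        raise ValueError("empty similarity matrix")
    if n == 1:
        return APResult(items=items, exemplar_idx=np.zeros(1, int),
                        labels=np.ones(1, int), n_clusters=1,
                        responsibility=np.zeros((1, 1)),
                        availability=np.zeros((1, 1)), iterations=0,
                        converged=True, net_similarity=float(s[0, 0]))

    off = ~np.eye(n, dtype=bool)
    pref = float(np.quantile(s[off], q))
    np.fill_diagonal(s, pref)

    rng = np.random.default_rng(seed)
    scale = np.max(np.abs(s)) or 1.0
    jitter = rng.normal(0.0, 1.0, size=(n, n))
    s = s + 1e-12 * scale * (jitter + jitter.T) / 2

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)
    stable = 0
    last_ex: frozenset[int] | None = None
    it = 0
    for it in range(1, max_iter + 1):
        # responsibilities: r(i,k) <- s(i,k) - max_{k' != k} [a(i,k') + s(i,k')]
        AS = A + s
        first_k = np.argmax(AS, axis=1)
        first = AS[idx, first_k]
        AS[idx, first_k] = -np.inf
        second = np.max(AS, axis=1)
        AS[idx, first_k] = first
        Rnew = s - first[:, None]
        Rnew[idx, first_k] = s[idx, first_k] - second
        R = damping * R + (1 - damping) * Rnew

        # availabilities: a(i,k) <- min{0, r(k,k) + sum_{i' not in {i,k}} max(0, r(i',k))}
        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, 0.0)
        colsum = Rp.sum(axis=0)
        Anew = np.minimum(0.0, R[idx, idx][None, :] + colsum[None, :] - Rp)
        Anew[idx, idx] = colsum  # a(k,k) <- sum_{i' != k} max(0, r(i',k))
        A = damping * A + (1 - damping) * Anew

        ex = frozenset(np.flatnonzero(np.diag(R) + np.diag(A) > 0).tolist())
        if ex and ex == last_ex:
            stable += 1
            if stable >= conv_iter:
                break
        else:
            stable = 0
            last_ex = ex
    converged = stable >= conv_iter
    if not converged:
        logger.warning("affinity propagation did not converge in %d iterations",
                       max_iter)

    exemplars = np.flatnonzero(np.diag(R) + np.diag(A) > 0)
    if exemplars.size == 0:
        exemplars = np.array([int(np.argmax(np.diag(R) + np.diag(A)))])
    assign = exemplars[np.argmax(s[:, exemplars], axis=1)]
    assign[exemplars] = exemplars
    # standard refinement: per cluster, re-choose the member maximising the
    # within-cluster similarity sum, then reassign; repeat to stability
    for _ in range(20):
        new_ex = []
        for e in np.unique(assign):
            members = np.flatnonzero(assign == e)
            within = s[np.ix_(members, members)].sum(axis=0)
            new_ex.append(int(members[np.argmax(within)]))
        new_ex = np.array(sorted(set(new_ex)))
        new_assign = new_ex[np.argmax(s[:, new_ex], axis=1)]
        new_assign[new_ex] = new_ex
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    exemplars = np.unique(assign[assign == np.arange(n)])
    uniq = {int(e): j + 1 for j, e in enumerate(sorted(set(assign[exemplars])))}
    labels = np.array([uniq[int(e)] for e in assign])
    return APResult(items=items, exemplar_idx=assign, labels=labels,
                    n_clusters=len(uniq), responsibility=R, availability=A,
                    iterations=it, converged=converged,
                    net_similarity=net_similarity(s, exemplars, assign))


def summarize_clusters(result: APResult, conc: pd.DataFrame) -> pd.DataFrame:
    """Per-sample summed concentration of each cluster's member proteins.

    Sums are taken within each replicate and then averaged over replicates,
    so uneven replicate counts do not bias the per-sample value. ``conc`` is
    a replicate-level concentration table.
    """
    present = set(conc["protein_id"])
    missing = [it for it in result.items if it not in present]
    if missing:
        raise ValueError(f"cluster member(s) missing from the table: "
                         f"{missing[:5]}")
    label = dict(zip(result.items, result.labels))
    sub = conc[conc["protein_id"].isin(label)].copy()
    sub["cluster"] = sub["protein_id"].map(label)
    per_rep = (sub.groupby(["cluster", "sample_id", "replicate_id"])
               ["concentration"].sum().reset_index())
    out = (per_rep.groupby(["cluster", "sample_id"])["concentration"]
           .mean().rename("cluster_sum").reset_index())
    return out


def cluster_eggs(features: pd.DataFrame, q: float = 0.0,
                 metric: str = "pearson", **ap_kwargs) -> APResult:
    """Cluster eggs on their composition features.

    ``features``: one row per egg (index = egg id), columns = albumen and
    yolk cluster concentration sums, lipid mg/g, total carotenoid ug/g and
    egg weight. Rows with missing values are dropped (logged). Features are
    2-SD standardised; similarity is the Pearson correlation between egg
    feature vectors (or negative squared Euclidean distance with
    ``metric='euclidean'``).
    """
    from .infer import standardize_2sd

    complete = features.dropna()
    dropped = len(features) - len(complete)
    if dropped:
        logger.info("dropping %d egg(s) with incomplete composition", dropped)
    if len(complete) < 3:
        raise ValueError("need >= 3 eggs with complete features")
    varying = [c for c in complete.columns if complete[c].nunique() > 1]
    if not varying:
        # compositionally identical eggs: trivially one cluster
        n = len(complete)
        return APResult(items=list(map(str, complete.index)),
                        exemplar_idx=np.zeros(n, int),
                        labels=np.ones(n, int), n_clusters=1,
                        responsibility=np.zeros((n, n)),
                        availability=np.zeros((n, n)), iterations=0,
                        converged=True, net_similarity=0.0)
    if len(varying) < len(complete.columns):
        logger.info("dropping %d constant feature column(s)",
                    len(complete.columns) - len(varying))
    z = complete[varying].apply(
        lambda c: standardize_2sd(c.to_numpy(float)), axis=0)
    if metric == "pearson":
        sim = build_similarity(z, provenance="feature-correlation")
    elif metric == "euclidean":
        arr = z.to_numpy(float)
        d2 = ((arr[:, None, :] - arr[None, :, :]) ** 2).sum(axis=2)
        sim = SimilarityMatrix(s=-d2, items=list(map(str, complete.index)),
                               provenance="neg-squared-euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return run_ap(sim, q=q, **ap_kwargs)
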