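"""Calibration and validation studies for the pipeline's statistical engines.

Each routine runs a self-contained simulation study against a known truth:
variance-partition recovery on study-sized designs, affinity propagation
against an exhaustive exemplar search, enrichment type-I error under
independent annotations, uniformity of the bounded imputation, and
recovery/type-I behaviour of the standardised mixed-model effects. The
headline field summaries (extra-pair counts, the yearling-adult first-egg
contrast) are also recomputed here from their published count inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from . import assoc, apcluster, enrich, infer, quant, synthdata

__all__ = [
    "fisher_paternity_position",
    "extra_pair_percent",
    "age_contrast_z",
    "icc_recovery",
    "ap_oracle_study",
    "enrichment_type1",
    "imputation_uniformity",
    "lmm_recovery",
    "lmm_type1",
]


def fisher_paternity_position(ep_first: int = 13, wp_first: int = 24,
                              ep_later: int = 0, wp_later: int = 71) -> float:
    """Two-sided Fisher exact p: extra-pair eggs vs laying position.

    Defaults are the field counts: 13 extra-pair vs 24 within-pair among
    assigned first eggs, none among 71 later assigned eggs.
    """
    return assoc.fisher_exact([[ep_first, wp_first], [ep_later, wp_later]])


def extra_pair_percent(n_ep: int = 13, n_assigned: int = 108) -> float:
    """Extra-pair share of paternity-assigned eggs, in integer percent."""
    return float(round(100.0 * n_ep / n_assigned))


def age_contrast_z(mean_diff: float = 0.428, se: float = 0.151) -> float:
    """Wald z of the adult-vs-yearling first-egg weight contrast."""
    return mean_diff / se


def icc_recovery(n_datasets: int = 50, seed: int = 0) -> dict:
    """Mean between-female egg-weight percentage over simulated studies.

    Each dataset uses the default design (39 clutches, 114 eggs) generated
    with a between-female variance fraction of 0.80; the intercept-only
    mixed model re-estimates the split.
    """
    vals = []
    for k in range(n_datasets):
        cfg = synthdata.StudyConfig(
            seed=int(np.random.SeedSequence([seed, k]).generate_state(1)[0]
                     % 2**31))
        d = synthdata.generate_design(cfg)
        vals.append(infer.variance_partition(d["egg_weight"],
                                             d["female_id"]).between_pct)
    return {"mean_between_pct": float(np.mean(vals)),
            "sd_between_pct": float(np.std(vals, ddof=1)),
            "n_datasets": n_datasets}


def ap_oracle_study(n_instances: int = 100, seed: int = 0,
                    tol: float = 0.01) -> dict:
    """Affinity propagation vs exhaustive exemplar search on small instances.

    Random planar point sets (n <= 8), similarity = negative squared
    distance, preference at a random quantile. Also runs the four-point toy
    instance {0, 0.1, 5, 5.1} at q = 0.5, whose optimum is two clusters.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_instances):
        n = int(rng.integers(4, 9))
        pts = rng.uniform(0, 10, size=(n, 2))
        s = -((pts[:, None, :] - pts[None, :, :]) ** 2).sum(2)
        q = float(rng.uniform(0, 0.5))
        off = ~np.eye(n, dtype=bool)
        sp = s.copy()
        np.fill_diagonal(sp, np.quantile(s[off], q))
        res = apcluster.run_ap(s, q=q, seed=int(rng.integers(2**31)))
        achieved = apcluster.net_similarity(sp, np.unique(res.exemplar_idx),
                                            res.exemplar_idx)
        _, optimum = apcluster.exhaustive_exemplars(sp)
        if achieved >= optimum - tol * abs(optimum):
            hits += 1
    x = np.array([0.0, 0.1, 5.0, 5.1])
    toy = apcluster.run_ap(-(x[:, None] - x[None, :]) ** 2, q=0.5)
    return {"agreement_fraction": hits / n_instances,
            "toy_n_clusters": int(toy.n_clusters),
            "n_instances": n_instances}


def enrichment_type1(n_datasets: int = 500, n_sim: int = 10_000,
                     n_proteins: int = 60, cluster_sizes=(15, 15, 30),
                     seed: int = 0) -> dict:
    """Enrichment rate when annotations are independent of clusters.

    Returns the pooled per-(cluster, term) enrichment rate and the
    Monte-Carlo bound 0.05 + 2 * SE it must not exceed.
    """
    rng = np.random.default_rng(seed)
    pids = [f"P{i:03d}" for i in range(n_proteins)]
    assign = pd.DataFrame({
        "protein_id": pids,
        "cluster": np.repeat(np.arange(1, len(cluster_sizes) + 1),
                             cluster_sizes),
    })
    flagged = total = 0
    for d in range(n_datasets):
        rows = []
        for p in pids:
            for t in rng.choice(21, size=rng.integers(1, 6), replace=False):
                rows.append((p, f"FC{t:02d}"))
        ann = pd.DataFrame(rows, columns=["protein_id", "term_id"])
        res = enrich.funcat_enrichment(assign, ann, n_sim=n_sim,
                                       seed=int(rng.integers(2**31)))
        flagged += int(res["enriched"].sum())
        total += len(res)
    rate = flagged / total
    mc_se = float(np.sqrt(0.05 * 0.95 / total))
    return {"rate": rate, "bound": 0.05 + 2 * mc_se, "n_tests": total,
            "n_datasets": n_datasets}


def imputation_uniformity(n_draws: int = 10_000, seed: int = 0) -> dict:
    """Bounds and uniformity of imputed values in one replicate run.

    Takes the observed normalised intensities of a generated run, appends
    ``n_draws`` missing entries and imputes them; checks every draw lies in
    [run minimum, run 1% quantile] and KS-tests uniformity on that interval.
    """
    cfg = synthdata.StudyConfig(seed=seed, n_clutches=4, n_full_clutches=1,
                                target_n_eggs=11, n_albumen_proteins=150,
                                n_yolk_proteins=10)
    ds = synthdata.generate_dataset(cfg)
    t = ds.intensities[ds.intensities["compartment"] == "albumen"]
    run = (t.groupby(["sample_id", "replicate_id"])["intensity"]
           .count().idxmax())
    one = t[(t["sample_id"] == run[0])
            & (t["replicate_id"] == run[1])].dropna(subset=["intensity"])
    one = one.reset_index(drop=True)
    extra = pd.DataFrame({
        "protein_id": [f"MISS{i:05d}" for i in range(n_draws)],
        "compartment": "albumen",
        "sample_id": run[0],
        "egg_id": one["egg_id"].iloc[0],
        "replicate_id": run[1],
        "batch_id": one["batch_id"].iloc[0],
        "intensity": np.nan,
    })
    table = pd.concat([one, extra], ignore_index=True)
    norm = quant.normalize_total_signal(table)
    obs = norm["intensity"].dropna()
    lo, hi = float(obs.min()), float(np.quantile(obs, 0.01))
    imputed = quant.impute_missing(norm, seed=seed)
    draws = imputed.loc[imputed["protein_id"].str.startswith("MISS"),
                        "intensity"].to_numpy()
    in_bounds = bool(((draws >= lo) & (draws <= hi)).all())
    ks_p = float(stats.kstest(draws, stats.uniform(lo, hi - lo).cdf).pvalue)
    return {"all_in_bounds": in_bounds, "ks_p": ks_p, "n_draws": n_draws}


def _recovery_design(seed: int) -> pd.DataFrame:
    return synthdata.generate_design(synthdata.StudyConfig(seed=seed))


def lmm_recovery(n_sim: int = 200, seed: int = 0, effect: float = 0.5,
                 sd_female: float = 0.3, sd_slope: float = 0.05,
                 sd_resid: float = 0.5) -> dict:
    """Recovery of a known standardised laying-order effect.

    Responses are simulated on the study design with female random
    intercepts and laying-order random slopes; the raw slope is solved so
    the population standardised effect equals ``effect``. Bias is reported
    against that target; CI coverage against the dataset-specific
    standardised truth (the estimand actually defined by the per-dataset
    2-SD scaling).
    """
    d = _recovery_design(seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    lo = d["laying_order"].to_numpy(float)
    lo_c = lo - lo.mean()
    fem = pd.factorize(d["female_id"])[0]
    n_f = fem.max() + 1
    vlo = lo.var(ddof=1)

    def gap(b):
        tot = (b ** 2 * vlo + sd_female ** 2
               + sd_slope ** 2 * np.mean(lo_c ** 2) + sd_resid ** 2)
        return b * np.sqrt(vlo) / np.sqrt(tot) - effect

    b = brentq(gap, 0, 100)
    spec = infer.ModelSpec("y", ("laying_order",), model_id="recovery")
    est, covered = [], 0
    d = d.copy()
    for _ in range(n_sim):
        y = (b * lo + rng.normal(0, sd_female, n_f)[fem]
             + rng.normal(0, sd_slope, n_f)[fem] * lo_c
             + rng.normal(0, sd_resid, len(d)))
        d["y"] = y
        e = infer.fit_lmm(spec, d).estimates[0]
        est.append(e.beta)
        truth_ds = b * lo.std(ddof=1) / y.std(ddof=1)
        covered += (e.ci_low <= truth_ds <= e.ci_high)
    return {"mean_estimate": float(np.mean(est)),
            "bias": float(np.mean(est) - effect),
            "coverage": covered / n_sim, "n_sim": n_sim}


def lmm_type1(n_sim: int = 1000, seed: int = 0, sd_female: float = 0.3,
              sd_slope: float = 0.05, sd_resid: float = 0.5,
              alpha: float = 0.05) -> dict:
    """False-positive rate of the laying-order test under the null."""
    d = _recovery_design(seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 12]))
    lo = d["laying_order"].to_numpy(float)
    lo_c = lo - lo.mean()
    fem = pd.factorize(d["female_id"])[0]
    n_f = fem.max() + 1
    spec = infer.ModelSpec("y", ("laying_order",), model_id="null")
    hits = 0
    d = d.copy()
    for _ in range(n_sim):
        d["y"] = (rng.normal(0, sd_female, n_f)[fem]
                  + rng.normal(0, sd_slope, n_f)[fem] * lo_c
                  + rng.normal(0, sd_resid, len(d)))
        e = infer.fit_lmm(spec, d).estimates[0]
        hits += e.p_raw < alpha
    return {"false_positive_rate": hits / n_sim, "n_sim": n_sim}
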