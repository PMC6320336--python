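"""Synthetic egg-composition datasets with known ground truth.

Emulates a wild blue tit egg-collection study: 39 clutches sampled during a
single short breeding season, with the 1st and 9th egg collected from every
clutch and every second egg (odd laying positions) from a subset of 10
clutches — 114 eggs in the default design. Each egg carries life-history
covariates (female identity and age, laying order, lay date, clutch size,
embryo sex, paternity), compartment weights and total protein assays; the
proteome generator layers known fixed effects, female random intercepts and
laying-order random slopes, MS batch effects and intensity-dependent
(missing-not-at-random) dropout on top of log-normal protein intensities, so
every downstream stage can be validated against the generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "StudyConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_design",
    "generate_proteome",
    "generate_yolk_chemistry",
    "generate_dataset",
    "write_dataset",
]

N_FUNCAT_TERMS = 21
FUNCAT_TERMS = [f"FC{i:02d}" for i in range(1, N_FUNCAT_TERMS + 1)]

# species name, mean concentration (µg/g wet yolk), CV (fraction), presence rate
CAROTENOID_SPECIES = [
    ("lutein", 22.1, 0.89, 1.00),
    ("zeaxanthin", 7.2, 0.87, 1.00),
    ("beta_carotene", 3.6, 0.69, 1.00),
    ("beta_zeacarotene", 3.5, 1.75, 0.67),
    ("gamma_carotene", 1.7, 1.34, 1.00),
    ("gamma_carotene_z", 1.2, 0.92, 1.00),
]


@dataclass
class StudyConfig:
    """Design constants of the emulated study.

    Defaults reproduce the study conditions: 39 clutches, eggs 1 and 9 from
    each plus every second egg from 10 fully-sampled clutches (114 eggs),
    clutch sizes 7-15, extra-pair paternity confined to first-laid eggs at a
    rate giving ~12% extra-pair among all paternity-assigned eggs, 1-3
    technical replicates per sample, and ~15% missing intensities overall.
    """

    n_clutches: int = 39
    n_full_clutches: int = 10
    clutch_size_range: tuple[int, int] = (7, 15)
    target_n_eggs: int | None = 114
    # 13 of 37 assigned first eggs were extra-pair; only first eggs can be EP,
    # which puts the overall assigned fraction at ~12%.
    ep_rate_first_eggs: float = 13.0 / 37.0
    n_unassigned_clutches: int = 1  # clutches with unknown social father
    n_albumen_proteins: int = 171
    n_yolk_proteins: int = 156
    n_funcat_terms: int = N_FUNCAT_TERMS
    replicates_per_sample: tuple[int, int] = (1, 3)
    n_ms_batches: int = 6
    n_hplc_batches: int = 4
    missing_rate: float = 0.15
    season_days: int = 12
    # egg weight model (g): grand mean / total SD from the field summary,
    # between-female fraction dominating at 0.80
    egg_weight_mean: float = 1.16
    egg_weight_sd: float = 0.11
    egg_weight_icc: float = 0.80
    clutch_size_slope: float = -0.029  # g per additional egg (~2.5%)
    # laying-order slope on egg weight: + for yearlings, - for adults
    age_lo_slope: float = 0.006
    # yolk chemistry
    carotenoid_lo_effect: float = 0.45  # share of latent variance tied to LO
    lipid_mean: float = 222.1  # mg/g wet yolk
    lipid_sd: float = 21.8
    lipid_lo_slope: float = -2.5  # mg/g per laying position
    lipid_icc: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.clutch_size_range
        if lo > hi:
            raise ValueError(f"clutch_size_range inverted: ({lo}, {hi})")
        if not (0.0 <= self.ep_rate_first_eggs <= 1.0):
            raise ValueError("ep_rate_first_eggs must lie in [0, 1]")
        if self.n_full_clutches < 0:
            raise ValueError("n_full_clutches must be >= 0")
        for name in ("n_clutches", "n_albumen_proteins",
                     "n_yolk_proteins", "n_funcat_terms", "n_ms_batches",
                     "n_hplc_batches"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_full_clutches > self.n_clutches:
            raise ValueError("n_full_clutches cannot exceed n_clutches")
        r_lo, r_hi = self.replicates_per_sample
        if not (1 <= r_lo <= r_hi):
            raise ValueError("replicates_per_sample must be an increasing range >= 1")


@dataclass
class GroundTruth:
    """Generating parameters of the synthetic proteome, kept for recovery tests.

    Fixed-effect coefficients act on the natural-log intensity scale per raw
    covariate unit; categorical covariates are coded yearling=0/adult=1,
    female=0/male=1, within-pair=0/extra-pair=1.
    """

    protein_id: np.ndarray
    compartment: np.ndarray  # 'albumen' or 'yolk' per protein
    baseline_log: np.ndarray
    beta_laying_order: np.ndarray
    beta_female_age: np.ndarray
    beta_paternity: np.ndarray
    beta_sex: np.ndarray
    beta_lay_date: np.ndarray
    beta_clutch_size: np.ndarray
    sd_female: float = 0.35
    sd_slope: float = 0.04
    sd_batch: float = 0.25
    sd_replicate: float = 0.30
    missing_slope: float = 0.8  # logistic decline of dropout with log intensity
    missing_intercept: float | None = None  # calibrated to the target rate

    def __post_init__(self) -> None:
        n = len(self.protein_id)
        for name in ("compartment", "baseline_log", "beta_laying_order",
                     "beta_female_age", "beta_paternity", "beta_sex",
                     "beta_lay_date", "beta_clutch_size"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"GroundTruth field {name} has wrong length")
        for name in ("sd_female", "sd_slope", "sd_batch", "sd_replicate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_id)

    @classmethod
    def default(cls, config: StudyConfig, rng: np.random.Generator) -> "GroundTruth":
        """Study-flavoured truth: log-normal baselines spanning ~6 orders of
        magnitude; laying order affects a majority of proteins with mixed
        signs (more increases than decreases); other predictors touch only a
        small minority."""
        n_a, n_y = config.n_albumen_proteins, config.n_yolk_proteins
        n = n_a + n_y
        pid = np.array([f"AP{i:04d}" for i in range(n_a)]
                       + [f"YP{i:04d}" for i in range(n_y)])
        comp = np.array(["albumen"] * n_a + ["yolk"] * n_y)
        baseline = rng.uniform(np.log(1e2), np.log(1e8), size=n)

        def sparse_effect(frac_pos, frac_neg, scale):
            u = rng.uniform(size=n)
            mag = rng.exponential(scale, size=n)
            out = np.where(u < frac_pos, mag,
                           np.where(u < frac_pos + frac_neg, -mag, 0.0))
            return out

        return cls(
            protein_id=pid,
            compartment=comp,
            baseline_log=baseline,
            beta_laying_order=sparse_effect(0.30, 0.20, 0.06),
            beta_female_age=sparse_effect(0.08, 0.04, 0.30),
            beta_paternity=sparse_effect(0.02, 0.06, 0.35),
            beta_sex=sparse_effect(0.02, 0.02, 0.25),
            beta_lay_date=sparse_effect(0.02, 0.02, 0.03),
            beta_clutch_size=sparse_effect(0.02, 0.02, 0.05),
        )

    @classmethod
    def null(cls, config: StudyConfig, rng: np.random.Generator,
             **overrides) -> "GroundTruth":
        """Truth with every fixed effect zero (baselines still drawn)."""
        n = config.n_albumen_proteins + config.n_yolk_proteins
        zeros = np.zeros(n)
        base = cls.default(config, rng)
        return cls(
            protein_id=base.protein_id,
            compartment=base.compartment,
            baseline_log=base.baseline_log,
            beta_laying_order=zeros.copy(),
            beta_female_age=zeros.copy(),
            beta_paternity=zeros.copy(),
            beta_sex=zeros.copy(),
            beta_lay_date=zeros.copy(),
            beta_clutch_size=zeros.copy(),
            **overrides,
        )


def _sampled_positions(clutch_size: int, fully_sampled: bool) -> list[int]:
    if fully_sampled:
        return [p for p in range(1, clutch_size + 1, 2)]
    return [1, 9]


def _n_odd(clutch_size: int) -> int:
    return (clutch_size + 1) // 2


def generate_design(config: StudyConfig) -> pd.DataFrame:
    """Draw the per-egg design table (one :class:`EggRecord` row per egg).

    Sampled clutches are constrained to >= 9 eggs so that the 9th egg exists.
    When ``target_n_eggs`` is set, the sizes of the fully-sampled clutches are
    nudged within bounds until the total egg count matches exactly, emulating
    the fixed size of the real collection.
    """
    rng = np.random.default_rng(config.seed)
    n, n_full = config.n_clutches, config.n_full_clutches
    lo_size = max(9, config.clutch_size_range[0])
    hi_size = config.clutch_size_range[1]
    if lo_size > hi_size:
        raise ValueError("clutch_size_range does not admit clutches with a 9th egg")

    sizes = rng.integers(lo_size, hi_size + 1, size=n)
    full_idx = rng.choice(n, size=n_full, replace=False)
    full_mask = np.zeros(n, dtype=bool)
    full_mask[full_idx] = True
    # every-second-egg sampling never reached position 15 in the study;
    # cap fully sampled clutches so sampled orders stay within {1,...,13}
    full_hi = min(hi_size, 14)
    sizes[full_mask] = np.minimum(sizes[full_mask], full_hi)

    if config.target_n_eggs is not None:
        target_odd = config.target_n_eggs - 2 * (n - n_full)
        if not (n_full * _n_odd(lo_size) <= target_odd <= n_full * _n_odd(full_hi)):
            raise ValueError("target_n_eggs unreachable for this design")
        # each +/-2 on a clutch size moves its odd-position count by 1
        for _ in range(10_000):
            diff = target_odd - sum(_n_odd(s) for s in sizes[full_mask])
            if diff == 0:
                break
            step = 2 if diff > 0 else -2
            cand = [i for i in full_idx if lo_size <= sizes[i] + step <= full_hi]
            sizes[rng.choice(cand)] += step
        else:  # pragma: no cover
            raise RuntimeError("design repair failed to converge")

    female_age = np.where(rng.uniform(size=n) < 0.5, "yearling", "adult")
    lay_date = rng.integers(0, config.season_days, size=n)
    unknown_father = np.zeros(n, dtype=bool)
    if config.n_unassigned_clutches > 0:
        unknown_father[rng.choice(n, size=config.n_unassigned_clutches,
                                  replace=False)] = True

    rows = []
    for c in range(n):
        fid = f"F{c + 1:03d}"
        for pos in _sampled_positions(int(sizes[c]), bool(full_mask[c])):
            if unknown_father[c]:
                pat = "unknown"
            elif pos == 1:
                pat = ("extra-pair"
                       if rng.uniform() < config.ep_rate_first_eggs
                       else "within-pair")
            else:
                pat = "within-pair"
            rows.append({
                "egg_id": f"{fid}E{pos:02d}",
                "female_id": fid,
                "laying_order": pos,
                "lay_date": int(lay_date[c]),
                "clutch_size": int(sizes[c]),
                "female_age": female_age[c],
                "embryo_sex": "male" if rng.uniform() < 0.5 else "female",
                "paternity": pat,
                "fully_sampled": bool(full_mask[c]),
            })
    design = pd.DataFrame(rows)

    # Egg weight: grand mean + fixed trends (clutch size; age-dependent
    # laying-order slope) + female intercept + residual. The two random
    # variances are calibrated so that, together with the fixed trends, the
    # between-female share of total variance hits the configured fraction.
    cs_dev = design["clutch_size"] - design["clutch_size"].mean()
    lo_dev = design["laying_order"] - design["laying_order"].mean()
    slope = np.where(design["female_age"] == "yearling",
                     config.age_lo_slope, -config.age_lo_slope)
    fixed = config.clutch_size_slope * cs_dev + slope * lo_dev
    fm = fixed.groupby(design["female_id"]).transform("mean")
    var_between_fixed = float(np.var(fm, ddof=0))
    var_within_fixed = float(np.var(fixed - fm, ddof=0))
    tot = config.egg_weight_sd ** 2
    var_f = max(0.0, config.egg_weight_icc * tot - var_between_fixed)
    var_e = max(0.0, (1.0 - config.egg_weight_icc) * tot - var_within_fixed)
    b_f = rng.normal(0.0, np.sqrt(var_f), size=n)
    fmap = {f"F{c + 1:03d}": b_f[c] for c in range(n)}
    resid = rng.normal(0.0, np.sqrt(var_e), size=len(design))
    design["egg_weight"] = (config.egg_weight_mean + fixed.to_numpy()
                            + design["female_id"].map(fmap).to_numpy() + resid)
    design["egg_weight"] = design["egg_weight"].clip(lower=0.5)

    # compartment weights scale roughly isometrically with egg weight
    rel = design["egg_weight"] / config.egg_weight_mean
    alb = 0.83 * rel * np.exp(rng.normal(0, 0.04, size=len(design)))
    yolk = 0.27 * rel * np.exp(rng.normal(0, 0.06, size=len(design)))
    # keep albumen + yolk below total egg weight (shell makes up the rest)
    scale = np.minimum(1.0, 0.95 * design["egg_weight"] / (alb + yolk))
    design["albumen_weight"] = alb * scale
    design["yolk_weight"] = yolk * scale

    # total protein assays per compartment (mg/g wet), with the study's
    # laying-order increase in albumen and female-age effect in yolk
    alb_conc = (52.4 + 0.6 * lo_dev
                + rng.normal(0, 4.0, size=len(design))).clip(lower=5.0)
    yolk_conc = (61.2 + 0.3 * lo_dev
                 + 3.0 * (design["female_age"] == "adult")
                 + rng.normal(0, 5.5, size=len(design))).clip(lower=5.0)
    design["albumen_protein_mg"] = alb_conc * design["albumen_weight"]
    design["yolk_protein_mg"] = yolk_conc * design["yolk_weight"]
    return design


def _assign_batches(keys: pd.DataFrame, n_batches: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Randomised-block assignment of runs to batches: shuffle, deal round-robin."""
    order = rng.permutation(len(keys))
    batch = np.empty(len(keys), dtype=int)
    batch[order] = np.arange(len(keys)) % n_batches + 1
    return batch


def generate_proteome(design: pd.DataFrame, truth: GroundTruth,
                      config: StudyConfig
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the replicate-level intensity table and FunCat annotation.

    Log intensity = baseline + fixed effects x covariates + female intercept
    + laying-order random slope + MS batch effect + replicate noise; values
    then drop out with probability decreasing logistically in log intensity
    (missing-not-at-random), calibrated to ``config.missing_rate`` overall.

    Returns the long intensity table (protein_id, compartment, sample_id,
    replicate_id, batch_id, intensity with NaN for missing) and the long
    annotation table (protein_id, term_id), 1-16 of 21 first-level terms per
    protein.
    """
    if design.empty:
        raise ValueError("design is empty")
    expected = config.n_albumen_proteins + config.n_yolk_proteins
    if truth.n_proteins != expected:
        raise ValueError(
            f"truth covers {truth.n_proteins} proteins, config expects {expected}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_eggs = len(design)
    n_prot = truth.n_proteins

    x_lo = design["laying_order"].to_numpy(float)
    x_age = (design["female_age"] == "adult").to_numpy(float)
    x_pat = (design["paternity"] == "extra-pair").to_numpy(float)
    x_sex = (design["embryo_sex"] == "male").to_numpy(float)
    x_ld = design["lay_date"].to_numpy(float)
    x_cs = design["clutch_size"].to_numpy(float)
    # centre covariates so baselines stay interpretable as typical-egg levels
    fixed = (np.outer(x_lo - x_lo.mean(), truth.beta_laying_order)
             + np.outer(x_age - x_age.mean(), truth.beta_female_age)
             + np.outer(x_pat, truth.beta_paternity)
             + np.outer(x_sex - x_sex.mean(), truth.beta_sex)
             + np.outer(x_ld - x_ld.mean(), truth.beta_lay_date)
             + np.outer(x_cs - x_cs.mean(), truth.beta_clutch_size))

    females = design["female_id"].unique()
    fidx = design["female_id"].map({f: i for i, f in enumerate(females)}).to_numpy()
    u = rng.normal(0, truth.sd_female, size=(len(females), n_prot))
    v = rng.normal(0, truth.sd_slope, size=(len(females), n_prot))
    lo_c = x_lo - x_lo.mean()
    egg_log = (truth.baseline_log[None, :] + fixed
               + u[fidx] + v[fidx] * lo_c[:, None])  # (n_eggs, n_prot)

    # replicate runs: each sample is an (egg, compartment); its replicate runs
    # are dealt into MS batches in a randomised block
    n_rep = rng.integers(config.replicates_per_sample[0],
                         config.replicates_per_sample[1] + 1, size=n_eggs)
    runs = []
    for e in range(n_eggs):
        for r in range(1, int(n_rep[e]) + 1):
            runs.append((e, r))
    runs = pd.DataFrame(runs, columns=["egg_idx", "replicate_id"])
    runs["batch_id"] = _assign_batches(runs, config.n_ms_batches, rng)

    b = rng.normal(0, truth.sd_batch, size=(config.n_ms_batches + 1, n_prot))
    eps = rng.normal(0, truth.sd_replicate, size=(len(runs), n_prot))
    log_i = egg_log[runs["egg_idx"].to_numpy()] + b[runs["batch_id"].to_numpy()] + eps

    # calibrate the dropout intercept against the realised log intensities
    med = float(np.median(log_i))
    slope = truth.missing_slope
    if truth.missing_intercept is None and config.missing_rate > 0:
        def rate(m0):
            return float(np.mean(expit(m0 - slope * (log_i - med)))) - config.missing_rate
        truth.missing_intercept = brentq(rate, -50.0, 50.0)
    m0 = truth.missing_intercept if truth.missing_intercept is not None else -np.inf
    p_miss = expit(m0 - slope * (log_i - med)) if config.missing_rate > 0 else 0.0
    miss = rng.uniform(size=log_i.shape) < p_miss

    egg_ids = design["egg_id"].to_numpy()
    comp_suffix = {"albumen": "A", "yolk": "Y"}
    n_runs = len(runs)
    table = pd.DataFrame({
        "protein_id": np.tile(truth.protein_id, n_runs),
        "compartment": np.tile(truth.compartment, n_runs),
        "egg_id": np.repeat(egg_ids[runs["egg_idx"].to_numpy()], n_prot),
        "replicate_id": np.repeat(runs["replicate_id"].to_numpy(), n_prot),
        "batch_id": np.repeat(runs["batch_id"].to_numpy(), n_prot),
        "intensity": np.where(miss, np.nan, np.exp(log_i)).ravel(),
    })
    table["sample_id"] = (table["egg_id"] + "_"
                          + table["compartment"].map(comp_suffix))
    table = table[["protein_id", "compartment", "sample_id", "egg_id",
                   "replicate_id", "batch_id", "intensity"]]

    # FunCat annotation: 1-16 of the 21 first-level terms per protein,
    # small term counts being the most common
    terms = FUNCAT_TERMS[:config.n_funcat_terms]
    k = np.minimum(1 + rng.geometric(0.35, size=n_prot) - 1 + (
        rng.uniform(size=n_prot) < 0.08) * rng.integers(3, 10, size=n_prot), 16)
    k = np.clip(k, 1, min(16, len(terms)))
    ann_rows = []
    for i in range(n_prot):
        for t in rng.choice(len(terms), size=int(k[i]), replace=False):
            ann_rows.append((truth.protein_id[i], terms[t]))
    annotation = pd.DataFrame(ann_rows, columns=["protein_id", "term_id"])
    return table, annotation


def generate_yolk_chemistry(design: pd.DataFrame, config: StudyConfig
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-egg yolk carotenoid and lipid tables.

    Six carotenoid species share one latent egg factor (hence all-positive
    inter-species correlations) that declines with laying order; species
    means/CVs follow the field summary (lutein 22.1 ug/g CV 89%, ...,
    beta-zeacarotene detected in ~67% of eggs). Lipids are Gaussian around
    222.1 mg/g wet yolk, declining with laying order, with a between-female
    component. HPLC batch labels are attached per egg.
    """
    if design.empty:
        raise ValueError("design is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = len(design)
    lo = design["laying_order"].to_numpy(float)
    z_lo = (lo - lo.mean()) / (lo.std() if lo.std() > 0 else 1.0)

    females = design["female_id"].unique()
    fidx = design["female_id"].map({f: i for i, f in enumerate(females)}).to_numpy()

    # shared latent factor, unit variance: laying-order part + female + egg
    delta = config.carotenoid_lo_effect
    rest = max(0.0, 1.0 - delta ** 2)
    f_female = rng.normal(0, 1, size=len(females))[fidx]
    f_egg = rng.normal(0, 1, size=n)
    latent = -delta * z_lo + np.sqrt(rest) * (np.sqrt(0.4) * f_female
                                              + np.sqrt(0.6) * f_egg)

    rho = 0.6  # share of each species' log-variance carried by the latent factor
    caro = pd.DataFrame({"egg_id": design["egg_id"].to_numpy()})
    for name, mean, cv, presence in CAROTENOID_SPECIES:
        s2 = np.log1p(cv ** 2)
        mu = np.log(mean) - s2 / 2
        logc = mu + np.sqrt(s2) * (np.sqrt(rho) * latent
                                   + np.sqrt(1 - rho) * rng.normal(0, 1, size=n))
        conc = np.exp(logc)
        if presence < 1.0:
            conc = np.where(rng.uniform(size=n) < presence, conc, np.nan)
        caro[name] = conc
    caro["total_carotenoids"] = caro[[s[0] for s in CAROTENOID_SPECIES]].sum(
        axis=1, skipna=True)
    caro["hplc_batch"] = _assign_batches(caro, config.n_hplc_batches, rng)

    var_t = config.lipid_sd ** 2
    lo_dev = lo - lo.mean()
    var_lo = config.lipid_lo_slope ** 2 * float(np.var(lo_dev))
    var_f = max(0.0, config.lipid_icc * var_t)
    var_e = max(0.0, (1 - config.lipid_icc) * var_t - var_lo)
    lipid = (config.lipid_mean + config.lipid_lo_slope * lo_dev
             + rng.normal(0, np.sqrt(var_f), size=len(females))[fidx]
             + rng.normal(0, np.sqrt(var_e), size=n)).clip(min=10.0)
    lipids = pd.DataFrame({
        "egg_id": design["egg_id"].to_numpy(),
        "lipid_mg_per_g": lipid,
    })
    lipids["hplc_batch"] = caro["hplc_batch"]
    return caro, lipids


@dataclass
class SyntheticDataset:
    """Bundle of all generated tables plus the generating truth."""

    config: StudyConfig
    design: pd.DataFrame
    intensities: pd.DataFrame
    annotation: pd.DataFrame
    carotenoids: pd.DataFrame
    lipids: pd.DataFrame
    truth: GroundTruth


def generate_dataset(config: StudyConfig | None = None,
                     truth: GroundTruth | None = None) -> SyntheticDataset:
    """Generate a full synthetic study (design, proteome, yolk chemistry)."""
    config = config or StudyConfig()
    design = generate_design(config)
    if truth is None:
        truth = GroundTruth.default(
            config, np.random.default_rng(np.random.SeedSequence([config.seed, 3])))
    intensities, annotation = generate_proteome(design, truth, config)
    carotenoids, lipids = generate_yolk_chemistry(design, config)
    return SyntheticDataset(config, design, intensities, annotation,
                            carotenoids, lipids, truth)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset as TSVs plus a ground-truth sidecar; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [("metadata", ds.design), ("intensities", ds.intensities),
                     ("annotation", ds.annotation),
                     ("carotenoids", ds.carotenoids), ("lipids", ds.lipids)]:
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    truth_df = pd.DataFrame({
        "protein_id": ds.truth.protein_id,
        "compartment": ds.truth.compartment,
        "baseline_log": ds.truth.baseline_log,
        "beta_laying_order": ds.truth.beta_laying_order,
        "beta_female_age": ds.truth.beta_female_age,
        "beta_paternity": ds.truth.beta_paternity,
        "beta_sex": ds.truth.beta_sex,
        "beta_lay_date": ds.truth.beta_lay_date,
        "beta_clutch_size": ds.truth.beta_clutch_size,
    })
    p = outdir / "ground_truth.tsv"
    truth_df.to_csv(p, sep="\t", index=False)
    paths["ground_truth"] = p
    scalars = {k: v for k, v in asdict(ds.truth).items()
               if np.isscalar(v) or v is None}
    import json
    p = outdir / "ground_truth_scalars.json"
    p.write_text(json.dumps(scalars, indent=1))
    paths["ground_truth_scalars"] = p
    return paths
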