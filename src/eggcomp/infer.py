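"""Mixed-model inference on life-history predictors of egg composition.

Every model is a Gaussian linear mixed model fitted by REML with female
identity as random intercept and laying order as random slope, optionally an
assay-batch random intercept crossed with female. Continuous predictors and
responses are standardised by centring and dividing by two standard
deviations so that their coefficients are comparable with those of untouched
0/1 binary predictors; protein concentration responses are rank-transformed
first (robustness to extreme values), carotenoid responses log-transformed.
Inference is Wald (normal): z statistics, beta +/- 1.96 SE confidence
intervals. Within-model multiplicity uses a single-step max-|z| adjustment
under the joint normal of the model's contrasts; across models of a family
(>= 5 models) Benjamini-Hochberg FDR is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "EffectEstimate",
    "FitResult",
    "VariancePartition",
    "standardize_2sd",
    "rank_transform",
    "fit_lmm",
    "variance_partition",
    "adjust_pvalues",
    "benjamini_hochberg",
    "test_interactions",
]

CONTINUOUS_PREDICTORS = ("laying_order", "lay_date", "clutch_size", "egg_weight")
BINARY_CODING = {
    "female_age": {"yearling": 0.0, "adult": 1.0},
    "embryo_sex": {"female": 0.0, "male": 1.0},
    "paternity": {"within-pair": 0.0, "extra-pair": 1.0},
}
A_PRIORI_INTERACTIONS = (
    ("female_age", "laying_order"),
    ("female_age", "clutch_size"),
    ("embryo_sex", "laying_order"),
)
_SINGLE_STEP_SEED = 186283  # fixed so adjusted p-values are reproducible
_SINGLE_STEP_DRAWS = 100_000


def standardize_2sd(values) -> np.ndarray:
    """Centre and divide by two sample standard deviations (ddof=1)."""
    x = np.asarray(values, dtype=float)
    if np.unique(x[~np.isnan(x)]).size < 2:
        raise ValueError("standardize_2sd needs >= 2 distinct values")
    sd = np.nanstd(x, ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    return (x - np.nanmean(x)) / (2.0 * sd)


def rank_transform(values) -> np.ndarray:
    """Average ranks (ties share their mean rank), NaN kept as NaN."""
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = ~np.isnan(x)
    out[mask] = stats.rankdata(x[mask], method="average")
    return out


@dataclass
class ModelSpec:
    """One model of the battery: response, transform, terms, random structure."""

    response: str
    fixed_terms: tuple[str, ...]
    transform: str = "none"  # none | rank | log
    interactions: tuple[tuple[str, str], ...] = ()
    random_slope: bool = True
    include_batch: bool = False
    subset: str = "all"  # all | first_eggs
    model_id: str = ""

    def __post_init__(self) -> None:
        if self.transform not in ("none", "rank", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if "paternity" in self.fixed_terms and self.subset != "first_eggs":
            # paternity comparisons only exist among first-laid eggs
            object.__setattr__(self, "subset", "first_eggs")
        if not self.model_id:
            self.model_id = f"{self.response}~{'+'.join(self.fixed_terms)}"


@dataclass
class EffectEstimate:
    """A single term's standardised effect with Wald inference."""

    model: str
    term: str
    beta: float
    se: float
    z: float
    p_raw: float
    ci_low: float = field(default=np.nan)
    ci_high: float = field(default=np.nan)
    p_single_step: float | None = None
    p_fdr: float | None = None

    def __post_init__(self) -> None:
        if np.isnan(self.ci_low):
            self.ci_low = self.beta - 1.96 * self.se
        if np.isnan(self.ci_high):
            self.ci_high = self.beta + 1.96 * self.se


@dataclass
class FitResult:
    """Fitted model: estimates plus the machinery multiplicity needs."""

    spec: ModelSpec
    estimates: list[EffectEstimate]
    cov_terms: pd.DataFrame | None  # covariance of the tested coefficients
    converged: bool
    dropped_slope: bool
    variance_components: dict[str, float]
    n_obs: int


@dataclass
class VariancePartition:
    between_pct: float
    within_pct: float


def _code_predictors(data: pd.DataFrame, terms) -> pd.DataFrame:
    """Code terms: binaries to 0/1 (unstandardised), continuous to 2-SD scale."""
    cols = {}
    for t in terms:
        col = data[t]
        if t in BINARY_CODING:
            if col.dtype == object:
                known = col.map(BINARY_CODING[t])
                if known.isna().any():
                    bad = sorted(col[known.isna()].unique())
                    raise ValueError(f"unknown levels for {t}: {bad}")
                cols[t] = known.to_numpy(float)
            else:
                cols[t] = col.to_numpy(float)
        else:
            cols[t] = standardize_2sd(col.to_numpy(float))
    return pd.DataFrame(cols, index=data.index)


def _transform_response(y: np.ndarray, transform: str) -> np.ndarray:
    if transform == "rank":
        y = rank_transform(y)
    elif transform == "log":
        if np.nanmin(y) <= 0:
            raise ValueError("log transform needs positive response values")
        y = np.log(y)
    return standardize_2sd(y)


def fit_lmm(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit one battery model by REML and return Wald effect estimates.

    ``data`` holds one row per egg with the response column, the covariates,
    ``female_id`` and (if ``spec.include_batch``) a ``batch`` column. A
    singular random-slope fit is refitted without the slope and flagged.
    """
    df = data.copy()
    if spec.subset == "first_eggs":
        df = df[df["laying_order"] == 1]
    if "paternity" in spec.fixed_terms:
        df = df[df["paternity"].isin(["within-pair", "extra-pair"])]
    needed = [spec.response, "female_id", *spec.fixed_terms]
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    if df["female_id"].nunique() < 2:
        raise ValueError("need >= 2 females to fit a mixed model")

    y = _transform_response(df[spec.response].to_numpy(float), spec.transform)
    terms = [t for t in spec.fixed_terms if df[t].nunique() > 1]
    dropped_const = set(spec.fixed_terms) - set(terms)
    if dropped_const:
        logger.info("dropping constant term(s) in subset %r: %s",
                    spec.subset, sorted(dropped_const))
    X = _code_predictors(df, terms)
    for a, b in spec.interactions:
        if a in dropped_const or b in dropped_const:
            continue
        pair = _code_predictors(df, [t for t in (a, b) if t not in X.columns])
        Xa = X[a] if a in X.columns else pair[a]
        Xb = X[b] if b in X.columns else pair[b]
        X[f"{a}:{b}"] = Xa * Xb
    term_names = list(X.columns)
    exog = np.column_stack([np.ones(len(df)), X.to_numpy(float)])
    exog_names = ["Intercept", *term_names]

    use_slope = spec.random_slope and df["laying_order"].nunique() > 1
    lo_std = (standardize_2sd(df["laying_order"].to_numpy(float))
              if df["laying_order"].nunique() > 1 else np.zeros(len(df)))
    use_batch = (spec.include_batch and "batch" in df.columns
                 and df["batch"].nunique() > 1)

    # formula-safe column names (interaction terms contain ':')
    safe = {t: t.replace(":", "_x_") for t in term_names}
    fdf = pd.DataFrame({safe[t]: X[t].to_numpy(float) for t in term_names})
    fdf["_y"] = y
    fdf["female_id"] = df["female_id"].to_numpy()
    fdf["_lo_std"] = lo_std
    if use_batch:
        fdf["batch"] = df["batch"].to_numpy()
    fdf["_one"] = 1

    def _fit(with_slope: bool):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if use_batch:
                # crossed female x batch random intercepts (and optionally a
                # per-female laying-order slope) as variance components
                # within a single all-encompassing group
                vc = {"female": "0 + C(female_id)", "batch": "0 + C(batch)"}
                if with_slope:
                    vc["slope"] = "0 + C(female_id):_lo_std"
                formula = "_y ~ " + " + ".join(safe[t] for t in term_names)
                model = MixedLM.from_formula(formula, groups="_one",
                                             vc_formula=vc, re_formula="0",
                                             data=fdf)
            else:
                re = (np.column_stack([np.ones(len(df)), lo_std])
                      if with_slope else np.ones((len(df), 1)))
                model = MixedLM(y, exog, groups=df["female_id"].to_numpy(),
                                exog_re=re)
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
        return res

    dropped = False
    res = _fit(use_slope)
    if use_slope:
        # near-zero slope variance => singular fit; refit without the slope
        try:
            if use_batch:
                vc_names = list(res.model.exog_vc.names)
                slope_var = (float(np.asarray(res.vcomp)[vc_names.index("slope")])
                             if "slope" in vc_names else 1.0)
            else:
                slope_var = float(np.asarray(res.cov_re)[-1, -1])
        except Exception:
            slope_var = 1.0
        if not np.isfinite(slope_var) or slope_var < 1e-8:
            res = _fit(False)
            dropped = True

    if use_batch:
        fit_names = ["Intercept", *(safe[t] for t in term_names)]
        lookup = {safe[t]: t for t in term_names}
    else:
        fit_names = exog_names
        lookup = {t: t for t in term_names}
    params = pd.Series(np.asarray(res.fe_params), index=fit_names)
    cov = pd.DataFrame(np.asarray(res.cov_params())[:len(fit_names),
                                                    :len(fit_names)],
                       index=fit_names, columns=fit_names)
    params = params.rename(lookup)
    cov = cov.rename(index=lookup, columns=lookup)
    ests = []
    for t in term_names:
        var_t = float(cov.loc[t, t])
        beta = float(params[t])
        se = float(np.sqrt(var_t)) if var_t > 0 else np.nan
        z = beta / se if np.isfinite(se) and se > 0 else np.nan
        p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        ests.append(EffectEstimate(model=spec.model_id, term=t, beta=beta,
                                   se=se, z=z, p_raw=p))
    vcomp = {}
    if use_batch:
        for nm, val in zip(res.model.exog_vc.names, np.asarray(res.vcomp)):
            vcomp[nm] = float(val)
    else:
        cov_re = np.asarray(res.cov_re)
        vcomp["female"] = float(cov_re[0, 0])
        if use_slope and not dropped and cov_re.shape[0] > 1:
            vcomp["slope"] = float(cov_re[1, 1])
    vcomp["residual"] = float(res.scale)
    return FitResult(spec=spec, estimates=ests,
                     cov_terms=cov.loc[term_names, term_names],
                     converged=bool(getattr(res, "converged", True)),
                     dropped_slope=dropped, variance_components=vcomp,
                     n_obs=len(df))


def variance_partition(values, groups) -> VariancePartition:
    """Between/within-female variance split from an intercept-only LMM."""
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    mask = ~np.isnan(y)
    y, g = y[mask], g[mask]
    if pd.unique(g).size < 2:
        raise ValueError("need >= 2 groups")
    counts = pd.Series(g).value_counts()
    if (counts < 2).all():
        raise ValueError("need >= 2 observations in at least one group")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = MixedLM(y, np.ones((len(y), 1)), groups=g).fit(reml=True)
        vf = float(np.asarray(res.cov_re)[0, 0])
        ve = float(res.scale)
        between = 100.0 * vf / (vf + ve)
    except Exception as exc:
        logger.warning("variance partition fit degenerate (%s); "
                       "reporting 0%% between", exc)
        between = 0.0
    return VariancePartition(between_pct=between, within_pct=100.0 - between)


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted p values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def _single_step(fit: FitResult) -> None:
    """Max-|z| single-step adjustment within one model (Monte Carlo)."""
    terms = [e.term for e in fit.estimates]
    if len(terms) == 1:
        fit.estimates[0].p_single_step = fit.estimates[0].p_raw
        return
    zs = np.array([e.z for e in fit.estimates])
    if fit.cov_terms is None or not np.all(np.isfinite(fit.cov_terms.to_numpy())):
        logger.warning("missing contrast covariance for %s; Bonferroni fallback",
                       fit.spec.model_id)
        for e in fit.estimates:
            e.p_single_step = min(1.0, e.p_raw * len(terms))
        return
    cov = fit.cov_terms.loc[terms, terms].to_numpy()
    try:
        dv = np.diag(cov)
        if np.any(~np.isfinite(dv)) or np.any(dv <= 0):
            raise np.linalg.LinAlgError("degenerate contrast variances")
        d = np.sqrt(dv)
        corr = cov / np.outer(d, d)
        corr = (corr + corr.T) / 2
        # ridge for numerical PSD-ness
        w, V = np.linalg.eigh(corr)
        corr = (V * np.clip(w, 1e-10, None)) @ V.T
        L = np.linalg.cholesky(corr + 1e-12 * np.eye(len(terms)))
    except np.linalg.LinAlgError:
        logger.warning("contrast covariance unusable for %s; Bonferroni "
                       "fallback", fit.spec.model_id)
        for e in fit.estimates:
            e.p_single_step = min(1.0, e.p_raw * len(terms))
        return
    rng = np.random.default_rng(_SINGLE_STEP_SEED)
    draws = rng.standard_normal((_SINGLE_STEP_DRAWS, len(terms))) @ L.T
    maxabs = np.abs(draws).max(axis=1)
    for e, z in zip(fit.estimates, zs):
        if np.isfinite(z):
            e.p_single_step = float((1 + np.sum(maxabs >= abs(z)))
                                    / (1 + _SINGLE_STEP_DRAWS))
            e.p_single_step = max(e.p_single_step, e.p_raw)
        else:
            e.p_single_step = np.nan


def adjust_pvalues(fits: list[FitResult], min_family: int = 5
                   ) -> list[EffectEstimate]:
    """Apply single-step correction within models and BH-FDR across models.

    FDR families group the same term across models (e.g. the laying-order
    effect across all protein models) and are corrected only when at least
    ``min_family`` models contribute; smaller families keep the single-step
    value.
    """
    for fit in fits:
        _single_step(fit)
    all_ests = [e for fit in fits for e in fit.estimates]
    by_term: dict[str, list[EffectEstimate]] = {}
    for e in all_ests:
        by_term.setdefault(e.term, []).append(e)
    for term, ests in by_term.items():
        ps = np.array([e.p_single_step for e in ests], dtype=float)
        ok = np.isfinite(ps)
        if ok.sum() >= min_family:
            adj = np.full(len(ests), np.nan)
            adj[ok] = benjamini_hochberg(ps[ok])
            for e, a in zip(ests, adj):
                e.p_fdr = float(a) if np.isfinite(a) else np.nan
        else:
            for e in ests:
                e.p_fdr = e.p_single_step
    return all_ests


def test_interactions(data: pd.DataFrame, response: str,
                      main_terms: tuple[str, ...] = ("laying_order",
                                                     "female_age",
                                                     "clutch_size",
                                                     "embryo_sex"),
                      transform: str = "none",
                      include_batch: bool = False) -> list[FitResult]:
    """Fit the three a-priori interaction models for one response.

    Exactly female age x laying order, female age x clutch size and embryo
    sex x laying order, each added to the main-effects model.
    """
    fits = []
    for a, b in A_PRIORI_INTERACTIONS:
        terms = tuple(dict.fromkeys([*main_terms, a, b]))
        spec = ModelSpec(response=response, fixed_terms=terms,
                         transform=transform, interactions=((a, b),),
                         include_batch=include_batch,
                         model_id=f"{response}:{a}x{b}")
        fits.append(fit_lmm(spec, data))
    return fits
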