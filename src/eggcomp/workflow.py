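"""End-to-end orchestration of the egg-composition pipeline.

Stages run in the order quantify -> model -> cluster -> enrich -> associate
on either a synthetic dataset (generated in place from the design constants)
or TSV inputs. All randomness flows from a master seed through fixed
sub-seeds, so re-running a configuration reproduces byte-identical outputs;
a manifest records seeds, stage toggles and filter counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthdata, quant, infer, apcluster, enrich, assoc

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "write_report", "default_battery"]


@dataclass
class PipelineConfig:
    """Seeds, stage toggles and settings for one pipeline run."""

    seed: int = 0
    input_dir: str | None = None  # None: self-generate via synthdata
    output_dir: str | None = None
    study: dict = field(default_factory=dict)  # StudyConfig overrides
    run_quant: bool = True
    run_model: bool = True
    run_cluster: bool = True
    run_enrich: bool = True
    run_assoc: bool = True
    ap_q: float = 0.0
    ap_damping: float = 0.9
    ap_max_iter: int = 1000
    ap_conv_iter: int = 100
    enrich_n_sim: int = 10_000
    assoc_n_perm: int = 10_000
    summarize_method: str = "lmm"

    def sub_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def default_battery(responses: dict[str, str],
                    include_batch: bool = False) -> list[infer.ModelSpec]:
    """Main-effects models (all eggs) plus the paternity model (first eggs).

    ``responses`` maps response column -> transform. Egg weight is excluded
    as a predictor of itself.
    """
    specs = []
    for resp, transform in responses.items():
        terms = ["laying_order", "female_age", "lay_date", "clutch_size",
                 "embryo_sex"]
        if resp != "egg_weight":
            terms.append("egg_weight")
        specs.append(infer.ModelSpec(
            response=resp, fixed_terms=tuple(terms), transform=transform,
            include_batch=include_batch, model_id=f"{resp}:main"))
        specs.append(infer.ModelSpec(
            response=resp, fixed_terms=tuple([*terms, "paternity"]),
            transform=transform, include_batch=include_batch,
            subset="first_eggs", model_id=f"{resp}:paternity"))
    return specs


def _estimates_frame(fits: list[infer.FitResult]) -> pd.DataFrame:
    rows = []
    for f in fits:
        for e in f.estimates:
            rows.append({"model": e.model, "term": e.term, "beta": e.beta,
                         "se": e.se, "ci_low": e.ci_low, "ci_high": e.ci_high,
                         "z": e.z, "p_raw": e.p_raw,
                         "p_single_step": e.p_single_step, "p_fdr": e.p_fdr,
                         "n_obs": f.n_obs, "converged": f.converged,
                         "dropped_slope": f.dropped_slope})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the result bundle.

    The bundle maps stage names to data frames plus a ``manifest`` dict; when
    ``config.output_dir`` is set every table is also written as TSV.
    """
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "stages": {}, "counts": {}}
    bundle: dict = {"manifest": manifest}

    try:
        if config.input_dir:
            d = Path(config.input_dir)
            design = pd.read_csv(d / "metadata.tsv", sep="\t")
            intensities = pd.read_csv(d / "intensities.tsv", sep="\t")
            annotation = pd.read_csv(d / "annotation.tsv", sep="\t")
            carotenoids = pd.read_csv(d / "carotenoids.tsv", sep="\t")
            lipids = pd.read_csv(d / "lipids.tsv", sep="\t")
        else:
            study = synthdata.StudyConfig(seed=config.sub_seed("synthdata"),
                                          **config.study)
            ds = synthdata.generate_dataset(study)
            design, intensities, annotation = ds.design, ds.intensities, ds.annotation
            carotenoids, lipids = ds.carotenoids, ds.lipids
            bundle["truth"] = ds.truth
    except Exception as exc:
        raise RuntimeError(f"stage 'input' failed: {exc}") from exc
    bundle.update(design=design, annotation=annotation,
                  carotenoids=carotenoids, lipids=lipids)
    manifest["counts"]["eggs"] = int(len(design))
    manifest["counts"]["proteins_raw"] = int(intensities["protein_id"].nunique())

    sample_conc: dict[str, pd.DataFrame] = {}
    rep_conc: dict[str, pd.DataFrame] = {}
    if config.run_quant:
        manifest["stages"]["quant"] = True
        try:
            for comp, suffix, total_col, weight_col in [
                    ("albumen", "A", "albumen_protein_mg", "albumen_weight"),
                    ("yolk", "Y", "yolk_protein_mg", "yolk_weight")]:
                sub = intensities[intensities["compartment"] == comp]
                if sub.empty:
                    continue
                sid = design["egg_id"] + f"_{suffix}"
                totals = dict(zip(sid, design[total_col]))
                weights = dict(zip(sid, design[weight_col]))
                # compared biological groups: first vs later-laid eggs
                first = dict(zip(design["egg_id"], design["laying_order"] == 1))
                groups = {s: ("first" if first[s.rsplit("_", 1)[0]] else "later")
                          for s in sub["sample_id"].unique()}
                res = quant.quantify(sub, totals, weights, groups,
                                     seed=config.sub_seed("impute"),
                                     summarize=config.summarize_method)
                rep_conc[comp] = res["replicate_concentrations"]
                sample_conc[comp] = res["sample_concentrations"]
                manifest["counts"][f"proteins_kept_{comp}"] = len(res["kept"])
        except Exception as exc:
            raise RuntimeError(f"stage 'quant' failed: {exc}") from exc
        bundle["sample_concentrations"] = sample_conc
        bundle["replicate_concentrations"] = rep_conc

    egg_meta = design.set_index("egg_id")
    chem = (carotenoids.set_index("egg_id")[["total_carotenoids"]]
            .join(lipids.set_index("egg_id")[["lipid_mg_per_g"]])
            .join(carotenoids.set_index("egg_id")["hplc_batch"]))

    if config.run_model:
        manifest["stages"]["model"] = True
        try:
            data = egg_meta.join(chem).reset_index()
            data["batch"] = data["hplc_batch"]
            battery = default_battery({"egg_weight": "none",
                                       "lipid_mg_per_g": "none",
                                       "total_carotenoids": "log"},
                                      include_batch=True)
            fits = [infer.fit_lmm(s, data) for s in battery]
            infer.adjust_pvalues(fits)
            bundle["composition_effects"] = _estimates_frame(fits)
            vp = infer.variance_partition(data["egg_weight"], data["female_id"])
            bundle["egg_weight_variance"] = vp
            manifest["counts"]["composition_models"] = len(fits)

            protein_fits = []
            for comp, conc in sample_conc.items():
                wide = conc.pivot(index="sample_id", columns="protein_id",
                                  values="concentration")
                meta = egg_meta.loc[[s.rsplit("_", 1)[0] for s in wide.index]]
                meta = meta.set_index(wide.index)
                rep = rep_conc[comp]
                batch = (rep.sort_values("replicate_id")
                         .groupby("sample_id")["batch_id"].first())
                for pid in wide.columns:
                    pdat = meta.copy()
                    pdat["conc"] = wide[pid]
                    pdat["batch"] = batch.reindex(wide.index).to_numpy()
                    spec = infer.ModelSpec(
                        response="conc",
                        fixed_terms=("laying_order", "female_age", "lay_date",
                                     "clutch_size", "egg_weight", "embryo_sex"),
                        transform="rank", include_batch=True,
                        model_id=f"{comp}:{pid}")
                    protein_fits.append(infer.fit_lmm(spec, pdat))
            if protein_fits:
                infer.adjust_pvalues(protein_fits)
                bundle["protein_effects"] = _estimates_frame(protein_fits)
                manifest["counts"]["protein_models"] = len(protein_fits)
        except Exception as exc:
            raise RuntimeError(f"stage 'model' failed: {exc}") from exc

    cluster_sums: dict[str, pd.DataFrame] = {}
    if config.run_cluster:
        manifest["stages"]["cluster"] = True
        try:
            bundle["protein_clusters"] = {}
            for comp, conc in sample_conc.items():
                wide = conc.pivot(index="protein_id", columns="sample_id",
                                  values="concentration")
                # batch-adjusted abundances can dip <= 0 for trace proteins;
                # floor at half the smallest positive value before the log
                floor = wide[wide > 0].min().min() / 2.0
                sim = apcluster.build_similarity(np.log(wide.clip(lower=floor)))
                res = apcluster.run_ap(sim, q=config.ap_q,
                                       damping=config.ap_damping,
                                       max_iter=config.ap_max_iter,
                                       conv_iter=config.ap_conv_iter,
                                       seed=config.sub_seed(f"ap-{comp}"))
                bundle["protein_clusters"][comp] = res
                cluster_sums[comp] = apcluster.summarize_clusters(
                    res, rep_conc[comp])
                manifest["counts"][f"clusters_{comp}"] = res.n_clusters
        except Exception as exc:
            raise RuntimeError(f"stage 'cluster' failed: {exc}") from exc
        bundle["cluster_sums"] = cluster_sums

    if config.run_enrich:
        if not config.run_cluster:
            raise RuntimeError("stage 'enrich' needs the cluster stage")
        manifest["stages"]["enrich"] = True
        try:
            bundle["enrichment"] = {}
            for comp, res in bundle["protein_clusters"].items():
                bundle["enrichment"][comp] = enrich.funcat_enrichment(
                    res.assignments().rename(columns={"item_id": "protein_id"}),
                    annotation, n_sim=config.enrich_n_sim,
                    seed=config.sub_seed(f"enrich-{comp}"))
        except Exception as exc:
            raise RuntimeError(f"stage 'enrich' failed: {exc}") from exc

    if config.run_assoc:
        if not config.run_cluster:
            raise RuntimeError("stage 'assoc' needs the cluster stage")
        manifest["stages"]["assoc"] = True
        try:
            feats = {}
            for comp, sums in cluster_sums.items():
                piv = sums.pivot(index="sample_id", columns="cluster",
                                 values="cluster_sum")
                piv.index = [s.rsplit("_", 1)[0] for s in piv.index]
                piv.columns = [f"{comp[0].upper()}{c}" for c in piv.columns]
                feats[comp] = piv
            features = chem[["lipid_mg_per_g", "total_carotenoids"]].join(
                egg_meta[["egg_weight"]])
            for piv in feats.values():
                features = features.join(piv)
            egg_res = apcluster.cluster_eggs(
                features, q=config.ap_q, damping=config.ap_damping,
                max_iter=config.ap_max_iter, conv_iter=config.ap_conv_iter,
                seed=config.sub_seed("ap-eggs"))
            bundle["egg_clusters"] = egg_res
            manifest["counts"]["egg_clusters"] = egg_res.n_clusters
            kept_eggs = list(egg_res.items)
            preds = egg_meta.loc[kept_eggs, ["clutch_size", "lay_date",
                                             "laying_order", "female_age",
                                             "embryo_sex", "paternity"]]
            labels = pd.Series(egg_res.labels, index=kept_eggs)
            bundle["egg_cluster_association"] = assoc.egg_cluster_association(
                labels, preds, n_perm=config.assoc_n_perm,
                seed=config.sub_seed("assoc"))
        except RuntimeError:
            raise
        except Exception as exc:
            raise RuntimeError(f"stage 'assoc' failed: {exc}") from exc

    if config.output_dir:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: dict, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = dict(bundle["manifest"])
    for key in ("design", "annotation", "carotenoids", "lipids",
                "composition_effects", "protein_effects",
                "egg_cluster_association"):
        if key in bundle and isinstance(bundle[key], pd.DataFrame):
            bundle[key].to_csv(out / f"{key}.tsv", sep="\t", index=False)
    for comp, df in bundle.get("sample_concentrations", {}).items():
        df.to_csv(out / f"concentrations_{comp}.tsv", sep="\t", index=False)
    for comp, res in bundle.get("protein_clusters", {}).items():
        res.assignments().to_csv(out / f"clusters_{comp}.tsv", sep="\t",
                                 index=False)
    for comp, df in bundle.get("enrichment", {}).items():
        df.to_csv(out / f"enrichment_{comp}.tsv", sep="\t", index=False)
    if "egg_clusters" in bundle:
        bundle["egg_clusters"].assignments().to_csv(
            out / "egg_clusters.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))


def write_report(bundle: dict, outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Tabular report: effect grids, protein rankings, cluster summaries.

    Sections with missing inputs are skipped and noted in the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, pd.DataFrame] = {}
    notes = []

    if "composition_effects" in bundle:
        report["effects_grid"] = bundle["composition_effects"][
            ["model", "term", "beta", "ci_low", "ci_high", "p_fdr"]]
    else:
        notes.append("composition effects unavailable")

    if "protein_effects" in bundle and len(bundle["protein_effects"]):
        pe = bundle["protein_effects"].sort_values("beta", ascending=False)
        report["protein_effect_ranking"] = pe
        sig = pe[pe["p_fdr"] < 0.05] if pe["p_fdr"].notna().any() else pe.iloc[:0]
        if sig.empty:
            notes.append("zero protein effects significant after FDR")
    else:
        notes.append("protein effects unavailable")

    if "enrichment" in bundle:
        for comp, df in bundle["enrichment"].items():
            mat = df.pivot(index="cluster", columns="term", values="enriched")
            report[f"enrichment_matrix_{comp}"] = mat.reset_index()

    if "egg_cluster_association" in bundle:
        report["egg_cluster_association"] = bundle["egg_cluster_association"]

    for name, df in report.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    manifest = dict(bundle.get("manifest", {}))
    manifest["report_notes"] = notes
    (outdir / "report_manifest.json").write_text(
        json.dumps(manifest, indent=1, default=str))
    return report
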