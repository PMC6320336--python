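"""Mixed-model battery: life-history predictors of egg weight, yolk lipids,
carotenoids and every quantitated protein, with 2-SD standardised effects,
single-step within-model correction and FDR across model families."""

import numpy as np
import pandas as pd
from common import SEED, WORK, load, save

from eggcomp import infer
from eggcomp.workflow import default_battery, _estimates_frame


def main() -> None:
    design = load("metadata")
    caro = load("carotenoids")
    lipids = load("lipids")
    data = (design.set_index("egg_id")
            .join(caro.set_index("egg_id")[["total_carotenoids",
                                            "hplc_batch"]])
            .join(lipids.set_index("egg_id")[["lipid_mg_per_g"]])
            .reset_index())
    data["batch"] = data["hplc_batch"]

    vp = infer.variance_partition(data["egg_weight"], data["female_id"])
    print(f"egg weight variance: {vp.between_pct:.1f}% between clutches")

    battery = default_battery({"egg_weight": "none", "lipid_mg_per_g": "none",
                               "total_carotenoids": "log"},
                              include_batch=True)
    fits = [infer.fit_lmm(s, data) for s in battery]
    inter = infer.test_interactions(data, "egg_weight")
    infer.adjust_pvalues(fits + inter)
    comp = _estimates_frame(fits + inter)
    save(comp, "composition_effects")
    lo = comp[(comp.term == "laying_order") & comp.model.str.endswith("main")]
    print("laying-order effects (standardised beta, FDR p):")
    for _, r in lo.iterrows():
        print(f"  {r.model:24s} {r.beta:+.3f}  p_fdr={r.p_fdr:.3f}")
    ia = comp[comp.term.str.contains(":")]
    for _, r in ia.iterrows():
        print(f"  interaction {r.term:28s} {r.beta:+.3f} "
              f"p_single_step={r.p_single_step:.3f}")

    protein_fits = []
    for comp_name in ("albumen", "yolk"):
        sc = load(f"concentrations_{comp_name}", WORK)
        rc = load(f"replicate_concentrations_{comp_name}", WORK)
        wide = sc.pivot(index="sample_id", columns="protein_id",
                        values="concentration")
        eggs = [s.rsplit("_", 1)[0] for s in wide.index]
        meta = design.set_index("egg_id").loc[eggs].set_index(wide.index)
        batch = (rc.sort_values("replicate_id")
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
                model_id=f"{comp_name}:{pid}")
            protein_fits.append(infer.fit_lmm(spec, pdat))
    infer.adjust_pvalues(protein_fits)
    pe = _estimates_frame(protein_fits)
    save(pe, "protein_effects")
    for comp_name in ("albumen", "yolk"):
        sub = pe[pe.model.str.startswith(comp_name)
                 & (pe.term == "laying_order")]
        up = ((sub.p_fdr < 0.05) & (sub.beta > 0)).sum()
        dn = ((sub.p_fdr < 0.05) & (sub.beta < 0)).sum()
        print(f"{comp_name}: laying order significant (FDR<0.05) for "
              f"{up} proteins up, {dn} down of {len(sub)}")


if __name__ == "__main__":
    main()
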