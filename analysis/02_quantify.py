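"""Label-free quantitation: identification/quantitation filters, total-signal
normalisation, bounded-uniform imputation and concentration estimation for
both egg compartments."""

import pandas as pd
from common import DATA, SEED, WORK, load, save

from eggcomp import quant

SUFFIX = {"albumen": "A", "yolk": "Y"}


def main() -> None:
    design = load("metadata")
    intensities = load("intensities")
    for comp in ("albumen", "yolk"):
        sub = intensities[intensities["compartment"] == comp]
        sid = design["egg_id"] + f"_{SUFFIX[comp]}"
        totals = dict(zip(sid, design[f"{comp}_protein_mg"]))
        weights = dict(zip(sid, design[f"{comp}_weight"]))
        first = dict(zip(design["egg_id"], design["laying_order"] == 1))
        groups = {s: ("first" if first[s.rsplit("_", 1)[0]] else "later")
                  for s in sub["sample_id"].unique()}
        res = quant.quantify(sub, totals, weights, groups, seed=SEED)
        n_raw = sub["protein_id"].nunique()
        print(f"{comp}: {len(res['kept'])}/{n_raw} proteins quantitated "
              f"(identified in >=2 replicates in >= half of one group)")
        sc = res["sample_concentrations"]
        top = (sc.groupby("protein_id")["concentration"].mean()
               .sort_values(ascending=False))
        share = top.head(10).sum() / top.sum()
        print(f"  top-10 proteins carry {100 * share:.1f}% of the summed "
              f"concentration; dynamic range "
              f"{top.max() / top[top > 0].min():.1e}")
        save(res["replicate_concentrations"],
             f"replicate_concentrations_{comp}", WORK)
        save(sc, f"concentrations_{comp}", WORK)


if __name__ == "__main__":
    main()
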