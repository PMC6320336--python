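"""Affinity-propagation clustering of whole eggs on their composition:
protein cluster sums (both compartments), yolk lipid and total carotenoid
concentrations, and egg weight."""

import numpy as np
import pandas as pd
from common import RESULTS, SEED, load, save

from eggcomp import apcluster


def main() -> None:
    design = load("metadata").set_index("egg_id")
    caro = load("carotenoids").set_index("egg_id")
    lipids = load("lipids").set_index("egg_id")
    features = (lipids[["lipid_mg_per_g"]]
                .join(caro[["total_carotenoids"]])
                .join(design[["egg_weight"]]))
    for comp in ("albumen", "yolk"):
        sums = load(f"cluster_sums_{comp}", RESULTS)
        piv = sums.pivot(index="sample_id", columns="cluster",
                         values="cluster_sum")
        piv.index = [s.rsplit("_", 1)[0] for s in piv.index]
        piv.columns = [f"{comp[0].upper()}{c}" for c in piv.columns]
        features = features.join(piv)

    res = apcluster.cluster_eggs(features, q=0.0, seed=SEED)
    sizes = np.bincount(res.labels)[1:]
    print(f"egg clustering on {features.shape[1]} features: "
          f"{res.n_clusters} clusters (sizes {sorted(sizes, reverse=True)})")
    save(res.assignments().rename(columns={"item_id": "egg_id"}),
         "egg_clusters")
    means = features.loc[res.items].groupby(res.labels).mean()
    print(means.round(2).to_string())


if __name__ == "__main__":
    main()
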