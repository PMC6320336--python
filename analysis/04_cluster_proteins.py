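"""Affinity-propagation clustering of the albumen and yolk proteomes
(Pearson similarity on log concentrations, preference quantile q = 0) and
per-egg cluster concentration sums."""

import numpy as np
from common import SEED, WORK, load, save

from eggcomp import apcluster


def main() -> None:
    for comp in ("albumen", "yolk"):
        sc = load(f"concentrations_{comp}", WORK)
        rc = load(f"replicate_concentrations_{comp}", WORK)
        wide = sc.pivot(index="protein_id", columns="sample_id",
                        values="concentration")
        floor = wide[wide > 0].min().min() / 2.0
        sim = apcluster.build_similarity(np.log(wide.clip(lower=floor)))
        res = apcluster.run_ap(sim, q=0.0, seed=SEED)
        sizes = np.bincount(res.labels)[1:]
        print(f"{comp}: {res.n_clusters} protein clusters "
              f"(sizes {sorted(sizes, reverse=True)}), "
              f"converged={res.converged} after {res.iterations} sweeps")
        save(res.assignments(), f"protein_clusters_{comp}")
        sums = apcluster.summarize_clusters(res, rc)
        save(sums, f"cluster_sums_{comp}")


if __name__ == "__main__":
    main()
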