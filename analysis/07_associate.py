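"""Do life-history traits predict the egg clusters? Functional chi-square
per categorised predictor with FDR across the battery, plus the Fisher
exact test of extra-pair paternity against laying position."""

import pandas as pd
from common import RESULTS, SEED, load, save

from eggcomp import assoc


def main() -> None:
    design = load("metadata").set_index("egg_id")
    eggs = load("egg_clusters", RESULTS).set_index("egg_id")
    preds = design.loc[eggs.index, ["clutch_size", "lay_date", "laying_order",
                                    "female_age", "embryo_sex", "paternity"]]
    out = assoc.egg_cluster_association(eggs["cluster"], preds,
                                        n_perm=10_000, seed=SEED)
    save(out, "egg_cluster_association")
    print("functional chi-square of predictors on egg clusters:")
    print(out.round(4).to_string(index=False))

    assigned = design[design["paternity"] != "unknown"]
    first = assigned["laying_order"] == 1
    ep = assigned["paternity"] == "extra-pair"
    table = [[int((first & ep).sum()), int((first & ~ep).sum())],
             [int((~first & ep).sum()), int((~first & ~ep).sum())]]
    p = assoc.fisher_exact(table)
    print(f"extra-pair vs laying position {table}: Fisher exact p = {p:.2e}")


if __name__ == "__main__":
    main()
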