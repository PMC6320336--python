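"""Monte-Carlo FunCat enrichment of the protein clusters (10,000 random
reassignments per compartment; a cluster is enriched in a term when its
observed carrier count exceeds the null 95% quantile)."""

from common import RESULTS, SEED, load, save

from eggcomp import enrich


def main() -> None:
    annotation = load("annotation")
    for comp in ("albumen", "yolk"):
        clusters = load(f"protein_clusters_{comp}", RESULTS)
        assign = clusters.rename(columns={"item_id": "protein_id"})
        res = enrich.funcat_enrichment(assign, annotation, n_sim=10_000,
                                       seed=SEED)
        save(res, f"enrichment_{comp}")
        hits = res[res.enriched]
        print(f"{comp}: {len(hits)} enriched (cluster, term) pairs of "
              f"{len(res)} tested")
        for _, r in hits.iterrows():
            print(f"  cluster {r.cluster}: {r.term} "
                  f"(observed {r.observed} > q95 {r.null_q95:.1f}, "
                  f"p_emp={r.p_emp:.4f})")


if __name__ == "__main__":
    main()
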