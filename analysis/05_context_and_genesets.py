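"""Where do the changes fall?  CpG-density-context enrichment of gains and
losses, promoter-to-gene mapping, and a hypergeometric gene-set enrichment
against sets built from the planted truth.  Writes
results/context_enrichment.tsv and results/geneset_enrichment.tsv."""

import pandas as pd

from _common import RESULTS_DIR, load_or_simulate

from crcmeth import diffmeth
from crcmeth.annotation import (
    context_enrichment,
    geneset_enrichment,
    map_promoter_genes,
    promoter_universe,
)


def main() -> None:
    bm, ann, _, truth = load_or_simulate()
    records = pd.read_csv(RESULTS_DIR / "dmc_records.tsv", sep="\t")
    hits = records.loc[records["is_dmc"]]

    tables = []
    for direction in ("gain", "loss"):
        probes = hits.loc[hits["direction"] == direction, "probe_id"].unique()
        tables.append(context_enrichment(probes, bm.probe_ids, ann, direction))
    context = pd.concat(tables, ignore_index=True)
    context.to_csv(RESULTS_DIR / "context_enrichment.tsv", sep="\t", index=False)

    print("context enrichment (odds ratio, q):")
    for _, row in context.iterrows():
        flag = " *" if row["q"] < 0.05 else ""
        print(f"  {row['direction']:>4} {row['island_context']:>8}: "
              f"OR = {row['odds_ratio']:6.2f}, q = {row['q']:.2e}{flag}")

    union = diffmeth.dmc_union(records)
    hit_genes, _ = map_promoter_genes(union, ann)
    universe = promoter_universe(ann)
    print(f"promoter genes hit: {len(hit_genes)} of {len(universe)} on the array")

    # gene sets built from the planted truth: genes whose probes carry gains,
    # losses, or no change
    gene_of = ann.frame["gene_symbols"].str[0]
    sets = {
        f"planted_{d}": set(gene_of[truth.probes["direction"] == d])
        for d in ("gain", "loss", "none")
    }
    enrich = geneset_enrichment(hit_genes & universe, universe, sets)
    enrich.to_csv(RESULTS_DIR / "geneset_enrichment.tsv", sep="\t", index=False)
    print("gene-set enrichment of promoter DMC genes:")
    for _, row in enrich.iterrows():
        print(f"  {row['set']:>15}: overlap {row['overlap']}/{row['set_size']}, "
              f"q = {row['q']:.2e}")


if __name__ == "__main__":
    main()
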