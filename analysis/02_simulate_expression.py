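"""Genomics arm: simulate a gene-set collection and an RNA-seq count matrix
for the phantom cohort, planting a positive proliferation-volume coupling
and a negative apoptosis-volume coupling.

Reads results/features.csv; writes results/genesets.gmt,
results/geneset_categories.tsv, results/counts.tsv and
results/counts_filter_report.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from radiogen.expr_sim import (
    ExpressionSimSpec,
    PlantedAssociation,
    gene_universe,
    generate_expression,
)
from radiogen.expression import filter_genes, write_counts
from radiogen.genesets import generate_geneset_collection, write_category_map, write_gmt

CATEGORY_LABELS = [
    "immune_regulation", "extracellular_signaling", "cell_growth",
    "metabolism", "signal_transduction", "disease_specific",
]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--n-genes", type=int, default=2000)
    ap.add_argument("--n-sets", type=int, default=60)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    features = pd.read_csv(args.out_dir / "features.csv", index_col=0)
    uni = gene_universe(args.n_genes)
    coll = generate_geneset_collection(
        args.n_sets, (20, 120), uni, CATEGORY_LABELS, args.seed)
    # rename two background sets as the planted fixtures
    sids = list(coll.sets)
    for old, new, cat in [(sids[0], "proliferation", "cell_growth"),
                          (sids[1], "apoptosis", "cell_growth")]:
        coll.sets[new] = coll.sets.pop(old)[:40]
        coll.categories[new] = cat
        coll.categories.pop(old)

    planted = (
        PlantedAssociation("proliferation", "S1_volume", 0.6, "+"),
        PlantedAssociation("apoptosis", "S1_volume", 0.6, "-"),
    )
    sim = ExpressionSimSpec(n_samples=len(features), n_genes=args.n_genes,
                            planted=planted, rng_seed=args.seed + 1)
    expr = generate_expression(sim, coll, features)
    kept, report = filter_genes(expr)

    write_gmt(coll, args.out_dir / "genesets.gmt")
    write_category_map(coll.categories, args.out_dir / "geneset_categories.tsv")
    write_counts(expr, args.out_dir / "counts.tsv")
    report.to_csv(args.out_dir / "counts_filter_report.tsv", sep="\t")

    print(f"simulated {expr.n_genes} genes x {expr.n_samples} samples; "
          f"{len(coll)} gene sets")
    print(f"gene filter keeps {kept.n_genes}/{expr.n_genes} genes "
          f"({len(report)} removed)")
    print("planted: proliferation + vs S1_volume, apoptosis - vs S1_volume "
          "(Spearman 0.6)")


if __name__ == "__main__":
    main()
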