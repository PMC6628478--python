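"""Association summaries: signed significance matrix, disease-pathway
exclusion, per-category association counts, and the clustered heatmap.

Reads results/enrichment.tsv and results/geneset_categories.tsv; writes
results/association_matrix.tsv, results/category_summary.tsv,
results/heatmap_order.json and results/heatmap.png.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from radiogen.association import (
    category_summary,
    cluster_heatmap_order,
    filter_pathways,
    plot_heatmap,
    significance_matrix,
)
from radiogen.genesets import read_category_map


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--exclude-category", action="append",
                    default=["disease_specific"])
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    results = pd.read_csv(args.out_dir / "enrichment.tsv", sep="\t")
    categories = read_category_map(args.out_dir / "geneset_categories.tsv")

    mat = significance_matrix(results, alpha=args.alpha)
    n_active = int((mat.abs().sum(axis=1) > 0).sum())
    print(f"{n_active}/{len(mat)} gene sets have >= 1 significant "
          f"association at adjusted p <= {args.alpha}")

    kept, dropped = filter_pathways(mat, categories, args.exclude_category)
    print(f"excluded {len(dropped)} pathways in categories "
          f"{args.exclude_category}; {len(kept)} remain")
    kept.to_csv(args.out_dir / "association_matrix.tsv", sep="\t")

    summary = category_summary(kept, categories)
    summary.to_csv(args.out_dir / "category_summary.tsv", sep="\t")
    if not summary.empty:
        print("mean associations per pathway by category:")
        for cat, row in summary.iterrows():
            print(f"  {cat}: {row['mean_associations_per_pathway']:.1f} "
                  f"over {int(row['n_pathways'])} pathways")

    active = kept[kept.abs().sum(axis=1) > 0]
    if len(active) >= 2:
        rows, cols = cluster_heatmap_order(active)
        (args.out_dir / "heatmap_order.json").write_text(json.dumps({
            "rows": [str(active.index[i]) for i in rows],
            "columns": [str(active.columns[j]) for j in cols],
        }, indent=2))
        plot_heatmap(active, path=args.out_dir / "heatmap.png")
        print(f"clustered heatmap over {len(active)} active pathways "
              f"written to heatmap.png")


if __name__ == "__main__":
    main()
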