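"""Association sweep: directional GSEA of every gene set against every
radiomic phenotype with a random-gene-set null and per-phenotype BH FDR.

Reads results/counts.tsv, results/features_z.csv, results/genesets.gmt;
writes results/enrichment.tsv (long format, one row per phenotype-set pair).
"""

import argparse
from pathlib import Path

import pandas as pd

from radiogen.enrichment import GseaParams, run_gsea
from radiogen.expression import filter_genes, normalize_counts, read_counts
from radiogen.genesets import read_gmt


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--n-null", type=int, default=2000,
                    help="random gene sets per test")
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    expr = read_counts(args.out_dir / "counts.tsv")
    expr, _ = filter_genes(expr)
    expr = normalize_counts(expr)
    features_z = pd.read_csv(args.out_dir / "features_z.csv", index_col=0)
    coll = read_gmt(args.out_dir / "genesets.gmt",
                    args.out_dir / "geneset_categories.tsv")

    params = GseaParams(n_null=args.n_null, alpha=args.alpha)
    results = run_gsea(expr, features_z, coll, params, rng_seed=args.seed)
    results.to_csv(args.out_dir / "enrichment.tsv", sep="\t", index=False)

    n_sig = int((results["direction"] != "none").sum())
    print(f"{len(results)} phenotype-set tests "
          f"({features_z.shape[1]} phenotypes x {len(coll)} sets)")
    print(f"{n_sig} significant directional associations at "
          f"adjusted p <= {args.alpha}")
    planted = results[results["set_id"].isin(["proliferation", "apoptosis"])]
    vol = planted[planted["phenotype"] == "S1_volume"]
    for _, r in vol.iterrows():
        print(f"  {r['set_id']} vs S1_volume: es {r['es']:+.3f}, "
              f"direction {r['direction']}, q_pos {r['q_pos']:.4f}, "
              f"q_neg {r['q_neg']:.4f}")


if __name__ == "__main__":
    main()
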