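"""Summaries of enrichment results: signed significance matrix, category
counts, disease-pathway exclusion, and clustered heatmap orderings."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


def significance_matrix(results: pd.DataFrame, alpha: float = 0.05
                        ) -> pd.DataFrame:
    """Gene sets x phenotypes matrix of {+1, -1, 0} significance calls.

    An entry is nonzero iff min(q_pos, q_neg) <= alpha; the smaller adjusted
    p-value picks the sign.  If both directions are significant (rare and
    pathological under split-direction testing), the sign of the enrichment
    score decides and a warning is logged.  Rows with no significant entry
    are retained.
    """
    dup = results.duplicated(subset=["set_id", "phenotype"])
    if dup.any():
        pairs = results.loc[dup, ["set_id", "phenotype"]].values.tolist()
        raise ValueError(f"duplicate (set, phenotype) rows: {pairs[:5]}")
    q_pos = results["q_pos"].to_numpy()
    q_neg = results["q_neg"].to_numpy()
    sign = np.zeros(len(results), dtype=int)
    hit = np.minimum(q_pos, q_neg) <= alpha
    sign[hit] = np.where(q_pos[hit] <= q_neg[hit], 1, -1)
    both = (q_pos <= alpha) & (q_neg <= alpha)
    if both.any():
        warnings.warn(f"{int(both.sum())} cells significant in both "
                      "directions; es sign decides", stacklevel=2)
        sign[both] = np.where(results.loc[both, "es"] >= 0, 1, -1)
    tall = results.assign(sign=sign)
    mat = tall.pivot(index="set_id", columns="phenotype", values="sign")
    return mat.fillna(0).astype(int)


def filter_pathways(
    matrix: pd.DataFrame,
    category_map: dict[str, str],
    exclude_categories: list[str],
) -> tuple[pd.DataFrame, list[str]]:
    """Drop rows whose category is excluded (e.g. disease-specific pathways).

    Every row must be mapped; returns (filtered matrix, dropped set ids).
    """
    unmapped = [sid for sid in matrix.index if sid not in category_map]
    if unmapped:
        raise ValueError(f"rows without category mapping: {unmapped[:10]}")
    excluded = set(exclude_categories)
    dropped = [sid for sid in matrix.index if category_map[sid] in excluded]
    kept = matrix.drop(index=dropped)
    if kept.empty:
        warnings.warn("all pathways excluded; matrix is empty", stacklevel=2)
    return kept, dropped


def category_summary(
    matrix: pd.DataFrame,
    category_map: dict[str, str],
    sort_by: str = "mean_associations_per_pathway",
) -> pd.DataFrame:
    """Per-category association counts over pathways with >= 1 association.

    Pathways with no significant entry do not contribute to either the
    pathway count or the mean (the alternative — averaging over all category
    members — is a caller choice: pass a matrix that retains them and
    compute directly).
    """
    unmapped = [sid for sid in matrix.index if sid not in category_map]
    if unmapped:
        raise ValueError(f"rows without category mapping: {unmapped[:10]}")
    n_assoc = matrix.abs().sum(axis=1)
    active = matrix.index[n_assoc > 0]
    if len(active) == 0:
        return pd.DataFrame(columns=["category", "n_pathways",
                                     "total_associations",
                                     "mean_associations_per_pathway"]
                            ).set_index("category")
    df = pd.DataFrame({
        "set_id": active,
        "category": [category_map[s] for s in active],
        "n_assoc": n_assoc[active].values,
    })
    grouped = df.groupby("category").agg(
        n_pathways=("set_id", "size"),
        total_associations=("n_assoc", "sum"),
    )
    grouped["mean_associations_per_pathway"] = (
        grouped["total_associations"] / grouped["n_pathways"]
    )
    return grouped.sort_values(sort_by, ascending=False)


def cluster_heatmap_order(matrix: pd.DataFrame
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Row and column leaf orderings from average-linkage hierarchical
    clustering on Euclidean distance of the signed entries.

    Deterministic: SciPy's linkage breaks ties by observation index, so two
    runs on the same matrix give the same orderings.  A single row (or
    column) maps to the identity ordering.
    """
    values = matrix.to_numpy(dtype=float)

    def _order(data: np.ndarray) -> np.ndarray:
        if data.shape[0] < 2:
            return np.arange(data.shape[0])
        link = hierarchy.linkage(pdist(data, metric="euclidean"),
                                 method="average")
        return hierarchy.leaves_list(link)

    return _order(values), _order(values.T)


def plot_heatmap(matrix: pd.DataFrame, path=None, ax=None):
    """Thin optional rendering of the clustered signed matrix (green +1,
    red -1, white 0); the orderings and the matrix are the tested artifacts."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    row_order, col_order = cluster_heatmap_order(matrix)
    ordered = matrix.iloc[row_order, col_order]
    if ax is None:
        _, ax = plt.subplots(
            figsize=(max(6, 0.25 * ordered.shape[1]),
                     max(4, 0.25 * ordered.shape[0]))
        )
    cmap = ListedColormap(["#b2182b", "#ffffff", "#1b7837"])
    ax.imshow(ordered.to_numpy(), cmap=cmap, vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(ordered.shape[1]))
    ax.set_xticklabels(ordered.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(ordered.shape[0]))
    ax.set_yticklabels(ordered.index, fontsize=5)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
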