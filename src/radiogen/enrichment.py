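"""Directional gene set enrichment against radiomic phenotypes.

For each (phenotype, gene set) pair: per-gene Spearman correlations rank the
filtered gene universe, a weighted Kolmogorov-Smirnov running-sum statistic
scores the set, a random-gene-set null (sets of matched size drawn uniformly
from the universe) yields nominal p-values tested separately for positive
and negative association, and Benjamini-Hochberg FDR is controlled per
phenotype (and per direction) across all sets.  An association is called
significant when the adjusted p-value is <= alpha (default 0.05).

The random-gene-set null treats genes, not samples, as the exchangeable
unit; it is the literal sampling scheme of the procedure this package
implements and is known to be anti-conservative when genes within a set are
co-expressed.  A sample-permutation null is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix
from .genesets import GeneSetCollection


@dataclass(frozen=True)
class GseaParams:
    n_null: int = 10_000          # random gene sets per (phenotype, set) test
    alpha: float = 0.05           # significance level on adjusted p-values
    weight_p: float = 1.0         # KS weight exponent on |rho|
    min_set_size: int = 5         # after restriction to the filtered universe
    bh_pool_directions: bool = False  # pool +/- p-values in one BH batch
    null_mode: str = "gene"       # "gene" (random gene sets) or "sample"

    def __post_init__(self) -> None:
        if self.null_mode not in ("gene", "sample"):
            raise ValueError("null_mode must be 'gene' or 'sample'")


@dataclass
class GeneLevelStats:
    """Per-gene Spearman rho vs one phenotype, and the descending ranking."""

    phenotype_name: str
    rho: pd.Series                      # indexed by gene id
    constant_genes: list[str] = field(default_factory=list)

    @property
    def ranking(self) -> pd.Index:
        order = np.argsort(-self.rho.to_numpy(), kind="stable")
        return self.rho.index[order]


def gene_level_statistics(
    expr: ExpressionMatrix, phenotype: pd.Series | np.ndarray,
    phenotype_name: str = "phenotype",
) -> GeneLevelStats:
    """Spearman rho of every gene's expression against one phenotype.

    Ties get average ranks; genes with constant expression are assigned
    rho = 0 and flagged.  Uses the normalized view when present (the choice
    is immaterial: Spearman is rank-invariant to per-sample monotone
    scaling).
    """
    values = expr.normalized if expr.normalized is not None else expr.counts
    x = values.to_numpy(dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if y.shape[0] != x.shape[1]:
        raise ValueError(
            f"phenotype has {y.shape[0]} samples, expression has {x.shape[1]}"
        )
    if np.all(y == y[0]):
        raise ValueError("phenotype is constant; Spearman undefined")
    if x.shape[1] < 4:
        raise ValueError("need >= 4 paired samples")

    rx = stats.rankdata(x, axis=1, method="average")
    ry = stats.rankdata(y, method="average")
    rx_c = rx - rx.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum(axis=1) * (ry_c**2).sum())
    constant = denom == 0
    denom[constant] = 1.0
    rho = (rx_c @ ry_c) / denom
    rho[constant] = 0.0
    series = pd.Series(rho, index=values.index, name="rho")
    return GeneLevelStats(
        phenotype_name=phenotype_name,
        rho=series,
        constant_genes=values.index[constant].tolist(),
    )


# ---------------------------------------------------------------------------
# running-sum enrichment score


def _es_from_positions(
    positions: np.ndarray, weights_sorted: np.ndarray, n_total: int
) -> np.ndarray:
    """Enrichment scores for one or many member-position vectors.

    ``positions``: (..., k) 0-based positions of set members in the
    descending-|rho| ranking, sorted ascending along the last axis.
    ``weights_sorted``: (n_total,) the per-gene hit weights
    |rho|^p / (their sum is computed per set).  The running sum adds the
    member's normalized weight at a hit and subtracts 1/(n_total - k) at
    each miss; the extreme deviations occur at hit points, so only those
    need evaluation.
    """
    positions = np.asarray(positions)
    k = positions.shape[-1]
    if k >= n_total:
        # degenerate: set == universe, running sum returns to 0 at the end;
        # maximum is reached just before the first miss (there is none);
        # define es as the max of the all-hit walk, i.e. 1.0
        return np.ones(positions.shape[:-1])
    miss = 1.0 / (n_total - k)
    w = weights_sorted[positions]
    w_sum = w.sum(axis=-1, keepdims=True)
    zero_sets = (w_sum == 0).squeeze(-1)
    w_sum = np.where(w_sum == 0, 1.0, w_sum)
    w_norm = w / w_sum
    cum_hits = np.cumsum(w_norm, axis=-1)
    idx = np.arange(k)
    # misses before (and not including) hit i: positions_i - i
    misses_before = positions - idx
    after_hit = cum_hits - miss * misses_before            # just after hit i
    before_hit = after_hit - w_norm                        # just before hit i
    top = after_hit.max(axis=-1)
    bottom = np.minimum(before_hit.min(axis=-1), 0.0)
    es = np.where(top >= -bottom, top, bottom)
    if np.ndim(es) == 0:
        es = np.float64(es)
    return np.where(zero_sets, 0.0, es)


def enrichment_score(
    stats_: GeneLevelStats, set_members: list[str], weight_p: float = 1.0
) -> float:
    """Signed maximum deviation of the weighted KS running sum.

    Walk the descending-rho ranking; at member genes add
    |rho|^p / sum_set |rho|^p, at non-members subtract 1/(N - k).  The score
    is the running sum's extreme of largest magnitude, in [-1, 1].
    """
    ranking = stats_.ranking
    ranking_set = set(ranking)
    in_universe = list(dict.fromkeys(g for g in set_members if g in ranking_set))
    if not in_universe:
        raise ValueError("gene set has no members in the analyzed universe")
    n = len(ranking)
    pos_map = pd.Series(np.arange(n), index=ranking)
    positions = np.sort(pos_map[list(in_universe)].to_numpy())
    weights_sorted = np.abs(stats_.rho[ranking].to_numpy()) ** weight_p
    if weights_sorted[positions].sum() == 0:
        warnings.warn("all member |rho| weights are zero; es set to 0",
                      stacklevel=2)
        return 0.0
    return float(_es_from_positions(positions, weights_sorted, n))


def random_geneset_null(
    stats_: GeneLevelStats,
    set_size: int,
    n_null: int,
    rng: np.random.Generator | int,
    weight_p: float = 1.0,
) -> np.ndarray:
    """Null enrichment scores from random gene sets of matched size.

    Each replicate draws ``set_size`` genes uniformly without replacement
    from the analyzed universe and computes the running-sum score.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.Generator(np.random.PCG64(int(rng)))
    n = len(stats_.rho)
    if set_size > n:
        raise ValueError(f"set_size {set_size} exceeds universe size {n}")
    if n_null < 100:
        warnings.warn(f"n_null={n_null} < 100 gives unstable p-values",
                      stacklevel=2)
    weights_sorted = np.abs(stats_.rho[stats_.ranking].to_numpy()) ** weight_p
    if set_size == n:
        return np.full(n_null, _es_from_positions(
            np.arange(n), weights_sorted, n))
    # Draw random GENES (in fixed universe order), then map to ranking
    # positions.  Sampling genes rather than positions makes the null
    # equivariant under phenotype negation: with the same seed, negating the
    # phenotype reverses the ranking and flips the sign of every null score,
    # so p_pos and p_neg swap exactly.
    order = np.argsort(-stats_.rho.to_numpy(), kind="stable")
    pos_of_gene = np.empty(n, dtype=np.intp)
    pos_of_gene[order] = np.arange(n)
    keys = rng.random((n_null, n))
    sampled_genes = np.argpartition(keys, set_size, axis=1)[:, :set_size]
    positions = np.sort(pos_of_gene[sampled_genes], axis=1)
    return _es_from_positions(positions, weights_sorted, n)


def directional_pvalues(
    es_observed: float, null_es: np.ndarray
) -> tuple[float, float]:
    """Add-one empirical p-values for positive and negative association."""
    null_es = np.asarray(null_es)
    b = len(null_es)
    p_pos = (np.sum(null_es >= es_observed) + 1.0) / (b + 1.0)
    p_neg = (np.sum(null_es <= es_observed) + 1.0) / (b + 1.0)
    return float(p_pos), float(p_neg)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# the full phenotype x gene-set sweep


def _pair_rng(master_seed: int, phen_idx: int, set_idx: int) -> np.random.Generator:
    """Deterministic substream per (phenotype, set), independent of loop order."""
    ss = np.random.SeedSequence([int(master_seed), int(phen_idx), int(set_idx)])
    return np.random.Generator(np.random.PCG64(ss))


def run_gsea(
    expr: ExpressionMatrix,
    feature_table: pd.DataFrame,
    genesets: GeneSetCollection,
    params: GseaParams = GseaParams(),
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Directional enrichment of every gene set against every phenotype.

    ``feature_table`` is cases x phenotypes with rows aligned to the
    expression samples (matched by id when both carry ids).  Returns a
    long-format table with one row per (phenotype, set): es, directional
    nominal and BH-adjusted p-values, the called direction, and set size.
    """
    sample_ids = expr.sample_ids
    ft = feature_table
    if ft.index.is_unique and set(map(str, ft.index)) >= set(map(str, sample_ids)):
        ft = ft.loc[[type(ft.index[0])(s) for s in sample_ids]]
    elif len(ft) != expr.n_samples:
        missing = sorted(set(map(str, sample_ids)) - set(map(str, ft.index)))
        raise ValueError(f"feature table does not match samples; unmatched: "
                         f"{missing[:10]}")

    universe = expr.gene_ids
    collection, dropped = genesets.restrict(universe, params.min_set_size)
    if dropped:
        warnings.warn(
            f"{len(dropped)} gene sets below min_set_size "
            f"{params.min_set_size} after universe restriction: skipped",
            stacklevel=2,
        )
    set_ids = list(collection.sets)

    if params.null_mode == "sample":
        return _run_gsea_sample_null(expr, ft, collection, params, rng_seed)

    rows = []
    for phen_idx, phen in enumerate(ft.columns):
        stats_ = gene_level_statistics(expr, ft[phen].to_numpy(), phen)
        weights_sorted = np.abs(stats_.rho[stats_.ranking].to_numpy()) ** params.weight_p
        pos_map = pd.Series(np.arange(len(universe)), index=stats_.ranking)
        for set_idx, sid in enumerate(set_ids):
            members = collection.sets[sid]
            positions = np.sort(pos_map[members].to_numpy())
            es = float(_es_from_positions(positions, weights_sorted,
                                          len(universe)))
            rng = _pair_rng(rng_seed, phen_idx, set_idx)
            null = random_geneset_null(stats_, len(members), params.n_null,
                                       rng, params.weight_p)
            p_pos, p_neg = directional_pvalues(es, null)
            rows.append({
                "phenotype": phen, "set_id": sid,
                "category": (collection.categories or {}).get(sid),
                "es": es, "p_pos": p_pos, "p_neg": p_neg,
                "n_genes_in_set_analyzed": len(members),
            })
    results = pd.DataFrame(rows)
    return _adjust_and_call(results, params)


def _adjust_and_call(results: pd.DataFrame, params: GseaParams) -> pd.DataFrame:
    """BH adjustment per phenotype (per direction unless pooled) + calls."""
    results = results.copy()
    q_pos = np.empty(len(results))
    q_neg = np.empty(len(results))
    for _, idx in results.groupby("phenotype").groups.items():
        idx = np.asarray(idx)
        if params.bh_pool_directions:
            pooled = np.concatenate([results.loc[idx, "p_pos"],
                                     results.loc[idx, "p_neg"]])
            q = bh_adjust(pooled)
            q_pos[idx] = q[: len(idx)]
            q_neg[idx] = q[len(idx):]
        else:
            q_pos[idx] = bh_adjust(results.loc[idx, "p_pos"].to_numpy())
            q_neg[idx] = bh_adjust(results.loc[idx, "p_neg"].to_numpy())
    results["q_pos"] = q_pos
    results["q_neg"] = q_neg
    alpha = params.alpha
    direction = np.where(
        np.minimum(q_pos, q_neg) > alpha,
        "none",
        np.where(q_pos <= q_neg, "+", "-"),
    )
    # pathological double-significance: sign of es decides
    both = (q_pos <= alpha) & (q_neg <= alpha)
    if both.any():
        warnings.warn(f"{int(both.sum())} tests significant in both "
                      "directions; es sign decides", stacklevel=2)
        direction[both] = np.where(results.loc[both, "es"] >= 0, "+", "-")
    results["direction"] = direction
    results["alpha"] = alpha
    return results


def _run_gsea_sample_null(expr, ft, collection, params, rng_seed):
    """Optional sample-permutation null: permute the phenotype across
    samples, recompute gene stats and es per replicate."""
    universe = expr.gene_ids
    set_ids = list(collection.sets)
    rows = []
    for phen_idx, phen in enumerate(ft.columns):
        y = ft[phen].to_numpy()
        stats_ = gene_level_statistics(expr, y, phen)
        weights = np.abs(stats_.rho[stats_.ranking].to_numpy()) ** params.weight_p
        pos_map = pd.Series(np.arange(len(universe)), index=stats_.ranking)
        rng = _pair_rng(rng_seed, phen_idx, 0)
        null_es = {sid: np.empty(params.n_null) for sid in set_ids}
        for b in range(params.n_null):
            perm = rng.permutation(len(y))
            stats_b = gene_level_statistics(expr, y[perm], phen)
            w_b = np.abs(stats_b.rho[stats_b.ranking].to_numpy()) ** params.weight_p
            pos_b = pd.Series(np.arange(len(universe)), index=stats_b.ranking)
            for sid in set_ids:
                members = collection.sets[sid]
                positions = np.sort(pos_b[members].to_numpy())
                null_es[sid][b] = _es_from_positions(positions, w_b,
                                                     len(universe))
        for sid in set_ids:
            members = collection.sets[sid]
            positions = np.sort(pos_map[members].to_numpy())
            es = float(_es_from_positions(positions, weights, len(universe)))
            p_pos, p_neg = directional_pvalues(es, null_es[sid])
            rows.append({
                "phenotype": phen, "set_id": sid,
                "category": (collection.categories or {}).get(sid),
                "es": es, "p_pos": p_pos, "p_neg": p_neg,
                "n_genes_in_set_analyzed": len(members),
            })
    return _adjust_and_call(pd.DataFrame(rows), params)
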