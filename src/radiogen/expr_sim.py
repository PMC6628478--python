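"""Simulated RNA-seq count matrices with planted phenotype associations.

Counts are negative-binomial with gene-specific log-normal means.  Genes in
a planted set are coupled to a chosen radiomic phenotype through a Gaussian
copula acting on latent normals before the NB quantile mapping, so the
expected sample Spearman correlation matches a requested effect size while
the marginal count distribution is preserved.  Background genes are
independent of every phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .genesets import GeneSetCollection


@dataclass(frozen=True)
class PlantedAssociation:
    gene_set_id: str
    phenotype_name: str
    target_spearman_rho: float
    direction: str = "+"  # "+" or "-"

    def __post_init__(self) -> None:
        if not 0 <= abs(self.target_spearman_rho) <= 1:
            raise ValueError("|target_spearman_rho| must be <= 1")
        if self.direction not in ("+", "-"):
            raise ValueError("direction must be '+' or '-'")

    @property
    def signed_rho(self) -> float:
        rho = abs(self.target_spearman_rho)
        return rho if self.direction == "+" else -rho


@dataclass(frozen=True)
class ExpressionSimSpec:
    n_samples: int = 47
    n_genes: int = 5000
    library_size_mean: float = 2.0e6
    dispersion: float = 0.3
    #: SD of log gene mean; wide enough that a realistic minority of genes
    #: sits below typical expression-filter thresholds
    mean_log_sigma: float = 1.5
    planted: tuple[PlantedAssociation, ...] = ()
    rng_seed: int = 0


def gene_universe(n_genes: int) -> list[str]:
    """The gene identifiers the simulator emits, in order."""
    return [f"gene{i + 1:05d}" for i in range(n_genes)]


def _latent_to_spearman_loading(rho_s: float) -> float:
    """Latent normal correlation giving Spearman ``rho_s`` after any
    monotone marginal transform: r = 2 sin(pi * rho_s / 6)."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def generate_expression(
    spec: ExpressionSimSpec,
    genesets: GeneSetCollection,
    phenotypes: pd.DataFrame,
) -> ExpressionMatrix:
    """Simulate a genes x samples NB count matrix with planted signal.

    ``phenotypes`` is a cases x features table whose rows define the samples
    (one column per radiomic phenotype).  Every planted gene set id must
    exist in ``genesets`` and every planted phenotype in ``phenotypes``.
    Deterministic given ``spec.rng_seed``.
    """
    n = spec.n_samples
    if len(phenotypes) != n:
        raise ValueError(
            f"phenotype table has {len(phenotypes)} rows, spec expects {n}"
        )
    for pa in spec.planted:
        if pa.gene_set_id not in genesets.sets:
            raise ValueError(f"unknown gene set id {pa.gene_set_id!r}")
        if pa.phenotype_name not in phenotypes.columns:
            raise ValueError(f"unknown phenotype {pa.phenotype_name!r}")

    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([spec.rng_seed]))
    )
    gene_ids = gene_universe(spec.n_genes)
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    # gene-specific NB means: log-normal around the per-gene share of reads
    base_mean = spec.library_size_mean / spec.n_genes
    mu = rng.lognormal(mean=np.log(base_mean), sigma=spec.mean_log_sigma,
                       size=spec.n_genes)
    r = 1.0 / spec.dispersion  # NB size parameter
    p_nb = r / (r + mu)  # per-gene success probability

    # latent normals: independent by default
    z = rng.standard_normal((spec.n_genes, n))

    # normal scores of each planted phenotype (rank -> normal quantile)
    for pa in spec.planted:
        pheno = phenotypes[pa.phenotype_name].to_numpy(dtype=float)
        ranks = stats.rankdata(pheno, method="average")
        u_pheno = stats.norm.ppf((ranks - 0.5) / n)
        u_pheno = (u_pheno - u_pheno.mean()) / u_pheno.std()
        a = _latent_to_spearman_loading(pa.signed_rho)
        members = genesets.sets[pa.gene_set_id]
        rows = [gene_index[g] for g in members if g in gene_index]
        if not rows:
            raise ValueError(
                f"gene set {pa.gene_set_id!r} has no members in the simulated "
                "universe"
            )
        z[rows] = a * u_pheno[None, :] + np.sqrt(1 - a**2) * z[rows]

    # NB quantile mapping of the latent normals preserves the marginal
    u = stats.norm.cdf(z)
    counts = stats.nbinom.ppf(u, r, p_nb[:, None]).astype(np.int64)

    sample_ids = (
        phenotypes.index.astype(str).tolist()
        if phenotypes.index.is_unique
        else [f"case{i + 1:03d}" for i in range(n)]
    )
    df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(counts=df)
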