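# radiogen

A radiogenomics analysis pipeline: from dynamic contrast-enhanced (DCE)
breast MRI to gene-expression pathway associations, exercised end to end on
synthetic phantoms and simulated RNA-seq counts with planted signal.

The pipeline mirrors the imaging-genomics workflow used to relate breast
tumour MRI phenotypes to transcriptional pathway activity:

1. **Phantoms** — DCE series (1 pre- + 5 post-contrast frames, 75 s apart,
   anisotropic voxels) containing a spiculated-sphere lesion with a
   persistent, plateau or washout enhancement curve and known ground truth.
2. **Segmentation** — from a single seed point, fuzzy c-means clustering of
   relative enhancement delineates the lesion from parenchyma.
3. **Radiomics** — 38 phenotypes in six categories: size (S1–S4), shape
   (G1–G3), morphology (M1–M3), enhancement texture (T1–T14, Haralick GLCM
   statistics), kinetic curve assessment (K1–K10) and enhancement-variance
   kinetics (V1–V4); cohort tables are z-scored to zero mean, unit variance.
4. **Expression** — simulated negative-binomial count matrices in which
   chosen gene sets are coupled to chosen phenotypes at a target Spearman
   correlation through a Gaussian copula; gene filtering (zero in ≥ 10
   samples, or mean < 8) and CPM normalization.
5. **Enrichment** — for every (phenotype, gene set) pair: per-gene Spearman
   statistics, a weighted running-sum enrichment score, nominal p-values
   from 10,000 random gene sets tested separately for positive and negative
   association, and Benjamini–Hochberg FDR per phenotype (significant at
   adjusted p ≤ 0.05).
6. **Association** — signed significance matrix (+1/−1/0), disease-pathway
   exclusion, per-category association counts, and hierarchically clustered
   heatmap orderings.

The statistic at the core is the weighted Kolmogorov–Smirnov running sum:
genes ranked by descending Spearman ρ against a phenotype; at set members
the sum rises by |ρ|^p / Σ_set |ρ|^p, elsewhere it falls by 1/(N − k); the
enrichment score is the signed extreme, and its null distribution comes
from random gene sets of matched size.  See `docs/methods.md` for every
formula and numerical choice.

## Worked example

The `analysis/` scripts run the whole study on a synthetic 47-case cohort,
planting a positive proliferation–volume coupling and a negative
apoptosis–volume coupling (Spearman 0.6, 40-gene sets) among 58 background
sets:

```bash
python analysis/01_simulate_cohort.py --seed 7
python analysis/02_simulate_expression.py --seed 7
python analysis/03_run_enrichment.py --seed 7
python analysis/04_summarize_associations.py
```

prints (abridged):

```
extracted 38 features for 47 cases
segmentation Dice: mean 0.998, min 0.993
2280 phenotype-set tests (38 phenotypes x 60 sets)
66 significant directional associations at adjusted p <= 0.05
  proliferation vs S1_volume: es +0.992, direction +, q_pos 0.0300, q_neg 1.0000
  apoptosis vs S1_volume: es -0.978, direction -, q_pos 1.0000, q_neg 0.0300
excluded 10 pathways in categories ['disease_specific']; 50 remain
mean associations per pathway by category:
  cell_growth: 22.0 over 3 pathways
```

Reading: segmentation recovers the known lesion masks almost perfectly
(Dice ≈ 1); the planted proliferation set is called significantly
*positively* associated with lesion volume and the apoptosis set
*negatively* (enrichment scores ±0.98, adjusted p = 0.03), with the
remaining significant calls concentrated in the size-correlated features of
the same planted sets; background sets stay at chance.  Tables land in
`results/` (`features.csv`, `enrichment.tsv`, `association_matrix.tsv`,
`category_summary.tsv`, `heatmap.png`).

## Layout

```
src/radiogen/    library: phantom, segmentation, radiomics, texture,
                 expression, expr_sim, genesets, enrichment, association,
                 pipeline
analysis/        numbered driver scripts (the study, step by step)
scripts/         acceptance.py
tests/           pytest suite (unit, property and acceptance tests)
docs/methods.md  models, formulas, parameter defaults, limitations
```
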