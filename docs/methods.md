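# Methods

This note documents the models, formulas and numerical choices behind
`radiogen`: a pipeline that segments breast lesions from dynamic
contrast-enhanced (DCE) MRI, extracts 38 radiomic phenotypes in six
categories, and associates them with gene-expression pathways through a
directional, permutation-based gene set enrichment procedure.  The package
runs entirely on synthetic phantoms and simulated count matrices with
planted signal, so every stage is testable without clinical data.

## Phantom model

A phantom is a 4D series: one pre-contrast frame at t = 0 and five
post-contrast frames at 75 s spacing (both configurable), on a
96 × 96 × 64 grid with anisotropic (0.76, 0.76, 1.6) mm voxels, echoing a
clinical breast protocol at desk scale.  The lesion is a spiculated sphere:
in spherical coordinates the surface radius is

    r(θ, φ) = R · (1 + a · P(θ, φ)),

where R is the nominal radius (mm), a ≥ 0 the spiculation amplitude, and P
a fixed band-limited perturbation (a sum of six cosine waves with random
orientation, spatial frequency 2–5 cycles over the sphere, normalized to
unit peak).  P is drawn from a per-phantom substream, so shape is
reproducible and surface area — hence irregularity — grows monotonically
with a.

Lesion signal follows

    S(x, t) = B · (1 + h(x) · E_peak · c(t)) + ε(x, t),

with baseline B, per-voxel multiplicative heterogeneity
h(x) ~ N(1, σ_h) truncated at 0.1, additive acquisition noise
ε ~ N(0, σ_n B), and a normalized kinetic curve c(t) with peak 1:

* **persistent** — saturating exponential rise, exactly 1 at the last frame;
* **plateau** — linear rise to 1 at the second post-contrast frame, then flat;
* **washout** — same rise, then linear decay losing 30% of peak by the last
  frame.

These are minimal parameterizations of the three canonical breast DCE curve
types.  No pharmacokinetic (Tofts-type) modeling or MRI physics is
simulated.  A consequence of multiplicative heterogeneity is that the
spatial variance of enhancement is proportional to the squared mean curve,
which pins the variance-kinetics peak time to the enhancement peak time —
a property the tests exploit.

The default synthetic cohort (47 cases, matching the emulated study size)
draws radii uniformly from 5–12 mm, spiculation 0–0.3, peak enhancement
0.6–1.6, heterogeneity SD 0.05–0.25, mixed kinetic types, and 5% noise.

## Segmentation

The only operator input is a seed voxel.  Within a cubic region of interest
(half-width 20 mm per axis) the per-voxel feature is the **mean relative
enhancement over the post-contrast frames**,

    E(x) = mean_t (S_t(x) − S_0(x)) / (S_0(x) + ε₀),     ε₀ = 10⁻⁶ · max S.

Averaging across frames rather than using a single post-contrast frame
suppresses acquisition noise; with a single frame, small lesions whose
first-frame enhancement is only ~0.3 of baseline segmented poorly (Dice
< 0.2), while the averaged feature restores Dice > 0.99 on the same cases.
Enhancement is relative, so the mask is invariant to global intensity
scaling.

Fuzzy c-means (m = 2, two clusters, tolerance 1e-5) is run on the ROI
values with **deterministic initialization**: centres spread evenly over
[min, max] of the ROI values.  Quantile-based initialization was rejected
because the lesion occupies only a few percent of the ROI, so any interior
quantile pair starts both centres inside the background mode and the
iteration converges to a split of the background.  Voxels with membership
≥ 0.5 in the highest-centre cluster are candidates; the returned mask is
the 26-connected candidate component containing the seed (or the component
whose centroid is nearest the seed, if the seed voxel itself was excluded;
failure if that distance exceeds the ROI half-width), hole-filled in 3D and
slice-wise.  An empty candidate set raises an explicit "no lesion found"
error.

## The 38 radiomic phenotypes

Exactly 38 features in six categories (4/3/3/14/10/4).  The formulas below
are the package's frozen reference definitions.

**Size (S1–S4).** S1 = voxel count × voxel volume (mm³);
S2 = (6·S1/π)^⅓ (effective diameter, mm); S3 = isosurface area at level 0.5
of the lightly smoothed binary mask via marching cubes (mm²);
S4 = greatest pairwise distance between surface voxel centres (mm, via the
convex hull).  The pre-smoothing Gaussian (σ = 0.6 of the finest voxel
pitch) suppresses the staircase bias of a raw binary isosurface: unsmoothed,
a digital sphere reads ~9–12% high in area; smoothed, +2–3%, and the small
positive residual keeps sphericity of a digital sphere just below its
theoretical ceiling.

**Shape (G1–G3).** Sphericity G1 = π^⅓ (6·S1)^⅔ / S3 (capped at 1),
irregularity G2 = 1 − G1, surface-to-volume ratio G3 = S3/S1.

**Morphology (M1–M3).** On the first-post-contrast enhancement map:
M1 = mean over interior boundary voxels of |n̂ · ∇E| where n̂ is the outward
normal (negative gradient of the Gaussian-smoothed mask, σ = 1.5 mm);
M2 = variance of those values; M3 = variance of the normalized 20-bin
histogram of radial gradient projections r̂ · ∇E over the lesion.  Boundary
voxels on the volume border lack outward neighbours and are skipped with a
warning.

**Enhancement texture (T1–T14).** Lesion intensities at the first
post-contrast frame are min–max quantized to 32 gray levels; a single
symmetric co-occurrence matrix is pooled over the 13 unique 3D offsets at
distance 1 (both voxels inside the mask) — pooling, rather than per-offset
averaging, keeps the matrix well-populated for small lesions.  The 14
classical Haralick statistics follow, in order: energy, contrast,
correlation, homogeneity (inverse difference moment), entropy, sum average,
sum variance (centred on the sum average), sum entropy, difference
variance, difference entropy, information measures of correlation 1 and 2,
maximal correlation coefficient (square root of the second-largest
eigenvalue of the Q matrix), and variance (centred on the marginal mean).
Logs are base 2.  A single-level (constant) lesion yields energy 1,
entropy 0, contrast 0; correlation-type features are reported missing with
a warning.

**Kinetics (K1–K10).** The characteristic curve E_t is the mean enhancement
of the most-enhancing subregion (top decile of first-post-contrast
enhancement within the lesion; decile configurable), evaluated at each
post-contrast frame.  K1 = max E_t; K2 = time of the (first) maximum;
K3 = K1/K2 (uptake rate); K4 = (K1 − E_last) / ((t_last − K2) · K1) when
the peak precedes the last frame, else 0 (washout rate);
K5 = (E_last − K1)/K1 clipped to [−1, 1] (curve shape index);
K6 = E at the first post-contrast frame; K7 = K6 / E_last (signal
enhancement ratio; missing if E_last = 0); K8 = subregion volume (mm³);
K9 = Σ (ΔE/Δt)² Δt over consecutive post-contrast intervals;
K10 = K9 / Σ E_t² Δt.

**Enhancement-variance kinetics (V1–V4).** var_t = spatial variance of the
enhancement map over the lesion per post-contrast frame; V1 = max var_t;
V2 = its (first) time; V3 = V1/V2; V4 = analogous post-peak decrease rate.

Cohort feature tables are z-scored per column with sample SD (n − 1);
zero-variance columns are set to 0 and flagged.  Missing values stay NaN
and propagate to pairwise-complete rank statistics downstream.

## Expression simulation and filtering

Counts are negative binomial (dispersion 0.3) with gene means drawn
log-normal around library_size / n_genes (log-SD 1.5).  Planted
associations use a Gaussian copula: the target phenotype's sample ranks are
mapped to normal scores u; for each gene in a planted set the latent normal
is z = a·u + √(1 − a²)·ε with a = 2 sin(π ρ_s / 6), the latent correlation
whose induced Spearman correlation is ρ_s under any monotone marginal
transform; counts are the NB quantiles of Φ(z).  This preserves integer NB
marginals exactly while controlling the expected sample Spearman
correlation (recovered within ±0.1 at n = 200 in the calibration test).

The gene filter drops a gene if its count is zero in ≥ 10 samples or its
mean count over all samples is < 8 (both thresholds configurable; the
boundaries are inclusive/strict exactly as stated).  Normalization is
counts-per-million.  **Caveat:** CPM rescales each sample by its own
library size, so a gene's across-sample ranks — and hence gene-phenotype
Spearman correlations — are only invariant to this choice when library
sizes are equal; within-sample ranks are always preserved.  The simulator's
log-normal means under-represent the heavy low-expression tail of real
RNA-seq, so the filter removes far fewer genes here (<1%) than it would on
real data (~40%).

## Enrichment

For one phenotype, each gene's statistic is the Spearman rank correlation
(average ranks for ties) between its normalized expression and the
phenotype across samples; constant genes get ρ = 0 and a flag.  Genes are
ranked by descending ρ and a weighted Kolmogorov–Smirnov running sum scores
a set: at member genes add |ρ|^p / Σ_set |ρ|^p (p = 1 by default), at
non-members subtract 1/(N − k); the enrichment score (ES) is the extreme of
largest magnitude, in [−1, 1].  Only hit points need evaluation, which
makes the null computation vectorizable over replicates.

The null draws B = 10,000 (configurable) random gene sets of matched size
uniformly from the analyzed universe.  This gene-sampling null treats genes
as exchangeable and is known to be anti-conservative when set members are
co-expressed; it is retained as the procedure's defining choice, and a
sample-permutation null is available via `null_mode="sample"`.  The null
draws *genes* (in fixed universe order) rather than ranking positions, so
negating the phenotype reverses the ranking, flips the sign of every null
score, and swaps p_pos and p_neg exactly under the same seed.

Directional p-values use the add-one convention:
p_pos = (#{null ≥ ES} + 1)/(B + 1), p_neg analogous with ≤, avoiding zero
p-values.  Benjamini–Hochberg FDR is controlled per phenotype across all
sets, separately per direction (pooled mode available); an association is
significant at adjusted p ≤ 0.05.  Sets with fewer than 5 members after
restriction to the filtered universe are skipped with a report.  Each
(phenotype, set) test uses a deterministic RNG substream derived from the
master seed and the pair's indices, so results do not depend on iteration
order.

Under a fully null simulation the empirical rate of nominal p ≤ 0.05 is
(B·0.05 rounded)/（B + 1) ≈ 0.05 by construction of the add-one estimator;
the calibration test checks the measured rate lies in (0.03, 0.07) over
2000 tests, and the tiny-universe test checks agreement with exhaustive
enumeration of all subsets.

## Association summaries

The significance matrix has entries +1/−1/0 per (set, phenotype): nonzero
iff min(q_pos, q_neg) ≤ α, signed by the smaller q; in the pathological
case where both directions pass, the ES sign decides and a warning is
logged.  Disease-specific pathways can be excluded by category before
summarizing.  Category summaries count, per category, the pathways with at
least one association and the mean number of associated features per such
pathway (averaging over *active* pathways; callers wanting the
all-members denominator can compute it from the retained matrix).  Heatmap
orderings come from average-linkage hierarchical clustering on Euclidean
distances of the signed rows/columns; SciPy's tie-breaking by observation
index makes the leaf order deterministic.  Rendering is a thin optional
matplotlib layer; the orderings and matrices are the tested artifacts.

## Problem sizes and limitations

The analysis scripts and the acceptance script use desk-scale sizes chosen
as the package's defaults: 47-case cohorts on the 96 × 96 × 64 grid, 2000
simulated genes, collections of 30–60 sets, and null sizes of 1000–2000
for the sweeps (the single-test default remains 10,000).  Feature
extraction takes well under a second per phantom; a full cohort sweep runs
in a few minutes on one core.

What passing tests do and do not show: the phantoms are motion-free,
bias-field-free, single-lesion images with Gaussian noise and exactly known
ground truth, and the simulated counts have independent background genes —
real DCE-MRI and RNA-seq violate all of these (registration error, partial
volume, co-expression, batch effects).  The pipeline's statistical
machinery is validated here against oracles and planted signal; its
clinical feature definitions are frozen reference formulas, not a claim of
equivalence to any particular proprietary workstation.
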