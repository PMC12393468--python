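# Methods

This note documents the models, parameter choices and numerical decisions
behind `spotcell`, and what the synthetic study does and does not establish
about real tissue.

## Synthetic tissue generator

The generator is the package's study design: it fixes the conditions under
which every downstream claim is tested.

**Geometry.** Each sample is a square lattice (default 40×40 spots at
100 px pitch; 1 px ≈ 1 µm) with ten subregions: six soma layers (SUB,
CA1–CA4, DG) interleaved with three fiber layers (SO, SR, ML) as horizontal
bands, plus vascular foci (default 3 vessels of 160 px radius, centers
rejection-sampled at least two radii apart).  Spots inside a vessel radius
are relabeled VAS.  A square lattice with a symmetrized 6-nearest-neighbor
graph stands in for Visium's hexagonal packing; the clustering contract
(expression + coordinates → smooth domains) is unaffected by lattice type.

**Expression.** A shared log-normal baseline (σ = 0.6) over G = 300 genes
is perturbed per type: each of the 7 cell types carries 10 marker genes at
fold 8; each band domain carries one "program" gene expressed only by its
host type (Exc for soma layers; the dominant glial type for fiber layers)
and amplified 30× inside its domain.  Program genes for fiber layers are a
generator design choice beyond the soma-layer programs: without them the
three fiber bands would share one composition prior and be mutually
unidentifiable, and domain annotation would have no marker set for them
(VAS uses the VC marker block).  Planted effects are multiplicative on the
type profile before renormalization, so library sizes stay
multinomial-exact: two group effects (AD/CA1/Exc and PART/CA2/Exc, +2 log2)
and one vessel gradient (AD-only, Ast, level multipliers 4 / 2.5 / 1.5 / 1).
Effect sizes are chosen for testability, not biological fidelity.

**Sampling.** Spot compositions are Dirichlet with concentration 10 around
class means (soma layers Exc-rich at 0.55; fiber layers Ast/Oli-rich; VAS
VC-rich at 0.50); counts are Multinomial(N_s, θ_s·φ') with
N_s ~ round(LogNormal(log 4000, 0.35)), matching the order of magnitude of
counts per spot in FFPE Visium data.  Reference cells (default 200/type)
are multinomial draws from the unperturbed type profiles — deliberately
*without* domain programs or group effects, reproducing the mild
reference/tissue mismatch of a real external reference.

**What passing tests show.** Recovery at these conditions demonstrates the
estimators are correct and well-calibrated under their own model (clean
multinomial noise, no batch effects, no segmentation error, no spatial
transcript diffusion, markers that truly separate types).  Real tissue
violates all of these to some degree; the synthetic results bound what the
method can do, not what it will do on any given dataset.

**Noisy-band fixture.** Band-recovery-under-noise uses the default config
at a median library of ~1,200 counts (`noisy_band_config`).  A pilot scan
over library size located this as the regime where expression alone leaves
band assignment ambiguous (ARI ≈ 0.7 unsmoothed) while spatial smoothing
restores it — i.e. where the smoothing term has something to do.

## Spatial domains

Counts are scaled to 10,000 per spot, log1p-transformed, reduced to the top
2,000 genes by dispersion (capped at G) and projected to d = 20 principal
components via full SVD with a fixed sign convention (largest-magnitude
loading positive), making the embedding bit-reproducible.  Multi-sample
runs embed jointly after per-spot normalization with no batch correction
(the generator plants none); the neighbor graph never crosses samples.

Clustering is ICM on the joint objective

    J = Σ_s [ −‖e_s − μ_{c_s}‖²/(2σ²) − (d/2)·log σ² ] + β·E_same

where `E_same` counts equal-label edges of the symmetrized m-NN graph
(m = 6).  Labels are swept sequentially (each spot takes the label
maximizing its data score plus β times its neighbors carrying that label),
then centroids and the shared spherical variance are re-estimated.  Each of
the three update families cannot decrease J, so the objective trace is
non-decreasing sweep over sweep — the reason J includes the `log σ²` term
and counts each edge once rather than summing per-spot bonuses (which
double-counts edges and is not monotone under the same updates).  Empty
clusters are reseeded at the worst-fit spot (logged; this is the one
operation allowed to lower J).  Defaults: β = 1, max 20 sweeps.

Model selection minimizes BIC = −2 logL + (k·d + 1)·log n with the
spherical Gaussian likelihood at the converged labels; the elbow (largest
second difference) is reported alongside.  Cluster naming scores each
cluster by the mean z-scored normalized expression of each domain's
markers; ties within 1e-12 are left UNASSIGNED; several clusters may share
a domain name.

## Deconvolution

Reference profiles are type-summed counts with pseudocount ε = 0.5 applied
to the sums (not per cell), keeping φ strictly positive as EM requires.
Genes whose reference fraction exceeds 0.1 in any type are dropped
(a simple stand-in for outlier-gene filtering of dominant transcripts);
the working gene universe is the spot/reference intersection with φ rows
renormalized.

EM is initialized uniform (θ = 1/K) and stopped at max|Δθ| < 1e-6 or 500
iterations; all spots are updated in one vectorized batch, which changes
nothing statistically (per-spot problems are independent).  Uniform
initialization makes the estimator fully deterministic; possible
multimodality is covered by the grid-search oracle test, which compares EM
against a 2,001-point exhaustive search on K = 2 instances.  The NNLS
estimator (`min_{θ≥0} ‖x/Σx − φᵀθ‖₂`, renormalized) is an internal second
method for cross-estimator comparisons, not a replacement.

The split-half benchmark shuffles each type's reference cells (seeded),
halves them (first half takes the extra cell when odd), deconvolves the
tissue with both halves and correlates the vectorized per-type allocation
blocks (Pearson over all spots × genes), averaging over types then splits.
Pearson-on-allocations is the declared reading of "correlation of gene
expression levels"; Spearman per-type proportion comparisons
(`compare_proportions`) use scipy's t-approximation for the p-value, the
field default.

## Pseudo-cells

A pseudo-cell is emitted for every (spot, type) with θ ≥ 0.02; the floor
avoids near-empty cells and is surfaced in the config.  Counts are
deterministic half-up roundings of the allocated expression; the fractional
matrix is retained for statistics that do not need integers.  QC is a
single pass, cells first (default min_genes 30 here ≈ 10% of the 300-gene
universe; the equivalent threshold on a genome-wide universe is 300) then
genes detected in < 3 remaining cells.

Annotation clusters pseudo-cells by seeded k-means in the per-cell
z-scored marker-score space (one feature per reference type) and names each
cluster by its highest mean marker score.  Raw-gene PCA k-means was
evaluated first and assigns only ~0.4–0.5 of pseudo-cells to their origin
type at these conditions: pseudo-cells of low-fraction types carry ~100–400
counts, and their gene-level noise dominates Euclidean distances.  The
marker-score features aggregate exactly the evidence the annotation step
uses and restore agreement ≈ 1.0; the contract (cluster, then annotate
clusters, report a confusion matrix against allocation origin) is
unchanged.

## Statistics

Differential expression is the two-sample Mann–Whitney rank-sum test — the
test the named single-cell toolchain actually performs despite the common
"signed-rank" label — exact for small tie-free samples, otherwise the
tie-corrected normal approximation with continuity correction
(scipy.stats.mannwhitneyu).  Genes are tested on 10k-scaled log1p values;
log2 fold changes use de-logged means with ε = 1e-9; BH adjustment is
applied within each contrast and significance is p_adj < 0.05 throughout.
Domain markers maximize log2FC among significant positive rows (ties:
smaller p, then lexicographic gene id).  A gene is "uniquely up" in a group
iff significant and positive against *both* other groups, making the three
sets disjoint by construction.  Composition contrasts are Welch t-tests on
per-spot fractions within each domain, BH-adjusted jointly across all
(domain × type × contrast) rows — the same FDR family as the DGE, since no
other adjustment is specified for them.  Degenerate contrasts (zero
variance in both groups) report t = 0, p = 1, flagged.

## Communication and rings

Group profiles are symmetric 10%-trimmed means of de-logged normalized
expression (groups smaller than 1/trim fall back to the plain mean).
Inside the mass-action product, profile values are divided by 100
(percent-of-library units): typical genes then score ~0.3 and strong
domain markers ~1, so the Hill half-saturation Kh = 0.5 sits inside the
dynamic range instead of saturating on 10k-scaled values.  Receptor
activity is the geometric mean over subunits (zero if any subunit is
absent).  Inter-subregion networks weight each sender→receiver entry by
exp(−d/λ) with d the centroid distance and λ the median off-diagonal
centroid distance; cell-cell networks within a ring level use weight 1,
since spots of one level share the spatial stratum.  The optional
population factor √(p_sender·p_receiver) is off by default.

Significance: spot→label assignments are shuffled within sample (preserving
per-sample library structure), the full network is recomputed, and
p_raw = (1 + #{perm ≥ obs}) / (1 + n_perm) with Bonferroni over all entries
tested.  These p-values are valid but conservative-discrete (granularity
1/(n_perm+1)); entries computed from the same permutations are dependent,
so uniformity diagnostics pool over independent replicates.

Ring levels bin each spot by its minimum distance to any VAS spot of the
same sample: (0, 200] px level 1, (200, 400] level 2, (400, 600] level 3,
beyond 600 level 4 — the distal complement that reconciles a three-ring
definition with four reported levels — and VAS spots themselves are level
"VAS".  Using the minimum over all vessels realizes the "closest level"
tie-break exactly.  Ring DGE contrasts level 1 vs level 3 pseudo-cells of
one type via the shared rank-sum machinery.

## Pipeline

A single seed fans out to per-stage seeds (stage-name CRC mixed in, kept
below 2³¹) so stages can be rerun in isolation without seed collisions.
All report tables are written with stable sorting on key columns and 6
significant digits, making identical config + seed byte-identical; the
manifest records the config hash and SHA-256 of every output.  Default
problem sizes (six 40×40 samples, G = 300, 200 reference cells per type;
the determinism check and the CLI stage-isolation tests use a 22×14 /
120-gene reduction) were chosen as the desk-scale regime in which all
recovery targets are measurable in minutes on one CPU.

## Known limitations

- The deconvolution assumes the reference spans the tissue's cell types
  and that profiles are constant within type; collinear profiles (low
  marker fold) make θ unidentifiable, as the fold-1 warning flags.
- The EM point estimate carries no posterior uncertainty; robustness is
  quantified empirically by the split-half benchmark instead.
- The ICM clustering optimizes a local objective; with heavy noise and
  many clusters it can hit empty-cluster reseeds (logged) and local optima.
  The Potts bonus uses a fixed β rather than estimating it.
- The communication scheme is a declared functional form (trimmed means,
  geometric-mean subunits, Hill with Kh = 0.5, exponential distance decay);
  it tests the stage contract, and is not a reimplementation of any
  specific published tool's internals.
- Pseudo-cells inherit the deconvolution's errors; they are computational
  constructs, not measured cells, and the generator does not simulate
  spatial transcript diffusion, segmentation noise or FFPE degradation.
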