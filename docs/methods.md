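# Methods

`nichecov` analyses single-cell-resolution spatial transcriptomics together
with a matched scRNA-seq reference. It answers three questions: what is each
spatial cell's type, which cell types predict each other's presence in the
local niche, and which latent gene programs covary between co-localised cell
types. A particle-based tissue simulator provides ground truth for all of
it, so the package is fully testable without external data.

## Cell type annotation by soft MNN label transfer

Both modalities are restricted to the shared gene set (exact, case-sensitive
id match, reference gene order; cells with fewer than `min_count = 5` total
transcripts are removed). Counts are variance-stabilised with analytic
negative-binomial Pearson residuals

    r_gc = (x_gc - mu_gc) / sqrt(mu_gc + mu_gc^2 / theta),
    mu_gc = depth_c * p_g,

with fixed overdispersion `theta = 100` and clipping at `sqrt(n_cells)`.
The analytic residual was chosen over a fitted regularised model because it
is deterministic, dependency-free and an adequate variance stabilisation at
the few-hundred-gene panel sizes typical of imaging-based platforms.
Normalisation is fitted independently per modality on the shared genes.

Both residual matrices are projected onto the top `n_pcs = 50` principal
components. The loadings are fitted on the *stacked* residual matrices of
both modalities and each modality's projection is standardised per column.
A shared loading basis is essential: principal components fitted
independently per modality have arbitrary order and sign, and nearest
neighbours across two unrelated bases are meaningless.

Anchors are soft mutual nearest neighbours: query cell q and reference cell
r are MNN iff r is among the K = 50 reference KNN of q and q is among the K
query KNN of r (KD-tree, Euclidean distance on standardised PCs). A query
cell whose MNN partners carry one unique reference label becomes an anchor;
a cell with partners of several labels is "confused" and resolved by
majority vote over non-confused anchors among its K query-side neighbours,
restricted to voters in the cell's own guide cluster; unresolved ties give
the sentinel label `NM`. If more than 10% of cells end up `NM` (threshold
configurable; no canonical value exists) the confused cells are re-voted
with inverse-distance weights, which cannot tie.

Guide clusters are Leiden communities (resolution 0.4, seed-controlled) on
a 15-nearest-neighbour graph of the query embedding. They serve two
purposes: pruning dispersed anchors — for each label, anchors falling in a
guide cluster that holds less than `r = 0.15` of that label's anchors are
removed — and gating the iterative annotation: a non-anchor cell accepts
the majority label of anchors among its K nearest query neighbours only if
that label's modal guide cluster equals the cell's own. The vote is
iterated three times, newly labelled cells joining the voter set; remaining
cells are `NM`.

## Niche interactions by composition classification

Niches are either direct Delaunay contacts with centroid distance at most
`max_dist = 100` length units ("radius 0", juxtacrine) or all cells within a
radius R (paracrine). `NM` cells are excluded from both the central cells
and the neighbour counts. Neighbour counts Lambda are converted to
enrichment ratios against the global type frequencies f,

    X_ij = Lambda_ij / (f_j * sum_k Lambda_ik),

so a niche whose composition matches the global frequencies scores 1
everywhere. Cells with empty neighbourhoods are dropped and reported.

An L2-penalised multinomial logistic regression (lbfgs, balanced class
weights, features z-scored) predicts the central type from X. The inverse
penalty C is selected on a 9-point logarithmic grid 1e-4..1e4 by stratified
5-fold cross-validated grid search (default accuracy scoring); the reported
coefficient matrix beta is the per-fold mean at the selected C, with the
fold standard deviation as uncertainty, and the confusion matrix is the
row-normalised mean held-out confusion. A directed interaction graph is
drawn from the row-normalised coefficients (each central type's row divided
by its maximum absolute entry) with edges where the normalised coefficient
exceeds a cutoff (0.01 by default).

Per-domain consistency uses the z-score Z_dj = (f_dj - mu_j) / sigma_j of
the type frequency within a domain against its mean and population standard
deviation across domains (zero-variance types get Z = 0), plus the
observed/expected ratio; profiles are compared to other domain partitions
via best-match Pearson correlation. Annotation quality is measured with
ARI, mean per-matched-type intersection-over-union (the "Jaccard" variant
used here), and class-frequency-weighted precision.

## Latent factors and niche covariation

Per cell type, expression on shared genes is scaled gene-wise by its
standard deviation without centring (centring would break non-negativity)
and factorised with `LF = 3` non-negative factors (3-5 is a reasonable
range; intra-type variability is limited).

*Integrative NMF* jointly factorises the reference and spatial submatrices:

    min ||E_sc - H_sc (W + V_sc)||_F^2 + lambda ||H_sc V_sc||_F^2
      + ||E_sp - H_sp (W + V_sp)||_F^2 + lambda ||H_sp V_sp||_F^2

over non-negative W (shared gene factors), H_x (cell loadings) and V_x
(modality-specific heterogeneity). The solver is block-coordinate descent
where every block — rows of H_x, columns of V_x and W — is an exact
non-negative least-squares solve, so the objective is non-increasing by
construction; W is initialised by NNDSVDa on the stacked matrices, V at
zero. Convergence: relative decrease below 1e-6 or 100 iterations. The
penalty lambda is scanned over even integers 0, 2, 4, ... and fixed when
the alignment score

    score = 1 - (x_bar - K/n) / (K - K/n)

(K = 1% of the downsampled size n, x_bar = mean same-dataset count among K
nearest neighbours in merged factor space) changes by less than 0.001
between successive values; the scan warns and stops at lambda = 40.

*Transfer NMF* is the alternative for data with segmentation spill-over:
W and H_sc are learned from the reference alone by KL-divergence NMF with
multiplicative updates and NNDSVDa initialisation (at most 1000
iterations), then W is frozen — bit-identical before and after — and the
spatial loadings follow from the Frobenius multiplicative update
H <- H * (E W^T) / (H W W^T) iterated to relative change < 1e-6. The KL
update and the fixed-basis transfer are hand-written because the contract
requires the per-iteration objective and a frozen W; the independent
scikit-learn KL-NMF serves as a cross-check in the tests, not as the
implementation. Mixing losses (KL for the reference fit, Frobenius for the
transfer) is deliberate: the Frobenius update is the standard fixed-basis
projection and is validated by the planted-loading recovery test.

Factors are ordered by increasing normalised entropy of their sum-normalised
H_sc columns, E = -sum p log2 p / log2(n_cells) (0 = one-hot, 1 = uniform;
all matrices permuted jointly so the reconstruction is unchanged).

*Covariation.* For a central type k, niche types are those whose normalised
interaction coefficient exceeds a cutoff. For each instance of k, each
niche type's factors are averaged over that instance's neighbours of the
type; instances with no retained-type neighbour are excluded, and an
instance missing one particular type is imputed at the column mean (zero
after standardisation). Response and predictors are standardised — the
coefficients are therefore on the standardised scale — and the ridge
penalty eta is selected from 2^-10 .. 2^10 (21 points; with fewer instances
than predictors the floor is raised to 1) by efficient leave-one-out
negative mean squared error. Coefficient p-values are two-tailed
t-statistics from the ridge sandwich covariance
sigma^2 (X'X + eta I)^-1 X'X (X'X + eta I)^-1 with residual degrees of
freedom n - trace(hat matrix). The normalised score S is the coefficient
divided by the regression's maximum absolute coefficient.

## Factor annotation and ligand-receptor candidates

Each full-transcriptome gene is associated with each factor by Spearman
correlation (or cosine similarity) of its expression with the H_sc column
across the type's reference cells; constant genes get 0 and are flagged.
Top gene lists break score ties lexicographically. For a covarying
(sender factor, receiver factor) pair, ligand-receptor candidates from a
3-column TSV database are retained when the ligand (receptor) has a raw
count above zero in at least `f_LR = 0.1` of sender (receiver) cells and an
absolute factor association of at least `c_LR = 0.1`; the low defaults
favour sensitivity, and all four metrics are reported so candidates can be
inspected. The 30-pair database in `data/lr_pairs_toy.tsv` is synthetic
fixture data for tests and demos, not a curated resource.

## Tissue simulator

Ground-truth tissues are 2D Langevin dynamics of n_types x cells_per_type
particles (default 6 x 200) in a periodic [-50, 50]^2 box under truncated
(rc = 5, no energy shift) Lennard-Jones pair potentials with sigma = 2 and
a per-type-pair well depth eps encoding affinity. Two benchmark scenarios
raise specific pairs: scenario 1 sets eps(T0,T2) = 3 and eps(T3,T5) = 5;
scenario 2 additionally eps(T2,T3) = 10 and eps(T1,T3) = 8. Particles start
uniformly at random with minimum separation sigma (rejection sampling;
overfull boxes raise), velocities are Maxwell-Boltzmann at T = 1, and a
BAOAB integrator with dt = 0.005 and damping time 1.0 thermostats the
system; forces use a cell-list-backed Verlet neighbour list with skin
0.5 rc, and the numba-compiled kernel keeps a full run in tens of seconds.
The default run length of 1e5 steps (500 reduced time units) was chosen at
the equilibration plateau: the mean kinetic temperature holds at T within
1% and the pairwise contact counts between the high-affinity pairs stop
drifting well before that point. The final configuration is the snapshot.

Synthetic expression on a snapshot assigns each type a gene block (default
10 of 60 genes: 5 constitutive markers with rate 5.0 against a baseline of
0.2, and 5 factor-responsive genes with loading 1.0). A cell's factor
activity is a base draw N(1, 0.3) plus, when a coupling map and gamma are
set, gamma times the mean base activity of neighbouring partner-type cells
(radius 5) plus N(0, noise_sd) — a planted cross-type covariation of known
strength. Rates exp(baseline + loading * activity) are normalised per cell,
scaled by a lognormal depth (median 1000), and counts are drawn
gamma-Poisson with dispersion theta = 10. The reference uses the same
programs with independent activities. The generator emulates marker-driven
type identity, sequencing depth variation and overdispersion; it does not
emulate segmentation errors, spill-over, spatial expression gradients
within a type, or batch effects — passing tests demonstrate correctness of
the inference machinery under the stated generative model, not robustness
to those artefacts.

## Numerical and design notes

- All randomness flows from explicit integer seeds (simulator seeds are
  split via `SeedSequence`; clustering, folds and downsampling are seeded),
  and repeated runs are bit-identical.
- Enrichment features, MNN pairs, radius graphs, ARI and domain z-scores
  are each tested against brute-force O(n^2) re-implementations.
- Delaunay neighbourhoods of simulated snapshots are computed on the plain
  coordinates; the periodic boundary is ignored at this step, which only
  affects the thin boundary layer of the box.
- Degenerate inputs: all-zero count matrices, empty gene intersections,
  zero-variance genes/factors/domains, empty niches and overfull simulation
  boxes all raise or warn explicitly rather than propagating NaNs.

## Problem sizes used in the benchmark suite

The acceptance checks simulate 5 seeds per scenario at the full 6 x 200
default, fit the classifier per seed, and take the majority partner per
rank; null calibration uses 5 equal-affinity simulations and 200
uncoupled ridge regressions of 150 instances each; parameter recovery uses
1000 planted instances. These sizes give stable majority outcomes while
keeping a complete run in the minutes range on one CPU.
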