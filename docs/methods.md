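# Methods

## The problem

FDG-PET measures regional glucose metabolism. Treating each subject's
vector of ROI-level SUVR values (standardized uptake value ratios,
normalized to cerebellar gray matter) as one draw from a multivariate
distribution, the *metabolic connectome* of a group is the conditional
dependence graph of those ROI values across subjects. Unlike fMRI
connectivity, there is no time series: one scan yields one number per
ROI, so the network is estimated *across subjects* by construction, and
group comparison requires re-estimating the network for every relabeled
or resampled subject set.

This package implements that full chain — image I/O and ROI extraction,
sparse inverse covariance estimation (SICE), binary graph metrics, the
lost/preserved/reconfigured hub taxonomy, permutation and bootstrap
inference with FDR control, and spatial Infomax ICA for DMN/SN-like
subnetworks — together with a synthetic-data module that plants known
network structure so every stage can be scored against ground truth.

## Network estimation (SICE)

The group network is the graphical-lasso estimate of the precision
matrix Θ, maximizing

    log det Θ − trace(SΘ) − λ Σ_{i≠j} |Θ_ij|,

where S is the subjects × ROI correlation matrix (columns z-scored, so
penalization is invariant to per-ROI intensity scale). Off-diagonal
zeros of Θ encode conditional independence; retained edges are weighted
by partial correlations −Θ_ij/√(Θ_ii Θ_jj). The convex solve is
delegated to scikit-learn's coordinate-descent graphical lasso (LARS
fallback at extreme penalties); every returned Θ is verified SPD by
Cholesky and its stationarity (KKT) residual is assertable.

**Density matching.** A penalty λ is not comparable between groups, so
groups are compared at matched edge *densities*: for each target density
the penalty is found by bisection (edge count is monotone non-increasing
in λ), with a tolerance floor of half an edge since counts are integers.
Metrics are computed per density across a sweep (default 0.10–0.40, step
0.02) and summarized by span-normalized trapezoidal AUC.

**Small groups.** With n subjects ≪ p ROIs the sample correlation
matrix is singular; the penalized problem is unbounded at small λ and
the solver is pathologically slow. The covariance step therefore
supports Ledoit–Wolf shrinkage toward the identity,
S′ = (1−γ)S + γI, applied automatically when n ≤ p (γ estimated by the
Ledoit–Wolf formula, capped at 0.95). With standardized S this preserves
the unit diagonal. Shrinkage is off when n > p, so large-sample
estimates are the plain penalized MLE.

**Numerical tolerances.** Final network fits use solver tolerance 1e-4
(max 200 iterations). Inside permutation and bootstrap replicates the
tolerance is loosened to 1e-3 (max 100 iterations) and the density
bisection is warm-bracketed around the observed penalty: replicate fits
only feed null/CI distributions, and spot checks show group-difference
p-values change by ≲0.005 while the replication loops run an order of
magnitude faster. Entries with |Θ_ij| ≤ 1e-8 are treated as exact zeros.

## Graph metrics

Binary undirected metrics with the standard toolbox definitions: degree;
clustering C_i = 2t_i/(k_i(k_i−1)); BFS shortest paths with unreachable
pairs reported (not imputed); global/nodal efficiency (mean inverse
distance, 1/∞ = 0); local efficiency (global efficiency of each
neighbor-induced subgraph); Newman degree assortativity over the doubled
edge list; hierarchy β as the negated log–log regression slope of C on k
over eligible nodes (k ≥ 2, C > 0); synchronizability λ₂/λ_max of the
combinatorial Laplacian (0 for disconnected graphs); and the
participation coefficient 1 − Σ_m (k_im/k_i)² over a greedy-modularity
partition. Undefined cases (regular graphs for assortativity, no degree
variation for hierarchy) propagate as NaN rather than silently becoming
0. Weighted variants are not validated and out of scope. Every metric is
checked against independent brute-force implementations on random graphs
(n ≤ 12) to 1e-10.

## Hubs and the reconfiguration taxonomy

A hub is a node whose criterion strictly exceeds mean + 1 sample SD.
Degree centrality is the default criterion; the participation
coefficient is available behind a flag (field usage conflates the two,
and the degree rule is the self-consistent reading). Comparing hub sets
between a control-like and a target group partitions nodes into lost
(control only), preserved (both), reconfigured (target only), and
non-hub; the partition and its role-swap symmetry are tested invariants.

The pipeline's default applies the rule to degree AUC over the
configured density sweep. A caveat established on planted data: at small
n, high-density graphs are substantially false edges, and integrating
them *dilutes* hub contrast — recovery of planted hubs at n = 50, p = 40
was 19/20 at the planted density but only 12/20 for AUC over 0.10–0.40.
For hub inference prefer per-density mode near the believed true
sparsity, or a narrow low-density sweep.

## Inference

**Permutation tests.** Group labels are shuffled with group sizes
preserved; the statistic — including covariance, penalty calibration,
and SICE fit for network statistics — is fully re-computed on each
split. p is the plain fraction of permuted |differences| at least as
large as observed (two-sided default; one-sided and (b+1)/(B+1) variants
available). Default 5000 permutations. An exhaustive-enumeration variant
serves as the exact oracle at small n. A multi-metric version estimates
one network per group per permutation and reads all global metrics off
it, sharing the shuffle sequence across metrics.

**Bootstrap edges.** Subjects are resampled with replacement within each
group (B = 1000 default, 95% percentile CIs); per-edge partial
correlation differences get CIs and two-sided bootstrap p-values; edges
whose CI excludes 0 are enhanced/weakened. The density-matching penalty
is calibrated once per group on the full sample and reused across
resamples (refit available). Degenerate resamples (zero-variance
columns, unbounded fits) are redrawn.

**GLM and FDR.** ROI contrasts are OLS on z-scored responses with
design [intercept, group, covariates] (age, sex); with no covariates the
group t is algebraically the pooled two-sample t. The group coefficient
on standardized y is the effect size, filtered at |β| > 0.8 (magnitude,
so both directions pass). Multiple testing uses Benjamini–Hochberg
(statsmodels), applied within each density level.

## Spatial ICA

Subjects are mixtures; voxels are samples. Model order is selected by
MDL on the PCA eigenvalue spectrum (sphericity likelihood of trailing
eigenvalues plus 0.5·k(2n−k)·log N), clamped to [1, n−1]. After PCA
whitening to rank k, Infomax unmixing runs natural-gradient ascent with
the logistic nonlinearity (implemented here directly; it is the method
under study — scikit-learn's FastICA is the independent cross-check in
tests). Learning rate 0.05, annealed by 0.9 whenever the update norm
grows by >5%; convergence when the relative update < 1e-7, max 512
iterations; non-convergence is flagged, never hidden. Components are
ordered by explained variance with each map's largest-|value| voxel made
positive, so runs are bit-reproducible under a fixed seed. Maps are
z-scored per component and thresholded at z > 1.96 (positive tail; a
two-tailed option exists for template matching). Templates are assigned
greedily by spatial correlation of |z| with the mask, without
replacement, ties to the lowest component index. ICA recovery is always
scored up to permutation and sign (Hungarian matching).

## Synthetic data: what it emulates and what it does not

The generator mirrors the study design the package targets: two groups
(6 vs 12 family members; 32 vs 33 in a replication arm), SUVR-like
positive mean level 1.2, age ~ N(50, 10), sex ~ Bernoulli(0.5), default
p = 40 ROIs for speed with 172 available.

**Planted networks.** Sparse precision matrices with hub nodes: hub
degree is 5× the scattered mean-degree scale 2m/p (comfortably above
the ≥3×-median contract), background edges uniform ±[0.1, 0.4],
hub-incident edges ±[0.25, 0.4]. Hub-edge strengths sit in the upper
range because identifiability is the point of planting: a 0.1 precision
entry is statistically invisible at n ≈ 50, and a "planted hub" whose
edges cannot be detected at study-scale n cannot score anything.
Positive-definiteness is enforced by uniform diagonal inflation until
the smallest eigenvalue reaches 0.1 — chosen over nearest-SPD projection
because it preserves the planted support exactly. Alternating edge signs
keep the inflation mild.

**Group pairs.** The target precision derives from the control one by
pruning a planted lost hub to a floor degree (its kept edges re-drawn at
background-weak strength — strong floor edges leak partial correlation
through 2-step paths and spuriously re-hub the node in finite-sample
estimates) and adding hub-strength edges to planted reconfigured nodes,
which are chosen among ≤median-degree non-hubs so the plant is
unambiguous. The complete edit log and truth sets are returned.

**ICA volumes.** Subject volumes are linear mixtures of compact
Gaussian blobs (spatially sparse, hence super-Gaussian — the regime
Infomax assumes) plus iid Gaussian noise, with a toy label atlas over
the blob cores.

What the generator does *not* emulate: PET physics (scatter,
attenuation, partial-volume effects), anatomical geometry, spatially
correlated noise, site/scanner effects, or non-Gaussian SUVR marginals.
Passing tests therefore demonstrate that the estimation and inference
machinery recovers truth under the model's own assumptions at realistic
sample sizes — not that real scans satisfy those assumptions.

## Problem sizes used in tests and the acceptance script

Simulation sizes are chosen to make every check sharp but cheap: support
recovery at p = 20, n = 400, 20 seeds; permutation calibration at the
6-vs-12 design with 200 permutations × 500 null replicates (using a
cheap transparent statistic — calibration of the shuffling machinery is
statistic-agnostic, and the SICE-chain statistic is exercised separately);
hub-taxonomy recovery at p = 40, n = 50/group, 20 seeds, planted density
0.08; ICA at 12×12×8 voxels, 30 subjects, 3 sources; the end-to-end
study at p = 40 with 500 permutations and B = 200 (5000/1000 are the
full-scale defaults).

## Known limitations

- Gaussianity: SICE assumes multivariate-normal ROI values; heavy tails
  inflate false edges.
- The bootstrap percentile CI under L1 shrinkage is conservative for
  weak edges (soft-thresholding biases weights toward zero), so edge
  "power" figures are lower bounds.
- Density matching equates edge counts, not information: at very small n
  the matched networks can differ in reliability between groups.
- Greedy modularity (for the participation coefficient) is a heuristic;
  near-degenerate partitions can flip module assignments between similar
  graphs.
- MDL order selection assumes iid Gaussian residual eigenvalues; strong
  spatial noise correlation biases k upward.
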