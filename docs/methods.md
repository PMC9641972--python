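# Methods

This package re-implements, as one tested pipeline, the statistical
machinery commonly used to compare microbial communities across habitats:
alpha/beta diversity, Levins niche breadth, the βNTI + RC_bray null-model
partition of community-assembly processes, the Sloan neutral community
model, Mantel / partial-Mantel environment association, and Spearman
co-occurrence networks.  A synthetic-community generator with known
assembly regimes provides the ground truth against which every inference
stage is validated.

## Community data

An analysis operates on three aligned objects: an OTU count table (taxa ×
samples, non-negative integers; every sample total > 0; all-zero taxa are
flagged but allowed), a rooted phylogeny whose tips are the OTU ids, and
per-sample metadata (habitat group among Sur_FL, Sur_PA, Bot_FL, Bot_PA,
Sed; coordinates; numeric covariates, which may be missing for sediment).
Identifier matching is exact and case-sensitive: fuzzy matching hides data
errors.  Taxa absent from the tree are dropped (with a logged count)
before any phylogenetic computation, since nearest-taxon distances are
undefined for them.  Counts are kept raw; none of the estimators here
requires rarefaction, and subsampling is easy to apply upstream if wanted.

## Diversity

Alpha indices per sample: observed richness; Chao1 in the bias-corrected
form S_obs + F1(F1−1)/(2(F2+1)) (robust when doubletons are absent; the
classic form is a flag away); ACE with the conventional rare/abundant
cutoff of 10; Shannon H = −Σ p ln p in nats.  Beta diversity is
Bray–Curtis, by default on per-sample proportions so sequencing depth does
not masquerade as turnover.  Group structure is tested by PERMANOVA
(Anderson's pseudo-F on the Gower-centred distance matrix) and ANOSIM;
both use permutation p-values with the (1 + exceedances)/(1 + n_perm)
estimator, so p can never be 0 and is floored at 1/(n_perm+1).  The
"within-group beta diversity" summary is the multiset of within-group
pairwise Bray–Curtis distances.

## Levins niche breadth

For taxon j with proportions P_ij of its total abundance across samples,
B_j = 1/Σ_i P_ij² ranges from 1 (single-sample specialist) to the number
of samples (even generalist), and is invariant to rescaling the taxon's
row.  The community-level breadth of a sample is the unweighted mean of
B_j over taxa present (count > 0); an abundance-weighted mean is provided
as an option but not the default, because the community-level usage in the
literature is a plain average.

## Assembly null models

For a pair of communities k and m, the abundance-weighted beta mean
nearest taxon distance is

  βMNTD = ½ [ Σ_i f_ik · min_{j∈m} d(i,j)  +  Σ_j f_jm · min_{i∈k} d(j,i) ],

with f the within-sample relative abundances and d the cophenetic distance
on the tree (unweighted variant: f = 1/richness).  βNTI is the z-score of
the observed βMNTD against 999 randomizations that shuffle the assignment
of taxa to tips — a joint row/column permutation of the cophenetic matrix,
shared across all pairs of a group so the group has one coherent null
ensemble.  Pairs whose null spread is zero (e.g. on a star phylogeny) are
flagged degenerate and excluded.  Because a z-score is scale-free, βNTI is
invariant to multiplying all branch lengths by a constant; the test suite
also checks the sampled null against exhaustive permutation enumeration on
small trees.

RC_bray ranks the observed Bray–Curtis within a null of probabilistically
reassembled pairs.  Each reassembly preserves the sample's observed
richness and total count: taxa are drawn without replacement with
probability proportional to their occurrence frequency in the
metacommunity table (Gumbel top-k sampling), receive one individual each,
and the remaining individuals are allotted multinomially in proportion to
metacommunity mean relative abundance restricted to the drawn taxa.
RC = 2·[(#{null < obs} + ½·#{null = obs})/n_null] − 1 ∈ [−1, 1], with
equality meaning agreement within 1e-10.  Bray–Curtis is computed on
proportions for both observed and null communities.

Classification per pair: βNTI < −2 homogeneous selection; βNTI > +2
heterogeneous selection; otherwise RC < −0.95 homogenizing dispersal,
RC > +0.95 dispersal limitation, else drift.  Exact boundary values fall
to the stochastic/drift side (the inequalities are strict).  Pairs are
formed within habitat groups, and each group's own samples serve as its
metacommunity for RC_bray; both follow from reading the per-group process
fractions as within-group comparisons.  Group fractions over the
n(n−1)/2 pairs sum to 1.

## Sloan neutral community model

Under neutral death–replacement dynamics with local community size N and
immigration probability m, a taxon of metacommunity mean relative
abundance p has locally Beta(Nmp, Nm(1−p)) distributed relative abundance;
its expected occurrence frequency above a detection limit d is
1 − I_d(Nmp, Nm(1−p)).  The fit minimizes the sum of squared differences
between observed occurrence frequencies (fraction of samples with count
> 0) and this prediction over m ∈ (10⁻⁶, 1], seeding a bounded scalar
search with a 50-point log grid — the objective is one-dimensional and the
procedure fully deterministic.  R² = 1 − SSE/SST may be negative for
grossly non-neutral data.  N defaults to the mean sample depth.

The detection limit defaults to d = ln(2)/N rather than the conventional
1/N: detection in count data means drawing the taxon at least once among N
reads, a soft event of probability ≈ 1 − e^(−Nx), and the sharp threshold
that best mimics it is the abundance where that probability crosses one
half.  With d = 1/N the fitted m overestimates strongly-mixed communities
(generating m = 0.5 recovered as ≈ 0.7 in our validation; ≈ 0.45 with
ln(2)/N, and small m essentially exact under both).  The conventional
value remains one argument away.  Per-taxon 95% prediction bands are
Wilson binomial intervals at the realized sample count; taxa outside the
bands are flagged but never refitted.

## Environment association

Geographic distance is the haversine great-circle distance (Earth radius
6371 km).  Environmental distance is Euclidean on z-standardized
covariates (sample SD), since units are heterogeneous (PSU, °C, dbar,
mg/l); zero-variance covariates are dropped with a warning.  The Mantel
statistic is the Pearson correlation of the strictly-upper triangles; the
partial Mantel r(A,B|C) uses the standard residual (partial correlation)
form and reduces to the simple Mantel r when C carries no pattern.  Both
tests permute the row/column order of the first matrix and are one-sided
(greater), the direction in which community–environment association is
read; the permuted statistic is recomputed in full each iteration.

## Co-occurrence networks

The meta-community network is built on the top-500 OTUs by summed relative
abundance (ties broken lexicographically).  All pairwise Spearman
correlations (midranks for ties) are tested with the t-approximation on
n − 2 degrees of freedom — at 75 samples this is accurate and keeps the
~125k tests fast — and Benjamini–Hochberg adjusted across all tested
pairs at once, because one meta-community network is built and subnetworks
are extracted from it rather than re-estimated per habitat.  Edges require
|r| > 0.7 and q < 0.01; constant taxa are skipped (their rank correlation
is undefined).  Edge sign is stored as an attribute; topology is computed
on the unsigned simple graph, and the positive-edge fraction is reported
separately.

Network-level topology: average degree 2E/N, density, mean local
transitivity over nodes with degree ≥ 2, average path length and diameter
on the largest connected component (the graph may be disconnected),
modularity Q of the greedy-modularity partition (deterministic, no
resolution parameter), and Freeman centralizations — Σ(c_max − c_i)
normalized by the star-graph maximum, which attains exactly 1 on stars and
0 on vertex-transitive graphs.  Node-level: degree, local transitivity
(undefined below degree 2), normalized betweenness, and closeness within
the node's component (isolated nodes: 0).  Habitat subnetworks are the
induced subgraphs on taxa with nonzero abundance in the habitat's samples;
correlations are inherited, not recomputed.

## Synthetic communities

The generator emulates the layout of a coastal survey — 75 samples in
five habitat groups of 15 (surface/bottom × free-living/particle-associated
water fractions plus sediment), several hundred OTUs, lognormal
rank-abundance structure — under four generating processes:

* **Neutral** — each sample drawn from the stationary law of the Sloan
  death–replacement process: Dirichlet(Nmp) relative abundances followed
  by a multinomial draw of N individuals (exact multinomial at m = 1).
  This is the distribution the explicit event dynamics converge to, so it
  is used directly; a vectorized death–replacement event loop is available
  through `burn_in` for validation, with a warning when fewer than N
  events (one community turnover) are requested.  An explicit burn-in long
  enough to mix at small m (~N/m generations) would dominate the runtime
  of every test for no statistical difference.
* **Selection** — taxon trait optima evolve by Brownian motion on the
  tree (root 0, variance = branch length) and sampling weight is
  meta_p · exp(−(env − optimum)²/2σ²).  Identical env across samples gives
  homogeneous selection, divergent env heterogeneous selection.  An
  optional Dirichlet `drift_concentration` κ draws each sample's
  multinomial probabilities around the filtered expectation, adding
  ecological drift within the selected pool.
* **Dispersal limitation** — site pools re-weight the metacommunity by a
  Gaussian field with covariance exp(−d/decay) on great-circle distances,
  so nearby sites share pools and Bray–Curtis increases with distance.

**Phylogeny.**  Plain Yule trees are provided, but the regime generator
uses a two-timescale clustered phylogeny (`simulate_clustered_phylogeny`):
a compressed deep radiation into ~5-tip crowns joined by long stems,
mirroring the shape of 97%-identity OTU trees where short terminal
branches sit within genus-level clades.  This matters quantitatively: on a
300-taxon Yule tree the taxa-shuffle null is too dispersed for βNTI to
fall below about −1.5 no matter how strong the filtering, because the
null's common-mode variance bounds the attainable z-score.  With tight
crowns and near-equal stems, nearest-taxon distances become bimodal
(≈0 to a cluster-mate, ≈2 stem lengths otherwise), the null concentrates,
and selection regimes generate the decisive |βNTI| > 2 signal that the
classifier is supposed to detect.

**Frozen regime settings** (criterion scale: 300 taxa, N = 5000, 15
samples): metacommunity lognormal(0, 0.8) in the regime wrapper (1.0 in
the 75-sample layout, 1.5 as the generic default); homogeneous selection
with a shared optimum at +1.2 trait SD, σ = 0.3, κ = 8; heterogeneous
selection with optima spread over ±2 trait SD, σ = 0.3, no added drift;
neutral m = 0.5; dispersal decay 50 km (water-column groups in the layout:
120 km surface, 60 km bottom).  These were fixed by pilot runs of the
regime-separability requirement during generator design and are not
re-tuned.

**What the generator does not emulate**: sequencing noise (PCR bias,
chimeras, uneven depth), taxonomic structure, genuinely coupled
environment–community responses in the 75-sample layout (its CTD
covariates vary with latitude/longitude but do not drive composition, so
the layout's partial-Mantel r is expectedly near 0), and the
ubiquitous-rare occupancy structure of real surveys beyond what lognormal
abundance induces.  Passing tests therefore demonstrate that the
*inference machinery* is correct and well calibrated on data satisfying
each model's assumptions — not that real marine communities behave this
way.

## Numerical choices and degenerate inputs

Permutation p-values never report 0 (see above).  βNTI uses running
mean/variance accumulation over the null ensemble; null SD ≤ 1e-10 flags
degeneracy.  RC ties use a 1e-10 tolerance.  The NCM objective clips p to
(1e-12, 1−1e-12) to keep the Beta parameters positive.  Spearman networks
drop constant taxa; a two-taxon table is special-cased (scipy returns a
scalar).  Zero-variance environmental covariates are dropped; an empty
covariate set is an error.  Empty graphs report undefined (NaN/None)
topology rather than failing.  All stochastic stages take explicit seeds;
the pipeline derives per-stage seeds from the run seed via
`SeedSequence.spawn`, making end-to-end reports byte-identical under a
fixed seed.

## Problem sizes

Default validation sizes were chosen so the full 999-randomization null
models stay within minutes on one core: regime recovery uses 300 taxa ×
15 samples × 5 seeds per regime; NCM recovery 300 taxa × 200 samples × 10
seeds; test-suite pipeline runs use reduced tables (the pipeline's own
defaults are 400 taxa × 75 samples at 999 randomizations, as in
`scripts/acceptance.py`).

## Known limitations

* The RC_bray reassembly weighting (occurrence frequency for membership,
  mean relative abundance for allotment) follows the common framework
  convention; the underlying literature admits variants, and results for
  near-boundary pairs can shift between them.
* βNTI power is scale-dependent: at a few hundred taxa the homogeneous-
  selection signal is intrinsically weak unless the phylogeny carries
  tip-level niche conservatism (see above).  Real datasets with thousands
  of OTUs do not face this limit.
* The NCM fit assumes one shared N and detection limit; strongly uneven
  depths deserve per-sample treatment the model does not provide.
* Partial Mantel permutes the first matrix only; its known mild
  liberality under strong spatial autocorrelation of the control is not
  corrected here (the calibration test covers exchangeable nulls).
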