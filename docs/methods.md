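# Methods

This note documents the models and procedures `mycoassembly` implements, the
defaults it ships with and why, the design choices made where several
reasonable options existed, and what the synthetic-data generators do and do
not emulate.

## Data model

The central object is a sample × OTU table of non-negative integer read
counts (`OtuTable`). Counts are integral by contract: fractional inputs are
rejected rather than rounded, because every downstream operation
(rarefaction, occupancy, presence counts) is defined on reads. Distance
matrices are scikit-bio `DistanceMatrix` objects, which validate symmetry
and the zero diagonal on construction; trees are Newick files parsed by
dendropy, with missing branch lengths an error by default (cophenetic
distances are meaningless without them). The internal table orientation is
samples-as-rows; file readers accept either orientation explicitly.

The fungal-OTU phylogeny used by the MNTD/βNTI machinery is a user-supplied
input. The package does not build trees; how such a tree is constructed
(marker choice, alignment, inference) is outside its scope, and results are
conditional on the supplied topology and branch lengths.

## Rarefaction and community transforms

Rarefaction draws each retained sample's counts without replacement
(multivariate hypergeometric) to a common depth — default 1,055 reads, the
smallest-sample convention — under a mandatory seed. Samples below the depth
are dropped with a logged warning; OTU columns left empty are removed. The
Hellinger transform (square root of within-sample relative abundance)
precedes Bray–Curtis dissimilarity, which stabilizes the influence of
dominant taxa. A pair of all-zero samples makes Bray–Curtis undefined; this
is an error by default, with opt-in NaN propagation. Geographic distances
are great-circle (haversine) on a 6,371-km sphere, in km.

## Ordination and spatial eigenvectors

PCoA double-centres −D²/2 (Gower) and eigendecomposes; axes are scaled by
√eigenvalue so Euclidean-embeddable inputs are reproduced exactly, axis
signs are fixed deterministically, and negative eigenvalues are reported,
not corrected. PCNM truncates the geographic distance matrix at the longest
minimum-spanning-tree edge t, replaces larger entries by 4t, and keeps the
positive-eigenvalue PCoA axes. On an equidistant transect the leading
eigenvector is a single long wave (one interior sign change), not a
monotone trend — the construction removes the linear gradient; this matches
the behaviour of the reference R implementation (`vegan::pcnm`) on identical
input, which was used as a development cross-check.

## Permutation tests

All permutation p-values use (1 + hits)/(1 + n_perm) with a default of 999
permutations and mandatory seeds. PerMANOVA is one-factor (the designs this
package targets test a single grouping), partitioning squared
dissimilarities into within- and between-group sums; on univariate Euclidean
input the pseudo-F reduces exactly to the classical one-way ANOVA F, which
the tests exploit as an oracle. PERMDISP embeds samples by PCoA (imaginary
axes subtracted in squared distances), measures each sample's distance to
its group centre — spatial median by default, centroid by flag; bias
correction off — and permutes those distances across groups; singleton
groups are excluded with a warning. Mantel correlates lower-triangle
entries (Pearson default, Spearman via rank-transformed entries) and is
one-tailed "greater", permuting the second matrix's rows and columns
jointly. The partial Mantel residualizes both the first and second matrices
on the third and permutes the second (the simple method — an approximation,
documented as such); when the first matrix carries no variance beyond the
conditioning matrix the partial r is 0 by convention. Environmental vector
fitting regresses each variable on the first two ordination axes (axis
count configurable), reporting the fitted-variance r², a unit-norm
direction, and a permutation p from shuffling the variable.

## Phylogenetic null models

MNTD is the (abundance-weighted by default) mean distance from each taxon in
a community to its nearest co-occurring neighbour; βMNTD is the symmetric
between-community analogue, with shared taxa contributing distance 0. The
null model shuffles taxa labels on the cophenetic matrix **across the OTUs
present in the analysed table** (not the whole tree), the ecosystem default
for this statistic family. NTI negates the z-score so clustering is
positive; βNTI keeps the raw sign so greater-than-expected turnover is
positive, and |βNTI| > 2 is classed deterministic. Two implementation
details matter:

- OTU order is canonicalized (sorted ids) before drawing null permutations,
  making every output invariant to input column order under a fixed seed.
- All-pair βNTI nulls reuse the same label shuffles across pairs (one
  shuffle = one null replicate for every pair), which keeps replicates
  coherent between pairs and reduces the computation to one matrix product
  per replicate.

A null sd below 10⁻⁹ relative tolerance is treated as zero (the shuffle can
reproduce the observed statistic exactly, e.g. for a community containing
every taxon, leaving only summation-order noise); such results are flagged
undefined rather than divided through. Whether NTI should weight abundances
is not settled usage; the default here is abundance-weighted with a flag,
and the between-community metric is always abundance-weighted by default.
The stochastic fraction is not further partitioned (no Raup–Crick step).

## Sloan neutral model

The model predicts occupancy from mean relative abundance:
occ(p) = 1 − B(d; Nmp, Nm(1−p)), with N the common rarefied depth, detection
limit d = 1/N (one read — the standard operationalization), and m the
probability that a local death is replaced by an immigrant. m is estimated
by bounded scalar least squares on m ∈ [10⁻⁶, 1] (tolerance 10⁻⁸); the loss
is unimodal on simulated data and the fit is insensitive to initialization.
R² is computed on untransformed frequencies; the log-abundance axis is for
plotting only. Confidence bands are Wilson score intervals with n = number
of samples (normal approximation by flag); OTUs are classed above/within/
below the band. A bootstrap-over-OTUs CI for m is provided as a clearly
labelled reporting extension, since no analytic uncertainty is defined for
this fit. Unequal row sums are an error unless forced: N is only meaningful
for a rarefied table.

## Preference analysis

Preference is analysed at a single site to remove site effects. The
interaction matrix holds presence counts (number of samples of plant j
containing OTU i); OTUs below a configurable occurrence threshold (default
total ≥ 3 at the site) are dropped as rare. d′ is the standardized
Kullback–Leibler specialization of a focal row against partner availability
q_j (columns' share of the grand total), scaled by d_max = ln(total/A_i)
with d_min taken as 0 — the exact minimum is omitted because inference
relies on the randomization SES, not the raw scaling. The null is the
Patefield algorithm (fixed row and column sums, via
`scipy.stats.random_table`); a sample-label-shuffle alternative (row sums
fixed, columns free within per-plant capacities) is available by flag since
the methods lineage for this analysis admits both. Standardized d′ and 2DP
are (observed − μ_null)/σ_null with two-sided rank p-values; BH-FDR is
applied within each family (OTUs, plants, pairs) with undefined cells
(zero null variance) excluded; 2DP > 1.6 flags strong preference. Default
n_rand = 1,000.

## Group comparisons

Kruskal–Wallis uses the tie-corrected H (defined as 0 when all observations
are identical) with a χ² reference on k−1 df. The Conover–Iman post-hoc uses
t statistics on mean ranks with the pooled tie-corrected rank variance
shrunk by (N−1−H)/(N−k), on N−k df. The p-adjustment inside the post-hoc is
configurable (none, BH, Holm; the pipeline default is BH) and recorded in
the run summary — no single convention dominates usage. The compact letters
display assigns letters to maximal cliques of the non-significance graph,
in group order. Accumulation curves use the exact hypergeometric expectation
E[S_k] = Σ_j (1 − C(n−m_j, k)/C(n, k)) by default; the random method
(default 100 permutations) adds an sd and is checked against the exact form.

## Synthetic data

The generators emulate the study design the package is shaped around:
63 samples of 5 host species across 8 sites on a ~1,900-km transect,
rarefied depth 1,055, 288 OTUs. Metacommunity abundances are lognormal
(σ = 1.5), giving the strong skew typical of EM communities (a few tens of
OTUs holding most reads). Trees are seeded pure-birth (Yule) trees,
optionally rescaled to unit ultrametric depth.

**Neutral tables.** Per sample, each OTU's local relative abundance is
drawn from Beta(Nmp, Nm(1−p)) and the draws are normalized to the simplex;
the local community of N individuals is then realized directly from those
proportions (floor(N·x), remainder reads to already-present OTUs by largest
fractional part). Rows therefore sum exactly to N and an OTU is present
precisely when its proportion clears the model's one-read detection limit.
This is the model's own construction — N is the local community size, and
the beta is the stationary distribution of composition *in that finite
community*. Layering a further binomial read-resampling stage on top would
double-count sampling noise: OTUs below 1/N would still be detected with
substantial probability, and the fitted m comes out 25–45% high at
m ∈ {0.1, 0.3}. With the direct construction, recovery error stays below
~8% across m ∈ {0.01, 0.1, 0.3}.

**Host-structured tables.** Each host's mean profile mixes a shared pool
with a host-specific pool at mixture weight = preference strength; with
clade filtering the host pools concentrate on the two deep clades of the
supplied tree, producing between-clade turnover (βNTI > 2 between hosts).
Site structure is a multiplicative log-normal field following an
Ornstein–Uhlenbeck process along the transect, so between-site correlation
decays as exp(−decay·distance); per-sample counts are Dirichlet-multinomial
(concentration 50 — moderate overdispersion). Site environmental variables
(MAT, MAP, soil N, P, N:P, Ca, Mg, altitude) follow simple latitudinal
gradients with noise.

**What the generators do not emulate.** Sequence-level artefacts (chimeras,
clustering error), unequal sampling depths before rarefaction, realistic
per-sample sparsity (generated communities are denser than typical EM root
samples), multi-factor confounding between host and site, and spatial
kernels beyond exponential decay. Passing tests therefore demonstrate that
the statistics behave correctly under their own assumptions — calibrated
nulls, power under injected signal, exact oracles — not that any particular
field system satisfies those assumptions.

## Verification problem sizes

The test suite verifies each stage at sizes chosen to keep the full run
within a few minutes while leaving no stage untested: the nearest-taxon
oracle on 200 random instances (≤ 20 tips, ≤ 10 samples); βNTI calibration
on 25 neutral samples over a 100-tip tree (300 pairs, 999 shuffles) and
power on clade-filtered communities; Sloan recovery at N = 1,000 with 60
samples and 300 OTUs over m ∈ {0.01, 0.1, 0.3} (5 seeds each); PerMANOVA
and Mantel type-I error over 200 replicate datasets (199 permutations);
preference calibration over 100 fixed-marginal null matrices; and the full
pipeline, twice, on the default 63-sample fixture with paper-scale defaults
(999 permutations/shuffles, 1,000 randomizations) for byte-identical
bundles.

## Known limitations

- One-factor PerMANOVA only; no strata or multi-factor designs.
- NMDS is deliberately absent: PCoA serves ordination display, and the
  inferential statistics (PerMANOVA, PERMDISP) do not depend on the display
  embedding.
- Random-forest variable importance is referenced in the pipeline report as
  an external optional step, not computed.
- The partial Mantel uses the simple permutation scheme; residual-based
  permutation alternatives exist and can give slightly different p-values.
- The Patefield null ignores the per-plant sample-count cap on interaction
  cells; the shuffle null respects it. Both are provided because the
  appropriate null depends on how presence counts were collected.
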