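# Methods

`otukit` implements the community-level analysis of a 16S rRNA amplicon
survey at the OTU-table stage: everything downstream of read processing and
97%-identity clustering, and nothing upstream of it. The input contract is
an OTU × sample matrix of non-negative integer read counts, a per-sample
metadata table (site, plant, compartment ∈ {rhizosphere, phyllosphere},
short code), and optionally an OTU → lineage map.

## Preprocessing

Filtering runs in a fixed order: dataset-wide singleton OTUs (total reads
< 2) are removed first, since single reads are most often sequencing
artifacts; then OTUs whose lineage contains a configurable label
(default `Chloroplast`, matched case-insensitively at any rank) are
removed — host-plastid 16S is a contaminant in plant-associated samples;
then samples below `min_reads` (default 1000) are excluded as failed runs.
The chloroplast filter precedes rarefaction so plastid reads never consume
part of a sample's rarefied depth. OTUs without a taxonomy entry are
treated as unclassified and never removed by the taxonomy filter.

Rarefaction subsamples each sample's reads uniformly **without
replacement** — a multivariate hypergeometric draw over its OTU counts —
to a common target depth (default 7125 reads). Samples below the target
are kept unchanged by default (`keep_below_depth=True`), trading perfectly
equal effort for complete habitat coverage; they can be dropped instead.
The draw is seeded, and columns are processed in table order, so a seed
fully determines the output. The per-cell expectation is
`depth × count / sample_depth`, which the test suite verifies by
Monte-Carlo over 1000 seeds.

## Alpha diversity

Per sample: observed richness `S_obs`; Chao1 expected richness, by default
the bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))` (F1 singleton, F2
doubleton OTUs), which remains defined when F2 = 0 — the classic
`S_obs + F1²/(2F2)` form is available behind a flag; Simpson diversity
1 − D with the plug-in estimator `D = Σ p_i²` by default and the
finite-sample form `Σ n_i(n_i−1)/(N(N−1))` behind a flag; and Pielou
equitability `H / ln S_obs` with natural-log Shannon H (the ratio is
base-invariant), undefined below two observed OTUs. The coverage ratio
`S_obs / S_Chao1 ∈ (0, 1]` is the per-sample completeness diagnostic.
These estimators are delegated to scikit-bio's alpha-diversity functions.
The analytic rarefaction curve
`E[S(q)] = Σ_i [1 − C(N−N_i, q) / C(N, q)]` is computed with
log-gamma binomials for numerical safety; it is nondecreasing and concave
in q, and the tests check it against Monte-Carlo subsampling.

## Beta diversity

Pairwise dissimilarities (via scipy): Bray-Curtis on counts,
Jaccard and Sørensen (Dice) on presence/absence. Jaccard similarity is
simply 1 − distance; ordination consumes the distance form.

The multiple-site partition follows the Sørensen-family decomposition of
total beta diversity into turnover and nestedness. With `S_i` the
richness of site i, `S_T` the pooled richness and `b_ij` the number of
OTUs present in i but absent from j:

    bSIM = Σmin / (Σmin + (ΣS_i − S_T))
    bSOR = (Σmin + Σmax) / (2(ΣS_i − S_T) + Σmin + Σmax)
    bNES = bSOR − bSIM

with Σmin/Σmax the sums over site pairs of min/max(b_ij, b_ji). The
additive identity bSOR = bSIM + bNES holds exactly (tested to 1e−12), the
n = 2 case reduces to the pairwise Simpson/Sørensen closed forms, nested
pairs give bSIM = 0 and equal-richness disjoint pairs give bNES = 0. When
the denominator vanishes (all sites identical) all components are defined
as 0. `partition_by_group` computes one partition per metadata group
(default site × compartment), treating each individual sample of the
group as one "site" of the partition — the multi-site reading, chosen over
averaging pairwise values because it is the computation behind the
standard `beta.multi`-style implementations of the decomposition.

## Permutation tests and ordination

ANOSIM and one-way PERMANOVA both consume a distance matrix and a
grouping factor with at least two groups of at least two samples.
ANOSIM ranks all off-diagonal distances (average ranks for ties) and
reports `R = (mean between-group rank − mean within-group rank)/(M/2)`,
M = n(n−1)/2; R ∈ [−1, 1] and is invariant under order-preserving
transforms of the distances. PERMANOVA uses
`SS_total = (1/N) Σ_{i<j} d²_ij`, `SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij`
and `pseudo-F = (SS_between/(a−1)) / (SS_within/(N−a))`. Both p-values
come from seeded label permutations with the `(1 + #{perm ≥ obs})/(1 +
n_perm)` estimator (default 9999 permutations), so p is never exactly 0
and the same seed is bit-reproducible. The statistics and permutation
machinery are delegated to scikit-bio, which implements exactly these
conventions; the package validates inputs (a constant distance matrix
makes R undefined and is rejected) and handles the degenerate
`SS_within = 0` case itself, reporting an infinite pseudo-F flag with a
permutation-only p-value. The test suite checks both statistics against
independent oracles (first-principles rank computation and exhaustive
label enumeration for ANOSIM; Gower double-centering for the PERMANOVA
sum-of-squares decomposition) and verifies near-nominal type-I error
under exchangeable simulations.

Non-metric MDS embeds samples in 2-D minimizing Kruskal stress-1 with
monotone regression of embedded distances on dissimilarity ranks
(scikit-learn's SMACOF). Restart 0 is initialized from classical metric
scaling, the remaining restarts (default 20 total) from seeded random
configurations; the reported stress is the minimum over restarts.
Defaults: `max_iter=300`, `tol=1e−7`.

## Niche breadth and guild classification

For OTU j over the N samples of the analyzed table, Levins' niche breadth
is

    B_j = 1 / Σ_i P_ij²,   P_ij = (reads of j in sample i) / (total reads of j)

so Σ_i P_ij = 1, B = 1 for an OTU confined to one sample, and B = N for a
perfectly even OTU. P_ij is deliberately the share of the *OTU's* reads
(not the renormalized sample-relative abundance): it reproduces the
B = 1 singleton limit, bounds B by the sample count, and on equal-depth
(rarefied) tables the two readings coincide anyway — a regression test
asserts this. B is always computed on the filtered, rarefied table.

Classification is strict on the mathematical value: generalist iff
B > 20, specialist iff B < 10, otherwise intermediate (values within
floating-point noise of a threshold count as equal, hence intermediate).
An OTU is *abundant* when its dataset total strictly exceeds 0.2% of the
grand total. *Abundant specialists* are abundant ∧ specialist; their
preferred habitats are the plant × compartment groups where the mean
per-sample relative abundance strictly exceeds 20%. All four thresholds
are parameters with these defaults.

Generalists can be identified two ways: from the whole table
(`mode="whole"`), or conservatively as the intersection of the
whole-table call with per-site and per-compartment calls
(`mode="intersection"`, the default) — an OTU must look like a generalist
in every subset. Since B is bounded by the number of samples, a subset
with at most 20 samples can never contribute generalists at the default
threshold; the function documents this rather than silently rescaling.

Shared-OTU accounting reports, for every pair of groups of a partition
(default: the two compartments), the counts of group-exclusive and shared
OTUs, an OTU belonging to a group when it has ≥ 1 read in ≥ 1 of its
samples.

## Synthetic communities

The generator emulates the post-clustering product of a three-site,
two-compartment field survey. Default geometry: site 1 has one plant with
8 replicate individuals, sites 2–3 have three plants with 5 replicates,
two compartments each — 76 samples. Three planted guilds:

* **generalists** (default 30; jointly 30% of non-specialist reads,
  lognormal σ = 0.5 spread): identical expected relative abundance in
  every sample, so their B approaches the sample count;
* **specialists** (default 14, one per plant × compartment group,
  assigned round-robin): expected share `specialist_load` (default 0.4)
  of their preferred group's reads, zero elsewhere, so their B is bounded
  by the group's replicate count and they exceed the 20% preference rule
  in expectation. Loads of specialists sharing a group must sum below 1;
  one specialist per group keeps any load in (0, 1) admissible, which is
  why 14 is the default count;
* **background** (default 950): lognormal mean abundances (σ = 1.5,
  heavy-tailed), multiplied per site by a lognormal factor of scale
  `site_effect` (default 1.0) so sites diverge compositionally;
  `site_effect = 0` with no specialists is an exchangeable null.

Per sample, counts are multinomial at a depth uniform on `depth_range`
(default 3000–12000, deliberately straddling the 7125-read rarefaction
depth so some samples are retained below depth, as in real surveys).
Optional Dirichlet-multinomial overdispersion is off by default — the
multinomial is the simplest model consistent with rarefied read data.
A single seeded generator drives everything, so a seed reproduces the
dataset byte for byte.

What the generator does **not** emulate: sequence-level error, chimeras
and clustering noise; taxonomic structure; correlations between OTUs
(compositional interactions); depth-dependent contamination. Passing the
recovery and calibration tests therefore shows the pipeline's statistics
behave correctly under a clean compositional model, not that any real
survey's biological conclusions are reproduced.

## Problem sizes used by the automated checks

Null calibration runs 200 simulations of a reduced geometry (3 sites ×
1 plant × 3 replicates × 2 compartments, 160 OTUs, depths 1000–2000,
199 permutations) and checks both tests' rejection rates at α = 0.05
within three binomial standard errors. Guild recovery runs 20 seeds of
the default geometry with `depth_range=(5000, 12000)` and
`site_effect=2.0` — the regime where recovery is claimed — requiring
≥ 90% of planted generalists and specialists recovered at default
thresholds after singleton filtering and rarefaction to 7125 reads.
The exhaustive-enumeration check of the ANOSIM p-value compares the
Monte-Carlo estimator at 9999 permutations with the exact enumeration
fraction within 0.02 (≈ 3 binomial SE plus the +1 estimator offset),
since the `(1+c)/(1+n)` estimator cannot be bit-equal to an exact
fraction.

## Known limitations

* Rarefaction discards reads; variance-stabilizing alternatives
  (e.g. proportion or compositional transforms) are out of scope.
* PERMANOVA is one-way only; nested or multi-factor designs and
  dispersion tests (PERMDISP) are not implemented.
* The abundance-based (Bray-Curtis) balanced/gradient beta partition is
  not implemented — only the presence/absence Sørensen family.
* The intersection mode for generalists is undefined in spirit for
  subsets smaller than the generalist threshold (B cannot exceed the
  sample count); users with small subsets should lower the threshold or
  use whole-dataset mode explicitly.
* nMDS minimization is non-convex; different restart counts can yield
  slightly different stress. The seed and restart count are recorded in
  every result for reproducibility.
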