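# Methods

## Model and assumptions

The package treats genet assignment as threshold clustering of a
pairwise genetic distance matrix. The generative picture behind it: each
genet starts as one sexually produced seed with a diploid multilocus
genotype; clonal propagation copies that genotype to every ramet of the
genet, perturbed only by rare somatic mutations inherited along the
clonal lineage; genotyping adds independent per-sample noise (allele
dropout, random allele miscalls, missing calls). Under this model the
distribution of all pairwise distances is a mixture of a within-genet
component concentrated near zero and a between-genet component whose
location is set by population-level allele frequencies and relatedness.
Assignment is possible exactly when the two components are separated;
every threshold estimator here is a way of locating that separation.

Assumptions worth stating explicitly:

* diploidy, and phase-blind unordered allele pairs (all three distance
  models ignore phase);
* within-genet variation is small relative to between-genet variation —
  the method fails loudly (unimodal-histogram error), not silently, when
  this breaks;
* loci are treated as independent (no linkage structure enters any
  statistic);
* missing data are rare enough that pairwise-complete deletion without
  rescaling is acceptable for the integer distance models. The per-pair
  count of loci actually compared is stored in the matrix metadata, and
  the relative dissimilarity divides by it.

## Distance models

* **Infinite-allele (IAM).** Per locus, `2 − |multiset intersection|` of
  the two allele pairs (0, 1 or 2 unmatched copies), summed over
  pairwise-complete loci. Reported as raw counts, not per-locus
  averages, so values are directly comparable to mismatch counts.
* **Stepwise (SSR).** Per locus, the minimum over the two possible
  allele pairings of the summed squared repeat-score differences. The
  allele-pairing convention is a package decision (documented here
  because several programs differ silently on it): the pairing
  minimizing the squared sum is always taken.
* **Dissimilarity.** The IAM count, or (relative form) the fraction of
  compared allele copies that differ, in [0, 1]. The relative form is
  the default edge weight for the minimum spanning network.

## Threshold estimators

* **Plateau.** Histogram of all pairwise distances at bin width 1
  (distances are integers; no smoothing). Mode detection: local maxima
  are computed with flat tops collapsed; the primary peak is the global
  maximum, and the secondary peak is the local maximum with the greatest
  topographic prominence relative to the primary (the deepest separating
  valley). Raw peak height is deliberately *not* used to pick the second
  mode: with tens of thousands of pairs the between-genet bulk is
  jagged, and two of its sub-peaks can both outrank the within-genet
  peak, which collapses the assignment to one genet. Prominence keeps
  the two modes on opposite sides of the deepest valley by construction.
  The valley (minimum-count bin between the peaks, ties leftmost) splits
  the histogram; the modes are each segment's argmax. Among maximal runs
  of integer thresholds strictly between the modes over which the genet
  count is constant, the longest run wins (ties: the lower run) and the
  threshold is its maximum. Degenerate inputs (all-zero distances, a
  single mode) raise with advice to set the threshold manually.
* **Gap.** Putative thresholds are the distinct agglomeration merge
  heights; the threshold sits `fraction` (default 0.5) of the way into
  the widest gap between consecutive values, ties resolved to the
  lowest gap.
* **Sexual.** Simulate `n_sim` (default 1000) offspring by Mendelian
  segregation from random pairs of the observed genotypes, a
  `selfing_fraction` (default 0.5 — the mixture of outcrossing and
  selfing is not otherwise constrained, so equal weight is the neutral
  choice, recorded in the diagnostics) of them selfed; the threshold is
  the minimum pairwise distance among the simulated offspring. Anything
  closer than the closest conceivable seed pair is called clonal.

## Assignment

`d ≤ t` merges (a threshold that is itself an attained distance merges
that pair); a strict-inequality variant would shift every boundary case
and is intentionally not the default, since the plateau threshold is
chosen as the top of a window in which no merge happens anyway. Single
linkage equals connected components of the thresholded pair graph (the
tests verify this against a union-find oracle); complete linkage is the
conservative farthest-neighbour agglomeration, with merge order by
ascending distance and scipy's deterministic earliest-index tie-break.
Genets are relabelled 1..G by descending size, ties broken by smallest
member sample id, so labels are reproducible.

## Filtering

Strict inequalities exactly as printed in the rules (`> 90 %` of samples
at depth, MAF `> 0.01`, drop samples `< 90 %` genotyped). MAF is
computed once, from allele counts over all non-missing calls of all
samples, *before* sample exclusion; no re-estimation pass follows. A
consequence documented in the filter report: if sample filtering drops
anybody, re-running the filter on the reduced data could change the MAF
verdicts, so idempotence is only guaranteed when no samples are removed.
Calls below the depth cutoff at surviving loci are masked to missing for
all downstream distances — the depth rule gates genotypes, not just
loci.

## Spatial statistics

Distance classes are half-open 1-m bins [k, k+1) from 0 to 18 m
(co-located pairs land in the first class); classes under a configurable
minimum pair count are flagged excluded. Three correlograms:

* **Genet identity.** Each sample is its genet's centered one-hot
  vector z_i; per class k, I_k = (N / W_k) Σ⟨z_i, z_j⟩ / Σ⟨z_i, z_i⟩
  over ordered pairs in the class — a join-count-equivalent multivariate
  Moran's I for a categorical variable. No closed-form moments are used:
  the permutation null carries all inference.
* **Mantel correlogram** (within-genet, and between genet
  representatives). Per class, the normalized cross-product between
  centered genetic *similarities* (negated centered distances) and the
  class indicator, so positive values mean genetically similar pairs at
  that distance — the sign convention matching how ramet-level
  correlograms are conventionally read. Constant distance matrices are
  flagged undefined. Genet representatives are the members nearest their
  genet's coordinate centroid (ties: lowest sample id).

Inference: one permutation of the coordinate rows yields one full
correlogram, preserving cross-class dependence; positions rather than
labels are permuted (marginally equivalent). Two-sided p = (b+1)/(n_perm+1)
with b the number of permutations with |I| ≥ |I_obs|; the significance
flag is p < 0.05, and the 2.5/97.5 percentile envelope is reported
alongside. At n_perm = 200 the per-class null rejection probability is
exactly 10/201 ≈ 4.98 %, which the calibration test checks empirically.

## Minimum spanning network

Nodes are genets represented by their medoid MLG (the member minimizing
summed within-genet distance; a real observed genotype, never a
consensus that no ramet carries). Kruskal construction on ascending
edges; at each weight level, every edge joining two components that were
distinct before the level is accepted, so tied alternative MST edges are
retained and the graph is a network, not one arbitrary tree. Relative
dissimilarity is the default (and configurable) edge distance.

## The synthetic generator

What it emulates: founder genotypes under Hardy–Weinberg with per-locus
minor allele frequencies uniform on [0.05, 0.5]; Mendelian outcrossing
and selfing; pseudo-annual clonal spread (each ramet lives one season,
daughters displaced by rhizome steps of truncated-normal length, mean
0.451 m, SD 0.215 m, uniform direction; mothers die, with a persistence
flag for generality; out-of-arena steps are clipped to the boundary);
grid sampling (nearest ramet within 0.5 m of each 1-m grid point, each
ramet captured at most once, equidistant ties to the lowest ramet id);
heritable somatic mutations on lineage edges (default 1e-4 per locus per
edge; SNPs flip to the other allele, SSRs step ±1 repeat with a
reflecting bound at 1); non-heritable per-call noise (allele dropout
1e-3, random allele error 5e-4, missingness 1e-3 — keeping mean
per-sample missingness near 0.1 %; note that with a few hundred loci a
single missing call is already ~0.3 % of one sample's calls, so
"negligible missingness" is a statement about the average); and
negative-binomial read depths (mean 45, dispersion 8) with a lognormal
per-locus amplification bias (log-SD 0.35) emulating
restriction-fragment bias.

Two calibrated presets fix the study conditions:

* **Validation family** (15 genets, 264 loci, 28 samples): two unrelated
  founders with 8 and 7 clonal ramets arranged as lineage chains, plus
  13 outcrossed half-sib offspring of the first founder by distinct
  unrelated sires. The 2 + 13 composition is an assumption (only the
  total of 15 genets is fixed by the validation design) and is recorded
  in the run manifest.
* **Main plot** (61 genets, 363 loci, 372 samples on a 21 × 21 grid):
  a fixed genet-size profile — dominant genet 126 samples (33.9 %),
  30 singletons, total 372 — placed by spatial region-growing: each
  multi-ramet genet expands from a seed cell into free neighbouring
  cells with probability proportional to its remaining quota, so large
  genets form wide compact patches; a boxed-in genet jumps to the
  nearest free cell. Growth claims double as the clonal lineage for
  somatic-mutation inheritance. The size profile is fixed rather than
  emergent so that the true genet count is exactly 61 for every seed,
  which is what the recovery checks require; the free-running
  `simulate_clonal_spread` walker is the mechanistic counterpart and is
  tested separately.

What the generator does **not** emulate — and hence what passing
recovery tests do not show about real data: linkage between loci, allele
frequency spectra skewed toward rare variants, relatedness among
founders beyond the designed half-sib family, seed-dispersal kernels and
recruitment dynamics, read-level artefacts (mapping error, allele-
specific bias within a locus beyond dropout), and batch structure in
depth or error rates. The presets produce between-genet distances whose
bulk is larger relative to the locus count than a natural population
with many rare alleles would show; the within/between separation — the
property the method needs — is emulated faithfully, the absolute scale
of the between mode is not.

## Numerical and reproducibility choices

Distances for SNP data use an exact integer fast path (biallelic IAM
equals the absolute dosage difference) verified against the general
multiset path in the tests. All randomness flows through
`numpy.random.Generator`; the pipeline fans a single seed into per-stage
child seeds via `SeedSequence.spawn`, so stages can be re-run in
isolation and identical config + seed reproduces every artifact, byte
for byte for `report.json`. Problem sizes in the test suite are chosen
to keep the whole suite fast while leaving every statistical check
well-powered: 100 seeds for the validation-family recovery, 25 for the
main-plot recovery, 200 seeds × 200 permutations for the correlogram
calibration.

## Known limitations

* The plateau estimator needs a genuinely bimodal histogram; sparse
  data (few samples or few loci) can leave the between-genet component
  too thin for mode detection, in which case the package refuses rather
  than guesses.
* Probabilistic clone-calling (p_sex-style statistics) and
  genotype-likelihood error models are out of scope; the threshold is a
  hard boundary.
* The identity correlogram's I values are comparable across classes
  within one analysis but are not calibrated to any closed-form scale;
  only the permutation-based significance should be interpreted.
* SSR fragment-length-to-repeat-score conversion is the caller's
  responsibility; the stepwise distance consumes repeat scores.
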