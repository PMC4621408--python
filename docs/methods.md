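# Methods

`microsync` reimplements, as one tested pipeline, the standard analysis
chain for a temporally resolved freshwater 16S survey: an OTU count
table over 81 samples (9 sites x 9 sampling months) is filtered,
rarefied, and analysed for (i) alpha/beta diversity and sample staging,
(ii) genus-level temporal synchrony, and (iii) stage-specific OTU
co-occurrence networks with module detection and cross-stage tracing.
Because no raw sequencing data is available for the original survey,
the pipeline ships a synthetic-data generator with planted ground truth;
every claim the test suite makes is a recovery or calibration statement
about that generator, not about the original lake.

## Preprocessing

* **Low-abundance filter.** An OTU is kept iff its total count over all
  samples is *strictly greater* than `min_fraction` x the grand total
  (default `1e-5`, i.e. 0.001% of all reads).
* **Lineage exclusion.** OTUs whose Greengenes-style lineage carries a
  given name at a given rank are dropped; the default use removes the
  class `Chloroplast`, which in that taxonomy collects eukaryotic
  plastid reads. Matching is exact on the prefix-stripped name.
* **Rarefaction.** Each sample is subsampled *without replacement*
  (multivariate hypergeometric) to a common depth; samples below the
  depth are dropped with a warning rather than padded. The depth is a
  required parameter — the appropriate value depends on the survey's
  sequencing effort and should sit on the plateau of the rarefaction
  curves (the drivers use 20,000 of a simulated 50,000).
* **Rank aggregation.** Counts are summed into taxa at a chosen rank.
  OTUs unassigned at that rank aggregate under their most specific
  assigned prefix (`unclassified <family>` etc.), so unclassified
  genera of different families — common among dominant freshwater
  lineages — remain distinct taxa.

## Diversity and ordination

Alpha metrics: observed species; Shannon entropy in **bits** (log base
2); Gini–Simpson `1 - sum p_i^2`; Faith's PD as the branch length of the
minimal rooted subtree spanning the observed tips **and the root** (the
"whole tree" convention that matches the metric's usual name in QIIME
output). Beta metrics: Jaccard distance on presence/absence, and
**unweighted** UniFrac — the fraction of observed branch length leading
to tips of exactly one of the two samples, ignoring branches with no
observed descendants.

PCoA applies Gower double centering to `-d^2/2` and reports the full
eigenvalue spectrum; axes with non-positive eigenvalues are omitted from
the coordinates and no Lingoes/Cailliez correction is applied, so the
reported negative eigenvalues are the diagnostic for non-Euclidean
input. UPGMA uses average linkage with merge height = half the average
inter-cluster distance (the ultrametric convention, so cophenetic
distances reproduce an ultrametric input exactly); ties are broken by
the lexicographically smallest member pair, which makes dendrograms
reproducible across runs and platforms.

## Permutation statistics

All permutation p-values use the add-one estimator
`p = (b + 1) / (n + 1)`, whose smallest attainable value at `n = 9999`
permutations is `1e-4`; that floor is what a permutation test reports
when the observed statistic beats every resample.

* **PERMANOVA** is one-way (a single factor at a time — month, site or
  stage), using Anderson's pseudo-F computed directly from squared
  distances: `SS_total = sum d_ij^2 / N`, `SS_within` summed per group,
  `F = (SS_between/(a-1)) / (SS_within/(N-a))`. `R^2` is
  `SS_between/SS_total`. Permuted statistics within `1e-10` relative of
  the observed count as ties (hits), which keeps degenerate inputs
  (all-equal distances) at `p = 1`.
* **Mantel** correlates strictly-lower-triangle entries and permutes
  rows and columns of the second matrix jointly; the default
  alternative is two-sided on `|r|`.
* Both tests also offer `method="exact"` (full enumeration of label
  permutations) for very small N; the test suite uses it against an
  independent enumeration oracle.
* **Kruskal–Wallis screen**: per-taxon tie-corrected H with the
  chi-square approximation (via `scipy.stats.kruskal`), Bonferroni
  correction by the number of taxa actually tested, capped at 1;
  constant taxa report `H = 0, p = 1` instead of erroring.

## Genus synchrony

The monthly abundance of genus G is
`Abund[G, T] = log10(1 + sum_s R_{G,T,s})`, the log of its summed
rarefied counts over the sites sampled in month T. The +1 pseudocount
makes months with zero reads well-defined; both the aggregation across
sites (`sum`/`mean`) and the log base are configuration options, since
the convention admits either reading. Profiles are standardized per
genus (`Z = (Abund - mean) / sd`, sample sd); genera with zero temporal
variance are flagged degenerate, set to zero rows, excluded from
fitting, and assigned to the nearest final center afterwards.

Clustering is K-means (Lloyd, Euclidean on the 9-dimensional Z rows)
with 100 random data-point initializations, keeping the restart with
the smallest within-cluster SS (`sklearn.cluster.KMeans` with
`init="random", n_init=100`). Model selection uses the within-SS /
between-SS ratio as a function of k; the recommended k is the one with
the largest *relative* drop of the ratio (for four planted seasonal
archetypes this sits at k = 4). Cluster summaries report each cluster's
share of total reads and its representatives — the smallest prefix of
members, by descending abundance, that strictly exceeds half of the
cluster's reads.

## Co-occurrence networks

Per stage (group of samples): OTUs present in fewer than half of the
stage's samples are removed (`presence >= ceil(0.5 x group size)`, so 4
of 9 is removed and 5 of 9 kept); Pearson correlations are computed on
per-sample **relative abundances** (so sample depth cancels);
zero-variance OTUs are dropped with a warning. An undirected signed
edge joins two OTUs iff `|PCC| >= threshold`; isolated nodes stay in
the node set. The fixed study-wide threshold is 0.90; alternatively the
threshold can be chosen on a grid (default 0.50–0.98 step 0.02) by
maximizing the `r^2` of a least-squares line on `log10 N(k)` vs
`log10 k` (raw, unbinned degree histogram, k >= 1) — the scale-free
criterion; ties prefer the larger (sparser) threshold. Network density
is reported as mean degree `2E/N`, with the literal `E/N` available,
since "average edges per node" admits both readings.

## MCODE modules and tracing

Vertex weight = core-clustering coefficient: the order k of the highest
k-core of the vertex's closed neighborhood times that core's density.
Complexes grow greedily from the highest-weight unvisited seed,
breadth-first over unvisited neighbors with weight `>= seed weight x
(1 - vwp)`; defaults are the Cytoscape plugin's (`vwp = 0.2`, haircut
on, fluff off, 2-core required). Haircut iteratively removes members
whose induced degree falls below 2 (never a member with degree >= 2);
edge signs are ignored for topology. Modules are ranked by average
within-module degree (descending, ties by size then seed id); the
native density x size score is reported alongside. Tracing projects a
module's member set into each stage's network and reports retained
members, induced edges, the edge-retention ratio relative to the source
module (which can exceed 1 if a stage gains edges), and first
neighbors. Family-level module composition uses the same
most-specific-prefix labelling as rank aggregation.

## Synthetic data generator

The generator emulates the survey design: 81 samples = 9 sites x 9
months (Jan, Mar–Jun, Aug–Oct, Dec), ~600 OTUs in 120 genera, counts
drawn multinomially at 50,000 reads per sample (fixed-depth counts make
rarefaction a near no-op, so pipeline tests isolate the downstream
math; overdispersed counts would only blur the planted structure).
Community structure has four layers:

1. **Base abundances**: per-genus log-normal (log10 sd 1.0), split
   among the genus's OTUs by a Dirichlet draw — a few taxa dominate, as
   in real bacterioplankton communities.
2. **Seasonality**: each genus follows one of four phase-shifted cosine
   archetypes (peaks in Apr/Oct/Jan/Jul, amplitude 1.0 log10 units),
   the planted truth for synchrony recovery.
3. **Noise**: a per-OTU-per-month term (log10 sd 0.1), a per-genus site
   effect (sd 0.1) and a per-OTU per-sample term (sd 0.3). Most OTU
   noise is placed at the *sample* level deliberately: month-level
   noise is shared across the sites of a month, and within a two-month
   stage it has only two effective observations, so a large month-level
   component would manufacture spurious high sample correlations
   between unrelated OTUs — background correlation is meant to be ~0.
4. **Planted modules**: per seasonal stage, 2 blocks of 10 "bloom"
   OTUs, abundant inside their stage (base weight 60x a typical OTU)
   and ~20x rarer outside it. Within the stage, each sample draws a
   block factor f and each member a latent score
   `z_i = sqrt(rho) f + sqrt(1-rho) e_i` (`rho = 0.95`); the member's
   abundance is scaled by the *linear* multiplier
   `1 + 0.5 x clip(z_i, ±1.96)`. A linear (rather than log-normal)
   multiplier is used because Pearson correlation survives linear maps:
   a log-normal factor provably caps the realized abundance PCC near
   0.92 regardless of its scale, below the 0.9 edge threshold the
   networks use. The winsorization keeps the multiplier positive
   without skewing it.

Realized in-block PCC is still slightly below the latent 0.95 (compositional
closure and multinomial noise), and the sampling sd of a correlation at
n samples is ~(1-r^2)/sqrt(n-3), so network/module recovery is
evaluated at ~40 samples per stage (20 sites) — at the survey's own 9
sites a two-month stage has 18 samples and a 0.9 threshold sits within
sampling noise of the planted correlation. The generator does **not**
emulate: compositionality-aware association structure, overdispersion
beyond the multinomial, chimeras/PCR bias, or taxonomically realistic
lineage names. Passing recovery tests therefore demonstrate the
pipeline's correctness on data satisfying its assumptions, not
performance on real surveys.

`make_permanova_fixture` builds Gaussian point clouds with a
between-group mean shift of `delta` within-group sd (Euclidean
distances): `delta = 0` is an exchangeable null used for calibration;
`delta = 20` guarantees the observed pseudo-F beats every permutation,
saturating the add-one floor. `make_archetype_profiles` draws genus
profiles directly as archetype curve + N(0, 0.3) noise — the
synchrony-recovery condition without the count layer.

## Numerical choices and degenerate inputs

* Permutation tie tolerance `1e-10` relative; exact enumeration for
  n <= ~7 objects.
* K-means restart ties resolve to the first (lowest-index) restart;
  UPGMA and MCODE ties break lexicographically.
* Zero-variance rows/OTUs: flagged and excluded (synchrony), dropped
  with a warning (PCC), or reported as `H=0, p=1` (Kruskal–Wallis) —
  never silent NaNs.
* Degree power-law fits require >= 3 distinct positive degrees and
  error otherwise (a regular graph has no fittable distribution).
* The pipeline derives per-stage seeds from one global seed via
  `numpy.random.SeedSequence(seed, spawn_key=(stage_index,))`, so each
  stage is independently reproducible and the log records every seed.

## Problem sizes

Default driver scale (81 samples, ~680 OTUs, depth 50,000, 9999
permutations, 100 K-means restarts) runs the full chain in well under
two minutes on one CPU; recovery tests use 10–20 seeds at the sizes
stated above.

## Known limitations

* Plain PCC with a hard threshold is blind to compositional artefacts;
  SparCC-style measures are out of scope by design.
* One-way PERMANOVA only; no stratified/multi-factor designs.
* The scale-free criterion and the fixed 0.90 threshold are both
  provided, but the relationship between them (which the original
  protocol leaves unexplained) is the user's choice.
* UPGMA is O(n^3) as implemented — fine for tens to hundreds of
  samples, not for thousands.
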