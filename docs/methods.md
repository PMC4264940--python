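# Methods

This note documents the models implemented in `barcodelim`, the defaults
and why they were chosen, what the simulator does and does not emulate, and
the numerical decisions a user auditing results will want to know.

## Distances (`barcodelim.distances`)

Pairwise distances are computed on the proportion scale under three models:
the raw mismatch proportion p; JC69, d = −(3/4)·ln(1 − (4/3)p); and K2P,
d = −(1/2)·ln(1 − 2P − Q) − (1/4)·ln(1 − 2Q), with P and Q the transition
(A↔G, C↔T) and transversion proportions. Sites containing `N` or `-` in
either sequence of a pair are excluded for that pair (pairwise deletion);
IUPAC ambiguity codes other than N are folded to N on input. A pair whose
log arguments are non-positive raises a saturation error naming the pair
rather than returning NaN — a saturated barcode pair indicates data that
should not be pushed through gap-based delimitation silently.

## ABGD (`barcodelim.abgd`)

The prior grid is the geometric series P_k = P_min·(P_max/P_min)^(k/(n−1)),
default 10 values over [0.001, 0.1] — the grid whose interior values are
0.0359, 0.0215, 0.0129, 0.00774, 0.00464, 0.00278, 0.00167.

Gap inference on the sorted pairwise distances: the prior limit is the
largest observed distance ≤ P (the largest distance still attributable to
intraspecific divergence under the prior). A candidate gap between
consecutive sorted distances qualifies when its lower edge is at or above
the prior limit and its width exceeds X (default 1.5) times the local
spacing scale. The scale is the **median spacing between consecutive
distinct distances** in a window of max(3, ⌈0.1·m⌉) ranks on either side of
the candidate, the candidate itself excluded, with ties identified at a
1e-9 relative tolerance. This choice is deliberate and load-bearing:

* a tie-diluted *mean* lets a single 1/L quantum step in the sparse tail of
  intraspecific divergences qualify as "the gap" (oversplitting);
* the window *maximum* is dominated by genuine deep-phylogeny gaps above
  the barcode gap and suppresses the true gap (undersplitting);
* the mean over distinct spacings is shrunk by near-coincidences between
  distances contributed by groups diverging at different scales.

The median over distinct spacings is robust to all three effects. The
first qualifying gap (ascending) is the barcode gap; the initial partition
connects specimens with d ≤ the gap's lower edge and takes connected
components; with no qualifying gap the data form one OTU. The recursive
partition re-applies the same search inside every group of ≥ 3 members
until nothing splits; sub-structure that is smeared into the global
distance continuum becomes locally detectable, so recursion only adds
splits. On a fixed dataset the initial OTU count is non-increasing in P.

On strongly irregular *continuous* distance spreads the rule can still
declare a gap (spacing fluctuations are roughly exponential); this mirrors
the known sensitivity of gap-based delimitation rather than a defect to be
papered over, and the recursive counts in real scans are typically larger
than initial counts for the same reason.

## GMYC (`barcodelim.gmyc`)

On an ultrametric tree (root-to-tip spread ≤ 1e-6 relative), a threshold
height T classifies branches: crossing branches define the OTUs,
everything above is a Yule diversification process, and each subtree below
is an independent coalescent process. Between consecutive branching events
the total rate is b_i = λ₁·k_i^p₁ + λ₂·Σ_j [n_ij(n_ij−1)]^p₂, where k_i is
the number of diversification lineages — all crossing branches above T,
and the (constant) number of OTUs below it, the species lineages
persisting to the present — and n_ij the lineage count of coalescent
process j. The log-likelihood is Σ ln b_i − Σ b_i x_i with the ln-term
counted once per branching event (the root is conditioned on, the final
tip-ward interval contributes only its exponential factor; intervals of
zero length from simultaneous events contribute their ln-terms). The null
model is one process over the whole tree, b_i = λ·[n_i(n_i−1)]^p.

Fitting: candidate thresholds are midpoints between consecutive distinct
node heights plus one candidate below the shallowest node; for each
candidate, (log λ₁, p₁, log λ₂, p₂) are optimized by L-BFGS-B with bounds
λ ∈ [1e-8, 1e8], p ∈ [0.01, 10], from three deterministic starts (a
moment-matched start — events divided by lineage-time — and two fixed
perturbations). Exponent placement [n(n−1)]^p follows the original mixed
model and was verified against hand-computed likelihoods on 4-tip trees.
The likelihood-ratio statistic 2·(logL_GMYC − logL_null) is referred to χ²
with 3 d.f. (the software convention that the threshold is not a free
parameter); the d.f. is an argument for users who prefer mixture
references. Confidence sets are all candidates within 2 log-units of the
optimum, summarized as min–max cluster/entity counts. Cluster = OTU with
≥ 2 tips; entities = all OTUs. Run GMYC on haplotype-collapsed data:
zero-length cherries carry no information about the transition and inflate
the coalescent rate estimate.

The multiple-threshold variant greedily splits the OTU whose subdivision
at its crown most improves the log-likelihood, stopping when the gain is
≤ 2 log-units (about one AIC-worth per added threshold) or a threshold cap
is reached; it can only refine the single-threshold partition.

Time-unit invariance: rescaling all branch lengths and re-optimizing
leaves the partition and (up to optimizer tolerance) the LR unchanged, as
λ absorbs the scale; this is checked in the test suite.

## RESL-style clustering (`barcodelim.resl`)

Single linkage connects specimens with d < t (default t = 0.022,
p-distance, the BIN convention). Every pre-cluster of ≥ 4 members is
refined by Markov clustering of the similarity graph s = max(0, 1 − d/t):
column-normalize; iterate expansion (matrix power e = 2) and inflation
(entrywise power r = 2.0, renormalize) until the largest entry change is
< 1e-8 (cap 200 iterations); entries < 1e-12 are pruned for stability.
Self-loops are set to each column's maximum off-diagonal similarity, which
makes the clustering invariant to uniform rescaling of the similarities.
Clusters are read off attractor rows; refinement can split but never
merges across pre-clusters. This approximates the published refined
single-linkage procedure; BIN identifiers and the BOLD server's exact
behaviour are out of scope.

## Consensus (`barcodelim.consensus`)

Comparison units are the connected components of the union graph in which
each method contributes edges between its co-clustered specimens — the
join of the three partitions — so every OTU of every method lies inside
exactly one unit. A unit is FULL if the three induced sub-partitions are
identical, PARTIAL if exactly two are (the agreeing pair is the majority),
DISCORDANT otherwise. "Two methods generated similar results" is
implemented as exact identity of induced sub-partitions; anything weaker
is not testable from the protocol's definitions. OTU bookkeeping: FULL
units contribute their agreed OTU count, PARTIAL units their majority
count (a `finest` alternative is exposed), DISCORDANT units one each.
The finest competing sub-partition of a PARTIAL unit is carried forward
as the split candidate for resolution.

## Resolution (`barcodelim.resolution`)

FULL units pass through; DISCORDANT units collapse to one OTU each (the
methods' disagreement is the reason not to split). For each PARTIAL unit,
sister pairs of the candidate split are read innermost-first off the guide
tree (repeatedly pairing the two groups whose joint MRCA subtends the
fewest tips). For each pair: sympatric (region sets intersect) → the split
is kept; allopatric → merged, on the conservative presumption that
divergence between allopatric lineages is phylogeographic variation within
one taxon. A lone specimen allopatric from its multi-member sister is
merged into it by the same rule and flagged as a singleton merge. In
mixed multi-way units, an allopatric decision fuses only the
phylogenetically closest live group on each side, never collapsing an
earlier kept split. Pure diagnostic sites (state sets disjoint between
groups, ambiguous positions ignored, 1-based) and monophyly on the guide
tree are reported per decision but are decision-neutral — in practice they
flag nearly every boundary and so cannot arbitrate. Sympatric keeps carry
a standing warning that shared region labels may hide microallopatry.

Guide trees: neighbor-joining (via scikit-bio) with midpoint rooting by
default; any rooted tree covering the specimens may be supplied instead
(rooting convention is the user's choice then). The final partition, its
per-category bookkeeping (FULL + resolved PARTIAL + DISCORDANT = total),
and a seeded OTU accumulation curve (mean ± sd of cumulative distinct OTUs
over random specimen orderings) complete the outputs.

## Simulator (`barcodelim.simulate`)

The generator emulates the data regime the protocol assumes: a Yule
species tree conditioned on the species count; within each species a
Kingman coalescent with pairwise rate 2/θ so that two conspecific lineages
diverge by θ in expectation, censored at species boundaries and continued
in ancestral species (deep coalescence and hence gene-tree/species-tree
discordance can occur across short internodes); K80 sequence evolution via
closed-form transition probabilities with κ = 4 over 654 sites, so
simulated divergences match the K2P estimator in expectation (model
misspecification is deliberately not part of the fixtures). Per-species
sampling is either fixed or drawn from a geometric law with q = 0.26,
making ~46% of species singletons or doubletons — the rarity profile of
real barcode surveys. Each species holds a private region; with
probability `sympatry_fraction` a species additionally shares one region
with its sister clade, exercising the sympatry rule in both directions.

Internal split heights are mapped linearly onto [`min_split_height`,
`root_height` = 0.2 substitutions/site]: the shallowest split is pinned to
the preset depth and the root stays clear of distance saturation, at the
cost of distorting the Yule depth distribution (rank order is preserved).
Presets: `separated` (min split 0.05, θ = 0.002 — the shallowest
interspecific divergence is ~25× the coalescent depth, so a barcode gap is
essentially guaranteed) and `hard` (min split 0.008, θ = 0.004 — scales
overlap and the engines start to disagree). All randomness flows through
one `numpy.random.Generator(PCG64(seed))`; outputs are byte-identical
across runs and platforms for a fixed config.

What passing recovery tests on `separated` data shows: the engines and the
consensus/resolution plumbing are correct under the protocol's own
assumptions. What it does not show: robustness to introgression,
incomplete lineage sorting at barcode-gap scales, alignment error,
heterogeneous θ across species, or non-K80 evolution — real surveys must
treat the output as hypotheses, not species.

## Validation experiment sizes

The packaged experiments use sizes that exercise the claims while keeping
the suite quick to run: 50 seeded replicates of 8 species × 4 tips for
parameter recovery (each engine and the full pipeline must recover the
true partition in ≥ 90%); 100 single-population coalescent trees of 20
tips for the GMYC type-I error (≤ 10% rejections at α = 0.05); 100 random
≤ 30-specimen instances for gap-finder/brute-force equivalence; 1000
random partition triples of ≤ 12 specimens for consensus equivalence;
1000 random site-pattern counts for closed-form distance agreement at
1e-9. ABGD runs at the grid prior 0.0215 ≈ 10×θ in these experiments: the
prior is by definition an upper bound on intraspecific divergence, so it
must sit above the coalescent tail (~5×θ) while staying far below the
shallowest interspecific divergence (~0.1). The pipeline's default
operating prior is 0.01 (nearest grid value 0.00774), matching common
practice on real COI data.

## Known limitations

* ABGD here is a documented re-implementation of the gap heuristic, not a
  bit-exact port of the reference C code; web-server output files will not
  match byte-for-byte.
* RESL is an approximation; BIN identifiers are out of scope.
* GMYC assumes the supplied tree is correct; tree uncertainty is not
  integrated (no Bayesian/bGMYC variant).
* Sympatry is only as good as the region labels; the package consumes
  labels and does not geocode coordinates to regions.
* DISCORDANT units always count as one OTU; with more than three methods
  the categories would need redefinition (not supported).
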