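# Methods

This note documents the models, parameter choices, numerical
conventions and limitations of `pipetarget`. Notation: P denotes a
pleiotropic p-value combined across diseases, R² an LD strength,
γ the random-walk restart probability, J the number of retained
predictors and K the number of prioritizable genes.

## SNP scoring and LD expansion

Lead SNPs are retained at P strictly below the genome-wide threshold
T = 5×10⁻⁸ and scored `S_SNP = R²·(log₁₀((1−P)/P) − log₁₀((1−T)/T))`,
which is zero at the threshold, strictly decreasing in P and linear in
R². Duplicate rsids collapse to the smallest p. LD proxies at
R² ≥ 0.8 inherit the combined p-value of their lead — the proxy's own
per-disease statistics are upstream of this package — and LD enters
only through the R² factor. A proxy reachable from several leads keeps
the assignment that maximizes its score, consistent with the maximum
scoring used throughout the gene-evidence layer. Chromosome names are
normalized by stripping a `chr` prefix; positions are 1-based.

## Gene evidence

*nGene*: a gene is supported by any retained SNP within ±20 kb of the
gene body (window configurable; the choice of gene body over TSS is a
convention, and rankings are insensitive to moderate window changes
because scoring is max-based). Score = max S_SNP over supporting SNPs.

*cGene*/*eGene*: per evidence dataset (one tissue or cell type), the
link strength between SNP and gene is reduced to a rank via the
empirical CDF over **all** SNP–gene pairs of that dataset, so that
`S_gene = max S_SNP · eCDF(x)`. For eQTL datasets the strength is a
p-value and x = −log₁₀(p); Hi-C interaction scores are already
"larger = stronger" and are used directly. The eCDF counts with ≤
(right-continuous), hence values in (0, 1]; scores are invariant under
any strictly increasing transform of the strengths. Datasets with
fewer than two pairs are rejected (the eCDF would be degenerate).

## Network propagation

The interaction network keeps edges at combined confidence ≥ 700,
symmetrized and deduplicated, isolated nodes dropped. Confidence is a
filter, not a weight (a weighted mode exists behind a flag). The
adjacency is normalized symmetrically, W = D^(−1/2)AD^(−1/2); a
column-stochastic D⁻¹A mode is available via configuration. Each
seed-score set is normalized to sum 1 and diffused by
`P_t = (1−γ)WP_{t−1} + γP_0` with γ = 0.75, tolerance 10⁻¹⁰ (L1) and
an iteration cap of 10⁴; the stationary vector is the affinity
predictor. Because (1−γ)·‖W‖ < 1 the iteration is a contraction and
agrees with the closed-form solve γ(I−(1−γ)W)⁻¹P₀ to < 10⁻⁸,
which the test suite verifies on random graphs. Note that under the
symmetric normalization the stationary vector's total mass is not
exactly 1; only the stochastic mode conserves mass. Downstream scoring
is rank-based per predictor, so the normalization choice affects
rankings only mildly.

## Predictor selection

A random forest (1000 trees by default; 200 inside the pipeline's
bundled runs, which is ample at fixture scale) is trained to separate
clinical proof-of-concept targets (pooled across the disorder system's
diseases) from simulated negatives. Importance is the out-of-bag
permutation decrease in accuracy, averaged over trees, repeated across
seeded replicates; a cGene/eGene predictor is retained when its median
importance reaches the proximity (nGene) baseline's median, and the
baseline itself is always retained. Trees are grown with
`max_features=1`: with strongly correlated predictors, larger feature
subsets let one predictor absorb all splits and drive the others'
permutation importance to zero, turning the retention rule into a
coin flip; forcing single-feature splits gives every informative
predictor split opportunities so importance reflects each predictor's
own signal. The forest is only a filter — the final scoring is
unsupervised.

## Credit scoring

Per retained predictor, affinities are converted to P-like values by
the gene-wise eCDF (values in [1/K, 1], large = good). Per gene,
`x = −2 Σ_j ln P_j` is referred to the **lower** tail of χ²(2J):
because the P-like values are large for strong genes — the reverse of
textbook Fisher inputs — a top gene has x near 0 and a combined value
CP near 0, and the whole chain eCDF → x → lower-tail CDF → −log is
monotone, so larger affinities always mean larger credit. The lower
tail is used literally and no upper-tail mode is offered, to keep a
single self-consistent convention. CP is computed in log space
(`chi2.logcdf`) to avoid underflow; a gene whose x is exactly 0 (the
column max of every retained predictor) has CP = 0 exactly, which is
floored at the smallest positive double and flagged. −log₁₀ CP is then
min–max rescaled onto [0, 10]; ranks break ties by ascending gene id.

Degenerate regime worth knowing about: with J = 1 the top-ranked gene
hits the CP = 0 floor by construction, and its floored −log₁₀ CP
(≈ 323) compresses all other credits toward 0. Rankings are unchanged
(the chain is monotone), but amplitude-sensitive consumers — the
crosstalk score and the weighted LPA running sum — lose resolution.
With J ≥ 2 diverse predictors no gene tops every column and the credit
spectrum is smooth; at the scale this method is meant for (tens of
tissue-specific predictors, ~15k genes) the degenerate case cannot
occur.

## Pathway crosstalk

Pathway interaction lists are merged into one gene network (edge
provenance retained). Node score = credit − t. The threshold t is
scanned over midpoints of consecutive credit order statistics,
descending from the k = ⌈1.1·target⌉ largest credit, and the accepted
solution is the largest found subnetwork not exceeding that cap; this
keeps the terminal set commensurate with the target size. For fixed t,
positive-score nodes are terminals; Dijkstra with the cost of entering
node v equal to max(0, t − credit(v)) gives the terminal metric
closure, whose minimum spanning tree is expanded back to graph paths;
on the resulting Steiner tree the exact maximum-score connected
subtree is taken by dynamic programming (best(v) = score(v) + Σ
positive best(child)), which generalizes iterative pruning of
negative-score leaves to dropping whole unprofitable branches.

Significance: credits are shuffled within degree-quantile bins
(10 bins), the subnetwork is re-found at the observed t, and its total
node score recorded; the p-value is the upper tail of a normal fit to
the permutation null — far below the 1/n resolution of counting when
the signal is strong — with the empirical (1+k)/(1+N) count reported
alongside. The graph and hence the degree sequence are untouched.

## Evaluation analyses

*Proof-of-concept targets*: genes with a drug record at development
phase ≥ 2 for the disease (exact indication string match).

*Simulated negatives*: the druggable landscape (any gene with any drug
record, any phase, any indication) minus the disease's indicated genes
and their direct interaction neighbors. The full eligible pool is
returned unless a subsample size is requested.

*Benchmarking AUC*: Mann–Whitney with midrank ties; equals the
probability that a random positive outranks a random negative.

*LPA*: genes are ranked by credit (ties by id); the running score
rises by credit^w (w = 1) at set members, normalized by the members'
total weight, and falls uniformly otherwise. ES is the maximum
positive deviation, the leading edge the members at or before the
peak, coverage the recovered fraction of the requested set. The null
re-draws size-matched gene sets (default 50,000 permutations;
CLI-reducible); NES divides ES by the mean positive null ES and
p = (1 + #{null ≥ ES})/(1 + N), so p is never 0. FDR across diseases
is Benjamini–Hochberg, floored at 1/N so that
PICT = log₁₀(NES·Coverage/FDR) stays finite; PICT is reported missing
when NES ≤ 0 or coverage = 0. A caveat inherited from weighted GSEA:
when one gene's weight dominates the column (the J = 1 floor case
above), random sets containing that gene reach ES ≈ 1 and the planted
set's p degrades to a few percent even when the ranking is essentially
perfect.

*Disease relationships*: diseases sharing leading-edge
proof-of-concept targets are joined with weight = shared count, and a
minimum spanning tree on cost 1/weight keeps the strongest-sharing
backbone; isolated diseases remain as nodes.

*Modules and enrichment*: spin-glass community detection with
simulated annealing (igraph's implementation of the
Reichardt–Bornholdt model; γ = 1, geometric cooling 0.99, per
connected component, components of ≤ 3 nodes taken as single modules
since the annealer is undefined there; seeded and deterministic).
Enrichment is a one-sided (greater) Fisher exact test — the p-value is
the exhaustive hypergeometric upper tail — with a Haldane–Anscombe
0.5 correction for zero cells in the odds ratio, an adjusted Woolf
logit 95% CI (0.5 added to every cell in the variance for
finiteness), and BH FDR across terms. The enrichment universe is the
crosstalk network's gene set, the narrowest defensible choice.

*Supra-hexagonal map*: a centered hexagonal lattice with r rings holds
3r(r+1)+1 hexagons (r = 3 → 37, r = 5 → 91), indexed center-outward
then around each ring. Unless given, r is the smallest value with at
least 5√N units. Training is a two-phase batch SOM (Gaussian
neighborhood on lattice distance; rough phase radius r → 1, finetune
1 → 0; 50 epochs each; seeded uniform init in the data range).
Clusters come from Ward linkage on the codebook with a contiguity
repair pass that reassigns hexagons disconnected from their cluster's
main component to the nearest adjacent cluster. Targetability
overlays report, per hexagon, the fraction of mapped genes flagged
targetable (empty hexagons are missing, not 0) and per cluster the
gene-level fraction (not the mean of hexagon fractions).

## Synthetic study design

The generator emulates every input class with one seeded RNG, so a
config + seed reproduces a bundle byte for byte. Defaults: 200 genes
on 4 chromosomes (100 kb spacing), 12 lead SNPs with 3 proxies each
(R² ~ U(0.8, 1), plus one sub-threshold decoy proxy per lead), 2 Hi-C
and 2 eQTL datasets, a preferential-attachment interaction network
(m = 3) with confidences in [700, 1000) plus sub-threshold decoy
edges, 20 planted targets, signal strength 0.8, 3 diseases.

Planted signal enters every layer the way the method expects real
signal to: lead SNPs anchor near planted genes with probability equal
to the signal strength (p-values 10^−U(8,30); background leads
10^−U(7.5,10)), and half of the signal leads are *distal* — placed
30–70 kb away, outside the proximity window, so their targets are
reachable only through the regulatory-link evidence, which is the
scenario Hi-C/eQTL evidence exists for. Each evidence dataset draws
its own "active" subset of planted genes (p = 0.7), emulating
tissue-specificity; active links have p-values U(0,1)^(1+9s) (eQTL) or
exponential scores scaled by (1+9s) (Hi-C), identical to background at
s = 0 — the indistinguishability at zero signal is KS-tested. Planted
genes form a community in the interaction network (pairwise edges at
0.4) and carry phase ≥ 2 drug records for overlapping subsets of the
simulated diseases; 80 background genes get decoy records so the
druggable landscape strictly contains the disease targets.

The pathway layer is a ring of locally dense modules: the planted
module and 13 background pathways all share one topology (member ring
plus chords at 0.25), consecutive modules share a single linker gene.
Two properties matter: node degree carries no information about the
planted signal (so degree-binned permutation can actually break the
credit–module association), and the merged network has a large
diameter (so scattered nulls pay real connection costs). Early, denser
designs produced diameter-2 graphs on which the permutation test is
powerless by construction, observed signal or not.

What the fixture does **not** emulate: realistic LD structure or
genome geography, correlated eQTL effects across tissues, the heavy
right tail of real PPI degree distributions, indication ontologies, or
the scale of real studies (~15k genes, ~100 predictors). Passing tests
demonstrate the machinery recovers planted signal under faithful but
idealized conditions; they say nothing about biological validity on
real cohorts.

Problem sizes in the bundled runs (200 genes, 10⁴ LPA permutations,
10³ crosstalk permutations) were chosen so a full pipeline run
completes in seconds on one CPU while leaving every statistic far from
its resolution limits.

## Known limitations

- The lower-tail combination chain is self-consistent but singular at
  its top end (the CP = 0 floor); see the credit-scoring section.
- The permutation p-value from the normal fit assumes the null scores
  are approximately Gaussian; the empirical count p is reported for
  when they are not.
- LD proxies inherit their lead's combined p-value; with real
  summary statistics a proxy's own cross-disease evidence may differ.
- Predictor retention compares medians across replicates; with few
  replicates and near-equal importances the decision is noisy, and the
  pipeline proceeds with the proximity predictor alone in the worst
  case (with the degeneracy noted above).
- Exact-string indication matching; no disease-ontology mapping.
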