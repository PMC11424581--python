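# Methods

`rejuvenet` implements a multiscale network analysis of single-cell
rejuvenation experiments: quality control and clustering selection,
construction of profile-consistent transcriptional regulatory networks
(TRNs) under inhibition-dominant Boolean logic, master-regulator scoring by
activation simulation, selection of differentially active signaling
intermediates with TRN–signaling crosstalk extraction, and ligand–receptor
cell–cell interaction scoring. This note records the models, the defaults,
the numerical choices, and what the synthetic benchmarks do and do not
demonstrate.

## Inhibition-dominant TRN pruning

Inputs are a signed prior knowledge network (PKN) of TF→gene edges and a
booleanized differential-expression profile: genes with positive
log-fold-change map to state 1, negative to state 0. Genes with a
log-fold-change of exactly 0 carry no direction and are excluded (the
booleanization is defined only on signed changes). DE tables are first
filtered with the disjunctive rule |log-FC| > 0.25 OR expressed in more
than 10% of cells in *both* conditions; both comparisons are strict,
matching the "greater than" reading of the thresholds.

Under inhibition dominance, one active inhibitor switches a gene off no
matter how many activators point at it. An edge subset S is consistent
with the profile when, for every target g:

* state(g) = 1: S contains no inhibitor with an up-regulated source, and
  if S contains any edge into g, at least one is an activator with an
  up-regulated source;
* state(g) = 0: S contains an up-regulated inhibitor, or no up-regulated
  activator.

The pruner returns the lexicographically optimal consistent subset —
first maximize the number of explained genes (genes retaining ≥ 1 edge),
then the number of retained edges. Because no constraint couples two
targets, the problem decomposes per gene, and each per-gene subproblem has
a closed-form optimum; the implementation enumerates subsets exactly for
genes with at most 20 candidate in-edges and applies the equivalent closed
form above that, logging the split. Tests verify both solvers against a
global brute-force enumeration over all edge subsets on instances with up
to 12 edges. Sources that are not in the supplied TF universe are
discarded; self-loops are allowed and can explain a TF's own state. Genes
left with no edge are absent from the TRN, whose size N is the number of
unique TFs plus targets of retained edges.

## Master-regulator scoring

Each TF is scored by clamping it active in an otherwise undetermined
network and propagating: a node is 0 if any determined inhibitor is
active, else 1 if any determined activator is active, else undetermined.
Propagation runs a depth-first pass from the clamped TF (targets visited
in lexicographic order) followed by synchronous sweeps until a fixed point,
bounded by N sweeps. The synchronous sweep makes the result independent of
traversal order; the test suite checks the returned state against an
exhaustive fixed-point enumeration over {0, 1, undetermined}^N on small
networks, and verifies that node/edge-order permutations never change a
score. Cyclic inhibition can oscillate; nodes still changing at the sweep
bound are forced undetermined with a warning.

The score is the fraction of the *whole* network whose simulated state is
determined and matches the booleanized profile, counting the TF itself.
Three corner cases pin the definition down: the root of a fully
hierarchical consistent network scores 1.0; an end node that predicts only
its own up-regulated state scores exactly 1/N (hence the denominator is N,
not the reachable set); and a TF whose own booleanized state is 0 scores 0
outright — activating it cannot explain its observed repression, and this
global short-circuit is the only reading under which all three cases are
mutually consistent. Undetermined nodes never count as matches. TFs with
score ≥ 0.30 are classified as master regulators (the threshold is
inclusive). Cross-condition aggregation ranks TFs by mean score with
absent TFs counted as 0; because mean score and mean rank can disagree,
the per-condition mean rank is emitted as an additional column and the
full TF × condition matrix is exported for external clustering.

Network hierarchy is summarized by the Krackhardt score
H = 1 − (mutually reachable unordered pairs) / (pairs reachable in ≥ 1
direction), checked exhaustively against a reachability-matrix oracle on
all 4-node digraphs and on sampled 5-node digraphs.

## QC filtering and clustering selection

Per-cell metrics are the mitochondrial and ribosomal count fractions,
detected features, and total counts (prefix matching is case-sensitive;
choose the dialect per species). Filtering is conjunctive at ``nmads`` = 3
median absolute deviations (normal-consistency constant 1.4826):
pct_mito is fenced on the upper side only (low mitochondrial content is
never a damage signal), pct_ribo, log10(features) and log10(counts) on
both sides, plus a two-sided fence on the residuals of the least-squares
fit log10(features) ~ log10(counts). Cells with zero counts are removed
unconditionally. Degenerate spreads are handled explicitly: an
all-identical metric passes every cell, while a zero MAD on a
non-constant metric collapses the fence to the median, so anything off
the majority value (above it, for mito) is an outlier.

Clustering algorithms are a callback contract — any labelling of an
embedding qualifies as a candidate. Candidates are scored with the
Calinski–Harabasz index [B/(k−1)]/[W/(n−k)]; W = 0 maps to +inf so
zero-scatter partitions outrank every finite score, and k = 1 or k = n is
an invalid candidate. Ties break toward fewer clusters, then input order,
for determinism. The winner is kept unless it has more than 30 clusters,
in which case a caller-supplied coarse fallback partition is used
(the cap is inclusive: exactly 30 clusters is allowed).

## Signaling intermediates and crosstalk

Signaling-intermediate activity scores in [0, 1] per condition are inputs
produced upstream; missing values are first-class and never imputed. A
molecule is differentially active when its treated score is present and
> 0.70 and its control score is < 0.30 *or missing* (an absent control
score counts as inhibited); both tables must be non-empty. Both
thresholds are strict, so the rule is deliberately asymmetric: a molecule
active only in control is never selected.

Crosstalk extraction requires some TF to have outgoing edges in both the
TRN and the signaling network; without such a shared source the crosstalk
is absent even if the graphs touch at sink nodes. The two edge lists are
then concatenated and weakly connected components computed on the union;
a single component is taken whole, otherwise only the component containing
the intermediate. Edge directions and signs are preserved in the output;
only component membership treats the graph as undirected.

Overrepresentation analysis is the hypergeometric upper tail of the
query/set overlap against the background (sets are intersected with the
background first), BH-adjusted, flagged at q < 0.05. p-values are tested
against exhaustive enumeration of all query draws on small backgrounds,
and the null false-flag rate against simulation.

## Cell–cell communication

The interaction score of (sender type, ligand, receiver type, receptor)
is the product of the mean ligand expression over sender cells expressing
the ligand (count > 0) and the mean receptor expression over receiver
cells expressing the receptor; an empty expressing population scores 0.
Any non-negative expression matrix is accepted; raw versus normalized
input rescales scores but leaves percentile ranks unchanged under
monotone per-gene scaling. Significance is the fraction of stratum scores
strictly below the record's score, computed within each (sender, receiver)
stratum over the whole scaffold — ties share the lower rank, so a stratum
of identical scores has no significant interaction. The top decile
(significance ≥ 0.90) is significant within a condition; the reported
treated-unique set keeps treated records with significance strictly above
0.90 whose channel is not significant in control. A channel present but
non-significant in control still counts as treated-unique; records tied
exactly at the cutoff are excluded and surfaced in the log. Receptor–TF
compatibility filtering is accepted as an external keep-list hook rather
than computed.

## Synthetic data and what it shows

Every generator returns machine-checkable truth, and one integer seed
feeds a splittable per-operation generator, so adding a generator never
perturbs existing draws.

* **Planted networks** are rooted out-trees (Krackhardt hierarchy exactly
  1) whose profile is the forward simulation from the activated root;
  a chosen fraction of non-root nodes is then flipped. Inhibitory edges
  are placed only into leaves: a switched-off internal node would leave
  its subtree undetermined and no root could fully explain the network
  even at zero noise. The explained fraction is measured, not assumed —
  the PKN is pruned against the noisy profile, the root simulated, and
  matches counted over the full node set (flipped leaves drop out of the
  TRN but stay in the denominator).
* **Count matrices** are gamma-Poisson (variance μ + dispersion·μ², 0.5
  by default) at a base mean of 5 UMIs with 10% independent dropout and a
  multiplicative 2^lfc condition effect on each cell type's private DE
  genes (lfc is log2). The accompanying DE tables carry the generating
  parameters — planted lfc and the closed-form positive fraction
  (1 − dropout)·(1 − (1 + αμ)^(−1/α)) — not re-estimated statistics,
  because DE estimation is an upstream tool's job.
* **Intermediate tables** draw planted molecules in (0.70, 1] treated /
  [0, 0.30) control; decoys are mid-range in both conditions or missing
  in one.
* **Ligand–receptor experiments** share one baseline draw bit-for-bit
  between conditions, so a decoy's treated rank can never exceed its
  control rank and any decoy passing the treated decile is suppressed by
  the uniqueness filter; planted channels (default 2 of 50 scaffold
  pairs, ~50× the decoy expression) are silent in control. Under this
  construction recovery has precision = recall = 1 by design, which the
  suite confirms across 50 seeds.

These fixtures deliberately omit ambient RNA, doublets, batch effects and
cell-cycle structure (upstream concerns), and real PKNs are noisier and
denser than out-trees. Passing the recovery suites therefore demonstrates
correctness of the algorithms' semantics, not robustness to biological
confounders.

## Problem sizes and defaults

The benchmark suites use networks of 7–100 nodes, 200 master-regulator
recovery runs at ≤ 10% profile noise, 50-pair scaffolds over 50 seeds,
100 clustering-selection runs on 2–6 Gaussian blobs separated by ~12σ,
and exhaustive oracle enumeration up to 4-node digraphs (sampled at 5
nodes) — sizes at which the exact oracles remain enumerable while
exercising every code path. All thresholds (0.25/0.10 DE filter, 0.30 MR
classification, 0.70/0.30 intermediate activity, 0.90 communication
significance, 3 MADs, 30-cluster cap) live in `PipelineConfig`; upstream
tools' settings (e.g. hotspot cutoff 30 / percentile 70) ride along in
`PipelineConfig.passthrough` without interpretation.

## Known limitations

* The pruner's lexicographic objective (explained genes, then edges) is
  one defensible formalization of profile-consistent pruning; other
  objectives (e.g. edge-weight maximization) would need a different
  solver.
* Non-convergent cyclic inhibition is resolved by forcing oscillating
  nodes undetermined rather than reporting all attractors.
* Gene identifiers are plain case-sensitive symbols; cross-species
  ortholog mapping is the caller's responsibility.
* The communication module scores only ligand–receptor channels; other
  routes (e.g. extracellular vesicles) are out of scope.
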