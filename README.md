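# rejuvenet

Multiscale network analysis of single-cell rejuvenation experiments.

Rejuvenation interventions — heterochronic parabiosis, calorie
restriction, exercise, partial reprogramming, metformin, rapamycin — shift
cells from an aged toward a more youthful transcriptional state, but every
study processes its data differently, which makes their effects hard to
compare. `rejuvenet` provides one tested pipeline for the network layers of
such a comparison: from QC'd single-cell counts and per-cell-type
differential-expression tables it builds profile-consistent transcriptional
regulatory networks (TRNs), identifies the master-regulator transcription
factors orchestrating the response, links them to differentially active
signaling intermediates, and scores ligand–receptor cell–cell
communication. It is written for computational biologists who have count
matrices, DE tables, a signed TF→gene prior network, and upstream signaling
scores in hand.

## The model

**TRN construction.** A differential-expression profile is booleanized
(positive log-FC → 1, negative → 0, after keeping genes with |log-FC| >
0.25 or expressed in > 10% of cells in both conditions). A signed prior
knowledge network of TF→gene edges is then pruned under *inhibition
dominance*: one up-regulated inhibitor suffices to switch a gene off, no
matter how many activators point at it. The retained edges are the
maximal subset consistent with the profile — maximizing explained genes,
then edges — and form a TRN of size N (unique TFs + targets). These
networks are strongly hierarchical (Krackhardt hierarchy ≈ 1), which
motivates the search for master regulators.

**Master-regulator score.** Each TF is clamped active in an otherwise
undetermined network and its influence propagated under the same
inhibition-dominant rule to a fixed point. The score is the fraction of
the N network nodes whose simulated state is determined and matches the
booleanized profile:

    score(tf) = |{ g : sim(g) determined, sim(g) = profile(g) }| / N

A root TF that explains every node scores 1.0; an end node predicting
only its own up-regulated state scores 1/N; a TF whose own booleanized
state is 0 scores 0. TFs scoring ≥ 0.30 are classified as master
regulators.

**Signaling and communication layers.** A signaling intermediate is
differentially active when its activity score is > 0.70 in the treated
condition and < 0.30 (or missing) in control; the crosstalk between a TRN
and a signaling network is the weakly connected component around the
intermediate, gated on a TF with outgoing edges in both. Ligand–receptor
channels are scored as the product of mean ligand expression over
expressing sender cells and mean receptor expression over expressing
receiver cells, called significant in the top decile of their
sender–receiver stratum, and reported when significant only in the
treated condition. A generic hypergeometric overrepresentation analysis
(BH-FDR 0.05) annotates any resulting gene set.

Every stage is testable offline: the `synth` module generates all five
input kinds with planted ground truth (a known master regulator, known
differential intermediates, known treated-unique channels).

## Worked example

Build a planted regulatory network, prune it against its booleanized
profile, and score every TF:

```python
import rejuvenet as r

planted = r.make_planted_trn(r.SimSpec(n_tfs=4, n_targets=8, branching=2,
                                       inhibitor_fraction=0.25, seed=7))
trn = r.prune_pkn(planted.pkn, planted.profile, set(planted.pkn["source"]))
print("network size N =", trn.n, "| hierarchy =", r.krackhardt_hierarchy(trn))
table = r.score_all(trn, planted.profile)
print(table.to_string(index=False))
print("master regulators:", sorted(r.classify(table)))
```

prints

```
network size N = 12 | hierarchy = 1.0
   tf    score  determined  n  is_mr
TF000 1.000000          12 12   True
TF001 0.666667           8 12   True
TF002 0.250000           3 12  False
TF003 0.500000           6 12   True
master regulators: ['TF000', 'TF001', 'TF003']
```

The planted root TF000 explains all 12 node states (score 1.0) and tops
the table; deeper TFs explain only their subtrees (TF001 determines 8 of
12 nodes, so 0.667 of the network), and TF002, below the 30% threshold,
is not a master regulator. The hierarchy of 1.0 says reachability in the
pruned network is perfectly antisymmetric — a pure regulatory cascade.

The same steps are available from the shell:

```sh
rejuvenet --seed 7 simulate --kind trn --out sim/
rejuvenet prune --pkn sim/pkn.tsv --de de.tsv --tf-list tfs.tsv \
          --out-trn trn.tsv --out-stats stats.json
rejuvenet score --trn trn.tsv --profile sim/profile.tsv --out scores.tsv
```

plus `qc`, `cluster-select`, `aggregate`, `intermediates`, `crosstalk`,
`ora` and `cellcomm` subcommands; see `rejuvenet --help`.

## Layout

| module | contents |
| --- | --- |
| `rejuvenet.io` | Matrix Market + TSV sidecar matrices, signed edge lists (TSV/SIF), DE/score tables, profiles, GMT |
| `rejuvenet.config` | `PipelineConfig` with every threshold |
| `rejuvenet.synth` | planted-truth generators for all pipeline inputs |
| `rejuvenet.qc` | QC metrics, MAD filtering, Calinski–Harabasz selection |
| `rejuvenet.trn` | DE filtering, booleanization, inhibition-dominant pruning, hierarchy |
| `rejuvenet.scoring` | activation simulation, TF scores, MR classification, aggregation |
| `rejuvenet.crosstalk` | differential intermediates, shared components, ORA |
| `rejuvenet.cellcomm` | ligand–receptor scoring, decile significance, treated-unique calls |
| `rejuvenet.cli` | `rejuvenet` command-line entry point |

See `docs/methods.md` for the full account of the models, defaults and
numerical choices.
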