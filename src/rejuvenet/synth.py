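"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates one of the pipeline's external inputs — a prior
knowledge network with a booleanized profile, count matrices with planted
differential expression, signaling-intermediate score tables, and a
ligand-receptor experiment — and returns machine-checkable truth alongside
the data. At zero noise each construction is exact: the corresponding
pipeline stage recovers the planted truth completely.

All randomness flows from one integer seed through per-operation
:class:`numpy.random.SeedSequence` spawn keys, so adding a new generator
never perturbs the draws of an existing one.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CellMatrix
from .trn import TRN, prune_pkn
from .scoring import simulate_activation

__all__ = [
    "SimSpec",
    "PlantedNetwork",
    "make_planted_trn",
    "make_counts",
    "make_intermediate_tables",
    "make_lr_experiment",
]


def _rng(seed: int, op: str) -> np.random.Generator:
    """Splittable per-operation generator from one global seed."""
    key = zlib.crc32(op.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# planted regulatory networks


@dataclass
class SimSpec:
    """Shape of a planted regulatory network.

    ``noise_fraction`` is the fraction of non-root nodes whose profile
    state is flipped against the planted logic after forward simulation.
    """

    n_tfs: int = 3
    n_targets: int = 4
    branching: int = 2
    inhibitor_fraction: float = 0.0
    noise_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs < 1 or self.n_targets < 0 or self.branching < 1:
            raise ValueError("counts must be positive")
        for f in (self.inhibitor_fraction, self.noise_fraction):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0,1]")


@dataclass
class PlantedNetwork:
    """An out-tree PKN whose root explains the profile up to planted noise."""

    pkn: pd.DataFrame
    profile: dict[str, int]
    planted_mr: str
    explained_fraction: float
    spec: SimSpec = field(repr=False, default=None)

    @property
    def nodes(self) -> list[str]:
        return list(self.profile)


def make_planted_trn(spec: SimSpec) -> PlantedNetwork:
    """Build a rooted out-tree PKN with a forward-simulated profile.

    TFs occupy the upper levels (every edge source must be a TF) and
    targets hang off them as leaves. Inhibitory edges are placed only into
    leaves: under inhibition-dominant propagation a switched-off node
    determines nothing downstream, so an internal inhibitor would leave
    its whole subtree undetermined and the root could never explain the
    full network even without noise. The profile is the forward simulation
    from root = active, after which ``noise_fraction`` of the non-root
    nodes are flipped. ``explained_fraction`` is measured, not assumed:
    the PKN is pruned against the (noisy) profile and the root's
    activation simulated on the result; the fraction is matched nodes over
    the full network size.
    """
    rng = _rng(spec.seed, "planted_trn")
    n = spec.n_tfs + spec.n_targets
    tfs = [f"TF{i:03d}" for i in range(spec.n_tfs)]
    targets = [f"G{i:04d}" for i in range(spec.n_targets)]
    nodes = tfs + targets
    root = tfs[0]

    parent_of = {
        i: min((i - 1) // spec.branching, spec.n_tfs - 1) for i in range(1, n)
    }
    has_children = set(parent_of.values())
    edges = []
    for i in range(1, n):
        is_leaf = i not in has_children
        sign = -1 if (is_leaf and rng.random() < spec.inhibitor_fraction) else 1
        edges.append((nodes[parent_of[i]], nodes[i], sign))
    pkn = pd.DataFrame(edges, columns=["source", "target", "sign"])

    # forward simulation: every internal node is activated (inhibitors only
    # point into leaves), so each child's state is determined by its edge sign
    profile = {root: 1}
    for parent, child, sign in edges:
        profile[child] = 1 if sign == 1 else 0

    n_flip = int(round(spec.noise_fraction * (n - 1)))
    if n_flip:
        flips = rng.choice(nodes[1:], size=n_flip, replace=False)
        for g in flips:
            profile[g] = 1 - profile[g]

    trn = prune_pkn(pkn, profile, tf_universe=set(tfs))
    if root in trn.nodes:
        sim = simulate_activation(trn, root)
        matched = sum(
            1 for g in nodes if sim.get(g) is not None and sim[g] == profile[g]
        )
    else:
        matched = 1 if profile[root] == 1 else 0  # root explains only itself
    return PlantedNetwork(
        pkn=pkn,
        profile=profile,
        planted_mr=root,
        explained_fraction=matched / n,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# count matrices with planted differential expression


def _p_positive(mean: float, dispersion: float, dropout: float) -> float:
    """P(observed count > 0) for the gamma-Poisson draw with dropout."""
    if mean <= 0:
        return 0.0
    if dispersion > 0:
        p_zero = (1.0 + dispersion * mean) ** (-1.0 / dispersion)
    else:
        p_zero = float(np.exp(-mean))
    return (1.0 - dropout) * (1.0 - p_zero)


def make_counts(
    cell_types: Sequence[str],
    n_cells_per_type: int = 50,
    de_genes_per_type: int = 10,
    lfc: float = 1.0,
    nb_dispersion: float = 0.5,
    dropout: float = 0.1,
    seed: int = 0,
    n_housekeeping: int = 50,
    base_mean: float = 5.0,
) -> tuple[CellMatrix, dict[str, pd.DataFrame]]:
    """Negative-binomial counts with a planted condition effect.

    Each cell type gets ``de_genes_per_type`` private genes whose mean is
    multiplied by 2**lfc in the treated condition (``lfc`` is a log2 fold
    change); all other genes are housekeeping. Counts are gamma-Poisson
    (variance = mu + dispersion * mu^2) with independent Bernoulli dropout.
    The returned per-type DE tables carry the *generating* parameters —
    avg_log_fc is the planted lfc, pct fields the closed-form expected
    positive fractions — not re-estimated statistics.
    """
    rng = _rng(seed, "counts")
    cell_types = list(cell_types)
    hk = [f"HK{i:04d}" for i in range(n_housekeeping)]
    de: dict[str, list[str]] = {
        ct: [f"DE_{ct}_{i:03d}" for i in range(de_genes_per_type)]
        for ct in cell_types
    }
    genes = hk + [g for ct in cell_types for g in de[ct]]

    cells, meta_rows = [], []
    for cond in ("treated", "control"):
        for ct in cell_types:
            for i in range(n_cells_per_type):
                cells.append(f"{ct}_{cond}_{i:04d}")
                meta_rows.append((ct, cond, f"r{i % 2 + 1}"))
    meta = pd.DataFrame(
        meta_rows, columns=["cell_type", "condition", "replicate"],
        index=pd.Index(cells, name="barcode"),
    )

    mu = np.full((len(genes), len(cells)), base_mean)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for j, (ct, cond, _) in enumerate(meta_rows):
        if cond == "treated":
            for g in de[ct]:
                mu[gene_pos[g], j] = base_mean * 2.0 ** lfc

    if nb_dispersion > 0:
        lam = rng.gamma(shape=1.0 / nb_dispersion, scale=mu * nb_dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam)
    if dropout > 0:
        counts = counts * (rng.random(counts.shape) >= dropout)

    matrix = CellMatrix(sp.csr_matrix(counts), genes, cells, meta)

    tables = {}
    pct_hk = _p_positive(base_mean, nb_dispersion, dropout)
    pct_de_treat = _p_positive(base_mean * 2.0 ** lfc, nb_dispersion, dropout)
    for ct in cell_types:
        rows = [
            (g, float(lfc), 1e-6 if lfc != 0 else 1.0, pct_de_treat, pct_hk)
            for g in de[ct]
        ] + [(g, 0.0, 1.0, pct_hk, pct_hk) for g in hk]
        tables[ct] = pd.DataFrame(
            rows, columns=["gene", "avg_log_fc", "p_adj", "pct_cond1", "pct_cond2"]
        )
    return matrix, tables


# ---------------------------------------------------------------------------
# signaling intermediate score tables


def make_intermediate_tables(
    n_molecules: int,
    n_differential: int,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series, set[str]]:
    """Score tables with planted differentially active intermediates.

    Planted molecules draw treated scores in (0.70, 1] and control scores
    in [0, 0.30); decoys are either mid-range in both conditions or
    missing (NA) in one of them. The truth set is returned.
    """
    if n_differential > n_molecules:
        raise ValueError("cannot plant more differential molecules than exist")
    rng = _rng(seed, "intermediates")
    molecules = [f"M{i:04d}" for i in range(n_molecules)]
    planted = set(rng.choice(molecules, size=n_differential, replace=False))
    treated, control = {}, {}
    for mol in molecules:
        if mol in planted:
            treated[mol] = rng.uniform(0.701, 1.0)
            control[mol] = rng.uniform(0.0, 0.299)
        else:
            kind = rng.integers(0, 3)
            if kind == 0:  # mid-range in both
                treated[mol] = rng.uniform(0.35, 0.65)
                control[mol] = rng.uniform(0.35, 0.65)
            elif kind == 1:  # absent from control
                treated[mol] = rng.uniform(0.35, 0.65)
                control[mol] = np.nan
            else:  # absent from treated
                treated[mol] = np.nan
                control[mol] = rng.uniform(0.35, 0.65)
    return (
        pd.Series(treated, name="score"),
        pd.Series(control, name="score"),
        planted,
    )


# ---------------------------------------------------------------------------
# ligand-receptor experiments


def make_lr_experiment(
    cell_types: Sequence[str] = ("A", "B"),
    scaffold_size: int = 50,
    planted_unique: int = 2,
    seed: int = 0,
    n_cells_per_type: int = 30,
    baseline_mean: float = 1.0,
    planted_mean: float = 50.0,
) -> tuple[CellMatrix, CellMatrix, pd.DataFrame, set[tuple[str, str, str, str]]]:
    """Two-condition matrices with treated-unique communication channels.

    The scaffold pairs ligand ``L_i`` with receptor ``R_i``. Baseline
    (decoy) expression is drawn once and shared bit-for-bit by the treated
    and control matrices, so a decoy's percentile rank in the treated
    condition can never exceed its control rank. Planted channels express
    ligand and receptor at ``planted_mean`` (well above the decoy scale)
    in their sender/receiver populations of the treated matrix only, and
    are fully silent in control. Truth is the set of
    (sender, receiver, ligand, receptor) planted channels.
    """
    if planted_unique * 10 >= scaffold_size:
        raise ValueError("need scaffold_size > 10 * planted_unique for the "
                         "planted channels to occupy the top decile")
    rng = _rng(seed, "lr_experiment")
    cell_types = list(cell_types)
    ligands = [f"L{i:03d}" for i in range(scaffold_size)]
    receptors = [f"R{i:03d}" for i in range(scaffold_size)]
    scaffold = pd.DataFrame({"ligand": ligands, "receptor": receptors})
    genes = ligands + receptors

    def build(cond: str) -> tuple[list[str], pd.DataFrame]:
        cells, rows = [], []
        for ct in cell_types:
            for i in range(n_cells_per_type):
                cells.append(f"{ct}_{cond}_{i:03d}")
                rows.append((ct, cond, "r1"))
        meta = pd.DataFrame(
            rows, columns=["cell_type", "condition", "replicate"],
            index=pd.Index(cells, name="barcode"),
        )
        return cells, meta

    treated_cells, treated_meta = build("treated")
    control_cells, control_meta = build("control")
    baseline = rng.poisson(baseline_mean, size=(len(genes), len(treated_cells)))
    treated_counts = baseline.copy()
    control_counts = baseline.copy()

    gene_pos = {g: i for i, g in enumerate(genes)}
    type_cols = {
        ct: np.flatnonzero(treated_meta["cell_type"].to_numpy() == ct)
        for ct in cell_types
    }
    pair_idx = rng.choice(scaffold_size, size=planted_unique, replace=False)
    truth = set()
    for idx in pair_idx:
        sender = cell_types[rng.integers(len(cell_types))]
        receiver = cell_types[rng.integers(len(cell_types))]
        lig, rec = ligands[idx], receptors[idx]
        for gene, ct in ((lig, sender), (rec, receiver)):
            row = gene_pos[gene]
            treated_counts[row, :] = 0
            treated_counts[row, type_cols[ct]] = 1 + rng.poisson(
                planted_mean, size=len(type_cols[ct])
            )
            control_counts[row, :] = 0
        truth.add((sender, receiver, lig, rec))

    treated = CellMatrix(
        sp.csr_matrix(treated_counts), genes, treated_cells, treated_meta
    )
    control = CellMatrix(
        sp.csr_matrix(control_counts), genes, control_cells, control_meta
    )
    return treated, control, scaffold, truth
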