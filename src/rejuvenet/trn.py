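"""Booleanization and inhibition-dominant pruning of prior knowledge networks.

A prior knowledge network (PKN) of signed TF->gene edges is pruned against a
booleanized differential-expression profile under *inhibition-dominant*
logic: one up-regulated inhibitor suffices to turn a gene off no matter how
many activators point at it. The retained, profile-consistent subnetwork is
the transcriptional regulatory network (TRN) on which master regulators are
scored.

Consistency of an edge subset S for a target gene g with profile state s(g):

* s(g) = 1 — S may contain no inhibitor whose source is up-regulated, and if
  S contains any edge into g it must contain at least one activator with an
  up-regulated source (something must switch g on, and nothing may be able
  to switch it off).
* s(g) = 0 — either S contains an up-regulated inhibitor (which dominates),
  or S contains no up-regulated activator (nothing switches g on).

The objective is lexicographic: first maximize the number of genes that are
explained (retain at least one edge), then the number of retained edges.
Because no constraint couples two different targets, the problem decomposes
per gene and each subproblem has a closed-form optimum; an explicit
enumeration solver is kept for small in-degrees and cross-checked in tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TRN",
    "UndefinedMetricError",
    "filter_de",
    "booleanize",
    "prune_pkn",
    "krackhardt_hierarchy",
    "signal_dependent_fraction",
]


class UndefinedMetricError(ValueError):
    """A network statistic is undefined for the given input."""


@dataclass
class TRN:
    """A pruned, profile-consistent regulatory network.

    ``edges`` has columns source/target/sign; the node set is the union of
    sources and targets of retained edges, and the network size N counts
    unique TFs plus targets.
    """

    edges: pd.DataFrame

    def __post_init__(self) -> None:
        self.edges = (
            self.edges[["source", "target", "sign"]]
            .drop_duplicates(ignore_index=True)
            .astype({"sign": int})
        )

    @property
    def nodes(self) -> set[str]:
        return set(self.edges["source"]) | set(self.edges["target"])

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def tfs(self) -> set[str]:
        return set(self.edges["source"])

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for s, t, w in self.edges.itertuples(index=False):
            g.add_edge(s, t, sign=int(w))
        return g


def filter_de(
    table: pd.DataFrame, lfc_min: float = 0.25, pct_min: float = 0.10
) -> pd.DataFrame:
    """Keep genes with |avg_log_fc| > lfc_min OR expressed in more than
    ``pct_min`` of cells in *both* conditions.

    Both comparisons are strict, matching the "greater than" phrasing of
    the thresholds.
    """
    keep = (table["avg_log_fc"].abs() > lfc_min) | (
        (table["pct_cond1"] > pct_min) & (table["pct_cond2"] > pct_min)
    )
    return table[keep].reset_index(drop=True)


def booleanize(table: pd.DataFrame) -> dict[str, int]:
    """Map log-fold-changes to Boolean states: positive -> 1, negative -> 0.

    Genes with avg_log_fc exactly 0 carry no direction and are excluded.
    """
    nonzero = table[table["avg_log_fc"] != 0]
    return {
        str(g): (1 if lfc > 0 else 0)
        for g, lfc in zip(nonzero["gene"], nonzero["avg_log_fc"])
    }


# ---------------------------------------------------------------------------
# pruning


def _consistent(edges: list[tuple[str, int]], state: int, profile: Mapping[str, int]) -> bool:
    """Check the consistency conditions for one target's edge subset.

    ``edges`` is a list of (source, sign) pairs retained for the target.
    """
    up_act = any(profile[s] == 1 and w == 1 for s, w in edges)
    up_inh = any(profile[s] == 1 and w == -1 for s, w in edges)
    if state == 1:
        return not up_inh and (not edges or up_act)
    return up_inh or not up_act


def _best_subset_closed_form(
    edges: list[tuple[str, int]], state: int, profile: Mapping[str, int]
) -> list[tuple[str, int]]:
    """Per-gene lexicographic optimum in closed form."""
    up_act = [e for e in edges if profile[e[0]] == 1 and e[1] == 1]
    up_inh = [e for e in edges if profile[e[0]] == 1 and e[1] == -1]
    if state == 1:
        if not up_act:
            return []
        return [e for e in edges if e not in up_inh]
    if up_inh:
        return list(edges)
    return [e for e in edges if e not in up_act]


def _best_subset_enumerate(
    edges: list[tuple[str, int]], state: int, profile: Mapping[str, int]
) -> list[tuple[str, int]]:
    """Per-gene optimum by subset enumeration (small in-degrees only)."""
    best: list[tuple[str, int]] = []
    best_key = (0, 0)
    for r in range(len(edges) + 1):
        for combo in itertools.combinations(edges, r):
            subset = list(combo)
            if _consistent(subset, state, profile):
                key = (1 if subset else 0, len(subset))
                if key > best_key:
                    best, best_key = subset, key
    return best


def prune_pkn(
    pkn: pd.DataFrame,
    profile: Mapping[str, int],
    tf_universe: Iterable[str] | None = None,
    max_enum_edges: int = 20,
) -> TRN:
    """Prune a PKN to the maximal profile-consistent TRN.

    Edges are first restricted to profile genes, with sources additionally
    restricted to ``tf_universe`` when given (non-TF sources are discarded).
    Each target's in-edge set is then solved independently for the
    lexicographic (explained genes, retained edges) optimum; targets with
    at most ``max_enum_edges`` candidate in-edges go through the exact
    enumeration solver, larger ones through the equivalent closed-form
    rule. Genes that retain no edge are absent from the TRN.
    """
    if not profile:
        logger.warning("empty profile: returning empty TRN")
        return TRN(pd.DataFrame(columns=["source", "target", "sign"]))
    tf_set = set(tf_universe) if tf_universe is not None else None

    mask = pkn["source"].isin(profile) & pkn["target"].isin(profile)
    if tf_set is not None:
        mask &= pkn["source"].isin(tf_set)
    cand = pkn[mask].drop_duplicates()
    if cand.empty:
        logger.warning("no PKN edge connects profile genes: empty TRN")
        return TRN(pd.DataFrame(columns=["source", "target", "sign"]))

    kept_rows: list[tuple[str, str, int]] = []
    n_enum = n_closed = 0
    for target, grp in cand.groupby("target", sort=True):
        edges = [(s, int(w)) for s, w in zip(grp["source"], grp["sign"])]
        if len(edges) <= max_enum_edges:
            best = _best_subset_enumerate(edges, profile[target], profile)
            n_enum += 1
        else:
            best = _best_subset_closed_form(edges, profile[target], profile)
            n_closed += 1
        kept_rows.extend((s, target, w) for s, w in best)
    logger.info(
        "pruned %d -> %d edges (%d genes enumerated exactly, %d via closed form)",
        len(cand), len(kept_rows), n_enum, n_closed,
    )
    return TRN(pd.DataFrame(kept_rows, columns=["source", "target", "sign"]))


# ---------------------------------------------------------------------------
# network statistics


def krackhardt_hierarchy(network: TRN | nx.DiGraph) -> float:
    """Krackhardt hierarchy score of a digraph.

    H = 1 - (mutually reachable unordered pairs) / (pairs reachable in at
    least one direction). 1 means reachability is perfectly antisymmetric
    (a pure hierarchy); 0 means every connected pair is reciprocal.
    """
    g = network.graph() if isinstance(network, TRN) else network
    nodes = list(g.nodes)
    if len(nodes) < 2:
        raise UndefinedMetricError("hierarchy needs at least 2 nodes")
    desc = {v: nx.descendants(g, v) for v in nodes}
    reachable = symmetric = 0
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            uv, vu = v in desc[u], u in desc[v]
            if uv or vu:
                reachable += 1
                if uv and vu:
                    symmetric += 1
    if reachable == 0:
        raise UndefinedMetricError("no reachable node pair")
    return 1.0 - symmetric / reachable


def signal_dependent_fraction(
    de_genes: Iterable[str],
    trn: TRN,
    pkn: pd.DataFrame,
    sd_tfs: Iterable[str],
) -> float:
    """Fraction of unexplained DE genes reachable by signal-dependent TFs.

    Among DE genes that are absent from the TRN but have at least one
    regulator in the PKN, the fraction whose PKN regulators intersect the
    curated signal-dependent TF list.
    """
    sd = set(sd_tfs)
    trn_nodes = trn.nodes
    regulators: dict[str, set[str]] = {}
    for s, t in zip(pkn["source"], pkn["target"]):
        regulators.setdefault(t, set()).add(s)
    pool = [
        g for g in set(de_genes)
        if g not in trn_nodes and regulators.get(g)
    ]
    if not pool:
        raise UndefinedMetricError(
            "no DE gene is both unexplained and regulated in the PKN"
        )
    hits = sum(1 for g in pool if regulators[g] & sd)
    return hits / len(pool)
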