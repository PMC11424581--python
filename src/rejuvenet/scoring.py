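"""Boolean activation simulation and master-regulator scoring.

Every TF in a TRN is scored by clamping it to the active state in an
otherwise undetermined network, propagating under inhibition-dominant
logic, and counting how much of the booleanized expression profile the
resulting fixed point reproduces. The score of a TF is

    score(tf) = |{g : state(g) determined and state(g) = profile(g)}| / N

with N the full network size. A TF whose own booleanized state is 0 scores
0 outright: activating it cannot explain its own observed repression. A TF
at the root of a fully hierarchical consistent network scores 1.0, and an
end node that only predicts its own up-regulated state scores 1/N.

Update rule for a node g (the clamped TF stays 1): if any inhibitor of g is
determined and active, g is 0 — inhibition dominates any number of
activators; otherwise if any activator is determined and active, g is 1;
otherwise g is undetermined. Propagation runs a depth-first pass from the
clamped TF (targets in lexicographic order) and then synchronous sweeps to
the fixed point; the sweep removes any dependence on traversal order.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .trn import TRN

logger = logging.getLogger(__name__)

__all__ = [
    "simulate_activation",
    "tf_score",
    "score_all",
    "classify",
    "aggregate_top",
]

State = Optional[int]  # 1, 0 or None (undetermined)


def _adjacency(trn: TRN) -> tuple[dict[str, list[tuple[str, int]]], dict[str, list[tuple[str, int]]]]:
    out_edges: dict[str, list[tuple[str, int]]] = {v: [] for v in trn.nodes}
    in_edges: dict[str, list[tuple[str, int]]] = {v: [] for v in trn.nodes}
    for s, t, w in trn.edges.itertuples(index=False):
        out_edges[s].append((t, int(w)))
        in_edges[t].append((s, int(w)))
    for v in out_edges:
        out_edges[v].sort()
    return out_edges, in_edges


def _rule(regulators: list[tuple[str, int]], state: Mapping[str, State]) -> State:
    """Inhibition-dominant evaluation of one node from its regulators."""
    if any(w == -1 and state[s] == 1 for s, w in regulators):
        return 0
    if any(w == 1 and state[s] == 1 for s, w in regulators):
        return 1
    return None


def simulate_activation(trn: TRN, tf: str) -> dict[str, State]:
    """Clamp ``tf`` active and propagate to the inhibition-dominant fixed point.

    Returns the state of every TRN node: 1, 0 or None (undetermined). If
    cyclic inhibition prevents convergence within N synchronous sweeps, the
    oscillating nodes are forced undetermined and a warning is logged.
    """
    if tf not in trn.nodes:
        raise KeyError(f"TF {tf!r} not in network")
    out_edges, in_edges = _adjacency(trn)
    state: dict[str, State] = {v: None for v in trn.nodes}
    state[tf] = 1

    # depth-first pass from the activated TF, targets in lexicographic order
    stack = [t for t, _ in reversed(out_edges[tf])]
    seen = {tf}
    while stack:
        g = stack.pop()
        if g in seen:
            continue
        seen.add(g)
        state[g] = _rule(in_edges[g], state)
        if state[g] is not None:
            stack.extend(t for t, _ in reversed(out_edges[g]) if t not in seen)

    # synchronous sweeps to the fixed point (bounded by N)
    n = trn.n
    for _ in range(n):
        new = {
            v: (1 if v == tf else _rule(in_edges[v], state)) for v in state
        }
        if new == state:
            return state
        state = new
    changed = {
        v for v in state
        if v != tf and state[v] != _rule(in_edges[v], state)
    }
    for v in changed:
        state[v] = None
    logger.warning(
        "activation of %s did not converge in %d sweeps; %d node(s) forced "
        "undetermined", tf, n, len(changed),
    )
    return state


def tf_score(trn: TRN, profile: Mapping[str, int], tf: str) -> float:
    """Master-regulator score of one TF against the booleanized profile."""
    if tf not in trn.nodes:
        raise KeyError(f"TF {tf!r} not in network")
    missing = trn.nodes - set(profile)
    if missing:
        raise ValueError(f"profile missing states for {sorted(missing)[:5]}")
    if profile[tf] == 0:
        return 0.0
    sim = simulate_activation(trn, tf)
    matched = sum(
        1 for g, s in sim.items() if s is not None and s == profile[g]
    )
    return matched / trn.n


def score_all(trn: TRN, profile: Mapping[str, int], mr_threshold: float = 0.30) -> pd.DataFrame:
    """Score every TF (source node) of the TRN.

    Returns one row per TF with columns tf, score, determined (matched
    node count), n (network size) and is_mr (score >= mr_threshold).
    """
    n = trn.n
    rows = []
    for tf in sorted(trn.tfs):
        s = tf_score(trn, profile, tf)
        rows.append((tf, s, int(round(s * n)), n, s >= mr_threshold))
    return pd.DataFrame(rows, columns=["tf", "score", "determined", "n", "is_mr"])


def classify(table: pd.DataFrame, mr_threshold: float = 0.30) -> set[str]:
    """Master regulators: TFs determining at least ``mr_threshold`` of the
    network (inclusive threshold)."""
    return set(table.loc[table["score"] >= mr_threshold, "tf"])


def aggregate_top(
    tables: Mapping[str, pd.DataFrame], k: int = 30
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank TFs by mean score across conditions; absent TFs count as 0.

    Returns ``(ranking, matrix)``: the top-k table with mean_score and
    mean_rank columns (rank is the within-condition descending rank, also
    with absent TFs ranked last), and the full TF x condition score matrix
    for external clustering/heatmaps.
    """
    if not tables:
        raise ValueError("need at least one score table")
    conditions = list(tables)
    matrix = pd.DataFrame(
        {
            cond: tbl.set_index("tf")["score"]
            for cond, tbl in tables.items()
        }
    ).fillna(0.0)
    matrix = matrix.sort_index()
    mean_score = matrix.mean(axis=1)
    mean_rank = matrix.rank(axis=0, ascending=False, method="average").mean(axis=1)
    ranking = (
        pd.DataFrame(
            {
                "tf": matrix.index.to_numpy(),
                "mean_score": mean_score.to_numpy(),
                "mean_rank": mean_rank.to_numpy(),
            }
        )
        .sort_values(["mean_score", "tf"], ascending=[False, True])
        .head(k)
        .reset_index(drop=True)
    )
    return ranking, matrix[conditions]
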