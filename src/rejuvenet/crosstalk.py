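"""Differentially active signaling intermediates, TRN-signaling crosstalk
components, and generic overrepresentation analysis.

Signaling intermediates arrive as per-condition activity scores in [0,1]
(from an upstream hotspot tool). A molecule is differentially active when
it is activated in the treated condition (score above 0.70) and inhibited
in the control (score below 0.30, with a missing control score counting as
inhibited). Crosstalk between a TRN and a signaling network is the weakly
connected component, around the intermediate, of the union graph — gated
on some TF having outgoing edges in both networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "CrosstalkComponent",
    "differential_intermediates",
    "shared_component",
    "ora",
]


@dataclass
class CrosstalkComponent:
    """A TRN-signaling union subgraph around one signaling intermediate."""

    intermediate: str
    genes: set[str]
    edges: pd.DataFrame  # source, target, sign — directions preserved


def differential_intermediates(
    treated: pd.Series,
    control: pd.Series,
    active: float = 0.70,
    inhibited: float = 0.30,
) -> set[str]:
    """Molecules activated in the treated condition and inhibited in control.

    Selection: treated score present and > ``active``; control score
    < ``inhibited``, or missing (NA entries count as inhibited). Presence
    in the treated condition is mandatory, so the rule is not symmetric
    under swapping the two tables. Both tables must be non-empty.
    """
    if treated.empty or control.empty:
        raise ValueError("both condition tables must be non-empty")
    out = set()
    for mol, score in treated.items():
        if pd.isna(score) or score <= active:
            continue
        ctrl = control.get(mol)
        if ctrl is None or pd.isna(ctrl) or ctrl < inhibited:
            out.add(str(mol))
    return out


def shared_component(
    trn_edges: pd.DataFrame,
    sig_edges: pd.DataFrame,
    intermediate: str,
) -> CrosstalkComponent | None:
    """Extract the crosstalk component around a signaling intermediate.

    Requires some TF to have outgoing edges in *both* the TRN and the
    signaling network; without such a shared source the crosstalk is
    declared absent (returns None) even if the graphs touch at sink nodes.
    Otherwise the two edge sets are concatenated and weak connected
    components computed on the union: a single component is returned
    whole, and with several only the one containing the intermediate.
    """
    if intermediate not in set(sig_edges["source"]) | set(sig_edges["target"]):
        raise ValueError(f"intermediate {intermediate!r} not in signaling edges")
    shared_sources = set(trn_edges["source"]) & set(sig_edges["source"])
    if not shared_sources:
        logger.info("no TF with outgoing edges in both networks: no crosstalk")
        return None

    cols = ["source", "target", "sign"]
    parts = [
        df if "sign" in df.columns else df.assign(sign=1)
        for df in (trn_edges, sig_edges)
    ]
    union = pd.concat(
        [df[cols] for df in parts], ignore_index=True
    ).drop_duplicates(ignore_index=True)

    g = nx.DiGraph()
    for s, t, w in union.itertuples(index=False):
        g.add_edge(s, t, sign=int(w))
    comps = list(nx.weakly_connected_components(g))
    if len(comps) == 1:
        nodes = comps[0]
    else:
        nodes = next((c for c in comps if intermediate in c), None)
        if nodes is None:
            logger.warning(
                "intermediate %s in no union component: empty crosstalk",
                intermediate,
            )
            return None
    sub = union[union["source"].isin(nodes) & union["target"].isin(nodes)]
    return CrosstalkComponent(
        intermediate=intermediate,
        genes=set(nodes),
        edges=sub.reset_index(drop=True),
    )


def ora(
    query: Iterable[str],
    background: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation analysis with BH-FDR control.

    For each gene set (intersected with the background), the upper-tail
    hypergeometric probability of observing at least the overlap between
    query and set is computed; q-values are Benjamini-Hochberg adjusted
    and sets with q < ``fdr`` flagged as enriched.
    """
    query = set(query)
    background = set(background)
    if not query or not background:
        raise ValueError("query and background must be non-empty")
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    n_bg, n_q = len(background), len(query)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & background
        k = len(query & members)
        p = float(hypergeom.sf(k - 1, n_bg, len(members), n_q)) if members else 1.0
        rows.append((name, k, len(members), p))
    df = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"])
    if df.empty:
        return df.assign(q=pd.Series(dtype=float), enriched=pd.Series(dtype=bool))
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df["enriched"] = df["q"] < fdr
    return df.sort_values(["q", "p", "set"]).reset_index(drop=True)
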