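"""Ligand-receptor cell-cell interaction scoring.

An interaction between a sender and a receiver cell type through a
ligand-receptor pair is scored as the product of the mean ligand
expression over sender cells expressing the ligand and the mean receptor
expression over receiver cells expressing the receptor ("expressing"
meaning count > 0). Significance is a percentile rank within the stratum
of all scaffold pairs for that sender-receiver pair; the top decile is
significant. The reported hits are the interactions that are significant
only in the treated condition.

Scores depend on the expression scale of the supplied matrix (raw or
normalized), but percentile ranks — and hence significance calls — are
invariant under any strictly monotone per-gene rescaling applied to both
factors' scales uniformly.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import CellMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "interaction_score",
    "score_condition",
    "significance",
    "treated_unique",
]

KEY = ["sender_type", "receiver_type", "ligand", "receptor"]


def _expressing_mean(m: CellMatrix, gene: str, cell_idx: np.ndarray) -> float:
    row = m.counts[m.gene_index(gene), :].toarray().ravel()[cell_idx]
    expressing = row[row > 0]
    return float(expressing.mean()) if expressing.size else 0.0


def interaction_score(
    m: CellMatrix,
    sender_type: str,
    receiver_type: str,
    ligand: str,
    receptor: str,
) -> float:
    """mean ligand expression (expressing senders) x mean receptor
    expression (expressing receivers); 0 when either expressing set is
    empty. Raises KeyError naming a gene absent from the matrix."""
    senders = m.cells_of_type(sender_type)
    receivers = m.cells_of_type(receiver_type)
    if senders.size == 0 or receivers.size == 0:
        raise ValueError(
            f"cell type missing from matrix: "
            f"{sender_type if senders.size == 0 else receiver_type!r}"
        )
    return _expressing_mean(m, ligand, senders) * _expressing_mean(
        m, receptor, receivers
    )


def score_condition(
    m: CellMatrix,
    scaffold: pd.DataFrame,
    cell_types: Sequence[str] | None = None,
    condition: str | None = None,
) -> pd.DataFrame:
    """Score every scaffold pair for every ordered (sender, receiver)
    cell-type pair, including autocrine (sender = receiver) strata.

    Scaffold rows with a gene absent from the matrix are skipped with a
    warning (the scaffold is a generic database; matrices only carry
    measured genes). Returns records with KEY columns, score and condition.
    """
    if cell_types is None:
        cell_types = sorted(m.cell_meta["cell_type"].unique())
    genes = set(m.gene_ids)
    usable = scaffold[
        scaffold["ligand"].isin(genes) & scaffold["receptor"].isin(genes)
    ]
    skipped = len(scaffold) - len(usable)
    if skipped:
        logger.warning("skipping %d scaffold pair(s) with unmeasured genes", skipped)

    dense = {
        g: m.counts[m.gene_index(g), :].toarray().ravel()
        for g in set(usable["ligand"]) | set(usable["receptor"])
    }
    type_idx = {ct: m.cells_of_type(ct) for ct in cell_types}

    def emean(gene: str, idx: np.ndarray) -> float:
        v = dense[gene][idx]
        v = v[v > 0]
        return float(v.mean()) if v.size else 0.0

    rows = []
    for sender in cell_types:
        for receiver in cell_types:
            si, ri = type_idx[sender], type_idx[receiver]
            if si.size == 0 or ri.size == 0:
                continue
            for lig, rec in usable[["ligand", "receptor"]].itertuples(index=False):
                rows.append(
                    (sender, receiver, lig, rec, emean(lig, si) * emean(rec, ri))
                )
    df = pd.DataFrame(rows, columns=KEY + ["score"])
    df["condition"] = condition if condition is not None else ""
    return df


def significance(records: pd.DataFrame, cutoff: float = 0.90) -> pd.DataFrame:
    """Percentile-rank scores within each (sender, receiver) stratum.

    significance = fraction of stratum scores strictly below the record's
    score, so ties share the lower rank and a stratum of identical scores
    is never significant. ``significant`` flags the top decile
    (significance >= cutoff).
    """
    df = records.copy()

    def rank(group: pd.DataFrame) -> pd.Series:
        s = group["score"].to_numpy()
        below = (s[:, None] > s[None, :]).sum(axis=1)
        return pd.Series(below / len(s), index=group.index)

    parts = [
        rank(grp) for _, grp in df.groupby(["sender_type", "receiver_type"], sort=False)
    ]
    df["significance"] = pd.concat(parts).reindex(df.index)
    df["significant"] = df["significance"] >= cutoff
    n_tied_top = int(
        ((df["significance"] == df["significance"]) & df["significant"]).sum()
    )
    logger.debug("%d record(s) flagged significant", n_tied_top)
    return df


def treated_unique(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    cutoff: float = 0.90,
) -> pd.DataFrame:
    """Interactions with treated significance strictly above ``cutoff``
    whose (sender, receiver, ligand, receptor) key is not significant in
    the control condition.

    Uniqueness is at the significant-interaction level: a channel present
    but non-significant in control still counts as treated-unique.
    """
    for name, df in (("treated", treated), ("control", control)):
        if "significance" not in df.columns:
            raise ValueError(f"{name} records lack significance; run significance()")
    ctrl_sig = set(
        map(tuple, control.loc[control["significance"] >= cutoff, KEY].to_numpy())
    )
    strict = treated[treated["significance"] > cutoff]
    ties = treated[
        (treated["significance"] == cutoff) & (treated["significance"] > 0)
    ]
    if not ties.empty:
        logger.info(
            "%d interaction(s) tied exactly at the %.2f cutoff were excluded",
            len(ties), cutoff,
        )
    keep = [tuple(r) not in ctrl_sig for r in strict[KEY].to_numpy()]
    return strict[keep].reset_index(drop=True)
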