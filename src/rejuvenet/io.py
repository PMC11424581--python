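"""Readers and writers for the external formats the pipeline touches.

All tabular formats are plain TSV; count matrices are Matrix Market
coordinate files with ``genes``/``barcodes``/``cell_meta`` TSV sidecars
(the cellranger triplet plus a metadata table). Readers are strict:
malformed input raises :class:`FormatError` naming the offending file
(and line, where meaningful) instead of silently coercing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "CellMatrix",
    "read_cell_matrix",
    "write_cell_matrix",
    "read_edge_list",
    "write_edge_list",
    "read_de_table",
    "write_de_table",
    "read_score_table",
    "write_score_table",
    "read_profile",
    "write_profile",
    "read_gmt",
    "read_gene_list",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# cell matrices


@dataclass
class CellMatrix:
    """Raw UMI counts (genes x cells) with per-cell metadata.

    ``cell_meta`` is indexed by barcode and carries at least ``cell_type``,
    ``condition`` and ``replicate`` columns. Counts are kept sparse (CSR)
    and must be non-negative integers.
    """

    counts: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.gene_ids):
            raise FormatError(
                f"matrix has {n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if n_cells != len(self.cell_ids):
            raise FormatError(
                f"matrix has {n_cells} columns but {len(self.cell_ids)} barcodes"
            )
        data = self.counts.data
        if data.size and (data < 0).any():
            raise FormatError("negative counts in matrix")
        if data.size and not np.allclose(data, np.round(data)):
            raise FormatError("non-integer counts in matrix")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene symbols; deduplicate before construction")
        missing = set(self.cell_ids) - set(self.cell_meta.index)
        if missing:
            raise FormatError(f"{len(missing)} cells missing from metadata")
        self.cell_meta = self.cell_meta.loc[self.cell_ids]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def cells_of_type(self, cell_type: str) -> np.ndarray:
        """Column indices of cells annotated with ``cell_type``."""
        return np.flatnonzero((self.cell_meta["cell_type"] == cell_type).to_numpy())


def _dedupe_gene_rows(
    counts: sp.csr_matrix, genes: list[str]
) -> tuple[sp.csr_matrix, list[str]]:
    """Resolve duplicate symbols by keeping the row with the larger total count."""
    totals = np.asarray(counts.sum(axis=1)).ravel()
    best: dict[str, int] = {}
    for i, g in enumerate(genes):
        if g not in best or totals[i] > totals[best[g]]:
            best[g] = i
    if len(best) == len(genes):
        return counts, genes
    keep = sorted(best.values())
    dropped = len(genes) - len(keep)
    logger.warning(
        "resolved %d duplicate gene symbol(s) by keeping the higher-count row", dropped
    )
    kept_genes = [genes[i] for i in keep]
    return sp.csr_matrix(counts)[keep, :], kept_genes


def read_cell_matrix(
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    meta_path: str | Path,
) -> CellMatrix:
    """Read a Matrix Market count file with its three TSV sidecars.

    The genes file may have one column (symbols) or two (id, symbol —
    cellranger style; the last column is taken as the symbol). The metadata
    table must have a ``barcode`` column (or barcodes as its first column)
    plus ``cell_type``, ``condition`` and ``replicate``. Barcodes without
    metadata are dropped with a warning.
    """
    try:
        counts = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"{mtx_path}: not a readable Matrix Market file ({exc})")
    if counts.data.size and not np.allclose(counts.data, np.round(counts.data)):
        raise FormatError(f"{mtx_path}: non-integer counts")
    counts.data = np.round(counts.data)

    genes_df = pd.read_csv(genes_path, sep="\t", header=None, dtype=str)
    genes = genes_df.iloc[:, -1].tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)[0].tolist()
    if counts.shape[0] != len(genes):
        raise FormatError(
            f"{genes_path}: lists {len(genes)} genes but matrix declares "
            f"{counts.shape[0]} rows"
        )
    if counts.shape[1] != len(barcodes):
        raise FormatError(
            f"{barcodes_path}: lists {len(barcodes)} barcodes but matrix declares "
            f"{counts.shape[1]} columns"
        )

    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "barcode" in meta.columns:
        meta = meta.set_index("barcode")
    else:
        meta = meta.set_index(meta.columns[0])
    required = {"cell_type", "condition", "replicate"}
    if not required.issubset(meta.columns):
        raise FormatError(
            f"{meta_path}: missing columns {sorted(required - set(meta.columns))}"
        )

    counts, genes = _dedupe_gene_rows(counts, genes)

    known = [i for i, b in enumerate(barcodes) if b in meta.index]
    if len(known) < len(barcodes):
        logger.warning(
            "dropping %d cell(s) absent from %s", len(barcodes) - len(known), meta_path
        )
        counts = counts[:, known]
        barcodes = [barcodes[i] for i in known]
    return CellMatrix(counts, genes, barcodes, meta.loc[barcodes])


def write_cell_matrix(m: CellMatrix, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(m.counts), field="integer")
    pd.Series(m.gene_ids).to_csv(out / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(m.cell_ids).to_csv(
        out / "barcodes.tsv", sep="\t", index=False, header=False
    )
    m.cell_meta.rename_axis("barcode").to_csv(out / "cell_meta.tsv", sep="\t")


# ---------------------------------------------------------------------------
# edge lists

_POS_TOKENS = {"+1", "1", "+", "activation", "activates", "stimulation"}
_NEG_TOKENS = {"-1", "−1", "-", "inhibition", "inhibits", "repression"}


def _parse_sign(token: str) -> int:
    t = token.strip().lower()
    if t in _POS_TOKENS:
        return 1
    if t in _NEG_TOKENS:
        return -1
    raise ValueError(token)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a signed edge list as a DataFrame (source, target, sign).

    Two dialects are accepted: a headered 3-column TSV
    (``source<TAB>target<TAB>sign``) and SIF-style whitespace-separated
    ``source relation target`` lines. Signs may be numeric (+1/-1) or the
    tokens activation/inhibition. Exact duplicate rows are dropped.
    """
    path = Path(path)
    with open(path, newline=None) as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        logger.warning("%s: empty edge list", path)
        return pd.DataFrame(columns=["source", "target", "sign"])

    header = [c.strip().lower() for c in lines[0].split("\t")]
    rows: list[tuple[str, str, int]] = []
    if "source" in header and "target" in header and "sign" in header:
        i_s, i_t, i_g = header.index("source"), header.index("target"), header.index("sign")
        for lineno, ln in enumerate(lines[1:], start=2):
            parts = ln.split("\t")
            try:
                rows.append((parts[i_s].strip(), parts[i_t].strip(), _parse_sign(parts[i_g])))
            except (IndexError, ValueError):
                raise FormatError(f"{path}:{lineno}: unparseable edge row {ln!r}")
    else:  # SIF dialect: source relation target
        for lineno, ln in enumerate(lines, start=1):
            parts = ln.split()
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            try:
                sign = _parse_sign(parts[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: unknown sign token {parts[1]!r}")
            rows.append((parts[0], parts[2], sign))

    df = pd.DataFrame(rows, columns=["source", "target", "sign"])
    before = len(df)
    df = df.drop_duplicates(ignore_index=True)
    if len(df) < before:
        logger.info("%s: dropped %d duplicate edge(s)", path, before - len(df))
    df["sign"] = df["sign"].astype(np.int8)
    return df


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges[["source", "target", "sign"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# DE and score tables

#: accepted aliases (lowercased) for each canonical DE-table column
DE_ALIASES: Mapping[str, tuple[str, ...]] = {
    "gene": ("gene", "symbol", "feature", "gene_symbol"),
    "avg_log_fc": ("avg_log_fc", "avg_log2fc", "avg_logfc", "log_fc", "logfc", "lfc"),
    "p_adj": ("p_adj", "padj", "p_val_adj", "adj_p", "fdr", "qvalue"),
    "pct_cond1": ("pct_cond1", "pct.1", "pct1", "pct_1"),
    "pct_cond2": ("pct_cond2", "pct.2", "pct2", "pct_2"),
}


def _map_columns(
    found: Iterable[str], aliases: Mapping[str, tuple[str, ...]], path: Path
) -> dict[str, str]:
    lower = {c.lower(): c for c in found}
    mapping = {}
    for canon, names in aliases.items():
        hit = next((lower[n] for n in names if n in lower), None)
        if hit is None:
            raise FormatError(
                f"{path}: missing required column {canon!r}; found {sorted(found)}"
            )
        mapping[hit] = canon
    return mapping


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a per-cell-type differential expression table.

    Canonical columns: gene, avg_log_fc, p_adj, pct_cond1, pct_cond2.
    Common Seurat-style aliases (avg_log2FC, p_val_adj, pct.1, pct.2) are
    mapped automatically.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty DE table", path)
        return pd.DataFrame(
            columns=["gene", "avg_log_fc", "p_adj", "pct_cond1", "pct_cond2"]
        )
    df = df.rename(columns=_map_columns(df.columns, DE_ALIASES, path))
    df = df[["gene", "avg_log_fc", "p_adj", "pct_cond1", "pct_cond2"]]
    for col in ("avg_log_fc", "p_adj", "pct_cond1", "pct_cond2"):
        df[col] = pd.to_numeric(df[col])
    bad = df[
        (df["p_adj"] < 0) | (df["p_adj"] > 1)
        | (df["pct_cond1"] < 0) | (df["pct_cond1"] > 1)
        | (df["pct_cond2"] < 0) | (df["pct_cond2"] > 1)
    ]
    if not bad.empty:
        raise FormatError(f"{path}: p_adj/pct values outside [0,1] for {len(bad)} row(s)")
    if df["gene"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene rows")
    return df.reset_index(drop=True)


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


_SCORE_ALIASES: Mapping[str, tuple[str, ...]] = {
    "molecule": ("molecule", "gene", "symbol", "intermediate"),
    "score": ("score", "activity", "final_score"),
}


def read_score_table(path: str | Path) -> pd.Series:
    """Read a per-molecule activity score table into a Series.

    Missing scores (``NA``) are preserved as NaN — the differential-activity
    rule treats an absent control score as inhibited, so they must never be
    imputed to a number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", na_values=["NA", "NaN", ""])
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty score table", path)
        return pd.Series(dtype=float, name="score")
    df = df.rename(columns=_map_columns(df.columns, _SCORE_ALIASES, path))
    scores = pd.to_numeric(df["score"])
    present = scores.dropna()
    if ((present < 0) | (present > 1)).any():
        raise FormatError(f"{path}: scores outside [0,1]")
    s = pd.Series(scores.to_numpy(), index=df["molecule"].astype(str), name="score")
    if s.index.duplicated().any():
        raise FormatError(f"{path}: duplicate molecule rows")
    return s


def write_score_table(scores: pd.Series, path: str | Path) -> None:
    scores.rename_axis("molecule").rename("score").to_csv(
        path, sep="\t", na_rep="NA"
    )


# ---------------------------------------------------------------------------
# boolean profiles, gene lists, GMT


def read_profile(path: str | Path) -> dict[str, int]:
    """Read a booleanized profile TSV (gene<TAB>state with state in {0,1})."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "gene" not in cols or "state" not in cols:
        raise FormatError(f"{path}: expected columns gene/state, found {list(df.columns)}")
    states = df[cols["state"]].astype(int)
    if not states.isin([0, 1]).all():
        raise FormatError(f"{path}: states must be 0 or 1")
    genes = df[cols["gene"]].astype(str)
    if genes.duplicated().any():
        raise FormatError(f"{path}: duplicate genes")
    return dict(zip(genes, states))


def write_profile(profile: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"gene": list(profile), "state": [int(v) for v in profile.values()]}
    ).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> set[str]:
    """One symbol per line; blank lines and ``#`` comments ignored."""
    out = set()
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if ln and not ln.startswith("#"):
            out.add(ln.split("\t")[0])
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets in GMT format (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        parts = ln.rstrip().split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT rows need name, description, members")
        sets[parts[0]] = set(parts[2:])
    return sets
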