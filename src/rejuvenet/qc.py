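"""Cell quality control and Calinski-Harabasz clustering selection.

QC filtering is threshold-free: cells are dropped when a metric lies more
than ``nmads`` median absolute deviations from the per-dataset median.
Clustering candidates (produced by any algorithm — Leiden over a resolution
sweep in the intended use) are scored with the Calinski-Harabasz index and
the best one kept, unless it fragments into more than ``max_clusters``
clusters, in which case a caller-supplied coarse fallback partition is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .io import CellMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "InvalidClusteringError",
    "ClusteringCandidate",
    "compute_qc_metrics",
    "mad_filter",
    "calinski_harabasz",
    "select_clustering",
]


class InvalidClusteringError(ValueError):
    """A clustering candidate is degenerate (k = 1 or k = n)."""


@dataclass
class ClusteringCandidate:
    labels: np.ndarray
    resolution_tag: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.size == 0:
            raise ValueError("candidate has no labels")

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def compute_qc_metrics(
    m: CellMatrix,
    mito_prefix: str = "mt-",
    ribo_prefixes: Sequence[str] = ("Rps", "Rpl"),
) -> pd.DataFrame:
    """Per-cell QC metrics: pct_mito, pct_ribo, n_features, n_counts, empty.

    Prefix matching is exact (case-sensitive); pick the dialect for the
    species at hand ("mt-" for mouse, "MT-" for human). Cells with zero
    counts are flagged ``empty`` for unconditional removal; their pct
    metrics are reported as 0.
    """
    counts = m.counts.tocsc()
    genes = np.asarray(m.gene_ids)
    mito_mask = np.char.startswith(genes.astype(str), mito_prefix)
    ribo_mask = np.zeros(len(genes), dtype=bool)
    for p in ribo_prefixes:
        ribo_mask |= np.char.startswith(genes.astype(str), p)
    if not mito_mask.any():
        logger.warning("no gene matches mitochondrial prefix %r", mito_prefix)
    if not ribo_mask.any():
        logger.warning("no gene matches ribosomal prefixes %r", tuple(ribo_prefixes))

    n_counts = np.asarray(counts.sum(axis=0)).ravel()
    n_features = counts.getnnz(axis=0)
    mito = np.asarray(counts[mito_mask, :].sum(axis=0)).ravel()
    ribo = np.asarray(counts[ribo_mask, :].sum(axis=0)).ravel()
    empty = n_counts == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(empty, 0.0, mito / np.maximum(n_counts, 1))
        pct_ribo = np.where(empty, 0.0, ribo / np.maximum(n_counts, 1))
    return pd.DataFrame(
        {
            "pct_mito": pct_mito,
            "pct_ribo": pct_ribo,
            "n_features": n_features.astype(int),
            "n_counts": n_counts.astype(int),
            "empty": empty,
        },
        index=pd.Index(m.cell_ids, name="barcode"),
    )


def _mad_bounds(values: np.ndarray, nmads: float, upper_only: bool = False):
    """(lo, hi) MAD fence.

    An all-identical metric passes every cell (degenerate rule, logged).
    A zero MAD on a non-constant metric collapses the fence to the median:
    more than half the cells sit exactly at the median, and anything off
    it (above it, for upper-sided criteria) is an outlier.
    """
    med = float(np.median(values))
    mad = float(median_abs_deviation(values, scale="normal"))
    if mad == 0.0 and np.all(values == values[0]):
        logger.info("constant QC metric; criterion passes all cells")
        return -np.inf, np.inf
    if mad == 0.0:
        logger.info("zero MAD on a non-constant metric; fence collapses to the median")
    lo = -np.inf if upper_only else med - nmads * mad
    return lo, med + nmads * mad


def mad_filter(qc: pd.DataFrame, nmads: float = 3.0) -> pd.Index:
    """Barcodes of cells passing every MAD criterion.

    Criteria (conjunctive): pct_mito below median + nmads*MAD (upper-sided
    — low mitochondrial content is never a damage signal); pct_ribo,
    log10(n_features) and log10(n_counts) within median +/- nmads*MAD; and
    the residual of the least-squares fit log10(n_features) ~
    log10(n_counts) within +/- nmads*MAD of the residual distribution.
    Empty cells are removed unconditionally. MAD is scaled by the normal
    consistency constant 1.4826; a zero MAD makes that criterion pass all
    cells.
    """
    if len(qc) < 3:
        raise ValueError("mad_filter needs at least 3 cells")
    live = qc[~qc["empty"]]
    lf = np.log10(live["n_features"].to_numpy(dtype=float))
    lc = np.log10(live["n_counts"].to_numpy(dtype=float))
    if np.ptp(lc) == 0:  # constant depth: the fit degenerates to the mean
        slope, intercept = 0.0, float(np.mean(lf))
    else:
        slope, intercept = np.polyfit(lc, lf, deg=1)
    resid = lf - (slope * lc + intercept)

    keep = np.ones(len(live), dtype=bool)
    for values, upper_only in [
        (live["pct_mito"].to_numpy(dtype=float), True),
        (live["pct_ribo"].to_numpy(dtype=float), False),
        (lf, False),
        (lc, False),
        (resid, False),
    ]:
        lo, hi = _mad_bounds(values, nmads, upper_only=upper_only)
        keep &= (values >= lo) & (values <= hi)
    kept = live.index[keep]
    logger.info("mad_filter kept %d / %d cells", len(kept), len(qc))
    return kept


def calinski_harabasz(embedding: np.ndarray, labels: Sequence) -> float:
    """Calinski-Harabasz index: [B/(k-1)] / [W/(n-k)].

    B is the size-weighted between-cluster sum of squared centroid
    distances to the grand centroid, W the within-cluster sum of squares.
    W = 0 (all clusters are single points or duplicates) returns +inf,
    which ranks above every finite score. k = 1 or k = n is signalled as
    :class:`InvalidClusteringError`.
    """
    x = np.asarray(embedding, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    labels = np.asarray(labels)
    n = x.shape[0]
    uniq, inv = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2 or k >= n:
        raise InvalidClusteringError(f"k={k} undefined for n={n}")
    grand = x.mean(axis=0)
    b = w = 0.0
    for ci in range(k):
        pts = x[inv == ci]
        centroid = pts.mean(axis=0)
        b += len(pts) * float(np.sum((centroid - grand) ** 2))
        w += float(np.sum((pts - centroid) ** 2))
    if w == 0.0:
        return np.inf
    return (b / (k - 1)) / (w / (n - k))


def select_clustering(
    embedding: np.ndarray,
    candidates: Sequence[ClusteringCandidate],
    max_clusters: int = 30,
    fallback: ClusteringCandidate | None = None,
) -> np.ndarray:
    """Pick the candidate with the highest Calinski-Harabasz score.

    Degenerate candidates (k = 1 or k = n) are skipped. Ties break toward
    fewer clusters, then input order. If the winner has more than
    ``max_clusters`` clusters the fallback partition is returned instead.
    """
    scored = []
    for i, cand in enumerate(candidates):
        try:
            s = calinski_harabasz(embedding, cand.labels)
        except InvalidClusteringError:
            logger.info("skipping degenerate candidate %s", cand.resolution_tag)
            continue
        scored.append((-s, cand.n_clusters, i, cand))
    if not scored:
        raise InvalidClusteringError("no valid clustering candidate")
    scored.sort(key=lambda t: t[:3])
    best = scored[0][3]
    if best.n_clusters > max_clusters:
        if fallback is None:
            raise ValueError(
                f"best candidate has {best.n_clusters} > {max_clusters} clusters "
                "and no fallback was provided"
            )
        logger.info(
            "best candidate %s has %d clusters (> %d); using fallback %s",
            best.resolution_tag, best.n_clusters, max_clusters,
            fallback.resolution_tag,
        )
        return np.asarray(fallback.labels)
    return np.asarray(best.labels)
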