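"""Tissue-specificity calling from an FPKM atlas.

A gene is *tissue-specific* when it is strongly expressed in exactly one
tissue (FPKM above ``high_threshold``, default 100) while being unexpressed
or only weakly expressed everywhere else (FPKM below ``low_threshold``,
default 10).  Genes whose expression never reaches ``detection_threshold``
(default 1 FPKM) in any tissue are set aside as undetected before calling.

The module also provides the downstream reporting used for atlas summaries:
expression-level binning of the calls, per-gene row Z-scores, and a
complete-linkage leaf order for heatmap display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CallerConfig",
    "SpecificityCall",
    "BIN_LABELS",
    "BIN_EDGES",
    "expression_bin",
    "filter_undetected",
    "call_tissue_specific",
    "bin_by_level",
    "bin_share",
    "row_zscore",
    "cluster_order",
]

#: Expression-level bins for called genes, half-open [a, b) with the
#: boundary assigned to the upper bin; the last bin is unbounded above.
BIN_LABELS = ("100–500", "500–1000", "1000–5000", ">5000")
BIN_EDGES = (100.0, 500.0, 1000.0, 5000.0, np.inf)


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds of the specificity caller, in FPKM.

    ``strict_zero`` switches the off-target rule from 0 <= FPKM < low
    (default: a silent gene supports specificity) to the literal
    0 < FPKM < low, which would reject genes with any fully silent
    off-target tissue.
    """

    high_threshold: float = 100.0
    low_threshold: float = 10.0
    detection_threshold: float = 1.0
    strict_zero: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.detection_threshold <= self.low_threshold < self.high_threshold):
            raise ValueError(
                "thresholds must satisfy 0 <= detection <= low < high; got "
                f"detection={self.detection_threshold}, low={self.low_threshold}, "
                f"high={self.high_threshold}"
            )


@dataclass(frozen=True)
class SpecificityCall:
    """One gene's tissue-specific assignment."""

    gene_id: str
    target_tissue: str
    target_fpkm: float
    max_off_target_fpkm: float
    bin_label: str = field(default="")

    def __post_init__(self) -> None:
        if not self.bin_label:
            object.__setattr__(self, "bin_label", expression_bin(self.target_fpkm))


def expression_bin(fpkm: float) -> str:
    """Bin label for a called gene's target FPKM.

    Bins are half-open [100,500), [500,1000), [1000,5000), [5000,inf);
    a boundary value belongs to the upper bin.
    """
    if fpkm < BIN_EDGES[0]:
        raise ValueError(f"called gene must have target FPKM > 100, got {fpkm}")
    idx = int(np.searchsorted(BIN_EDGES[1:-1], fpkm, side="right"))
    return BIN_LABELS[idx]


def filter_undetected(
    matrix: ExpressionMatrix, config: CallerConfig = CallerConfig()
) -> tuple[ExpressionMatrix, list[str]]:
    """Split the catalog into detected genes and undetected gene ids.

    A gene is undetected iff its maximum FPKM over all tissues is strictly
    below ``config.detection_threshold``.  Input order is preserved on both
    sides of the partition.
    """
    vals = matrix.values()
    undet_mask = vals.max(axis=1) < config.detection_threshold
    genes = np.asarray(matrix.gene_ids, dtype=object)
    detected = ExpressionMatrix(matrix.data.loc[~undet_mask])
    return detected, list(genes[undet_mask])


def call_tissue_specific(
    matrix: ExpressionMatrix, config: CallerConfig = CallerConfig()
) -> list[SpecificityCall]:
    """Call tissue-specific genes under the threshold rule.

    A gene is called for tissue *t* iff FPKM(t) > ``high_threshold`` and
    every other tissue is below ``low_threshold`` (strictly; zero counts as
    "unexpressed" and is allowed unless ``strict_zero``).  The thresholds
    guarantee at most one call per gene.  Undetected genes are filtered
    first.  Output is sorted by (target_tissue, descending target FPKM,
    gene id).
    """
    detected, _ = filter_undetected(matrix, config)
    vals = detected.values()
    genes = detected.gene_ids
    tissues = detected.tissue_labels

    high = vals > config.high_threshold
    low = vals < config.low_threshold
    if config.strict_zero:
        low &= vals > 0
    # called iff the target column is high and all n-1 others are low
    ok = high & (low.sum(axis=1, keepdims=True) - low == vals.shape[1] - 1)

    calls = []
    for r, c in np.argwhere(ok):
        off = np.delete(vals[r], c)
        calls.append(
            SpecificityCall(
                gene_id=genes[r],
                target_tissue=tissues[c],
                target_fpkm=float(vals[r, c]),
                max_off_target_fpkm=float(off.max()),
            )
        )
    calls.sort(key=lambda s: (s.target_tissue, -s.target_fpkm, s.gene_id))
    return calls


def calls_to_frame(calls: list[SpecificityCall]) -> pd.DataFrame:
    """Tabular view of calls (gene, target tissue, FPKM, max off-target, bin)."""
    return pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "target_tissue": s.target_tissue,
                "target_fpkm": s.target_fpkm,
                "max_off_target_fpkm": s.max_off_target_fpkm,
                "bin": s.bin_label,
            }
            for s in calls
        ],
        columns=["gene_id", "target_tissue", "target_fpkm", "max_off_target_fpkm", "bin"],
    )


def bin_by_level(calls: list[SpecificityCall]) -> pd.DataFrame:
    """Count calls per (tissue, expression bin).

    Returns a tissue × bin DataFrame whose row sums equal the per-tissue
    call counts.  Bin boundaries are half-open, boundary upward.
    """
    tissues = sorted({s.target_tissue for s in calls})
    table = pd.DataFrame(0, index=tissues, columns=list(BIN_LABELS), dtype=int)
    table.index.name = "tissue"
    for s in calls:
        table.loc[s.target_tissue, expression_bin(s.target_fpkm)] += 1
    return table


def bin_share(bin_counts: dict[str, int] | pd.Series, total: int) -> float:
    """Percentage of all called genes falling in one expression bin.

    ``bin_counts`` holds the per-tissue counts of that bin (e.g. the
    1000–5000 class); ``total`` is the overall number of tissue-specific
    calls.  Returns 100 × Σcounts / total.
    """
    if total <= 0:
        raise ValueError("total call count must be positive")
    counts = pd.Series(bin_counts)
    if (counts < 0).any():
        raise ValueError("bin counts must be non-negative")
    return float(100.0 * counts.sum() / total)


def row_zscore(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene standardization (x − row mean) / row sd, sample sd (n−1).

    Constant rows have zero variance and are mapped to all-zero with a
    logged warning; every other row comes out with mean 0 and sample sd 1.
    """
    vals = matrix.values()
    if vals.shape[1] < 2:
        raise ValueError("row Z-scores need at least 2 tissues")
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        names = [matrix.gene_ids[i] for i in np.flatnonzero(flat)[:5]]
        logger.warning(
            "%d constant row(s) mapped to all-zero Z-scores (e.g. %s)",
            int(flat.sum()), names,
        )
    z = np.divide(vals - mean, sd, out=np.zeros_like(vals), where=sd != 0)
    return pd.DataFrame(z, index=matrix.gene_ids, columns=matrix.tissue_labels)


def cluster_order(zmatrix: pd.DataFrame | np.ndarray) -> list[int]:
    """Dendrogram leaf order from complete-linkage clustering.

    Agglomerative clustering on Euclidean row distances with complete
    linkage (inter-cluster distance = maximum pairwise member distance),
    the combination conventionally used for expression heatmaps.  Equal
    merge distances resolve to the earliest-formed (smallest original
    index) pair, so the order is deterministic.
    """
    arr = np.asarray(zmatrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need a 2-D matrix with at least one row")
    if arr.shape[0] == 1:
        return [0]
    tree = linkage(pdist(arr, metric="euclidean"), method="complete")
    return [int(i) for i in leaves_list(tree)]
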