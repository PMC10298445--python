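"""Reading, validating and writing gene × tissue FPKM matrices.

The expression matrix is the entry point of the whole pipeline: rows are
genes, columns are tissues, cells are non-negative FPKM values (fragments
per kilobase of transcript per million mapped reads).  The matrix is dense:
every (gene, tissue) cell must be present, duplicates on either axis are
rejected, and at least two tissues are required (tissue specificity is
meaningless against a single tissue).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "validate_matrix",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A dense gene × tissue FPKM matrix.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with one column per tissue, float64
        FPKM values.  The index and columns must be unique and the values
        finite and non-negative for the matrix to be *valid*; use
        :func:`validate_matrix` to check without raising.
    """

    data: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def tissue_labels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Row subset preserving the given order."""
        return ExpressionMatrix(self.data.loc[list(gene_ids)])

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.tissue_labels == other.tissue_labels
            and np.array_equal(self.values(), other.values())
        )


def _hard_validate(frame: pd.DataFrame, source: str) -> None:
    if frame.shape[1] < 2:
        raise ValueError(
            f"{source}: expression matrix needs at least 2 tissues, "
            f"found {frame.shape[1]}"
        )
    dup_genes = frame.index[frame.index.duplicated()].unique()
    if len(dup_genes):
        raise ValueError(f"{source}: duplicate gene id(s): {list(dup_genes)}")
    dup_tissues = [t for t in frame.columns[frame.columns.duplicated()]]
    if dup_tissues:
        raise ValueError(f"{source}: duplicate tissue label(s): {dup_tissues}")
    bad = ~np.isfinite(frame.to_numpy()) | (frame.to_numpy() < 0)
    if bad.any():
        r, c = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"{source}: invalid FPKM at gene {frame.index[r]!r}, "
            f"tissue {frame.columns[c]!r}: {frame.iat[r, c]!r} "
            "(must be finite and >= 0)"
        )


def read_expression_matrix(
    path,
    delimiter: str = "\t",
    tissue_map: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a delimited gene × tissue FPKM table.

    The first row is the tissue header, the first column the gene id.
    Scientific notation is accepted; values are kept at double precision.

    Parameters
    ----------
    tissue_map
        Optional column → tissue-label map.  Columns mapping to the same
        tissue label (replicate libraries) are collapsed by arithmetic
        mean; unmapped columns keep their own label.

    Raises
    ------
    ValueError
        On duplicate gene ids, fewer than two tissues, missing cells, or
        negative / non-numeric values (the offending coordinate is named).
    """
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    frame = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        try:
            frame[col] = raw[col].astype(float)
        except (TypeError, ValueError):
            bad_rows = raw.index[pd.to_numeric(raw[col], errors="coerce").isna()]
            raise ValueError(
                f"{path}: non-numeric FPKM at gene {bad_rows[0]!r}, "
                f"tissue {col!r}"
            ) from None
    if frame.isna().to_numpy().any():
        r, c = map(int, np.argwhere(frame.isna().to_numpy())[0])
        raise ValueError(
            f"{path}: missing FPKM at gene {frame.index[r]!r}, "
            f"tissue {frame.columns[c]!r}"
        )
    if tissue_map:
        frame = frame.rename(columns=dict(tissue_map))
        frame = frame.T.groupby(level=0, sort=False).mean().T
    _hard_validate(frame, str(path))
    return ExpressionMatrix(frame)


def write_expression_matrix(matrix: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    """Write a TSV re-readable by :func:`read_expression_matrix`.

    Values are serialized with :func:`repr`-grade precision so the
    round-trip is exact at double precision.
    """
    frame = matrix.data.copy()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep=delimiter, float_format="%.17g")


def validate_matrix(matrix: ExpressionMatrix) -> list[str]:
    """Report invariant violations; an empty list means the matrix is valid.

    Never raises: each violation is a human-readable string naming the
    offending label or cell.
    """
    violations: list[str] = []
    frame = matrix.data
    if frame.shape[1] < 2:
        violations.append(f"fewer than 2 tissues ({frame.shape[1]})")
    for g in frame.index[frame.index.duplicated()].unique():
        violations.append(f"duplicate gene id: {g!r}")
    seen: set[str] = set()
    for t in frame.columns:
        if t in seen:
            violations.append(f"duplicate tissue label: {t!r}")
        seen.add(t)
    vals = frame.to_numpy(dtype=float)
    for r, c in np.argwhere(~np.isfinite(vals) | (vals < 0)):
        violations.append(
            f"invalid FPKM at gene {frame.index[r]!r}, "
            f"tissue {frame.columns[c]!r}: {frame.iat[int(r), int(c)]!r}"
        )
    return violations
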