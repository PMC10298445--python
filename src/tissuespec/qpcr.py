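"""Relative-expression analysis of qPCR Ct tables and specificity verdicts.

Expression is quantified with the 2^−ΔCT method: for each replicate,
ΔCT = Ct(target gene) − Ct(reference gene) in the same tissue sample, and
relative expression is 2^−ΔCT (one extra cycle of the target halves the
estimate).  Replicates are paired by replicate id with the reference
(housekeeping) gene measured in the same tissue.

A predicted tissue-specific gene is *validated* when its target-tissue
mean relative expression is strictly highest and a two-sample Student
t-test on log2 relative expression is significant against every other
detected tissue.  Tissues where the target was never detected (N.D.)
cannot defeat specificity — they contribute no comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CtTable",
    "ValidationVerdict",
    "load_ct_table",
    "relative_expression",
    "compare_tissues",
    "significance_code",
    "validate_specificity",
]

ND_TOKENS = {"ND", "N.D.", "N.D", "ND.", "nd", ""}


@dataclass
class CtTable:
    """Replicate Ct measurements for target and reference genes.

    ``data`` columns: gene_id, tissue, replicate, ct (float; NaN encodes
    a not-detected well).  ``reference_gene_id`` names the housekeeping
    gene used for normalization.
    """

    data: pd.DataFrame
    reference_gene_id: str

    def __post_init__(self) -> None:
        required = {"gene_id", "tissue", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing column(s): {sorted(missing)}")
        bad = self.data["ct"].dropna() <= 0
        if bad.any():
            row = self.data.loc[bad[bad].index[0]]
            raise ValueError(
                f"non-positive Ct for gene {row.gene_id!r} in {row.tissue!r}"
            )
        targets = self.data[self.data["gene_id"] != self.reference_gene_id]
        ref = self.data[self.data["gene_id"] == self.reference_gene_id]
        for tissue in targets.loc[targets["ct"].notna(), "tissue"].unique():
            if ref[(ref["tissue"] == tissue) & ref["ct"].notna()].empty:
                raise ValueError(
                    f"reference gene {self.reference_gene_id!r} has no "
                    f"measurement in tissue {tissue!r}"
                )

    @property
    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.data["tissue"]))

    @property
    def gene_ids(self) -> list[str]:
        genes = dict.fromkeys(self.data["gene_id"])
        genes.pop(self.reference_gene_id, None)
        return list(genes)


@dataclass(frozen=True)
class ValidationVerdict:
    """Per-gene outcome of the qPCR specificity check."""

    gene_id: str
    predicted_tissue: str
    verdict: str  # "specific" | "not_specific" | "not_detected"
    mean_expression: dict[str, float] = field(default_factory=dict)
    sd_expression: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    codes: dict[str, str] = field(default_factory=dict)


def load_ct_table(path, reference_gene_id: str) -> CtTable:
    """Load a Ct CSV (gene_id, tissue, replicate, ct).

    ND tokens ("ND", "N.D.", empty cell) become not-detected wells.
    """
    frame = pd.read_csv(path, dtype={"gene_id": str, "tissue": str, "replicate": str})
    frame.columns = [c.strip() for c in frame.columns]
    ct = frame["ct"].astype(str).str.strip()
    frame["ct"] = pd.to_numeric(ct.where(~ct.isin(ND_TOKENS) & (ct != "nan")), errors="raise")
    return CtTable(frame, reference_gene_id)


def write_ct_table(table: CtTable, path) -> None:
    out = table.data.copy()
    out["ct"] = out["ct"].map(lambda v: "ND" if pd.isna(v) else f"{v:.17g}")
    out.to_csv(path, index=False)


def relative_expression(table: CtTable, gene_id: str, tissue: str) -> pd.Series:
    """Per-replicate 2^−ΔCT of one gene in one tissue.

    Replicates are paired with the reference gene by replicate id;
    unpaired replicates are dropped with a warning.  A tissue where all
    target wells are ND yields an empty series (not detected).
    """
    d = table.data
    tgt = d[(d["gene_id"] == gene_id) & (d["tissue"] == tissue)].set_index("replicate")["ct"]
    ref = d[(d["gene_id"] == table.reference_gene_id) & (d["tissue"] == tissue)]
    ref = ref.set_index("replicate")["ct"]
    if tgt.empty:
        raise ValueError(f"gene {gene_id!r} not measured in tissue {tissue!r}")
    tgt = tgt.dropna()
    if tgt.empty:
        return pd.Series(dtype=float, name=gene_id)  # all ND
    paired = tgt.index.intersection(ref.dropna().index)
    dropped = tgt.index.difference(paired)
    if len(dropped):
        logger.warning(
            "gene %s in %s: %d unpaired replicate(s) dropped", gene_id, tissue, len(dropped)
        )
    dct = tgt.loc[paired] - ref.loc[paired]
    return pd.Series(np.power(2.0, -dct.to_numpy()), index=paired, name=gene_id)


def significance_code(p: float) -> str:
    """Star code: *** p<0.001, ** p<0.01, otherwise n.s."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return "n.s."


def compare_tissues(
    values_target,
    values_other,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> tuple[float, str]:
    """Two-sided two-sample Student t-test on log2 relative expression.

    Classic equal-variance test by default; ``equal_var=False`` gives the
    Welch variant.  With zero variance on both sides and equal means the
    p-value is 1.  Requires at least two replicates per side.
    """
    a = np.log2(np.asarray(values_target, dtype=float))
    b = np.log2(np.asarray(values_other, dtype=float))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 replicates on each side of the t-test")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        p = 1.0 if math.isclose(a.mean(), b.mean()) else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    return p, significance_code(p)


def validate_specificity(
    table: CtTable,
    predictions: dict[str, str],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> tuple[list[ValidationVerdict], float]:
    """Check each predicted gene → tissue assignment against the Ct data.

    A gene is ``specific`` iff its predicted-tissue mean relative
    expression is strictly highest among detected tissues and every
    pairwise t-test against a detected non-target tissue has p < alpha.
    ``not_detected`` means the target tissue itself had only ND wells.
    Returns the verdicts and the consistency percentage,
    100 × #specific / #predictions.
    """
    if not predictions:
        raise ValueError("no predictions to validate")
    missing = [g for g in predictions if g not in set(table.data["gene_id"])]
    if missing:
        raise ValueError(f"predicted gene(s) absent from Ct table: {missing}")

    verdicts: list[ValidationVerdict] = []
    for gene_id, target in predictions.items():
        values = {t: relative_expression(table, gene_id, t) for t in table.tissues}
        means = {t: float(v.mean()) for t, v in values.items() if len(v)}
        sds = {t: float(v.std(ddof=1)) if len(v) > 1 else float("nan")
               for t, v in values.items() if len(v)}
        if target not in means:
            verdicts.append(
                ValidationVerdict(gene_id, target, "not_detected", means, sds)
            )
            continue
        p_values: dict[str, float] = {}
        codes: dict[str, str] = {}
        ok = all(means[target] > m for t, m in means.items() if t != target)
        for t in means:
            if t == target:
                continue
            p, code = compare_tissues(values[target], values[t], alpha, equal_var)
            p_values[t], codes[t] = p, code
            if p >= alpha:
                ok = False
        verdicts.append(
            ValidationVerdict(
                gene_id, target, "specific" if ok else "not_specific",
                means, sds, p_values, codes,
            )
        )
    n_specific = sum(v.verdict == "specific" for v in verdicts)
    consistency = 100.0 * n_specific / len(predictions)
    return verdicts, consistency


def verdicts_to_frame(verdicts: list[ValidationVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": v.gene_id,
                "predicted_tissue": v.predicted_tissue,
                "verdict": v.verdict,
                "target_mean": v.mean_expression.get(v.predicted_tissue, float("nan")),
                "max_other_mean": max(
                    (m for t, m in v.mean_expression.items() if t != v.predicted_tissue),
                    default=float("nan"),
                ),
                "worst_p": max(v.p_values.values(), default=float("nan")),
            }
            for v in verdicts
        ],
        columns=["gene_id", "predicted_tissue", "verdict", "target_mean",
                 "max_other_mean", "worst_p"],
    )
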