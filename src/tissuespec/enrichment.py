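"""Over-representation testing of gene sets against a term annotation.

Given a study set (e.g. the tissue-specific genes of one tissue) and a
gene → term map (GO terms, KEGG pathways, or any other categorical
annotation supplied by the user), each term is scored with the one-sided
hypergeometric over-representation tail: the probability of drawing at
least the observed number of term-annotated genes when sampling the study
set at random from the background.  Terms with raw p < alpha are flagged
significant; Benjamini–Hochberg adjusted p-values are reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationMap",
    "EnrichmentResult",
    "load_annotation",
    "hypergeom_pvalue",
    "enrich",
]


@dataclass
class AnnotationMap:
    """Gene → term annotation with an explicit background universe."""

    term_to_genes: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    background: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for term, genes in self.term_to_genes.items():
            if not genes:
                raise ValueError(f"term {term!r} annotates no genes")
            stray = genes - self.background
            if stray:
                raise ValueError(
                    f"term {term!r} annotates gene(s) outside the background: "
                    f"{sorted(stray)[:5]}"
                )


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation outcome.

    k of the n study genes carry the term; K of the N background genes do.
    """

    term_id: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    p_adjusted: float
    significant: bool
    description: str = ""


def load_annotation(path, background: set[str] | None = None) -> AnnotationMap:
    """Load a gene → term TSV (gene_id, term_id[, description]).

    Duplicate (gene, term) lines collapse to one (set semantics).  Unless
    an explicit ``background`` is given, the background is every gene that
    appears in the file — including genes annotated to no term if they
    occur with an empty term field.
    """
    frame = pd.read_csv(
        path, sep="\t", header=None, dtype=str, comment="#",
        names=["gene_id", "term_id", "description"],
    )
    if frame.empty:
        raise ValueError(f"{path}: empty annotation file")
    term_to_genes: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    seen_genes: set[str] = set()
    for row in frame.itertuples(index=False):
        seen_genes.add(row.gene_id)
        if pd.isna(row.term_id) or row.term_id == "":
            continue  # background-only gene
        term_to_genes.setdefault(row.term_id, set()).add(row.gene_id)
        if isinstance(row.description, str) and row.description:
            descriptions[row.term_id] = row.description
    return AnnotationMap(
        term_to_genes=term_to_genes,
        descriptions=descriptions,
        background=background if background is not None else seen_genes,
    )


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """One-sided over-representation tail P(X >= k), X ~ Hypergeom(N, K, n).

    N background genes of which K carry the term; n study genes of which k
    carry it.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(
            f"invalid hypergeometric parameters k={k}, n={n}, K={K}, N={N}"
        )
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    study: set[str],
    annotation: AnnotationMap,
    alpha: float = 0.05,
    flag_on_adjusted: bool = False,
) -> list[EnrichmentResult]:
    """Test every term hit by the study set for over-representation.

    Study genes outside the background are dropped with a warning.  One
    result per term with k >= 1, sorted ascending by raw p-value.  The
    ``significant`` flag uses the raw p < alpha rule by default;
    ``flag_on_adjusted`` switches it to the BH-adjusted p-value.
    """
    stray = study - annotation.background
    if stray:
        logger.warning(
            "%d study gene(s) outside the background dropped (e.g. %s)",
            len(stray), sorted(stray)[:5],
        )
    study_in = study & annotation.background
    if not study_in:
        raise ValueError("study set is empty after intersecting the background")

    N = len(annotation.background)
    n = len(study_in)
    rows = []
    for term, genes in annotation.term_to_genes.items():
        k = len(study_in & genes)
        if k == 0:
            continue
        K = len(genes)
        rows.append((term, k, K, hypergeom_pvalue(k, n, K, N)))
    if not rows:
        return []
    padj = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            term_id=term,
            k=k,
            n=n,
            K=K,
            N=N,
            p_value=p,
            p_adjusted=float(pa),
            significant=bool((pa if flag_on_adjusted else p) < alpha),
            description=annotation.descriptions.get(term, ""),
        )
        for (term, k, K, p), pa in zip(rows, padj)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
                "description": r.description,
            }
            for r in results
        ],
        columns=["term_id", "k", "n", "K", "N", "p_value", "p_adjusted",
                 "significant", "description"],
    )
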