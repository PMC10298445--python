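"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of its seed and emits exactly the
formats the analysis modules read, together with a :class:`TruthTable`
recording what was planted.  The expression generator emulates the shape
of a bulk plant transcriptome atlas: a large gene catalog, a small planted
fraction of tissue-specific genes per tissue with margins well clear of
the caller thresholds, an undetected fraction, and skewed FPKM magnitudes
whose right tail reaches the >5000 class (seed storage-protein genes in
real atlases reach tens of thousands of FPKM).

The planted margins are deliberately generous (targets >= 150 FPKM,
off-targets <= 8 FPKM, undetected <= 0.5 FPKM against 100/10/1
thresholds), so the caller must recover the planted truth exactly; the
generators probe bookkeeping correctness, not borderline calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix
from .motifs import IUPAC_SETS, Motif
from .qpcr import CtTable

__all__ = [
    "TruthTable",
    "SOYBEAN_TISSUES",
    "SOYBEAN_SPECIFIC_COUNTS",
    "SOYBEAN_N_GENES",
    "SOYBEAN_N_UNDETECTED",
    "gen_expression_matrix",
    "soybean_scale_matrix",
    "gen_genome_annotation",
    "plant_motifs",
    "gen_ct_table",
    "qpcr_case_study",
]

#: The nine tissues of the soybean RNA-seq atlas the pipeline targets.
SOYBEAN_TISSUES = (
    "leaf", "stem", "SAM", "flower", "pod", "seed", "root", "root_hair", "nodule",
)

#: Planted per-tissue specific-gene counts for the full-catalog scenario
#: (flower-dominated, none in SAM or root hair, a handful elsewhere).
SOYBEAN_SPECIFIC_COUNTS = {
    "flower": 117, "seed": 99, "root": 40, "leaf": 21, "pod": 6, "stem": 3, "nodule": 2,
}

SOYBEAN_N_GENES = 56044
SOYBEAN_N_UNDETECTED = 3731


@dataclass
class TruthTable:
    """Ground truth planted by the generators, serializable to JSON."""

    planted_specific: dict[str, str] = field(default_factory=dict)
    planted_undetected: set[str] = field(default_factory=set)
    planted_motifs: dict[str, list[tuple[str, int, str, str]]] = field(default_factory=dict)
    planted_fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)
    gene_anchors: dict[str, tuple[str, str, int]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "planted_specific": self.planted_specific,
            "planted_undetected": sorted(self.planted_undetected),
            "planted_motifs": self.planted_motifs,
            "planted_fold_changes": self.planted_fold_changes,
            "gene_anchors": self.gene_anchors,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def gen_expression_matrix(
    n_genes: int,
    tissues=SOYBEAN_TISSUES,
    spec_per_tissue: dict[str, int] | None = None,
    n_undetected: int = 0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, TruthTable]:
    """Simulate an FPKM atlas with planted specific and undetected genes.

    Planted specific genes draw their target FPKM log-uniformly in
    [150, 20000] (populating every expression bin including the >5000
    tail) and off-target FPKM uniformly in [0, 8].  Undetected genes draw
    all tissues uniformly in [0, 0.5].  The remaining background genes
    draw a skewed log-normal profile, post-adjusted so that none of them
    satisfies the specificity rule or falls below the 1-FPKM detection
    floor (either at least two tissues exceed 100 FPKM or an off-target
    lands in [10, 100]).
    """
    tissues = list(tissues)
    spec_per_tissue = dict(spec_per_tissue or {})
    unknown = set(spec_per_tissue) - set(tissues)
    if unknown:
        raise ValueError(f"spec_per_tissue names unknown tissue(s): {sorted(unknown)}")
    n_specific = sum(spec_per_tissue.values())
    if n_specific + n_undetected > n_genes:
        raise ValueError(
            f"cannot plant {n_specific} specific + {n_undetected} undetected "
            f"genes in a {n_genes}-gene catalog"
        )
    rng = np.random.default_rng(seed)
    n_t = len(tissues)
    vals = np.empty((n_genes, n_t))

    order = rng.permutation(n_genes)
    spec_idx = order[:n_specific]
    undet_idx = order[n_specific:n_specific + n_undetected]
    bg_idx = order[n_specific + n_undetected:]

    truth = TruthTable()
    width = max(6, len(str(n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(n_genes)]

    # planted tissue-specific genes
    pos = 0
    for tissue, count in spec_per_tissue.items():
        col = tissues.index(tissue)
        for i in spec_idx[pos:pos + count]:
            row = rng.uniform(0.0, 8.0, n_t)
            row[col] = np.exp(rng.uniform(np.log(150.0), np.log(20000.0)))
            vals[i] = row
            truth.planted_specific[genes[i]] = tissue
        pos += count

    # undetected genes: minor expression everywhere
    vals[undet_idx] = rng.uniform(0.0, 0.5, (len(undet_idx), n_t))
    truth.planted_undetected = {genes[i] for i in undet_idx}

    # background: skewed, detected, never tissue-specific
    m = len(bg_idx)
    bg = rng.lognormal(mean=1.5, sigma=1.5, size=(m, n_t))
    high = bg > 100.0
    low = bg < 10.0
    would_call = (high & (low.sum(axis=1, keepdims=True) - low == n_t - 1)).any(axis=1)
    if would_call.any():
        rows = np.flatnonzero(would_call)
        other = (bg[rows].argmax(axis=1) + 1) % n_t
        bg[rows, other] = rng.uniform(10.0, 100.0, len(rows))
    faint = bg.max(axis=1) < 1.0
    if faint.any():
        bg[np.flatnonzero(faint), 0] = rng.uniform(1.0, 100.0, int(faint.sum()))
    vals[bg_idx] = bg

    frame = pd.DataFrame(vals, index=genes, columns=tissues)
    frame.index.name = "gene_id"
    return ExpressionMatrix(frame), truth


def soybean_scale_matrix(seed: int = 0) -> tuple[ExpressionMatrix, TruthTable]:
    """The full-catalog scenario: 56,044 genes × 9 tissues, 3,731 planted
    undetected, and 288 planted tissue-specific genes across 7 tissues."""
    return gen_expression_matrix(
        SOYBEAN_N_GENES,
        SOYBEAN_TISSUES,
        SOYBEAN_SPECIFIC_COUNTS,
        SOYBEAN_N_UNDETECTED,
        seed,
    )


def gen_genome_annotation(
    n_genes: int,
    chrom_length: int,
    seed: int = 0,
    chrom: str = "Chr01",
    cds_length: int = 300,
) -> tuple[dict[str, str], list[str], TruthTable]:
    """Simulate a toy chromosome with strand-alternating single-CDS genes.

    Returns (genome map, GFF3 lines, truth).  Each CDS begins with an ATG
    on its own strand.  The first gene sits close to the left chromosome
    edge so that its promoter truncates; later genes have generous and
    variable upstream room.
    """
    spacing = chrom_length // n_genes
    if spacing < cds_length + 600:
        raise ValueError(
            f"{n_genes} genes of {cds_length} bp CDS overcrowd a "
            f"{chrom_length} bp chromosome"
        )
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=chrom_length, p=[0.325, 0.175, 0.175, 0.325])
    lines = ["##gff-version 3"]
    truth = TruthTable()
    for i in range(n_genes):
        gid = f"gene{i + 1:03d}"
        strand = "+" if i % 2 == 0 else "-"
        slot = i * spacing
        if i == 0:
            offset = int(rng.integers(400, 600))  # forces promoter truncation
        else:
            offset = int(rng.integers(300, spacing - cds_length - 100))
        cds_lo = slot + offset + 1  # 1-based
        cds_hi = cds_lo + cds_length - 1
        if strand == "+":
            seq[cds_lo - 1:cds_lo + 2] = list("ATG")
            anchor = cds_lo
        else:
            seq[cds_hi - 3:cds_hi] = list("CAT")  # revcomp ATG at the 3' genomic end
            anchor = cds_hi
        lines.append(
            f"{chrom}\ttoy\tgene\t{cds_lo}\t{cds_hi}\t.\t{strand}\t.\tID={gid}"
        )
        lines.append(
            f"{chrom}\ttoy\tmRNA\t{cds_lo}\t{cds_hi}\t.\t{strand}\t.\t"
            f"ID={gid}.1;Parent={gid}"
        )
        lines.append(
            f"{chrom}\ttoy\tCDS\t{cds_lo}\t{cds_hi}\t.\t{strand}\t0\t"
            f"ID={gid}.1.cds;Parent={gid}.1"
        )
        truth.gene_anchors[gid] = (chrom, strand, anchor)
    return {chrom: "".join(seq)}, lines, truth


def _resolve_word(consensus: str, rng: np.random.Generator) -> str:
    """Resolve a degenerate consensus to one concrete A/C/G/T word."""
    return "".join(
        rng.choice(sorted(IUPAC_SETS[c] - {"N"} or {"A"})) for c in consensus
    )


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def plant_motifs(
    promoter_lengths: dict[str, int],
    placements: dict[str, list[tuple[Motif, int, str]]],
    background_gc: float = 0.5,
    seed: int = 0,
) -> tuple[dict[str, str], TruthTable]:
    """Generate background promoter sequences and write motif words into them.

    Background bases are i.i.d. with the stated GC content.  Each
    placement (motif, start, strand) is resolved to a concrete word
    (degenerate positions drawn at random and recorded in the truth
    table) and written at the stated 0-based offset, reverse-complemented
    for − strand placements.  Overlapping placements within a promoter are
    a hard error.
    """
    rng = np.random.default_rng(seed)
    gc = background_gc / 2.0
    at = (1.0 - background_gc) / 2.0
    truth = TruthTable()
    sequences: dict[str, str] = {}
    for pid, length in promoter_lengths.items():
        seq = rng.choice(list("ACGT"), size=length, p=[at, gc, gc, at])
        intervals: list[tuple[int, int]] = []
        for motif, start, strand in placements.get(pid, []):
            w = len(motif.consensus)
            if start < 0 or start + w > length:
                raise ValueError(
                    f"{pid}: placement of {motif.name} at {start} exceeds "
                    f"promoter length {length}"
                )
            for lo, hi in intervals:
                if start < hi and start + w > lo:
                    raise ValueError(
                        f"{pid}: overlapping placements at [{start},{start + w}) "
                        f"and [{lo},{hi})"
                    )
            intervals.append((start, start + w))
            word = _resolve_word(motif.consensus, rng)
            seq[start:start + w] = list(word if strand == "+" else _revcomp(word))
            truth.planted_motifs.setdefault(pid, []).append(
                (motif.name, start, strand, word)
            )
        sequences[pid] = "".join(seq)
    return sequences, truth


def gen_ct_table(
    genes: list[str],
    tissues: list[str],
    fold_map: dict[str, dict[str, float]],
    noise_sd: float = 0.2,
    n_replicates: int = 3,
    seed: int = 0,
    reference_gene_id: str = "GmActin",
    base_ct: float = 20.0,
) -> CtTable:
    """Simulate a replicate Ct table with planted fold-changes.

    For each tissue and replicate the reference (housekeeping) gene draws
    Ct = base_ct + Normal(0, noise_sd); a target gene with planted fold f
    draws Ct = (that reference Ct) − log2(f) + Normal(0, noise_sd), so at
    zero noise its 2^−ΔCT is exactly f.  A fold of 0 is emitted as ND.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    rows = []
    for tissue in tissues:
        for rep in range(1, n_replicates + 1):
            ref_ct = base_ct + rng.normal(0.0, noise_sd)
            rows.append((reference_gene_id, tissue, f"r{rep}", ref_ct))
            for gene in genes:
                fold = fold_map.get(gene, {}).get(tissue, 1.0)
                if fold == 0:
                    rows.append((gene, tissue, f"r{rep}", np.nan))
                else:
                    ct = ref_ct - np.log2(fold) + rng.normal(0.0, noise_sd)
                    rows.append((gene, tissue, f"r{rep}", ct))
    frame = pd.DataFrame(rows, columns=["gene_id", "tissue", "replicate", "ct"])
    return CtTable(frame, reference_gene_id)


def qpcr_case_study(
    seed: int = 42,
    n_true: int = 10,
    n_false: int = 2,
    fold: float = 64.0,
    noise_sd: float = 0.2,
    n_replicates: int = 3,
    tissues: tuple[str, ...] = ("leaf", "stem", "root", "flower", "pod", "seed"),
) -> tuple[CtTable, dict[str, str], TruthTable]:
    """The 12-gene validation design: predicted tissue-specific genes of
    which ``n_true`` carry their fold-excess in the predicted tissue and
    ``n_false`` have it planted in a different tissue instead.

    Returns (Ct table, predictions, truth); with the default 64-fold
    excess and 0.2-cycle noise the validation stage recovers exactly the
    planted split, giving 100 × n_true/(n_true + n_false) % consistency.
    """
    rng = np.random.default_rng(seed)
    genes = [f"Gv{i + 1:02d}" for i in range(n_true + n_false)]
    predictions: dict[str, str] = {}
    fold_map: dict[str, dict[str, float]] = {}
    truth = TruthTable()
    for i, gene in enumerate(genes):
        predicted = tissues[i % len(tissues)]
        predictions[gene] = predicted
        if i < n_true:
            express_in = predicted
        else:  # plant the excess in some other tissue
            others = [t for t in tissues if t != predicted]
            express_in = others[int(rng.integers(len(others)))]
        fold_map[gene] = {t: (fold if t == express_in else 1.0) for t in tissues}
        truth.planted_specific[gene] = express_in
    truth.planted_fold_changes = fold_map
    table = gen_ct_table(
        genes, list(tissues), fold_map,
        noise_sd=noise_sd, n_replicates=n_replicates,
        seed=int(rng.integers(2**31)),
    )
    return table, predictions, truth
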