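"""Strand-aware promoter extraction upstream of the translation start.

Here a *promoter* is the N-kb (default 3 kb) genomic window immediately 5'
of a gene's initiation codon (ATG) — the anchor is the first base of the
first CDS segment of the representative transcript, not the transcription
start site.  Coordinates are GFF3 1-based closed on input and 0-based
half-open internally and in BED output.  Windows clipped at a chromosome
edge are truncated and flagged, never padded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "PromoterRecord",
    "read_genome",
    "read_annotation_gff3",
    "extract_promoters",
    "write_promoters",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene's translation-start anchor on the genome.

    ``cds_start_genomic`` is the 1-based genomic position of the first
    base of the start codon of the representative transcript: the minimum
    CDS coordinate on the + strand, the maximum CDS end on the − strand.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_start_genomic: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.cds_start_genomic < 1:
            raise ValueError(f"{self.gene_id}: CDS start {self.cds_start_genomic} < 1")


@dataclass(frozen=True)
class PromoterRecord:
    """An extracted upstream window.

    ``interval`` is 0-based half-open genomic [start, end); ``sequence``
    is given 5'→3' relative to the gene (reverse-complemented for −
    strand genes) and never includes the ATG itself.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    truncated: bool

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if len(self.sequence) != self.length:
            raise ValueError(
                f"{self.gene_id}: sequence length {len(self.sequence)} != "
                f"interval length {self.length}"
            )


def read_genome(path) -> dict[str, str]:
    """Read a FASTA into an id → uppercase-sequence map."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def _representative_mrna(mrnas: list[tuple[str, int]]) -> str:
    """Pick the representative transcript id.

    Preference order: the isoform whose id carries the ``.1`` suffix, then
    the longest total CDS, then the lexicographically first id.
    """
    dot1 = [m for m, _ in mrnas if m.endswith(".1")]
    if dot1:
        return sorted(dot1)[0]
    return sorted(mrnas, key=lambda m: (-m[1], m[0]))[0][0]


def read_annotation_gff3(path, genome: dict[str, str] | None = None) -> list[GeneModel]:
    """Build one GeneModel per gene from a GFF3 with gene/mRNA/CDS features.

    CDS features link to mRNAs and mRNAs to genes via ``Parent``.  Genes
    without any CDS are skipped with a warning.  If ``genome`` is given,
    anchors falling outside their chromosome are a hard error.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas: list[tuple[str, int]] = []
        cds_by_mrna: dict[str, list[gffutils.Feature]] = {}
        for mrna in db.children(gene, featuretype="mRNA"):
            cds = list(db.children(mrna, featuretype="CDS"))
            if not cds:
                continue
            mrnas.append((mrna.id, sum(c.end - c.start + 1 for c in cds)))
            cds_by_mrna[mrna.id] = cds
        if not mrnas:
            logger.warning("gene %s has no CDS; skipped", gene.id)
            continue
        rep = _representative_mrna(mrnas)
        cds = cds_by_mrna[rep]
        if gene.strand == "+":
            anchor = min(c.start for c in cds)
        else:
            anchor = max(c.end for c in cds)
        if genome is not None:
            chrom_seq = genome.get(gene.seqid)
            if chrom_seq is None:
                raise ValueError(f"gene {gene.id}: chromosome {gene.seqid!r} not in genome")
            if anchor > len(chrom_seq):
                raise ValueError(
                    f"gene {gene.id}: CDS start {anchor} beyond chromosome "
                    f"{gene.seqid} length {len(chrom_seq)}"
                )
        models.append(
            GeneModel(
                gene_id=gene.id, chrom=gene.seqid,
                strand=gene.strand, cds_start_genomic=anchor,
            )
        )
    return models


def extract_promoters(
    genome: dict[str, str],
    models: list[GeneModel],
    length: int = 3000,
) -> list[PromoterRecord]:
    """Extract the ``length``-bp window upstream of each gene's ATG.

    + strand: genomic [cds_start−1−length, cds_start−1), as-is.
    − strand: genomic [cds_start, cds_start+length), reverse-complemented.
    Windows are clipped at chromosome edges and flagged ``truncated``;
    the start codon itself is never included.
    """
    records: list[PromoterRecord] = []
    for m in models:
        chrom_seq = genome[m.chrom]
        if m.strand == "+":
            end = m.cds_start_genomic - 1  # 0-based position of the A of ATG
            start = max(0, end - length)
            seq = chrom_seq[start:end]
        else:
            start = m.cds_start_genomic  # first base 3' of the (revcomp) ATG
            end = min(len(chrom_seq), start + length)
            seq = str(Seq(chrom_seq[start:end]).reverse_complement())
        truncated = (end - start) < length
        if end - start == 0:
            logger.warning("gene %s: zero-length promoter at chromosome edge", m.gene_id)
        records.append(
            PromoterRecord(
                gene_id=m.gene_id, chrom=m.chrom, start=start, end=end,
                strand=m.strand, sequence=seq, truncated=truncated,
            )
        )
    return records


def write_promoters(records: list[PromoterRecord], fasta_path, bed_path) -> None:
    """Write promoter sequences (FASTA) and intervals (BED6).

    BED names carry a ``_truncated`` suffix for clipped windows; BED is
    0-based half-open with the gene's strand in column 6.
    """
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.gene_id, description="")
        for r in records
    ]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    with open(bed_path, "w") as fh:
        for r in records:
            name = r.gene_id + ("_truncated" if r.truncated else "")
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")
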