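"""IUPAC cis-element library and both-strand promoter scanner.

Plant cis-regulatory elements (PLACE-style) are short degenerate consensus
motifs.  The builtin library holds the eleven tissue-specificity elements
used for soybean promoter annotation (root-hair, anther/meristem, nodule,
fruit, endosperm, embryo, seed and pollen classes).  The scanner tests
every overlapping window on both strands, reports concrete matched words
with 0-based offsets, and counts occurrences (overlaps included), the
PLACE convention.

A sequence ``N`` (unknown base) matches only a consensus ``N``: unknown
genomic context can therefore never create a hit for an informative motif
position.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "Motif",
    "MotifHit",
    "IUPAC_SETS",
    "builtin_library",
    "load_motif_table",
    "write_motif_table",
    "iupac_match",
    "reverse_complement_consensus",
    "scan_sequence",
    "scan_promoter",
    "distribution_table",
]

#: Base sets of the IUPAC degenerate nucleotide code.  A sequence N is
#: matched only by a consensus N (conservative rule).
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGTN"),
}

_IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

# name, consensus, tissue class of the builtin plant cis-element library
_BUILTIN = [
    ("RHERPATEXPA7", "KCACGW", "root-hair-specific"),
    ("SITEIIATCYTC", "TGGGCY", "anther- and meristem-specific"),
    ("NODCON1GM", "AAAGAT", "nodule-specific"),
    ("TGTCACACMCUCUMISIN", "TGTCACA", "fruit-specific"),
    ("AACACOREOSGLUB1", "AACAAAC", "endosperm-specific"),
    ("DPBFCOREDCDC3", "ACACNNG", "embryo-specific"),
    ("ACGTOSGLUB1", "GTACGTG", "endosperm-specific"),
    ("GCN4OSGLUB1", "TGAGTCA", "endosperm-specific"),
    ("RYREPEATBNNAPA", "CATGCA", "seed-specific"),
    ("POLLEN2LELAT52", "TCCACCATA", "pollen-specific"),
    ("CANBNNAPA", "CNAACAC", "embryo- and endosperm-specific"),
]


@dataclass(frozen=True)
class Motif:
    """A named IUPAC degenerate consensus with its tissue class."""

    name: str
    consensus: str
    tissue_class: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"motif {self.name!r}: empty consensus")
        for i, ch in enumerate(self.consensus):
            if ch not in IUPAC_SETS:
                raise ValueError(
                    f"motif {self.name!r}: invalid IUPAC character {ch!r} "
                    f"at position {i + 1}"
                )


@dataclass(frozen=True)
class MotifHit:
    """A positioned, stranded concrete match in a promoter."""

    promoter_id: str
    motif_name: str
    start: int
    strand: str
    matched: str

    @property
    def end(self) -> int:
        return self.start + len(self.matched)


def builtin_library() -> list[Motif]:
    """The eleven builtin tissue-specificity cis-elements."""
    return [Motif(*row) for row in _BUILTIN]


def _check_unique_names(motifs: list[Motif], source: str) -> None:
    seen: set[str] = set()
    for m in motifs:
        if m.name in seen:
            raise ValueError(f"{source}: duplicate motif name {m.name!r}")
        seen.add(m.name)


def load_motif_table(path) -> list[Motif]:
    """Load a motif TSV (name, consensus, tissue_class)."""
    frame = pd.read_csv(
        path, sep="\t", header=None, dtype=str, comment="#",
        names=["name", "consensus", "tissue_class"],
    )
    motifs = [
        Motif(row.name, row.consensus, row.tissue_class or "")
        for row in frame.itertuples(index=False)
    ]
    _check_unique_names(motifs, str(path))
    return motifs


def write_motif_table(motifs: list[Motif], path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f"{m.name}\t{m.consensus}\t{m.tissue_class}\n")


def iupac_match(consensus: str, window: str) -> bool:
    """True iff every window base is in its consensus position's IUPAC set."""
    if len(consensus) != len(window):
        raise ValueError(
            f"length mismatch: consensus {len(consensus)} vs window {len(window)}"
        )
    return all(b in IUPAC_SETS[c] for c, b in zip(consensus, window))


def reverse_complement_consensus(consensus: str) -> str:
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(consensus))


def scan_sequence(
    promoter_id: str,
    sequence: str,
    library: list[Motif],
    forward_only: bool = False,
) -> list[MotifHit]:
    """Scan one uppercase sequence against a motif library.

    Every overlapping window is tested against each consensus (strand +)
    and its reverse complement (strand −).  A window matching both — a
    palindromic site — is reported once, on the + strand.  Hits are sorted
    by (start, motif name, strand).
    """
    hits: list[MotifHit] = []
    for motif in library:
        w = len(motif.consensus)
        rc = reverse_complement_consensus(motif.consensus)
        for start in range(len(sequence) - w + 1):
            window = sequence[start:start + w]
            if iupac_match(motif.consensus, window):
                hits.append(MotifHit(promoter_id, motif.name, start, "+", window))
            elif not forward_only and iupac_match(rc, window):
                hits.append(MotifHit(promoter_id, motif.name, start, "-", window))
    hits.sort(key=lambda h: (h.start, h.motif_name, h.strand))
    return hits


def scan_promoter(promoter, library: list[Motif], forward_only: bool = False) -> list[MotifHit]:
    """Scan a PromoterRecord (or any object with gene_id and sequence)."""
    return scan_sequence(promoter.gene_id, promoter.sequence, library, forward_only)


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "promoter_id": h.promoter_id, "motif": h.motif_name,
                "start": h.start, "end": h.end, "strand": h.strand,
                "matched": h.matched,
            }
            for h in hits
        ],
        columns=["promoter_id", "motif", "start", "end", "strand", "matched"],
    )


def distribution_table(
    hits_by_promoter: dict[str, list[MotifHit]],
    library: list[Motif],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-promoter motif counts and tissue-class proportions.

    Returns ``(counts, proportions)``: a promoter × motif count matrix
    whose row sums are the per-promoter hit totals, and a promoter ×
    tissue-class table of hit proportions (percent of that promoter's
    elements).  A promoter with no hits has undefined proportions; it is
    reported as all-zero with ``no_hits`` set.
    """
    names = [m.name for m in library]
    classes = sorted({m.tissue_class for m in library})
    class_of = {m.name: m.tissue_class for m in library}
    promoters = list(hits_by_promoter)
    counts = pd.DataFrame(0, index=promoters, columns=names, dtype=int)
    counts.index.name = "promoter_id"
    for pid, hits in hits_by_promoter.items():
        for h in hits:
            counts.loc[pid, h.motif_name] += 1
    props = pd.DataFrame(0.0, index=promoters, columns=classes)
    props.index.name = "promoter_id"
    props["no_hits"] = False
    for pid in promoters:
        total = int(counts.loc[pid].sum())
        if total == 0:
            props.loc[pid, "no_hits"] = True
            continue
        for name in names:
            props.loc[pid, class_of[name]] += 100.0 * counts.loc[pid, name] / total
    return counts, props
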