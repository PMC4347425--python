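"""Nucleotide/protein containers, translation, and ORF discovery.

Coordinates are 0-based half-open on the forward strand throughout; ORFs
found on the reverse strand are re-mapped to forward-strand offsets of the
source sequence.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUC_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid, stops rendered as '*'
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_STANDARD.stop_codons)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AlphabetError(ValueError):
    """A sequence contains characters outside its declared alphabet."""


@dataclass(frozen=True)
class NucSeq:
    """A named nucleotide sequence over {A, C, G, T, N}."""

    id: str
    residues: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def validate(self) -> "NucSeq":
        """Raise :class:`AlphabetError` (with the offending position) on bad characters."""
        for pos, ch in enumerate(self.residues):
            if ch not in NUC_ALPHABET:
                raise AlphabetError(
                    f"{self.id}: invalid nucleotide {ch!r} at position {pos}"
                )
        return self


@dataclass(frozen=True)
class ProtSeq:
    """A named amino-acid sequence (20 standard residues plus X and *)."""

    id: str
    residues: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def has_internal_stop(self) -> bool:
        body = self.residues[:-1] if self.residues.endswith("*") else self.residues
        return "*" in body


@dataclass(frozen=True)
class OrfSpan:
    """An open reading frame, ATG to (and including) the first in-frame stop.

    ``start``/``end`` are forward-strand offsets on the source sequence even
    for reverse-strand ORFs.  ``has_stop`` is False when the frame ran off the
    end of the sequence without a stop codon.
    """

    start: int
    end: int
    strand: str  # '+' or '-'
    frame: int  # frame index on the ORF's own strand, in {0,1,2}
    has_stop: bool = True

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def length_aa(self) -> int:
        n = self.length_nt // 3
        return n - 1 if self.has_stop else n


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


def translate(nuc: NucSeq, offset: int = 0) -> ProtSeq:
    """Translate under the standard genetic code.

    Codons containing N translate to X; a trailing partial codon is dropped;
    stop codons are rendered as ``*``.  Non-ACGTN characters are rejected
    with the position of the first offender.
    """
    if offset not in (0, 1, 2):
        raise ValueError(f"frame offset must be 0, 1 or 2, got {offset}")
    if len(nuc) < 3:
        raise ValueError(f"{nuc.id}: sequence shorter than one codon")
    nuc.validate()
    s = nuc.residues
    aas = []
    for i in range(offset, len(s) - 2, 3):
        codon = s[i : i + 3]
        aas.append("X" if "N" in codon else CODON_TO_AA[codon])
    return ProtSeq(id=nuc.id, residues="".join(aas), description=nuc.description)


def _orfs_one_strand(s: str) -> list[tuple[int, int, int, bool]]:
    """All maximal ORFs (first-ATG-after-previous-stop) as (start, end, frame, has_stop)."""
    out = []
    n = len(s)
    for frame in range(3):
        atg: Optional[int] = None
        i = frame
        while i + 3 <= n:
            codon = s[i : i + 3]
            if atg is None:
                if codon == "ATG":
                    atg = i
            elif codon in STOP_CODONS:
                out.append((atg, i + 3, frame, True))
                atg = None
            i += 3
        if atg is not None:
            out.append((atg, i, frame, False))  # ran off the end, no stop
    return out


def find_longest_orf(nuc: NucSeq, search_both_strands: bool = True) -> Optional[OrfSpan]:
    """Longest ATG->stop span over six frames (three if one strand).

    Ties break by earlier forward-strand start, then '+' strand over '-'.
    Returns None when no ATG exists in any searched frame.  An ORF that
    reaches the sequence end without a stop codon is reported with
    ``has_stop=False``.
    """
    if len(nuc) < 3:
        raise ValueError(f"{nuc.id}: sequence shorter than one codon")
    nuc.validate()
    n = len(nuc)
    candidates: list[OrfSpan] = []
    for start, end, frame, has_stop in _orfs_one_strand(nuc.residues):
        candidates.append(OrfSpan(start, end, "+", frame, has_stop))
    if search_both_strands:
        rc = reverse_complement(nuc.residues)
        for start, end, frame, has_stop in _orfs_one_strand(rc):
            # re-map reverse-strand offsets onto the forward coordinate system
            candidates.append(OrfSpan(n - end, n - start, "-", frame, has_stop))
    candidates = [c for c in candidates if c.length_nt >= 3]
    if not candidates:
        return None
    return min(candidates, key=lambda c: (-c.length_nt, c.start, c.strand == "-"))


# ---------------------------------------------------------------------------
# FASTA I/O (wrapped at 60 columns on output, Biopython's default)


def read_fasta(path: str | Path) -> list[NucSeq]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            NucSeq(id=rec.id, residues=str(rec.seq).upper(), description=rec.description).validate()
        )
    return records


def read_fasta_protein(path: str | Path) -> list[ProtSeq]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise AlphabetError(f"{rec.id}: invalid amino acids {sorted(bad)}")
        records.append(ProtSeq(id=rec.id, residues=seq, description=rec.description))
    return records


def write_fasta(seqs: Iterable[NucSeq | ProtSeq], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description) for s in seqs
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def orf_report(seqs: Iterable[NucSeq], search_both_strands: bool = True):
    """Per-sequence longest-ORF table: seq_id, strand, start, end, length_nt, length_aa."""
    import pandas as pd

    rows = []
    for s in seqs:
        orf = find_longest_orf(s, search_both_strands=search_both_strands)
        if orf is None:
            rows.append((s.id, ".", -1, -1, 0, 0))
        else:
            rows.append((s.id, orf.strand, orf.start, orf.end, orf.length_nt, orf.length_aa))
    return pd.DataFrame(
        rows, columns=["seq_id", "strand", "start", "end", "length_nt", "length_aa"]
    )
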