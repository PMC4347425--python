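"""Functional/pseudogene curation of odorant-receptor genes.

An OR gene is called functional when its longest open reading frame reaches a
minimum coding length (default 900 nt, stop codon included) and it carries no
disqualifying annotation; anything shorter, ORF-less, or annotated as
frameshifted is a pseudogene.  A manual override list can force individual
genes to functional status (with the original evidence retained), mirroring
expert curation of borderline cases such as a 293-residue receptor that still
carries all family motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .seq import NucSeq, ProtSeq, find_longest_orf, translate


@dataclass(frozen=True)
class Motif:
    """A short consensus pattern scanned with a Hamming-distance tolerance."""

    name: str
    pattern: str
    max_mismatches: int = 1


#: Consensus patterns conserved across the OR family: the TM3 "DRY box",
#: a TM6 cysteine motif, and the TM7 NPxxY-like region.  Data, not code —
#: callers may supply their own set.
DEFAULT_MOTIFS: tuple[Motif, ...] = (
    Motif("dry_box", "MAYDRYVAIC", 1),
    Motif("tm6_cys", "KAFSTCASH", 1),
    Motif("npxxy", "PMLNPFIY", 1),
)


@dataclass(frozen=True)
class MotifMatch:
    name: str
    matched: bool
    position: Optional[int]  # start offset of the best match, None if unmatched


@dataclass(frozen=True)
class MotifReport:
    matches: tuple[MotifMatch, ...]

    @property
    def all_present(self) -> bool:
        return all(m.matched for m in self.matches)


@dataclass(frozen=True)
class CurationDecision:
    gene_id: str
    status: str  # 'functional' | 'pseudogene'
    coding_length_nt: int
    reasons: tuple[str, ...]  # subset of {'no_orf','short_orf','frameshift_annotation'}
    overridden: bool = False
    motif_report: Optional[MotifReport] = None

    @property
    def is_functional(self) -> bool:
        return self.status == "functional"


def _best_hamming_match(text: str, pattern: str, max_mm: int) -> Optional[int]:
    """Leftmost window with the fewest mismatches, provided it is <= max_mm."""
    m = len(pattern)
    if m == 0 or m > len(text):
        return None
    best_pos, best_mm = None, max_mm + 1
    for i in range(len(text) - m + 1):
        mm = 0
        for a, b in zip(text[i : i + m], pattern):
            if a != b:
                mm += 1
                if mm >= best_mm:
                    break
        if mm < best_mm:
            best_pos, best_mm = i, mm
            if mm == 0:
                break
    return best_pos if best_mm <= max_mm else None


def scan_or_motifs(prot: ProtSeq, motifs: Sequence[Motif] = DEFAULT_MOTIFS) -> MotifReport:
    """Scan a protein for the configured OR-family motifs.

    Each motif allows its own number of mismatches; ``all_present`` is the
    conjunction over motifs.
    """
    if not prot.residues:
        raise ValueError(f"{prot.id}: empty protein")
    if not motifs:
        raise ValueError("empty motif set")
    matches = []
    for motif in motifs:
        pos = _best_hamming_match(prot.residues, motif.pattern, motif.max_mismatches)
        matches.append(MotifMatch(motif.name, pos is not None, pos))
    return MotifReport(tuple(matches))


def classify_or_gene(
    gene: NucSeq,
    min_coding_nt: int = 900,
    overrides: Optional[Mapping[str, str]] = None,
    frameshift_annotated: bool = False,
    include_stop_in_length: bool = True,
    motifs: Optional[Sequence[Motif]] = DEFAULT_MOTIFS,
) -> CurationDecision:
    """Classify one OR gene as functional or pseudogene.

    Pseudogene iff the longest ORF is absent, its coding length is strictly
    below ``min_coding_nt`` (a gene of exactly the threshold length is
    functional), or the gene carries a frameshift annotation.  ``overrides``
    maps gene id -> justification and forces functional status while keeping
    the original reasons on record.
    """
    if min_coding_nt <= 0:
        raise ValueError("min_coding_nt must be positive")
    if not gene.residues:
        raise ValueError(f"{gene.id}: empty sequence")
    orf = find_longest_orf(gene)
    reasons: list[str] = []
    motif_report = None
    if orf is None:
        coding_len = 0
        reasons.append("no_orf")
    else:
        coding_len = orf.length_nt
        if not include_stop_in_length and orf.has_stop:
            coding_len -= 3
        if coding_len < min_coding_nt:
            reasons.append("short_orf")
        if motifs:
            sub = NucSeq(gene.id, gene.residues[orf.start : orf.end])
            if orf.strand == "-":
                from .seq import reverse_complement

                sub = NucSeq(gene.id, reverse_complement(sub.residues))
            prot = translate(sub)
            prot = ProtSeq(prot.id, prot.residues.rstrip("*"))
            if prot.residues:
                motif_report = scan_or_motifs(prot, motifs)
    if frameshift_annotated:
        reasons.append("frameshift_annotation")
    overridden = bool(overrides and gene.id in overrides)
    status = "functional" if (not reasons or overridden) else "pseudogene"
    return CurationDecision(
        gene_id=gene.id,
        status=status,
        coding_length_nt=coding_len,
        reasons=tuple(reasons),
        overridden=overridden and bool(reasons),
        motif_report=motif_report,
    )


def curate_family(
    genes: Iterable[NucSeq],
    min_coding_nt: int = 900,
    overrides: Optional[Mapping[str, str]] = None,
    frameshift_annotations: Optional[Mapping[str, bool]] = None,
    **kwargs,
) -> dict[str, CurationDecision]:
    fs = frameshift_annotations or {}
    return {
        g.id: classify_or_gene(
            g,
            min_coding_nt=min_coding_nt,
            overrides=overrides,
            frameshift_annotated=bool(fs.get(g.id, False)),
            **kwargs,
        )
        for g in genes
    }


def read_overrides(path: str | Path) -> dict[str, str]:
    """Override list: tab-separated gene_id<TAB>justification, '#' comments allowed."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2 or not parts[1].strip():
            raise ValueError(f"override entry needs a justification: {line!r}")
        out[parts[0]] = parts[1]
    return out


def curation_table(decisions: Mapping[str, CurationDecision]) -> pd.DataFrame:
    rows = []
    for gid in decisions:
        d = decisions[gid]
        rows.append(
            {
                "gene_id": d.gene_id,
                "status": d.status,
                "coding_length_nt": d.coding_length_nt,
                "reasons": ",".join(d.reasons) or ".",
                "overridden": d.overridden,
                "all_motifs_present": (
                    d.motif_report.all_present if d.motif_report else False
                ),
            }
        )
    return pd.DataFrame(rows)
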