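"""Cross-species presence/absence screening of OR genes.

Each query gene is aligned against each species' genome; the best local hit
is summarized as percent identity and query coverage, a counterpart is
declared present when both reach their thresholds (default 70/70, inclusive),
and the per-species calls are folded into a lineage category:

* ``human_only``        - absent from chimpanzee, dog, mouse and rat
* ``human_chimp_only``  - present in chimpanzee, absent from dog, mouse, rat
* ``shared``            - anything else

The screen's "selected set" is the human-restricted categories minus curated
pseudogenes (unless manually overridden).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .align import AlignmentHit, AlignParams, seed_and_extend_align
from .curation import CurationDecision
from .seq import NucSeq, read_fasta

SCREEN_SPECIES = ("chimpanzee", "dog", "mouse", "rat")


@dataclass(frozen=True)
class PresenceCall:
    query_id: str
    species: str
    present: bool
    best_identity_pct: float
    best_coverage_pct: float
    best_hit: Optional[AlignmentHit] = None


@dataclass(frozen=True)
class LineageProfile:
    query_id: str
    calls: Mapping[str, PresenceCall]
    category: Optional[str]  # None when a species screen failed
    incomplete: bool = False


def summarize_best_hit(
    hits: Sequence[AlignmentHit], query_len: int
) -> tuple[float, float, Optional[AlignmentHit]]:
    """(identity_pct, coverage_pct, best hit) of the highest-scoring hit.

    Best = highest score, ties to more matches then smaller target start.
    Identity uses all alignment columns of that hit (gaps count against it);
    coverage is the aligned fraction of the query.  No hits -> (0, 0, None).
    """
    if query_len <= 0:
        raise ValueError("query_len must be positive")
    if not hits:
        return 0.0, 0.0, None
    best = min(hits, key=lambda h: (-h.score, -h.matches, h.t_start))
    identity = 100.0 * best.matches / best.aligned_cols if best.aligned_cols else 0.0
    coverage = 100.0 * (best.q_end - best.q_start) / query_len
    return identity, coverage, best


def call_presence(
    query_id: str,
    species: str,
    identity_pct: float,
    coverage_pct: float,
    id_threshold: float = 70.0,
    cov_threshold: float = 70.0,
    best_hit: Optional[AlignmentHit] = None,
) -> PresenceCall:
    """Inclusive thresholding on both axes ("at least" semantics)."""
    for thr in (id_threshold, cov_threshold):
        if not (0 < thr <= 100):
            raise ValueError(f"threshold {thr} outside (0, 100]")
    present = identity_pct >= id_threshold and coverage_pct >= cov_threshold
    return PresenceCall(query_id, species, present, identity_pct, coverage_pct, best_hit)


def classify_lineage(query_id: str, calls: Mapping[str, PresenceCall]) -> LineageProfile:
    if set(calls) != set(SCREEN_SPECIES):
        raise ValueError(
            f"expected presence calls for exactly {SCREEN_SPECIES}, got {sorted(calls)}"
        )
    present = {sp for sp, c in calls.items() if c.present}
    if not present:
        category = "human_only"
    elif present == {"chimpanzee"}:
        category = "human_chimp_only"
    else:
        category = "shared"
    return LineageProfile(query_id, dict(calls), category)


@dataclass
class ScreenResult:
    profiles: dict[str, LineageProfile]
    screen_table: pd.DataFrame  # query_id, species, identity, coverage, present
    lineage_table: pd.DataFrame  # query_id, category
    category_counts: dict[str, int]
    selected: list[str]
    failures: list[str]  # per-species failure messages


def run_lineage_screen(
    queries: Sequence[NucSeq],
    genomes: Mapping[str, Union[str, Path, Sequence[NucSeq]]],
    curation: Mapping[str, CurationDecision],
    params: AlignParams = AlignParams(),
    id_threshold: float = 70.0,
    cov_threshold: float = 70.0,
) -> ScreenResult:
    """Screen every query against every species genome and select the
    human-restricted, non-pseudogene set.

    ``genomes`` maps species name to either loaded contigs or a FASTA path.
    An unreadable genome is recorded as a failure and every query is flagged
    incomplete (category None) rather than silently called absent.
    """
    if not genomes:
        raise ValueError("no target genomes given")
    if set(genomes) != set(SCREEN_SPECIES):
        raise ValueError(f"genomes must cover exactly {SCREEN_SPECIES}")
    missing = [q.id for q in queries if q.id not in curation]
    if missing:
        raise ValueError(f"no curation decision for: {missing}")

    loaded: dict[str, Optional[Sequence[NucSeq]]] = {}
    failures: list[str] = []
    for sp, src in genomes.items():
        if isinstance(src, (str, Path)):
            try:
                loaded[sp] = read_fasta(src)
            except Exception as exc:  # unreadable genome: flagged, not fatal
                loaded[sp] = None
                failures.append(f"{sp}: {exc}")
        else:
            loaded[sp] = list(src)

    profiles: dict[str, LineageProfile] = {}
    rows = []
    for q in queries:
        calls: dict[str, PresenceCall] = {}
        incomplete = False
        for sp in SCREEN_SPECIES:
            contigs = loaded[sp]
            if contigs is None:
                incomplete = True
                continue
            hits = seed_and_extend_align(q, contigs, params)
            ident, cov, best = summarize_best_hit(hits, len(q))
            calls[sp] = call_presence(
                q.id, sp, ident, cov, id_threshold, cov_threshold, best
            )
            rows.append(
                {
                    "query_id": q.id,
                    "species": sp,
                    "best_identity_pct": round(ident, 2),
                    "best_coverage_pct": round(cov, 2),
                    "present": calls[sp].present,
                }
            )
        if incomplete:
            profiles[q.id] = LineageProfile(q.id, calls, None, incomplete=True)
        else:
            profiles[q.id] = classify_lineage(q.id, calls)

    lineage_rows = [
        {"query_id": qid, "category": p.category or "incomplete"}
        for qid, p in profiles.items()
    ]
    counts: dict[str, int] = {}
    for p in profiles.values():
        key = p.category or "incomplete"
        counts[key] = counts.get(key, 0) + 1

    selected = [
        q.id
        for q in queries
        if profiles[q.id].category in ("human_only", "human_chimp_only")
        and (curation[q.id].is_functional)
    ]
    return ScreenResult(
        profiles=profiles,
        screen_table=pd.DataFrame(
            rows,
            columns=[
                "query_id",
                "species",
                "best_identity_pct",
                "best_coverage_pct",
                "present",
            ],
        ),
        lineage_table=pd.DataFrame(lineage_rows, columns=["query_id", "category"]),
        category_counts=counts,
        selected=selected,
        failures=failures,
    )
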