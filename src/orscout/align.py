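"""Seed-and-extend local nucleotide alignment.

Exact k-mer seeds locate candidate regions of the target; each seed cluster
is then resolved by a full affine-gap Smith-Waterman over a window spanning
the cluster, so the reported hit in a window is the optimal local alignment
through that region.  Gap cost convention: a gap of length L costs
``gap_open + (L - 1) * gap_extend`` (both negative), i.e. the first gapped
position pays the open penalty.

All coordinates are 0-based half-open; reverse-strand hits report query
offsets on the forward query.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence, Union

import numpy as np
from numba import njit

from .seq import NucSeq, reverse_complement

_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def encode(residues: str) -> np.ndarray:
    """A->0 ... T->3, anything else (N) -> 4, which never matches."""
    return _BASE_CODE[np.frombuffer(residues.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class AlignParams:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -3  # cost of the first position of a gap
    gap_extend: int = -1  # each additional position
    k: int = 11  # seed k-mer size
    min_score: int = 30
    diag_merge: int = 64  # seeds within this diagonal band join one cluster
    window_pad: int = 50
    # clusters whose best gapless seed extension scores below this fraction of
    # min_score are skipped before the DP; 0 disables the prefilter
    prefilter_fraction: float = 0.5

    def __post_init__(self):
        if self.k < 4:
            raise ValueError("seed size k must be >= 4")
        if self.gap_open > 0 or self.gap_extend > 0 or self.mismatch > 0:
            raise ValueError("penalties must be <= 0")


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment.  ``aligned_cols`` counts every match, mismatch and
    gap column of the alignment; ``matches`` the identical ones."""

    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str
    matches: int
    aligned_cols: int
    score: int

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.matches / self.aligned_cols if self.aligned_cols else 0.0


@njit(cache=True)
def _sw_traceback(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = q.shape[0], t.shape[0]
    NEG = -(1 << 30)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in query (consumes target)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in target (consumes query)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 E, 3 F
    ptrE = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 open (from H), 1 extend
    ptrF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open
            e_ext = E[i, j - 1] + gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            else:
                E[i, j] = e_open
                ptrE[i, j] = 0
            f_open = H[i - 1, j] + gap_open
            f_ext = F[i - 1, j] + gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            else:
                F[i, j] = f_open
                ptrF[i, j] = 0
            if qi == t[j - 1] and qi < 4:
                diag = H[i - 1, j - 1] + match
            else:
                diag = H[i - 1, j - 1] + mismatch
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback from (bi, bj)
    i, j = bi, bj
    matches = 0
    cols = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                cols += 1
                if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            cols += 1
            nxt = ptrE[i, j]
            j -= 1
            state = 1 if nxt == 1 else 0
        else:
            cols += 1
            nxt = ptrF[i, j]
            i -= 1
            state = 2 if nxt == 1 else 0
    return best, i, bi, j, bj, matches, cols


@njit(cache=True)
def _gapless_extension_score(q, t, q_pos, t_pos, k, match, mismatch, xdrop):  # pragma: no cover
    """Seed score plus best X-drop ungapped extension in both directions."""
    score = k * match
    # rightward
    gain = 0
    best_gain = 0
    i, j = q_pos + k, t_pos + k
    while i < q.shape[0] and j < t.shape[0]:
        gain += match if (q[i] == t[j] and q[i] < 4) else mismatch
        if gain > best_gain:
            best_gain = gain
        if best_gain - gain > xdrop:
            break
        i += 1
        j += 1
    score += best_gain
    # leftward
    gain = 0
    best_gain = 0
    i, j = q_pos - 1, t_pos - 1
    while i >= 0 and j >= 0:
        gain += match if (q[i] == t[j] and q[i] < 4) else mismatch
        if gain > best_gain:
            best_gain = gain
        if best_gain - gain > xdrop:
            break
        i -= 1
        j -= 1
    return score + best_gain


def smith_waterman(
    query: str, target: str, params: AlignParams = AlignParams()
) -> tuple[int, int, int, int, int, int, int]:
    """Full-matrix optimal local alignment.

    Returns (score, q_start, q_end, t_start, t_end, matches, aligned_cols).
    """
    return _sw_traceback(
        encode(query),
        encode(target),
        params.match,
        params.mismatch,
        params.gap_open,
        params.gap_extend,
    )


@lru_cache(maxsize=128)
def _kmer_index(target: NucSeq, k: int) -> dict[str, list[int]]:
    """k-mer -> positions index of a contig, cached so many queries can scan
    the same genome without re-indexing."""
    s = target.residues
    index: dict[str, list[int]] = {}
    for j in range(len(s) - k + 1):
        index.setdefault(s[j : j + k], []).append(j)
    return index


def _seed_positions(query: str, target: NucSeq, k: int) -> list[tuple[int, int]]:
    """(q_pos, t_pos) of every shared exact k-mer."""
    index = _kmer_index(target, k)
    out = []
    for i in range(len(query) - k + 1):
        hits = index.get(query[i : i + k])
        if hits:
            for j in hits:
                out.append((i, j))
    return out


def _cluster_seeds(
    seeds: list[tuple[int, int]], qlen: int, diag_merge: int
) -> list[list[tuple[int, int]]]:
    """Group seeds into nearby-diagonal runs, then merge groups whose target
    extents overlap (within a query length), so each cluster is resolved by
    one DP window."""
    with_diag = sorted((t - q, t, q) for q, t in seeds)
    groups: list[list[tuple[int, int]]] = []
    cur: list[tuple[int, int]] = []
    cur_diag, cur_hi = None, 0
    for d, t, q in with_diag:
        if cur and d - cur_diag <= diag_merge and abs(t - cur_hi) <= qlen + diag_merge:
            cur.append((q, t))
            cur_diag, cur_hi = d, max(cur_hi, t)
        else:
            if cur:
                groups.append(cur)
            cur = [(q, t)]
            cur_diag, cur_hi = d, t
    if cur:
        groups.append(cur)
    # merge groups with overlapping target extents
    groups.sort(key=lambda g: min(t for _, t in g))
    merged: list[list[tuple[int, int]]] = []
    for g in groups:
        lo = min(t for _, t in g)
        if merged and lo <= max(t for _, t in merged[-1]) + qlen:
            merged[-1].extend(g)
        else:
            merged.append(list(g))
    return merged


def _align_one_strand(
    query: str,
    query_fwd_len: int,
    target: NucSeq,
    strand: str,
    query_id: str,
    params: AlignParams,
) -> list[AlignmentHit]:
    seeds = _seed_positions(query, target, params.k)
    if not seeds:
        return []
    qlen = len(query)
    q_enc = encode(query)
    t_enc = encode(target.residues)
    prefilter_min = params.prefilter_fraction * params.min_score
    hits = []
    for cluster in _cluster_seeds(seeds, qlen, params.diag_merge):
        if prefilter_min > 0:
            # spread up to 16 probes across the cluster
            step = max(1, len(cluster) // 16)
            best = max(
                _gapless_extension_score(
                    q_enc, t_enc, qp, tp, params.k, params.match, params.mismatch, 12
                )
                for qp, tp in cluster[::step]
            )
            if best < prefilter_min:
                continue
        # a local alignment through any seed of the cluster cannot consume
        # more query than remains on either side of it
        t_lo = min(t for _, t in cluster)
        t_hi = max(t for _, t in cluster)
        left = max(q for q, _ in cluster) + params.window_pad
        right = qlen - min(q for q, _ in cluster) + params.window_pad
        w_lo = max(0, t_lo - left)
        w_hi = min(len(target), t_hi + params.k + right)
        window = target.residues[w_lo:w_hi]
        score, qs, qe, ts, te, matches, cols = smith_waterman(query, window, params)
        if score < params.min_score or qe == qs:
            continue
        if strand == "-":
            qs, qe = query_fwd_len - qe, query_fwd_len - qs
        hits.append(
            AlignmentHit(
                query_id=query_id,
                target_id=target.id,
                q_start=qs,
                q_end=qe,
                t_start=w_lo + ts,
                t_end=w_lo + te,
                strand=strand,
                matches=matches,
                aligned_cols=cols,
                score=score,
            )
        )
    return hits


def seed_and_extend_align(
    query: NucSeq,
    target: Union[NucSeq, Sequence[NucSeq]],
    params: AlignParams = AlignParams(),
) -> list[AlignmentHit]:
    """Align a query against one or more target contigs, both strands.

    Hits are returned sorted by score descending (ties: more matches, then
    smaller target start, then target id, then '+' strand), deduplicated on
    identical coordinates; deterministic for fixed inputs and parameters.
    """
    if len(query) < params.k:
        raise ValueError(
            f"query {query.id} shorter than seed size k={params.k}"
        )
    contigs = [target] if isinstance(target, NucSeq) else list(target)
    qlen = len(query)
    rc = reverse_complement(query.residues)
    all_hits: dict[tuple, AlignmentHit] = {}
    for contig in contigs:
        for strand, qseq in (("+", query.residues), ("-", rc)):
            for h in _align_one_strand(qseq, qlen, contig, strand, query.id, params):
                key = (h.target_id, h.strand, h.q_start, h.q_end, h.t_start, h.t_end)
                prev = all_hits.get(key)
                if prev is None or h.score > prev.score:
                    all_hits[key] = h
    return sorted(
        all_hits.values(),
        key=lambda h: (-h.score, -h.matches, h.t_start, h.target_id, h.strand == "-"),
    )
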