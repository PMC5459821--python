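"""Pairwise alignment helpers shared across the pipeline.

Two alignment flavours are used:

* a "glocal" (end-gap-free global) alignment, whose column-wise identity
  underlies the 97% OTU threshold and chimera parent modelling; and
* a local alignment with BLAST-like match/mismatch/gap scores, from which
  bit scores and E-values are derived for best-hit species calling.

Bit scores use fixed Karlin-Altschul-style constants; they are configuration
for ranking and tie detection, not estimates fitted to any database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

from Bio import Align

__all__ = [
    "MATCH",
    "MISMATCH",
    "GAP_OPEN",
    "GAP_EXTEND",
    "LAMBDA",
    "KA_K",
    "glocal_identity",
    "glocal_match_vector",
    "LocalHit",
    "local_align",
    "database_hits",
    "bit_score",
    "evalue",
]

MATCH = 2.0
MISMATCH = -3.0
GAP_OPEN = -5.0
GAP_EXTEND = -2.0

# Karlin-Altschul-style constants (configuration; see module docstring).
LAMBDA = 0.625
KA_K = 0.41


@lru_cache(maxsize=None)
def _glocal_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    # Cheap (but not free) end gaps -> "glocal".  A small per-column end-gap
    # cost stops the aligner from dovetailing both ends of two same-length
    # sequences instead of aligning their substitutions as mismatch columns;
    # genuine overhangs still route through end gaps, which the identity
    # computation then excludes.
    end_gap = -2.0
    aligner.open_left_insertion_score = end_gap
    aligner.extend_left_insertion_score = end_gap
    aligner.open_right_insertion_score = end_gap
    aligner.extend_right_insertion_score = end_gap
    aligner.open_left_deletion_score = end_gap
    aligner.extend_left_deletion_score = end_gap
    aligner.open_right_deletion_score = end_gap
    aligner.extend_right_deletion_score = end_gap
    return aligner


@lru_cache(maxsize=None)
def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def _trim_terminal(rows: tuple[str, str]) -> tuple[str, str]:
    """Drop alignment columns where either sequence has a terminal gap."""
    a, b = rows
    n = len(a)
    start = 0
    while start < n and (a[start] == "-" or b[start] == "-"):
        start += 1
    end = n
    while end > start and (a[end - 1] == "-" or b[end - 1] == "-"):
        end -= 1
    # only trim runs that are genuinely terminal gaps of one row
    # (the loops above can overshoot into internal columns only if a terminal
    # gap run abuts an internal one, which the scoring scheme never produces
    # for both rows simultaneously).
    return a[start:end], b[start:end]


def glocal_identity(a: str, b: str) -> float:
    """Fractional identity of an end-gap-free global alignment.

    Identity = matching columns / alignment columns, with internal gaps
    counted as mismatching columns and terminal gap columns excluded.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if a == b:
        return 1.0
    aln = _glocal_aligner().align(a, b)[0]
    ra, rb = _trim_terminal((str(aln[0]), str(aln[1])))
    if not ra:
        return 0.0
    matches = sum(x == y and x != "-" for x, y in zip(ra, rb))
    return matches / len(ra)


def glocal_match_vector(query: str, subject: str) -> list[int]:
    """Per-query-position match indicator against ``subject``.

    Entry ``i`` is 1 when query position ``i`` aligns to an identical subject
    base in the glocal alignment, else 0 (mismatch, gap, or unaligned
    overhang).
    """
    if query == subject:
        return [1] * len(query)
    aln = _glocal_aligner().align(query, subject)[0]
    rq, rs = str(aln[0]), str(aln[1])
    out = [0] * len(query)
    qpos = 0
    for cq, cs in zip(rq, rs):
        if cq != "-":
            if cs != "-" and cq == cs:
                out[qpos] = 1
            qpos += 1
    return out


def bit_score(raw_score: float) -> float:
    """Normalised bit score of a raw alignment score."""
    return (LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def evalue(raw_score: float, query_len: int, db_len: int) -> float:
    """Expected hit count for a raw score against a database of ``db_len``."""
    return query_len * db_len * 2.0 ** (-bit_score(raw_score))


@dataclass
class LocalHit:
    """One local alignment of a query against a named subject."""

    query_id: str
    subject_id: str
    species: tuple[str, ...]
    raw_score: float
    bit_score: float
    evalue: float
    identity_pct: float
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    subject_aligned_seq: str


def local_align(
    query: str,
    subject: str,
    *,
    query_id: str = "query",
    subject_id: str = "subject",
    species: Sequence[str] = (),
    db_len: Optional[int] = None,
) -> Optional[LocalHit]:
    """Best local alignment of ``query`` against ``subject``.

    An exact-substring fast path short-circuits the dynamic programme: a
    full-length perfect match is necessarily the optimal local alignment
    under positive match / negative mismatch+gap scores.
    """
    if not query or not subject:
        raise ValueError("cannot align an empty sequence")
    n_db = db_len if db_len is not None else len(subject)

    pos = subject.find(query)
    if pos >= 0:
        raw = MATCH * len(query)
        return LocalHit(
            query_id=query_id,
            subject_id=subject_id,
            species=tuple(species),
            raw_score=raw,
            bit_score=bit_score(raw),
            evalue=evalue(raw, len(query), n_db),
            identity_pct=100.0,
            query_interval=(0, len(query)),
            subject_interval=(pos, pos + len(query)),
            subject_aligned_seq=query,
        )

    alignments = _local_aligner().align(query, subject)
    if len(alignments) == 0:  # pragma: no cover
        return None
    return _hit_from_alignment(alignments[0], query, subject, query_id, subject_id, species, n_db)


def _hit_from_alignment(aln, query, subject, query_id, subject_id, species, n_db):
    raw = float(aln.score)
    if raw <= 0:
        return None
    q_blocks, s_blocks = aln.aligned[0], aln.aligned[1]
    q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
    s_start, s_end = int(s_blocks[0][0]), int(s_blocks[-1][1])
    matches = 0
    columns = 0
    prev_qe = prev_se = None
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        if prev_qe is not None:
            columns += (qs - prev_qe) + (ss - prev_se)  # gap columns
        for i in range(qe - qs):
            columns += 1
            if query[qs + i] == subject[ss + i]:
                matches += 1
        prev_qe, prev_se = qe, se
    identity = 100.0 * matches / columns if columns else 0.0
    return LocalHit(
        query_id=query_id,
        subject_id=subject_id,
        species=tuple(species),
        raw_score=raw,
        bit_score=bit_score(raw),
        evalue=evalue(raw, len(query), n_db),
        identity_pct=identity,
        query_interval=(q_start, q_end),
        subject_interval=(s_start, s_end),
        subject_aligned_seq=subject[s_start:s_end],
    )


def database_hits(
    query: str,
    subjects: Sequence[tuple[str, tuple[str, ...], str]],
    *,
    query_id: str = "query",
) -> list[LocalHit]:
    """Local-align ``query`` against a whole database of subjects.

    ``subjects`` holds ``(subject_id, species_labels, sequence)`` triples;
    E-values are computed against the summed database length.  When at least
    one subject contains the query as an exact substring, that perfect match
    attains the maximum possible local score (``MATCH * len(query)``), so
    every non-exact subject is strictly dominated and the dynamic programme
    is skipped for all of them — the returned hit list then contains exactly
    the perfect matches.  Otherwise every subject is aligned.
    """
    db_len = sum(len(seq) for _, _, seq in subjects)
    exact: list[LocalHit] = []
    for subject_id, species, seq in subjects:
        if query in seq:
            hit = local_align(
                query, seq, query_id=query_id, subject_id=subject_id,
                species=species, db_len=db_len,
            )
            exact.append(hit)
    if exact:
        return exact
    hits = []
    for subject_id, species, seq in subjects:
        hit = local_align(
            query, seq, query_id=query_id, subject_id=subject_id,
            species=species, db_len=db_len,
        )
        if hit is not None:
            hits.append(hit)
    return hits
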