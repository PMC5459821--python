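"""Length filtering and abundance-ordered de novo chimera detection.

Chimera detection follows the abundance-ranked two-parent strategy: each
dereplicated query is modelled as a splice of two more-abundant candidate
parents; it is flagged when the best two-parent model explains the query
measurably better than any single parent does.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .align import glocal_match_vector
from .io import SequenceRecord

__all__ = [
    "ChimeraVerdict",
    "length_filter",
    "dereplicate",
    "detect_chimeras",
    "remove_chimeras",
]


def length_filter(reads: Sequence[SequenceRecord], min_len: int = 1000) -> tuple[list[SequenceRecord], int]:
    """Keep reads of length >= ``min_len``; returns (kept, removed_count)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [r for r in reads if len(r) >= min_len]
    return kept, len(reads) - len(kept)


def dereplicate(reads: Iterable[SequenceRecord]) -> list[tuple[str, int]]:
    """Exact-string dereplication.

    Returns ``(sequence, abundance)`` pairs sorted by decreasing abundance,
    ties broken lexicographically by sequence.
    """
    counts: dict[str, int] = {}
    for read in reads:
        counts[read.residues] = counts.get(read.residues, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass
class ChimeraVerdict:
    read_id: str
    is_chimera: bool
    parent_a: Optional[str] = None
    parent_b: Optional[str] = None
    crossover: Optional[int] = None
    score: Optional[float] = None  # h, >= 0 whenever parents were evaluated


def _kmer_set(seq: str, k: int = 8) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


# Vote weighting of the chimera score h.  A query position is diagnostic
# when exactly one of the two candidate parents matches the query there.  A
# diagnostic position matching the segment's model parent is a "yes" vote,
# one matching the other parent a "no" vote.  Each segment scores
# Y / (Y + BETA*N); h is the product of the two segment scores, so a query
# fully explained by a single parent (one segment with no support) scores 0.
# BETA penalises contradicting votes heavily, as in abundance-based chimera
# scoring practice.
_BETA = 8.0


def _segment_score(yes: int, no: int) -> float:
    if yes == 0:
        return 0.0
    return yes / (yes + _BETA * no)


def detect_chimeras(
    uniques: Sequence[tuple[str, int]],
    min_parent_fold: float = 2.0,
    min_score: float = 0.28,
    min_divergence_pct: float = 0.8,
    *,
    max_candidates: int = 64,
    max_parents_tested: int = 8,
) -> list[ChimeraVerdict]:
    """Flag two-parent splices among abundance-sorted unique sequences.

    ``uniques`` must be sorted by decreasing abundance (as produced by
    :func:`dereplicate`).  For each query, candidate parents are the more
    abundant sequences with abundance >= ``min_parent_fold`` times the
    query's, pre-filtered to the ``max_candidates`` best k-mer sharers and
    then the ``max_parents_tested`` best by single-parent identity.  The
    query is flagged when the best two-parent model beats the best single
    parent by >= ``min_divergence_pct`` percentage points of identity and its
    vote score h reaches ``min_score``.
    """
    abundances = [a for _, a in uniques]
    if any(abundances[i] < abundances[i + 1] for i in range(len(abundances) - 1)):
        raise ValueError("uniques must be sorted by decreasing abundance")

    verdicts: list[ChimeraVerdict] = []
    kmer_cache = [_kmer_set(seq) for seq, _ in uniques]

    for qi, (query, q_abund) in enumerate(uniques):
        read_id = f"unique_{qi + 1}"
        cand_idx = [
            i
            for i in range(len(uniques))
            if i != qi and uniques[i][1] >= min_parent_fold * q_abund
        ]
        if len(cand_idx) < 2:
            verdicts.append(ChimeraVerdict(read_id, False))
            continue
        if len(cand_idx) > max_candidates:
            qk = kmer_cache[qi]
            cand_idx.sort(key=lambda i: -len(qk & kmer_cache[i]))
            cand_idx = cand_idx[:max_candidates]

        L = len(query)
        vectors = {i: glocal_match_vector(query, uniques[i][0]) for i in cand_idx}
        single_ident = {i: 100.0 * sum(v) / L for i, v in vectors.items()}
        # drop candidates identical to the query: the model can never beat them
        best_single = max(single_ident.values())
        ranked = sorted(cand_idx, key=lambda i: -single_ident[i])[:max_parents_tested]

        best = None  # (model_ident, h, a_idx, b_idx, crossover)
        for ai in range(len(ranked)):
            for bi in range(ai + 1, len(ranked)):
                a, b = ranked[ai], ranked[bi]
                va, vb = vectors[a], vectors[b]
                # prefix sums for O(L) crossover scan, both parent orders:
                # pa/pb count matches, pab/pba count one-sided (diagnostic)
                # matches favouring a resp. b.
                pa, pb, pab, pba = [0], [0], [0], [0]
                for x, y in zip(va, vb):
                    pa.append(pa[-1] + x)
                    pb.append(pb[-1] + y)
                    pab.append(pab[-1] + (x and not y))
                    pba.append(pba[-1] + (y and not x))
                for left, right, pl, pr, pd_l, pd_r in (
                    (a, b, pa, pb, pab, pba),
                    (b, a, pb, pa, pba, pab),
                ):
                    for k in range(1, L):
                        m = pl[k] + (pr[L] - pr[k])
                        ident = 100.0 * m / L
                        if best is not None and ident <= best[0]:
                            continue
                        h = _segment_score(pd_l[k], pd_r[k]) * _segment_score(
                            pd_r[L] - pd_r[k], pd_l[L] - pd_l[k]
                        )
                        best = (ident, h, left, right, k)

        if best is None:
            verdicts.append(ChimeraVerdict(read_id, False, score=0.0))
            continue
        model_ident, h, left, right, crossover = best
        # the optimal crossover is a plateau between flanking diagnostic
        # positions; report its midpoint as the splice estimate
        vl, vr = vectors[left], vectors[right]
        pl, pr = [0], [0]
        for x, y in zip(vl, vr):
            pl.append(pl[-1] + x)
            pr.append(pr[-1] + y)
        best_m = max(pl[k] + pr[L] - pr[k] for k in range(1, L))
        plateau = [k for k in range(1, L) if pl[k] + pr[L] - pr[k] == best_m]
        crossover = plateau[len(plateau) // 2]
        is_chimera = (model_ident - best_single >= min_divergence_pct) and (h >= min_score)
        if is_chimera:
            verdicts.append(
                ChimeraVerdict(
                    read_id,
                    True,
                    parent_a=f"unique_{left + 1}",
                    parent_b=f"unique_{right + 1}",
                    crossover=crossover,
                    score=h,
                )
            )
        else:
            verdicts.append(ChimeraVerdict(read_id, False, score=h))
    return verdicts


def remove_chimeras(
    reads: Sequence[SequenceRecord], verdicts: Sequence[ChimeraVerdict], uniques: Sequence[tuple[str, int]]
) -> list[SequenceRecord]:
    """Drop reads whose dereplicated sequence was flagged chimeric."""
    flagged = {
        uniques[int(v.read_id.split("_")[1]) - 1][0] for v in verdicts if v.is_chimera
    }
    return [r for r in reads if r.residues not in flagged]


def write_verdicts(verdicts: Iterable[ChimeraVerdict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["read_id", "is_chimera", "parent_a", "parent_b", "crossover", "h"])
        for v in verdicts:
            writer.writerow(
                [
                    v.read_id,
                    int(v.is_chimera),
                    v.parent_a or "",
                    v.parent_b or "",
                    v.crossover if v.crossover is not None else "",
                    f"{v.score:.4f}" if v.score is not None else "",
                ]
            )
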