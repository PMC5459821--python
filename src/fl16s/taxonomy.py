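"""Bootstrap naive-Bayes rank classification and alignment species calls.

Two independent tracks, mirroring common practice: a k-mer naive-Bayes
classifier with bootstrap confidences assigns ranks down the lineage, while
species-level calls for core-microbiome work come from best-hit local
alignment against non-redundant type-strain references.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .align import database_hits
from .io import SequenceRecord, reverse_complement
from .synthetic import RANKS, ReferenceSet

__all__ = [
    "TaxonomyAssignment",
    "WordModel",
    "train_classifier",
    "classify",
    "assign_species_by_alignment",
]

UNASSIGNED = "unassigned"


@dataclass
class TaxonomyAssignment:
    """Per-rank labels with bootstrap confidences for one query."""

    query_id: str
    labels: dict[str, str]  # rank -> taxon (or UNASSIGNED)
    confidences: dict[str, float]  # rank -> bootstrap confidence in [0, 1]
    assigned_rank: Optional[str]  # deepest rank of the contiguous run >= threshold


@dataclass
class WordModel:
    """Word-probability model: log P(word | leaf taxon) over observed words."""

    k: int
    leaves: list[str]  # leaf taxa (species)
    lineages: dict[str, dict[str, str]]  # leaf -> rank -> taxon
    vocabulary: dict[str, int]
    log_probs: np.ndarray  # (n_leaves, n_words)
    log_prob_unseen: np.ndarray = field(default=None)  # per-leaf fallback

    def words_of(self, seq: str) -> list[str]:
        return [seq[i : i + self.k] for i in range(len(seq) - self.k + 1)]

    def score_words(self, word_indices: np.ndarray, unseen_count: int) -> np.ndarray:
        """Total log-likelihood per leaf for the given observed-word indices."""
        scores = self.log_probs[:, word_indices].sum(axis=1)
        if unseen_count:
            scores = scores + unseen_count * self.log_prob_unseen
        return scores


def train_classifier(refs: ReferenceSet, k: int = 8) -> WordModel:
    """Train the word model on a reference set, one leaf per species.

    Word probabilities use add-half smoothing,
    ``P(w | leaf) = (n_w + 0.5) / (n_seqs + 1)``, restricted to the words
    observed anywhere in training; unseen words share one fallback
    probability per leaf.  Every trained rank must carry at least two taxa.
    """
    if not 6 <= k <= 10:
        raise ValueError("k must be in [6, 10]")
    lineages = {name: refs.lineage(name) for name in refs.species_names}
    for rank in RANKS:
        taxa = {lin[rank] for lin in lineages.values()}
        if len(taxa) < 2:
            raise ValueError(f"rank {rank!r} has fewer than 2 taxa; cannot train")

    vocabulary: dict[str, int] = {}
    leaf_words: list[set[str]] = []
    leaves = list(refs.species_names)
    for name in leaves:
        seq = refs.sequences[name]
        words = {seq[i : i + k] for i in range(len(seq) - k + 1)}
        leaf_words.append(words)
        for w in words:
            vocabulary.setdefault(w, len(vocabulary))

    n_leaves, n_words = len(leaves), len(vocabulary)
    log_probs = np.empty((n_leaves, n_words))
    # one training sequence per leaf: P = (1{w in seq} + 0.5) / 2
    p_absent = math.log(0.5 / 2.0)
    p_present = math.log(1.5 / 2.0)
    log_probs.fill(p_absent)
    for i, words in enumerate(leaf_words):
        idx = [vocabulary[w] for w in words]
        log_probs[i, idx] = p_present
    model = WordModel(
        k=k,
        leaves=leaves,
        lineages=lineages,
        vocabulary=vocabulary,
        log_probs=log_probs,
        log_prob_unseen=np.full(n_leaves, p_absent),
    )
    return model


def _query_word_indices(model: WordModel, seq: str) -> tuple[np.ndarray, int]:
    words = {seq[i : i + model.k] for i in range(len(seq) - model.k + 1)}
    idx = [model.vocabulary[w] for w in words if w in model.vocabulary]
    unseen = len(words) - len(idx)
    return np.array(idx, dtype=np.intp), unseen


def classify(
    model: WordModel,
    query: SequenceRecord | str,
    n_bootstrap: int = 100,
    confidence_threshold: float = 0.8,
    seed: int = 0,
) -> TaxonomyAssignment:
    """Classify a query with bootstrap confidences per rank.

    Each bootstrap trial scores a random subsample of ``ceil(W/8)`` of the
    query's ``W`` distinct words and votes for the maximum-likelihood leaf.
    A rank's confidence is the vote fraction of its winning taxon; the
    assignment stops at the deepest rank of the contiguous run (from phylum
    down) with confidence >= ``confidence_threshold``.  Both orientations are
    scored and the better one used, so the call is reverse-complement
    invariant.
    """
    seq = query.residues if isinstance(query, SequenceRecord) else query
    query_id = query.id if isinstance(query, SequenceRecord) else "query"
    if len(seq) < model.k:
        raise ValueError("query shorter than word length")

    best = None  # (total_score, word_indices, unseen)
    for oriented in (seq, reverse_complement(seq)):
        idx, unseen = _query_word_indices(model, oriented)
        if idx.size == 0 and unseen == 0:
            continue
        total = float(model.score_words(idx, unseen).max()) if idx.size else -math.inf
        if best is None or total > best[0]:
            best = (total, idx, unseen)
    assert best is not None
    _, idx, unseen = best

    n_words = idx.size + unseen
    subsample = max(1, math.ceil(n_words / 8))
    rng = np.random.default_rng(seed)
    votes = np.zeros(len(model.leaves), dtype=np.int64)
    # treat unseen words as indistinguishable: sampling operates on the
    # observed-word index array plus `unseen` sentinel slots
    pool = np.concatenate([idx, np.full(unseen, -1, dtype=np.intp)])
    for _ in range(n_bootstrap):
        take = rng.choice(pool.size, size=subsample, replace=False)
        sampled = pool[take]
        obs = sampled[sampled >= 0]
        n_unseen = int((sampled < 0).sum())
        scores = model.score_words(obs, n_unseen)
        votes[int(scores.argmax())] += 1

    labels: dict[str, str] = {}
    confidences: dict[str, float] = {}
    for rank in RANKS:
        tally: dict[str, int] = {}
        for leaf, v in zip(model.leaves, votes):
            taxon = model.lineages[leaf][rank]
            tally[taxon] = tally.get(taxon, 0) + int(v)
        winner = max(tally, key=lambda t: (tally[t], t))
        labels[rank] = winner
        confidences[rank] = tally[winner] / n_bootstrap

    assigned_rank = None
    final_labels = dict(labels)
    for rank in RANKS:
        if confidences[rank] >= confidence_threshold:
            assigned_rank = rank
        else:
            for deeper in RANKS[RANKS.index(rank):]:
                final_labels[deeper] = UNASSIGNED
            break
    return TaxonomyAssignment(query_id, final_labels, confidences, assigned_rank)


def assign_species_by_alignment(
    query: SequenceRecord | str,
    nr_refs: Sequence[tuple[tuple[str, ...], str]],
    min_identity_pct: float = 90.0,
) -> Optional[str]:
    """Best-hit species call against non-redundant references.

    ``nr_refs`` holds ``(species_labels, sequence)`` pairs as produced by
    reference deduplication.  The best hit by bit score wins when its
    identity exceeds ``min_identity_pct``; ties across different species (the
    resolvability situation) return ``None``.
    """
    if not nr_refs:
        raise ValueError("empty reference")
    seq = query.residues if isinstance(query, SequenceRecord) else query
    subjects = [(f"nr_{i}", species, ref_seq) for i, (species, ref_seq) in enumerate(nr_refs)]
    hits = database_hits(seq, subjects)
    if not hits:
        return None
    best_bits = max(h.bit_score for h in hits)
    top = [h for h in hits if h.bit_score == best_bits]
    if top[0].identity_pct <= min_identity_pct:
        return None
    species = {sp for h in top for sp in h.species}
    if len(species) != 1:
        return None
    return species.pop()


def write_assignments(assignments: Sequence[TaxonomyAssignment], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        header = ["query_id"]
        for rank in RANKS:
            header += [rank, f"{rank}_confidence"]
        header.append("assigned_rank")
        writer.writerow(header)
        for a in assignments:
            row = [a.query_id]
            for rank in RANKS:
                row += [a.labels[rank], f"{a.confidences[rank]:.2f}"]
            row.append(a.assigned_rank or "")
            writer.writerow(row)
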