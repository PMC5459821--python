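"""Open-reference greedy OTU clustering at a fixed identity threshold.

A closed-reference pass assigns each unique sequence to its best reference
centroid at or above the threshold; survivors are clustered de novo in
decreasing-abundance order, UCLUST-style: join the first existing centroid
reached at or above the threshold, otherwise found a new one.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .align import glocal_identity
from .io import SequenceRecord, write_fasta
from .synthetic import ReferenceSet

__all__ = ["OtuTable", "pairwise_identity", "cluster_otus"]


def pairwise_identity(a: str, b: str) -> float:
    """Fractional identity in [0, 1] of an end-gap-free glocal alignment."""
    return glocal_identity(a, b)


@dataclass
class OtuTable:
    """Samples x OTUs count matrix with centroid sequences."""

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_samples, n_otus), non-negative ints
    centroids: dict[str, str]
    provenance: dict[str, str] = field(default_factory=dict)  # closed_ref | de_novo

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError("counts shape does not match sample/otu ids")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        for otu in self.otu_ids:
            if otu not in self.centroids:
                raise ValueError(f"OTU {otu} has no centroid")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_ids.index(sample_id)]

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.counts.sum(axis=0) > 0
        otus = [o for o, k in zip(self.otu_ids, keep) if k]
        return OtuTable(
            otus,
            list(self.sample_ids),
            self.counts[:, keep],
            {o: self.centroids[o] for o in otus},
            {o: self.provenance[o] for o in otus if o in self.provenance},
        )

    # -- persistence -------------------------------------------------------
    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["#OTU_ID"] + self.sample_ids)
            for j, otu in enumerate(self.otu_ids):
                writer.writerow([otu] + [int(c) for c in self.counts[:, j]])

    def write_biom_json(self, path: str | Path) -> None:
        payload = {
            "format": "Biological Observation Matrix 1.0.0",
            "type": "OTU table",
            "matrix_type": "dense",
            "shape": [len(self.otu_ids), len(self.sample_ids)],
            "rows": [{"id": o, "metadata": {"provenance": self.provenance.get(o)}} for o in self.otu_ids],
            "columns": [{"id": s, "metadata": None} for s in self.sample_ids],
            "data": self.counts.T.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    def write_centroids(self, path: str | Path) -> None:
        write_fasta(
            [SequenceRecord(o, self.centroids[o]) for o in self.otu_ids], path
        )


def _kmer_set(seq: str, k: int = 8) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _kmer_reject(qk: set[str], ck: set[str], threshold: float) -> bool:
    """Conservative pre-filter: skip alignment when shared distinct k-mers
    are too few for the identity threshold to be reachable.

    With mismatch fraction 1-t, at most 8*(1-t) of a sequence's 8-mers can be
    disrupted (union bound), so the shared fraction cannot fall below
    1 - 8*(1-t); a 0.15 safety margin absorbs distinct-set and indel effects.
    """
    bound = max(0.0, 1.0 - 8.0 * (1.0 - threshold) - 0.15)
    if bound <= 0.0:
        return False
    denom = min(len(qk), len(ck))
    return denom > 0 and len(qk & ck) / denom < bound


def cluster_otus(
    reads_per_sample: Mapping[str, Sequence[SequenceRecord]],
    refs: Optional[ReferenceSet] = None,
    threshold: float = 0.97,
) -> OtuTable:
    """Open-reference clustering of per-sample reads into an OTU table.

    Pass 1 (closed-reference, when ``refs`` given): every unique sequence
    joins the best-identity reference at or above ``threshold``.  Pass 2 (de
    novo): remaining uniques, in decreasing total abundance (ties broken
    lexicographically), join the earliest-founded centroid reached at or
    above ``threshold``, else become a new centroid.  Counts are aggregated
    per sample; total counts equal the number of input reads.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")

    sample_ids = list(reads_per_sample)
    # unique sequence -> per-sample counts
    per_sample: dict[str, dict[str, int]] = {}
    for sid in sample_ids:
        for read in reads_per_sample[sid]:
            row = per_sample.setdefault(read.residues, {})
            row[sid] = row.get(sid, 0) + 1
    uniques = sorted(
        per_sample.items(), key=lambda kv: (-sum(kv[1].values()), kv[0])
    )

    otu_ids: list[str] = []
    centroids: dict[str, str] = {}
    provenance: dict[str, str] = {}
    assignment: dict[str, str] = {}  # unique sequence -> otu_id

    # pass 1: closed reference (best hit >= threshold)
    remaining: list[tuple[str, dict[str, int]]] = []
    if refs is not None:
        ref_items = [(name, refs.sequences[name]) for name in refs.species_names]
        ref_kmers = [(_kmer_set(seq)) for _, seq in ref_items]
        for seq, counts in uniques:
            qk = _kmer_set(seq)
            best_name, best_ident = None, threshold
            for (name, ref_seq), rk in zip(ref_items, ref_kmers):
                if _kmer_reject(qk, rk, threshold):
                    continue
                ident = glocal_identity(seq, ref_seq)
                if ident > best_ident or (ident == best_ident and best_name is None):
                    best_name, best_ident = name, ident
            if best_name is None:
                remaining.append((seq, counts))
                continue
            otu = f"ref:{best_name}"
            if otu not in centroids:
                otu_ids.append(otu)
                centroids[otu] = refs.sequences[best_name]
                provenance[otu] = "closed_ref"
            assignment[seq] = otu
    else:
        remaining = list(uniques)

    # pass 2: de novo greedy in decreasing abundance order
    denovo_order: list[str] = []
    denovo_kmers: list[set[str]] = []
    for seq, _counts in remaining:
        qk = _kmer_set(seq)
        joined = None
        for otu, ck in zip(denovo_order, denovo_kmers):
            if _kmer_reject(qk, ck, threshold):
                continue
            if glocal_identity(seq, centroids[otu]) >= threshold:
                joined = otu
                break
        if joined is None:
            joined = f"denovo:{len(denovo_order) + 1}"
            otu_ids.append(joined)
            centroids[joined] = seq
            provenance[joined] = "de_novo"
            denovo_order.append(joined)
            denovo_kmers.append(qk)
        assignment[seq] = joined

    counts = np.zeros((len(sample_ids), len(otu_ids)), dtype=np.int64)
    otu_index = {o: j for j, o in enumerate(otu_ids)}
    for seq, sample_counts in uniques:
        j = otu_index[assignment[seq]]
        for sid, n in sample_counts.items():
            counts[sample_ids.index(sid), j] += n

    table = OtuTable(otu_ids, sample_ids, counts, centroids, provenance)
    return table.drop_empty_otus()
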