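"""Sequence I/O and dual-barcode demultiplexing.

Reads and writes FASTA/FASTQ, carries the amplicon primer/barcode scheme,
and splits pooled reads back into per-sample bins using the asymmetric
(forward, reverse) 16-base barcode pairs at the read ends.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

__all__ = [
    "IUPAC_CODES",
    "SequenceRecord",
    "PrimerScheme",
    "ManifestRow",
    "SampleManifest",
    "DemuxResult",
    "reverse_complement",
    "iupac_match",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_manifest",
    "write_manifest",
    "demultiplex",
]

#: IUPAC nucleotide codes mapped to the set of concrete bases they stand for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# Strict alphabet for stored sequences (degenerate codes allowed in primers,
# not in reads/references).
_STRICT = frozenset("ACGT")
_IUPAC = frozenset(IUPAC_CODES)


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(a: str, b: str) -> bool:
    """True when two IUPAC codes share at least one concrete base."""
    try:
        return not IUPAC_CODES[a].isdisjoint(IUPAC_CODES[b])
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"not an IUPAC nucleotide code: {exc}") from None


@dataclass
class SequenceRecord:
    """One read or reference sequence.

    Parameters
    ----------
    id
        Unique record identifier (FASTA header up to first whitespace).
    residues
        Upper-case DNA string over ``{A, C, G, T}``.
    qualities
        Optional per-base Phred scores, same length as ``residues``.
    annotations
        Free-form metadata (sample, barcodes, orientation, ...).
    """

    id: str
    residues: str
    qualities: Optional[list[int]] = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.residues):
            raise ValueError(
                f"record {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.residues)} residues"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self, id_suffix: str = "") -> "SequenceRecord":
        quals = None if self.qualities is None else self.qualities[::-1]
        return SequenceRecord(
            self.id + id_suffix,
            reverse_complement(self.residues),
            quals,
            dict(self.annotations),
        )


def _validate_residues(rec_id: str, seq: str, *, allow_degenerate: bool = False) -> str:
    seq = seq.upper()
    allowed = _IUPAC if allow_degenerate else _STRICT
    for pos, ch in enumerate(seq):
        if ch not in allowed:
            raise ValueError(
                f"record {rec_id!r}: invalid character {ch!r} at offset {pos}"
            )
    return seq


def read_fasta(path: str | Path, *, allow_degenerate: bool = False) -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    Both single-line and wrapped sequence dialects are accepted.  Characters
    outside the allowed alphabet raise :class:`ValueError` naming the record
    and the 0-based offset of the first offending character.
    """
    records: list[SequenceRecord] = []
    header: Optional[str] = None
    chunks: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        seq = _validate_residues(header, "".join(chunks), allow_degenerate=allow_degenerate)
        records.append(SequenceRecord(header, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise ValueError(f"{path}:{lineno}: malformed FASTA header")
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"{path}:{lineno}: sequence before first header")
                chunks.append(line)
    _flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, *, width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Parse a 4-line-per-record FASTQ file."""
    records: list[SequenceRecord] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) % 4:
        # trailing blank lines are tolerated
        while lines and not lines[-1]:
            lines.pop()
    if len(lines) % 4:
        raise ValueError(f"{path}: truncated FASTQ (line count not a multiple of 4)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@") or not plus.startswith("+"):
            raise ValueError(f"{path}: malformed FASTQ record at line {i + 1}")
        rec_id = head[1:].split()[0]
        seq = _validate_residues(rec_id, seq)
        quals = [ord(c) - 33 for c in qual]
        records.append(SequenceRecord(rec_id, seq, quals))
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path, *, default_quality: int = 30) -> None:
    with open(path, "w") as fh:
        for rec in records:
            quals = rec.qualities or [default_quality] * len(rec.residues)
            fh.write(f"@{rec.id}\n{rec.residues}\n+\n")
            fh.write("".join(chr(q + 33) for q in quals) + "\n")


# ---------------------------------------------------------------------------
# Primer / barcode scheme
# ---------------------------------------------------------------------------

#: Gene-specific and adapter primers of the two-step barcoding construct.
DEFAULT_GENE_FWD = "AGAGTTTGATCMTGGCTCAG"  # 27F
DEFAULT_GENE_REV = "TACGGYTACCTTGTTACGACTT"  # 1492R
DEFAULT_M13F = "TGTAAAACGACGGCCAGT"
DEFAULT_M13R = "GGAAACAGCTATGACCATG"

#: Hypervariable-region flanking primers (forward, reverse) per region.
DEFAULT_REGION_FLANKS: dict[str, tuple[str, str]] = {
    "V3V4": ("ACTCCTACGGGAGGCAGCAG", "CTACCAGGGTATCTAATC"),  # 338F / 786R
    "V5V6": ("GGATTAGATACCCTGGTAGTCC", "CTCACGRCACGAGCTGACG"),  # 785F / 1081R
}

BARCODE_LENGTH = 16

# Five forward + five reverse 16-mers (configuration, not data): mutually
# distant 16-mers so that single-substitution decoding is unambiguous.
DEFAULT_FWD_BARCODES: dict[str, str] = {
    "F01": "ACACACACGTGTGTGT",
    "F02": "CACACACATGTGTGTG",
    "F03": "ACAGACAGACAGACAG",
    "F04": "TGTCTGTCTGTCTGTC",
    "F05": "ACGTACGTACGTACGT",
}
DEFAULT_REV_BARCODES: dict[str, str] = {
    "R01": "CTGCGTGTCTGCGTGT",
    "R02": "CATGTATCCATGTATC",
    "R03": "GCAGTCGAGCAGTCGA",
    "R04": "TCAGACGATCAGACGA",
    "R05": "GAGCTCTGGAGCTCTG",
}


@dataclass
class PrimerScheme:
    """Primers, adapters, barcodes and region flanks of the amplicon design."""

    gene_fwd: str = DEFAULT_GENE_FWD
    gene_rev: str = DEFAULT_GENE_REV
    m13f: str = DEFAULT_M13F
    m13r: str = DEFAULT_M13R
    fwd_barcodes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_FWD_BARCODES))
    rev_barcodes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_REV_BARCODES))
    region_flanks: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_FLANKS)
    )

    def __post_init__(self) -> None:
        for name, primer in [
            ("gene_fwd", self.gene_fwd),
            ("gene_rev", self.gene_rev),
            ("m13f", self.m13f),
            ("m13r", self.m13r),
        ] + [(f"flank:{r}:{i}", p) for r, pair in self.region_flanks.items() for i, p in enumerate(pair)]:
            bad = set(primer) - _IUPAC
            if bad:
                raise ValueError(f"{name}: non-IUPAC characters {sorted(bad)}")
        for label, bcs in [("fwd", self.fwd_barcodes), ("rev", self.rev_barcodes)]:
            for bc_id, bc in bcs.items():
                if len(bc) != BARCODE_LENGTH:
                    raise ValueError(f"{label} barcode {bc_id}: length {len(bc)} != {BARCODE_LENGTH}")
                if set(bc) - _STRICT:
                    raise ValueError(f"{label} barcode {bc_id}: non-ACGT characters")

    # -- serialisation -----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "gene_fwd": self.gene_fwd,
            "gene_rev": self.gene_rev,
            "m13f": self.m13f,
            "m13r": self.m13r,
            "fwd_barcodes": dict(self.fwd_barcodes),
            "rev_barcodes": dict(self.rev_barcodes),
            "region_flanks": {k: list(v) for k, v in self.region_flanks.items()},
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PrimerScheme":
        payload = yaml.safe_load(Path(path).read_text())
        payload["region_flanks"] = {k: tuple(v) for k, v in payload["region_flanks"].items()}
        return cls(**payload)


@dataclass(frozen=True)
class ManifestRow:
    sample_id: str
    site: str
    group: str
    fwd_barcode_id: str
    rev_barcode_id: str


class SampleManifest:
    """Sample sheet mapping samples to sites, groups and barcode pairs."""

    def __init__(self, rows: Sequence[ManifestRow]):
        self.rows = list(rows)
        ids = [r.sample_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in manifest")
        pairs = [(r.fwd_barcode_id, r.rev_barcode_id) for r in self.rows]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (fwd, rev) barcode pair in manifest")

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.rows]

    def by_pair(self) -> dict[tuple[str, str], str]:
        return {(r.fwd_barcode_id, r.rev_barcode_id): r.sample_id for r in self.rows}

    def groups(self) -> dict[str, str]:
        return {r.sample_id: r.group for r in self.rows}

    def sites(self) -> dict[str, str]:
        return {r.sample_id: r.site for r in self.rows}

    def validate_against(self, scheme: PrimerScheme) -> None:
        for row in self.rows:
            if row.fwd_barcode_id not in scheme.fwd_barcodes:
                raise ValueError(f"{row.sample_id}: unknown forward barcode {row.fwd_barcode_id}")
            if row.rev_barcode_id not in scheme.rev_barcodes:
                raise ValueError(f"{row.sample_id}: unknown reverse barcode {row.rev_barcode_id}")


def read_manifest(path: str | Path) -> SampleManifest:
    rows = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rec in reader:
            rows.append(
                ManifestRow(
                    rec["sample_id"],
                    rec["site"],
                    rec["group"],
                    rec["fwd_barcode_id"],
                    rec["rev_barcode_id"],
                )
            )
    return SampleManifest(rows)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["sample_id", "site", "group", "fwd_barcode_id", "rev_barcode_id"])
        for row in manifest:
            writer.writerow([row.sample_id, row.site, row.group, row.fwd_barcode_id, row.rev_barcode_id])


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _decode_end(observed: str, barcodes: Mapping[str, str], max_mm: int) -> Optional[str]:
    """Closest barcode id by Hamming distance; None when no unique hit ≤ max_mm."""
    best_id, best_d, tied = None, max_mm + 1, False
    for bc_id, bc in barcodes.items():
        d = _hamming(observed, bc)
        if d < best_d:
            best_id, best_d, tied = bc_id, d, False
        elif d == best_d:
            tied = True
    if best_id is None or tied:
        return None
    return best_id


@dataclass
class DemuxResult:
    """Outcome of demultiplexing a read pool."""

    assigned: dict[str, list[SequenceRecord]]
    unassigned: list[SequenceRecord]
    counts: dict[str, int]

    @property
    def n_unassigned(self) -> int:
        return len(self.unassigned)

    def report_rows(self) -> list[tuple[str, int]]:
        rows = sorted(self.counts.items())
        rows.append(("unassigned", self.n_unassigned))
        return rows

    def write_report(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["sample_id", "n_assigned"])
            writer.writerows(self.report_rows())


def demultiplex(
    reads: Iterable[SequenceRecord],
    scheme: PrimerScheme,
    manifest: SampleManifest,
    max_barcode_mismatch: int = 1,
    *,
    trim: bool = True,
) -> DemuxResult:
    """Assign reads to samples by their terminal (forward, reverse) barcodes.

    Each read is examined in both orientations.  The leading 16-mer is decoded
    against the forward barcode set and the trailing 16-mer against the
    reverse-complemented reverse barcode set, each within
    ``max_barcode_mismatch`` substitutions.  A read is assigned when exactly
    one orientation decodes to a pair present in the manifest; ties at equal
    distance leave the read unassigned.  Assigned reads are trimmed of the
    barcode and M13 adapter on both ends (the gene primers are retained so the
    insert stays a full-length amplicon).
    """
    manifest.validate_against(scheme)
    pair_to_sample = manifest.by_pair()
    rc_rev = {bc_id: reverse_complement(bc) for bc_id, bc in scheme.rev_barcodes.items()}

    lead_trim = BARCODE_LENGTH + len(scheme.m13f)
    tail_trim = BARCODE_LENGTH + len(scheme.m13r)

    assigned: dict[str, list[SequenceRecord]] = {s: [] for s in manifest.sample_ids}
    unassigned: list[SequenceRecord] = []

    for read in reads:
        hits = []  # (sample_id, oriented_record)
        for orient, rec in (("fwd", read), ("rev", read.reverse_complement())):
            if len(rec.residues) < lead_trim + tail_trim + 1:
                continue
            fwd_id = _decode_end(rec.residues[:BARCODE_LENGTH], scheme.fwd_barcodes, max_barcode_mismatch)
            rev_id = _decode_end(rec.residues[-BARCODE_LENGTH:], rc_rev, max_barcode_mismatch)
            if fwd_id is None or rev_id is None:
                continue
            sample = pair_to_sample.get((fwd_id, rev_id))
            if sample is None:
                continue
            hits.append((sample, orient, rec, fwd_id, rev_id))
        if len(hits) != 1:
            unassigned.append(read)
            continue
        sample, orient, rec, fwd_id, rev_id = hits[0]
        if trim:
            residues = rec.residues[lead_trim : len(rec.residues) - tail_trim]
            quals = None
            if rec.qualities is not None:
                quals = rec.qualities[lead_trim : len(rec.qualities) - tail_trim]
        else:
            residues, quals = rec.residues, rec.qualities
        annotations = dict(read.annotations)
        annotations.update(
            sample=sample, fwd_barcode=fwd_id, rev_barcode=rev_id, orientation=orient
        )
        assigned[sample].append(SequenceRecord(read.id, residues, quals, annotations))

    counts = {s: len(v) for s, v in assigned.items()}
    return DemuxResult(assigned=assigned, unassigned=unassigned, counts=counts)
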