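"""Synthetic reference taxonomies and barcoded community read sets.

Everything downstream of sequencing is exercised against communities with a
known truth table: a reference of ~1,450 nt 16S-like sequences carrying the
real primer motifs at canonical offsets, species pairs engineered to be
indistinguishable over one hypervariable region but not the others, and
CCS-like reads decorated with the two-step barcode construct.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io import (
    PrimerScheme,
    SampleManifest,
    SequenceRecord,
    reverse_complement,
    write_fasta,
)

__all__ = [
    "ReferenceSet",
    "CommunitySpec",
    "ReadTruth",
    "generate_reference_set",
    "simulate_reads",
    "SCAFFOLD_LENGTH",
    "REGION_LAYOUT",
]

RANKS = ("phylum", "class", "order", "family", "genus", "species")

# --- scaffold geometry -----------------------------------------------------
# Concrete expansions of the degenerate primer positions used on the template
# (M->A in 27F, Y->T in 1492R, R->A in 1081R).
_P27F = "AGAGTTTGATCATGGCTCAG"
_P338F = "ACTCCTACGGGAGGCAGCAG"
_P785F = "GGATTAGATACCCTGGTAGTCC"
_P1081R_SITE = reverse_complement("CTCACGACACGAGCTGACG")
_P1492R_SITE = reverse_complement("TACGGTTACCTTGTTACGACTT")

SCAFFOLD_LENGTH = 1450

# Fixed motif placement.  The 786R reverse-flank site is the reverse
# complement of CTACCAGGGTATCTAATC, which is a substring of the 785F site
# (the two primers overlap on the real gene), so placing 785F pins both.
_MOTIFS = {
    "p27f": (0, _P27F),
    "p338f": (318, _P338F),
    "p785f": (757, _P785F),
    "p1081r": (1034, _P1081R_SITE),
    "p1492r": (SCAFFOLD_LENGTH - len(_P1492R_SITE), _P1492R_SITE),
}

#: Template coordinates of the extractable regions (primer-exclusive).
#: V3V4 runs from the end of the 338F site to the start of the 786R site
#: (420 nt); V5V6 from the end of the 785F site to the start of the 1081R
#: site (255 nt).
REGION_LAYOUT: dict[str, tuple[int, int]] = {
    "FULL": (0, SCAFFOLD_LENGTH),
    "V3V4": (338, 758),
    "V5V6": (779, 1034),
}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class ReferenceSet:
    """Synthetic type-strain reference with per-region confusability truth.

    ``species`` rows are ``(species, genus, family, order, class, phylum)``;
    ``confusable_pairs`` lists ``(species_a, species_b, region)`` triples whose
    extracted subsequences over that region are character-identical although
    the full-length sequences differ.
    """

    species: list[tuple[str, str, str, str, str, str]]
    sequences: dict[str, str]
    region_layout: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(REGION_LAYOUT)
    )
    confusable_pairs: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def species_names(self) -> list[str]:
        return [row[0] for row in self.species]

    def lineage(self, species_name: str) -> dict[str, str]:
        for row in self.species:
            if row[0] == species_name:
                name, genus, family, order, klass, phylum = row
                return {
                    "phylum": phylum,
                    "class": klass,
                    "order": order,
                    "family": family,
                    "genus": genus,
                    "species": name,
                }
        raise KeyError(species_name)

    def region_sequence(self, species_name: str, region: str) -> str:
        start, end = self.region_layout[region]
        return self.sequences[species_name][start:end]

    # -- persistence -------------------------------------------------------
    def write(self, fasta_path: str | Path, taxonomy_path: str | Path) -> None:
        recs = [SequenceRecord(name, self.sequences[name]) for name in self.species_names]
        write_fasta(recs, fasta_path)
        with open(taxonomy_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            for name, genus, family, order, klass, phylum in self.species:
                lineage = ";".join([phylum, klass, order, family, genus, name])
                writer.writerow([name, lineage])


def _mutate_positions(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> None:
    """Substitute each position with a uniformly drawn *different* base."""
    for pos in positions:
        current = seq[pos]
        choices = _BASES[_BASES != current]
        seq[pos] = rng.choice(choices)


def _free_positions() -> np.ndarray:
    fixed = np.zeros(SCAFFOLD_LENGTH, dtype=bool)
    for start, motif in _MOTIFS.values():
        fixed[start : start + len(motif)] = True
    return np.flatnonzero(~fixed)


def _region_mismatch_frac(a: np.ndarray, b: np.ndarray, bounds: tuple[int, int]) -> float:
    s, e = bounds
    return float(np.mean(a[s:e] != b[s:e]))


def generate_reference_set(
    n_species: int,
    n_confusable_pairs: int = 0,
    region_for_confusion: str = "V3V4",
    seed: int = 0,
    *,
    mutation_rate: float = 0.10,
    min_region_divergence: float = 0.03,
) -> ReferenceSet:
    """Build a reference of ``n_species`` scaffold-derived sequences.

    The first ``2 * n_confusable_pairs`` species form pairs that are
    character-identical over ``region_for_confusion`` but diverge by at least
    ``min_region_divergence`` in every other region; all other species pairs
    diverge by at least that fraction in every region.  Deterministic for a
    fixed seed.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if n_confusable_pairs < 0:
        raise ValueError("n_confusable_pairs must be >= 0")
    if region_for_confusion not in REGION_LAYOUT:
        raise ValueError(f"unknown region {region_for_confusion!r}")
    if n_confusable_pairs and n_species < 2 * n_confusable_pairs + 1:
        raise ValueError("need n_species >= 2*n_confusable_pairs + 1")

    rng = np.random.default_rng(seed)
    free = _free_positions()

    # Conserved backbone shared by all species.
    scaffold = np.array(list("A" * SCAFFOLD_LENGTH), dtype="S1")
    scaffold[:] = rng.choice(_BASES, size=SCAFFOLD_LENGTH)
    for start, motif in _MOTIFS.values():
        scaffold[start : start + len(motif)] = np.frombuffer(motif.encode(), dtype="S1")

    conf_bounds = REGION_LAYOUT[region_for_confusion]
    non_full_regions = {r: b for r, b in REGION_LAYOUT.items() if r != "FULL"}

    def diverged_everywhere(cand: np.ndarray, others: list[np.ndarray]) -> bool:
        for other in others:
            for bounds in non_full_regions.values():
                if _region_mismatch_frac(cand, other, bounds) < min_region_divergence:
                    return False
        return True

    sequences: list[np.ndarray] = []
    for _ in range(n_species):
        for _attempt in range(200):
            cand = scaffold.copy()
            n_mut = rng.binomial(free.size, mutation_rate)
            picks = rng.choice(free, size=n_mut, replace=False)
            _mutate_positions(cand, picks, rng)
            if diverged_everywhere(cand, sequences):
                sequences.append(cand)
                break
        else:  # pragma: no cover - probabilistically unreachable
            raise RuntimeError("could not generate a sufficiently divergent species")

    confusable: list[tuple[str, str, str]] = []
    names = [f"Species_{i + 1:03d}" for i in range(n_species)]
    for p in range(n_confusable_pairs):
        a, b = 2 * p, 2 * p + 1
        s, e = conf_bounds
        # make B share A's confusion region verbatim; B keeps its own
        # divergence elsewhere, so the full-length sequences still differ.
        sequences[b][s:e] = sequences[a][s:e]
        if np.array_equal(sequences[a], sequences[b]):  # pragma: no cover
            raise RuntimeError("confusable pair collapsed to identical sequences")
        confusable.append((names[a], names[b], region_for_confusion))

    # Lineage: confusable pairs share a genus (the real-world situation the
    # analysis probes); everything rolls up two-at-a-time into higher ranks.
    species_rows = []
    for i, name in enumerate(names):
        if i < 2 * n_confusable_pairs:
            genus_idx = i // 2
        else:
            genus_idx = n_confusable_pairs + (i - 2 * n_confusable_pairs)
        # modulo rollup keeps every rank populated with >= 2 taxa for any
        # reference with >= 2 genera, while staying a consistent hierarchy
        # (family determines order, order class, class phylum)
        genus = f"Genus_{genus_idx + 1:02d}"
        family = f"Family_{genus_idx % 16 + 1:02d}"
        order = f"Order_{genus_idx % 8 + 1:02d}"
        klass = f"Class_{genus_idx % 4 + 1:02d}"
        phylum = f"Phylum_{genus_idx % 2 + 1:02d}"
        species_rows.append((name, genus, family, order, klass, phylum))

    seq_map = {name: seq.tobytes().decode() for name, seq in zip(names, sequences)}
    return ReferenceSet(species=species_rows, sequences=seq_map, confusable_pairs=confusable)


def add_region_confusion(refs: ReferenceSet, species_a: str, species_b: str, region: str) -> None:
    """Make ``species_b`` share ``species_a``'s sequence over ``region``.

    Grafts the region in place and records the pair, so a reference can carry
    confusable pairs in more than one region (e.g. one V3V4 pair and one
    V5V6 pair).  The two species must not already coincide elsewhere.
    """
    if region not in refs.region_layout or region == "FULL":
        raise ValueError(f"cannot graft region {region!r}")
    s, e = refs.region_layout[region]
    sa, sb = refs.sequences[species_a], refs.sequences[species_b]
    grafted = sb[:s] + sa[s:e] + sb[e:]
    if grafted == sa:
        raise ValueError("graft would make the sequences fully identical")
    refs.sequences[species_b] = grafted
    refs.confusable_pairs.append((species_a, species_b, region))


# ---------------------------------------------------------------------------
# Community specification and read simulation
# ---------------------------------------------------------------------------


@dataclass
class CommunitySpec:
    """Sampling design: who is in each sample and how reads are generated."""

    samples: list[tuple[str, str, str]]  # (sample_id, site, group)
    composition: dict[str, dict[str, float]]
    n_reads: int
    error_rate: float = 0.0064
    chimera_rate: float = 0.0
    barcode_assignment: dict[str, tuple[str, str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if not 0.0 <= self.chimera_rate <= 1.0:
            raise ValueError("chimera_rate must be in [0, 1]")
        for sample_id, _, _ in self.samples:
            comp = self.composition.get(sample_id)
            if comp is None:
                raise ValueError(f"sample {sample_id}: no composition")
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"sample {sample_id}: composition sums to {total}")
        if not self.barcode_assignment:
            self.barcode_assignment = self._default_barcodes()
        pairs = list(self.barcode_assignment.values())
        if len(set(pairs)) != len(pairs):
            raise ValueError("barcode_assignment must be injective")

    def _default_barcodes(self) -> dict[str, tuple[str, str]]:
        from .io import DEFAULT_FWD_BARCODES, DEFAULT_REV_BARCODES

        fwd_ids = sorted(DEFAULT_FWD_BARCODES)
        rev_ids = sorted(DEFAULT_REV_BARCODES)
        if len(self.samples) > len(fwd_ids) * len(rev_ids):
            raise ValueError("more samples than available barcode pairs")
        out = {}
        for i, (sample_id, _, _) in enumerate(self.samples):
            out[sample_id] = (fwd_ids[i % len(fwd_ids)], rev_ids[i // len(fwd_ids)])
        return out

    def to_manifest(self) -> SampleManifest:
        from .io import ManifestRow

        rows = [
            ManifestRow(sid, site, group, *self.barcode_assignment[sid])
            for sid, site, group in self.samples
        ]
        return SampleManifest(rows)


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    sample_id: str
    species: str
    is_chimera: bool
    parent_b: Optional[str] = None
    crossover: Optional[int] = None


def _apply_noise(seq: str, error_rate: float, rng: np.random.Generator, indel_fraction: float = 0.10) -> str:
    """I.i.d. per-base errors: mostly substitutions, a small indel fraction."""
    if error_rate == 0.0:
        return seq
    out: list[str] = []
    for ch in seq:
        if rng.random() >= error_rate:
            out.append(ch)
            continue
        r = rng.random()
        if r >= indel_fraction:  # substitution to a different base
            out.append(str(rng.choice([b for b in "ACGT" if b != ch])))
        elif r >= indel_fraction / 2:  # insertion before the base
            out.append(str(rng.choice(list("ACGT"))))
            out.append(ch)
        # else: deletion, emit nothing
    return "".join(out)


def simulate_reads(
    refs: ReferenceSet, spec: CommunitySpec, scheme: Optional[PrimerScheme] = None
) -> tuple[list[SequenceRecord], list[ReadTruth]]:
    """Generate barcoded reads and their truth table.

    Each read is ``fwd_barcode + M13F + template + rc(M13R) + rc(rev_barcode)``
    where the template is a full reference sequence (27F..1492R sites
    included) or, for chimeras, a two-parent splice at a uniform crossover in
    the interior 20-80% of the template.  Per-base noise at
    ``spec.error_rate`` is applied to the whole decorated read.
    """
    scheme = scheme or PrimerScheme()
    for sid, _, _ in spec.samples:
        for sp in spec.composition[sid]:
            if sp not in refs.sequences:
                raise ValueError(f"composition references unknown species {sp!r}")
        fwd_id, rev_id = spec.barcode_assignment[sid]
        if fwd_id not in scheme.fwd_barcodes or rev_id not in scheme.rev_barcodes:
            raise ValueError(f"sample {sid}: barcode ids not in scheme")

    rng = np.random.default_rng(spec.seed)
    m13r_rc = reverse_complement(scheme.m13r)

    reads: list[SequenceRecord] = []
    truth: list[ReadTruth] = []
    counter = 0
    for sample_id, _site, _group in spec.samples:
        comp = spec.composition[sample_id]
        species_names = sorted(comp)
        probs = np.array([comp[s] for s in species_names])
        fwd_bc = scheme.fwd_barcodes[spec.barcode_assignment[sample_id][0]]
        rev_bc_rc = reverse_complement(scheme.rev_barcodes[spec.barcode_assignment[sample_id][1]])
        picks = rng.choice(len(species_names), size=spec.n_reads, p=probs)
        for pick in picks:
            counter += 1
            read_id = f"read_{counter:06d}"
            species = species_names[pick]
            template = refs.sequences[species]
            is_chimera = False
            parent_b: Optional[str] = None
            crossover: Optional[int] = None
            if spec.chimera_rate and rng.random() < spec.chimera_rate and len(species_names) >= 2:
                others = [s for s in species_names if s != species]
                parent_b = str(others[rng.integers(len(others))])
                lo = int(0.2 * len(template))
                hi = int(0.8 * len(template))
                crossover = int(rng.integers(lo, hi))
                template = template[:crossover] + refs.sequences[parent_b][crossover:]
                is_chimera = True
            decorated = fwd_bc + scheme.m13f + template + m13r_rc + rev_bc_rc
            noisy = _apply_noise(decorated, spec.error_rate, rng)
            reads.append(SequenceRecord(read_id, noisy, annotations={"sample_truth": sample_id}))
            truth.append(ReadTruth(read_id, sample_id, species, is_chimera, parent_b, crossover))
    return reads, truth


def write_truth_table(truth: list[ReadTruth], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["read_id", "sample_id", "species", "is_chimera", "parent_b", "crossover"])
        for t in truth:
            writer.writerow(
                [t.read_id, t.sample_id, t.species, int(t.is_chimera), t.parent_b or "", t.crossover if t.crossover is not None else ""]
            )
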