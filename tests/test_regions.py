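from __future__ import annotations

import numpy as np
import pytest

from fl16s.align import bit_score
from fl16s.io import SequenceRecord, demultiplex, reverse_complement
from fl16s.regions import (
    ExtractionFailure,
    NonRedundantReference,
    RegionSlice,
    build_nj_tree,
    call_species,
    dedup_references,
    extract_region,
    extract_region_verbose,
    locate_primer,
    nj_from_distances,
    resolvability_report,
)
from fl16s.synthetic import REGION_LAYOUT, CommunitySpec, generate_reference_set, simulate_reads

from .oracles import gotoh_local_score, nj_topology_4taxa


class TestDedupReferences:
    def test_identical_same_species(self):
        nr = dedup_references([("SpA", "ACGTACGT"), ("SpA", "ACGTACGT")])
        assert len(nr) == 1
        assert nr[0].species == ("SpA",)

    def test_substring_containment_keeps_longest(self):
        nr = dedup_references([("SpA", "TTACGTACGTTT"), ("SpB", "ACGTACGT")])
        assert len(nr) == 1
        assert nr[0].sequence == "TTACGTACGTTT"
        assert set(nr[0].species) == {"SpA", "SpB"}

    def test_disjoint_set_preserved(self):
        refs = [("S1", "AAAA"), ("S2", "CCCC"), ("S3", "GGGG")]
        assert len(dedup_references(refs)) == 3

    def test_conflicting_labels_recorded_on_representative(self):
        nr = dedup_references([("SpA", "ACGTACGT"), ("SpB", "ACGTACGT")])
        assert len(nr) == 1
        assert set(nr[0].species) == {"SpA", "SpB"}


class TestLocatePrimer:
    def test_degenerate_match_zero_mismatches(self):
        hit = locate_primer("TTTTCTCACGACACGAGCTGACGTTTT", "CTCACGRCACGAGCTGACG")
        assert hit is not None
        assert hit[2] == 0  # R matches A

    def test_degenerate_mismatch_counted(self):
        hit = locate_primer("TTTTCTCACGTCACGAGCTGACGTTTT", "CTCACGRCACGAGCTGACG")
        assert hit is not None
        assert hit[2] == 1  # R does not match T

    def test_absent_primer_returns_none(self):
        assert locate_primer("A" * 100, "CTCACGRCACGAGCTGACG") is None

    def test_reverse_strand_found(self):
        primer = "ACTCCTACGGGAGGCAGCAG"
        seq = "TT" + reverse_complement(primer) + "TT"
        hit = locate_primer(seq, primer)
        assert hit is not None and hit[3] == "-"

    def test_primer_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            locate_primer("ACG", "ACGTACGT")


class TestExtractRegion:
    def test_zero_noise_interval_matches_construction(self, small_refs, scheme):
        name = small_refs.species_names[2]
        read = SequenceRecord("r1", small_refs.sequences[name])
        for region in ("V3V4", "V5V6"):
            slice_ = extract_region(read, region, scheme)
            assert slice_ is not None
            assert slice_.interval == REGION_LAYOUT[region]
            assert slice_.sequence == small_refs.region_sequence(name, region)

    def test_missing_flank_reported(self, small_refs, scheme):
        name = small_refs.species_names[0]
        seq = small_refs.sequences[name]
        start, end = REGION_LAYOUT["V3V4"]
        # delete the reverse flank site (just after the region)
        broken = seq[: end] + seq[end + 22 :]
        truncated = broken[:700]  # drop everything holding the rev flank
        read = SequenceRecord("r1", truncated)
        slice_, reason = extract_region_verbose(read, "V3V4", scheme)
        assert slice_ is None
        assert reason == ExtractionFailure.MISSING_FLANK

    def test_inverted_interval_distinct_failure(self, scheme):
        fwd, rev = scheme.region_flanks["V3V4"]
        # reverse-flank site placed before the forward flank
        seq = "T" * 30 + reverse_complement(rev) + "T" * 10 + fwd + "T" * 30
        read = SequenceRecord("r1", seq)
        slice_, reason = extract_region_verbose(read, "V3V4", scheme)
        assert slice_ is None
        assert reason == ExtractionFailure.INVERTED_INTERVAL

    def test_include_primers_grows_by_flank_lengths(self, small_refs, scheme):
        read = SequenceRecord("r1", small_refs.sequences[small_refs.species_names[1]])
        excl = extract_region(read, "V3V4", scheme, include_primers=False)
        incl = extract_region(read, "V3V4", scheme, include_primers=True)
        fwd, rev = scheme.region_flanks["V3V4"]
        assert len(incl.sequence) == len(excl.sequence) + len(fwd) + len(rev)

    def test_full_region_is_parent(self, scheme):
        read = SequenceRecord("r1", "ACGT" * 50)
        slice_ = extract_region(read, "FULL", scheme)
        assert slice_.sequence == read.residues
        assert slice_.interval == (0, len(read.residues))


def _nr(refs) -> list[NonRedundantReference]:
    return dedup_references([(n, refs.sequences[n]) for n in refs.species_names])


class TestCallSpecies:
    def test_unique_mapping_resolved(self, small_refs, scheme):
        nr = _nr(small_refs)
        name = small_refs.species_names[4]  # not in the confusable pair
        read = SequenceRecord("r1", small_refs.sequences[name])
        slice_ = extract_region(read, "V3V4", scheme)
        call = call_species(slice_, nr)
        assert call.verdict == "resolved"
        assert call.species == name

    def test_confusable_pair_ambiguous_in_region(self, small_refs, scheme):
        nr = _nr(small_refs)
        a, b, region = small_refs.confusable_pairs[0]
        read = SequenceRecord("r1", small_refs.sequences[a])
        slice_ = extract_region(read, region, scheme)
        call = call_species(slice_, nr)
        assert call.verdict == "ambiguous"
        tied_species = {sp for h in call.tied_hits for sp in h.species}
        assert tied_species == {a, b}

    def test_same_read_full_length_resolved(self, small_refs, scheme):
        nr = _nr(small_refs)
        a, _b, _region = small_refs.confusable_pairs[0]
        read = SequenceRecord("r1", small_refs.sequences[a])
        call = call_species(extract_region(read, "FULL", scheme), nr)
        assert call.verdict == "resolved"
        assert call.species == a

    def test_empty_slice_rejected(self, small_refs):
        with pytest.raises(ValueError):
            call_species(RegionSlice("r", "V3V4", "", (0, 0)), _nr(small_refs))

    def test_oracle_equivalence_brute_force_dp(self):
        """Verdicts match a from-scratch DP scan over every reference."""
        rng = np.random.default_rng(99)

        def mutate(s, n):
            out = list(s)
            for i in rng.choice(len(s), n, replace=False):
                out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
            return "".join(out)

        base = "".join(rng.choice(list("ACGT"), 150))
        refs = []
        for i in range(12):
            refs.append((f"Sp{i:02d}", mutate(base, 25)))
        # a confusable pair: same middle 60 bases
        twin = list(mutate(base, 25))
        twin[40:100] = list(refs[0][1][40:100])
        refs.append(("Sp12", "".join(twin)))
        nr = [NonRedundantReference((s,), q) for s, q in refs]
        db_len = sum(len(q) for _, q in refs)

        queries = [
            refs[0][1][40:100],        # shared segment -> tie expected
            refs[3][1][20:120],        # unique segment -> resolved
            mutate(refs[5][1], 8)[10:140],  # noisy query -> DP path
            "".join(rng.choice(list("ACGT"), 80)),  # random -> likely no_hit
        ]
        for qi, q in enumerate(queries):
            call = call_species(RegionSlice(f"q{qi}", "V3V4", q, (0, len(q))), nr)
            # independent brute-force: plain-python affine SW against all refs
            scored = []
            for sp, ref_seq in refs:
                raw = gotoh_local_score(q, ref_seq)
                bits = bit_score(raw)
                ev = len(q) * db_len * 2.0 ** (-bits)
                scored.append((sp, raw, bits, ev))
            hits = [t for t in scored if t[3] <= 1e-10]
            if not hits:
                assert call.verdict == "no_hit"
                continue
            best_raw = max(t[1] for t in hits)
            top_species = {t[0] for t in hits if t[1] == best_raw}
            if len(top_species) == 1:
                assert call.verdict == "resolved"
                assert call.species in top_species
            else:
                assert call.verdict == "ambiguous"


class TestResolvabilityReport:
    def test_no_confusion_all_regions_resolve(self, scheme):
        refs = generate_reference_set(5, 0, "V3V4", seed=21)
        reads = {
            "S1": [SequenceRecord(n, refs.sequences[n]) for n in refs.species_names]
        }
        report = resolvability_report(reads, _nr(refs), scheme=scheme)
        assert all(v == 1.0 for v in report.values())

    def test_confusable_fraction_arithmetic(self, scheme):
        refs = generate_reference_set(5, 1, "V3V4", seed=22)
        a, b, _ = refs.confusable_pairs[0]
        spec = CommunitySpec(
            [("TC", "TC", "andaman")],
            {"TC": {a: 0.3, b: 0.3, refs.species_names[2]: 0.4}},
            n_reads=400,
            error_rate=0.0,
            seed=33,
        )
        reads, truth = simulate_reads(refs, spec)
        res = demultiplex(reads, scheme, spec.to_manifest())
        report = resolvability_report({"TC": res.assigned["TC"]}, _nr(refs), scheme=scheme)
        # truth-table arithmetic: exactly the confusable reads fail in V3V4
        n_conf = sum(t.species in (a, b) for t in truth)
        expected = 1.0 - n_conf / len(truth)
        assert report[("TC", "V3V4")] == pytest.approx(expected)
        assert report[("TC", "FULL")] == 1.0
        assert report[("TC", "V5V6")] == 1.0

    def test_single_resolved_read(self, small_refs, scheme):
        name = small_refs.species_names[6]
        reads = {"S1": [SequenceRecord("r", small_refs.sequences[name])]}
        report = resolvability_report(reads, _nr(small_refs), regions=("FULL",), scheme=scheme)
        assert report[("S1", "FULL")] == 1.0

    def test_region_monotonicity_per_read(self, scheme):
        refs = generate_reference_set(7, 2, "V5V6", seed=44)
        nr = _nr(refs)
        for name in refs.species_names:
            read = SequenceRecord(name, refs.sequences[name])
            resolved = {}
            for region in ("FULL", "V3V4", "V5V6"):
                call = call_species(extract_region(read, region, scheme), nr)
                resolved[region] = call.verdict == "resolved"
            assert resolved["FULL"] >= resolved["V3V4"]
            assert resolved["FULL"] >= resolved["V5V6"]

    def test_complementary_pattern_two_pair_reference(self, scheme):
        """One V3V4-confusable pair + one V5V6-confusable pair."""
        refs34 = generate_reference_set(9, 1, "V3V4", seed=55)
        a34, b34, _ = refs34.confusable_pairs[0]
        # graft a V5V6-confusable pair into the same reference
        s, e = REGION_LAYOUT["V5V6"]
        seqs = dict(refs34.sequences)
        c, d = refs34.species_names[2], refs34.species_names[3]
        seqs[d] = seqs[d][:s] + seqs[c][s:e] + seqs[d][e:]
        refs34.sequences.update(seqs)
        nr = _nr(refs34)
        calls = {}
        for name in (a34, b34, c, d):
            read = SequenceRecord(name, refs34.sequences[name])
            calls[name] = {
                region: call_species(extract_region(read, region, scheme), nr).verdict
                for region in ("FULL", "V3V4", "V5V6")
            }
        for name in (a34, b34):
            assert calls[name]["V3V4"] == "ambiguous"
            assert calls[name]["V5V6"] == "resolved"
            assert calls[name]["FULL"] == "resolved"
        for name in (c, d):
            assert calls[name]["V3V4"] == "resolved"
            assert calls[name]["V5V6"] == "ambiguous"
            assert calls[name]["FULL"] == "resolved"


class TestNjTree:
    def test_additive_four_taxon_recovery(self):
        # additive matrix with interior branch 4 and leaf branches 2,1,1,2
        D = np.array(
            [[0, 3, 7, 8], [3, 0, 6, 7], [7, 6, 0, 3], [8, 7, 3, 0]], dtype=float
        )
        tree = nj_from_distances(D, ["A", "B", "C", "D"])
        # four-point-condition oracle for the topology
        expected = nj_topology_4taxa(D.tolist())
        splits = tree.splits()
        assert len(splits) == 1
        index = {"A": 0, "B": 1, "C": 2, "D": 3}
        side = frozenset(index[n] for n in next(iter(splits)))
        assert side in expected
        # branch lengths recovered exactly: check leaf-to-leaf path sums
        dist = _tree_distances(tree)
        for i, x in enumerate("ABCD"):
            for j, y in enumerate("ABCD"):
                if i < j:
                    assert dist[(x, y)] == pytest.approx(D[i, j])

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = nj_from_distances(D, ["A", "B", "C"])
        lengths = {child.name: ln for child, ln in tree.children}
        assert lengths["A"] == pytest.approx((4 + 6 - 8) / 2)
        assert lengths["B"] == pytest.approx((4 + 8 - 6) / 2)
        assert lengths["C"] == pytest.approx((6 + 8 - 4) / 2)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            nj_from_distances(np.zeros((2, 2)), ["A", "B"])
        with pytest.raises(ValueError):
            build_nj_tree([SequenceRecord("a", "ACGT"), SequenceRecord("b", "ACGT")])

    def test_bootstrap_deterministic(self, small_refs):
        recs = [
            SequenceRecord(n, small_refs.sequences[n])
            for n in small_refs.species_names[:5]
        ]
        t1 = build_nj_tree(recs, n_bootstrap=40, seed=6)
        t2 = build_nj_tree(recs, n_bootstrap=40, seed=6)
        assert t1.newick() == t2.newick()

    def test_newick_parses_with_dendropy(self, small_refs):
        import dendropy

        recs = [
            SequenceRecord(n, small_refs.sequences[n])
            for n in small_refs.species_names[:4]
        ]
        tree = build_nj_tree(recs, n_bootstrap=10, seed=1)
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert len(parsed.leaf_nodes()) == 4


def _tree_distances(tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths of a TreeNode tree."""
    # walk with explicit path accumulation keyed by ancestor ids
    leaf_depths: dict[str, list[tuple[int, float]]] = {}

    def walk(node, ancestors):
        if not node.children:
            leaf_depths[node.name] = list(ancestors)
            return
        for child, ln in node.children:
            walk(child, [(aid, d + ln) for aid, d in ancestors] + [(id(node), ln)])

    walk(tree, [(id(tree), 0.0)])
    out = {}
    leaves = sorted(leaf_depths)
    for i, x in enumerate(leaves):
        for y in leaves[i + 1 :]:
            ax = dict(leaf_depths[x])
            ay = dict(leaf_depths[y])
            common = set(ax) & set(ay)
            # distance via the deepest common ancestor = min summed depth
            out[(x, y)] = min(ax[a] + ay[a] for a in common)
    return out
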