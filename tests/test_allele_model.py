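"""Rearranged-haplotype algebra: construction, liftover, junctions,
microhomology and unequal crossing over."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from invseek import allele_model as am
from invseek.allele_model import (
    CoordinateError,
    RearrangementAllele,
    ReferenceGenome,
    Segment,
    build_allele,
    extract_junctions,
    microhomology,
    revcomp,
    unequal_crossover,
)
from invseek.architecture import RoseCombArchitecture


class TestBuildAllele:
    def test_inversion_preserves_length(self, full_arch):
        assert len(full_arch.r1()) == full_arch.ref_length

    def test_duplication_allele_length(self, full_arch):
        # wild type plus the 91 kb reverse duplication plus one extra flank copy
        assert len(full_arch.r2()) == full_arch.ref_length + 90_970 + 198

    def test_single_forward_segment_is_identity(self, ref):
        wt = build_allele(len(ref), [Segment(0, len(ref), "+")], "wt")
        assert wt.sequence(ref) == ref.sequence

    def test_inversion_conserves_base_pair_composition(self, toy_arch, ref):
        # reverse complementation swaps A<->T and C<->G, so the conserved
        # quantities are the base-pair (AT / GC) contents
        from collections import Counter

        c1 = Counter(toy_arch.r1().sequence(ref))
        c0 = Counter(ref.sequence)
        assert c1["A"] + c1["T"] == c0["A"] + c0["T"]
        assert c1["G"] + c1["C"] == c0["G"] + c0["C"]

    def test_out_of_bounds_segment_rejected(self):
        allele = RearrangementAllele("bad", (Segment(0, 2000, "+"),))
        with pytest.raises(CoordinateError):
            allele.validate_against(1000)

    def test_reverse_segment_is_reverse_complemented(self, ref):
        a = build_allele(len(ref), [Segment(100, 200, "-")], "rc")
        assert a.sequence(ref) == revcomp(ref.sequence[100:200])

    def test_sequence_matches_segment_map_reconstruction(self, toy_arch, ref):
        for allele in toy_arch.alleles().values():
            seq = allele.sequence(ref)
            rebuilt = []
            for placed in allele.segment_map:
                seg = placed.segment
                sub = ref.sequence[seg.start : seg.end]
                rebuilt.append(sub if seg.orientation == "+" else revcomp(sub))
            assert seq == "".join(rebuilt)


class TestLiftover:
    @pytest.mark.parametrize("allele_name", ["r", "R1", "R2"])
    def test_roundtrip_identity(self, toy_arch, allele_name):
        allele = toy_arch.alleles()[allele_name]
        rng = np.random.default_rng(11)
        for pos in rng.integers(0, len(allele), size=1000):
            ref_pos, orient = allele.to_reference(int(pos))
            hits = allele.from_reference(ref_pos)
            assert (int(pos), orient) in hits

    def test_forward_and_reverse_formulas(self):
        allele = RearrangementAllele(
            "a", (Segment(100, 200, "+"), Segment(300, 400, "-"))
        )
        assert allele.to_reference(10) == (110, "+")
        # position o inside the reversed [300, 400) maps to 300 + (end-1 - o)
        assert allele.to_reference(100) == (399, "-")
        assert allele.to_reference(199) == (300, "-")

    def test_liftover_agrees_with_unique_kmer_search(self, toy_arch, ref):
        allele = toy_arch.r1()
        seq = allele.sequence(ref)
        rng = np.random.default_rng(5)
        k = 31
        for pos in rng.integers(0, len(allele) - k, size=50):
            pos = int(pos)
            placed = allele.owning_segment(pos)
            if pos + k > placed.allele_end:  # kmer crosses a junction
                continue
            kmer = seq[pos : pos + k]
            ref_pos, orient = allele.to_reference(pos)
            if orient == "+":
                assert ref.sequence[ref_pos : ref_pos + k] == kmer
            else:
                assert revcomp(ref.sequence[ref_pos - k + 1 : ref_pos + 1]) == kmer

    def test_position_outside_allele_rejected(self, toy_arch):
        with pytest.raises(CoordinateError):
            toy_arch.r1().to_reference(len(toy_arch.r1()))


class TestJunctions:
    def test_wildtype_has_none(self, full_arch):
        assert extract_junctions(full_arch.wildtype()) == []

    def test_r1_breakpoint_coordinates(self, full_arch):
        j = extract_junctions(full_arch.r1())
        assert len(j) == 2
        proximal, distal = j
        assert proximal.left.ref_pos == 16_499_781
        assert proximal.right.ref_pos == 23_881_384
        assert distal.left.ref_pos == 16_499_781
        assert distal.right.ref_pos == 23_881_384
        assert proximal.left.orientation == "+" and proximal.right.orientation == "-"

    def test_r2_junctions_share_proximal_region(self, full_arch):
        # the duplication allele has two novel adjacencies; both involve the
        # proximal region (16,499,583 / 16,499,781), while the wild-type
        # distal context is retained intact
        j = extract_junctions(full_arch.r2())
        assert len(j) == 2
        assert j[0].left.ref_pos == 16_499_781  # shared with R1
        assert j[1].left.ref_pos == 23_790_414
        assert j[1].right.ref_pos == 16_499_583

    def test_flank_sequences_attached(self, toy_arch, ref):
        j = extract_junctions(toy_arch.r1(), ref, flank=100)
        seq = toy_arch.r1().sequence(ref)
        pos = j[0].allele_position
        assert j[0].left_flank == seq[pos - 100 : pos]
        assert j[0].right_flank == seq[pos : pos + 100]

    def test_small_flank_rejected(self, toy_arch, ref):
        with pytest.raises(ValueError):
            extract_junctions(toy_arch.r1(), ref, flank=10)

    def test_contiguous_segments_yield_no_junction(self):
        a = RearrangementAllele(
            "split", (Segment(0, 500, "+"), Segment(500, 1000, "+"))
        )
        assert extract_junctions(a) == []


def _planted_junction(seed, n_match, mismatch_at=(), w=50):
    """Junction strings with a planted right-extension overlap."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def rand(n):
        return "".join(rng.choice(bases, size=n))

    j_left = rand(w)
    j_right = rand(w)
    side_a = list(rand(w))
    other = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for i in range(n_match):
        side_a[i] = other[j_right[i]] if i in mismatch_at else j_right[i]
    side_a[n_match] = other[j_right[n_match]]
    if n_match + 1 < w:  # block chance run-through past the planted overlap
        side_a[n_match + 1] = other[j_right[n_match + 1]]
    side_b = list(rand(w))
    side_b[-1] = other[j_left[-1]]  # no left extension
    side_b[-2] = other[j_left[-2]]
    return "".join(side_a), "".join(side_b), j_left + j_right


class TestMicrohomology:
    def test_seven_bp_overlap_with_one_mismatch(self):
        a, b, j = _planted_junction(seed=3, n_match=7, mismatch_at={3})
        rep = microhomology(a, b, j, max_mismatch=1)
        assert (rep.overlap_len, rep.mismatches) == (7, 1)

    def test_two_bp_exact_overlap(self):
        a, b, j = _planted_junction(seed=4, n_match=2)
        rep = microhomology(a, b, j, max_mismatch=0)
        assert (rep.overlap_len, rep.mismatches) == (2, 0)
        assert rep.ambiguity_interval == (0, 2)

    def test_single_bp_overlap(self):
        a, b, j = _planted_junction(seed=5, n_match=1)
        rep = microhomology(a, b, j, max_mismatch=0)
        assert (rep.overlap_len, rep.mismatches) == (1, 0)

    def test_no_shared_bases(self):
        a, b, j = _planted_junction(seed=6, n_match=0)
        rep = microhomology(a, b, j, max_mismatch=0)
        assert (rep.overlap_len, rep.mismatches) == (0, 0)

    def test_short_flanks_rejected(self):
        with pytest.raises(ValueError):
            microhomology("ACGT", "ACGT", "ACGTACGT", scan_window=50)

    @staticmethod
    def _brute_force(side_a, side_b, junction_seq, max_mm, w):
        mid = len(junction_seq) // 2
        j_left, j_right = junction_seq[:mid], junction_seq[mid:]
        best = 0
        for l in range(w + 1):
            mm_l = sum(
                x != y for x, y in zip(j_left[mid - l :], side_b[len(side_b) - l :])
            )
            if mm_l > max_mm:
                continue
            for r in range(w + 1):
                mm_r = sum(x != y for x, y in zip(j_right[:r], side_a[:r]))
                if mm_l + mm_r <= max_mm:
                    best = max(best, l + r)
        return best

    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    def test_agrees_with_brute_force_scan(self, max_mm):
        rng = np.random.default_rng(42 + max_mm)
        bases = np.array(list("ACGT"))
        w = 20
        for _ in range(200):
            a = "".join(rng.choice(bases, size=w))
            b = "".join(rng.choice(bases, size=w))
            j = "".join(rng.choice(bases, size=2 * w))
            rep = microhomology(a, b, j, max_mismatch=max_mm, scan_window=w)
            assert rep.overlap_len == self._brute_force(a, b, j, max_mm, w)
            assert rep.mismatches <= max_mm


class TestUnequalCrossover:
    def test_reproduces_r2_segment_map_at_printed_coordinates(self, full_arch):
        recombinant = unequal_crossover(
            full_arch.r1(),
            full_arch.wildtype(),
            pos_a=full_arch.proximal + 90_970,
            pos_b=16_499_583,
        )
        assert recombinant.segments == full_arch.r2().segments

    def test_reproduces_r2_sequence_at_toy_scale(self, toy_arch, ref):
        recombinant = toy_arch.r2_by_crossover()
        assert recombinant.sequence(ref) == toy_arch.r2().sequence(ref)

    def test_self_crossover_is_identity(self, toy_arch):
        r1 = toy_arch.r1()
        out = unequal_crossover(r1, r1, 1000, 1000)
        assert out.segments == r1.normalized().segments

    @given(
        pos_a=st.integers(min_value=0, max_value=3000),
        pos_b=st.integers(min_value=0, max_value=3000),
    )
    def test_length_conservation(self, pos_a, pos_b):
        a = RearrangementAllele("a", (Segment(0, 1500, "+"), Segment(1500, 3000, "-")))
        b = RearrangementAllele("b", (Segment(0, 3000, "+"),))
        out = unequal_crossover(a, b, pos_a, pos_b)
        assert len(out) == pos_a + (len(b) - pos_b)

    def test_out_of_range_position_rejected(self, toy_arch):
        with pytest.raises(CoordinateError):
            unequal_crossover(toy_arch.r1(), toy_arch.wildtype(), -1, 0)


class TestIO:
    def test_fasta_roundtrip(self, ref, tmp_path):
        path = tmp_path / "ref.fa"
        ref.to_fasta(path)
        back = ReferenceGenome.from_fasta(path)
        assert back.name == ref.name and back.sequence == ref.sequence

    def test_yaml_spec_roundtrip(self, toy_arch, tmp_path):
        path = tmp_path / "r2.yaml"
        toy_arch.r2().to_yaml(path)
        back = RearrangementAllele.from_yaml(path)
        assert back.segments == toy_arch.r2().segments
        assert back.name == "R2"

    def test_bed_export_has_strand_column(self, toy_arch, tmp_path):
        path = tmp_path / "r1.bed"
        toy_arch.r1().to_bed(path, "chr7T")
        lines = [l.split("\t") for l in path.read_text().splitlines()]
        assert len(lines) == 3
        assert [l[5] for l in lines] == ["+", "-", "+"]
        assert int(lines[1][1]) == toy_arch.proximal


def test_reference_alphabet_enforced():
    with pytest.raises(ValueError):
        ReferenceGenome("bad", "ACGTX")
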