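"""Exon correspondence, splicing-ortholog criteria, cause classification."""

from __future__ import annotations

import random

import numpy as np
import pytest

from conftest import make_protein, random_seq
from orthoqa.align import PairwiseAlignment, ProteinCluster, pairwise_align
from orthoqa.splice import (
    build_exon_correspondence,
    classify_nonconservation,
    conservation_profile,
    core_protein_sets,
    count_reference_support,
    splice_profile_pair,
)


def nt_oracle(aln: PairwiseAlignment, p, q) -> np.ndarray:
    """Brute-force per-nucleotide mapping: expand every aligned residue
    pair to its three nucleotide pairs, apply the terminal gap-free
    extension one nucleotide at a time, and label each nucleotide with its
    exon (positions after an exon inherit the previous exon's label)."""
    p_map = p.comparison_exon_map()
    q_map = q.comparison_exon_map()

    def exon_of(pos, emap):
        if not emap or pos < emap[0][0]:
            return None
        label = None
        for i, (s, e) in enumerate(emap):
            if pos >= s:
                label = i
            if pos < e:
                break
        return label

    pairs = []
    for (qs, qe), (ss, se) in aln.blocks:
        for i, j in zip(range(qs, qe), range(ss, se)):
            for k in range(3):
                pairs.append((3 * i + k, 3 * j + k))
    if pairs:
        a0, b0 = pairs[0]
        ia, ib = exon_of(a0, p_map), exon_of(b0, q_map)
        if ia is not None and ib is not None:
            sa, sb = p_map[ia][0], q_map[ib][0]
            a, b = a0 - 1, b0 - 1
            ext = []
            while a >= sa and b >= sb:
                ext.append((a, b))
                a -= 1
                b -= 1
            pairs = ext[::-1] + pairs
        a1, b1 = pairs[-1]
        ia, ib = exon_of(a1, p_map), exon_of(b1, q_map)
        if ia is not None and ib is not None:
            ea, eb = p_map[ia][1], q_map[ib][1]
            a, b = a1 + 1, b1 + 1
            while a < ea and b < eb:
                pairs.append((a, b))
                a += 1
                b += 1
    matrix = np.zeros((len(p_map), len(q_map)), dtype=np.int64)
    for a, b in pairs:
        i, j = exon_of(a, p_map), exon_of(b, q_map)
        if i is not None and j is not None:
            matrix[i, j] += 1
    return matrix


def random_fixture(rng: random.Random):
    """A random protein pair with random exon maps and a random monotone
    block alignment over their residues."""
    def rand_exons(total_nt, max_exons=10):
        n = rng.randint(1, max_exons)
        cuts = sorted(rng.sample(range(1, total_nt), min(n - 1, total_nt - 1)))
        lens = [b - a for a, b in zip([0] + cuts, cuts + [total_nt])]
        return [ln for ln in lens if ln > 0]

    la, lb = rng.randint(10, 80), rng.randint(10, 80)
    p = make_protein(random_seq(rng, la), rand_exons(3 * la), pid="P", gene="gp")
    q = make_protein(random_seq(rng, lb), rand_exons(3 * lb), pid="Q", gene="gq")
    blocks = []
    i = j = 0
    while i < la and j < lb and len(blocks) < 5:
        i += rng.randint(0, 5)
        j += rng.randint(0, 5)
        if i >= la or j >= lb:
            break
        ln = rng.randint(1, min(la - i, lb - j))
        blocks.append(((i, i + ln), (j, j + ln)))
        i += ln
        j += ln
    aln = PairwiseAlignment("P", "Q", tuple(blocks), 1.0, 1.0)
    return aln, p, q


class TestExonCorrespondence:
    def test_identical_structures_diagonal(self):
        seq = random_seq(random.Random(0), 100)
        p = make_protein(seq, [115, 185], pid="P", gene="gp")
        q = make_protein(seq, [115, 185], pid="Q", gene="gq")
        corr = build_exon_correspondence(pairwise_align(p, q), p, q)
        assert corr.overlap.tolist() == [[115, 0], [0, 185]]
        assert corr.junction_offsets_p == [0]
        prof = conservation_profile(corr)
        assert prof.all_exons_aligned and prof.one_to_one
        assert prof.all_90pct_overlap and prof.all_len_within_15
        assert prof.junctions_aligned is True

    def test_terminal_extension_recovers_first_exon(self):
        seq = random_seq(random.Random(1), 100)
        p = make_protein(seq, [115, 185], pid="P", gene="gp")
        q = make_protein(seq, [115, 185], pid="Q", gene="gq")
        # alignment that only covers residues 10..100: the leading 30 nt
        # must be recovered by the gap-free terminal extension
        aln = PairwiseAlignment("P", "Q", (((10, 100), (10, 100)),), 1.0, 1.0)
        corr = build_exon_correspondence(aln, p, q)
        assert corr.overlap[0, 0] == 115

    def test_split_exon_half_and_half(self):
        seq = random_seq(random.Random(2), 50)
        p = make_protein(seq, [150], pid="P", gene="gp")
        q = make_protein(seq, [75, 75], pid="Q", gene="gq")
        corr = build_exon_correspondence(pairwise_align(p, q), p, q)
        assert corr.overlap.tolist() == [[75, 75]]
        prof = conservation_profile(corr)
        assert not prof.all_90pct_overlap
        assert classify_nonconservation(corr, prof).category == "split_merge"

    def test_empty_alignment_zero_overlap(self):
        p = make_protein("WWWW", [12], pid="P", gene="gp")
        q = make_protein("PPPP", [12], pid="Q", gene="gq")
        corr = build_exon_correspondence(pairwise_align(p, q), p, q)
        assert corr.overlap.sum() == 0

    @pytest.mark.parametrize("seed", range(40))
    def test_matrix_matches_per_nucleotide_oracle(self, seed):
        rng = random.Random(seed)
        aln, p, q = random_fixture(rng)
        corr = build_exon_correspondence(aln, p, q)
        assert corr.overlap.tolist() == nt_oracle(aln, p, q).tolist()


def spliced_pair(exons_p, exons_q, insert_at, n_insert):
    """Base protein plus a version with ``n_insert`` residues inserted at
    ``insert_at``, with independently chosen exon structures."""
    rng = random.Random(17)
    base = random_seq(rng, sum(exons_p) // 3)
    other = base[:insert_at] + "W" * n_insert + base[insert_at:]
    p = make_protein(base, exons_p, pid="P", gene="gp")
    q = make_protein(other, exons_q, pid="Q", gene="gq")
    return p, q


class TestNinetyPercentRule:
    def test_length_variant_exon_115_vs_133_not_conserved(self):
        # one internal exon pair fully aligned at 115 vs 133 nt:
        # 115 < 0.9 * 133, so the pair is not splicing-orthologous
        p, q = spliced_pair([90, 115, 95], [90, 133, 95], insert_at=40, n_insert=6)
        corr, prof = splice_profile_pair(p, q, pairwise_align)
        assert corr.overlap[1, 1] == 115
        assert not prof.all_90pct_overlap
        assert classify_nonconservation(corr, prof).category == "one_to_one_length_vary"

    def test_length_variant_exon_120_vs_133_conserved(self):
        p, q = spliced_pair([90, 120, 90], [90, 133, 95], insert_at=70, n_insert=6)
        corr, prof = splice_profile_pair(p, q, pairwise_align)
        assert corr.overlap[1, 1] == 120
        assert prof.all_90pct_overlap

    def test_overlap_boundary_is_inclusive(self):
        # exon pair 90 vs 100 nt with 90 aligned nt: 90 >= 0.9*100 exactly,
        # so the pair is conserved (the threshold comparison uses >=)
        p = make_protein(random_seq(random.Random(3), 100), [120, 90, 90], pid="P", gene="gp")
        q = make_protein(p.sequence[:70] + "WWW" + p.sequence[70:], [120, 100, 89],
                         pid="Q", gene="gq")
        aln = PairwiseAlignment("P", "Q", (((0, 70), (0, 70)), ((70, 100), (73, 103))), 1.0, 1.0)
        corr = build_exon_correspondence(aln, p, q)
        assert corr.overlap[1, 1] == 90
        assert conservation_profile(corr).all_90pct_overlap

    def test_non_transitive_chain(self):
        # single-exon CDS of ~1000/900/810 nt (999 for divisibility):
        # A-B and B-C conserved, A-C not
        rng = random.Random(9)
        a_seq = random_seq(rng, 333)
        A = make_protein(a_seq, [999], pid="A", gene="ga", species=1)
        B = make_protein(a_seq[:300], [900], pid="B", gene="gb", species=2)
        C = make_protein(a_seq[:270], [810], pid="C", gene="gc", species=3)

        def conserved(x, y):
            _, prof = splice_profile_pair(x, y, pairwise_align)
            return prof.all_90pct_overlap

        assert conserved(A, B)
        assert conserved(B, C)
        assert not conserved(A, C)

    def test_single_exon_junctions_undefined(self):
        p = make_protein("MAAAAAAAAA", [30], pid="P", gene="gp")
        q = make_protein("MAAAAAAAAA", [30], pid="Q", gene="gq")
        _, prof = splice_profile_pair(p, q, pairwise_align)
        assert prof.junctions_aligned is None
        assert prof.all_90pct_overlap


class TestClassification:
    def test_exon_loss_internal(self):
        rng = random.Random(4)
        base = random_seq(rng, 120)
        # q lacks residues 40..80 (one whole 120-nt exon)
        p = make_protein(base, [120, 120, 120], pid="P", gene="gp")
        q = make_protein(base[:40] + base[80:], [120, 120], pid="Q", gene="gq")
        corr, prof = splice_profile_pair(p, q, pairwise_align)
        assert not prof.all_90pct_overlap
        assert classify_nonconservation(corr, prof).category == "exon_loss"

    def test_truncation_outside_alignment(self):
        # first coding exon entirely outside the local alignment
        rng = random.Random(5)
        base = random_seq(rng, 120)
        p = make_protein(base, [120, 120, 120], pid="P", gene="gp")
        q = make_protein("W" * 40 + base[40:], [120, 120, 120], pid="Q", gene="gq")
        aln = pairwise_align(p, q)
        corr = build_exon_correspondence(aln, p, q)
        prof = conservation_profile(corr)
        assert not prof.all_90pct_overlap
        assert classify_nonconservation(corr, prof).category in ("not_all_aligned", "exon_loss")

    def test_conserved_pair_raises(self):
        p = make_protein("MAAAAAAAAA", [30], pid="P", gene="gp")
        corr, prof = splice_profile_pair(p, make_protein("MAAAAAAAAA", [30], pid="Q", gene="gq"),
                                         pairwise_align)
        with pytest.raises(ValueError):
            classify_nonconservation(corr, prof)


class TestProperties:
    @pytest.mark.parametrize("seed", range(15))
    def test_profile_symmetry(self, seed):
        rng = random.Random(seed)
        _, p, q = random_fixture(rng)
        _, prof_pq = splice_profile_pair(p, q, pairwise_align)
        _, prof_qp = splice_profile_pair(q, p, pairwise_align)
        assert prof_pq == prof_qp

    @pytest.mark.parametrize("seed", range(15))
    def test_threshold_monotonicity(self, seed):
        rng = random.Random(seed + 100)
        aln, p, q = random_fixture(rng)
        corr = build_exon_correspondence(aln, p, q)
        at_09 = conservation_profile(corr, overlap_threshold=0.9).all_90pct_overlap
        at_10 = conservation_profile(corr, overlap_threshold=1.0).all_90pct_overlap
        assert not (at_10 and not at_09)

    def test_implication_chain(self):
        for seed in range(20):
            rng = random.Random(seed + 500)
            aln, p, q = random_fixture(rng)
            prof = conservation_profile(build_exon_correspondence(aln, p, q))
            if prof.all_90pct_overlap:
                assert prof.one_to_one
            if prof.one_to_one:
                assert prof.all_exons_aligned


class TestReferenceSupport:
    def make_chain_cluster(self):
        rng = random.Random(9)
        a_seq = random_seq(rng, 333)
        A = make_protein(a_seq, [999], pid="A", gene="ga", species=1)
        B = make_protein(a_seq[:300], [900], pid="B", gene="gb", species=2)
        C = make_protein(a_seq[:270], [810], pid="C", gene="gc", species=3)
        cluster = ProteinCluster("s", [A, B, C], r=3)
        conserved = {}
        for x, y in ((A, B), (B, C), (A, C)):
            _, prof = splice_profile_pair(x, y, pairwise_align)
            conserved[frozenset((x.protein_id, y.protein_id))] = prof.all_90pct_overlap
        return cluster, conserved, (A, B, C)

    def test_support_is_pairwise_not_transitive(self):
        cluster, conserved, (A, B, C) = self.make_chain_cluster()
        refs = {1, 2, 3}
        sa, _ = count_reference_support(A, cluster, conserved, refs)
        sb, _ = count_reference_support(B, cluster, conserved, refs)
        sc, _ = count_reference_support(C, cluster, conserved, refs)
        assert (sa, sb, sc) == (1, 2, 1)

    def test_level_flags(self):
        cluster, conserved, (A, B, C) = self.make_chain_cluster()
        _, levels = count_reference_support(B, cluster, conserved, {1, 2, 3}, thresholds=(1, 2, 3))
        assert levels == {1: True, 2: True, 3: False}

    def test_no_reference_counterparts(self):
        p = make_protein("MAAA", pid="P", gene="gp", species=1)
        cluster = ProteinCluster("s", [p], r=0)
        s, _ = count_reference_support(p, cluster, {}, {2, 3})
        assert s == 0


class TestCoreSets:
    def test_boundary_min_organisms(self):
        support = {
            "set17": {t: 3 for t in range(17)},
            "set16": {t: 3 for t in range(16)},
        }
        core, counts = core_protein_sets(support, min_organisms=17, min_ref_support=3)
        assert core == ["set17"]
        assert all(counts[t] == 1 for t in range(17))

    def test_damaged_members_not_counted(self):
        support = {"s": {**{t: 3 for t in range(15)}, **{t: 0 for t in range(15, 20)}}}
        core, counts = core_protein_sets(support, min_organisms=15, min_ref_support=3)
        assert core == ["s"]
        assert 15 not in counts and counts[0] == 1
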