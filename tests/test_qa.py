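"""Domain, length, N-terminus and start-Met screens."""

from __future__ import annotations

import math
import random

import pytest

from conftest import make_protein, random_seq
from orthoqa.align import MSA, ProteinCluster, progressive_msa
from orthoqa.model import DomainHit
from orthoqa.qa import (
    ReferenceDistribution,
    domain_anomalies,
    domain_z_outliers,
    downstream_met_flags,
    jaccard_domain_score,
    label_regions,
    length_outliers,
    nterm_identity_outliers,
    screen_cluster,
    select_domain_representative,
)

REFS = set(range(1, 13))


def dom(sf, start=0, end=50, plen=50, frac=1.0):
    return DomainHit(sf, (start, end), plen, frac)


def prot_with_domains(pid, sfs, species=1, gene=None, seq=None, frac=1.0):
    return make_protein(
        seq or ("M" + "A" * 99),
        pid=pid,
        gene=gene or f"g{pid}",
        species=species,
        domains=[dom(sf, 10 * i, 10 * i + 30, 30, frac) for i, sf in enumerate(sfs)],
    )


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"A", "B", "C"}, {"A", "B", "C"}, 1.0),
            ({"A", "B"}, {"C", "D"}, 0.0),
            ({"A", "B"}, {"B", "C"}, 1 / 3),
        ],
    )
    def test_set_cardinality(self, a, b, expected):
        p = prot_with_domains("P", a)
        q = prot_with_domains("Q", b)
        assert jaccard_domain_score(p, q) == pytest.approx(expected)

    def test_both_empty_undefined(self):
        p = prot_with_domains("P", [])
        q = prot_with_domains("Q", [])
        assert jaccard_domain_score(p, q) is None

    def test_signal_peptide_is_pseudo_domain(self):
        p = make_protein("M" + "A" * 9, pid="P", signal=True)
        q = make_protein("M" + "A" * 9, pid="Q", gene="gq", signal=True)
        assert jaccard_domain_score(p, q) == 1.0
        assert jaccard_domain_score(p, q, include_signal=False) is None

    def test_symmetry_and_metric_spot_check(self):
        rng = random.Random(0)
        universe = list("ABCDEFGH")
        for _ in range(50):
            sets = [set(rng.sample(universe, rng.randint(1, 5))) for _ in range(3)]
            ps = [prot_with_domains(f"P{i}", s) for i, s in enumerate(sets)]
            j01 = jaccard_domain_score(ps[0], ps[1])
            assert j01 == jaccard_domain_score(ps[1], ps[0])
            d = lambda x, y: 1 - jaccard_domain_score(x, y)
            assert d(ps[0], ps[2]) <= d(ps[0], ps[1]) + d(ps[1], ps[2]) + 1e-12


class TestReferenceDistribution:
    def test_zero_sd_sentinel(self):
        dist = ReferenceDistribution.from_values("x", [1.0, 1.0, 1.0])
        assert dist.z(1.0) == 0.0
        assert math.isinf(dist.z(0.9))


def cluster_of(proteins, r=None):
    refs = {p.species for p in proteins if p.species in REFS}
    return ProteinCluster("s", list(proteins), r=len(refs) if r is None else r)


class TestDomainScreens:
    def test_uniform_domains_no_outliers(self):
        ps = [prot_with_domains(f"P{i}", {"A", "B"}, species=i) for i in range(1, 7)]
        flags = domain_z_outliers(cluster_of(ps), REFS)
        assert not any(flags.values())

    def test_divergent_protein_flagged_and_boundary_strict(self):
        ps = [prot_with_domains(f"P{i}", {"A"}, species=i) for i in range(1, 6)]
        bad = prot_with_domains("BAD", {"Z"}, species=13)
        flags = domain_z_outliers(cluster_of(ps + [bad]), REFS)
        assert flags["BAD"] and not flags["P1"]

    def test_missing_and_extra(self):
        refs = [prot_with_domains(f"P{i}", {"A", "B"}, species=i) for i in range(1, 6)]
        q_missing = prot_with_domains("QM", {"A"}, species=13)
        q_extra = prot_with_domains("QE", {"A", "B", "C"}, species=14)
        out = domain_anomalies(cluster_of(refs + [q_missing, q_extra]), REFS)
        assert out["QM"]["missing"] and not out["QM"]["extra"]
        assert out["QE"]["extra"] and not out["QE"]["missing"]
        assert not out["P1"]["missing"] and not out["P1"]["extra"]

    def test_truncated_arithmetic(self):
        # query fraction 0.5 < 0.6 and < 0.6 * 0.9 of every other member
        refs = [prot_with_domains(f"P{i}", {"A"}, species=i, frac=0.9) for i in range(1, 6)]
        q = prot_with_domains("Q", {"A"}, species=13, frac=0.5)
        out = domain_anomalies(cluster_of(refs + [q]), REFS)
        assert out["Q"]["truncated"]
        # 0.58 < 0.6 but not < 0.6 * 0.9 = 0.54: not truncated
        q2 = prot_with_domains("Q", {"A"}, species=13, frac=0.58)
        out2 = domain_anomalies(cluster_of(refs + [q2]), REFS)
        assert not out2["Q"]["truncated"]

    def test_small_r_produces_no_flags(self):
        ps = [prot_with_domains(f"P{i}", {"A"}, species=i) for i in range(1, 4)]
        assert domain_z_outliers(cluster_of(ps), REFS) == {}
        assert domain_anomalies(cluster_of(ps), REFS) == {}


class TestRepresentative:
    def test_max_mean_jaccard_then_length(self):
        refs = [prot_with_domains(f"R{i}", {"A", "B"}, species=i) for i in range(1, 6)]
        iso_a = prot_with_domains("A1", {"A", "B"}, species=13, gene="g13")
        iso_b = prot_with_domains("B1", {"A"}, species=13, gene="g13")
        cl = cluster_of(refs + [iso_a])
        rep = select_domain_representative([iso_a, iso_b], [cl], REFS)
        assert rep.protein_id == "A1"

    def test_tie_goes_to_longest(self):
        a = make_protein("M" + "A" * 399, pid="L1", gene="g", species=13)
        b = make_protein("M" + "A" * 349, pid="L2", gene="g", species=13)
        rep = select_domain_representative([a, b], [], REFS)
        assert rep.protein_id == "L1"


class TestRegions:
    def test_gap_free_is_single_conserved(self):
        msa = MSA(["a", "b"], ["MAAA", "MAAA"])
        part = label_regions(msa, ["a", "b"])
        assert part.blocks == [("conserved", 0, 4)]

    def test_leading_gaps_become_nterminal(self):
        rows = ["-" * 20 + "A" * 40 for _ in range(4)] + ["B" * 60]
        msa = MSA([f"r{i}" for i in range(5)], rows)
        part = label_regions(msa, [f"r{i}" for i in range(5)])
        assert part.blocks[0] == ("N-terminal", 0, 20)
        assert part.blocks[1] == ("conserved", 20, 60)

    def test_internal_gappy_block_is_intermediate(self):
        rows = []
        for i in range(5):
            mid = "-" * 30 if i < 2 else "C" * 30  # 40% gaps
            rows.append("A" * 20 + mid + "B" * 20)
        msa = MSA([f"r{i}" for i in range(5)], rows)
        part = label_regions(msa, [f"r{i}" for i in range(5)])
        assert ("intermediate", 20, 50) in part.blocks

    def test_no_conserved_column_all_nterminal(self):
        rows = ["A---", "-A--", "--A-", "---A", "A---"]
        msa = MSA([f"r{i}" for i in range(5)], rows)
        part = label_regions(msa, [f"r{i}" for i in range(5)])
        assert part.blocks == [("N-terminal", 0, 4)]


def make_msa_cluster(sequences: dict[str, str], species: dict[str, int]):
    ps = [
        make_protein(seq, pid=pid, gene=f"g{pid}", species=species[pid])
        for pid, seq in sequences.items()
    ]
    cl = cluster_of(ps)
    return cl, progressive_msa(ps)


class TestLengthOutliers:
    def test_equal_lengths_no_flags(self):
        base = random_seq(random.Random(0), 120)
        seqs = {f"P{i}": base for i in range(1, 7)}
        cl, msa = make_msa_cluster(seqs, {f"P{i}": i for i in range(1, 7)})
        part = label_regions(msa, [p.protein_id for p in cl.members])
        out = length_outliers(cl, msa, part, REFS)
        assert not any(flag for flag, _ in out.values())

    def test_nterm_truncation_flagged(self):
        base = "M" + random_seq(random.Random(1), 119)
        seqs = {f"P{i}": base for i in range(1, 7)}
        seqs["BAD"] = base[30:]
        species = {**{f"P{i}": i for i in range(1, 7)}, "BAD": 13}
        cl, msa = make_msa_cluster(seqs, species)
        part = label_regions(
            msa, [p.protein_id for p in cl.members if p.species in REFS]
        )
        out = length_outliers(cl, msa, part, REFS)
        assert out["BAD"][0]
        assert not out["P1"][0]

    def test_nterm_extension_flagged_via_window(self):
        base = "M" + random_seq(random.Random(2), 119)
        seqs = {f"P{i}": base for i in range(1, 7)}
        seqs["BAD"] = "M" + "W" * 40 + base[1:]
        species = {**{f"P{i}": i for i in range(1, 7)}, "BAD": 13}
        cl, msa = make_msa_cluster(seqs, species)
        part = label_regions(
            msa, [p.protein_id for p in cl.members if p.species in REFS]
        )
        out = length_outliers(cl, msa, part, REFS)
        assert out["BAD"][0]


class TestNtermIdentity:
    def test_scrambled_nterminus_flagged(self):
        rng = random.Random(3)
        base = "M" + random_seq(rng, 149)
        seqs = {f"P{i}": base for i in range(1, 7)}
        # divergent first 30 residues, conserved remainder
        seqs["BAD"] = "M" + "".join(
            "W" if c != "W" else "Y" for c in base[1:30]
        ) + base[30:]
        species = {**{f"P{i}": i for i in range(1, 7)}, "BAD": 13}
        cl, msa = make_msa_cluster(seqs, species)
        out = nterm_identity_outliers(cl, msa, REFS)
        assert out["BAD"]
        assert not out["P1"]

    def test_globally_divergent_not_flagged(self):
        # uniformly low identity: the log-ratio Z stays near the reference
        # mean, so the screen does not fire (it targets N-terminal-specific
        # divergence).  References carry a little natural spread.
        rng = random.Random(4)
        base = "M" + random_seq(rng, 149)
        # every second residue substituted: ~50% identity uniformly
        div = "".join(
            c if i % 2 == 0 else ("W" if c != "W" else "Y") for i, c in enumerate(base)
        )
        seqs = {}
        for i in range(1, 7):
            seq = list(base)
            for k in rng.sample(range(1, 150), 20):
                seq[k] = rng.choice("ACDEFGHIKLMNPQRSTVWY")
            seqs[f"P{i}"] = "".join(seq)
        seqs["DIV"] = div
        species = {**{f"P{i}": i for i in range(1, 7)}, "DIV": 13}
        cl, msa = make_msa_cluster(seqs, species)
        out = nterm_identity_outliers(cl, msa, REFS)
        assert not out["DIV"]


class TestDownstreamMet:
    def build(self, n_bad_refs):
        rng = random.Random(5)
        tail = random_seq(rng, 80)
        long = "M" + random_seq(rng, 19) + "M" + tail  # Met at residue 20
        short = "M" + tail  # starts at the downstream Met
        seqs = {}
        species = {}
        for i in range(1, 6):
            seqs[f"P{i}"] = short if i <= n_bad_refs else long
            species[f"P{i}"] = i
        seqs["Q"] = short
        species["Q"] = 13
        return make_msa_cluster(seqs, species)

    def test_majority_conserved_downstream_flagged(self):
        cl, msa = self.build(n_bad_refs=0)
        out = downstream_met_flags(cl, msa, REFS)
        # r=5: Q's initial Met aligns to internal Met in 5 refs > (5-1)/2
        assert out["Q"]

    def test_all_initial_mets_aligned_no_flags(self):
        rng = random.Random(6)
        base = "M" + random_seq(rng, 99)
        seqs = {f"P{i}": base for i in range(1, 6)}
        seqs["Q"] = base
        species = {**{f"P{i}": i for i in range(1, 6)}, "Q": 13}
        cl, msa = make_msa_cluster(seqs, species)
        assert not any(downstream_met_flags(cl, msa, REFS).values())

    def test_boundary_strictly_greater(self):
        # exactly 2 of 5 references differ: 2 == (5-1)/2, not flagged
        cl, msa = self.build(n_bad_refs=3)
        # Q (short) vs refs: P1..P3 short (agree), P4..P5 long (differ) -> 2
        out = downstream_met_flags(cl, msa, REFS)
        assert not out["Q"]


class TestScreenCluster:
    def test_small_r_no_flags_but_cluster_membership_tracked(self):
        ps = [prot_with_domains(f"P{i}", {"A"}, species=i) for i in range(1, 4)]
        flags = screen_cluster(cluster_of(ps), REFS)
        assert all(not f.any_flag() for f in flags.values())
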