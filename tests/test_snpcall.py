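"""SNP determination steps: filters, disjoint selection, allele calling."""

import numpy as np
import pytest

from snpdiscover.assembly import MicroAssembly
from snpdiscover.clusters import Cluster, ClusterStore, RepeatThresholds
from snpdiscover.records import Alignment, Read
from snpdiscover.snpcall import (
    SNPCall,
    call_alleles,
    filter_clusters,
    final_filters,
    select_disjoint,
)


def _read(bases, id):
    return Read(id=id, bases=bases, quals=np.full(len(bases), 40))


def _aln(seed, member, diffs, span=(0, 200)):
    return Alignment(id_a=seed, id_b=member, strand="+",
                     a_start=span[0], a_end=span[1],
                     b_start=span[0], b_end=span[1],
                     differences=[(p, a, b, p) for p, a, b in diffs],
                     identity=0.99, aligned_cols=span[1] - span[0])


def _store_with(clusters, genome_length=100_000, reads=()):
    store = ClusterStore(RepeatThresholds(expected_genome_length=genome_length))
    for r in reads:
        store.read_individual[r.id] = r.individual_id
    for c in clusters:
        store.clusters[c.seed_id] = c
    return store


def _cluster(seed, member_diffs):
    """member_diffs: list of per-member difference lists."""
    cl = Cluster(seed_id=seed)
    for i, diffs in enumerate(member_diffs):
        cl.members.append((f"{seed}_m{i}", _aln(seed, f"{seed}_m{i}", diffs)))
    cl.recount()
    return cl


class TestFilterClusters:
    def test_two_per_allele_cluster_kept(self):
        # 2 members differ at 100 (alt C x2), 2 members span it silently:
        # seed allele support = seed + 2 = 3, alt = 2
        cl = _cluster("s", [[(100, "A", "C")], [(100, "A", "C")], [], []])
        assert filter_clusters(_store_with([cl])) == [cl]

    def test_candidate_repeat_ignored(self):
        cl = _cluster("s", [[(100, "A", "C")], [(100, "A", "C")], [], []])
        cl.candidate_repeat = True
        assert filter_clusters(_store_with([cl])) == []

    def test_two_qualifying_positions_within_50bp_dropped(self):
        cl = _cluster("s", [
            [(100, "A", "C"), (130, "G", "T")],
            [(100, "A", "C"), (130, "G", "T")],
            [], [],
        ])
        assert filter_clusters(_store_with([cl])) == []

    def test_more_than_three_substitutions_dropped(self):
        cl = _cluster("s", [
            [(10, "A", "C"), (70, "G", "T"), (130, "A", "G"), (190, "C", "T")],
            [(10, "A", "C")],
            [], [],
        ])
        assert filter_clusters(_store_with([cl])) == []

    def test_multi_individual_requirement(self):
        reads = [Read(id=f"s_m{i}", bases="A" * 10, quals=np.full(10, 40),
                      individual_id="indA") for i in range(4)]
        seed = Read(id="s", bases="A" * 10, quals=np.full(10, 40),
                    individual_id="indA")
        cl = _cluster("s", [[(100, "A", "C")], [(100, "A", "C")], [], []])
        store = _store_with([cl], reads=[seed] + reads)
        assert filter_clusters(store, multi_individual=True) == []
        # move two members to a second individual
        store.read_individual["s_m0"] = "indB"
        store.read_individual["s_m1"] = "indB"
        assert filter_clusters(store, multi_individual=True) == [cl]


class TestSelectDisjoint:
    def _cl(self, seed, members):
        cl = Cluster(seed_id=seed)
        cl.members = [(m, None) for m in members]
        return cl

    def test_shared_member_first_wins(self):
        a = self._cl("a", ["x", "y"])
        b = self._cl("b", ["y", "z"])
        assert select_disjoint([a, b]) == [a]

    def test_disjoint_all_selected(self):
        a = self._cl("a", ["x"])
        b = self._cl("b", ["y"])
        assert select_disjoint([a, b]) == [a, b]

    def test_chain_greedy(self):
        a = self._cl("a", ["x"])
        b = self._cl("b", ["x", "y"])
        c = self._cl("c", ["y"])
        assert select_disjoint([a, b, c]) == [a, c]


def _asm(columns, contig=None):
    if contig is None:
        contig = "".join(max(set(b for b, _, _ in col), key=lambda b: sum(
            q for bb, q, _ in col if bb == b)) if col else "N" for col in columns)
    return MicroAssembly(contig=contig, placements=[], column_support=columns)


class TestCallAlleles:
    def test_biallelic_column(self):
        cols = [[("A", 40, f"r{i}") for i in range(3)] + [("G", 40, "r3"), ("G", 40, "r4")]]
        (cand,) = call_alleles(_asm(cols, contig="A"))
        assert cand[:5] == (0, "A", "G", 3, 2)

    def test_low_quality_support_not_counted(self):
        cols = [[("A", 40, "r0"), ("A", 40, "r1"), ("G", 40, "r2"), ("G", 15, "r3")]]
        assert call_alleles(_asm(cols, contig="A")) == []

    def test_triallelic_rejected(self):
        cols = [[("A", 40, "r0"), ("A", 40, "r1"), ("G", 40, "r2"),
                 ("G", 40, "r3"), ("T", 40, "r4"), ("T", 40, "r5")]]
        assert call_alleles(_asm(cols, contig="A")) == []

    def test_n_never_supports(self):
        cols = [[("A", 40, "r0"), ("A", 40, "r1"), ("N", 40, "r2"), ("N", 40, "r3")]]
        assert call_alleles(_asm(cols, contig="A")) == []


def _candidate(pos, s1=3, s2=2):
    return (pos, "A", "G", s1, s2, [f"x{i}" for i in range(s1)],
            [f"y{i}" for i in range(s2)])


class TestFinalFilters:
    contig = "ACGT" * 75  # 300 bp, homopolymer-free

    def test_single_candidate_passes(self):
        calls = final_filters([_candidate(150)], self.contig, "long_454")
        assert len(calls) == 1
        c = calls[0]
        assert isinstance(c, SNPCall)
        assert (c.flank_left, c.flank_right) == (150, 149)

    def test_two_candidates_suppressed(self):
        assert final_filters([_candidate(80), _candidate(200)],
                             self.contig, "long_454") == []

    def test_short_flank_suppressed(self):
        assert final_filters([_candidate(45)], self.contig, "long_454") == []
        # 45 bp left flank is fine for Illumina's 40 bp requirement
        assert len(final_filters([_candidate(45)], self.contig, "short_illumina")) == 1

    def test_homopolymer_window_suppressed(self):
        contig = "ACGT" * 30 + "GAAAAAG" + "CGTA" * 30
        pos = 120 + 3  # middle A of the AAAAA run
        cand = (pos, "A", "G", 3, 2, ["x0", "x1", "x2"], ["y0", "y1"])
        assert final_filters([cand], contig, "long_454") == []

    def test_four_bp_homopolymer_allowed(self):
        contig = "ACGT" * 30 + "GAAAAGC" + "CGTA" * 30
        pos = 120 + 2
        cand = (pos, "A", "G", 3, 2, ["x0", "x1", "x2"], ["y0", "y1"])
        assert len(final_filters([cand], contig, "long_454")) == 1


def test_snpcall_support_invariant():
    with pytest.raises(ValueError):
        SNPCall(contig="ACGT" * 50, position=100, allele_1="A", allele_2="G",
                support_1=1, support_2=2)
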