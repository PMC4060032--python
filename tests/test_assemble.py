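import numpy as np
import pytest
from Bio import Align
from hypothesis import given
from hypothesis import strategies as st

from radloci.assemble import (
    AssemblyConfig,
    LocusCluster,
    ReferenceLocus,
    alignment_identity,
    assemble_cluster,
    build_locus,
    cluster_forward,
    cluster_reference,
    consensus,
    divide_cluster,
)
from radloci.errors import FormatError
from radloci.reduce import reverse_complement


def _brute_force_greedy(members, bound):
    """Independent greedy assignment using an explicit distance matrix."""
    ordered = sorted(members, key=lambda m: (-m[2], m[0], m[1]))
    clusters = []
    for fwd, rev, count in ordered:
        for cluster in clusters:
            seed = cluster[0][0]
            if sum(a != b for a, b in zip(fwd, seed)) <= bound:
                cluster.append((fwd, rev, count))
                break
        else:
            clusters.append([(fwd, rev, count)])
    return clusters


class TestClusterForward:
    def test_identical_reads_one_cluster(self):
        members = [("ACGTACGTAC", "TTTTTTTTTT", 1)] * 5
        clusters = cluster_forward(members, 6)
        assert len(clusters) == 1 and len(clusters[0].members) == 5

    def test_distance_beyond_bound_splits(self):
        members = [("A" * 10, "T" * 10, 1), ("C" * 10, "T" * 10, 1)]
        assert len(cluster_forward(members, 6)) == 2

    def test_abundance_seeding_example(self):
        r1, r2, r3 = "AAAAAAAAAA", "AAAAAAAAAC", "CCCCCCCCCC"
        members = [(r1, "T" * 10, 5), (r2, "T" * 10, 3), (r3, "T" * 10, 4)]
        clusters = cluster_forward(members, 6)
        grouped = [{m[0] for m in c.members} for c in clusters]
        assert {r1, r2} in grouped and {r3} in grouped

    def test_unequal_lengths_rejected(self):
        with pytest.raises(FormatError, match="fixed-length"):
            cluster_forward([("AAAA", "TTTT", 1), ("AAAAA", "TTTT", 1)], 6)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            members = [
                (
                    "".join(rng.choice(list("ACGT"), 12)),
                    "".join(rng.choice(list("ACGT"), 8)),
                    int(rng.integers(1, 9)),
                )
                for _ in range(int(rng.integers(1, 7)))
            ]
            bound = int(rng.integers(0, 7))
            got = [
                [tuple(m) for m in c.members] for c in cluster_forward(members, bound)
            ]
            assert got == _brute_force_greedy(members, bound)

    def test_every_read_assigned_exactly_once(self):
        rng = np.random.default_rng(23)
        members = [
            ("".join(rng.choice(list("ACGT"), 10)), "A" * 5, 1) for _ in range(50)
        ]
        clusters = cluster_forward(members, 3)
        assert sum(len(c.members) for c in clusters) == 50


class TestDivideCluster:
    @staticmethod
    def _cluster(reverses):
        members = [("A" * 10, rev, count) for rev, count in reverses]
        return LocusCluster(1, "A" * 10, members)

    def test_identical_reverses_no_split(self):
        divided = divide_cluster(self._cluster([("CCCCC", 6)]))
        assert len(divided.subclusters) == 1

    def test_splits_on_strong_minor_column(self):
        divided = divide_cluster(self._cluster([("CCCCC", 6), ("CCACC", 4)]))
        sizes = sorted(sub.abundance for sub in divided.subclusters)
        assert sizes == [4, 6]

    def test_singleton_minor_not_split(self):
        divided = divide_cluster(self._cluster([("CCCCC", 9), ("CCACC", 1)]))
        assert len(divided.subclusters) == 1

    def test_partition_preserves_members(self):
        cluster = self._cluster([("CCCCC", 3), ("CCACC", 3), ("GCACC", 2)])
        divided = divide_cluster(cluster)
        flattened = sorted(
            m for sub in divided.subclusters for m in sub.members
        )
        assert flattened == sorted(cluster.members)

    def test_heterozygosity_strictly_drops_at_chosen_column(self):
        cluster = self._cluster([("CCCCC", 5), ("CCACC", 5)])
        divided = divide_cluster(cluster)
        for sub in divided.subclusters:
            assert len({rev[2] for _, rev, _ in sub.members}) == 1


class TestConsensusAndAssembly:
    def test_consensus_majority_and_tie_break(self):
        assert consensus([("AAAA", 5), ("GAAA", 5)]) == "AAAA"  # A before G
        assert consensus([("AAAA", 2), ("GAAA", 5)]) == "GAAA"

    def test_single_subcluster_reproduces_reads(self):
        members = [("ACGTACGTACGTACG", "TTTTGGGGCCCCAAA", 4)]
        cluster = divide_cluster(LocusCluster(1, members[0][0], list(members)))
        fwd, rev = assemble_cluster(cluster)
        assert (fwd, rev) == (members[0][0], members[0][1])

    def test_longest_candidate_contig_wins(self):
        # subcluster A: overlapping ends -> short merged contig;
        # subcluster B: non-overlapping -> longer padded contig wins
        fwd_a = "ACGTACGTACGTACGTACGT"
        rev_a = reverse_complement(fwd_a)  # full overlap, contig length 20
        fwd_b = "ACGTACGTACGTACGTACGA"
        rev_b = "GGGGGGGGGGGGGGGGGGGG"
        members = [(fwd_a, rev_a, 5), (fwd_b, rev_b, 5)]
        cluster = LocusCluster(1, fwd_a, members)
        divided = divide_cluster(cluster)
        assert len(divided.subclusters) == 2
        fwd, rev = assemble_cluster(divided)
        assert (fwd, rev) == (fwd_b, rev_b)


class TestBuildLocus:
    def test_non_overlapping_pair_gets_ten_n_spacer(self):
        locus = build_locus("ACGT", "GGCC")  # revcomp("GGCC") == "GGCC"
        assert locus.sequence == "ACGT" + "N" * 10 + "GGCC"
        assert len(locus.sequence) == 18
        assert locus.padded

    def test_overlap_of_ten_merges_without_padding(self):
        fwd = "A" * 10 + "CGCGCGCGTT"
        tail = "CGCGCGCGTT" + "G" * 10
        locus = build_locus(fwd, reverse_complement(tail))
        assert locus.sequence == "A" * 10 + tail
        assert not locus.padded
        assert "N" not in locus.sequence

    def test_overlap_of_nine_still_padded(self):
        fwd = "A" * 11 + "CGCGCGCGT"
        tail = "CGCGCGCGT" + "G" * 11
        locus = build_locus(fwd, reverse_complement(tail))
        assert locus.padded
        assert "N" * 10 in locus.sequence

    def test_padded_locus_has_exactly_one_ten_n_run(self):
        locus = build_locus("ACGTACGTAC", "TTTTGGGGCC")
        assert locus.sequence.count("N") == 10
        assert "N" * 10 in locus.sequence
        assert "N" * 11 not in locus.sequence


class TestIdentityAndReferenceClustering:
    def test_identical_sequences_identity_one(self):
        assert alignment_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_identity_matches_max_match_alignment_oracle(self):
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1.0
        aligner.open_gap_score = 0.0
        aligner.extend_gap_score = 0.0  # max matches == LCS
        rng = np.random.default_rng(29)
        for _ in range(500):
            a = "".join(rng.choice(list("ACGT"), int(rng.integers(5, 30))))
            b = "".join(rng.choice(list("ACGT"), int(rng.integers(5, 30))))
            expected = aligner.score(a, b) / min(len(a), len(b))
            assert alignment_identity(a, b) == pytest.approx(expected)

    def test_duplicates_collapse_to_one_representative(self):
        loci = [
            ReferenceLocus("a", "ACGTACGTACGTACGTACGT", 10, False, 1, 1),
            ReferenceLocus("b", "ACGTACGTACGTACGTACGT", 10, False, 2, 1),
        ]
        reps = cluster_reference(loci, 0.90)
        assert len(reps) == 1
        assert reps[0].id == "dDocent_Contig_1"

    def test_dissimilar_loci_stay_separate(self):
        loci = [
            ReferenceLocus("a", "ACGT" * 10, 20, False, 1, 1),
            ReferenceLocus("b", "AATT" * 10, 20, False, 2, 1),
        ]
        assert len(cluster_reference(loci, 0.95)) == 2

    def _random_loci(self, rng, n):
        return [
            ReferenceLocus(
                f"l{i}",
                "".join(rng.choice(list("ACGT"), int(rng.integers(15, 40)))),
                10,
                False,
                i,
                1,
            )
            for i in range(n)
        ]

    def test_agrees_with_brute_force_greedy_oracle(self):
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1.0
        aligner.open_gap_score = 0.0
        aligner.extend_gap_score = 0.0
        rng = np.random.default_rng(31)
        for _ in range(300):
            loci = self._random_loci(rng, int(rng.integers(2, 6)))
            threshold = float(rng.uniform(0.6, 0.95))
            ordered = sorted(loci, key=lambda l: (-len(l.sequence), l.sequence))
            reps = []
            for locus in ordered:
                for rep in reps:
                    ident = aligner.score(locus.sequence, rep.sequence) / min(
                        len(locus.sequence), len(rep.sequence)
                    )
                    if ident >= threshold:
                        break
                else:
                    reps.append(locus)
            got = cluster_reference(loci, threshold)
            assert [r.sequence for r in got] == [r.sequence for r in reps]

    def test_representative_count_monotone_in_threshold(self):
        rng = np.random.default_rng(37)
        for _ in range(50):
            loci = self._random_loci(rng, 8)
            sizes = [
                len(cluster_reference(loci, t)) for t in (0.5, 0.7, 0.9, 0.99)
            ]
            assert sizes == sorted(sizes)
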