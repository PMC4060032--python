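import json
import re

import numpy as np
import pytest

from radloci.errors import RadlociError
from radloci.io_formats import parse_sample_name, read_fastq_pairs, read_vcf
from radloci.reduce import reverse_complement
from radloci.simulate import (
    ECORI,
    MSPI,
    SimulationConfig,
    assign_genotypes,
    double_digest,
    expected_reference,
    generate_reads,
    simulate_genome,
    simulate_library,
    size_select,
)


class TestGenome:
    def test_length_and_alphabet(self):
        genome = simulate_genome(10_000, seed=1)
        assert len(genome) == 10_000
        assert set(genome) <= set("ACGT")

    def test_same_seed_identical(self):
        assert simulate_genome(5_000, seed=3) == simulate_genome(5_000, seed=3)

    def test_gc_content_within_sampling_error(self):
        genome = simulate_genome(1_000_000, gc_fraction=0.5, seed=5)
        gc = sum(b in "GC" for b in genome) / len(genome)
        se = (0.25 / 1_000_000) ** 0.5
        assert abs(gc - 0.5) < 3 * se


class TestDoubleDigest:
    def test_worked_example(self):
        fragments = double_digest("TTGAATTCAAAACCGGTT")
        assert len(fragments) == 1
        frag = fragments[0]
        assert (frag.start, frag.end) == (3, 13)
        assert "TTGAATTCAAAACCGGTT"[frag.start : frag.end] == "AATTCAAAAC"
        assert {frag.left_enzyme, frag.right_enzyme} == {"EcoRI", "MspI"}

    def test_no_second_enzyme_site_no_fragment(self):
        assert double_digest("TTGAATTCAAAATTTTTT") == []

    def test_internal_site_excluded(self):
        # EcoRI ... EcoRI ... MspI: only the inner A-B fragment remains
        genome = "TTGAATTCAAAAGAATTCAAAACCGGTT"
        fragments = double_digest(genome)
        assert len(fragments) == 1
        assert genome[fragments[0].start : fragments[0].end].count("GAATTC") == 0

    def test_same_enzyme_flanks_rejected(self):
        # two MspI cuts around a fragment with no EcoRI between them
        genome = "TTCCGGAAAAAACCGGTT"
        assert double_digest(genome) == []


class TestSizeSelect:
    def _fragments_of_lengths(self, lengths):
        genome = []
        fragments = []
        pos = 0
        from radloci.simulate import Fragment

        for L in lengths:
            fragments.append(Fragment(pos, pos + L, "EcoRI", "MspI"))
            pos += L
        return "A" * pos, fragments

    def test_window_bounds_inclusive(self):
        genome, frags = self._fragments_of_lengths([100, 350, 360, 400, 401])
        loci = size_select(genome, frags, (350, 400))
        assert [l.end - l.start for l in loci] == [350, 360, 400]
        assert [l.id for l in loci] == [1, 2, 3]

    def test_empty_input(self):
        assert size_select("AAAA", [], (350, 400)) == []

    def test_minus_strand_fragment_stored_ecori_first(self):
        from radloci.simulate import Fragment

        genome = "TTCCGGAAAAAAGAATTCTT"  # MspI cut at 3, EcoRI cut at 13
        frag = Fragment(3, 13, "MspI", "EcoRI")
        locus = size_select(genome, [frag], (5, 20))[0]
        assert locus.strand == "-"
        assert locus.sequence == reverse_complement(genome[3:13])


class TestGenotypes:
    def _loci(self, seed=11, n_ind=6):
        genome = simulate_genome(300_000, seed=seed)
        loci = size_select(genome, double_digest(genome))
        individuals = [f"POP1_IND{i:02d}" for i in range(1, n_ind + 1)]
        return genome, loci, individuals

    def test_zero_rates_give_monomorphic_truth(self):
        _, loci, individuals = self._loci()
        records = assign_genotypes(loci, individuals, 0.0, 0.0, 13)
        assert records == []
        for locus in loci:
            for h1, h2 in locus.haplotypes.values():
                assert h1 == h2 == locus.sequence

    def test_fixed_seed_reproducible(self):
        _, loci_a, ind = self._loci()
        _, loci_b, _ = self._loci()
        rec_a = assign_genotypes(loci_a, ind, 0.01, 0.001, 17)
        rec_b = assign_genotypes(loci_b, ind, 0.01, 0.001, 17)
        assert [(r.contig, r.position, r.genotypes) for r in rec_a] == [
            (r.contig, r.position, r.genotypes) for r in rec_b
        ]

    def test_every_listed_variant_realized_in_a_haplotype(self):
        _, loci, individuals = self._loci()
        records = assign_genotypes(loci, individuals, 0.01, 0.002, 19)
        assert records, "expected segregating sites"
        for rec in records:
            assert any(gt is not None and sum(gt) > 0 for gt in rec.genotypes)
        for locus in loci:
            if locus.variants:
                haps = [h for pair in locus.haplotypes.values() for h in pair]
                assert any(h != locus.sequence for h in haps)

    def test_realized_allele_counts_track_drawn_frequency(self):
        genome = simulate_genome(300_000, seed=23)
        loci = size_select(genome, double_digest(genome))
        individuals = [f"POP1_IND{i:03d}" for i in range(200)]
        records = assign_genotypes(loci, individuals, 0.01, 0.0, 23)
        assert records, "expected segregating sites"
        freqs = {
            (v.position + 1, locus.name): v.frequency
            for locus in loci
            for v in locus.variants
        }
        checked = 0
        for rec in records:
            f = freqs[(rec.position, rec.contig)]
            copies = sum(sum(gt) for gt in rec.genotypes if gt)
            n = 2 * len(individuals)
            sd = (n * f * (1 - f)) ** 0.5
            assert abs(copies - n * f) < 3.5 * sd + 3
            checked += 1
        assert checked >= 5


class TestReads:
    def test_error_free_reads_are_haplotype_substrings(self, clean_library):
        res = clean_library
        truth = {locus.sequence for locus in res.loci}
        n = 0
        for _, pair in read_fastq_pairs(res.out_dir):
            fwd = pair.forward.sequence
            rev = reverse_complement(pair.reverse.sequence)
            assert any(t.startswith(fwd) and t.endswith(rev) for t in truth)
            n += 1
        assert n == sum(res.pairs_per_individual.values())

    def test_poisson_pair_total(self, clean_library):
        res = clean_library
        expected = len(res.loci) * len(res.individuals) * 15.0
        total = sum(res.pairs_per_individual.values())
        assert abs(total - expected) < 3 * expected**0.5

    def test_filenames_follow_naming_convention(self, clean_library):
        files = sorted(p.name for p in clean_library.out_dir.glob("*.fq"))
        assert files
        for name in files:
            parse_sample_name(name)

    def test_read_length_longer_than_locus_rejected(self):
        genome = simulate_genome(300_000, seed=29)
        loci = size_select(genome, double_digest(genome))
        assign_genotypes(loci, [f"P_I{i}" for i in range(2)], 0, 0, 1)
        with pytest.raises(RadlociError, match="read length"):
            generate_reads(loci, "/tmp/radloci-unused", read_length=500, seed=1)


class TestLibraryOrchestration:
    def test_outputs_and_manifest(self, clean_library):
        res = clean_library
        manifest = json.loads((res.out_dir / "manifest.json").read_text())
        assert manifest["n_loci"] == len(res.loci)
        assert manifest["seed"] == 7
        samples, records = read_vcf(res.out_dir / "truth.vcf")
        assert samples == res.individuals
        assert records == []  # monomorphic library
        fasta = (res.out_dir / "truth_loci.fasta").read_text()
        assert fasta.count(">") == len(res.loci)

    def test_truth_vcf_consistent_with_haplotypes(self, tmp_path):
        config = SimulationConfig(
            genome_length=300_000,
            n_populations=1,
            individuals_per_population=5,
            mean_pairs_per_locus=5.0,
            snp_rate=0.01,
            indel_rate=0.001,
            seed=31,
        )
        res = simulate_library(config, tmp_path)
        _, records = read_vcf(tmp_path / "truth.vcf")
        assert len(records) == sum(len(l.variants) for l in res.loci)
        for rec in records:
            assert any(sum(gt) > 0 for gt in rec.genotypes if gt)

    def test_expected_reference_geometry(self, clean_library):
        expected = expected_reference(clean_library.loci, read_length=100)
        for locus in clean_library.loci:
            contig = expected[locus.name]
            assert contig.startswith(locus.sequence[:100])
            assert contig.endswith(locus.sequence[-100:])
            assert "N" * 10 in contig
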