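"""Assemble a de novo RAD reference and check it against the truth.

Reads are collapsed to unique forward+revcomp(reverse) composites, the
1X-50X coverage curve is tabulated, composites at >= 4X enter assembly
(forward-read Hamming clustering, reverse-read allele division,
consensus, ten-N padding, 90% identity de-duplication), and the result
is compared with the simulator's expected contigs.
"""

import tempfile

from radloci.assemble import assemble_reference
from radloci.io_formats import read_fastq_pairs
from radloci.reduce import coverage_curve, reduce_pairs, select_by_cutoff
from radloci.simulate import SimulationConfig, expected_reference, simulate_library

config = SimulationConfig(
    genome_length=500_000,
    n_populations=1,
    individuals_per_population=6,
    mean_pairs_per_locus=12.0,
    error_rate=0.002,
    snp_rate=0.005,
    seed=11,
)

with tempfile.TemporaryDirectory() as tmp:
    result = simulate_library(config, tmp)
    tally = reduce_pairs(pair for _, pair in read_fastq_pairs(tmp))
    curve = coverage_curve(tally)
    print(f"unique composites: {tally.n_unique} from {tally.n_pairs} pairs")
    print(f"coverage curve head (>=1X..>=5X): {curve[:5]}")

    selected = select_by_cutoff(tally, cutoff=4)
    reference = assemble_reference(selected)
    expected = expected_reference(result.loci, config.read_length)
    exact = sum(r.sequence in set(expected.values()) for r in reference)
    print(f"unique reads at >=4X: {len(selected)}")
    print(f"reference contigs   : {len(reference)} (truth has {len(result.loci)})")
    print(f"exactly recovered   : {exact}")
    print(f"first contig id     : {reference[0].id}, padded={reference[0].padded}")

# One contig per truth locus is the target: alleles of a locus merge in
# forward clustering and the longest per-cluster candidate represents it.
# With sequencing error and heterozygosity a consensus can differ from
# the truth fragment at a few bases, so 'exactly recovered' may sit just
# below the contig count.
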