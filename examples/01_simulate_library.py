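"""Simulate a small ddRAD library and look at what it contains.

A 500 kb random genome is digested with EcoRI and MspI; fragments cut by
one enzyme on each end and 350-400 bp long become RAD loci. Six diploid
individuals get haplotypes carrying SNPs/indels at population
frequencies, and 100 bp read pairs are sampled per individual per locus.
"""

import tempfile
from pathlib import Path

from radloci.simulate import SimulationConfig, simulate_library

config = SimulationConfig(
    genome_length=500_000,
    n_populations=1,
    individuals_per_population=6,
    mean_pairs_per_locus=12.0,
    error_rate=0.002,
    snp_rate=0.005,
    indel_rate=0.0005,
    seed=11,
)

with tempfile.TemporaryDirectory() as tmp:
    result = simulate_library(config, tmp)
    n_pairs = sum(result.pairs_per_individual.values())
    n_variants = sum(len(l.variants) for l in result.loci)
    print(f"RAD loci after digest + size selection : {len(result.loci)}")
    print(f"segregating variants across loci       : {n_variants}")
    print(f"read pairs over {len(result.individuals)} individuals          : {n_pairs}")
    print(f"files written: {sorted(p.name for p in Path(tmp).glob('*'))[:4]} ...")

# The locus count is what the enzymes and the size window allow on this
# genome; the pair total is Poisson around loci x individuals x mean.
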