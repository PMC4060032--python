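import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from radloci.io_formats import VariantRecord
from radloci.simulate import SimulationConfig, simulate_library

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_random_records(rng, n_records, n_samples, contig="chr1"):
    """Random VCF-like records with GT/DP for oracle tests."""
    records = []
    for i in range(n_records):
        n_alts = int(rng.integers(1, 3))
        bases = ["A", "C", "G", "T"]
        ref = bases[int(rng.integers(4))]
        alts = [b for b in bases if b != ref][:n_alts]
        genotypes, depths = [], []
        for _ in range(n_samples):
            if rng.random() < 0.15:
                genotypes.append(None)
                depths.append(None)
            else:
                gt = tuple(sorted(rng.integers(0, n_alts + 1, 2).tolist()))
                genotypes.append(gt)
                depths.append(int(rng.poisson(8)) if rng.random() > 0.05 else None)
        records.append(
            VariantRecord(
                contig=contig,
                position=i + 1,
                ref=ref,
                alts=alts,
                qual=float(np.round(rng.uniform(0, 100), 2)),
                genotypes=genotypes,
                depths=depths,
            )
        )
    return records


@pytest.fixture(scope="session")
def clean_library(tmp_path_factory):
    """Small error-free, monomorphic simulated library plus its truth."""
    out = tmp_path_factory.mktemp("clean_lib")
    config = SimulationConfig(
        genome_length=400_000,
        n_populations=1,
        individuals_per_population=4,
        mean_pairs_per_locus=15.0,
        error_rate=0.0,
        snp_rate=0.0,
        indel_rate=0.0,
        seed=7,
    )
    return simulate_library(config, out)
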