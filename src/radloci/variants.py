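"""Baseline variant filtering and population-informativeness metrics.

The pipeline's philosophy is to filter minimally and let the analyst
decide: the baseline filter keeps sites called in at least 90% of
individuals with site quality >= 30, and a separate minor-allele-count
filter (MAC >= 5) removes singleton/doubleton noise before pipeline
comparisons. Informative-ness of a call set is then summarized by the
number of SNPs genotyped at depth >= d in at least a fraction p of
individuals, over a grid of depths {3,5,10,20} and call rates
{0.75, 0.90, 0.99}.

Thresholds are inclusive throughout: a site at exactly 90% call rate,
QUAL exactly 30, or MAC exactly 5 survives ("less than five" is what gets
removed). "Called" means a non-missing genotype; site QUAL (not
per-genotype quality) carries the quality threshold, matching the
semantics of VCFtools' --max-missing/--minQ that the reference pipeline
invokes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .io_formats import VariantRecord

DEPTH_THRESHOLDS = (3, 5, 10, 20)
CALL_RATE_FRACTIONS = (0.75, 0.90, 0.99)


@dataclass(frozen=True)
class FilterConfig:
    call_rate: float = 0.90
    min_qual: float = 30.0
    min_mac: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.call_rate <= 1:
            raise ValueError("call rate must be in (0, 1]")
        if self.min_qual < 0 or self.min_mac < 0:
            raise ValueError("quality and MAC thresholds must be >= 0")


def filter_baseline(
    records: Iterable[VariantRecord],
    n_samples: int,
    config: FilterConfig | None = None,
) -> Iterator[VariantRecord]:
    """Keep sites called in >= call-rate of individuals with QUAL >= min.

    Passes SNPs, indels and complex events alike; order is preserved.
    """
    config = config or FilterConfig()
    for rec in records:
        if rec.n_called / n_samples >= config.call_rate and rec.qual >= config.min_qual:
            yield rec


def minor_allele_count(record: VariantRecord) -> int:
    """Copies of the second-most-frequent allele among called genotypes."""
    tallies: dict[int, int] = {}
    for gt in record.genotypes:
        if gt is None:
            continue
        for allele in gt:
            tallies[allele] = tallies.get(allele, 0) + 1
    ranked = sorted(tallies.values(), reverse=True)
    return ranked[1] if len(ranked) > 1 else 0


def filter_mac(
    records: Iterable[VariantRecord], min_mac: int = 5
) -> Iterator[VariantRecord]:
    """Keep sites whose minor allele count is >= min_mac."""
    for rec in records:
        if minor_allele_count(rec) >= min_mac:
            yield rec


def snp_metrics(
    records: Iterable[VariantRecord],
    n_samples: int,
    depths: Sequence[int] = DEPTH_THRESHOLDS,
    fractions: Sequence[float] = CALL_RATE_FRACTIONS,
) -> tuple[int, pd.DataFrame]:
    """Count SNPs genotyped at depth >= d in >= p of individuals.

    Returns (total SNP count, table with columns depth, call_rate,
    count). Only SNP records count (indels and complex events are
    excluded); a called genotype with no DP counts below every depth
    threshold, with a warning.
    """
    total = 0
    cells = {(d, p): 0 for d in depths for p in fractions}
    warned = False
    for rec in records:
        if not rec.is_snp():
            continue
        total += 1
        at_depth = {d: 0 for d in depths}
        for gt, dp in zip(rec.genotypes, rec.depths):
            if gt is None:
                continue
            if dp is None:
                if not warned:
                    warnings.warn(
                        "called genotype without DP; treated as below every "
                        "depth threshold",
                        stacklevel=2,
                    )
                    warned = True
                continue
            for d in depths:
                if dp >= d:
                    at_depth[d] += 1
        for d in depths:
            rate = at_depth[d] / n_samples
            for p in fractions:
                if rate >= p:
                    cells[(d, p)] += 1
    table = pd.DataFrame(
        [
            {"depth": d, "call_rate": p, "count": cells[(d, p)]}
            for d in depths
            for p in fractions
        ]
    )
    return total, table


def mean_depths(
    records: Sequence[VariantRecord], samples: Sequence[str]
) -> dict[str, float]:
    """Mean depth per individual over its called genotypes (0 if none)."""
    sums = {s: 0 for s in samples}
    counts = {s: 0 for s in samples}
    for rec in records:
        for sample, gt, dp in zip(samples, rec.genotypes, rec.depths):
            if gt is None or dp is None:
                continue
            sums[sample] += dp
            counts[sample] += 1
    return {s: (sums[s] / counts[s] if counts[s] else 0.0) for s in samples}


def drop_low_coverage_individuals(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    fraction: float = 0.10,
) -> tuple[list[VariantRecord], list[str]]:
    """Remove the lowest-coverage ceil(fraction * n) individuals.

    Individuals are ranked by mean depth over called genotypes, ties
    broken by sample name for determinism. Returned records are
    restricted to the retained samples; metrics afterwards should use the
    reduced sample count.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    n_drop = math.ceil(fraction * len(samples))
    if n_drop == 0:
        return list(records), list(samples)
    means = mean_depths(records, samples)
    ranked = sorted(samples, key=lambda s: (means[s], s))
    dropped = set(ranked[:n_drop])
    keep_idx = [i for i, s in enumerate(samples) if s not in dropped]
    retained = [samples[i] for i in keep_idx]
    reduced = [
        VariantRecord(
            contig=rec.contig,
            position=rec.position,
            ref=rec.ref,
            alts=list(rec.alts),
            qual=rec.qual,
            genotypes=[rec.genotypes[i] for i in keep_idx],
            depths=[rec.depths[i] for i in keep_idx],
        )
        for rec in records
    ]
    return reduced, retained
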