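"""End-to-end orchestration: trim -> reduce -> assemble -> filter/evaluate.

Read mapping and variant calling sit between assembly and filtering in a
full RAD workflow; they are external to this package, so the filter and
evaluation stages accept a VCF produced elsewhere. Every stage here is
deterministic, so re-running with identical inputs and configuration is
bit-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from .assemble import AssemblyConfig, assemble_reference
from .errors import RadlociError
from .io_formats import find_fastq_pairs, read_fastq_pairs, read_vcf, write_vcf
from .reduce import coverage_curve, reduce_pairs, render_curve, select_by_cutoff
from .trim import TrimConfig, trim_directory
from .variants import FilterConfig, drop_low_coverage_individuals, filter_baseline, snp_metrics

logger = logging.getLogger("radloci")


@dataclass
class RunConfig:
    in_dir: Path
    out_dir: Path
    cutoff: int
    trim: TrimConfig = field(default_factory=TrimConfig)
    assembly: AssemblyConfig = field(default_factory=AssemblyConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    vcf: Path | None = None
    skip_trim: bool = False
    drop_bottom: float = 0.0

    def __post_init__(self) -> None:
        self.in_dir = Path(self.in_dir)
        self.out_dir = Path(self.out_dir)
        if self.cutoff < 1:
            raise ValueError("coverage cutoff must be >= 1")


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Run the requested stages; returns a machine-readable summary.

    Stages: (1) trim each sample's pairs, writing R1/R2 files; (2) reduce
    *untrimmed* pairs to unique composites and print the coverage curve;
    (3) assemble the reference from composites at the cutoff; (4) if a
    VCF is supplied, apply the baseline filter and tabulate SNP metrics.
    Any stage failure raises with the stage name attached.
    """
    config.out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(config.out_dir / "radloci.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: dict[str, object] = {}
    started = time.time()
    try:
        samples = find_fastq_pairs(config.in_dir)
        if not samples:
            raise RadlociError(f"no samples found in {config.in_dir}")
        summary["n_samples"] = len(samples)
        logger.info("recognized %d samples", len(samples))

        if not config.skip_trim:
            stats = _stage("trim", trim_directory, config.in_dir,
                           config.out_dir / "trimmed", config.trim)
            summary["pairs_kept"] = sum(s["kept"] for s in stats.values())
            summary["pairs_dropped"] = sum(s["dropped"] for s in stats.values())

        tally = _stage(
            "reduce", reduce_pairs, (p for _, p in read_fastq_pairs(config.in_dir))
        )
        summary["n_pairs"] = tally.n_pairs
        summary["n_unique_composites"] = tally.n_unique
        curve = coverage_curve(tally)
        logger.info("coverage curve:\n%s", render_curve(curve))

        selected = _stage("reduce", select_by_cutoff, tally, config.cutoff)
        summary["n_selected"] = len(selected)
        reference = _stage(
            "assemble",
            assemble_reference,
            selected,
            config.assembly,
            config.out_dir / "reference.fasta",
        )
        summary["n_reference_loci"] = len(reference)

        if config.vcf is not None:
            vcf_samples, records = _stage("filter", read_vcf, config.vcf)
            kept = list(filter_baseline(records, len(vcf_samples), config.filters))
            write_vcf(kept, vcf_samples, config.out_dir / "filtered.vcf")
            summary["n_variants_in"] = len(records)
            summary["n_variants_kept"] = len(kept)
            if config.drop_bottom > 0:
                kept, vcf_samples = drop_low_coverage_individuals(
                    kept, vcf_samples, config.drop_bottom
                )
            total, table = snp_metrics(kept, len(vcf_samples))
            summary["n_snps"] = total
            table.to_csv(config.out_dir / "metrics.tsv", sep="\t", index=False)
    finally:
        logger.removeHandler(handler)
        handler.close()

    summary["runtime_s"] = round(time.time() - started, 2)
    _write_summary(summary, config.out_dir / "summary.tsv")
    return summary


def _stage(name, func, *args):
    try:
        return func(*args)
    except Exception as exc:
        logger.error("stage %s failed: %s", name, exc)
        raise RadlociError(f"stage {name!r} failed: {exc}") from exc


def _write_summary(summary: dict[str, object], path: Path) -> None:
    with open(path, "w") as handle:
        handle.write("key\tvalue\n")
        for key, value in summary.items():
            handle.write(f"{key}\t{value}\n")
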