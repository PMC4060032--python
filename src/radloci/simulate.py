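"""ddRAD library simulator with ground truth.

Emulates the laboratory protocol behind double-digest RAD data end to
end, at desk scale: a random genome is digested in silico with EcoRI
(G^AATTC) and MspI (C^CGG); fragments flanked by one cut of each enzyme —
the only fragments that receive both the barcoded and the generic adapter
and therefore amplify — are size-selected to 350-400 bp; each retained
fragment is a RAD locus. Segregating SNPs and short indels are drawn per
locus with population allele frequencies, each diploid individual gets
two haplotypes, and fixed-length paired reads are sampled per individual
per locus with Poisson depth and i.i.d. substitution errors.

Forward reads start at the EcoRI end of the fragment (the barcoded
adapter side), fixing read orientation; fragments whose EcoRI end faces
the other way on the genome's top strand are stored reverse-complemented,
with their genomic interval and strand retained.

Everything is driven by one seeded NumPy generator, so a fixed seed
reproduces the library bit for bit. Not modeled (irrelevant to the
stages this package implements): restriction-site polymorphism (allele
dropout), PCR duplicates, paralogs, machine-specific error profiles.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import RadlociError
from .io_formats import SampleName, SequenceRecord, write_fastq, write_vcf, VariantRecord
from .reduce import reverse_complement

QUAL_CORRECT = 37  # deliberately simple quality model:
QUAL_ERROR = 8  # right bases score high, wrong bases score low

_BASES = "ACGT"


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: recognition site plus cut offset.

    ``cut`` is the number of site bases left of the cut on the top strand
    (EcoRI G^AATTC and MspI C^CGG both cut after one base).
    """

    name: str
    site: str
    cut: int

    def __post_init__(self) -> None:
        if not 0 < self.cut < len(self.site):
            raise ValueError("cut offset must fall inside the recognition site")


ECORI = Enzyme("EcoRI", "GAATTC", 1)
MSPI = Enzyme("MspI", "CCGG", 1)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated library.

    Defaults mirror the protocol the package targets: EcoRI+MspI double
    digest, 350-400 bp size selection (inclusive), two sampled localities
    of 20 diploid individuals, 100 bp paired reads at a mean of 20 pairs
    per locus per individual. Genome length 2 Mb keeps a run at tens to
    hundreds of loci. Polymorphism and error rates are per-base.
    """

    genome_length: int = 2_000_000
    gc_fraction: float = 0.5
    enzyme_a: Enzyme = ECORI
    enzyme_b: Enzyme = MSPI
    size_window: tuple[int, int] = (350, 400)
    n_populations: int = 2
    individuals_per_population: int = 20
    read_length: int = 100
    mean_pairs_per_locus: float = 20.0
    error_rate: float = 0.005
    snp_rate: float = 0.005
    indel_rate: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.size_window
        if lo > hi:
            raise ValueError("size-selection window min must be <= max")
        for rate in (self.error_rate, self.snp_rate, self.indel_rate):
            if not 0 <= rate < 1:
                raise ValueError("rates must be in [0, 1)")

    @property
    def individuals(self) -> list[str]:
        return [
            str(SampleName(f"POP{p + 1}", f"IND{i + 1:02d}"))
            for p in range(self.n_populations)
            for i in range(self.individuals_per_population)
        ]


@dataclass(frozen=True)
class Variant:
    """A segregating variant in locus coordinates (0-based anchor)."""

    position: int
    ref: str
    alt: str
    frequency: float

    @property
    def kind(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "snp"
        return "ins" if len(self.alt) > len(self.ref) else "del"


@dataclass
class TruthLocus:
    """One retained restriction fragment and everything true about it."""

    id: int
    start: int  # genomic interval, 0-based half-open, top strand
    end: int
    strand: str  # '+' if the EcoRI end is leftmost on the top strand
    sequence: str  # sequenced orientation: EcoRI end first
    variants: list[Variant] = field(default_factory=list)
    haplotypes: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def name(self) -> str:
        return f"truth_locus_{self.id}"


@dataclass(frozen=True)
class Fragment:
    start: int
    end: int
    left_enzyme: str
    right_enzyme: str


def _rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_genome(
    length: int, gc_fraction: float = 0.5, seed: int | np.random.Generator = 0
) -> str:
    """I.i.d. random genome at the requested GC content."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    rng = _rng(seed)
    at, gc = (1 - gc_fraction) / 2, gc_fraction / 2
    codes = rng.choice(
        np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=[at, gc, gc, at]
    )
    return codes.tobytes().decode()


def double_digest(
    genome: str, enzyme_a: Enzyme = ECORI, enzyme_b: Enzyme = MSPI
) -> list[Fragment]:
    """Cut the top strand with both enzymes; keep proper A-B fragments.

    Cut coordinates are ``site start + cut offset`` (0-based; the cut
    lies immediately left of that coordinate). A fragment is retained
    only when its two flanking cuts come from *different* enzymes; taking
    consecutive cuts guarantees no internal site survives.
    """
    cuts: list[tuple[int, str]] = []
    for enzyme in (enzyme_a, enzyme_b):
        for m in re.finditer(f"(?={enzyme.site})", genome):
            cuts.append((m.start() + enzyme.cut, enzyme.name))
    cuts.sort()
    fragments = []
    for (left, left_enz), (right, right_enz) in zip(cuts, cuts[1:]):
        if left_enz != right_enz and right > left:
            fragments.append(Fragment(left, right, left_enz, right_enz))
    return fragments


def size_select(
    genome: str,
    fragments: Sequence[Fragment],
    window: tuple[int, int] = (350, 400),
    enzyme_a: Enzyme = ECORI,
) -> list[TruthLocus]:
    """Keep fragments inside the (inclusive) size window as RAD loci.

    Sequences are stored in sequenced orientation: the enzyme-A (EcoRI,
    barcoded-adapter) end first, reverse-complementing where needed.
    """
    lo, hi = window
    loci = []
    for frag in fragments:
        length = frag.end - frag.start
        if not lo <= length <= hi:
            continue
        seq = genome[frag.start : frag.end]
        if frag.left_enzyme == enzyme_a.name:
            strand = "+"
        else:
            strand = "-"
            seq = reverse_complement(seq)
        loci.append(
            TruthLocus(
                id=len(loci) + 1,
                start=frag.start,
                end=frag.end,
                strand=strand,
                sequence=seq,
            )
        )
    return loci


def _draw_variant_positions(
    rng: np.random.Generator, length: int, n_wanted: int, spacing: int = 6
) -> list[int]:
    """Distinct positions >= spacing apart, away from the locus ends."""
    candidates = rng.permutation(np.arange(1, length - spacing))
    accepted: list[int] = []
    for pos in candidates:
        if len(accepted) == n_wanted:
            break
        if all(abs(pos - a) >= spacing for a in accepted):
            accepted.append(int(pos))
    return accepted


def assign_genotypes(
    loci: Sequence[TruthLocus],
    individuals: Sequence[str],
    snp_rate: float,
    indel_rate: float,
    seed: int | np.random.Generator,
) -> list[VariantRecord]:
    """Draw segregating variants and diploid haplotypes for every locus.

    Per locus, segregating-site counts are binomial in the locus length
    at the per-base rates; allele frequencies are uniform on (0.05,
    0.95); each individual's two haplotypes carry the alternate allele by
    independent Bernoulli draws. Variants that end up on no haplotype are
    discarded (they would not be variants). Returns the truth VCF
    records (1-based positions in locus coordinates, GT only).
    """
    rng = _rng(seed)
    truth_records = []
    for locus in loci:
        seq = locus.sequence
        n_snps = rng.binomial(len(seq), snp_rate)
        n_indels = rng.binomial(len(seq), indel_rate)
        positions = _draw_variant_positions(rng, len(seq), n_snps + n_indels)
        # first n_snps drawn positions become SNPs, the rest indels
        proposals: list[Variant] = []
        for i, pos in enumerate(positions):
            freq = float(rng.uniform(0.05, 0.95))
            if i < n_snps:
                ref = seq[pos]
                alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
                proposals.append(Variant(pos, ref, alt, freq))
            else:
                size = int(rng.integers(1, 6))
                if rng.random() < 0.5 and pos + size + 1 <= len(seq):  # deletion
                    proposals.append(
                        Variant(pos, seq[pos : pos + size + 1], seq[pos], freq)
                    )
                else:  # insertion
                    ins = "".join(_BASES[b] for b in rng.integers(0, 4, size))
                    proposals.append(Variant(pos, seq[pos], seq[pos] + ins, freq))
        proposals.sort(key=lambda v: v.position)
        # carriage matrix: one Bernoulli(freq) per haplotype per variant
        carries = {
            ind: (
                rng.random(len(proposals)) < [v.frequency for v in proposals],
                rng.random(len(proposals)) < [v.frequency for v in proposals],
            )
            for ind in individuals
        }
        realized = [
            i
            for i in range(len(proposals))
            if any(c[0][i] or c[1][i] for c in carries.values())
        ]
        locus.variants = [proposals[i] for i in realized]

        def build_hap(mask: np.ndarray) -> str:
            hap = seq
            for i in reversed(realized):
                if mask[i]:
                    v = proposals[i]
                    hap = hap[: v.position] + v.alt + hap[v.position + len(v.ref) :]
            return hap

        locus.haplotypes = {
            ind: (build_hap(c[0]), build_hap(c[1])) for ind, c in carries.items()
        }
        for i in realized:
            v = proposals[i]
            genotypes = []
            for ind in individuals:
                a, b = int(carries[ind][0][i]), int(carries[ind][1][i])
                genotypes.append((min(a, b), max(a, b)))
            truth_records.append(
                VariantRecord(
                    contig=locus.name,
                    position=v.position + 1,
                    ref=v.ref,
                    alts=[v.alt],
                    qual=99.0,
                    genotypes=genotypes,
                )
            )
    return truth_records


def generate_reads(
    loci: Sequence[TruthLocus],
    out_dir: str | Path,
    read_length: int = 100,
    mean_pairs_per_locus: float = 20.0,
    error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> dict[str, int]:
    """Sample paired reads per individual per locus and write FASTQ files.

    Pair counts are Poisson; each pair copies a uniformly chosen
    haplotype: forward read = first ``read_length`` bases, reverse read =
    reverse complement of the last ``read_length`` bases. Substitution
    errors are i.i.d.; erroneous bases get quality 8, correct ones 37.
    Returns pairs written per individual.
    """
    rng = _rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not loci:
        raise RadlociError("no loci to sequence")
    individuals = sorted(loci[0].haplotypes)

    def with_errors(seq: str) -> SequenceRecord:
        quals = [QUAL_CORRECT] * len(seq)
        if error_rate > 0:
            mask = rng.random(len(seq)) < error_rate
            if mask.any():
                bases = list(seq)
                for pos in np.flatnonzero(mask):
                    bases[pos] = _BASES[
                        (_BASES.index(bases[pos]) + int(rng.integers(1, 4))) % 4
                    ]
                    quals[pos] = QUAL_ERROR
                seq = "".join(bases)
        return SequenceRecord("r", seq, quals)

    counts = {}
    for ind in individuals:
        fwd_records, rev_records = [], []
        for locus in loci:
            haps = locus.haplotypes[ind]
            if min(len(h) for h in haps) < read_length:
                raise RadlociError(
                    f"{locus.name}: haplotype shorter than the read length"
                )
            n_pairs = int(rng.poisson(mean_pairs_per_locus))
            for j in range(n_pairs):
                hap = haps[int(rng.integers(2))]
                fwd = with_errors(hap[:read_length])
                rev = with_errors(reverse_complement(hap[-read_length:]))
                rid = f"{locus.name}_{ind}_{j}"
                fwd_records.append(SequenceRecord(rid, fwd.sequence, fwd.qualities))
                rev_records.append(SequenceRecord(rid, rev.sequence, rev.qualities))
        write_fastq(fwd_records, out_dir / f"{ind}.F.fq")
        write_fastq(rev_records, out_dir / f"{ind}.R.fq")
        counts[ind] = len(fwd_records)
    return counts


def expected_reference(
    loci: Sequence[TruthLocus],
    read_length: int = 100,
    padding: int = 10,
    min_overlap: int = 10,
) -> dict[str, str]:
    """The contig a perfect assembly should produce for each truth locus.

    For the usual non-overlapping geometry this is
    ``fragment[:read_length] + 'N' * padding + fragment[-read_length:]``;
    if reads overlap by at least ``min_overlap`` the full fragment is
    expected instead.
    """
    expected = {}
    for locus in loci:
        seq = locus.sequence
        overlap = 2 * read_length - len(seq)
        if overlap >= min_overlap:
            expected[locus.name] = seq
        else:
            expected[locus.name] = (
                seq[:read_length] + "N" * padding + seq[-read_length:]
            )
    return expected


@dataclass
class SimulationResult:
    config: SimulationConfig
    loci: list[TruthLocus]
    individuals: list[str]
    truth_records: list[VariantRecord]
    pairs_per_individual: dict[str, int]
    out_dir: Path


def simulate_library(
    config: SimulationConfig, out_dir: str | Path
) -> SimulationResult:
    """Run the whole simulation and write FASTQ pairs plus truth files.

    Writes ``<POP>_<ID>.F.fq``/``.R.fq`` per individual,
    ``truth_loci.fasta`` (fragments in sequenced orientation),
    ``truth.vcf`` and a ``manifest.json`` recording the seed and counts.
    """
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(config.genome_length, config.gc_fraction, rng)
    fragments = double_digest(genome, config.enzyme_a, config.enzyme_b)
    loci = size_select(genome, fragments, config.size_window, config.enzyme_a)
    if not loci:
        raise RadlociError(
            "no fragments survived size selection; enlarge the genome"
        )
    individuals = config.individuals
    truth_records = assign_genotypes(
        loci, individuals, config.snp_rate, config.indel_rate, rng
    )
    counts = generate_reads(
        loci,
        out_dir,
        config.read_length,
        config.mean_pairs_per_locus,
        config.error_rate,
        rng,
    )
    with open(out_dir / "truth_loci.fasta", "w") as handle:
        for locus in loci:
            handle.write(f">{locus.name}\n{locus.sequence}\n")
    write_vcf(truth_records, individuals, out_dir / "truth.vcf")
    manifest = {
        "seed": config.seed,
        "genome_length": config.genome_length,
        "n_loci": len(loci),
        "n_individuals": len(individuals),
        "n_variants": len(truth_records),
        "n_pairs": sum(counts.values()),
    }
    with open(out_dir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2)
    return SimulationResult(config, loci, individuals, truth_records, counts, out_dir)
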