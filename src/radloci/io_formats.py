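"""File formats and naming conventions.

RAD pipelines live and die on plumbing: demultiplexed per-individual FASTQ
pairs named ``<POP>_<ID>.F.fq`` / ``<POP>_<ID>.R.fq`` (a single-word
locality code and a single-word sample identifier joined by one
underscore), an assembled reference in FASTA, and variant calls in VCF.
This module is the only place those formats are read or written: FASTQ and
FASTA go through Biopython, VCF through pysam/htslib.

Conventions enforced here:

* FASTQ qualities are PHRED+33 (Sanger). Other encodings are not
  auto-detected; out-of-range values fail loudly.
* Gzip is detected from the two magic bytes, never from the extension.
* VCF positions are 1-based on disk and on :class:`VariantRecord` (which is
  the VCF-facing type); everything internal to the package is 0-based
  half-open.
"""

from __future__ import annotations

import gzip
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlphabetError,
    FormatError,
    NamingConventionError,
    PairingError,
    TruncationError,
)

_VALID_SEQ = re.compile(r"^[ACGTN]*$")
_SUFFIX = re.compile(r"\.(?P<orient>[FR])\.fq(?P<gz>\.gz)?$")


class Orientation(Enum):
    """Which mate of a pair a file holds: F (forward) or R (reverse)."""

    FORWARD = "F"
    REVERSE = "R"


@dataclass(frozen=True)
class SampleName:
    """A population/locality code plus an individual identifier.

    Both tokens are single words: no underscores, no path separators.
    ``orientation`` is carried when the name was parsed from a mate file.
    """

    population: str
    individual: str
    orientation: Orientation | None = None

    def __post_init__(self) -> None:
        for token in (self.population, self.individual):
            if not token or re.search(r"[_/\\\s]", token):
                raise NamingConventionError(
                    f"invalid sample token {token!r}: tokens are single words "
                    "with no underscore or path separator"
                )

    def __str__(self) -> str:  # "<POP>_<ID>"
        return f"{self.population}_{self.individual}"

    def filename(self, orientation: Orientation | None = None) -> str:
        orient = orientation or self.orientation
        if orient is None:
            raise ValueError("orientation required to build a file name")
        return f"{self}.{orient.value}.fq"


@dataclass
class SequenceRecord:
    """A named sequence over {A,C,G,T,N}, optionally with PHRED qualities."""

    id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not _VALID_SEQ.match(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise AlphabetError(
                f"record {self.id!r} contains non-ACGTN characters: {bad}"
            )
        if self.qualities is not None:
            if len(self.qualities) != len(self.sequence):
                raise FormatError(
                    f"record {self.id!r}: {len(self.qualities)} qualities for "
                    f"{len(self.sequence)} bases"
                )
            if any(q < 0 or q > 93 for q in self.qualities):
                raise FormatError(
                    f"record {self.id!r}: quality outside [0, 93] "
                    "(input must be PHRED+33)"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadPair:
    """One sequenced fragment: forward and reverse mates plus origin."""

    forward: SequenceRecord
    reverse: SequenceRecord
    sample: SampleName | None = None


@dataclass
class VariantRecord:
    """One VCF site with per-individual GT and DP.

    ``position`` is 1-based (VCF convention; this type lives at the I/O
    boundary). ``genotypes[i]`` is a tuple of allele indices or ``None``
    for a missing call; ``depths[i]`` is ``None`` wherever the genotype is
    missing.
    """

    contig: str
    position: int
    ref: str
    alts: list[str]
    qual: float
    genotypes: list[tuple[int, int] | None]
    depths: list[int | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.depths:
            self.depths = [None] * len(self.genotypes)
        if len(self.depths) != len(self.genotypes):
            raise FormatError(
                f"{self.contig}:{self.position}: {len(self.depths)} depths for "
                f"{len(self.genotypes)} genotypes"
            )
        # DP is meaningless without a call
        self.depths = [
            None if gt is None else dp for gt, dp in zip(self.genotypes, self.depths)
        ]

    @property
    def n_called(self) -> int:
        return sum(gt is not None for gt in self.genotypes)

    def is_snp(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alts) >= 1
            and all(len(a) == 1 and a in "ACGT" for a in self.alts)
        )


def parse_sample_name(filename: str | Path) -> SampleName:
    """Parse ``<POP>_<ID>.F.fq[.gz]`` (or ``.R.fq[.gz]``) into its parts.

    Exactly one underscore is allowed in the stem; anything else is a
    naming-convention error naming the offending file.
    """
    name = Path(filename).name
    m = _SUFFIX.search(name)
    if m is None:
        raise NamingConventionError(
            f"{name!r} does not end in .F.fq, .R.fq, .F.fq.gz or .R.fq.gz"
        )
    stem = name[: m.start()]
    if stem.count("_") != 1:
        raise NamingConventionError(
            f"{name!r}: expected exactly one underscore separating locality "
            "and individual (e.g. LOCA_IND01.F.fq)"
        )
    pop, ind = stem.split("_")
    orient = Orientation.FORWARD if m.group("orient") == "F" else Orientation.REVERSE
    try:
        return SampleName(pop, ind, orient)
    except NamingConventionError as exc:
        raise NamingConventionError(f"{name!r}: {exc}") from None


def _open_maybe_gzip(path: Path) -> IO[str]:
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream one FASTQ file (plain or gzipped) as SequenceRecords."""
    with _open_maybe_gzip(Path(path)) as handle:
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                yield SequenceRecord(
                    rec.id,
                    str(rec.seq).upper(),
                    list(rec.letter_annotations["phred_quality"]),
                )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> int:
    """Write PHRED+33 FASTQ; returns the record count."""
    n = 0
    with open(path, "w") as handle:
        for rec in records:
            if rec.qualities is None:
                raise FormatError(f"record {rec.id!r} has no qualities")
            out = SeqRecord(Seq(rec.sequence), id=rec.id, description="")
            out.letter_annotations["phred_quality"] = rec.qualities
            SeqIO.write(out, handle, "fastq")
            n += 1
    return n


def find_fastq_pairs(directory: str | Path) -> list[tuple[SampleName, Path, Path]]:
    """Locate matched F/R files for every sample in a directory."""
    directory = Path(directory)
    files: dict[tuple[str, str], dict[Orientation, Path]] = {}
    for path in sorted(directory.iterdir()):
        if _SUFFIX.search(path.name) is None:
            continue
        name = parse_sample_name(path.name)
        files.setdefault((name.population, name.individual), {})[
            name.orientation
        ] = path
    pairs = []
    for (pop, ind), by_orient in sorted(files.items()):
        missing = {Orientation.FORWARD, Orientation.REVERSE} - set(by_orient)
        if missing:
            raise PairingError(
                f"sample {pop}_{ind}: missing "
                + " and ".join(sorted(o.value for o in missing))
                + " file"
            )
        pairs.append(
            (
                SampleName(pop, ind),
                by_orient[Orientation.FORWARD],
                by_orient[Orientation.REVERSE],
            )
        )
    return pairs


def read_fastq_pairs(
    directory: str | Path,
) -> Iterator[tuple[SampleName, ReadPair]]:
    """Stream positionally paired reads for every sample in a directory.

    Yields pairs in file order, one sample after another. A forward file
    without a reverse mate raises :class:`PairingError`; files of unequal
    record count raise :class:`TruncationError`. An empty directory yields
    nothing, with a warning.
    """
    pairs = find_fastq_pairs(directory)
    if not pairs:
        warnings.warn(f"no FASTQ sample pairs found in {directory}", stacklevel=2)
        return
    sentinel = object()
    for sample, f_path, r_path in pairs:
        fwd_iter: Iterator = read_fastq(f_path)
        rev_iter: Iterator = read_fastq(r_path)
        while True:
            fwd = next(fwd_iter, sentinel)
            rev = next(rev_iter, sentinel)
            if fwd is sentinel and rev is sentinel:
                break
            if fwd is sentinel or rev is sentinel:
                short = f_path.name if fwd is sentinel else r_path.name
                raise TruncationError(
                    f"sample {sample}: {short} has fewer records than its mate"
                )
            yield sample, ReadPair(fwd, rev, sample)


def write_reference_fasta(loci: Sequence, path: str | Path) -> int:
    """Write assembled reference loci as 80-column-wrapped FASTA.

    Locus ids must be unique; they are expected to already carry the
    sequential ``dDocent_Contig_<n>`` form assigned at final clustering.
    """
    ids = [locus.id for locus in loci]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"duplicate reference ids: {dupes}")
    with open(path, "w") as handle:
        writer = FastaWriter(handle, wrap=80)
        writer.write_file(
            SeqRecord(Seq(locus.sequence), id=locus.id, description="")
            for locus in loci
        )
    return len(loci)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    return [
        SequenceRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]


# --- VCF ------------------------------------------------------------------

def _vcf_header(samples: Sequence[str], contigs: Iterable[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##source=radloci")
    for contig in contigs:
        header.contigs.add(contig)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    for sample in samples:
        header.add_sample(sample)
    return header


def write_vcf(
    records: Sequence[VariantRecord], samples: Sequence[str], path: str | Path
) -> int:
    """Write VCF v4.2 with GT and DP FORMAT fields."""
    contigs: list[str] = []
    for rec in records:
        if rec.contig not in contigs:
            contigs.append(rec.contig)
    header = _vcf_header(samples, contigs)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            if len(rec.genotypes) != len(samples):
                raise FormatError(
                    f"{rec.contig}:{rec.position}: {len(rec.genotypes)} genotypes "
                    f"for {len(samples)} samples"
                )
            row = out.new_record(
                contig=rec.contig,
                start=rec.position - 1,
                alleles=(rec.ref, *rec.alts),
                qual=round(rec.qual, 2),
            )
            for sample, gt, dp in zip(samples, rec.genotypes, rec.depths):
                if gt is None:
                    row.samples[sample]["GT"] = (None, None)
                else:
                    row.samples[sample]["GT"] = gt
                    if dp is not None:
                        row.samples[sample]["DP"] = dp
            out.write(row)
    return len(records)


def read_vcf(path: str | Path) -> tuple[list[str], list[VariantRecord]]:
    """Read a VCF with GT (and optionally DP) into VariantRecords."""
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    with vcf:
        if "GT" not in vcf.header.formats:
            raise FormatError(f"{path}: no GT FORMAT declared in header")
        samples = list(vcf.header.samples)
        records = []
        for row in vcf:
            genotypes: list[tuple[int, int] | None] = []
            depths: list[int | None] = []
            for sample in samples:
                call = row.samples[sample]
                gt = call.get("GT")
                if gt is None or any(a is None for a in gt):
                    genotypes.append(None)
                    depths.append(None)
                else:
                    genotypes.append(tuple(gt))  # type: ignore[arg-type]
                    depths.append(call.get("DP"))
            records.append(
                VariantRecord(
                    contig=row.contig,
                    position=row.pos,
                    ref=row.ref,
                    alts=list(row.alts or ()),
                    qual=float(row.qual) if row.qual is not None else 0.0,
                    genotypes=genotypes,
                    depths=depths,
                )
            )
    return samples, records
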