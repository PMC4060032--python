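"""Adapter removal and 3' quality trimming of paired reads.

RAD genotypers downstream weigh base qualities themselves, so trimming is
deliberately gentle: bases below PHRED 10 (a 10% error chance) are trimmed
from the 3' end using the BWA partial-sum rule, after any adapter
read-through has been clipped. Reads are never filtered wholesale on a
quality window — trimming preserves the high-quality prefix of every read.

Both operations only ever shorten the 3' end, so trimmed output is always
a prefix of the input and trimming is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

from .errors import FormatError
from .io_formats import ReadPair, SequenceRecord, read_fastq_pairs, write_fastq

# Illumina TruSeq common adapter stem; the published library preparation
# uses double-digest RAD adapters built on this chemistry. Configurable
# because adapter kits vary.
DEFAULT_ADAPTER = "AGATCGGAAGAGC"

MIN_ADAPTER_OVERLAP = 3


@dataclass(frozen=True)
class TrimConfig:
    """Trimming parameters.

    quality: PHRED threshold for the 3' partial-sum trim (default 10).
    adapter: sequence whose read-through is clipped from the 3' end.
    min_length: pairs with either mate shorter than this are dropped.
    max_error_rate: highest tolerated mismatch fraction in an adapter match.
    """

    quality: int = 10
    adapter: str = DEFAULT_ADAPTER
    min_length: int = 20
    max_error_rate: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.quality <= 93:
            raise ValueError(f"quality threshold {self.quality} outside (0, 93]")
        if not 0 <= self.max_error_rate < 0.5:
            raise ValueError(f"error rate {self.max_error_rate} outside [0, 0.5)")
        if self.min_length < 1:
            raise ValueError("minimum retained length must be >= 1")
        if not self.adapter:
            raise ValueError("adapter sequence must be non-empty")


def quality_trim(record: SequenceRecord, threshold: int) -> SequenceRecord:
    """Trim the 3' suffix maximizing sum(threshold - q) over trimmed bases.

    This is the partial-sum rule BWA introduced (`-q`): scan from the 3'
    end accumulating ``threshold - q``; cut at the position where the
    accumulated sum is maximal and positive. The 5' end is never touched;
    the result may be empty.
    """
    if record.qualities is None:
        raise FormatError(f"record {record.id!r} has no qualities to trim on")
    quals = record.qualities
    best, best_cut, acc = 0, len(quals), 0
    for i in range(len(quals) - 1, -1, -1):
        acc += threshold - quals[i]
        if acc > best:  # strict: ties keep the longer read
            best, best_cut = acc, i
    return replace(
        record, sequence=record.sequence[:best_cut], qualities=quals[:best_cut]
    )


def adapter_trim(
    record: SequenceRecord, adapter: str = DEFAULT_ADAPTER, max_error_rate: float = 0.1
) -> SequenceRecord:
    """Clip 3' adapter read-through.

    Considers every 3'-anchored alignment of a read suffix against an
    adapter prefix with overlap >= 3 and mismatch fraction <= the error
    rate; picks the one with the most matching bases, preferring the
    longest overlap on ties, and removes that suffix.
    """
    seq = record.sequence
    best_k, best_score = 0, -1
    for k in range(MIN_ADAPTER_OVERLAP, min(len(seq), len(adapter)) + 1):
        suffix = seq[len(seq) - k :]
        mismatches = sum(a != b for a, b in zip(suffix, adapter))
        if mismatches <= max_error_rate * k:
            score = k - mismatches
            if score >= best_score:  # >= prefers longest among equal scores
                best_k, best_score = k, score
    if best_k == 0:
        return record
    keep = len(seq) - best_k
    quals = record.qualities[:keep] if record.qualities is not None else None
    return replace(record, sequence=seq[:keep], qualities=quals)


def trim_read(record: SequenceRecord, config: TrimConfig) -> SequenceRecord:
    """Adapter clip then quality trim, iterated to a fixpoint.

    A quality cut can expose a new 3' end that itself looks like the
    start of the adapter (and vice versa), so one pass of the two trims
    composed is not idempotent. Iterating until nothing changes is —
    and each pass strictly shortens the read, so the loop terminates.
    """
    while True:
        out = adapter_trim(record, config.adapter, config.max_error_rate)
        out = quality_trim(out, config.quality)
        if len(out) == len(record):
            return out
        record = out


def trim_pair(pair: ReadPair, config: TrimConfig) -> ReadPair | None:
    """Trim both mates; drop the pair jointly if either ends up too short.

    Dropping both mates (never orphaning one) keeps files positionally
    paired for every downstream stage.
    """
    fwd = trim_read(pair.forward, config)
    rev = trim_read(pair.reverse, config)
    if len(fwd) < config.min_length or len(rev) < config.min_length:
        return None
    return ReadPair(fwd, rev, pair.sample)


def trim_directory(
    in_dir: str | Path, out_dir: str | Path, config: TrimConfig | None = None
) -> dict[str, dict[str, int]]:
    """Trim every sample in a directory, writing ``<POP>_<ID>.R1.fq``/``.R2.fq``.

    Returns per-sample counts of kept and dropped pairs.
    """
    config = config or TrimConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stats: dict[str, dict[str, int]] = {}
    by_sample: dict[str, list[ReadPair]] = {}
    for sample, pair in read_fastq_pairs(in_dir):
        by_sample.setdefault(str(sample), []).append(pair)
    for sample_id, pairs in by_sample.items():
        kept = [t for t in (trim_pair(p, config) for p in pairs) if t is not None]
        write_fastq((p.forward for p in kept), out_dir / f"{sample_id}.R1.fq")
        write_fastq((p.reverse for p in kept), out_dir / f"{sample_id}.R2.fq")
        stats[sample_id] = {"kept": len(kept), "dropped": len(pairs) - len(kept)}
    return stats
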