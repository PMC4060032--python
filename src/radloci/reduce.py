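"""Data reduction: composite reads, unique-read tallies, coverage cutoff.

Fixed-length RAD loci shared across many individuals produce exactly
matching read pairs at high multiplicity, while sequencing errors and
private polymorphisms appear once or twice. The reduction stage exploits
this: each pair is collapsed into a single *composite* sequence (forward
read concatenated with the reverse-complemented reverse read), composites
are tallied exactly over the whole data set, the occurrence distribution
is displayed as a 1X..50X cumulative curve, and only composites at or
above a user-chosen coverage cutoff enter assembly.

Reduction runs on *untrimmed* reads: exact matching requires full-length,
equal-length sequences, and assembly consensus absorbs the low-quality
tails that trimming would remove. (Trimmed reads are what downstream
mapping uses; that stage is outside this package.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import AlphabetError, EmptySelectionError, FormatError
from .io_formats import ReadPair

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ALPHABET = set("ACGTN")

DEFAULT_MAX_LEVEL = 50


def reverse_complement(sequence: str) -> str:
    """Reverse-complement over {A,C,G,T,N}; N maps to N."""
    if not _ALPHABET.issuperset(sequence):
        bad = sorted(set(sequence) - _ALPHABET)
        raise AlphabetError(f"non-ACGTN characters in sequence: {bad}")
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CompositeRead:
    """Forward sequence ++ revcomp(reverse sequence), split at |forward|."""

    sequence: str
    split: int

    def __post_init__(self) -> None:
        if not 0 < self.split < len(self.sequence):
            raise FormatError(
                f"split point {self.split} outside (0, {len(self.sequence)})"
            )

    @property
    def forward(self) -> str:
        return self.sequence[: self.split]

    @property
    def reverse(self) -> str:
        """The original reverse-read sequence (re-complemented back)."""
        return reverse_complement(self.sequence[self.split :])


def compose_pair(pair: ReadPair) -> CompositeRead:
    """Collapse a read pair into its composite sequence."""
    fwd, rev = pair.forward.sequence, pair.reverse.sequence
    if not fwd or not rev:
        raise FormatError("cannot compose a pair with an empty mate")
    return CompositeRead(fwd + reverse_complement(rev), len(fwd))


def decompose(composite: CompositeRead) -> tuple[str, str]:
    """Inverse of :func:`compose_pair`: (forward, reverse) sequences."""
    return composite.forward, composite.reverse


@dataclass
class UniqueReadTally:
    """Exact occurrence counts of unique composites over the data set."""

    counts: dict[str, int] = field(default_factory=dict)
    splits: dict[str, int] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    def add(self, composite: CompositeRead) -> None:
        seq = composite.sequence
        known = self.splits.get(seq)
        if known is not None and known != composite.split:
            raise FormatError(
                "identical composite sequence with two split points "
                f"({known} vs {composite.split}): input reads are not fixed-length"
            )
        self.splits[seq] = composite.split
        self.counts[seq] = self.counts.get(seq, 0) + 1


def tally_unique(composites: Iterable[CompositeRead]) -> UniqueReadTally:
    """Count every unique composite across all individuals pooled."""
    tally = UniqueReadTally()
    for composite in composites:
        tally.add(composite)
    return tally


def coverage_curve(tally: UniqueReadTally, max_level: int = DEFAULT_MAX_LEVEL) -> list[int]:
    """values[k-1] = number of unique composites with occurrence >= k.

    The curve is non-increasing; values[0] is the distinct-composite
    count. Occurrences above ``max_level`` accumulate into the last bin.
    """
    values = [0] * max_level
    for count in tally.counts.values():
        top = min(count, max_level)
        for k in range(top):
            values[k] += 1
    return values


def render_curve(values: Sequence[int], width: int = 60) -> str:
    """ASCII rendering of the coverage curve (level, count, bar)."""
    peak = max(values) if values and max(values) > 0 else 1
    lines = ["level  unique_reads"]
    for level, count in enumerate(values, start=1):
        bar = "#" * max(1 if count else 0, round(width * count / peak))
        lines.append(f"{level:>5}  {count:>12}  {bar}")
    return "\n".join(lines)


@dataclass(frozen=True)
class SelectedRead:
    """A unique composite that passed the coverage cutoff."""

    id: str
    forward: str
    reverse: str
    count: int


def select_by_cutoff(tally: UniqueReadTally, cutoff: int) -> list[SelectedRead]:
    """Keep composites with occurrence >= cutoff, split back into mates.

    Output order is deterministic (descending count, then sequence) and
    record ids encode the occurrence count (``uniq_<n>_cov_<c>``) so
    assembly can seed clusters by abundance.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    chosen = sorted(
        ((seq, c) for seq, c in tally.counts.items() if c >= cutoff),
        key=lambda item: (-item[1], item[0]),
    )
    if not chosen:
        raise EmptySelectionError(
            f"no unique reads reach {cutoff}X coverage; choose a lower cutoff"
        )
    selected = []
    for n, (seq, count) in enumerate(chosen, start=1):
        composite = CompositeRead(seq, tally.splits[seq])
        selected.append(
            SelectedRead(
                id=f"uniq_{n}_cov_{count}",
                forward=composite.forward,
                reverse=composite.reverse,
                count=count,
            )
        )
    return selected


def write_selected(
    selected: Sequence[SelectedRead], forward_path: str | Path, reverse_path: str | Path
) -> None:
    """Write selected unique reads as paired FASTA files."""
    with open(forward_path, "w") as fwd, open(reverse_path, "w") as rev:
        for read in selected:
            fwd.write(f">{read.id}\n{read.forward}\n")
            rev.write(f">{read.id}\n{read.reverse}\n")


def reduce_pairs(
    pairs: Iterable[ReadPair] | Iterator[ReadPair],
) -> UniqueReadTally:
    """Convenience: compose and tally a stream of read pairs."""
    return tally_unique(compose_pair(pair) for pair in pairs)
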