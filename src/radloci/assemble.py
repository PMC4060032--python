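"""De novo RAD-locus reference assembly.

Selected unique read pairs are turned into a reference in four steps:

1. *Forward clustering*: greedy seeded clustering of forward reads under a
   Hamming-distance bound (default 6 mismatches, raised from the usual 4
   to accommodate highly polymorphic species with large effective
   population sizes). Reads are processed in descending abundance; a read
   joins the first cluster whose seed is within the bound, else founds a
   new cluster.
2. *Recursive division*: each cluster is recursively split on
   reverse-read columns into groups approximating single alleles. A
   column splits the cluster when its second-most-common base is backed
   by enough reads (count >= 2 and frequency >= 0.2 by default) — enough
   to suppress singleton sequencing errors while separating real alleles.
3. *Per-cluster assembly*: each allele subcluster yields abundance-
   weighted majority consensuses of its forward and reverse reads; the
   candidate contig built from them that is longest represents the
   cluster (one reference sequence per RAD locus, not per allele).
4. *Contig construction and final clustering*: forward and reverse
   consensuses are merged into one contig — joined directly when they
   share an exact overlap of >= 10 bp, otherwise concatenated around a
   ten-N spacer standing in for the unsequenced middle of the fragment —
   and the resulting loci are clustered at 90% identity by default,
   longest first, keeping one representative per cluster.

Every tie (abundance, lexicographic, leftmost column, first matching
representative) is broken by a total order, so output is bit-reproducible
regardless of input order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FormatError, RadlociError
from .io_formats import write_reference_fasta
from .reduce import SelectedRead, reverse_complement

PADDING_LENGTH = 10


@dataclass(frozen=True)
class AssemblyConfig:
    max_mismatches: int = 6
    minor_count: int = 2
    minor_frequency: float = 0.2
    min_overlap: int = 10
    identity: float = 0.90
    padding: int = PADDING_LENGTH

    def __post_init__(self) -> None:
        if not 0 <= self.identity <= 1:
            raise ValueError("identity threshold must be in [0, 1]")
        if self.max_mismatches < 0 or self.min_overlap < 1:
            raise ValueError("invalid clustering/overlap parameters")


Member = tuple[str, str, int]  # (forward, reverse, abundance)


@dataclass
class LocusCluster:
    """Read pairs grouped by forward-read similarity.

    ``seed`` is the forward sequence of the founding member; every
    member's forward read is within the mismatch bound of it.
    ``subclusters`` (after division) is a flat partition of the members
    into putative single-allele groups.
    """

    id: int
    seed: str
    members: list[Member]
    subclusters: list["LocusCluster"] | None = None

    @property
    def abundance(self) -> int:
        return sum(count for _, _, count in self.members)


@dataclass
class ReferenceLocus:
    """An assembled reference contig for one RAD locus."""

    id: str
    sequence: str
    forward_length: int
    padded: bool
    source_cluster_id: int
    member_count: int


def _hamming_within(a: str, b: str, bound: int) -> bool:
    mismatches = 0
    for x, y in zip(a, b):
        if x != y:
            mismatches += 1
            if mismatches > bound:
                return False
    return True


def cluster_forward(
    members: Sequence[Member] | Sequence[SelectedRead], max_mismatches: int = 6
) -> list[LocusCluster]:
    """Greedy abundance-seeded clustering of forward reads.

    All forward reads must be equal length (the fixed-length RAD
    assumption); violating input raises rather than mis-clusters.
    """
    normalized: list[Member] = [
        (m.forward, m.reverse, m.count) if isinstance(m, SelectedRead) else tuple(m)
        for m in members
    ]
    lengths = {len(fwd) for fwd, _, _ in normalized}
    if len(lengths) > 1:
        raise FormatError(
            f"forward reads of unequal length {sorted(lengths)}: "
            "input is not fixed-length RAD data"
        )
    ordered = sorted(normalized, key=lambda m: (-m[2], m[0], m[1]))
    clusters: list[LocusCluster] = []
    for member in ordered:
        for cluster in clusters:
            if _hamming_within(member[0], cluster.seed, max_mismatches):
                cluster.members.append(member)
                break
        else:
            clusters.append(
                LocusCluster(id=len(clusters) + 1, seed=member[0], members=[member])
            )
    return clusters


def _division_column(members: list[Member]) -> tuple[int, int, int] | None:
    """Pick the reverse-read column with the strongest minor base.

    Returns (column, minor count, total weight), or None for width-0
    input. Ties between columns go to the leftmost.
    """
    width = len(members[0][1])
    if width == 0:
        return None
    best: tuple[int, int, int] | None = None
    total = sum(count for _, _, count in members)
    for col in range(width):
        tallies: dict[str, int] = {}
        for _, rev, count in members:
            tallies[rev[col]] = tallies.get(rev[col], 0) + count
        ranked = sorted(tallies.values(), reverse=True)
        minor = ranked[1] if len(ranked) > 1 else 0
        if best is None or minor > best[1]:
            best = (col, minor, total)
    return best


def divide_cluster(
    cluster: LocusCluster, minor_count: int = 2, minor_frequency: float = 0.2
) -> LocusCluster:
    """Recursively partition a cluster by reverse-read polymorphism.

    At each step the column whose second-most-common base (abundance-
    weighted) is largest drives the split, provided that minor count
    passes both thresholds; otherwise the group is a leaf allele.
    The returned cluster carries the flattened leaf partition in
    ``subclusters``.
    """
    widths = {len(rev) for _, rev, _ in cluster.members}
    if len(widths) > 1:
        raise FormatError("reverse reads of unequal length within a cluster")

    def split(members: list[Member]) -> list[list[Member]]:
        choice = _division_column(members)
        if choice is None:
            return [members]
        col, minor, total = choice
        if minor < minor_count or minor < minor_frequency * total:
            return [members]
        parts: dict[str, list[Member]] = {}
        for member in members:
            parts.setdefault(member[1][col], []).append(member)
        leaves: list[list[Member]] = []
        for base in sorted(parts):
            leaves.extend(split(parts[base]))
        return leaves

    leaves = split(list(cluster.members))
    subclusters = [
        LocusCluster(id=cluster.id, seed=cluster.seed, members=leaf)
        for leaf in leaves
    ]
    return replace(cluster, subclusters=subclusters)


def consensus(sequences: Sequence[tuple[str, int]]) -> str:
    """Column-wise abundance-weighted majority; ties to the alphabetically
    first base."""
    if not sequences:
        return ""
    width = len(sequences[0][0])
    if any(len(seq) != width for seq, _ in sequences):
        raise FormatError("consensus requires equal-length sequences")
    out = []
    for col in range(width):
        tallies: dict[str, int] = {}
        for seq, count in sequences:
            tallies[seq[col]] = tallies.get(seq[col], 0) + count
        out.append(max(sorted(tallies), key=lambda b: tallies[b]))
    return "".join(out)


def build_locus(
    forward_consensus: str,
    reverse_consensus: str,
    min_overlap: int = 10,
    cluster_id: int = 0,
    member_count: int = 0,
    padding: int = PADDING_LENGTH,
) -> ReferenceLocus:
    """Merge forward and reverse consensuses into one reference contig.

    The reverse consensus arrives in raw reverse-read orientation and is
    reverse-complemented first, so contigs read along the sequenced top
    strand. With 350-400 bp inserts and 100 bp reads the two ends almost
    never overlap; the ten-N spacer then marks the unsequenced middle.
    An exact suffix/prefix overlap of >= ``min_overlap`` instead merges
    the ends into a full contig with no padding.
    """
    if not forward_consensus or not reverse_consensus:
        raise FormatError("cannot build a locus from an empty consensus")
    tail = reverse_complement(reverse_consensus)
    limit = min(len(forward_consensus), len(tail))
    overlap = 0
    for k in range(limit, min_overlap - 1, -1):
        if forward_consensus[-k:] == tail[:k]:
            overlap = k
            break
    if overlap:
        sequence = forward_consensus + tail[overlap:]
        padded = False
    else:
        sequence = forward_consensus + "N" * padding + tail
        padded = True
    return ReferenceLocus(
        id=f"cluster_{cluster_id}",
        sequence=sequence,
        forward_length=len(forward_consensus),
        padded=padded,
        source_cluster_id=cluster_id,
        member_count=member_count,
    )


def assemble_cluster(
    cluster: LocusCluster, min_overlap: int = 10, padding: int = PADDING_LENGTH
) -> tuple[str, str]:
    """Choose the cluster's representative (forward, reverse) consensuses.

    Each allele subcluster proposes a candidate contig; the longest wins
    (ties: the more abundant subcluster, then first in division order).
    """
    if cluster.subclusters is None:
        raise RadlociError("cluster must be divided before assembly")
    best = None
    for index, sub in enumerate(cluster.subclusters):
        fwd = consensus([(m[0], m[2]) for m in sub.members])
        rev = consensus([(m[1], m[2]) for m in sub.members])
        contig = build_locus(
            fwd, rev, min_overlap, cluster.id, len(sub.members), padding
        )
        key = (-len(contig.sequence), -sub.abundance, index)
        if best is None or key < best[0]:
            best = (key, fwd, rev)
    assert best is not None
    return best[1], best[2]


# --- final identity clustering -------------------------------------------

def alignment_identity(a: str, b: str) -> float:
    """Fraction of the shorter sequence matched in a best global alignment.

    With match scored 1 and mismatches/gaps 0, the maximal number of
    aligned matching positions equals the longest common subsequence;
    dividing by the shorter length gives an identity in [0, 1].
    """
    if not a or not b:
        return 0.0
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    sa = np.frombuffer(short.encode(), dtype=np.uint8)
    sb = np.frombuffer(long_.encode(), dtype=np.uint8)
    prev = np.zeros(len(sa) + 1, dtype=np.int32)
    for ch in sb:
        curr = np.empty_like(prev)
        curr[0] = 0
        matched = prev[:-1] + (sa == ch)
        np.maximum(matched, prev[1:], out=curr[1:])
        np.maximum.accumulate(curr, out=curr)
        prev = curr
    return float(prev[-1]) / len(sa)


def cluster_reference(
    loci: Sequence[ReferenceLocus], identity: float = 0.90
) -> list[ReferenceLocus]:
    """Greedy longest-first identity clustering of assembled loci.

    Loci are sorted by length descending (ties lexicographic); each joins
    the first existing representative with identity >= the threshold,
    else becomes a representative itself. Representatives are renumbered
    ``dDocent_Contig_<n>`` sequentially.
    """
    ordered = sorted(loci, key=lambda l: (-len(l.sequence), l.sequence))
    representatives: list[ReferenceLocus] = []
    for locus in ordered:
        for rep in representatives:
            if alignment_identity(locus.sequence, rep.sequence) >= identity:
                break
        else:
            representatives.append(locus)
    return [
        replace(rep, id=f"dDocent_Contig_{n}")
        for n, rep in enumerate(representatives, start=1)
    ]


def assemble_reference(
    selected: Sequence[SelectedRead],
    config: AssemblyConfig | None = None,
    out_fasta: str | Path | None = None,
) -> list[ReferenceLocus]:
    """Run the full assembly: cluster, divide, assemble, pad, de-duplicate."""
    config = config or AssemblyConfig()
    if not selected:
        raise RadlociError("no selected reads to assemble")
    clusters = cluster_forward(selected, config.max_mismatches)
    loci = []
    for cluster in clusters:
        divided = divide_cluster(cluster, config.minor_count, config.minor_frequency)
        fwd, rev = assemble_cluster(divided, config.min_overlap, config.padding)
        loci.append(
            build_locus(
                fwd,
                rev,
                config.min_overlap,
                cluster.id,
                len(cluster.members),
                config.padding,
            )
        )
    reference = cluster_reference(loci, config.identity)
    if out_fasta is not None:
        write_reference_fasta(reference, out_fasta)
    return reference
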