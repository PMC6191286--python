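"""Detection of endogenous transcripts processed into RISC-loaded sRNAs.

The procedure is: pool replicate read sets and collapse identical
sequences, discard low-copy / out-of-range / ambiguous reads, keep only
reads with exactly one exact sense-strand placement across the whole
transcript set, and then count, per transcript, the distinct 5' start
positions of the retained reads.  Each distinct start position is a
"stack" — a pile of reads sharing one processing end point — and the
per-transcript stack count is the evidence that an mRNA is being diced
into RISC-loaded fragments rather than randomly degraded.

Expression-level context comes from a conventional long-RNA-seq count
table via an RPKM filter, so that stacks are only interpreted on genes
that are actually expressed.

Filter defaults follow the pipeline conventions used throughout the
package: copy number >= 10 summed across the pooled replicates, read
length within [15, 50] nt, no ambiguous bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import GeneCountTable, SmallRead, TranscriptSet
from .read_matching import AlignmentRecord, find_placements

__all__ = [
    "StackProfile",
    "AbundanceRecord",
    "pool_and_collapse",
    "filter_reads",
    "unique_map",
    "count_stacks",
    "rank_by_stacks",
    "rpkm",
    "rpkm_filter",
]


@dataclass
class StackProfile:
    """Per-transcript set of unique read 5' start positions.

    ``stacks`` maps each distinct 0-based start position to the number
    of distinct read sequences starting there and their summed copy
    count.  Reads of different length sharing a start fall into one
    stack: the 5' end, not the length, defines the stack.
    """

    transcript_id: str
    stacks: dict[int, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_stacks(self) -> int:
        return len(self.stacks)

    @property
    def total_count(self) -> int:
        return sum(total for _, total in self.stacks.values())


@dataclass
class AbundanceRecord:
    """Expression (RPKM) and RISC occupancy (RPM) of one gene."""

    gene_id: str
    rpkm: float
    risc_rpm: float | None = None


def pool_and_collapse(
    reads: Iterable[SmallRead], replicate_ids: Sequence[str] | None = None
) -> list[SmallRead]:
    """Pool replicates into one set and collapse identical sequences.

    Counts are kept per replicate but summed across duplicate sequence
    records, so total copy numbers are conserved.  With `replicate_ids`
    given, only those replicates' counts are pooled.
    """
    order: list[str] = []
    merged: dict[str, dict[str, int]] = {}
    for read in reads:
        items = read.counts.items()
        if replicate_ids is not None:
            items = [(r, c) for r, c in items if r in replicate_ids]
        if read.sequence not in merged:
            merged[read.sequence] = {}
            order.append(read.sequence)
        for rep, c in items:
            merged[read.sequence][rep] = merged[read.sequence].get(rep, 0) + c
    return [SmallRead(seq, merged[seq], "pooled") for seq in order]


def filter_reads(
    collapsed: Iterable[SmallRead],
    min_count: int = 10,
    min_len: int = 15,
    max_len: int = 50,
) -> list[SmallRead]:
    """Keep abundant, length-bounded, unambiguous reads.

    All thresholds are inclusive: a read of exactly `min_count` copies
    or exactly `min_len`/`max_len` nucleotides is retained; any read
    containing ``N`` is removed.
    """
    return [
        read
        for read in collapsed
        if read.total_count >= min_count
        and min_len <= len(read) <= max_len
        and "N" not in read.sequence
    ]


def unique_map(
    reads: Iterable[SmallRead], transcripts: TranscriptSet
) -> list[AlignmentRecord]:
    """Retain reads with exactly one exact placement in the transcript set.

    A read is dropped if it matches nowhere, more than once within a
    transcript, or in more than one transcript; the survivors carry
    their single sense-strand placement.
    """
    if len(transcripts) == 0:
        raise ValueError("empty transcript set")
    records: list[AlignmentRecord] = []
    for read in reads:
        hits: list[tuple[str, int]] = []
        for t in transcripts:
            for start in find_placements(read.sequence, t.sequence):
                hits.append((t.transcript_id, start))
                if len(hits) > 1:
                    break
            if len(hits) > 1:
                break
        if len(hits) == 1:
            tid, start = hits[0]
            records.append(
                AlignmentRecord(read, tid, start, start + len(read), 1)
            )
    return records


def count_stacks(alignments: Iterable[AlignmentRecord]) -> dict[str, StackProfile]:
    """Count distinct 5' start positions ("stacks") per transcript."""
    profiles: dict[str, StackProfile] = {}
    for aln in alignments:
        profile = profiles.setdefault(aln.transcript_id, StackProfile(aln.transcript_id))
        n, total = profile.stacks.get(aln.start, (0, 0))
        profile.stacks[aln.start] = (n + 1, total + aln.read.total_count)
    return profiles


def rank_by_stacks(
    profiles: Iterable[StackProfile], top_n: int = 10
) -> list[StackProfile]:
    """Top transcripts by stack count.

    Descending by ``n_stacks``; ties break by higher total copy count,
    then lexicographic transcript id so the ranking is deterministic.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    ranked = sorted(
        profiles,
        key=lambda p: (-p.n_stacks, -p.total_count, p.transcript_id),
    )
    return ranked[:top_n]


def rpkm(read_count: int, length_nt: int, library_size: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if length_nt <= 0:
        raise ValueError("transcript length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return read_count / (length_nt / 1000.0) / (library_size / 1e6)


def rpkm_filter(
    count_table: GeneCountTable,
    min_rpkm: float = 10.0,
    risc_counts: dict[str, int] | None = None,
) -> list[AbundanceRecord]:
    """Genes expressed at or above an RPKM threshold (default 10).

    Optionally annotates each retained gene with its RISC occupancy in
    reads per million, computed from `risc_counts` (Ago-bound read
    counts per gene) over their grand total.
    """
    risc_total = sum(risc_counts.values()) if risc_counts else 0
    records = []
    for gene_id, length_nt, read_count in zip(
        count_table.rows["gene_id"],
        count_table.rows["length_nt"],
        count_table.rows["read_count"],
    ):
        value = rpkm(int(read_count), int(length_nt), count_table.library_size)
        if value >= min_rpkm:
            risc_rpm = None
            if risc_counts is not None and risc_total > 0:
                risc_rpm = risc_counts.get(gene_id, 0) * 1e6 / risc_total
            records.append(AbundanceRecord(str(gene_id), value, risc_rpm))
    return records
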