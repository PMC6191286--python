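"""Exact-match placement of small-RNA reads on a target ORF.

Reads are retained only when they match the target with 100% identity
across their entire length, on the sense strand (the direction of
transcription); mismatch-tolerant alignment is deliberately out of
scope, because only perfect full-length hits enter any downstream
statistic.  A minimum read length (default 19 nt) stands in for the
e-value cutoff of a heuristic aligner, which at these read lengths only
discards very short perfect matches.

Overlapping or abutting placements are merged into cluster regions —
the intervals on the source mRNA that give rise to RISC-loaded
fragments — and read-length distributions of different fractions
(Ago-bound vs total small RNA) can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import SmallRead, Transcript

__all__ = [
    "AlignmentRecord",
    "ClusterRegion",
    "LengthDistribution",
    "FractionComparison",
    "find_placements",
    "match_reads_to_orf",
    "cluster_alignments",
    "length_distribution",
    "compare_fractions",
]


@dataclass
class AlignmentRecord:
    """A sense-strand, full-length exact placement of a read.

    Coordinates are 0-based half-open; ``end - start`` equals the read
    length and the transcript substring at ``[start, end)`` equals the
    read sequence exactly.
    """

    read: SmallRead
    transcript_id: str
    start: int
    end: int
    n_placements_on_target: int = 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ClusterRegion:
    """A merged interval of overlapping read placements on a transcript."""

    transcript_id: str
    start: int
    end: int
    n_reads: int
    total_count: int


@dataclass
class LengthDistribution:
    """Histogram of read lengths with count-weighted mean and modal peak."""

    histogram: dict[int, float]
    mean_length: float
    peak_length: int


@dataclass
class FractionComparison:
    """Ago-bound vs total fraction length-distribution contrast."""

    mean_difference: float
    peak_difference: int
    ks_statistic: float


def find_placements(sequence: str, target: str) -> list[int]:
    """All start offsets (possibly overlapping) of an exact sense match."""
    placements = []
    i = target.find(sequence)
    while i != -1:
        placements.append(i)
        i = target.find(sequence, i + 1)
    return placements


def match_reads_to_orf(
    reads: Iterable[SmallRead],
    orf_sequence: str | Transcript,
    min_len: int = 19,
    transcript_id: str | None = None,
) -> list[AlignmentRecord]:
    """Place reads on a single target ORF by full-length exact matching.

    One :class:`AlignmentRecord` is emitted per (read, placement); a
    read matching the target at several offsets yields several records,
    each carrying the total number of placements.  Reads shorter than
    `min_len`, containing ``N``, or without any exact placement are
    absent from the output.
    """
    if isinstance(orf_sequence, Transcript):
        if transcript_id is None:
            transcript_id = orf_sequence.transcript_id
        orf_sequence = orf_sequence.sequence
    if transcript_id is None:
        transcript_id = "orf"
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if not orf_sequence:
        raise ValueError("empty ORF sequence")

    records: list[AlignmentRecord] = []
    for read in reads:
        if len(read) < min_len or "N" in read.sequence:
            continue
        placements = find_placements(read.sequence, orf_sequence)
        for start in placements:
            records.append(
                AlignmentRecord(
                    read=read,
                    transcript_id=transcript_id,
                    start=start,
                    end=start + len(read),
                    n_placements_on_target=len(placements),
                )
            )
    return records


def cluster_alignments(
    alignments: Iterable[AlignmentRecord], gap: int = 0
) -> list[ClusterRegion]:
    """Merge read placements into cluster regions per transcript.

    Two placements belong to the same region when the gap between them
    is at most `gap` nucleotides; with the default ``gap=0`` intervals
    merge on overlap or abutment.  Output is sorted by (transcript_id,
    start) and independent of input order.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    by_transcript: dict[str, list[AlignmentRecord]] = {}
    for aln in alignments:
        by_transcript.setdefault(aln.transcript_id, []).append(aln)

    regions: list[ClusterRegion] = []
    for tid in sorted(by_transcript):
        alns = sorted(by_transcript[tid], key=lambda a: (a.start, a.end))
        current: list[AlignmentRecord] = []
        cur_end = -1
        for aln in alns:
            if current and aln.start <= cur_end + gap:
                current.append(aln)
                cur_end = max(cur_end, aln.end)
            else:
                if current:
                    regions.append(_make_region(tid, current))
                current = [aln]
                cur_end = aln.end
        if current:
            regions.append(_make_region(tid, current))
    return regions


def _make_region(tid: str, members: Sequence[AlignmentRecord]) -> ClusterRegion:
    return ClusterRegion(
        transcript_id=tid,
        start=min(a.start for a in members),
        end=max(a.end for a in members),
        n_reads=len(members),
        total_count=sum(a.read.total_count for a in members),
    )


def length_distribution(
    items: Iterable[SmallRead | AlignmentRecord],
    weight_mode: str = "raw_count",
    replicate: str | None = None,
) -> LengthDistribution:
    """Read-length histogram weighted by copy counts.

    Accepts either reads or alignment records (weighted by the read's
    counts in both cases).  ``weight_mode='rpm'`` rescales the weights
    to sum to 10^6.  With `replicate` set, only that replicate's counts
    contribute.  The peak is the modal length; ties break toward the
    shorter length so the reported peak is deterministic.
    """
    if weight_mode not in {"raw_count", "rpm"}:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")

    histogram: dict[int, float] = {}
    for item in items:
        read = item.read if isinstance(item, AlignmentRecord) else item
        if replicate is None:
            weight = read.total_count
        else:
            weight = read.counts.get(replicate, 0)
        if weight <= 0:
            continue
        length = len(read)
        histogram[length] = histogram.get(length, 0.0) + weight

    total = sum(histogram.values())
    if total == 0:
        raise ValueError("empty input: no weighted reads to build a distribution")
    if weight_mode == "rpm":
        histogram = {k: v * 1e6 / total for k, v in histogram.items()}
        total = 1e6

    mean_length = sum(k * v for k, v in histogram.items()) / total
    # argmax with ties broken toward the shorter length
    peak_length = min(
        histogram, key=lambda k: (-histogram[k], k)
    )
    return LengthDistribution(histogram, mean_length, peak_length)


def _weighted_ks(h1: dict[int, float], h2: dict[int, float]) -> float:
    """Sup-difference of the weighted empirical CDFs of two histograms."""
    t1 = sum(h1.values())
    t2 = sum(h2.values())
    c1 = c2 = 0.0
    d = 0.0
    for length in sorted(set(h1) | set(h2)):
        c1 += h1.get(length, 0.0) / t1
        c2 += h2.get(length, 0.0) / t2
        d = max(d, abs(c1 - c2))
    return d


def compare_fractions(
    ago_dist: LengthDistribution, total_dist: LengthDistribution
) -> FractionComparison:
    """Contrast the Ago-bound against the total-fraction length profile.

    Returns the Ago-minus-total differences of mean and peak length
    (negative when Ago-bound reads run shorter, the direction seen when
    RISC loading trims fragments) plus the two-sample KS statistic on
    the weighted length ECDFs.
    """
    return FractionComparison(
        mean_difference=ago_dist.mean_length - total_dist.mean_length,
        peak_difference=ago_dist.peak_length - total_dist.peak_length,
        ks_statistic=_weighted_ks(ago_dist.histogram, total_dist.histogram),
    )
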