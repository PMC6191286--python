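"""Readers and writers for the pipeline's external formats.

All coordinates are 0-based half-open throughout the package and in BED
output.  Sequences are normalized at parse time: uppercased, RNA ``U``
converted to DNA ``T``, and any character outside ``{A, C, G, T, N}``
rejected with a :class:`FormatError` naming the offending record.

Formats handled here:

* FASTA — transcript / ORF sequences (via Bio.SeqIO)
* FASTA / FASTQ / collapsed TSV — small-RNA read sets
* TSV — 6mer seed-viability tables and long-RNA-seq gene count tables
* BED6 — read placements and merged cluster regions on transcripts
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

__all__ = [
    "FormatError",
    "Transcript",
    "TranscriptSet",
    "SmallRead",
    "SeedViabilityTable",
    "GeneCountTable",
    "BedRecord",
    "read_fasta",
    "write_fasta",
    "read_reads",
    "write_collapsed_tsv",
    "write_bed",
    "write_clusters_bed",
    "read_bed",
    "read_viability_table",
    "write_viability_table",
    "read_gene_counts",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_sequence(seq: str, record_name: str = "<sequence>") -> str:
    """Uppercase, map U->T, and validate the alphabet of a sequence."""
    s = str(seq).upper().replace("U", "T")
    if not s:
        raise FormatError(f"record {record_name!r}: empty sequence")
    bad = set(s) - VALID_BASES
    if bad:
        raise FormatError(
            f"record {record_name!r}: invalid characters {sorted(bad)}"
        )
    return s


@dataclass(frozen=True)
class Transcript:
    """A single transcript (or ORF) sequence."""

    transcript_id: str
    sequence: str

    @property
    def length_nt(self) -> int:
        return len(self.sequence)


class TranscriptSet:
    """Ordered collection of transcripts with unique identifiers."""

    def __init__(self, entries: Iterable[Transcript | tuple[str, str]]):
        self._entries: list[Transcript] = []
        self._index: dict[str, Transcript] = {}
        for entry in entries:
            if not isinstance(entry, Transcript):
                tid, seq = entry
                entry = Transcript(tid, normalize_sequence(seq, tid))
            if entry.transcript_id in self._index:
                raise FormatError(
                    f"duplicate transcript id {entry.transcript_id!r}"
                )
            if not entry.sequence:
                raise FormatError(
                    f"record {entry.transcript_id!r}: empty sequence"
                )
            self._entries.append(entry)
            self._index[entry.transcript_id] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self._entries)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._index

    def __getitem__(self, transcript_id: str) -> Transcript:
        return self._index[transcript_id]

    @property
    def ids(self) -> list[str]:
        return [t.transcript_id for t in self._entries]


@dataclass
class SmallRead:
    """A collapsed small-RNA sequence with per-replicate copy counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("read sequence must be non-empty")
        for rep, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for replicate {rep!r}")

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.sequence)


class SeedViabilityTable:
    """Map from each 6mer seed to its average % cell viability.

    Keys are stored in the DNA alphabet (U->T normalized) so seeds
    extracted from either RNA- or DNA-alphabet reads look up cleanly.
    """

    def __init__(self, entries: Mapping[str, float]):
        normalized: dict[str, float] = {}
        for seed, v in entries.items():
            s = normalize_sequence(seed, seed)
            if len(s) != 6:
                raise FormatError(f"seed {seed!r} is not a 6mer")
            if not math.isfinite(float(v)):
                raise FormatError(f"seed {seed!r}: non-finite viability {v!r}")
            if s in normalized:
                raise FormatError(f"duplicate seed {seed!r}")
            normalized[s] = float(v)
        if len(normalized) > 4096:
            raise FormatError("more than 4096 seed entries")
        self.entries = normalized

    def viability(self, seed: str) -> float | None:
        """Return the % viability for a 6mer, or None if absent."""
        return self.entries.get(seed.upper().replace("U", "T"))

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, seed: str) -> bool:
        return self.viability(seed) is not None


@dataclass
class GeneCountTable:
    """Long-RNA-seq per-gene counts used for the RPKM expression filter."""

    rows: pd.DataFrame  # columns: gene_id, length_nt, read_count
    library_size: int

    def __post_init__(self) -> None:
        required = {"gene_id", "length_nt", "read_count"}
        missing = required - set(self.rows.columns)
        if missing:
            raise FormatError(f"gene count table missing columns {sorted(missing)}")
        if self.library_size <= 0:
            raise FormatError("library_size must be positive")
        if (self.rows["length_nt"] < 1).any():
            raise FormatError("gene lengths must be >= 1 nt")
        if (self.rows["read_count"] < 0).any():
            raise FormatError("read counts must be non-negative")
        if self.library_size < int(self.rows["read_count"].sum()):
            raise FormatError("library_size smaller than sum of assigned reads")


class BedRecord(NamedTuple):
    """One BED6 line: a placement interval on a transcript."""

    transcript_id: str
    start: int
    end: int
    name: str
    score: int
    strand: str


# ---------------------------------------------------------------------------
# FASTA / FASTQ / TSV readers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> TranscriptSet:
    """Read a FASTA file of transcript/ORF sequences.

    Sequences are uppercased and U->T converted; duplicate identifiers or
    empty sequences raise :class:`FormatError` naming the record.
    """
    entries = []
    for record in SeqIO.parse(str(path), "fasta"):
        entries.append((record.id, normalize_sequence(record.seq, record.id)))
    return TranscriptSet(entries)


def write_fasta(transcripts: TranscriptSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.transcript_id}\n")
            for i in range(0, len(t.sequence), width):
                fh.write(t.sequence[i : i + width] + "\n")


def read_reads(
    path: str | Path,
    format: str,
    sample_id: str = "",
    replicate_id: str = "rep1",
) -> list[SmallRead]:
    """Read a small-RNA read set, collapsing identical sequences.

    Parameters
    ----------
    format
        One of ``fasta``, ``fastq``, ``collapsed_tsv``.  FASTA/FASTQ
        records each contribute one copy to `replicate_id`; quality
        strings are discarded.  A collapsed TSV must carry the columns
        ``sequence``, ``replicate_id``, ``count``.
    """
    if format not in {"fasta", "fastq", "collapsed_tsv"}:
        raise ValueError(f"unknown read format {format!r}")

    order: list[str] = []
    counts: dict[str, dict[str, int]] = {}

    def add(seq: str, rep: str, n: int) -> None:
        if seq not in counts:
            counts[seq] = {}
            order.append(seq)
        counts[seq][rep] = counts[seq].get(rep, 0) + n

    if format in {"fasta", "fastq"}:
        try:
            for record in SeqIO.parse(str(path), format):
                add(normalize_sequence(record.seq, record.id), replicate_id, 1)
        except ValueError as exc:  # Bio.SeqIO signals seq/qual mismatch etc.
            raise FormatError(str(exc)) from exc
    else:
        try:
            df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "replicate_id": str})
        except pd.errors.EmptyDataError:
            return []
        required = {"sequence", "replicate_id", "count"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"collapsed TSV missing columns {sorted(missing)}")
        for seq, rep, n in zip(df["sequence"], df["replicate_id"], df["count"]):
            n = int(n)
            if n < 0:
                raise FormatError(f"negative count for read {seq!r}")
            add(normalize_sequence(seq, seq), str(rep), n)

    return [SmallRead(seq, counts[seq], sample_id) for seq in order]


def write_collapsed_tsv(reads: Sequence[SmallRead], path: str | Path) -> None:
    """Write reads as a collapsed TSV (sequence, replicate_id, count)."""
    rows = []
    for read in reads:
        for rep in sorted(read.counts):
            rows.append((read.sequence, rep, read.counts[rep]))
    df = pd.DataFrame(rows, columns=["sequence", "replicate_id", "count"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def write_bed(alignments: Iterable, path: str | Path) -> None:
    """Write read placements as BED6 (name = read sequence, score = count)."""
    with open(path, "w") as fh:
        for aln in alignments:
            fh.write(
                f"{aln.transcript_id}\t{aln.start}\t{aln.end}\t"
                f"{aln.read.sequence}\t{aln.read.total_count}\t+\n"
            )


def write_clusters_bed(regions: Iterable, path: str | Path) -> None:
    """Write merged cluster regions as BED6 (score = total read count)."""
    with open(path, "w") as fh:
        for i, region in enumerate(regions, start=1):
            fh.write(
                f"{region.transcript_id}\t{region.start}\t{region.end}\t"
                f"cluster_{i}\t{region.total_count}\t+\n"
            )


def read_bed(path: str | Path) -> list[BedRecord]:
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise FormatError(f"line {line_no}: expected 6 BED columns")
            tid, start, end, name, score, strand = fields
            records.append(
                BedRecord(tid, int(start), int(end), name, int(score), strand)
            )
    return records


# ---------------------------------------------------------------------------
# Seed-viability and gene-count tables
# ---------------------------------------------------------------------------

def read_viability_table(path: str | Path) -> SeedViabilityTable:
    """Read a TSV seed-viability table.

    The first column must be ``seed``.  With a single numeric column the
    values are used as-is; with two numeric columns (e.g. viability
    measured in two cell lines) the per-seed average is stored.
    """
    df = pd.read_csv(path, sep="\t")
    if "seed" not in df.columns:
        raise FormatError("viability table missing 'seed' column")
    value_cols = [c for c in df.columns if c != "seed"]
    if not value_cols or len(value_cols) > 2:
        raise FormatError(
            "viability table needs one or two value columns, "
            f"found {value_cols!r}"
        )
    values = df[value_cols].mean(axis=1)
    return SeedViabilityTable(dict(zip(df["seed"], values)))


def write_viability_table(table: SeedViabilityTable, path: str | Path) -> None:
    df = pd.DataFrame(
        sorted(table.entries.items()), columns=["seed", "viability_percent"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_counts(path: str | Path, library_size: int | None = None) -> GeneCountTable:
    """Read a gene count TSV (gene_id, length_nt, read_count).

    When `library_size` is omitted it defaults to the sum of the count
    column, i.e. all mapped reads are assumed to be in the table.
    """
    df = pd.read_csv(path, sep="\t")
    if library_size is None:
        library_size = int(df["read_count"].sum())
    return GeneCountTable(df, library_size)
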