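"""Simulated Ago-bound / total small-RNA experiments with planted truth.

The generator emulates the study conditions the downstream analyses are
built for: a small transcriptome with planted processing clusters on
each transcript, reads sampled from those clusters as exact sense-strand
substrings, a length-distribution shift between the Ago-bound fraction
(peak ~20 nt, trimmed during RISC loading) and the total small-RNA
fraction (peak ~23 nt), a miRNA-like background population whose share
of the library distinguishes a wild-type regime (miRNAs dominate the
RISC) from a Drosha-knockout-like regime (miRNAs scarce, mRNA fragments
prominent), replicate structure, and background-read seeds drawn from
configurable viability bins.

Every stochastic draw flows from one integer seed, so identical configs
produce byte-identical outputs; a :class:`GroundTruth` records the
origin of every emitted read so recovery can be asserted exactly.

What the generator does *not* emulate: sequencing errors, quality
scores, adapter contamination, or genome-scale context.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import SmallRead, Transcript, TranscriptSet
from .seed_toxicity import viability_bin
from .io_formats import SeedViabilityTable

__all__ = [
    "ConfigError",
    "GenerationError",
    "SimulationConfig",
    "GroundTruth",
    "DEFAULT_VIABILITY_MIXTURE",
    "generate_transcriptome",
    "generate_viability_table",
    "planted_clusters_for",
    "simulate_reads",
    "write_reads_fastq",
    "simulate_experiment",
    "recode_synonymously",
]

BASES = np.array(list("ACGT"))
MIN_READ_LEN = 15
MAX_READ_LEN = 50
UNIQUE_KMER = 15  # no >=15-nt substring is shared anywhere in the transcriptome

# Mixture over the six viability bins used when synthesizing a seed screen:
# weights chosen so every bin is well populated, with most seeds in the
# mid-viability range and tails below 20% and above 100%, as a genome-wide
# seed screen shows.
DEFAULT_VIABILITY_MIXTURE = (0.12, 0.15, 0.21, 0.22, 0.18, 0.12)

# Value range (% viability) drawn uniformly within each bin.
_BIN_RANGES = ((2.0, 20.0), (20.0, 40.0), (40.0, 60.0), (60.0, 80.0), (80.0, 100.0), (100.0, 130.0))


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


class GenerationError(RuntimeError):
    """Raised when bounded rejection sampling cannot satisfy a constraint."""


@dataclass
class SimulationConfig:
    """Parameters of one simulated small-RNA experiment.

    Defaults describe the regime the pipeline targets: Ago-bound reads
    peaking at 20 nt against a 23-nt total fraction, duplicate
    libraries, and a Drosha-knockout-like background share (34% of
    RISC content being miRNA); set ``mirna_fraction=0.984`` for a
    wild-type-like RISC.
    """

    seed: int = 0
    n_transcripts: int = 3
    transcript_length_range: tuple[int, int] = (400, 900)
    planted_clusters: list[list[tuple[int, int]]] | None = None
    n_clusters_per_transcript: int = 3
    cluster_length: int = 60
    reads_per_cluster: int = 50
    ago_length_mean: float = 20.0
    total_length_mean: float = 23.0
    length_sd: float = 1.5
    mirna_fraction: float = 0.34
    n_background_reads: int = 1000
    n_replicates: int = 2
    seed_bin_mixture: tuple[float, ...] = (0.25, 0.20, 0.15, 0.15, 0.15, 0.10)
    mirna_pool_size: int = 50

    def __post_init__(self) -> None:
        lo, hi = self.transcript_length_range
        if not (0 < lo <= hi):
            raise ConfigError("invalid transcript_length_range")
        if not 0.0 <= self.mirna_fraction <= 1.0:
            raise ConfigError("mirna_fraction must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ConfigError("need at least one replicate")
        if len(self.seed_bin_mixture) != 6:
            raise ConfigError("seed_bin_mixture needs exactly 6 weights")
        if any(w < 0 for w in self.seed_bin_mixture):
            raise ConfigError("seed_bin_mixture weights must be non-negative")
        if abs(sum(self.seed_bin_mixture) - 1.0) > 1e-9:
            raise ConfigError("seed_bin_mixture must sum to 1 within 1e-9")
        if self.reads_per_cluster < 0:
            raise ConfigError("reads_per_cluster must be >= 0")


@dataclass
class GroundTruth:
    """Origin of every simulated read plus the planted structure.

    ``origins`` maps each unique read sequence either to its exact
    placement ``("cluster", transcript_id, start, end)`` or to
    ``("mirna_background", bin_index)``.  ``distinct_starts`` holds, per
    transcript, the 5' start positions actually drawn (the planted stack
    structure); ``bin_counts`` the per-viability-bin occurrence counts of
    background reads.
    """

    fraction: str
    origins: dict[str, tuple] = field(default_factory=dict)
    clusters: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    distinct_starts: dict[str, list[int]] = field(default_factory=dict)
    bin_counts: list[int] = field(default_factory=lambda: [0] * 6)
    n_cluster_occurrences: int = 0
    n_background_occurrences: int = 0

    def n_clusters(self, transcript_id: str) -> int:
        return len(self.clusters.get(transcript_id, []))

    def to_dict(self) -> dict:
        return {
            "fraction": self.fraction,
            "origins": {seq: list(origin) for seq, origin in self.origins.items()},
            "clusters": {t: [list(c) for c in cs] for t, cs in self.clusters.items()},
            "distinct_starts": self.distinct_starts,
            "bin_counts": self.bin_counts,
            "n_cluster_occurrences": self.n_cluster_occurrences,
            "n_background_occurrences": self.n_background_occurrences,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _kmers(sequence: str, k: int) -> set[str]:
    return {sequence[i : i + k] for i in range(len(sequence) - k + 1)}


def generate_transcriptome(config: SimulationConfig) -> TranscriptSet:
    """Random transcripts with globally unique 15-mers.

    Uniform random bases; rejection sampling guarantees that no 15-nt
    substring occurs twice anywhere in the transcriptome (across *or*
    within transcripts), so every read of >=15 nt drawn from a
    transcript has exactly one exact placement and unique-mapping logic
    is testable against ground truth.
    """
    rng = np.random.default_rng([config.seed, 10])
    lo, hi = config.transcript_length_range
    seen_kmers: set[str] = set()
    entries: list[Transcript] = []
    for i in range(config.n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        for _attempt in range(100):
            candidate = _random_sequence(rng, length)
            kmers = _kmers(candidate, UNIQUE_KMER)
            # uniqueness within the candidate itself, then against the rest
            if len(kmers) == length - UNIQUE_KMER + 1 and not (kmers & seen_kmers):
                seen_kmers |= kmers
                entries.append(Transcript(f"t{i + 1}", candidate))
                break
        else:
            raise GenerationError(
                f"could not generate transcript {i + 1} with unique 15-mers"
            )
    return TranscriptSet(entries)


def generate_viability_table(
    seed: int, mixture: Sequence[float] = DEFAULT_VIABILITY_MIXTURE
) -> SeedViabilityTable:
    """Synthetic stand-in for a 4096-seed viability screen.

    All 4096 DNA 6mers are present.  Per-bin seed counts follow the
    mixture exactly (largest-remainder apportionment), so every bin is
    populated by construction, spanning values below 20% and above 100%;
    values are drawn uniformly within each bin's range.
    """
    if len(mixture) != 6 or any(w < 0 for w in mixture):
        raise ValueError("mixture must be 6 non-negative weights")
    total_w = float(sum(mixture))
    if total_w <= 0:
        raise ValueError("mixture must have positive mass")

    rng = np.random.default_rng([seed, 11])
    all_seeds = ["".join(p) for p in itertools.product("ACGT", repeat=6)]
    order = rng.permutation(len(all_seeds))

    # largest-remainder apportionment of 4096 seeds over the six bins
    quotas = [w / total_w * len(all_seeds) for w in mixture]
    counts = [int(math.floor(q)) for q in quotas]
    remainders = sorted(
        range(6), key=lambda b: (quotas[b] - counts[b]), reverse=True
    )
    for b in remainders[: len(all_seeds) - sum(counts)]:
        counts[b] += 1

    entries: dict[str, float] = {}
    cursor = 0
    for b, n in enumerate(counts):
        lo, hi = _BIN_RANGES[b]
        for j in range(n):
            seed_6mer = all_seeds[order[cursor + j]]
            entries[seed_6mer] = float(rng.uniform(lo, hi))
        cursor += n
    return SeedViabilityTable(entries)


def planted_clusters_for(
    config: SimulationConfig, transcripts: TranscriptSet
) -> dict[str, list[tuple[int, int]]]:
    """Planted cluster intervals per transcript, identical across fractions.

    Explicit ``config.planted_clusters`` (one interval list per
    transcript, in transcript order) is validated and used as given;
    otherwise clusters of ``cluster_length`` nt are auto-placed, one per
    equal segment of the transcript, separated by at least one
    nucleotide so gap-0 merging can never fuse neighbours.
    """
    result: dict[str, list[tuple[int, int]]] = {}
    if config.planted_clusters is not None:
        if len(config.planted_clusters) != len(transcripts):
            raise ConfigError(
                "planted_clusters must list intervals for every transcript"
            )
        for t, intervals in zip(transcripts, config.planted_clusters):
            validated = []
            for start, end in intervals:
                if not (0 <= start < end <= t.length_nt):
                    raise ConfigError(
                        f"cluster ({start}, {end}) outside transcript "
                        f"{t.transcript_id!r} bounds"
                    )
                if end - start < MIN_READ_LEN:
                    raise ConfigError(
                        f"cluster ({start}, {end}) shorter than the minimum "
                        f"read length ({MIN_READ_LEN} nt)"
                    )
                validated.append((int(start), int(end)))
            result[t.transcript_id] = sorted(validated)
        return result

    rng = np.random.default_rng([config.seed, 12])
    n = config.n_clusters_per_transcript
    clen = config.cluster_length
    if clen < MIN_READ_LEN:
        raise ConfigError(
            f"cluster_length {clen} shorter than the minimum read length"
        )
    for t in transcripts:
        segment = t.length_nt // n
        if segment < clen + 2:
            raise ConfigError(
                f"transcript {t.transcript_id!r} too short for "
                f"{n} clusters of {clen} nt"
            )
        intervals = []
        for k in range(n):
            seg_start = k * segment
            offset = int(rng.integers(1, segment - clen))
            intervals.append((seg_start + offset, seg_start + offset + clen))
        result[t.transcript_id] = intervals
    return result


def _draw_length(rng: np.random.Generator, mean: float, sd: float) -> int:
    length = int(round(rng.normal(mean, sd)))
    return max(MIN_READ_LEN, min(MAX_READ_LEN, length))


def _build_mirna_pool(
    config: SimulationConfig,
    transcripts: TranscriptSet,
    table: SeedViabilityTable,
    rng: np.random.Generator,
    length_mean: float,
) -> list[tuple[str, int]]:
    """Synthetic miRNA-like sequences, each carrying a seed from one bin.

    Returns (sequence, bin_index) pairs.  Pool sizes per bin follow the
    configured mixture (at least one member per nonzero-weight bin);
    every sequence is checked absent from the whole transcriptome so
    background reads exercise the non-transcript code paths.
    """
    seeds_by_bin: dict[int, list[str]] = {b: [] for b in range(6)}
    for seed_6mer, v in table.entries.items():
        seeds_by_bin[viability_bin(v)].append(seed_6mer)
    for b in range(6):
        seeds_by_bin[b].sort()

    weights = np.asarray(config.seed_bin_mixture, dtype=float)
    quotas = weights * config.mirna_pool_size
    counts = np.floor(quotas).astype(int)
    counts[(weights > 0) & (counts == 0)] = 1
    order = np.argsort(-(quotas - np.floor(quotas)))
    shortfall = config.mirna_pool_size - int(counts.sum())
    for b in order:
        if shortfall <= 0:
            break
        if weights[b] > 0:
            counts[b] += 1
            shortfall -= 1

    pool: list[tuple[str, int]] = []
    seen: set[str] = set()
    for b in range(6):
        if counts[b] == 0:
            continue
        if not seeds_by_bin[b]:
            raise GenerationError(
                f"viability table has no seeds in bin {b + 1}; cannot draw "
                "background reads from the configured mixture"
            )
        for _ in range(int(counts[b])):
            for _attempt in range(100):
                length = _draw_length(rng, length_mean, config.length_sd)
                seed_6mer = seeds_by_bin[b][int(rng.integers(len(seeds_by_bin[b])))]
                seq = (
                    _random_sequence(rng, 1)
                    + seed_6mer
                    + _random_sequence(rng, length - 7)
                )
                in_transcriptome = any(seq in t.sequence for t in transcripts)
                if seq not in seen and not in_transcriptome:
                    pool.append((seq, b))
                    seen.add(seq)
                    break
            else:
                raise GenerationError("could not build a disjoint miRNA pool")
    return pool


def simulate_reads(
    config: SimulationConfig,
    transcripts: TranscriptSet,
    fraction: str,
    viability_table: SeedViabilityTable | None = None,
) -> tuple[list[SmallRead], GroundTruth]:
    """Simulate one fraction's collapsed read set with full ground truth.

    ``fraction`` selects the length regime: ``"ago"`` uses
    ``ago_length_mean`` (RISC-trimmed), ``"total"`` ``total_length_mean``.
    Cluster reads are exact sense-strand substrings at placements drawn
    uniformly inside each planted cluster; lengths are a discretized
    Normal clipped to [15, 50] nt (and to the cluster length).  A
    ``mirna_fraction`` share of the library comes from a disjoint
    miRNA-like pool whose seeds follow ``seed_bin_mixture``.  Occurrence
    counts are split over replicates multinomially.
    """
    if fraction not in {"ago", "total"}:
        raise ValueError("fraction must be 'ago' or 'total'")
    clusters = planted_clusters_for(config, transcripts)
    length_mean = (
        config.ago_length_mean if fraction == "ago" else config.total_length_mean
    )
    rng = np.random.default_rng([config.seed, 0 if fraction == "ago" else 1])

    truth = GroundTruth(fraction=fraction, clusters=clusters)
    order: list[str] = []
    occurrence_counts: dict[str, int] = {}

    def emit(seq: str, origin: tuple) -> None:
        if seq not in occurrence_counts:
            occurrence_counts[seq] = 0
            order.append(seq)
            truth.origins[seq] = origin
        occurrence_counts[seq] += 1

    starts: dict[str, set[int]] = {tid: set() for tid in clusters}
    for t in transcripts:
        for cs, ce in clusters.get(t.transcript_id, []):
            for _ in range(config.reads_per_cluster):
                length = min(_draw_length(rng, length_mean, config.length_sd), ce - cs)
                start = cs + int(rng.integers(0, ce - cs - length + 1))
                seq = t.sequence[start : start + length]
                emit(seq, ("cluster", t.transcript_id, start, start + length))
                starts[t.transcript_id].add(start)
                truth.n_cluster_occurrences += 1

    n_cluster = truth.n_cluster_occurrences
    f = config.mirna_fraction
    if f >= 1.0 and n_cluster > 0:
        raise ConfigError(
            "mirna_fraction 1.0 is inconsistent with reads_per_cluster > 0"
        )
    if n_cluster > 0 and f < 1.0:
        n_background = int(round(n_cluster * f / (1.0 - f)))
    else:
        n_background = config.n_background_reads if f > 0 else 0

    if n_background > 0:
        if viability_table is None:
            viability_table = generate_viability_table(config.seed)
        pool = _build_mirna_pool(config, transcripts, viability_table, rng, length_mean)
        members_by_bin: dict[int, list[str]] = {}
        for seq, b in pool:
            members_by_bin.setdefault(b, []).append(seq)
        bins = sorted(members_by_bin)
        probs = np.asarray([config.seed_bin_mixture[b] for b in bins], dtype=float)
        probs = probs / probs.sum()
        for _ in range(n_background):
            b = bins[int(rng.choice(len(bins), p=probs))]
            members = members_by_bin[b]
            seq = members[int(rng.integers(len(members)))]
            emit(seq, ("mirna_background", b))
            truth.bin_counts[b] += 1
            truth.n_background_occurrences += 1

    truth.distinct_starts = {
        tid: sorted(positions) for tid, positions in starts.items()
    }

    replicate_ids = [f"rep{i + 1}" for i in range(config.n_replicates)]
    probs = np.full(config.n_replicates, 1.0 / config.n_replicates)
    reads: list[SmallRead] = []
    for seq in order:
        split = rng.multinomial(occurrence_counts[seq], probs)
        counts = {rep: int(c) for rep, c in zip(replicate_ids, split)}
        reads.append(SmallRead(seq, counts, sample_id=fraction))
    return reads, truth


def write_reads_fastq(
    reads: Sequence[SmallRead], path: str | Path, replicate: str
) -> None:
    """Expand one replicate's collapsed counts into a plain FASTQ file.

    Quality strings are uniform placeholders (the generator has no error
    model); record ids are deterministic, so identical inputs produce
    byte-identical files.
    """
    with open(path, "w") as fh:
        serial = 0
        for i, read in enumerate(reads):
            for _copy in range(read.counts.get(replicate, 0)):
                serial += 1
                fh.write(
                    f"@sim_{replicate}_{serial}_u{i}\n{read.sequence}\n+\n"
                    f"{'I' * len(read.sequence)}\n"
                )


def recode_synonymously(sequence: str, seed: int) -> str:
    """Silently recode an ORF: swap each codon for a random synonym.

    Emulates a codon-recoded ("silent") construct that preserves the
    protein while maximally perturbing the nucleotide sequence: every
    codon with at least one synonym is replaced by a randomly chosen
    different synonymous codon; single-codon amino acids, stop codons
    and any trailing partial codon are left unchanged.
    """
    from Bio.Data.CodonTable import standard_dna_table

    forward = standard_dna_table.forward_table
    by_aa: dict[str, list[str]] = {}
    for codon, aa in forward.items():
        by_aa.setdefault(aa, []).append(codon)

    rng = np.random.default_rng([seed, 13])
    sequence = sequence.upper().replace("U", "T")
    out: list[str] = []
    for i in range(0, len(sequence) - len(sequence) % 3, 3):
        codon = sequence[i : i + 3]
        aa = forward.get(codon)
        if aa is None:
            out.append(codon)
            continue
        synonyms = sorted(c for c in by_aa[aa] if c != codon)
        out.append(synonyms[int(rng.integers(len(synonyms)))] if synonyms else codon)
    out.append(sequence[len(sequence) - len(sequence) % 3 :])
    return "".join(out)


def simulate_experiment(
    config: SimulationConfig, outdir: str | Path
) -> dict[str, Path]:
    """Generate and write a complete two-fraction experiment.

    Writes the transcriptome FASTA, the synthetic viability table, one
    collapsed-read TSV and one ground-truth JSON per fraction.  Returns
    the mapping of logical names to paths.
    """
    from .io_formats import write_collapsed_tsv, write_fasta, write_viability_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts = generate_transcriptome(config)
    table = generate_viability_table(config.seed)

    paths: dict[str, Path] = {}
    paths["transcriptome"] = outdir / "transcriptome.fasta"
    write_fasta(transcripts, paths["transcriptome"])
    paths["viability_table"] = outdir / "viability.tsv"
    write_viability_table(table, paths["viability_table"])

    for fraction in ("ago", "total"):
        reads, truth = simulate_reads(config, transcripts, fraction, table)
        reads_path = outdir / f"reads_{fraction}.tsv"
        truth_path = outdir / f"ground_truth_{fraction}.json"
        write_collapsed_tsv(reads, reads_path)
        truth.write_json(truth_path)
        paths[f"reads_{fraction}"] = reads_path
        paths[f"ground_truth_{fraction}"] = truth_path
    return paths
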