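"""6mer seed toxicity scoring of RISC-bound small RNAs.

The seed — positions 2-7 of the guide strand — is the minimal
determinant of miRNA-like targeting, and a prior screen of all 4096
possible 6mer seeds measured the % cell viability each one leaves
behind.  This module looks up each read's seed in such a table,
aggregates read abundance (RPM) into six viability bins, and compares
the full sliding-window 6mer content of two sequences (e.g. a wild-type
ORF against a recoded variant) with a two-sample Kolmogorov-Smirnov
test on their viability profiles.

Bin boundaries (% viability): (1) <20, (2) 20-40, (3) 40-60, (4) 60-80,
(5) 80-100 inclusive, (6) >100.  A seed with viability exactly 100 falls
in bin 5; anything above 100 (reads that *promote* growth relative to
control) in bin 6.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .io_formats import SeedViabilityTable, SmallRead

__all__ = [
    "SeedUndefinedError",
    "BIN_LABELS",
    "SeedBinSummary",
    "SequenceToxicityProfile",
    "extract_seed",
    "viability_bin",
    "rpm_normalize",
    "aggregate_seed_toxicity",
    "sequence_6mer_profile",
    "compare_sequence_toxicity",
]

BIN_LABELS = ("<20%", "20-40%", "40-60%", "60-80%", "80-100%", ">100%")


class SeedUndefinedError(ValueError):
    """Raised when a read is too short to carry a 6mer seed."""


@dataclass
class SeedBinSummary:
    """RPM of RISC-bound reads aggregated into six seed-viability bins."""

    rpm_per_bin: list[float]
    unmatched_rpm: float

    @property
    def total_rpm(self) -> float:
        return sum(self.rpm_per_bin) + self.unmatched_rpm


@dataclass
class SequenceToxicityProfile:
    """Viability of every overlapping 6mer a sequence can give rise to.

    ``windows`` holds one (position, 6mer, viability) triple per start
    offset; viability is None for 6mers absent from the table.
    """

    source_id: str
    windows: list[tuple[int, str, float | None]]

    @property
    def n_6mers(self) -> int:
        return len(self.windows)

    @property
    def viabilities(self) -> list[float]:
        return [v for _, _, v in self.windows if v is not None]


def extract_seed(read_sequence: str) -> str:
    """The 6mer seed: positions 2-7 (1-based) of the guide strand."""
    if len(read_sequence) < 7:
        raise SeedUndefinedError(
            f"read of length {len(read_sequence)} has no position-2-7 seed"
        )
    return read_sequence[1:7]


def viability_bin(viability_percent: float) -> int:
    """0-based index of the seed-toxicity bin holding a viability value."""
    v = viability_percent
    if v > 100:
        return 5
    if v >= 80:
        return 4
    if v < 20:
        return 0
    return int(v // 20)


def rpm_normalize(reads: Sequence[SmallRead]) -> list[tuple[SmallRead, float]]:
    """Attach a reads-per-million weight to each collapsed read.

    weight_i = count_i * 10^6 / sum(counts); the weights sum to 10^6.
    """
    total = sum(read.total_count for read in reads)
    if total <= 0:
        raise ValueError("cannot RPM-normalize a read set with zero total count")
    return [(read, read.total_count * 1e6 / total) for read in reads]


def aggregate_seed_toxicity(
    weighted_reads: Iterable[tuple[SmallRead, float]],
    table: SeedViabilityTable,
) -> SeedBinSummary:
    """Accumulate per-read RPM into the six seed-viability bins.

    Each read's seed is looked up in the table and its weight added to
    the bin containing that seed's viability; seeds absent from the
    table accumulate in ``unmatched_rpm``.  Reads shorter than 7 nt have
    no seed and must be excluded upstream (they raise
    :class:`SeedUndefinedError` here).
    """
    rpm_per_bin = [0.0] * 6
    unmatched = 0.0
    for read, weight in weighted_reads:
        seed = extract_seed(read.sequence)
        viability = table.viability(seed)
        if viability is None:
            unmatched += weight
        else:
            rpm_per_bin[viability_bin(viability)] += weight
    return SeedBinSummary(rpm_per_bin, unmatched)


def sequence_6mer_profile(
    sequence: str,
    table: SeedViabilityTable,
    source_id: str = "",
) -> SequenceToxicityProfile:
    """All overlapping 6mers of a sequence joined to their viability.

    Sliding window of width 6 and step 1, so a sequence of length L
    yields L - 5 6mers (e.g. 841 for an 846-nt ORF).
    """
    sequence = sequence.upper().replace("U", "T")
    if len(sequence) < 6:
        raise ValueError(
            f"sequence of length {len(sequence)} yields no 6mers"
        )
    windows = [
        (i, sequence[i : i + 6], table.viability(sequence[i : i + 6]))
        for i in range(len(sequence) - 5)
    ]
    return SequenceToxicityProfile(source_id, windows)


def compare_sequence_toxicity(
    profile_a: SequenceToxicityProfile,
    profile_b: SequenceToxicityProfile,
) -> tuple[float, float]:
    """Two-sample KS test between two sequences' viability profiles.

    Returns the two-sided KS statistic and its asymptotic p-value over
    the two viability multisets.
    """
    a = profile_a.viabilities
    b = profile_b.viabilities
    if not a or not b:
        raise ValueError("both profiles must contain viability values")
    result = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(result.statistic), float(result.pvalue)
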