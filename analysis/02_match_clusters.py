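#!/usr/bin/env python
"""Map Ago-bound and total reads onto their source transcript.

For the Drosha-knockout-like regime: place each fraction's reads on the
first transcript by full-length exact matching, merge placements into
cluster regions, compare recovered regions with the planted ones, and
contrast the two fractions' read-length distributions.

Writes BED placements/clusters and a length-comparison table under
results/match/.
"""

import json
from pathlib import Path

import pandas as pd

from riscfrag.io_formats import (
    read_fasta,
    read_reads,
    write_bed,
    write_clusters_bed,
)
from riscfrag.read_matching import (
    cluster_alignments,
    compare_fractions,
    length_distribution,
    match_reads_to_orf,
)

ROOT = Path(__file__).parent.parent / "results"


def main() -> None:
    data = ROOT / "data" / "drosha_ko"
    outdir = ROOT / "match"
    outdir.mkdir(parents=True, exist_ok=True)

    transcripts = read_fasta(data / "transcriptome.fasta")
    target = next(iter(transcripts))
    truth = json.loads((data / "ground_truth_ago.json").read_text())
    planted = truth["clusters"][target.transcript_id]

    distributions = {}
    for fraction in ("ago", "total"):
        reads = read_reads(data / f"reads_{fraction}.tsv", "collapsed_tsv")
        alignments = match_reads_to_orf(reads, target, min_len=15)
        regions = cluster_alignments(alignments, gap=0)
        write_bed(alignments, outdir / f"alignments_{fraction}.bed")
        write_clusters_bed(regions, outdir / f"clusters_{fraction}.bed")
        distributions[fraction] = length_distribution(alignments)
        print(
            f"[{fraction}] {len(alignments)} placements on "
            f"{target.transcript_id} merge into {len(regions)} regions "
            f"(planted: {len(planted)})"
        )

    report = compare_fractions(distributions["ago"], distributions["total"])
    rows = [
        ("ago_mean_length_nt", distributions["ago"].mean_length),
        ("total_mean_length_nt", distributions["total"].mean_length),
        ("ago_peak_length_nt", distributions["ago"].peak_length),
        ("total_peak_length_nt", distributions["total"].peak_length),
        ("mean_difference_nt", report.mean_difference),
        ("peak_difference_nt", report.peak_difference),
        ("ks_statistic", report.ks_statistic),
    ]
    pd.DataFrame(rows, columns=["metric", "value"]).to_csv(
        outdir / "length_comparison.tsv", sep="\t", index=False
    )
    print(
        f"\nAgo-bound reads peak at {distributions['ago'].peak_length} nt vs "
        f"{distributions['total'].peak_length} nt in the total fraction "
        f"(mean difference {report.mean_difference:+.2f} nt, "
        f"KS {report.ks_statistic:.3f}): the RISC-bound fragments are the "
        "trimmed, shorter species."
    )


if __name__ == "__main__":
    main()
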