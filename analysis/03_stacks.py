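#!/usr/bin/env python
"""Detect which transcripts are processed into RISC-loaded fragments.

Runs the collapse -> abundance/length filter -> unique-map -> stack
procedure on the Drosha-knockout-like Ago-bound reads, ranks transcripts
by stack count, and applies an RPKM >= 10 expression filter from a
synthetic long-RNA-seq count table (expression proportional to the
planted read load, plus one silent gene that is expressed but not
processed).

Writes the ranked stack table under results/stacks/.
"""

import json
from pathlib import Path

import pandas as pd

from riscfrag.io_formats import GeneCountTable, read_fasta, read_reads
from riscfrag.stack_analysis import (
    count_stacks,
    filter_reads,
    pool_and_collapse,
    rank_by_stacks,
    rpkm_filter,
    unique_map,
)

ROOT = Path(__file__).parent.parent / "results"


def main() -> None:
    data = ROOT / "data" / "drosha_ko"
    outdir = ROOT / "stacks"
    outdir.mkdir(parents=True, exist_ok=True)

    transcripts = read_fasta(data / "transcriptome.fasta")
    reads = read_reads(data / "reads_ago.tsv", "collapsed_tsv")
    truth = json.loads((data / "ground_truth_ago.json").read_text())

    collapsed = pool_and_collapse(reads)
    # min_count 1: the simulator emits mostly singleton placements, so the
    # distinct-start structure, not copy depth, carries the signal here
    retained = filter_reads(collapsed, min_count=1, min_len=15, max_len=50)
    alignments = unique_map(retained, transcripts)
    profiles = count_stacks(alignments)
    ranked = rank_by_stacks(profiles.values(), top_n=10)
    print(
        f"{len(retained)}/{len(collapsed)} collapsed reads pass the filters; "
        f"{len(alignments)} map uniquely."
    )

    # synthetic expression table: counts scale with the planted read load;
    # 'silent' is expressed but yields no RISC-bound fragments
    rows = [
        (t.transcript_id, t.length_nt,
         2000 * len(truth["distinct_starts"].get(t.transcript_id, [])))
        for t in transcripts
    ]
    rows.append(("silent", 1500, 40000))
    rows.append(("lowexpr", 5000, 10))
    counts = GeneCountTable(
        pd.DataFrame(rows, columns=["gene_id", "length_nt", "read_count"]),
        library_size=10**6,
    )
    expressed = {rec.gene_id: rec.rpkm for rec in rpkm_filter(counts, min_rpkm=10)}
    print(f"RPKM >= 10 genes: {sorted(expressed)} (of {len(rows)} in the table)")

    table = []
    for profile in ranked:
        planted = len(truth["distinct_starts"].get(profile.transcript_id, []))
        table.append({
            "gene_id": profile.transcript_id,
            "n_stacks": profile.n_stacks,
            "planted_distinct_starts": planted,
            "total_count": profile.total_count,
            "rpkm": expressed.get(profile.transcript_id),
        })
        print(
            f"  {profile.transcript_id}: {profile.n_stacks} stacks "
            f"(planted {planted}), {profile.total_count} copies"
        )
    pd.DataFrame(table).to_csv(outdir / "stack_ranking.tsv", sep="\t", index=False)

    recovered = all(r["n_stacks"] == r["planted_distinct_starts"] for r in table)
    print(
        "\nStack counts "
        + ("exactly match" if recovered else "DIVERGE from")
        + " the planted distinct 5' start positions; the expressed-but-"
        "unprocessed 'silent' gene shows no stacks, as it should."
    )


if __name__ == "__main__":
    main()
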