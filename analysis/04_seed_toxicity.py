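#!/usr/bin/env python
"""Seed-toxicity composition of the RISC in the two regimes, and the
theoretical toxicity of a recoded ORF.

Part 1: aggregate each regime's Ago-bound reads (RPM) into the six
seed-viability bins.  The wild-type-like RISC should sit in the
high-viability bins (protective miRNAs); the Drosha-knockout-like RISC
should shift toward low-viability (toxic) seeds.

Part 2: compare all overlapping 6mers of an 846-nt ORF-length sequence
against a synonymously recoded variant with a two-sample KS test — the
sequence-level question of whether recoding an ORF changes the toxicity
of the small RNAs it can shed.

Writes tables under results/seedtox/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from regimes import SEED

from riscfrag.io_formats import read_reads, read_viability_table
from riscfrag.seed_toxicity import (
    BIN_LABELS,
    aggregate_seed_toxicity,
    compare_sequence_toxicity,
    rpm_normalize,
    sequence_6mer_profile,
)
from riscfrag.synthetic_data import recode_synonymously

ROOT = Path(__file__).parent.parent / "results"


def main() -> None:
    outdir = ROOT / "seedtox"
    outdir.mkdir(parents=True, exist_ok=True)
    table = read_viability_table(ROOT / "data" / "wt" / "viability.tsv")

    rows = []
    toxic_share = {}
    for regime in ("wt", "drosha_ko"):
        reads = read_reads(
            ROOT / "data" / regime / "reads_ago.tsv", "collapsed_tsv"
        )
        summary = aggregate_seed_toxicity(rpm_normalize(reads), table)
        for label, rpm in zip(BIN_LABELS, summary.rpm_per_bin):
            rows.append({"regime": regime, "bin": label, "rpm": rpm})
        toxic_share[regime] = sum(summary.rpm_per_bin[:2]) / 1e6
        print(
            f"[{regime}] per-bin RPM: "
            + ", ".join(f"{l}={v:,.0f}" for l, v in zip(BIN_LABELS, summary.rpm_per_bin))
        )
    pd.DataFrame(rows).to_csv(outdir / "bin_rpm.tsv", sep="\t", index=False)
    print(
        f"\nShare of RISC content with seed viability <40%: "
        f"wt {100 * toxic_share['wt']:.1f}% vs Drosha k.o. "
        f"{100 * toxic_share['drosha_ko']:.1f}% — losing the miRNA background "
        "shifts the RISC toward toxic seeds."
    )

    rng = np.random.default_rng([SEED, 40])
    wt_orf = "".join(rng.choice(list("ACGT"), 846))
    recoded = recode_synonymously(wt_orf, SEED)
    profile_wt = sequence_6mer_profile(wt_orf, table, "wt_orf")
    profile_re = sequence_6mer_profile(recoded, table, "recoded_orf")
    statistic, pvalue = compare_sequence_toxicity(profile_wt, profile_re)
    pd.DataFrame(
        [
            ("n_6mers_wt", profile_wt.n_6mers),
            ("n_6mers_recoded", profile_re.n_6mers),
            ("ks_statistic", statistic),
            ("p_value", pvalue),
        ],
        columns=["metric", "value"],
    ).to_csv(outdir / "recoded_orf_ks.tsv", sep="\t", index=False)
    print(
        f"\nRecoded-ORF comparison: {profile_wt.n_6mers} 6mers per sequence, "
        f"KS statistic {statistic:.4f}, p = {pvalue:.3f} "
        + ("(profiles differ)" if pvalue < 0.05 else
           "(no significant difference: recoding preserves the theoretical "
           "toxicity of the shed small RNAs)")
    )


if __name__ == "__main__":
    main()
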