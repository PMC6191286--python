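"""The two simulated RISC regimes the analysis scripts run on.

Both share one transcriptome and viability screen (seed 1).  They differ
in how much of the RISC content is miRNA-like background and in how
toxic that background's seeds are:

* ``wt`` — miRNAs dominate the RISC (98.4% of bound reads) and carry
  mostly high-viability (non-toxic) seeds.
* ``drosha_ko`` — canonical miRNA biogenesis is disabled, so only 34%
  of bound reads are miRNAs and the remaining RISC content shifts
  toward toxic (low-viability) seeds.
"""

from riscfrag.synthetic_data import SimulationConfig

SEED = 1

_BASE = dict(
    seed=SEED,
    n_transcripts=3,
    transcript_length_range=(500, 900),
    n_clusters_per_transcript=3,
    cluster_length=60,
    reads_per_cluster=150,
    n_replicates=2,
)

REGIMES = {
    "wt": SimulationConfig(
        **_BASE,
        mirna_fraction=0.984,
        seed_bin_mixture=(0.02, 0.04, 0.09, 0.20, 0.40, 0.25),
    ),
    "drosha_ko": SimulationConfig(
        **_BASE,
        mirna_fraction=0.34,
        seed_bin_mixture=(0.25, 0.20, 0.15, 0.15, 0.15, 0.10),
    ),
}
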