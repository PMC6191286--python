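# Methods

## The procedure

The pipeline asks whether small RNAs bound by Argonaute (Ago) proteins
derive from mRNAs, and what that implies.

**Exact placement.** A read is assigned to a target ORF only if it
matches with 100% identity across its entire length, on the sense
strand (the direction of transcription). Mismatch-tolerant alignment is
deliberately absent: every downstream statistic is defined over perfect
full-length hits only, so exact substring search is the whole
contract, not an approximation of one. A minimum read length
(`min_len`, default 19 nt) plays the role a significance cutoff plays
in a heuristic aligner: at these lengths it only removes very short
perfect matches whose placement would be uninformative. All coordinates
are 0-based half-open, internally and in BED6 output.

**Clusters.** Placements on a transcript merge into cluster regions
when separated by at most `gap` nt (default 0 = overlap or abutment).
No minimum read support is imposed by default. The merging rule for
such regions is a genuine free parameter of this kind of analysis — the
count of regions on real data depends on it — so it is configurable and
region counts are never treated as a calibrated output.

**Fraction comparison.** Length histograms are weighted by copy counts
(or RPM) and summarized by the count-weighted mean and the modal peak
(ties broken toward the shorter length, so reports are deterministic).
The contrast between fractions reports mean and peak differences and a
two-sample KS statistic computed directly on the weighted length ECDFs
(a weighted two-sample KS is not available in scipy, so the
sup-difference is computed explicitly; it is tested against a
brute-force oracle).

**Stacks.** The endogenous-gene procedure is: pool replicates →
collapse identical sequences (counts conserved) → filter (total copies
≥ 10, length in [15, 50] nt inclusive, no `N`) → keep reads with
*exactly one* exact sense-strand placement across the whole transcript
set → count distinct 5′ start positions per transcript. Reads of
different lengths sharing a start form one stack: the 5′ end defines
the stack, because a processing machinery that cuts at a position and
trims 3′ ends produces exactly that signature. Filtering order is fixed
as collapse → abundance/length/N filter → unique mapping → stack
counting. The ≥10-copy threshold applies to counts summed across the
pooled replicates. Ranking is by stack count, ties broken by total copy
count then lexicographic id.

Unique mapping is defined against the supplied transcript set rather
than a genome; at desk scale the transcript set *is* the reference, and
"unique" means one placement across all transcripts and offsets.
Choosing which transcript represents a gene (e.g. the isoform with the
longest 3′UTR) is the caller's responsibility when building the set.

**Expression filter.** RPKM = count / (length/1000) / (library/10⁶),
genes kept at RPKM ≥ 10 (inclusive). RISC occupancy is reported as
reads per million (RPM): weight = count × 10⁶ / Σcounts.

**Seed toxicity.** The 6mer seed is positions 2–7 (1-based) of the
guide read, taken directly from the read sequence (no reverse
complementing: the read *is* the guide). Seeds are matched in the DNA
alphabet after U→T normalization. Viability bins are
(1) <20%, (2) [20, 40), (3) [40, 60), (4) [60, 80), (5) [80, 100]
**closed**, (6) >100%: the boundary convention is half-open with bin 5
closed at 100, so a seed leaving exactly 100% viability counts as
"80~100%" rather than ">100%" — "more viable than untreated control"
is reserved for strictly >100. A viability table may carry one value
column or two (e.g. two cell lines), in which case the per-seed average
is used. Sequence-level profiles take *every* overlapping window (step
1), so an L-nt sequence yields L−5 6mers (846 nt → 841); duplicate
6mers are counted each time they occur, since each position is an
independent potential fragment. Profile comparison uses the two-sided
two-sample KS test with the asymptotic p-value (`scipy.stats.ks_2samp`);
exact small-sample p-values are out of scope.

## The synthetic-data generator

The generator emulates the conditions the pipeline targets, and its
defaults are those conditions:

| parameter | default | meaning |
|---|---|---|
| `ago_length_mean` / `total_length_mean` | 20 / 23 nt | Ago-bound fragments are RISC-trimmed; the total cytosolic fraction runs longer |
| `length_sd` | 1.5 nt | spread of the discretized-Normal read length, clipped to [15, 50] nt (the pipeline's hard length filter) |
| `mirna_fraction` | 0.34 | share of the library that is miRNA-like background; 0.34 mimics a Drosha-knockout RISC, 0.984 a wild-type RISC |
| `n_replicates` | 2 | duplicate libraries; occurrence counts split multinomially |
| `n_clusters_per_transcript` / `cluster_length` | 3 / 60 nt | planted processing regions, auto-placed with ≥1 nt separation so gap-0 merging cannot fuse neighbours |
| `reads_per_cluster` | 50 | occurrences sampled uniformly within each cluster |
| `seed_bin_mixture` | (.25, .20, .15, .15, .15, .10) | viability-bin distribution of background-read seeds (toxic-shifted, the low-miRNA regime) |

Cluster reads are exact sense-strand substrings of their transcript at
the sampled placement; the ground truth records every origin, the
planted intervals, the distinct 5′ starts drawn, and per-bin background
occurrence counts. Transcripts are uniform-random sequences subjected
to a rejection check that no 15-nt substring occurs twice anywhere in
the transcriptome (within or across transcripts) — slightly stronger
than pairwise disjointness, and exactly what makes "unique placement"
provable for every planted read. Background (miRNA-like) sequences
carry a table seed from a mixture-drawn viability bin at positions 2–7
and are rejection-checked to be absent from the transcriptome. The
synthetic viability screen populates each bin with a largest-remainder
share of the 4096 seeds and draws values uniformly within the bin
(2–20, 20–40, …, 100–130%), so all bins are populated by construction;
it does not model the sequence-composition structure (e.g. G-richness
of toxic seeds) a real screen shows.

Not modelled: sequencing error, quality scores, adapters, expression
heterogeneity between transcripts, genome context (repeats,
paralogues), or a realistic miRNA length distribution distinct from the
fragment one. Passing recovery tests therefore shows the *logic* of the
pipeline is correct under its stated assumptions — exact reads, clean
uniqueness — not that the filters are robust to noisy real libraries.

A `recode_synonymously` helper produces the codon-recoded ("silent")
variant of an ORF used in the sequence-level toxicity comparison: every
codon with a synonym is swapped for a random *different* synonymous
codon, preserving the encoded protein while perturbing the nucleotide
sequence.

## Numerical and design choices

- Determinism: one integer seed per simulation; per-fraction and
  per-purpose generators derive from it (`default_rng([seed, k])`).
  Same config ⇒ byte-identical output files; CLI manifests contain no
  timestamps or absolute paths so whole output directories hash
  identically across reruns.
- Multi-placement reads on a single target ORF are reported once per
  placement with `n_placements_on_target` set; within the
  single-target analysis nothing justifies discarding them, whereas the
  multi-transcript stack analysis *does* discard them (uniqueness is
  its point).
- Degenerate inputs fail loudly: empty ORF, empty length distribution,
  zero-total RPM normalization, sequences under 6 nt (no windows),
  reads under 7 nt (no seed), zero-length transcripts in RPKM, clusters
  shorter than the 15-nt minimum read length.
- Boundary semantics are inclusive exactly as documented: copies ≥ 10,
  lengths 15 and 50 retained, RPKM ≥ 10 retained, viability 100 in
  bin 5.
- The analysis drivers and recovery tests run the stack stage with
  `min_count=1`: the generator emits mostly singleton placements, so
  planted-structure recovery is a statement about distinct starts, not
  copy depth; threshold behaviour is exercised separately on
  constructed read sets.
- Problem sizes: the drivers simulate 3 transcripts of 500–900 nt with
  150 reads/cluster; recovery suites run 20 simulations of 2
  transcripts at 30 reads/cluster and a 2000-read background for
  mixture recovery — small enough to run in seconds while leaving every
  statistical check well-powered.

## Known limitations

- Antisense matching, mismatches, and genome-scale alignment are out of
  scope by design; real libraries need an upstream aligner if the
  reference is a genome.
- The cluster count on real data depends on the unstated merging rule
  (`gap`, minimum support); treat region counts as descriptive.
- The asymptotic KS p-value is inaccurate for very small profiles
  (n ≲ 10); the statistic itself is exact.
- RPM/RPKM normalize within the supplied set/table; they are not
  cross-sample normalizations.
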