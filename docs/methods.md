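# Methods

## The screening procedure

`aptascreen` implements the standard in-silico candidate screen applied to the
terminal round of a SELEX experiment sequenced against both the selection
target and a counter-selection ("nontarget") sample. One read file per sample
is processed as:

1. **Trimming.** Each read is anchored on the library's two constant regions
   (for the built-in B02 layout: `GTACGCTAGGCGTTAGTCTC`-[N40]-
   `ATCGTACGACGGTCGTACCC`). The substring between the leftmost 5′ anchor and
   the leftmost 3′ anchor after it is the candidate aptamer sequence.
   Barcodes, adaptors and promoter remnants outside the anchors are discarded
   implicitly. Anchors match with at most `max_mismatch` substitutions each
   (default 0 — exact matching is the only fully reproducible default when no
   tolerance is documented for a dataset; indels in anchors are never
   allowed). Inserts are kept when their length is within
   `random_length ± length_tolerance` (default tolerance 0, because insertion
   or deletion sequencing errors otherwise silently shift species counts) and
   they contain no N. Every read lands in exactly one tally
   (extracted / no-anchor / off-length / ambiguous). Reads are assumed to be
   in library orientation; `revcomp_scan` retries the reverse complement on
   forward failure and is off by default.

2. **Counting and RPM.** Trimmed sequences are collapsed to unique species.
   Abundance is expressed as reads per million, RPM = count / N × 10⁶ with N
   the sample's total trimmed read count. N is fixed **before** abundance
   filtering and never recomputed, so RPM stays comparable across filter
   settings (the convention of the widely used SELEX counting tools). Species
   with fewer than `min_count` reads (default 8, i.e. count ≥ 8 survives) are
   removed; ranks are recomputed over survivors with ties broken
   lexicographically for cross-platform determinism.

3. **Clustering.** The filtered target pool is partitioned into mutational
   families by greedy, abundance-ordered clustering under unit-cost
   Levenshtein distance: walking species in rank order, each not-yet-assigned
   species seeds a new cluster and absorbs every remaining species within
   `max_distance` (default 6) of that **seed**. Membership is to the seed,
   not transitive, so chains of near neighbours do not merge families. The
   seed is by construction the cluster's most abundant member and serves as
   the family representative. Distances are computed on the random region
   only — the shared constant flanks would compress all pairwise distances
   toward zero. The distance kernel is edlib's banded Levenshtein alignment,
   with the radius used as an early-exit bound; tests pin it to the full
   textbook dynamic program.

   The customary description of a radius-6 clustering is ambiguous between
   "distance ≤ 6" and "fewer than 6 differences". The default here is the
   inclusive reading (≤ 6), matching common SELEX-tool behaviour; the strict
   reading (< 6) is available via `ClusterParams(inclusive=False)` and the
   CLI `--exclusive` flag so the sensitivity of a result to this choice can
   be measured rather than assumed.

4. **Enrichment screen.** For every sequence in the filtered target pool,
   x = target-pool RPM and y = nontarget-pool RPM (y = 0 when the sequence is
   absent from the counter pool — absence from the counter selection is the
   strongest evidence of specificity). The enrichment ratio is y/x;
   y/x ≤ 0.5 means the sequence is more than twice as abundant toward the
   target. Final candidates are cluster representatives with x **strictly**
   above `min_rpm_target` (default 500) and y/x at or below `max_enrichment`
   (default 0.5) — both read literally from their usual printed phrasing
   ("more than 500", "0.5 or less") and both switchable. Sequences with
   x = 0 carry no ratio and are never candidates. The screen deliberately
   operates on representatives only: one candidate per family.

5. **Exports.** Alongside `candidates.tsv`/`candidates.fasta` the screen
   writes the per-representative scatter table (x, y, ratio, candidate flag)
   and a log₂ median-normalized RPM matrix: per sample column,
   log₂((RPM + pseudo) / median(RPM + pseudo)), median taken as the midpoint
   of the two central order statistics for even n. With the default
   pseudo-RPM of 0, sequences absent from a sample are excluded from that
   column (NaN) rather than given an arbitrary floor; a positive pseudo count
   switches to joint visualization of both pools. Row dendrograms are left to
   downstream heatmap tools; the matrix is the deliverable.

## The synthetic study

Real terminal-round pools are modelled as a mixture of (i) a uniform random
N40 background — at desk-scale depths (tens of thousands of reads over a 4⁴⁰
space) background species essentially never recur, so the min-count filter
removes them entirely — and (ii) a small number of planted mutational
families: a seed 40-mer emitted through an i.i.d. per-base substitution
channel (each base independently replaced by a uniformly chosen different
base). At the default substitution rate of 0.02 the exact seed is emitted
with probability 0.98⁴⁰ ≈ 0.45, single mutants dominate the remainder, and a
copy falls outside the radius-6 cloud with probability ~2×10⁻⁶ — so planted
family structure is analytically tractable (binomial) and the expected
enrichment ratio of a family is simply its counter-pool fraction over its
target-pool fraction. An optional per-base indel channel exists for stress
tests of the length filter; it is off by default.

The canonical study (`default_pool_spec`) uses 50,000 reads per pool,
substitution rate 0.02 and seven families with heavy-tailed target shares:

| family | target share | counter share | expected outcome |
|--------|-------------:|--------------:|------------------|
| fam1   | 0.12   | 0.012  | candidate (ratio ≈ 0.1) |
| fam2   | 0.05   | 0.010  | candidate (ratio ≈ 0.2) |
| fam3   | 0.02   | 0.002  | candidate (ratio ≈ 0.1) |
| fam4   | 0.008  | 0.001  | candidate, low-abundance (seed RPM ≈ 3,600) |
| fam5   | 0.06   | 0.060  | rejected: unenriched (ratio ≈ 1) |
| fam6   | 0.01   | 0.020  | rejected: counter-enriched (ratio ≈ 2) |
| fam7   | 0.0005 | 0.0005 | rejected: below the RPM floor (seed RPM ≈ 220) |

Every should-pass family clears both thresholds by at least 2-fold, and every
decoy misses its failing threshold by at least 2-fold, so at these depths the
binomial sampling noise (relative SD of a ratio of two seed counts ≳ a few
percent) cannot flip an outcome except with negligible probability. Family
seeds are drawn with pairwise edit distance ≥ 16 (> 2× the clustering radius)
so planted clouds cannot merge. The generator is a pure function of its spec,
including the mandatory `rng_seed`; outputs are byte-reproducible.

What the simulation does **not** emulate: multi-round selection dynamics,
PCR amplification bias and chimeras, position-dependent sequencing error,
quality-score structure, non-uniform background (a Zipf-abundance background
can be approximated by planting many small unenriched families). Passing the
recovery tests therefore demonstrates the pipeline's correctness and
threshold behaviour, not robustness to every artefact of real HTS data.

`evaluate_recovery` assigns each candidate to the nearest planted seed within
the clustering radius. Precision counts candidates assigned to a family that
*should* pass — a candidate matching a planted decoy family is a screen false
positive, not a match; recall counts should-pass families recovered. With no
candidates precision is vacuously 1.

## Numerical and design choices

- Ties in abundance are broken lexicographically everywhere a total order is
  needed (ranking, greedy seeding); all outputs are byte-deterministic for
  identical inputs and configuration.
- RPM conservation (pre-filter RPM sums to 10⁶) holds to a relative
  tolerance of 10⁻⁶; all threshold comparisons are plain floating-point
  comparisons on exactly representable or well-separated values.
- Degenerate inputs fail loudly and early: empty read files, pools emptied by
  the min-count filter, identical target/nontarget paths, and all-zero
  heatmap columns raise distinct errors (the CLI maps them to distinct exit
  codes) rather than producing empty tables silently.
- Stage outputs are always materialized as TSV/JSON so any stage can be rerun
  or audited in isolation; the CLI subcommands compose to byte-identical
  outputs of the orchestrated run.
- Problem sizes in the test suite and acceptance script (50,000-read pools,
  20 replicate seeds, oracle cross-checks on pools of ≤ 50 species and
  sequences of ≤ 50 nt) were chosen as the smallest scales at which the
  binomial margins above are decisive; a laptop runs the whole suite in well
  under a minute of compute per replicate.

## Known limitations

- Anchor matching allows substitutions only; a single indel inside a constant
  region rejects the read (it would corrupt the insert boundary anyway).
- One file = one sample: no barcode demultiplexing, quality trimming or
  paired-end merging — upstream tools do this better.
- Only a single terminal round against one counter sample is screened;
  round-over-round enrichment trajectories are out of scope.
- The greedy clustering is O(clusters × species) distance computations; fine
  for post-filter pool sizes (hundreds to tens of thousands), not intended
  for millions of unfiltered species.
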