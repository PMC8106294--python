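# aptascreen

In-silico candidate discovery for SELEX aptamer selections sequenced against a
target and a counter-selection sample.

After the final round of a SELEX experiment, the enriched library is bound to
the target (e.g. a VLP displaying the receptor of interest) and, in parallel,
to a nontarget control; both bound fractions are sequenced. `aptascreen`
turns those two read files into a ranked list of candidate aptamers:

1. **trim** — anchor each read on the library's constant regions and extract
   the randomized insert (the built-in layout is the B02 library,
   `GTACGCTAGGCGTTAGTCTC`-[N40]-`ATCGTACGACGGTCGTACCC`);
2. **count** — collapse to unique species with reads-per-million
   (RPM = count / total reads × 10⁶) and drop species with fewer than 8 reads;
3. **cluster** — group the target pool into mutational families by greedy,
   abundance-ordered Levenshtein clustering (radius 6), each family
   represented by its most abundant member;
4. **screen** — for each sequence compute the enrichment ratio y/x from its
   nontarget RPM y and target RPM x, and keep representatives with
   x > 500 RPM and y/x ≤ 0.5 (at least 2-fold enrichment toward the target);
5. **export** — candidate TSV/FASTA, the per-representative x-y scatter
   table, and a log₂ median-normalized RPM matrix for heatmap rendering.

A synthetic-pool generator with planted mutational families and a known truth
manifest makes the whole pipeline testable end to end with no sequencing data,
and quantifies recovery as precision/recall. See `docs/methods.md` for the
model and every threshold convention.

## Worked example

Simulate a paired study (50,000 reads per pool, seven planted families, four
of which should pass the screen), run the screen, and score it:

```sh
aptascreen simulate --seed 1 --out-dir sim
aptascreen run-all --target-reads sim/target.fq --nontarget-reads sim/nontarget.fq --out-dir out
aptascreen evaluate --candidates out/candidates.tsv --truth sim/truth_manifest.tsv
```

which prints

```
wrote sim/target.fq, sim/nontarget.fq and truth_manifest.tsv (7 families)
4 final candidates -> out/candidates.tsv
precision=1.0000 recall=1.0000 (4 candidates)
```

`out/scatter.tsv` holds one row per cluster representative above the RPM
floor; with seed 1 it contains 6 rows, of which 4 are flagged candidates —
e.g. the top family's representative at x = 53,180 RPM, y = 5,280 RPM,
ratio 0.099 (candidate), and an abundant decoy at x = 26,280 RPM,
y = 26,920 RPM, ratio 1.024 (rejected: not enriched toward the target). The
two planted decoy families and the family planted below the RPM floor are the
three non-candidates, so precision and recall against the truth manifest are
both 1.0. The same run is available stage by stage (`aptascreen trim`,
`count`, `cluster`, `screen`) with byte-identical outputs, and as library
calls (`aptascreen.run_screen`).

The scripts under `analysis/` run this study as a narrative: `01` simulates
the pools, `02` runs the screen, `03` scores recovery, `04` repeats the whole
study across 20 seeds (all tables land in `results/`).

To screen real data, point `run-all` at your two read files (FASTQ or FASTA)
and, if your library differs from B02, set `--five-prime`, `--three-prime`
and `--random-length`. All thresholds (`--min-count`, `--max-distance`,
`--min-rpm`, `--max-enrichment`) default to the canonical screen parameters.

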