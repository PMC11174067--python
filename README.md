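# fibertol

Scoring and association pipeline for gastrointestinal tolerance of
high-dose dietary-fiber supplementation trials.

The package takes weekly symptom diaries from a two-arm trial
(fermentable arabinoxylan, AX, vs non-fermentable microcrystalline
cellulose, MCC; doses 25 g/day for females, 35 g/day for males) and

1. computes per-subject **severity** and **adaptation** scores:
   weekly composite rating (flatulence + bloating + stomachache, 0-12),
   MAX severity (peak weeks-1-5 rating minus baseline), MAX adaptation
   (peak minus week-6 rating), trapezoidal AUC severity over weeks 0-6
   (incremental or raw mode), and AUC adaptation (weeks-1-3 area /
   weeks-4-6 area, 1 for a constant trajectory);
2. derives microbiota features from relative-abundance tables:
   aggregation to phylum/family/genus and to co-abundance response
   groups (CARGs), a strict `> 0.15%` mean-abundance screen (`> 1.0%`
   for ex-vivo active ASVs), Shannon diversity and richness, and
   week-6-minus-baseline shifts (also for pH and SCFAs);
3. produces calorie-adjusted diet features and animal:plant ratios
   (meat:wgrain, chole:DF);
4. runs the windowed Spearman association analysis (weeks-1-3 scores
   against week-1 fecal samples, weeks-4-6 scores against week-6
   samples), profile correlations (baseline, shift, ex-vivo, pH/SCFA,
   diet), and Mann-Whitney / Wilcoxon rank-test tables, with a
   dual-alpha significance rule (p < 0.01 for microbiota-compositional
   cells, p < 0.05 elsewhere);
5. generates fully synthetic cohorts with planted, calibrated effects
   (a *B. longum*-like OTU wired to tolerance) so the entire pipeline is
   testable end to end without external data.

## Command line

```sh
fibertol simulate --seed 1 --out cohort/          # write synthetic input tables
fibertol scores --diaries cohort/diaries.csv --out scores.csv
fibertol features --abundance cohort/fecal_abundance.csv \
    --taxonomy cohort/taxonomy.csv --carg-map cohort/carg_map.csv \
    --whitelist cohort/significant_otus.csv --out features/
fibertol diet --diet cohort/diet.csv --out diet_features.csv
fibertol run --seed 1 --out runs/demo             # full pipeline on a simulated cohort
```

`fibertol run` accepts a YAML config (`--config run.yaml`) whose keys
are the materialized defaults in `fibertol.pipeline.DEFAULT_RUN_CONFIG`;
set `inputs:` to a mapping of file paths to analyze existing tables
instead of simulating.  Every run writes a `manifest.json` with the full
config and SHA-256 hashes of all outputs; reruns with the same seed are
byte-identical.

All I/O is delimited text (CSV/TSV auto-detected); abundance tables
given as percentages are renormalized to fractions on read.

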