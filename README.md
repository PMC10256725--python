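# serptools

Analysis toolkit for **selective ribosome profiling (SeRP)** of
co-translational factor binding — built for the setting where a tagged
factor (for example a nuclear import receptor in *Saccharomyces cerevisiae*)
is affinity-purified together with the ribosome–nascent-chain complexes it
engages, and ribosome-protected footprints are sequenced for both the
purified (IP) and the matched total translatome library, alongside an
untagged no-bait control.

From per-nucleotide footprint count tracks, `serptools` produces:

* **per-gene enrichment scores** — smoothed (100 nt moving average) gene
  profiles, position-wise enrichment `E(i) = IP(i) / total(i)`, and the
  trapezoidal area under each enrichment profile (introns excluded);
* **a calibrated hit list** — the per-gene statistic is the *no-bait-scaled
  AUC*, `100 · AUC_bait / (AUC_bait + AUC_no-bait)` (percent), thresholded
  at a cut-off calibrated to an empirical FDR (default 1%) against a curated
  true-positive gene list, after a filter cascade (coverage ≥ 80% in IP and
  total, pulldown AUC > 5, bait fold-change AUC ≥ no-bait fold-change AUC,
  mean replicate Pearson r ≥ 0.6);
* **binding-onset calls** — the first ORF position whose enrichment stays
  above a fold threshold (default 2) for a minimum run, the codon where the
  factor engages the nascent chain; a sustained return below threshold before
  the final ~30 codons classifies binding as *transient* (with a release
  codon) rather than *enduring*;
* **metagene summaries** — length-normalized profiles scaled to 0–100% of
  the ORF with 95% confidence bands, and onset-aligned ribosome occupancy
  with a paired two-sided t-test for a pre-onset translational pause;
* **binding-site sequence statistics** — amino-acid Fisher enrichment in
  onset-window peptides vs. full-length proteins (BH-adjusted), isoelectric
  points (Henderson–Hasselbalch bisection) with Mann–Whitney comparisons,
  GO-term over-representation, and the 100-residue / 50-overlap fragment
  tiling used to prepare structure-prediction input lists;
* **a synthetic-data generator** that writes complete experiments
  (bedGraph tracks × {bait, no-bait} × {IP, total} × replicates, GTF, FASTA,
  curated gene lists) with planted ground truth — onset codons, enrichment
  amplitudes, release codons, pre-onset pause — so every stage is testable
  by parameter recovery.

## Worked example

Simulate a small experiment (8 planted targets among 40 genes, 4 replicates)
and run the full pipeline:

```bash
cat > sim.yaml <<EOF
seed: 11
n_target_genes: 8
n_background_genes: 32
n_transposon_genes: 1
gene_length_range: [200, 400]
EOF
serp simulate --config sim.yaml --out dataset

cat > pipeline.yaml <<EOF
paths:
  annotation: dataset/annotation.gtf
  chrom_sizes: dataset/chrom.sizes
  tracks_dir: dataset
  proteins: dataset/proteins.fasta
  truth_set: dataset/true_positives.txt
  negative_set: dataset/true_negatives.txt
  output_dir: results
baits: [bait]
calibration_bait: bait
replicates: 4
seed: 11
EOF
serp run --config pipeline.yaml
```

which prints

```
bait: quantified=40 prefiltered=24 hits=8 threshold=53.81% (calibrated)
manifest: results/manifest.json
```

All 8 planted targets are recovered at the calibrated scaled-AUC cut-off of
53.81% with no false positives. `results/hits.bait.tsv` holds the per-gene
decision records (the top rows are the planted targets, scaled AUC ≈ 86%
against a background centered on 50%), and `results/onsets.bait.tsv` the
onset calls:

```
gene_id     bait  onset_nt  onset_codon  release_codon  mode      threshold_used
gene_0010   bait  295       99           NA             enduring  2
gene_0014   bait  408       136          NA             enduring  2
gene_0015   bait  89        30           NA             enduring  2
```

The planted onsets for these genes were codons 109, 138 and 40: detected
onsets sit a few codons upstream, the expected small bias of threshold
crossing on centered-smoothed profiles (see `docs/methods.md`).

The same analyses are available as a library (`serptools.simulate_dataset`,
`serptools.analyze_experiment`, `serptools.calibrate_threshold`,
`serptools.call_onset`, …) for in-memory simulation studies.

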