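# spermage

Analysis pipeline for detecting **age-associated DNA methylation changes in
paired sperm methylomes** — the design in which each donor provides two
samples years apart, so every methylation difference is measured within an
individual and tested for consistency across the cohort.

It is written for epigenomics researchers who want a transparent, fully
seeded re-implementation of the classic paired sliding-window scan:

* **Window scanner** — the core method. Probe-anchored 1000-bp candidate
  windows are enumerated over the array manifest; for each window the paired
  probe-level differences Δ<sub>pd</sub> = β<sub>aged</sub> − β<sub>young</sub>
  (probes × donors) are summarised by the Hodges–Lehmann pseudo-median
  (median of all Walsh averages (Δ<sub>i</sub>+Δ<sub>j</sub>)/2, i ≤ j) and
  tested with the Wilcoxon signed-rank test (exact null for n ≤ 25, tie-
  corrected normal approximation beyond). P-values are corrected across all
  candidate windows by Benjamini–Hochberg; a window is significant when
  q ≤ 10⁻⁴ and |log₂(pm<sub>aged</sub>/pm<sub>young</sub>)| ≥ 0.2, then it
  must survive an OLS regression of the per-sample window mean on age at
  collection (p ≤ 0.05). Significant windows of one direction merge into
  regions. FDRs are reported on the −10·log₁₀(q) scale (40 ⇔ q = 10⁻⁴,
  20 ⇔ 0.01, 13 ⇔ 0.05).
* **Preprocessing** — β = M/(M+U) from probe intensities, QC probe
  filtering, and the global (LINE-1-style) methylation trend: paired t-test
  on per-donor differences plus OLS of mean methylation on age.
* **Annotation** — CpG island / shore (±2 kb) / other context, promoter vs
  gene-body assignment, co-localization with nucleosome-retention and
  histone-mark tracks within 1 kb (Fisher exact on hypo vs hyper), and
  100-kb chromosomal cluster calling against a seeded permutation
  background.
* **Single-molecule analysis** — per-read epiallele profiles from targeted
  bisulfite amplicons: consensus CpG count (highest count covered by ≥ 10%
  of reads), binning by methylated-CpG count, pooling by age group
  (< 45 vs ≥ 45 years) and normalization to 100 reads.
* **Disease enrichment** — chi-squared (Fisher fallback at small expected
  counts) comparison of disease-association frequency in the affected gene
  set against the background of all disease-associated genes, Bonferroni
  corrected.
* **Synthetic data** — a seeded generator producing every input above with
  planted linear per-year drift at known windows, so each stage is
  verifiable end-to-end without donor data.

## Worked example

```sh
spermage demo --seed 7 --out-dir demo7
```

runs the full pipeline on a small generated cohort (17 paired donors,
500 candidate windows, 20 planted hypo- and 4 hypermethylation windows) and
prints:

```
regions: 20 hypo / 4 hyper regions; report in demo7/run_report.json
```

The run report shows each stage's counts. For seed 7:

```json
"scan": {
  "probes": 5000,
  "candidate_windows": 500,
  "significant_windows": 24,
  "windows_after_regression_filter": 24,
  "regions": 24, "regions_hypo": 20, "regions_hyper": 4
}
```

— every planted window is recovered and nothing else: the scanner calls 24
significant windows out of 500 candidates, all surviving the regression
filter, merging to exactly the 20 + 4 planted regions. The global-trend
stage reports a recovered slope of 0.00208 fraction methylation per year
(0.208 %/yr, regression p ≈ 8·10⁻¹⁵) against a planted 0.002, and the
enrichment stage flags the one planted disease (`disease_01`,
Bonferroni p ≈ 2.5·10⁻¹⁶) among 7 tested. `regions.tsv` lists the merged
calls, e.g.

```
chrom   start   end     direction  n_windows  best_q      mean_log2
chr1    22000   23000   hypo       1          2.99e-14    -0.379
```

The same stages are available individually (`spermage simulate`, `scan`,
`annotate`, `reads`, `enrich`, `run-all --config cfg.yaml`) and as library
functions (`spermage.scan`, `spermage.pseudo_median`, …).

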