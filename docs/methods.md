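# Methods

## The paired scanning model

The pipeline targets a longitudinal design: each of `n_donors` donors
(default 17) provides a *young* and an *aged* sample, collected 9–19 years
apart, with age at first collection between 23 and 56 years. Methylation is
observed as array-style β values in [0, 1] (β = methylated intensity /
total intensity). The working model is that a small set of genomic windows
drifts linearly with age at a per-window rate (fraction methylation per
year), identically across donors, while everything else is stable; the
scanner's job is to find those windows from the paired differences.

A candidate window is anchored at each manifest probe and spans 1000 bp.
Since probes are position-sorted, a candidate's probe set is a contiguous
run; candidates whose probe set is contained in an earlier candidate's are
collapsed (equivalently: keep the first anchor per distinct right
endpoint). Windows with fewer than 3 probes are discarded. This reproduces
sliding-window behaviour without assuming a step size, and merged calls
can end up shorter or longer than 1000 bp.

Per window, the test statistic pools **probe-level paired differences**
(probes × donors, ~5 × 17 = 85 observations). This choice is load-bearing:
with one observation per donor the minimum attainable two-sided exact
signed-rank p at n = 17 is 2·2⁻¹⁶ ≈ 3·10⁻⁵, which can never survive a
BH threshold of q ≤ 10⁻⁴ across thousands of windows; probe-level pooling
makes the published threshold attainable and matches window-level pooling
of a regional scanner. The cost is that probes within a window are treated
as exchangeable replicates of the regional effect.

Statistics per window:

* location — Hodges–Lehmann pseudo-median (median of all Walsh averages),
  robust to outlier probes/donors; computed for the paired differences and
  for each group's per-sample window means;
* effect size — log₂((pm_aged + ε)/(pm_young + ε)) with ε = 10⁻⁶ guarding
  zero pseudo-medians;
* significance — two-sided Wilcoxon signed-rank on the pooled differences.
  Zeros are dropped before ranking, ties get average ranks. For n ≤ 25 the
  null is the exact sign-flip permutation distribution (computed by
  convolving the rank-sum generating polynomial over doubled ranks so tied
  half-ranks stay integral); beyond that, a normal approximation with the
  standard tie-corrected variance n(n+1)(2n+1)/24 − Σ(t³−t)/48 and no
  continuity correction;
* multiplicity — BH step-up across **all** candidate windows passing the
  probe minimum, before any other filter, so the multiple-testing universe
  is fixed by the manifest, not by effect sizes;
* the regression filter (OLS of per-sample window mean on age at
  collection, keep iff p ≤ 0.05) runs **after** significance, as an
  additional screen; slopes are reported both as fraction/year and as
  %/year (×100);
* a paired t-test on per-donor window means is attached for confirmation
  but never filters.

Calling: significant = q ≤ 10⁻⁴ and |log₂ ratio| ≥ 0.2 and regression
keep. Overlapping or book-ended significant windows of one direction merge
into regions (book-ended merging avoids arbitrary 1-bp splits). Baseline
classification uses the young-group pseudo-median: low < 0.2,
intermediate 0.2–0.8, high > 0.8. Transformed FDRs are −10·log₁₀(q) with
q floored at 10⁻³⁰ (flagged) to keep the scale finite.

Degenerate inputs: all-zero differences give p = 1 (flagged); zero age
variance makes the regression filter inapplicable and drops the window
with a warning; zero variance of paired differences leaves the t-test
undefined (NaN, flagged); missing β values are excluded pairwise, never
imputed.

## What the synthetic generator emulates

`SyntheticConfig` defaults are the study conditions: 17 paired donors
(young age ~ U(23, 56), interval ~ U(9, 19) years), 10,000 candidate
windows tiled as 5-probe clusters (span 600 bp, pitch 6 kb over 20
chromosomes) plus background probes placed so they can never form a ≥3-
probe window, 139 planted hypo- and 8 hypermethylation windows, per-year
drift magnitudes U(0.0008, 0.0095) (0.08–0.95 %/yr), probe noise SD 0.02,
planted baselines U(0.2, 0.6) for hypo and U(0.05, 0.4) for hyper windows
(age-hypermethylating regions start low and stay low).

The β model is

    β(p, s) = clip( base_p + offset_d + drift_w · (age_s − mean young age) + ε,  0, 1 )

with per-donor offsets (SD 0.005) that cancel in paired differences,
independent Gaussian probe noise (a moment-matched Beta noise model is
available via `noise_model="beta"`), and drift anchored at the mean young
age so young-sample values sit at the configured baseline.

`recovery_config()` adds two floors to the sampled drift magnitude,
defining the planted-effect conditions for the recovery experiment: the
group |log₂ ratio| at the mean interval reaches 0.4 (so it is safely
beyond the 0.2 call threshold, and ≥ 0.3 as realised across donor-interval
sampling), and the absolute β change at the mean interval reaches 0.035 —
the cohort-scale average change at significant windows (0.032–0.039), and
the level at which a 0.02-noise Wilcoxon/BH test at ~85 paired
observations is decisively powered even at low baselines. Without the
second floor a low-baseline hypermethylation window can satisfy the
relative (log₂) condition with an absolute change of ~0.015 that is not
reliably detectable — a property of the statistics, not a bug.

Read populations are two-component beta-binomial mixtures (concentration
30) per amplicon and age group; the three default amplicons emulate the
three observed population shifts (low→lower, single shifted population,
bimodal→unimodal). A 5% minority of reads carries one extra CpG to
exercise the 10% consensus rule. The disease table is Bernoulli
association (rate 0.1 over 12 diseases) with one disease's rate multiplied
by 10 among the genes at planted windows. Global methylation is a linear
age trend (+0.002/yr around 0.72) with SD 0.01.

What it does **not** emulate — and hence what passing tests cannot show
about real data: array dye/Infinium chemistry and batch effects, probe-
density bias of promoter arrays, bisulfite conversion error, donor-specific
drift rates or nonlinear aging, correlated noise between neighbouring
probes, LD-like structure between windows, and a realistic genome-wide
bimodal β landscape outside the planted clusters. Recovery results measure
the scanner's correctness under its own model, not array performance.

## Numerical and design choices

* **Seeding** — one master seed; each artifact draws from
  `default_rng([seed, stream_tag])` with fixed tags, so adding artifacts
  never perturbs existing ones and identical configs give byte-identical
  files.
* **QC polarity** — the filter removes probes with QC p < 0.05 exactly as
  the source convention states it; since the usual detection-p convention
  is inverted, `polarity="above"` is an escape hatch for real data.
* **Coordinates** — manifest positions 1-based; every emitted interval
  0-based half-open BED. Co-localization distance is the edge-to-edge gap
  between half-open intervals (overlap ⇒ 0); "within 1 kb" is edge-to-edge,
  not midpoint.
* **Shores** — ±2 kb island flanks (standard convention; the upstream
  description never defines the flank).
* **Promoters** — strand-aware 1 kb upstream of / overlapping the TSS,
  with promoter precedence over body when both apply.
* **Chromosomal clusters** — occupancy counted by region midpoints (avoids
  double-counting long regions); background is uniform per-chromosome
  placement of the same number of midpoints, 1000 permutations by default
  (200 in the bundled pipeline for speed), add-one empirical p-values so
  p ∈ [1/(B+1), 1].
* **Consensus CpG rule** — "highest count covered by ≥ 10% of reads" is
  read as *exactly* that count (`rule="exact"`); a cumulative
  `rule="at_least"` variant is provided since the phrasing admits both.
  Reads longer than the consensus are discarded, not truncated. Age 45
  exactly goes to the aged group. Spline smoothing affects plots only.
* **Enrichment margins** — with the default background (genes with ≥ 1
  association, minus hits) the hit margin is likewise restricted to hit
  genes inside that universe, so both margins are drawn from the same gene
  pool; otherwise hit genes without any association deflate the hit rate
  and the unit-enrichment false-positive rate inflates far above nominal
  (observed ~34% instead of ~5%). A whole-genome background can be passed
  explicitly, in which case hits count as given. The Pearson chi-squared
  statistic (no continuity correction) is always reported; the p-value
  falls back to Fisher's exact test when any expected cell is below 5.
* **Problem sizes** — the acceptance script runs the reference scale
  (10,000 candidate windows, ~100,000 probes, 34 samples; a few minutes on
  one CPU). The test suite uses 120–500-window cohorts for end-to-end
  checks, 20 seeds for null specificity, and 100 seeds for chi-squared
  calibration; these sizes were chosen so the whole battery stays desk-
  scale while keeping every binomial/calibration band well-powered.

## Known limitations

* The scanner treats probes within a window as exchangeable; strong
  probe-level heterogeneity would be diluted rather than modelled.
* The BH universe is the candidate-window list, whose windows overlap and
  are therefore positively dependent; BH is robust to this (PRDS) but the
  q-values are conservative rather than exact.
* The exact signed-rank null conditions on the observed tie pattern of
  |differences|; with heavily discretised β data this is the standard but
  not unique convention.
* The permutation background for chromosomal clusters ignores probe
  density, so on real promoter-biased manifests it is anti-conservative in
  probe-dense regions; a density-matched background is out of scope.
* Disease enrichment reproduces the statistic only; it does not attempt to
  reconstruct any historical annotation-database snapshot.
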