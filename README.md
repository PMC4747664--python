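# sdig — Simpson's diversity index for gene expression

`sdig` asks an ecologist's question of a transcriptome: how evenly is a
sample's total expression spread across its genes? Each sample's expression
vector *g* = (*g*₁ … *g*_S) is normalized to proportions
*p*ᵢ = *g*ᵢ / Σ *g*ᵢ and scored with the Gini–Simpson index

    D = 1 − Σᵢ pᵢ²,

which runs from 0 (all expression in one gene) to 1 − 1/S (perfectly even
expression over S genes). The package implements a tumor-vs-normal
comparison of this score for hepatocellular carcinoma (HCC) cohorts, where
tumor tissue tends to express genes more evenly — hence more "diversely" —
than adjacent non-tumor tissue:

* **preprocessing** for the platforms such cohorts come on: two-channel
  cDNA microarray spot tables (flag filtering, the 1.5×-background
  well-measured rule, background correction, paired-channel or
  reference-ratio expression), log-scale aCGH matrices (inverse transform)
  and FPKM RNA-seq matrices (passthrough), plus a ≥2-replicate gene filter
  and within-group mean imputation;
* **per-sample diversity** (`sdig.diversity`), with compensated summation —
  at 20 000 genes D sits at ~0.9996 and group differences live in the
  fourth or fifth decimal;
* **positive-pair statistics** (`sdig.pair_stats`): over all M×N
  (tumor, normal) sample pairs, Q counts pairs where the tumor diversity is
  strictly greater, T = 100·Q/(M·N) is the proportion of positive pairs
  (PPPN, complement PNPN), and PPS is the analogous percentage over matched
  tumor/normal pairs only;
* **inference** (`sdig.inference`): a one-sided Welch two-sample t-test of
  mean tumor diversity > mean normal diversity, plus five-number summaries
  for box plots;
* **synthetic data** (`sdig.synthetic`): symmetric-Dirichlet expression
  profiles with controllable evenness (E[D] = 1 − (α+1)/(Sα+1) in closed
  form), simulated spot tables with known filter survivors, missing values —
  everything needed to exercise the pipeline without downloads.

## Worked example

```python
import sdig

# a paired cohort: 1000 genes, 20 tumor + 20 normal samples, tumor drawn
# more even (Dirichlet alpha 2.0) than normal (alpha 0.5)
cfg = sdig.SimulationConfig(paired=True, seed=2026)
matrix, truth = sdig.simulate_expression_matrix(cfg)

from sdig.preprocess import replicate_filter, impute_missing
matrix = impute_missing(replicate_filter(matrix))

report = sdig.dataset_report(matrix, paired=True, dataset_id="demo")
row, test = report["row"], report["test"]
print(f"Q = {row['Q']}, T = {row['T_pct']:.1f}%, PPS = {row['pps_pct']:.1f}%")
print(f"mean D tumor {row['mean_tumor']:.6f} vs normal {row['mean_normal']:.6f}")
print(f"Welch t = {test.t_statistic:.2f}, one-sided p = {test.p_value:.3g}")
```

prints

```
Q = 400, T = 100.0%, PPS = 100.0%
mean D tumor 0.998525 vs normal 0.997156
Welch t = 43.61, one-sided p = 9.65e-23
```

All 400 tumor/normal cross pairs are positive (T = 100%), every matched
pair is tumor-dominant (PPS = 100%), and the group means straddle the
closed-form expectations (0.998501 / 0.997006), so the evenness advantage
built into the simulation is recovered and is overwhelmingly significant.

The same analysis is scripted as a narrative under `analysis/`:
`01_simulate_cohorts.py` → `02_preprocess_two_channel.py` →
`03_diversity_comparison.py` → `04_null_calibration.py` →
`05_published_table_consistency.py`, each writing its tables under
`results/`. `analysis/06_real_geo_data.py` reruns real GEO accessions when
you download them and drop a YAML config under `data/geo/` (the six HCC
accessions GSE5093, GSE3500, GSE4024, GSE1898, GSE65484 and GSE65485 have
ready-made presets in `sdig.pipeline.PRESETS`; the data are not
redistributed here).

There is also a thin CLI: `sdig simulate | compute | compare | test | run`
(see `sdig --help`).

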