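# Methods

## The diversity score

A sample with expression vector *g* = (*g*₁ … *g*_S), *g*ᵢ ≥ 0, is scored
by the Gini–Simpson index of its expression proportions
*p*ᵢ = *g*ᵢ / Σ *g*ᵢ:

    D = 1 − Σᵢ pᵢ².

D is the probability that two units of expression drawn at random come
from different genes: 0 when a single gene carries everything,
1 − 1/S when all S genes are expressed equally. Two properties carry the
whole analysis and are enforced by property tests: scale invariance
(D(c·g) = D(g) for c > 0, so sequencing depth and labeling intensity
cancel) and monotonicity in evenness (transferring expression from a
low-proportion gene to a high-proportion one lowers D; merging two genes
with proportions a, b lowers D by exactly 2ab).

Zero-expression genes contribute p = 0 and are retained in the gene count;
they do not change D. With genome-scale S the index crowds against 1
(D ≈ 0.9996 at S ≈ 20 000) and group differences occupy the fourth decimal,
so Σp and Σp² use compensated (`math.fsum`) summation; proportions must sum
to 1 within 1e−12.

## Group comparison

With M tumor diversities DT₁…DT_M and N non-tumor diversities DN₁…DN_N:

* **Q** — the number of cross pairs (j, k) with DT_j > DN_k, strictly;
  a tie is not a positive pair. The production count sorts the normals and
  uses a binary-search sweep; tests pin it to the definitional double loop.
* **T (PPPN)** = 100·Q/(M·N) percent, complement PNPN = 100 − T. Stored at
  full precision; *display* rounding is half-up at a per-dataset precision
  (see "Display rounding" below).
* **PPS** — for cohorts with matched tumor/normal pairs only: the percent
  of matched pairs with tumor diversity strictly greater. Computed on the
  M matched pairs, never the cross product; reported as not-available for
  unpaired designs rather than raising.
* **Welch one-sided t-test** of H₁: mean tumor D > mean normal D, with
  Welch–Satterthwaite degrees of freedom, sample variances (n−1), and
  significance at p < 0.05 (0.01 reported as a second level). The same
  two-sample test is applied to paired cohorts as well — pairing informs
  only PPS. That forgoes the power of a paired test when pairing is
  informative; it is kept deliberately so paired and unpaired cohorts are
  compared on the same footing. Quartiles for the box-plot summaries use
  linear interpolation.

## Preprocessing

Two-channel microarray spot tables carry per-spot uncorrected mean
intensities (`ch1i_mean`, `ch2i_mean`), median local backgrounds
(`ch1b_median`, `ch2b_median`) and a quality flag (0 good, −50 no signal,
−100 poor signal). The cascade, in order:

1. **Flag filter** — only flag = 0 spots are kept.
2. **Well-measured rule** — the *uncorrected* intensity must exceed
   1.5 × the background median in *both* channels. Strict inequality at
   the boundary, and the uncorrected reading of "intensity"; both choices
   are defensible readings of the rule, so the factor and strictness are
   parameters (`factor=1.5`, `strict=True`).
3. **Background correction** — `chNd_mean = chNi_mean − chNb_median`;
   negatives are retained here.
4. **Expression values** — either *paired channels* (tumor and normal
   co-hybridized; each corrected channel becomes one sample's expression,
   negative corrected values become missing) or *reference ratio* (one
   channel a common reference; expression = sample/reference corrected
   intensity, spots with non-positive reference dropped). Negative values
   cannot enter: a proportion of total expression must be non-negative.
   Duplicate spots per gene are averaged after filtering.
5. **Replicate filter** — genes with fewer than 2 non-missing measurements
   across the whole dataset are dropped (threshold exposed).
6. **Imputation** — a missing cell takes the gene's observed within-group
   mean, falling back to the gene's overall observed mean when the group
   has no observation. Deterministic and parameter-free; chosen as the
   simplest method consistent with comparing group means afterwards
   (within-group means are unbiased for the group-level quantities the
   analysis consumes).

Log-scale matrices (aCGH) are inverse-transformed as base^v with base 2 by
default (the usual convention; exposed as a flag); FPKM matrices pass
through. No between-array normalization is performed — the diversity score
is scale-invariant per sample, which is the pipeline's normalization.

## Synthetic data

The generator draws each sample's proportions from a symmetric
Dirichlet(α) over S genes — the minimal evenness-controlled model on the
simplex. The closed form

    E[Σ pᵢ²] = (α + 1)/(Sα + 1),  E[D] = 1 − (α + 1)/(Sα + 1)

anchors the Monte-Carlo checks (20 000 draws at S = 3, 5 000 at S = 100,
2 000 at S = 1000, each within 3 empirical standard errors). Matrices
scale proportions by a global intensity and per-sample lognormal depth
(σ = 0.3), exercising scale invariance end to end; missing cells are
injected completely at random (default 5%). Spot tables are background
(gamma, mean 100) plus exponential signal on the same scale, so roughly
e^(−0.5) ≈ 61% of spots clear the 1.5× rule per channel and both filter
outcomes are well populated; flags are multinomial (90% / 5% / 5%). The
generator records the exact survivor set as an oracle for the filters.

Default cohort: S = 1000 genes, 20 + 20 samples, α_tumor = 2.0,
α_normal = 0.5 — a marked evenness advantage for tumor
(E[D] 0.9985 vs 0.9970). Null calibration uses α = 1 in both groups over
500 seeded replicates; the Welch rejection rate at 0.05 must sit within
3 binomial standard errors.

What the simulation does *not* emulate: gene–gene correlation, pathway
structure, platform-specific intensity response, batch effects, or
informative missingness. Passing tests therefore certify the pipeline's
arithmetic and its behavior under a controlled evenness signal, not
biological validity on real cohorts.

## Display rounding

The published per-dataset summaries display T at mixed precision (whole
percents for four datasets, one decimal for two) and round 85.75 up to 86.
No single precision rule reproduces every printed cell, so the package
stores full precision and renders displays by round-half-up at a
per-dataset decimal count recorded with the dataset descriptors
(`sdig.study`). The displayed mean T over the six datasets is the mean of
displayed values, rounded half-up (72.45 → 72, PNPN 28).

## Degenerate inputs and errors

All-zero expression vectors, empty groups, groups of size < 2 for the
t-test, and two zero-variance groups raise typed errors
(`DegenerateInputError` / `ValidationError`) naming the offending sample or
coordinate. Parsers never silently drop rows: rejected counts are logged
and kept + rejected = total. Missing values are NaN, never 0.

## Known limitations

* The real-cohort microarray reproduction depends on an imputation step
  whose original method is unspecified; different imputations perturb Q
  and T slightly, so real-data reruns are verified for direction
  (tumor mean ≥ normal mean), not digit-for-digit.
* D saturates with S: comparing cohorts profiled on platforms with very
  different gene counts compares different ceilings (1 − 1/S). Within-
  cohort contrasts (as here, with a common gene set per dataset) are
  unaffected.
* The one-sided test answers only "is tumor more diverse"; evidence in the
  opposite direction shows up as p > 0.5, never as significance.
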