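# Methods

## The experimental layout

Everything in this package assumes a balanced nested factorial: 2 geographic
origins (N, S) × 2 clonal genotypes nested within origin × 2 acclimation
temperatures (18 °C, 28 °C) × r biological replicates (default r = 3; 24
samples). Origins and temperatures are fixed factors; clones are random
draws from their origin's population. The balance is load-bearing: all sums
of squares are computed in closed form from cell and marginal means, and the
loaders reject any unbalanced design rather than approximating it.

## Per-gene nested mixed-model ANOVA

For one gene with observations y aligned to the design, the decomposition is

| term          | df (default) | SS                                                       |
|---------------|--------------|----------------------------------------------------------|
| T             | 1            | Σ_t n_t (ȳ_t − ȳ)²                                       |
| geo           | 1            | Σ_g n_g (ȳ_g − ȳ)²                                       |
| clone(geo)    | 2            | Σ_c n_c (ȳ_c − ȳ_geo(c))²                                |
| T×geo         | 1            | Σ_{t,g} n_{tg} (ȳ_{tg} − ȳ_t − ȳ_g + ȳ)²                 |
| T×clone(geo)  | 2            | Σ_{t,c} n_{tc} (ȳ_{tc} − ȳ_c − ȳ_{t,geo(c)} + ȳ_geo(c))² |
| error         | 16           | within-cell                                              |

These are the sequential (type-I) projections, which coincide with every
other type under balance; the test suite verifies them against an
independent indicator-matrix least-squares oracle at 1e-8.

Denominators follow the expected mean squares of the mixed model: T and
T×geo over MS(T×clone(geo)); clone(geo) over the residual. The geo
denominator is not uniquely dictated by the classical EMS table; we use
MS(clone(geo)) on (1, 2) df, the standard choice for a fixed factor sitting
over a nested random factor.

**Conditional pooling.** The T×clone(geo) denominator has only 2 df, so a
per-gene pre-test is applied: F = MS(T×clone)/MS(error) on (2, 16) df; if
its P exceeds 0.2 *strictly*, the interaction SS is pooled with the error SS
and the fixed effects are tested against (SS_T×clone + SS_error)/18 on
(1, 18) df. The pooled denominator applies to both T and T×geo by default
(`pool_applies_to="T"` restricts it to T). Region-wise tests (12
observations, 2 clones crossed with 2 temperatures) use the same rule with
(1, 1) unpooled and (1, 9) pooled df. A fully pooled alternative — T against
(SS_clone + SS_T×clone + SS_error)/10, algebraically the paired t-test on
temperature pairs — is provided for comparison but is less conservative and
not used in the default calls.

**Consequences of the pre-test (verified empirically in the suite).**
Conditional pooling is a selection step, and two of its consequences are
easy to miss:

- Under a complete null, each branch's *unconditional* sampling distribution
  of p_T is exactly uniform, and so is the pooled branch among the genes
  where the pre-test selects it. The unpooled branch *as selected*, however,
  is conservative: landing there means the interaction MS was large, which
  deflates the observed F for T. The marginal distribution of the reported
  p_T is therefore slightly conservative — FDR control is preserved.
- Power is capped by the pooling rate. A gene routed to the unpooled branch
  faces a 2-df (genome-wide) or 1-df (region) denominator on which even an
  enormous F cannot reach a BH-corrected threshold in a genome-scale batch.
  With no true interaction variance the pre-test still diverts 20% of genes
  (its calibrated rate) to that branch, so recovery of strong planted
  temperature effects plateaus near 80%; with realistic interaction variance
  (sigma_tclone ≈ 0.4·sigma_e) it drops towards 55%. Recovery *among pooled
  genes* is essentially complete at the planted effect sizes.

**Multiple testing.** Benjamini–Hochberg step-up q-values are computed
separately within each p-value family — genome-wide T, genome-wide T×geo,
and region-wise T for N and S — matching the way the margins of the
direction cross-tab are reported. Constant-expression genes get p = 1, are
flagged, and are excluded from each family's m (q = NaN) so they cannot
dilute the correction. Benjamini–Yekutieli is available as an option.
Degenerate denominators follow 0/0 → p = 1 (flagged constant) and x/0 →
p = 0.

## Plasticity classification and cross-tabulation

Per-origin plasticity is Δ = mean(28 °C) − mean(18 °C) over the 6 replicate
values (2 clones × 3 replicates), computed from raw balanced means (equal to
model-estimated effects under balance). Direction calls are up/down when the
region q_T < alpha and Δ is positive/negative, else ns; the 3×3 N×S
cross-tab with margins summarizes them. Genes with genome-wide q_T×geo <
alpha are classified Baldwin when |Δ_S| > |Δ_N|, canalized when |Δ_S| <
|Δ_N|; exact equality is kept as an explicit tie rather than broken
arbitrarily (a measurable event on synthetic data). Swapping the N/S labels
provably exchanges the two classes, and the suite checks this exactly.

## Enrichment

Each pathway is tested with Fisher's exact test (two-sided by default;
`greater` available) on the 2×2 table of (DE, non-DE) × (in, out of
pathway), with non-differentially-expressed genes as the reference margin.
The universe defaults to every gene in the matrix — mirroring an analysis
with no background-intensity filtering — with an annotated-only option.
BH correction runs across pathways. Odds ratios with an empty cell in the
denominator product are reported as inf (sentinel) rather than dropped.
KOG-identifier lists (one id per line, deduplicated, unannotated genes
counted and skipped) are written per direction for the all/N/S gene sets, in
the format pathway-projection servers such as iPATH accept.

## PCA geometry

Genes are centered across samples (no unit-variance scaling by default:
after quantile normalization all genes share an intensity scale; `scale=True`
is available). Sample scores are V·S from the SVD of the centered matrix;
variance fractions are s_i²/Σ‖·‖². Sign convention: each component is
oriented so the summary 18→28 °C arrow has a non-negative component on it,
making outputs deterministic across SVD implementations. Replicate-group
Euclidean centroids define per-clone 18→28 arrows, the summary temperature
arrow, and the N→S origin arrow; pairwise cosines among clone arrows
(how parallel the plastic responses are) and the temperature-origin cosine
(whether standing divergence is orthogonal to plasticity) are reported both
in the first-3-PC subspace and in full score space.

## Normalization and summarization

Quantile normalization maps every sample column onto the reference
distribution of order-statistic means. Ties within a column receive the mean
of the tied reference quantiles — the common microarray dialect. This makes
the transform rank-preserving and idempotent on tie-free columns; when ties
exist, tie-averaging alters the column's value multiset, so a second pass is
not a strict no-op (the suite tests idempotence on tie-free data and the tie
rule separately). Probe-level matrices (1–3 probes per gene) are summarized
to genes by the per-sample median; with an even probe count the midpoint of
the central pair is used. Input is assumed log2; a `log2` flag transforms
raw intensities with a hard error on non-positive values. Missing cells are
rejected (balanced closed-form ANOVA requires complete rows) unless
`drop_incomplete_genes` removes the affected genes.

## The synthetic-data generator

Expression is generated as

```
E_is = mu_i + tau_i·x_T + gamma_i·x_G + taugamma_i·x_T·x_G
       + a_{i,clone} + b_{i,clone}·x_T + eps_is
```

with effect coding x_T ∈ {−1 (18 °C), +1 (28 °C)}, x_G ∈ {−1 (N), +1 (S)},
clone intercepts a ~ N(0, sigma_clone²) and slopes b ~ N(0, sigma_tclone²)
drawn once per gene × clone (independent across genes: the per-gene ANOVA
treats genes independently, and sharing clone effects across genes would
induce cross-gene correlation the analysis does not model), and iid residual
noise. Under this coding per-origin plasticity has the closed form
Δ = 2(tau + taugamma·x_G), so Baldwin genes (|Δ_S| > |Δ_N|) are planted by
giving tau and taugamma the same sign and canalized genes by opposite signs;
the truth table records every parameter and the implied Δ values.

Defaults describe a mostly-null genome: 85% null genes, 6% temperature-only,
3% origin-only, 3% + 3% GxE classes; half-effects drawn uniformly from
0.25–1.0 log2 units per class (so temperature effects of 1–2 log2 units,
i.e. 2–4 fold); noise sigma_e = 0.25, sigma_clone = sigma_tclone = 0.1 log2
units; baselines uniform on 6–12 log2 intensity. Dye/array effects are not
simulated: the fitted model contains no dye term, and dye-swap structure is
treated as absorbed by normalization. Calibration simulations (FDR control,
pooling rate, null uniformity, enrichment calibration) use pure residual
noise (sigma_e = 1 or 0.25, other sigmas 0) so each layer is tested in
isolation; the enrichment-power simulation likewise plants strong
temperature effects without interaction variance, since the pooling-rate
power cap above otherwise throttles the DE list that feeds Fisher's test.

The annotation generator assigns each gene a KOG id (90% of genes by
default) and samples pathway memberships (default 125 pathways of 10–60
genes, genes reusable across pathways); enriched pathways sample genes with
selection weight = the odds multiplier (default 8) on non-null genes.

What the generator does *not* emulate: probe-sequence or hybridization
physics, spatial array artifacts, heavy-tailed or intensity-dependent noise,
correlated gene modules, and mean–variance coupling. Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery
under the stated model, not robustness to every failure mode of real
microarray data.

## Problem sizes and determinism

Calibration simulations run at 10,000 genes × 24 samples (a desk-scale
stand-in for a ~29k-gene array; the vectorized closed-form ANOVA makes this
a sub-second fit), recovery and enrichment simulations at 400–5,000 genes.
All randomness flows from a single seed; pipeline stages derive sub-seeds
via `SeedSequence([seed, stage_index])`, and re-running with the same
configuration reproduces every output byte-identically.

## Known limitations

- Unbalanced or incomplete designs are rejected, not approximated; there is
  no REML/likelihood fallback.
- No empirical-Bayes variance moderation: genes are fitted independently,
  which is exactly the classical route but less powerful at tiny n than
  shrinkage estimators.
- The conditional pooling rule's selection effects (conservatism and the
  power cap described above) are inherent to the published procedure and are
  reported, not corrected.
- Enrichment treats genes as exchangeable units; KOG-level aggregation is a
  thin convenience, not an ontology-aware method.
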