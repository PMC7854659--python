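# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and what the tests do and do not demonstrate.

## Study design assumed throughout

A two-condition, multi-tissue bulk RNA-seq experiment: each of three
tissues is sampled from the same animals under a control (CON) and a
treatment (RES) condition, seven biological replicates per condition by
default. Counts arrive as one genes × samples matrix with sample metadata
(tissue, condition, sex). Gene lists — differentially expressed genes (DEG,
from a companion differential-expression analysis) and a transcription
factor (TF) catalogue — are plain-text inputs; this package deliberately
does not compute differential expression or retrieve TF catalogues.

## Preprocessing

Two normalization strategies coexist because downstream consumers differ:

1. **Pooled** — all samples of all tissues together. Consumed by the Tau
   index, RIF scoring, and the tissue-to-tissue network, all of which
   compare expression *across* tissues and therefore need one common scale.
2. **Per-tissue** — each tissue's samples alone, plus a low-dispersion
   filter. Consumed by the condition-contrast analyses (differential
   co-expression and connectivity), which operate within one tissue.

Steps and defaults:

- **Low-expression filter**: a gene is dropped when its CPM is below 1 in at
  least 80% of samples; the boundary is read strictly as
  `n_low >= ceil(0.8 * n_samples)` (at 14 samples: 12 low samples remove,
  11 keep).
- **Size factors**: median-of-ratios against the per-gene geometric mean,
  restricted to genes with nonzero counts everywhere, rescaled to
  geometric mean 1.
- **Variance-stabilizing transform**: log2(count/sf + 1). This is a
  deliberate simplification of a fitted-dispersion VST: every consumer
  downstream needs only a monotone, roughly variance-stabilized scale, not
  the exact transform.
- **Dispersion filter** (per-tissue strategy only): the per-gene dispersion
  is the coefficient of variation of normalized values; genes below the
  0.2 quantile of that distribution are dropped. The CV-quantile reading is
  a stated choice — the measure is not uniquely pinned down by the
  literature this emulates — and it is isolated in one function.
- **Sex adjustment** (optional, default off): per-gene OLS residualization
  on the sex indicator with the grand mean restored. Off by default because
  the usual workflow folds sex into the upstream DE model instead.

## Tissue specificity (Tau)

τ = Σ(1 − x̂_i)/(n − 1) over per-tissue mean profiles, x̂ = profile /
max. Negative post-transform values are clipped to zero first so τ stays in
[0, 1] (the index assumes non-negative expression). Ties for the home
tissue break by tissue order. TS call at τ ≥ 0.8, inclusive. Properties
asserted by tests: scale invariance, permutation equivariance, and
monotonicity under concentration of mass onto the max tissue.

## Regulatory impact factors

RIF1 and RIF2 are widely used but their formulas circulate mostly as
implementations; the forms used here are

RIF1_i = (1/n_t) Σ_j ā_j d_j dw_ij²,
RIF2_i = (1/n_t) Σ_j [(e1_j r1_ij)² − (e2_j r2_ij)²],

with e1/e2 per-condition target means, ā their average, d their
difference, and dw the correlation change. This reconstruction is the
module's central assumption and lives in a single function
(`rif.rif_scores`) so an alternative variant is a one-function swap. Exact
algebraic properties (zero under identical conditions, antisymmetry under
condition swap, quadratic scaling in expression) are asserted in tests.
Scores are z-standardized over the TFs of one tissue; because the raw-score
distribution is finite and heavy-tailed, the fraction passing p ≤ 0.01 under
a null is only approximately nominal (the test asserts ≤ 0.10 on average).
A TF is "key" when either metric passes, two-sided.

## PCIT

For each conditioning gene z the three first-order partials and the trio
tolerance ε (mean partial/raw ratio) are computed; x–y is eliminated if
|r_xy| ≤ |ε·r_xz| and |r_xy| ≤ |ε·r_yz| for some z. Numerical guards, applied
identically in the naive oracle and the vectorized sweep:

- a ratio with |raw| < 1e−12 counts as 1 (maximal redundancy) rather than
  dividing by ~0;
- a flank with |r| = 1 makes the partial undefined; z is then treated as
  fully explaining the pair (eliminated);
- a pair with |r_xy| = 1 (duplicate genes) is never eliminated.

Note the tolerance rule is *permissive* for strongly correlated trios: a
pure common-driver pair with |r_xy| ≈ 0.9 survives, because ε < 2/3 in that
configuration. This is a property of the rule, not a bug (tests pin it
down with the brute-force oracle); the downstream edge rule additionally
requires |r| > 0.9 on surviving pairs, and a flag allows thresholding the
minimum |partial| instead. The vectorized path does one broadcasted
O(n²) sweep per conditioning gene (O(n³) work, O(n²) memory); it is
practical to roughly 3,000 genes on one core, and mask equality with the
naive O(n³) loop is asserted exactly, not approximately.

Condition-specific networks retain an edge only when an endpoint is a DEG
or TF — the rule used for the rewiring contrast — while the
tissue-to-tissue network takes the prioritized union DEG ∪ TS ∪
significant TFs as its node set.

Topology statistics: degree; global average of local clustering
coefficients (0 for degree < 2); per-group mean degree; hubs at degree ≥
mean + 2 SD (note a single spike among n nodes can only clear 2 SD when
(n−1)/√n > 2, i.e. n ≥ 6); scale-free fit as R² of the log10 frequency vs
log10 degree regression over distinct positive degrees, undefined (NaN)
below three distinct degrees.

## Differential co-expression

Analytic Fisher z difference test with BH adjustment by default; an
optional label-permutation mode (seed-controlled, add-one-corrected)
replaces the analytic p. At the default n = 7 per condition the normal
approximation is anti-conservative — the permutation mode is the safer
choice there, and the calibration claims in the tests use n = 30, where the
empirical type-I error at α = 0.05 lands in [0.04, 0.06] over 5,000 null
pairs. Classes map each condition to {+, −, 0} by (sign, p ≤ 0.05 on the
within-condition correlation t-test); 0/0 pairs are reported but sit
outside the eight informative classes. DC hubs use the shared
mean + 2 SD degree rule over significant-pair counts.

## Differential connectivity

K = degree / max degree per network; DK = K_CON − K_RES over the union of
node sets, with absent genes assigned K = 0 (they are maximally rewired) —
`drop_unshared=True` restricts to shared genes instead. DK is z-scored
with mean-centering by default; `center=False` gives the
divide-by-SD-only reading, one flag apart, since the phrasing "± 1.96 from
the SD" does not pin the centering down. Exchangeable inputs produce ~5%
significant calls by construction (checked on random graph pairs).

## Synthetic data generator

The generator is the package's test bed and defines its study conditions:

- **Count model**: per-gene, per-sample natural-log mean = baseline +
  planted effects + latent factors + N(0, bio_sd²) biological noise
  (bio_sd = 0.25), converted to within-sample proportions, scaled by a
  log-normal library size (mean 2e6, CV 0.1), then Gamma-Poisson with
  technical dispersion 0.01. Biological variability is thus carried by the
  explicit log-normal layer (which the correlation structure needs), and
  the NB dispersion covers residual technical overdispersion.
- **TS genes** (30/tissue): off-home abundance anchored at 0.5 CPM, home
  tissue elevated 100-fold. Anchoring in CPM units keeps the planted τ
  stable when the panel size changes — with a relative anchor, τ drifts
  with composition.
- **DE genes** (40): ±1 log2 fold change in RES, all tissues, alternating
  sign across genes.
- **Modules** (3 × 20 genes): one latent standard-normal factor per module
  and sample; the regulator carries it with loading 1 and no extra
  biological noise; target loadings are solved so the model-implied
  regulator–target correlation — including the expected count-noise
  variance ψ = dispersion + 1/μ — equals the configured coupling
  (a = ρ √((1+ψ)(σ²+ψ)/(1−ρ²(1+ψ)))). Verified by direct simulation at
  n = 500–1000: realized correlations sit within ±0.02 of target on the
  size-factor-normalized log scale. Default couplings CON→RES:
  0.9→0.9 (stable), +0.8→−0.8 (sign-flipped), 0.9→0.0 (decoupled);
  regulator–target pairs of modules with differing coupling are the
  planted "rewired" set. Target–target pairs correlate at ≈ ρ², so only
  regulator–target pairs flip sign in the ±0.8 module.
- **Module DE overlap**: half of each module's targets also receive the DE
  shift, with one coherent direction per module (alternating across
  modules). The coherence matters: RIF1's PIF weights are signed, and a
  regulator whose target program is half up- and half down-regulated
  scores near zero by cancellation — the coordinated program is the
  scenario RIF1 is designed to detect.
- **TF catalogue**: the module regulators plus background decoys sized to
  ~6.5% of the panel, the TF fraction typical of an expressed bovine
  transcriptome.
- **Sex**: balanced binary covariate, +0.35 natural-log additive effect on
  1% of genes, to exercise the optional adjustment.

What the generator does *not* emulate: batch effects beyond sex, read-level
artifacts, gene length and GC bias, count outliers, between-animal
correlation across tissues (samples are independent draws given the
factors), and realistic pathway-level correlation beyond the planted
modules. Passing recovery tests therefore demonstrates the pipeline's
statistical machinery under its own assumptions, not performance on real
tissue panels.

## Problem sizes and determinism

The default fixture (600 genes, 3 tissues, 7+7) runs the full workflow in
well under a minute on one core; recovery claims use a 30-per-condition
variant of the same fixture, where planted TS recall ≥ 95%, DC pair
recall ≥ 80% with class +/−, the decoupled regulator's |DK z| ≥ 1.96 and
the sign-flipped regulator ranks in the top 5% of |RIF1 z| — all verified
across multiple probe seeds before the test seeds were frozen. Every
stochastic component takes an explicit seed; `run_all` writes a manifest
(seed, thresholds, package versions, per-stage gene counts) sufficient to
reproduce a run bit-for-bit, and the test suite asserts byte-identical
reruns.

## Known limitations

- The RIF and PCIT formulas are reconstructions of algorithms whose
  reference implementations are not redistributable; both are isolated in
  single functions and their exact algebraic/oracle properties are pinned
  by tests, but variant implementations exist in the wild (e.g.
  sample-size-weighted correlations in RIF).
- The analytic DC p-value is anti-conservative at n = 7; use
  `permutations=` there.
- The CV-based dispersion filter is one defensible reading of "quantile
  dispersion"; results near the 0.2 quantile boundary depend on it.
- PCIT memory is O(n²) per conditioning gene; beyond a few thousand genes
  a chunked sweep would be needed.
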