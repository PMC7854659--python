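# coexnet

Multi-tissue, two-condition gene co-expression network analysis for bulk
RNA-seq. The package targets the classic developmental-programming design:
several fetal tissues (cerebrum, liver, muscle) sampled under a control
(CON) and a nutrient-restricted (RES) maternal diet, a handful of animals
per group, and the question *which regulatory relationships — not just which
genes — change between conditions?*

It provides, as composable library functions plus numbered analysis
drivers:

- **Tissue specificity (Tau).** For per-tissue mean expression x_i over n
  tissues, with x̂_i = x_i / max_i x_i,

  τ = Σ_i (1 − x̂_i) / (n − 1),

  τ = 0 for uniform and τ = 1 for single-tissue expression; genes with
  τ ≥ 0.8 are called tissue-specific (TS).
- **Regulatory impact factors (RIF1/RIF2).** Each candidate transcription
  factor i is scored against a target list (DE ∪ TS genes) by contrasting
  within-condition correlations r1_ij, r2_ij. With target abundance
  ā_j, differential expression d_j, PIF_j = ā_j·d_j and differential wiring
  dw_ij = r1_ij − r2_ij:

  RIF1_i = (1/n_t) Σ_j PIF_j · dw_ij²,  RIF2_i = (1/n_t) Σ_j [(e1_j r1_ij)² − (e2_j r2_ij)²],

  z-standardized over TFs; significance at p ≤ 0.01.
- **PCIT network inference.** Every gene trio (x, y, z) contributes first-order
  partial correlations and a local tolerance
  ε = (r_xy·z/r_xy + r_xz·y/r_xz + r_yz·x/r_yz)/3; the pair x–y is dropped
  if |r_xy| ≤ |ε·r_xz| and |r_xy| ≤ |ε·r_yz| for some z. Surviving pairs
  with |r| > 0.9 become edges. A naive triple-loop oracle and the vectorized
  production sweep return provably identical masks.
- **Differential co-expression (DC).** Per tissue, every gene pair is tested
  with the Fisher z statistic
  dz = (atanh r1 − atanh r2)/√(1/(n1−3) + 1/(n2−3)), BH-adjusted
  (q ≤ 0.05), and assigned one of the correlation classes
  (+/+, +/−, +/0, −/+, −/−, −/0, 0/+, 0/−) from each condition's sign and
  significance.
- **Differential connectivity (DK).** Condition networks are compared via
  max-normalized connectivity K ∈ [0, 1]; DK_i = K_CON(i) − K_RES(i) is
  z-scored, with |z| ≥ 1.96 flagging rewired genes, plus union ("central
  reference") networks with CON-only/RES-only/shared provenance tags.

Because the original animal data is not needed to exercise any of this, the
package ships a first-class synthetic generator (`coexnet.simulate`) that
plants TS genes, DE genes and latent-factor regulator modules whose
coupling differs between conditions — the ground truth every downstream
stage is tested against. See `docs/methods.md` for the model and its
limits.

## Worked example

The numbered drivers under `analysis/` reproduce the whole workflow on the
default synthetic study (600 genes, 3 tissues, 7 CON + 7 RES):

```sh
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_tissue_specificity.py
...
python analysis/07_differential_connectivity.py
```

`03_tissue_specificity.py` prints

```
90 TS genes at tau >= 0.8: {'liver': 30, 'cerebrum': 30, 'muscle': 30}
planted TS recall (correct home tissue): 90/90
TS calls outside the planted set: 0
```

— all 90 planted tissue-specific genes are recovered with the correct home
tissue and no false calls. `05_tissue_network.py` prints

```
prioritized 164 genes -> network with 164 nodes, 1323 edges
clustering coefficient 0.58, scale-free R^2 0.72
```

— the prioritized (DE ∪ TS ∪ TF) network is dense and clustered, with a
roughly scale-free degree distribution. `07_differential_connectivity.py`
prints, for muscle,

```
muscle: CON 401 edges, RES 447 edges -> connectivity gain in RES; 37 DK genes
  M2_REG: DK = -0.63, z = -3.42, significant = True
  M3_REG: DK = +0.77, z = +4.29, significant = True
```

— both planted rewired regulators (the sign-flipped module M2 and the
RES-decoupled module M3) are flagged as significantly differentially
connected even at the real study's 7-per-group size. Differential
co-expression at n = 7, by contrast, has very little power (driver 06
recovers only a few of the planted +/− pairs); the calibrated recovery
claims below therefore use a 30-per-group variant.

Equivalently, `coexnet.run_all(PipelineConfig(seed=7), outdir)` executes
every stage and writes all tables, SIF exports and a reproducibility
manifest in one call.

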