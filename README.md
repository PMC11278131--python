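# spatialrqa

Quantitative validation of synthetic histopathology by **spatial
heterogeneous recurrence quantification analysis (SHRQA)**.

When a generative model produces synthetic tissue images, visual inspection
alone cannot establish that the synthetic microstructure is statistically
faithful to real tissue. `spatialrqa` answers that question quantitatively:
it turns each image patch into a vector of 112 spatial-recurrence features
and tests whether groups of patches — e.g. real normal tissue (NO), its
synthetic counterpart (NS), and real cancer tissue (CO) — are
distinguishable in that feature space. The intended users are computational
pathology groups evaluating GAN-style image synthesis, but the machinery
applies to any cohorts of square texture patches.

## The method

Each patch passes through six deterministic steps:

1. **Pre-processing** — grayscale conversion, idempotent morphological noise
   reduction (3×3 grey opening–closing), and a robust contrast stretch
   mapping median ± 1.5·IQR onto [0, 1].
2. **Haar 2D-DWT** — the level-1 approximation (LL) subband, i.e. dyadic
   block means.
3. **Hilbert space-filling curve** — the subband is read into a 1-D
   attribute vector `v` along a Hilbert traversal, so 2-D pixel proximity is
   preserved in the 1-D ordering.
4. **Delay embedding** — state-space points `x_t = (v_t, v_{t+1})`.
5. **Quadtree symbolization / IFS projection** — the unit square is split
   into 4² = 16 dyadic cells; each point becomes its cell index, and a
   chaos-game (iterated-function-system) orbit gives the fractal view of the
   symbol sequence.
6. **Heterogeneous recurrence quantification** — per cell *c* with *k*
   visits in a length-*T* symbol sequence: occupancy `k/T`; pairwise
   recurrence rate `C(k,2)/C(T,2)` normalized by occupancy; mean and Shannon
   entropy of maximal visit-run lengths (runs ≥ 2); mean and entropy of
   recurrence times; self-transition probability `P(s_{t+1}=c | s_t=c)`.
   16 cells × 7 measures = **112 features**.

Cohort comparison follows the study design the pipeline re-enacts: a
cross-validated logistic **LASSO** selects the features carrying the
phenotype contrast (normal vs cancer), **Hotelling's T²** — the multivariate
two-sample t-test, `T² = (n₁n₂/(n₁+n₂)) d′S⁻¹d` with its exact F
approximation — compares each pair of cohorts on the selected features, and
a standardized **PCA** yields per-group mean ± 95% CI profiles on the
leading five components (radar-plot-ready). Generative-model metrics (**FID**
on embedding Gaussians, **Inception Score**, **Relative Inception Score** =
IS(synthetic)/IS(real)) accept any external embedding/probability tables; a
deterministic mock embedder is included so every path runs without a trained
network.

A seeded texture generator ships with the package: Gaussian-profile "glands"
on a jittered hexagonal lattice over a pink-noise background, where lattice
jitter and element-size dispersion emulate the regular-vs-disrupted contrast
between normal and malignant tissue, and a warp+noise perturbation emulates
generative near-copies. All analyses are therefore testable end to end with
no external data.

## Worked example

```python
from spatialrqa.pipeline import run_demo

bundle = run_demo("out", n_per_class=100, patch_size_px=128, seed=1)
for pair, r in bundle.comparisons.items():
    print(pair, f"T2={r['t_squared']:.1f}", f"p={r['p_value']:.4g}")
```

prints

```
NO_vs_NS T2=25.8 p=0.8406
NO_vs_CO T2=2230.1 p=1.121e-76
NS_vs_CO T2=2246.0 p=6.509e-77
```

Reading: the synthetic near-copies (NS) are statistically
indistinguishable from their real-analogue cohort (NO) — p = 0.84 on the 30
LASSO-selected features — while both are overwhelmingly distinguishable from
the cancer-analogue cohort (CO). This is the qualitative signature of a
generator that reproduces tissue microstructure: it preserves the spatial
recurrence profile of its phenotype without erasing the phenotype contrast.
The bundle directory also contains `features.csv` (112 features per patch),
`selection.json`, `pca_radar.csv` (per-group mean and 95% CI on the first
five PCs), `metrics.json` (mock-embedder FID ≈ 0.004 and RIS ≈ 1.0 between
NO and NS) and a `run_log.json` echoing the configuration and seeds.

The same pipeline runs on your own patches from the shell:

```bash
shrqa extract --input-dir patches/ --out features.csv
shrqa compare --group real=patches/real --group synthetic=patches/syn --out results/
shrqa qc                      # summarize the packaged pathologist QC table
```

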