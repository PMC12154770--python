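# grene

Analysis toolkit for **replicated multi-garden evolve-and-resequence
experiments** in selfing annual plants. A panel of inbred founder accessions
is sown in experimental gardens spanning a climate gradient; each garden
hosts up to 12 replicate trays, and pooled flower samples are sequenced at
~10X each season. Because every genome in the experiment is (nearly) a copy
of one of the sequenced founders, the pooled reads can be deconvolved into
founder-lineage frequencies, and lineage frequency change becomes a direct
readout of relative fitness.

The package implements the full analysis chain, plus a forward simulator
that generates realistic synthetic experiments so every method can be
validated against known truth:

- **Simulation** (`grene.sim`, `grene.panel`): founder panels with LD
  structure and genotype-correlated climates of origin; selfing
  Wright-Fisher-style reproduction with uniform or Poisson seed set,
  optional outcrossing (one crossover per chromosome), Gaussian stabilizing
  selection, soft density regulation, and pool-seq observation
  (multinomial flowers, Poisson depth, symmetric sequencing error).
- **Frequency reconstruction** (`grene.poolfreq`): allele frequencies from
  pooled counts; founder deconvolution by simplex-constrained ridge least
  squares (`AccessionDeconvolver`, a scikit-learn transformer); a
  linkage-based error-reduction step that re-projects allele frequencies
  through the founder haplotypes.
- **Neutral nulls and divergence** (`grene.drift`): Wright-Fisher variance
  p₀(1−p₀)/2N, non-WF accession-sorting simulations, the
  observed/expected variance-ratio test, Hudson F_ST (ratio of averages),
  PCA of frequency change, replicate repeatability (mean pairwise Spearman)
  and the heritability of frequency change (variance components).
- **Selection scan** (`grene.ldblocks`): founder LD-block partition by
  greedy r² chaining; replicate-consistent binomial LRT for parallel
  frequency shifts; cross-garden block-overlap permutation test.
- **Stabilizing selection** (`grene.stabsel`): the model
  log(p_{t+1}/p_t) = log(W_max/w̄) − V_s⁻¹ (z_origin − z_garden)², fitted
  globally and per accession (`StabilizingSelectionModel`), with the
  specialist–generalist trade-off, realized climatic optima and adaptation
  lags.
- **eGEA** (`grene.egea`): per-SNP association of frequency change with
  garden climate by Kendall τ, quasi-binomial GLM, or latent-factor-corrected
  regression; weighted-Z (WZA) pooling into LD blocks with genomic-control
  inflation correction and Benjamini–Hochberg FDR.
- **Forecasting** (`grene.forecast`): logistic allele trajectories,
  per-generation selection coefficients (odds ratio per generation, s =
  e^slope − 1), genomic-offset models (`GenomicOffsetModel`: per-SNP climate
  clines → GO = mean |p_adapt − genotype|), leave-one-out predictability of
  evolutionary trajectories, survival logistic regressions with
  predictability × climate interactions, and quadratic census fits that flag
  evolutionary-rescue rebounds.

## Worked example

Simulate 8 gardens along a 5–17 °C gradient (50 founders, 2,000 SNPs,
V_s⁻¹ = 0.03 per °C², 6 replicates each), sequence one tray at 10X,
reconstruct founder frequencies, test for excess variance, and fit the
stabilizing-selection model:

```python
import numpy as np, pandas as pd
from grene import (GardenDesign, SimParams, generate_founder_panel,
                   simulate_experiment, sample_poolseq, estimate_allele_freq,
                   deconvolve_accessions)
from grene.drift import simulate_neutral_sorting, variance_ratio_test, repeatability
from grene.stabsel import StabilizingSelectionModel, log_fitness_ratios

panel = generate_founder_panel(n_accessions=50, n_snps=2000, n_chroms=5, seed=1)
params = SimParams(w_max=1.0, v_s_inv=0.03, carrying_capacity=300, fecundity=10)
zs = np.linspace(5, 17, 8)
gardens = [GardenDesign(f"g{i}", {"bio1": float(z)}, n_replicates=6, n_generations=1)
           for i, z in enumerate(zs)]
traj = simulate_experiment(panel, gardens, params, seed=2)

pool = sample_poolseq(traj.acc_freq["g7"][0, 1], panel, n_flowers=100,
                      mean_depth=10, seed=3, sample_id="g7_rep0_gen1")
acc = deconvolve_accessions(estimate_allele_freq(pool), panel)
print(f"deconvolution MAE at 10X: {np.abs(acc.freq[0] - traj.acc_freq['g7'][0, 1]).mean():.4f}")

null = simulate_neutral_sorting(panel.start_freq, panel, N=300, reps=1000, seed=4)
delta = traj.allele_freq["g7"][:, 1] - panel.allele_freqs()
res = variance_ratio_test(delta, null, seed=0)
print(f"variance ratio in g7: {res.ratio:.2f} [{res.ci_low:.2f}, {res.ci_high:.2f}]")

rows = []
for gi, g in enumerate(traj.garden_ids):
    y, flag = log_fitness_ratios(traj.acc_freq[g][:, 0].mean(axis=0),
                                 traj.acc_freq[g][:, 1].mean(axis=0))
    d2 = (panel.z_origin.bio1.to_numpy() - zs[gi]) ** 2
    rows += [(a, g, d2[i], y[i]) for i, a in enumerate(panel.accession_ids) if not flag[i]]
df = pd.DataFrame(rows, columns=["accession", "garden", "dist2", "y"])
fit = StabilizingSelectionModel(min_gardens=3).fit(df[["accession", "garden", "dist2"]], df.y)
print(f"global Vs_inv: {fit.global_v_s_inv_:.4f} per degC^2, R^2 = {fit.r2_:.2f}")
```

Output:

```
deconvolution MAE at 10X: 0.0100
variance ratio in g7: 2.89 [2.30, 3.48]
global Vs_inv: 0.0319 per degC^2, R^2 = 0.92
```

The deconvolution recovers the 50 founder frequencies to ~1% at 10X
coverage; the warmest garden shows ~3-fold more allele-frequency variance
than neutral lineage sorting predicts (selection, not drift); and the
fitted selection strength (0.032 per °C²) recovers the generative value
(0.03).

A shell workflow is available through the CLI:

```bash
grene simulate --config sim.yaml --out run/ --seed 1
grene deconvolve --vcf run/founders.vcf --sync run/pools.sync --meta run/metadata.csv --out run/
grene scan --vcf run/founders.vcf --sync run/pools.sync --meta run/metadata.csv --garden warm --out run/
grene census-fit --census run/census.csv --out run/rescue.json
```

## Documentation

`docs/methods.md` describes the models, their assumptions, the default
parameters, what the synthetic data do and do not emulate, and the
package's numerical choices.
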