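# Methods

## The experimental system being modelled

The package targets evolve-and-resequence experiments in which a fixed panel
of inbred, highly selfing founder accessions (each a single homozygous
genome) is sown as a near-even seed mix into replicated outdoor trays across
many climatically distinct gardens, and the reproductive adults of each tray
are pool-sequenced over successive seasons. Two facts shape every method
here:

1. **Evolution is (mostly) lineage sorting.** With little outcrossing, the
   population is a competition among intact founder genotypes. Allele
   frequencies are linear images of lineage frequencies through the founder
   genotype matrix `G` (accessions × SNPs): `p = Gᵀf`.
2. **Sampling reproductive adults measures fitness.** Under soft selection,
   one generation of reproduction multiplies a lineage's frequency by its
   relative fitness: `p_{t+1}/p_t = w/w̄`.

## Forward simulator (`grene.sim`, `grene.panel`)

**Founder panel.** Synthetic accessions are mosaics of a small number of
ancestral haplotypes: each accession copies one ancestor along the
chromosome and switches ancestor with probability `1 − exp(−1/ld_decay)` per
SNP step (plus a small mutation flip rate). Shared ancestry over a scale of
`ld_decay` SNPs is what creates founder LD blocks; `ld_decay = 0` gives
independent SNPs (mean adjacent r² ≈ 1/(n−1), the finite-sample floor).
Climate of origin is built from each accession's genome-wide ancestry
composition (every ancestor carries a climate score) plus a residual noise
fraction (default 0.1), then scaled linearly into the requested span
(default one annual-mean-temperature-like variable over 4–18 °C). This makes
origin climate *heritable in the panel*: SNPs that differentiate ancestors
form clines with origin climate, which is the substrate that local
adaptation, climate-association scans and genomic offsets all require. The
seed mix is Dirichlet-jittered around `1/n_accessions` with total
concentration 5000, i.e. ~0.1%-scale deviations around the even mix (0.43%
per accession for a 231-founder panel).

**Fitness.** `w_a = W_max,a · exp(−Vs_inv,a (z_origin,a − z_garden)²)` —
Gaussian stabilizing selection around each accession's home climate.
`Vs_inv` has units of (climate unit)⁻²; with temperature in °C, values of
0.01–0.05 per °C² give the strong but not degenerate differentiation used
as the package's study condition.

**Reproduction and regulation.** Generations are discrete and
non-overlapping; sites with two generations per year are simply more
generation steps. Each plant's expected seed set is `fecundity · w/w̄`
(default fecundity 10). The *uniform* model draws the minimum-variance
integer count (floor plus a Bernoulli remainder); the *poisson* model draws
Poisson counts (overdispersed reproduction). The offspring pool is then
down-sampled without replacement to the carrying capacity (soft selection:
`w̄` is implicit normalization). In the neutral uniform case this reduces
exactly to multivariate-hypergeometric sampling of `N` survivors from the
`N·fecundity` seed pool; the simulator's one-generation variance matches
that closed form to within Monte-Carlo error (ratio 0.99 ± 0.01, 500
replicates), which is the calibration the drift nulls rely on. Outcrossed
offspring (probability `outcross_rate`, default 0) take one uniformly
placed crossover per chromosome between two parents; no genetic map is
modelled.

**Observation.** Flowers are drawn multinomially (over individuals or over
lineage frequencies), per-SNP depth is Poisson (default 10X), and alt reads
are binomial with a symmetric ref↔alt substitution error (default 0.7%,
the scale of reconstruction error reported for this kind of pipeline).

**What the generator does not emulate:** germination phenology, seed banks
and dormancy, weather time series within a season, spatial structure within
trays, migration between trays, reference-mapping bias, and base-quality
variation. Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under lineage sorting with clean counts — not that
real experiments meet these assumptions.

## Frequency reconstruction (`grene.poolfreq`)

Raw allele frequencies are `alt/(ref+alt)` with a configurable minimum
depth (default 1). Founder deconvolution solves

    f̂ = argmin ‖Gᵀf − p‖² + ridge·‖f‖²  s.t.  f ≥ 0, Σf = 1

via non-negative least squares on an augmented system (the sum constraint
enters as a heavily weighted row, and the result is renormalized onto the
simplex; ridge defaults to 1e-4 for rank safety — founder panels with
duplicated or near-duplicated accessions trigger a warning but still
return a regularized solution). Missing founder genotypes are mean-imputed
per SNP for deconvolution only; residual heterozygotes carry dosage 0.5.

The linkage-based error-reduction step is the projection `p_smooth = Gᵀf̂`.
Its error-suppression comes from pooling evidence across every SNP on each
founder haplotype: at 10X, raw per-SNP frequencies carry ~0.11 MAE while
the projection reaches ~0.04 on the simulator's default panels, and the
projection wins in ≥95/100 samples. The exact smoothing algorithm used by
any particular published pipeline is not uniquely specified in the
literature this emulates; projection-through-accessions is one admissible
realization and is documented as such. It is idempotent and maps
monomorphic founder SNPs to their fixed dosage exactly.

## Neutral nulls and the variance-ratio test (`grene.drift`)

The Wright-Fisher expectation is `Var(Δp) = p₀(1−p₀)/2N` with `N`
defaulting to the sequenced sample size (a conservative choice: the true
effective size can only be larger). The non-WF null resamples whole
lineages (establishment multinomial, then uniform or Poisson seed set with
hypergeometric regulation) and maps count draws through `G`, yielding the
null distribution of `Δp` per SNP and per starting-frequency bin (deciles
of p₀, bins under 50 SNPs merged).

The variance-ratio statistic is `mean(Δp²)/mean(Var_null)`. Two numerical
choices matter and were validated by self-null simulation:

- **Replicate-level uncertainty.** All SNPs in a replicate share one
  lineage-resampling draw, so SNP-level resampling understates run-to-run
  variance by ~6×. The CI is therefore a Student-t interval over
  per-replicate ratios (measured coverage 0.97 at nominal 0.95 over 200
  self-null runs); a SNP bootstrap is used only when a single replicate is
  supplied.
- **Replicate-level MWU.** The Mann-Whitney comparison is between
  replicate-level genome-mean squared changes of the observed and null
  draws (the exchangeable unit); per-SNP rank tests are grossly
  anti-conservative under the same dependence. The replicate-level form is
  calibrated (KS against U(0,1): p ≈ 0.08 over 300 self-null runs).

Hudson F_ST uses the genome-wide ratio of averages
`Σ[(p_a−p_b)² − corrections]/Σ[p_a(1−p_b)+p_b(1−p_a)]`, with the
within-population sampling correction `p(1−p)/(n−1)` applied when pool
depths are supplied. PCA of frequency change deliberately skips column
centering: rows are `p_t − p₀` vectors, so the founder state sits at the
origin by construction. Repeatability is the mean pairwise Spearman
correlation of frequency change across replicates; heritability of
frequency change is the one-way method-of-moments variance-component ratio
truncated to [0, 1]. On simulated gardens spanning selection strengths the
two statistics rank gardens almost identically (Spearman ≈ 0.99).

## LD blocks and the selection scan (`grene.ldblocks`)

Blocks are built by greedy chaining: extend the current block while the
next SNP's r² with any of the last `max_gap` (default 10) block SNPs
reaches `r2_threshold` (default 0.5); blocks never span chromosomes. The
defaults are chosen for sensible synthetic block sizes, not to reproduce
any particular empirical block count.

The parallel-selection LRT at a SNP compares: null — one common frequency
behind all replicates' counts at both timepoints; alternative — a common
starting frequency plus a single shared post-selection frequency (one
extra parameter, χ²(1) reference). The MLEs are pooled proportions, so the
statistic is invariant to replicate relabelling and ref/alt swaps, and
discordant replicate shifts score far below concordant ones. Per-block
summaries use the minimum SNP p with a within-block Bonferroni factor;
λ_GC (median statistic over the χ²(1) median) is reported as a calibration
diagnostic. The χ²(1) reference is adequate at the depths simulated here;
an empirical null from neutral simulation is recommended when depths are
very low. Cross-garden consistency uses a permutation test preserving each
garden's significant-set size, with the standard `(1+#exceed)/(n_perm+1)`
p-value and its `1/(n_perm+1)` floor.

## Stabilizing-selection fits (`grene.stabsel`)

The fitted model is

    log(p_{t+1}/p_t) = log W_max,a − Vs_inv,a · (z_origin,a − z_garden)² + γ_g

with garden offsets `γ_g = −log w̄_g` anchored to zero in the first garden
(offsets are identified only up to a constant; rescaling all fitnesses
moves intercepts, never slopes). The global fit shares one slope; the
accession-specific fit estimates per-accession intercepts and slopes
jointly with shared garden offsets by ordinary least squares (the joint
design is full rank whenever origins and gardens are in general position).
Accessions seen in fewer than `min_gardens` (default 3) gardens are
skipped with a recorded reason. Negative fitted `Vs_inv` is truncated to
zero and flagged rather than dropped. Log ratios add `epsilon = 1e-4`
(about half a flower in a 5,000-seed pool) to both frequencies; records
with `p_t < 1e-5` are flagged and excluded. Doubling epsilon moves the
global slope by <5% on simulated data.

Realized optima are frequency-weighted garden climates, `z_opt =
Σ w_g z_g / Σ w_g`, with enrichment weights `p₁/p₀` by default (evolved
frequency `p₁` offered as an alternative); the adaptation lag is
`z_opt − z_origin`. The specialist–generalist trade-off is the Spearman
correlation between fitted `W_max` and `Vs_inv`.

## eGEA and WZA (`grene.egea`)

The response defaults to the per-garden replicate-averaged logit frequency
change for the first sequenced interval (raw Δp offered). Three per-SNP
frameworks:

- **Kendall τ** against garden climate (exact p for small garden counts);
- **quasi-binomial GLM** of alt/depth on climate with depth variance
  weights (slope invariant to uniform depth rescaling; overdispersion by
  Pearson χ²/df; boundary/separation cases fall back to a
  Haldane-corrected refit and are flagged);
- **latent-factor regression**: the top-k left singular vectors of the
  centered garden × SNP response matrix are projected out of response and
  climate before a per-SNP t-test on n − 2 − k df. This is a light-weight
  stand-in for a full latent factor mixed model; k = 0 reduces to plain
  regression. *Caveat (measured):* when a strong causal signal is sparse,
  it can itself become the top variance axis and be absorbed by the
  factor, destroying power — the factor correction is for settings where
  confounding structure, not the signal, dominates. Power comparisons in
  the validation suite therefore use the Kendall framework.

WZA pooling: `z_block = Σ w_i z_i / √(Σ w_i²)` with `z_i = Φ⁻¹(1 − p_i)`
and founder-heterozygosity weights `2p(1−p)` (uniform weights available).
Block p-values are one-sided in z after a median-based genomic-control
correction (λ = median(z²)/0.455, capped below at 1) estimated across
blocks, then BH-FDR per climate variable (the 19-variable sweep is a loop
with per-variable FDR; no cross-variable correction). Under a uniform null
the block p distribution is uniform and the q < 0.05 block fraction stays
at its nominal bound.

## Forecasting (`grene.forecast`)

Logistic trajectories regress `logit(p)` (clipped at 1e-4) on time or
climate; the slope is the logistic β. Selection coefficients use the
haploid lineage-competition identity `odds(p_{t+1}) = (1+s)·odds(p_t)`, so
`ŝ = exp(slope) − 1` with the CI transformed from the regression slope CI
(diploid parameterizations are out of scope for a selfer). CI coverage was
validated against the forward simulator (capacity 2000 keeps drift small
relative to depth-100 binomial noise; measured coverage 0.93–0.96).

The genomic-offset model fits, per SNP, a logistic cline of evolved
frequency on training-garden climate; `p_adapt(z)` is the cline evaluated
at a query climate and `GO = mean_i |p_adapt,i − X_i|` over the SNP subset
(all SNPs by default; a climate-associated subset can be supplied, chosen
on training gardens only to avoid leakage). GO is bounded in [0, 1] and
invariant to SNP duplication. Leave-one-out validation trains on all other
gardens and scores the rank agreement (Spearman, per replicate) between
`−GO` and observed accession `log(p₁/p₀)`. The `go_plus_stabsel` scorer
adds the z-scored stabilizing-selection predicted log fitness (fitted on
training gardens); `climate_distance` ranks by `−(z_origin − z_garden)²`
as a no-genomics baseline. Under the simulator's local-adaptation
condition mean LOO r ≈ 0.4 and is ≈ 0 under neutrality, mirroring the
qualitative behaviour expected of offset methods.

Survival models are logistic regressions of replicate survival (census ≥ 1)
on per-replicate predictability r², garden temperature, and their
interaction; one-sided outcomes or separation trigger a ridge-penalized
refit (flagged), and the 50% survival isoline solves the fitted model for
temperature as a function of r². Census trajectories get a pooled
quadratic fit per garden; a rebound (the demographic signature of
evolutionary rescue) requires a positive quadratic coefficient, an
interior minimum, and statistical support (p < 0.05, or an exact fit with
no residual degrees of freedom, as with three noiseless points).

## Validation scales and numerical defaults

The validation suite and `scripts/acceptance.py` run everything at desk
scale, chosen so the full suite completes in a few minutes on one CPU while
keeping Monte-Carlo error well below the decision margins: panels of
30–50 accessions × 600–5,000 SNPs, 8–30 gardens, 200-run coverage
simulations, 2,000-block calibration scans, and 3,000-replicate neutral
nulls. Seeds are threaded through `numpy.random.SeedSequence` everywhere;
identical seeds give bit-identical simulations.

Known limitations: deconvolution assumes the founder panel is complete and
correct (contaminant genotypes are not modelled); the LRT treats replicates
as exchangeable and depths as the only noise source; the latent-factor
caveat above; block definitions ignore recombination maps; and the
survival isolines extrapolate a logistic fit outside the observed covariate
range if queried there.
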