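"""Neutral expectations, excess-variance tests, divergence and repeatability.

The central question these tools answer: are the observed allele-frequency
shifts in an evolve-and-resequence experiment larger than stochastic
sampling alone would produce?  Two nulls are provided:

* the classic Wright-Fisher binomial expectation Var(dp) = p0(1-p0)/2N, and
* non-WF "accession sorting" simulations, where whole selfing lineages are
  resampled each generation (uniform or Poisson seed set) and allele
  frequencies change only through the founder genotype matrix.

On top of the nulls: a variance-ratio test with CI and Mann-Whitney U
comparison, Hudson F_ST (genome-wide ratio of averages), PCA of frequency
change (centered at the founder state), replicate repeatability (mean
pairwise Spearman correlation of frequency change), and the heritability of
frequency change from one-way random-effects variance components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import FounderPanel

__all__ = [
    "DriftTestResult",
    "NeutralSortingNull",
    "RepeatabilityResult",
    "HeritabilityResult",
    "wf_variance",
    "simulate_neutral_sorting",
    "variance_ratio_test",
    "compute_fst",
    "pairwise_fst",
    "pca_frequency_change",
    "repeatability",
    "heritability_freq_change",
]


def wf_variance(p0, N) -> np.ndarray | float:
    """Wright-Fisher one-generation drift variance p0(1-p0)/(2N)."""
    p0 = np.asarray(p0, float)
    if np.any(p0 < 0) or np.any(p0 > 1):
        raise ValueError("p0 must lie in [0, 1]")
    N = np.asarray(N, float)
    if np.any(N < 1):
        raise ValueError("N must be >= 1")
    out = p0 * (1 - p0) / (2 * N)
    return float(out) if out.ndim == 0 else out


@dataclass
class NeutralSortingNull:
    """Null distribution of allele-frequency change under accession sorting."""

    delta: np.ndarray  # (reps, n_snps) simulated dp draws
    var: np.ndarray  # (n_snps,) mean squared dp
    p0: np.ndarray  # (n_snps,) founder allele frequency

    def binned_var(self, bins: np.ndarray) -> pd.DataFrame:
        idx = np.digitize(self.p0, bins) - 1
        rows = []
        for b in range(len(bins) - 1):
            sel = idx == b
            if sel.any():
                rows.append({"bin": b, "p0_lo": bins[b], "p0_hi": bins[b + 1],
                             "var": float(self.var[sel].mean()), "n_snps": int(sel.sum())})
        return pd.DataFrame(rows)


def _sorting_step(
    counts: np.ndarray,
    model: str,
    fecundity: int,
    N: int,
    rng: np.random.Generator,
) -> np.ndarray:
    out = np.empty_like(counts)
    for r in range(counts.shape[0]):
        if model == "uniform":
            pool = counts[r] * fecundity
        else:
            pool = rng.poisson(counts[r] * fecundity)
        total = int(pool.sum())
        if total <= N:
            out[r] = pool
        else:
            out[r] = rng.multivariate_hypergeometric(pool, N)
    return out


def simulate_neutral_sorting(
    start_freq: np.ndarray,
    panel: FounderPanel,
    N: int,
    offspring_model: str = "uniform",
    generations: int = 1,
    reps: int = 500,
    fecundity: int = 10,
    seed: int | None = None,
) -> NeutralSortingNull:
    """Simulate allele-frequency change under neutral accession resampling.

    Each replicate establishes N individuals multinomially from the seed mix
    and then reproduces neutrally (no outcrossing) for ``generations``
    steps under the chosen seed-set model.  Allele-frequency changes are
    implied through the founder genotype matrix; the returned object holds
    the raw draws and the per-SNP null variance of dp relative to the seed
    mix frequencies.
    """
    if offspring_model not in ("uniform", "poisson"):
        raise ValueError("offspring_model must be 'uniform' or 'poisson'")
    rng = np.random.default_rng(seed)
    G = panel.imputed_genotypes()
    start_freq = np.asarray(start_freq, float)
    p0 = start_freq @ G
    counts = rng.multinomial(N, start_freq, size=reps)
    for _ in range(generations):
        counts = _sorting_step(counts, offspring_model, fecundity, N, rng)
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    totals[totals == 0] = 1.0
    delta = (counts / totals) @ G - p0
    if generations == 0:
        delta = np.zeros((reps, G.shape[1]))
    return NeutralSortingNull(delta=delta, var=(delta**2).mean(axis=0), p0=p0)


@dataclass
class DriftTestResult:
    """Observed-vs-null excess variance of allele frequency change."""

    ratio: float
    ci_low: float
    ci_high: float
    mwu_p: float
    bins: pd.DataFrame
    n: int


def variance_ratio_test(
    delta: np.ndarray,
    null: NeutralSortingNull | np.ndarray,
    p0: np.ndarray | None = None,
    n_boot: int = 2000,
    n_bins: int = 10,
    min_snps_per_bin: int = 50,
    seed: int | None = None,
) -> DriftTestResult:
    """Ratio of observed mean squared dp to the neutral null variance.

    ``delta`` is (replicates x SNPs) or (SNPs,) observed frequency change;
    ``null`` is either a :class:`NeutralSortingNull` (simulated draws) or a
    per-SNP analytic variance vector (e.g. :func:`wf_variance`).

    The CI is replicate-based (Student-t over per-replicate ratios) when two
    or more replicates are available, because frequency changes share the
    same accession-resampling noise across SNPs and a SNP-level resample
    would understate the uncertainty; with a single replicate a bootstrap
    over SNPs is used instead.  The Mann-Whitney U likewise compares
    replicate-level genome-mean squared changes (observed vs null), the
    exchangeable unit of the experiment; per-SNP values are far too
    dependent (every SNP rides the same lineage resampling) for a
    sample-level rank test to be calibrated.
    """
    delta = np.atleast_2d(np.asarray(delta, float))
    finite = np.isfinite(delta)
    if not finite.any():
        raise ValueError("all observed frequency changes are missing")
    if delta.shape[1] < 100:
        raise ValueError("need >= 100 SNPs for a stable variance ratio")
    rng = np.random.default_rng(seed)

    if isinstance(null, NeutralSortingNull):
        null_var = null.var
        null_repmeans = (null.delta**2).mean(axis=1)
        if p0 is None:
            p0 = null.p0
    else:
        null_var = np.asarray(null, float)
        # analytic null: synthesize replicate-level genome means from
        # independent chi-square(1)-scaled draws of the per-SNP variance
        draws = null_var[None, :] * rng.chisquare(1.0, size=(500, len(null_var)))
        null_repmeans = draws.mean(axis=1)

    obs_sq = np.where(finite, delta**2, np.nan)
    obs_persnp = np.nanmean(obs_sq, axis=0)
    denom = float(np.mean(null_var))
    if denom <= 0:
        raise ValueError("null variance is zero")
    ratio = float(np.nanmean(obs_persnp) / denom)

    R = delta.shape[0]
    if R >= 2:
        rep_ratios = np.nanmean(obs_sq, axis=1) / denom
        se = rep_ratios.std(ddof=1) / np.sqrt(R)
        tq = stats.t.ppf(0.975, R - 1)
        ci = (float(ratio - tq * se), float(ratio + tq * se))
    else:
        boots = np.empty(n_boot)
        S = delta.shape[1]
        for b in range(n_boot):
            idx = rng.integers(0, S, size=S)
            boots[b] = np.nanmean(obs_persnp[idx]) / np.mean(null_var[idx])
        ci = tuple(np.quantile(boots, [0.025, 0.975]))

    obs_repmeans = np.nanmean(obs_sq, axis=1)
    mwu_p = float(
        stats.mannwhitneyu(
            obs_repmeans[np.isfinite(obs_repmeans)], null_repmeans,
            alternative="two-sided",
        ).pvalue
    )

    bins_df = pd.DataFrame()
    if p0 is not None:
        edges = np.unique(np.quantile(np.asarray(p0, float), np.linspace(0, 1, n_bins + 1)))
        if len(edges) > 2:
            idx = np.clip(np.digitize(p0, edges) - 1, 0, len(edges) - 2)
            rows = []
            pending_obs, pending_null, lo = [], [], None
            for b in range(len(edges) - 1):
                sel = idx == b
                pending_obs.append(obs_persnp[sel])
                pending_null.append(null_var[sel])
                lo = edges[b] if lo is None else lo
                n_acc = sum(len(x) for x in pending_obs)
                if n_acc >= min_snps_per_bin or b == len(edges) - 2:
                    o = np.concatenate(pending_obs)
                    nv = np.concatenate(pending_null)
                    if len(o) and np.mean(nv) > 0:
                        rows.append({"p0_lo": float(lo), "p0_hi": float(edges[b + 1]),
                                     "ratio": float(np.nanmean(o) / np.mean(nv)),
                                     "n_snps": int(len(o))})
                    pending_obs, pending_null, lo = [], [], None
            bins_df = pd.DataFrame(rows)

    return DriftTestResult(
        ratio=ratio, ci_low=ci[0], ci_high=ci[1], mwu_p=mwu_p,
        bins=bins_df, n=int(np.isfinite(obs_persnp).sum()),
    )


def compute_fst(
    freqs_a: np.ndarray,
    freqs_b: np.ndarray,
    n_a: np.ndarray | None = None,
    n_b: np.ndarray | None = None,
) -> float:
    """Hudson F_ST, genome-wide ratio of averages.

    sum[(pa-pb)^2 - corrections] / sum[pa(1-pb) + pb(1-pa)] over shared
    non-missing SNPs.  When per-SNP sample sizes (pool depths) ``n_a``/``n_b``
    are given, the numerator subtracts the within-population sampling terms
    pa(1-pa)/(na-1) + pb(1-pb)/(nb-1); the ratio-of-averages form avoids the
    instability of per-SNP ratios.
    """
    pa = np.asarray(freqs_a, float)
    pb = np.asarray(freqs_b, float)
    shared = np.isfinite(pa) & np.isfinite(pb)
    if n_a is not None:
        na = np.asarray(n_a, float)
        shared &= na > 1
    if n_b is not None:
        nb = np.asarray(n_b, float)
        shared &= nb > 1
    if shared.sum() == 0:
        raise ValueError("no shared non-missing SNPs")
    pa, pb = pa[shared], pb[shared]
    num = (pa - pb) ** 2
    if n_a is not None:
        num = num - pa * (1 - pa) / (np.asarray(n_a, float)[shared] - 1)
    if n_b is not None:
        num = num - pb * (1 - pb) / (np.asarray(n_b, float)[shared] - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    total = den.sum()
    if total <= 0:
        return 0.0
    return float(num.sum() / total)


def pairwise_fst(
    freq: np.ndarray,
    sample_ids: list[str],
    depth: np.ndarray | None = None,
    labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """All-pairs Hudson F_ST with optional within/between grouping labels."""
    freq = np.atleast_2d(freq)
    rows = []
    for i in range(freq.shape[0]):
        for j in range(i + 1, freq.shape[0]):
            fst = compute_fst(
                freq[i], freq[j],
                None if depth is None else depth[i],
                None if depth is None else depth[j],
            )
            row = {"a": sample_ids[i], "b": sample_ids[j], "fst": fst}
            if labels is not None:
                row["comparison"] = (
                    "within" if labels[sample_ids[i]] == labels[sample_ids[j]] else "between"
                )
            rows.append(row)
    return pd.DataFrame(rows)


def pca_frequency_change(
    delta: np.ndarray, n_components: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of frequency-change vectors, centered at the founder state.

    ``delta`` rows are samples' p_t - p_0 vectors.  No column mean is
    subtracted: the origin of the PC space is the founder composition, so a
    sample identical to the founders projects exactly to zero.

    Returns (scores, variance_explained_ratio).
    """
    delta = np.atleast_2d(np.asarray(delta, float))
    if delta.shape[0] < 3:
        raise ValueError("need >= 3 samples for a PCA of frequency change")
    delta = np.nan_to_num(delta, nan=0.0)
    k = min(n_components, *delta.shape)
    U, s, _ = np.linalg.svd(delta, full_matrices=False)
    scores = U[:, :k] * s[:k]
    total = float((s**2).sum())
    var_exp = (s[:k] ** 2 / total) if total > 0 else np.zeros(k)
    return scores, var_exp


@dataclass
class RepeatabilityResult:
    """Mean pairwise rank correlation of frequency change across replicates."""

    mean_rho: float
    ci_low: float
    ci_high: float
    pair_rhos: np.ndarray
    level: str


def repeatability(
    deltas: np.ndarray,
    level: str = "allele",
    n_boot: int = 2000,
    seed: int | None = None,
) -> RepeatabilityResult:
    """Mean over replicate pairs of Spearman correlation of frequency change.

    ``deltas`` is (replicates x features); features are SNPs for
    level="allele" or accessions for level="accession".
    """
    deltas = np.atleast_2d(np.asarray(deltas, float))
    R = deltas.shape[0]
    if R < 2:
        raise ValueError("need >= 2 replicates for repeatability")
    rhos = []
    for i in range(R):
        for j in range(i + 1, R):
            ok = np.isfinite(deltas[i]) & np.isfinite(deltas[j])
            rho = stats.spearmanr(deltas[i, ok], deltas[j, ok]).statistic
            rhos.append(rho)
    rhos = np.asarray(rhos, float)
    rng = np.random.default_rng(seed)
    if len(rhos) > 1:
        boots = rng.choice(rhos, size=(n_boot, len(rhos)), replace=True).mean(axis=1)
        ci = tuple(np.quantile(boots, [0.025, 0.975]))
    else:
        ci = (float(rhos[0]), float(rhos[0]))
    return RepeatabilityResult(
        mean_rho=float(np.nanmean(rhos)), ci_low=float(ci[0]), ci_high=float(ci[1]),
        pair_rhos=rhos, level=level,
    )


@dataclass
class HeritabilityResult:
    """Broad-sense heritability of accession frequency change."""

    h2: float
    sigma2_accession: float
    sigma2_residual: float
    defined: bool


def heritability_freq_change(delta_f: np.ndarray) -> HeritabilityResult:
    """Variance-components H2 of accession frequency change across replicates.

    One-way random-effects ANOVA (method of moments): groups are accessions,
    observations are replicate frequency changes.  H2 = s2_acc / (s2_acc +
    s2_res), truncated to [0, 1]; flagged undefined when the total variance
    is zero.
    """
    y = np.atleast_2d(np.asarray(delta_f, float))  # replicates x accessions
    R, A = y.shape
    if R < 2:
        raise ValueError("need >= 2 replicates")
    if A < 10:
        raise ValueError("need >= 10 accessions")
    grand = y.mean()
    acc_means = y.mean(axis=0)
    msb = R * float(((acc_means - grand) ** 2).sum()) / (A - 1)
    msw = float(((y - acc_means) ** 2).sum()) / (A * (R - 1))
    if msb + msw <= 0:
        return HeritabilityResult(np.nan, 0.0, 0.0, defined=False)
    s2a = max((msb - msw) / R, 0.0)
    h2 = s2a / (s2a + msw) if (s2a + msw) > 0 else np.nan
    return HeritabilityResult(
        h2=float(np.clip(h2, 0.0, 1.0)), sigma2_accession=float(s2a),
        sigma2_residual=float(msw), defined=np.isfinite(h2),
    )
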