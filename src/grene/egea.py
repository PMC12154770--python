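"""Experimental-evolution genome-environment association (eGEA).

Because every experimental population starts from the same founder mix,
climate-driven selection reveals itself as SNP frequency changes that vary
systematically with garden climate.  Three per-SNP frameworks test that
association across gardens:

* ``egea_kendall`` — Kendall's tau rank correlation (robust to nonlinear
  monotone clines),
* ``egea_glm`` — quasi-binomial GLM on alt/depth counts with depth weights
  (accounts for variable pool sizes and overdispersion),
* ``egea_latent_factor`` — a light-weight latent-factor correction: the top
  principal factors of the garden x SNP response matrix are regressed out
  of both response and climate before the per-SNP linear test (standing in
  for a full latent factor mixed model).

Per-SNP p-values are pooled into per-LD-block scores by the weighted-Z
analysis (WZA, weights = founder heterozygosity), inflation-corrected by a
median-based genomic-control factor, and FDR-adjusted with
Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ldblocks import LDBlockPartition

__all__ = [
    "garden_response",
    "egea_kendall",
    "egea_glm",
    "egea_latent_factor",
    "wza_pool",
    "fdr_correct",
    "EgeaResult",
]

_CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)


def garden_response(
    p0: np.ndarray, p1: np.ndarray, kind: str = "logit", clip: float = 1e-4
) -> np.ndarray:
    """Per-garden response per SNP: logit frequency change (default) or raw dp.

    Inputs are (gardens x SNPs) mean frequencies (replicate-averaged).
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    if kind == "dp":
        return p1 - p0
    if kind != "logit":
        raise ValueError("kind must be 'logit' or 'dp'")
    a = np.clip(p1, clip, 1 - clip)
    b = np.clip(p0, clip, 1 - clip)
    return np.log(a / (1 - a)) - np.log(b / (1 - b))


def _check_climate(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, float)
    if np.std(z) == 0:
        raise ValueError("climate variable is constant across gardens")
    return z


def egea_kendall(response: np.ndarray, climate: np.ndarray) -> pd.DataFrame:
    """Kendall tau between per-garden response and climate, per SNP.

    Exact p-values for small garden counts (scipy's default), normal
    approximation otherwise.
    """
    Y = np.atleast_2d(np.asarray(response, float))
    z = _check_climate(climate)
    if Y.shape[0] < 5:
        raise ValueError("need >= 5 gardens")
    tau = np.empty(Y.shape[1])
    p = np.empty(Y.shape[1])
    for s in range(Y.shape[1]):
        y = Y[:, s]
        ok = np.isfinite(y)
        if ok.sum() < 5 or np.std(y[ok]) == 0:
            tau[s], p[s] = 0.0, 1.0
            continue
        res = stats.kendalltau(z[ok], y[ok])
        tau[s], p[s] = res.statistic, res.pvalue
    return pd.DataFrame({"stat": tau, "p": p, "method": "kendall"})


def egea_glm(
    alt: np.ndarray,
    depth: np.ndarray,
    climate: np.ndarray,
) -> pd.DataFrame:
    """Quasi-binomial regression of alt/depth on climate, per SNP.

    Rows of ``alt``/``depth`` are garden(-replicate) observations; the
    climate vector aligns with rows.  Depths enter as variance weights, so
    the slope estimate is invariant to a uniform rescaling of coverage.
    Overdispersion is estimated by Pearson chi-square / df and inflates the
    Wald standard error.  Degenerate fits (e.g. complete separation on
    all-0/1 frequencies) fall back to a Haldane-corrected refit
    (0.5 added to both counts) and are flagged.
    """
    alt = np.atleast_2d(np.asarray(alt, float))
    depth = np.atleast_2d(np.asarray(depth, float))
    z = _check_climate(climate)
    X = sm.add_constant(z)
    S = alt.shape[1]
    slope = np.full(S, np.nan)
    se = np.full(S, np.nan)
    p = np.full(S, np.nan)
    flagged = np.zeros(S, dtype=bool)
    for s in range(S):
        d = depth[:, s]
        ok = np.isfinite(d) & (d > 0) & np.isfinite(alt[:, s])
        if ok.sum() < 3:
            continue
        frac = alt[ok, s] / d[ok]
        slope[s], se[s], p[s], flagged[s] = _glm_one(frac, d[ok], X[ok])
    return pd.DataFrame(
        {"stat": slope, "se": se, "p": p, "flagged": flagged, "method": "glm"}
    )


def _glm_one(frac, weights, X):
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    def fit_once(fr):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            warnings.simplefilter("error", PerfectSeparationWarning)
            return sm.GLM(
                fr, X, family=sm.families.Binomial(), var_weights=weights
            ).fit(scale="X2")

    if np.ptp(frac) == 0:
        # perfectly constant response: no association, no sampling evidence
        return 0.0, 0.0, 1.0, False
    flagged = False
    try:
        fit = fit_once(frac)
        if not np.all(np.isfinite(fit.bse)) or fit.bse[1] <= 0 or fit.bse[1] > 1e4:
            raise ValueError("degenerate fit")
    except Exception:
        flagged = True
        # Haldane-style shrinkage: pull proportions slightly off the boundary
        adj = (frac * weights + 0.5) / (weights + 1.0)
        try:
            fit = fit_once(adj)
        except Exception:
            return np.nan, np.nan, np.nan, True
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    p = float(fit.pvalues[1])
    if not np.isfinite(p):
        # zero-dispersion exact fit: the data carry no sampling noise
        flagged = True
        p = 1.0 if abs(slope) < 1e-10 else 0.0
    return slope, se, p, flagged


def egea_latent_factor(
    response: np.ndarray,
    climate: np.ndarray,
    k_factors: int = 1,
) -> pd.DataFrame:
    """Per-SNP linear association with latent-factor confounder correction.

    The top ``k_factors`` left singular vectors of the column-centered
    garden x SNP response matrix capture shared structure (e.g. a latent
    environmental gradient driving many SNPs).  They are projected out of
    every SNP's response and out of the climate variable; the residual
    per-SNP slope is tested with a t statistic on n - 2 - k degrees of
    freedom.  ``k_factors=0`` reduces exactly to the plain linear model.
    """
    Y = np.atleast_2d(np.asarray(response, float))
    z = _check_climate(climate)
    G = Y.shape[0]
    if k_factors >= G - 1:
        raise ValueError("k_factors must be < n_gardens - 1")
    if G < k_factors + 2:
        raise ValueError("need >= k_factors + 2 gardens")
    Y = np.nan_to_num(Y, nan=0.0)
    Yc = Y - Y.mean(axis=0)
    zc = z - z.mean()
    if k_factors > 0:
        U, _, _ = np.linalg.svd(Yc, full_matrices=False)
        F = U[:, :k_factors]
        Yc = Yc - F @ (F.T @ Yc)
        zc = zc - F @ (F.T @ zc)
    denom = float(zc @ zc)
    if denom <= 0:
        raise ValueError("climate variable has no variance after factor removal")
    slope = (zc @ Yc) / denom
    resid = Yc - np.outer(zc, slope)
    dof = G - 2 - k_factors
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 / denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        # exact (zero-residual) fits: evidence is infinite unless the slope
        # itself is zero
        t = np.where(se > 0, slope / se,
                     np.where(np.abs(slope) > 1e-12, np.inf, 0.0))
    p = 2 * stats.t.sf(np.abs(t), dof)
    return pd.DataFrame({"stat": slope, "p": p, "method": "latent_factor"})


def wza_pool(
    p_values: np.ndarray,
    partition: LDBlockPartition,
    weights: np.ndarray | None = None,
    correct_inflation: bool = True,
) -> pd.DataFrame:
    """Weighted-Z pooling of per-SNP p-values into per-block scores.

    block z = sum_i w_i z_i / sqrt(sum_i w_i^2) with z_i = Phi^-1(1 - p_i)
    and weights w_i defaulting to the founder expected heterozygosity
    2 p (1-p) implied by the partition's block mean MAF (uniform weights if
    none available).  Block p-values are one-sided in z after a median-based
    genomic-control correction (lambda = median(z^2)/chi2_1 median, capped
    below at 1) estimated across blocks.
    """
    p = np.asarray(p_values, float)
    if p.shape[0] != len(partition.block_of):
        raise ValueError("p-values must align with the partition's SNPs")
    tiny = np.finfo(float).tiny
    if np.any(p <= 0):
        warnings.warn("p-values of 0 clipped to machine minimum", UserWarning,
                      stacklevel=2)
    p = np.clip(p, tiny, 1 - 1e-16)
    z = stats.norm.isf(p)
    if weights is None:
        weights = np.ones_like(p)
    w = np.asarray(weights, float)

    rows = []
    for _, b in partition.blocks.iterrows():
        lo, hi = int(b.start_idx), int(b.end_idx)
        ok = np.isfinite(z[lo:hi]) & np.isfinite(w[lo:hi])
        if not ok.any():
            rows.append({"block_id": int(b.block_id), "z": np.nan})
            continue
        wi, zi = w[lo:hi][ok], z[lo:hi][ok]
        rows.append({
            "block_id": int(b.block_id),
            "z": float((wi * zi).sum() / np.sqrt((wi**2).sum())),
            "n_snps": int(ok.sum()),
        })
    out = pd.DataFrame(rows)
    zb = out.z.to_numpy()
    lam = 1.0
    ok = np.isfinite(zb)
    if correct_inflation and ok.sum() >= 2:
        lam = max(float(np.median(zb[ok] ** 2) / _CHI2_1_MEDIAN), 1.0)
    out["lambda_gc"] = lam
    out["z_corrected"] = zb / np.sqrt(lam)
    out["p"] = stats.norm.sf(out.z_corrected)
    return out


def fdr_correct(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(p_values, float)
    ok = np.isfinite(p)
    q = np.full(p.shape, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


@dataclass
class EgeaResult:
    """Combined per-SNP and per-block association scan for one climate variable."""

    snp: pd.DataFrame
    block: pd.DataFrame
    method: str
    climate_var: str


def egea_scan(
    response: np.ndarray,
    climate: np.ndarray,
    partition: LDBlockPartition,
    method: str = "kendall",
    climate_var: str = "bio1",
    k_factors: int = 1,
    depth: np.ndarray | None = None,
    alt: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> EgeaResult:
    """One full eGEA pass: per-SNP test -> WZA block pooling -> BH q-values."""
    if method == "kendall":
        snp = egea_kendall(response, climate)
    elif method == "latent_factor":
        snp = egea_latent_factor(response, climate, k_factors=k_factors)
    elif method == "glm":
        if alt is None or depth is None:
            raise ValueError("glm method requires alt and depth counts")
        snp = egea_glm(alt, depth, climate)
    else:
        raise ValueError("method must be kendall, latent_factor or glm")
    block = wza_pool(snp.p.to_numpy(), partition, weights=weights)
    block["q"] = fdr_correct(block.p.to_numpy())
    return EgeaResult(snp=snp, block=block, method=method, climate_var=climate_var)
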