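"""Trajectory models, selection coefficients, genomic offset and forecasting.

Allele trajectories are modelled on the logit scale: a linear regression of
logit(p) on time gives the logistic slope beta (= dp/(1-p)p per year), and
the same slope per generation converts to a per-generation selection
coefficient under haploid lineage competition, odds(p_t+1) = (1+s) odds(p_t),
i.e. s = exp(slope) - 1.

The genomic-offset model fits, across training gardens, a per-SNP logistic
cline of evolved allele frequency on climate; evaluated at a query climate z
it yields the climate-predicted adaptive frequency p_adapt(z), and an
accession's offset is the mean absolute mismatch between p_adapt and its
own alleles.  Lower offset predicts better expected fitness, which is
validated garden-by-garden with leave-one-out rank correlations against the
observed accession frequency changes, and linked to population survival by
logistic regression on predictability, temperature and their interaction.
U-shaped census trajectories (decline then rebound, the demographic
signature of evolutionary rescue) are detected with quadratic fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .panel import FounderPanel
from .stabsel import StabilizingSelectionModel, log_fitness_ratios

__all__ = [
    "fit_logistic_trajectory",
    "estimate_selection_coefficient",
    "SelectionEstimate",
    "GenomicOffsetModel",
    "go_score",
    "loo_predictability",
    "survival_model",
    "census_trajectory",
]


def _logit_regress(y_logit: np.ndarray, x: np.ndarray):
    """Slope/intercept/se/p of a simple linear regression (vectorized columns)."""
    Y = np.atleast_2d(y_logit.T).T  # (T, S)
    xc = x - x.mean()
    denom = float(xc @ xc)
    slope = (xc @ Y) / denom
    intercept = Y.mean(axis=0) - slope * x.mean()
    resid = Y - (np.outer(x, slope) + intercept)
    dof = len(x) - 2
    if dof > 0:
        se = np.sqrt((resid**2).sum(axis=0) / dof / denom)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, slope / se,
                         np.where(np.abs(slope) > 1e-12, np.inf, 0.0))
        p = 2 * stats.t.sf(np.abs(t), dof)
    else:
        se = np.full_like(slope, np.nan)
        p = np.full_like(slope, np.nan)
    return slope, intercept, se, p, dof


def fit_logistic_trajectory(
    freqs: np.ndarray,
    predictor: np.ndarray,
    clip: float = 1e-4,
    block_of: np.ndarray | None = None,
) -> pd.DataFrame:
    """Logistic slope beta of allele frequency vs time or climate.

    ``freqs`` is (observations x SNPs) (or a single trajectory); a linear
    regression of logit(p) on the predictor gives beta per SNP.  With
    ``block_of`` the per-SNP betas are additionally averaged per LD block
    (returned in attrs["block"]).  Series with fewer than 3 finite points
    are skipped (NaN row, reason implicit in ``n_obs``).
    """
    P = np.asarray(freqs, float)
    if P.ndim == 1:
        P = P[:, None]
    x = np.asarray(predictor, float)
    if P.shape[0] != len(x):
        raise ValueError("predictor must align with observations")
    S = P.shape[1]
    out = pd.DataFrame(
        {"beta": np.nan, "intercept": np.nan, "se": np.nan, "p": np.nan,
         "n_obs": 0}, index=range(S),
    )
    L = logit(np.clip(P, clip, 1 - clip))
    for s in range(S):
        ok = np.isfinite(L[:, s]) & np.isfinite(x)
        if ok.sum() < 3 or np.std(x[ok]) == 0:
            out.loc[s, "n_obs"] = int(ok.sum())
            continue
        b, a, se, p, _ = _logit_regress(L[ok, s], x[ok])
        out.loc[s, ["beta", "intercept", "se", "p", "n_obs"]] = (
            float(b[0]), float(a[0]), float(se[0]), float(p[0]), int(ok.sum())
        )
    if block_of is not None:
        blk = (
            pd.DataFrame({"block": np.asarray(block_of), "beta": out.beta})
            .groupby("block", as_index=False)
            .beta.mean()
        )
        out.attrs["block"] = blk
    return out


@dataclass
class SelectionEstimate:
    """Per-generation selection coefficient from an allele trajectory."""

    s: float
    ci_low: float
    ci_high: float
    n_generations: int


def estimate_selection_coefficient(
    freqs: np.ndarray,
    generations: np.ndarray | None = None,
    clip: float = 1e-4,
) -> SelectionEstimate:
    """Haploid lineage-competition selection coefficient.

    odds(p_t+1) = (1+s) odds(p_t) implies logit(p_t) is linear in t with
    slope log(1+s); s_hat = exp(slope) - 1, with the CI transformed from the
    regression slope CI (undefined with only two timepoints, where the
    slope is exact).
    """
    p = np.asarray(freqs, float)
    ok = np.isfinite(p)
    if ok.sum() < 2:
        raise ValueError("need >= 2 timepoints")
    t = np.arange(len(p), dtype=float) if generations is None else np.asarray(generations, float)
    t, p = t[ok], p[ok]
    y = logit(np.clip(p, clip, 1 - clip))
    if len(p) == 2:
        slope = (y[1] - y[0]) / (t[1] - t[0])
        s = float(np.expm1(slope))
        return SelectionEstimate(s, np.nan, np.nan, int(t[-1] - t[0]))
    b, _, se, _, dof = _logit_regress(y, t)
    tq = stats.t.ppf(0.975, dof)
    lo, hi = b[0] - tq * se[0], b[0] + tq * se[0]
    return SelectionEstimate(
        s=float(np.expm1(b[0])), ci_low=float(np.expm1(lo)),
        ci_high=float(np.expm1(hi)), n_generations=int(round(t[-1] - t[0])),
    )


class GenomicOffsetModel(BaseEstimator):
    """Per-SNP logistic climate clines and the genomic-offset score.

    ``fit(X, Y)`` takes training-garden climates X (n_gardens,) or
    (n_gardens, 1) and evolved allele frequencies Y (n_gardens x n_snps);
    each SNP gets a logistic cline logit(p) = a + b z.  ``predict(z)``
    evaluates the climate-predicted adaptive frequencies p_adapt(z) in
    (0, 1); ``offset(z, genotypes)`` returns each genotype's mean absolute
    mismatch GO = mean_i |p_adapt,i - X_i| over the SNP subset (lower =
    better predicted fit).

    Parameters
    ----------
    snp_subset : array of int, optional
        SNP indices used for scoring (e.g. top climate-associated blocks);
        all SNPs by default.
    clip : float
        Frequency clipping bound before the logit transform.
    """

    def __init__(self, snp_subset: np.ndarray | None = None, clip: float = 1e-4):
        self.snp_subset = snp_subset
        self.clip = clip

    def fit(self, X, Y):
        z = np.asarray(X, float).ravel()
        Y = np.atleast_2d(np.asarray(Y, float))
        if len(z) != Y.shape[0]:
            raise ValueError("one climate value per training garden required")
        if len(z) < 3:
            raise ValueError("need >= 3 training gardens")
        if np.std(z) == 0:
            raise ValueError("training climates are constant")
        sub = np.arange(Y.shape[1]) if self.snp_subset is None else np.asarray(self.snp_subset, int)
        if sub.size == 0:
            raise ValueError("snp_subset is empty")
        L = logit(np.clip(Y[:, sub], self.clip, 1 - self.clip))
        slope, intercept, _, _, _ = _logit_regress(L, z)
        self.subset_ = sub
        self.slope_ = slope
        self.intercept_ = intercept
        self.n_features_in_ = Y.shape[1]
        return self

    def predict(self, z: float | np.ndarray) -> np.ndarray:
        """Climate-predicted adaptive allele frequencies p_adapt(z)."""
        check_is_fitted(self, "slope_")
        z = np.asarray(z, float)
        return expit(self.intercept_ + np.multiply.outer(z, self.slope_))

    def offset(self, z: float, genotypes: np.ndarray) -> np.ndarray:
        """GO score per genotype row at climate z (mean |p_adapt - dosage|)."""
        check_is_fitted(self, "slope_")
        p_adapt = self.predict(float(z))
        G = np.atleast_2d(np.asarray(genotypes, float))[:, self.subset_]
        return np.nanmean(np.abs(G - p_adapt[None, :]), axis=1)


def go_score(model: GenomicOffsetModel, z_query: float, panel: FounderPanel) -> np.ndarray:
    """Per-accession genomic offset of the founder panel at a query climate."""
    return model.offset(z_query, panel.imputed_genotypes())


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.nanstd(x)
    return (x - np.nanmean(x)) / sd if sd > 0 else np.zeros_like(x)


def loo_predictability(
    garden_climates: np.ndarray,
    allele_p1: np.ndarray,
    acc_f0: np.ndarray,
    acc_f1: np.ndarray,
    panel: FounderPanel,
    z_origin: np.ndarray | None = None,
    scorer: str = "go",
    snp_subsets: dict[int, np.ndarray] | None = None,
    garden_ids: list[str] | None = None,
    epsilon: float = 1e-4,
) -> pd.DataFrame:
    """Leave-one-out prediction of per-accession frequency change ranks.

    For each garden, a genomic-offset model is trained on the remaining
    gardens' evolved allele frequencies (``allele_p1``: gardens x SNPs,
    replicate-averaged) and scores every accession at the held-out garden's
    climate.  Observed outcomes are the per-replicate accession log(p1/p0)
    (``acc_f0``/``acc_f1``: gardens x replicates x accessions).  Scorers:

    * ``go`` — rank by negative genomic offset;
    * ``go_plus_stabsel`` — combine (z-scored) negative offset with the
      stabilizing-selection predicted log fitness from a model fitted on the
      training gardens;
    * ``climate_distance`` — rank by negative squared climate distance
      between accession origin and the garden (baseline).

    Returns one row per garden x replicate with the Spearman r (and r^2)
    between predicted score and observed log frequency change.
    """
    z = np.asarray(garden_climates, float)
    G = len(z)
    if G < 3:
        raise ValueError("need >= 3 gardens for leave-one-out validation")
    allele_p1 = np.atleast_2d(allele_p1)
    acc_f0 = np.asarray(acc_f0, float)
    acc_f1 = np.asarray(acc_f1, float)
    if scorer in ("go_plus_stabsel", "climate_distance") and z_origin is None:
        raise ValueError(f"scorer {scorer!r} requires z_origin")
    ids = garden_ids or [f"garden{i}" for i in range(G)]
    geno = panel.imputed_genotypes()

    rows = []
    for g in range(G):
        train = np.setdiff1d(np.arange(G), [g])
        subset = None if snp_subsets is None else snp_subsets.get(g)
        model = GenomicOffsetModel(snp_subset=subset).fit(z[train], allele_p1[train])
        go = model.offset(z[g], geno)
        if scorer == "go":
            score = -go
        elif scorer == "climate_distance":
            score = -((np.asarray(z_origin, float) - z[g]) ** 2)
        elif scorer == "go_plus_stabsel":
            score = _zscore(-go) + _zscore(
                _stabsel_pred(acc_f0, acc_f1, z, z_origin, train, g, panel, epsilon)
            )
        else:
            raise ValueError("scorer must be go, go_plus_stabsel or climate_distance")
        for r in range(acc_f0.shape[1]):
            obs, _ = log_fitness_ratios(acc_f0[g, r], acc_f1[g, r], epsilon=epsilon)
            ok = np.isfinite(obs) & np.isfinite(score)
            rho = stats.spearmanr(score[ok], obs[ok]).statistic if ok.sum() > 2 else np.nan
            rows.append({
                "garden": ids[g], "replicate": r, "r": float(rho),
                "r2": float(rho**2) if np.isfinite(rho) else np.nan,
                "z_garden": float(z[g]), "scorer": scorer,
            })
    return pd.DataFrame(rows)


def _stabsel_pred(acc_f0, acc_f1, z, z_origin, train, g, panel, epsilon):
    """Predicted log fitness at garden g from a fit on the training gardens."""
    recs = []
    for gt in train:
        f0 = acc_f0[gt].mean(axis=0)
        f1 = acc_f1[gt].mean(axis=0)
        y, flag = log_fitness_ratios(f0, f1, epsilon=epsilon)
        d2 = (np.asarray(z_origin, float) - z[gt]) ** 2
        for a in range(len(f0)):
            if not flag[a]:
                recs.append((panel.accession_ids[a], f"g{gt}", d2[a], y[a]))
    df = pd.DataFrame(recs, columns=["accession", "garden", "dist2", "y"])
    model = StabilizingSelectionModel(min_gardens=2).fit(
        df[["accession", "garden", "dist2"]], df.y
    )
    d2q = (np.asarray(z_origin, float) - z[g]) ** 2
    amap = {a: i for i, a in enumerate(model.accessions_)}
    pred = np.empty(len(panel.accession_ids))
    for i, acc in enumerate(panel.accession_ids):
        j = amap.get(acc)
        if j is None:
            pred[i] = model.global_intercept_ - model.global_v_s_inv_ * d2q[i]
        else:
            pred[i] = model.log_w_max_[j] - model.v_s_inv_[j] * d2q[i]
    return pred


def survival_model(
    records: pd.DataFrame,
    year: int = 3,
    ridge: float = 1.0,
) -> dict:
    """Logistic regression of replicate survival on predictability and climate.

    ``records`` needs columns ``r2`` (per-replicate predictability),
    ``temp`` (garden temperature) and ``survived_y{year}`` (0/1).  The model
    is survival ~ r2 + temp + r2:temp.  With one-sided outcomes or complete
    separation the maximum-likelihood fit is degenerate: a ridge-penalized
    refit is returned and flagged.  The 50% survival isoline solves the
    fitted model for temp as a function of r2.
    """
    import statsmodels.api as sm

    col = f"survived_y{year}"
    df = records.dropna(subset=["r2", "temp", col])
    if len(df) < 20:
        raise ValueError("need >= 20 records")
    y = df[col].to_numpy(float)
    X = np.column_stack([
        np.ones(len(df)), df.r2.to_numpy(float), df.temp.to_numpy(float),
        df.r2.to_numpy(float) * df.temp.to_numpy(float),
    ])
    names = ["const", "r2", "temp", "r2:temp"]
    flagged = False
    if len(np.unique(y)) < 2:
        return {"coef": dict.fromkeys(names, np.nan),
                "se": dict.fromkeys(names, np.nan),
                "p": dict.fromkeys(names, np.nan),
                "flagged": True, "reason": "all outcomes identical", "n": len(df)}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 1e3):
            raise ValueError("separation")
        coef, ses, pvals = fit.params, fit.bse, fit.pvalues
    except Exception:
        flagged = True
        coef, ses, pvals = _ridge_logit(y, X, ridge)
    out = {"coef": dict(zip(names, map(float, coef))),
           "se": dict(zip(names, map(float, ses))),
           "p": dict(zip(names, map(float, pvals))),
           "flagged": flagged, "n": len(df)}
    b = out["coef"]
    out["isoline_temp_at_r2"] = lambda r2: (
        -(b["const"] + b["r2"] * r2) / (b["temp"] + b["r2:temp"] * r2)
        if (b["temp"] + b["r2:temp"] * r2) != 0 else np.nan
    )
    return out


def _ridge_logit(y, X, alpha):
    from scipy.optimize import minimize

    def nll(beta):
        eta = X @ beta
        return float(np.sum(np.log1p(np.exp(-np.abs(eta))) + np.maximum(eta, 0) - y * eta)
                     + 0.5 * alpha * beta[1:] @ beta[1:])

    res = minimize(nll, np.zeros(X.shape[1]), method="BFGS")
    beta = res.x
    mu = expit(X @ beta)
    W = mu * (1 - mu)
    H = X.T @ (W[:, None] * X) + alpha * np.diag([0.0, 1, 1, 1])
    se = np.sqrt(np.diag(np.linalg.pinv(H)))
    zstat = np.where(se > 0, beta / se, 0.0)
    return beta, se, 2 * stats.norm.sf(np.abs(zstat))


def census_trajectory(
    census: np.ndarray,
    times: np.ndarray | None = None,
) -> dict:
    """Quadratic fit of census size over generations; rebound detection.

    Replicate counts are pooled into one regression per garden.  A rebound
    (evolutionary-rescue signature) is flagged when the quadratic
    coefficient is positive, the parabola's minimum lies strictly inside
    the observed time range, and the coefficient is statistically supported
    (p < 0.05, or an exact fit with no residual degrees of freedom).
    Collinear (perfectly linear) counts give a zero quadratic term.
    """
    C = np.atleast_2d(np.asarray(census, float))
    T = C.shape[1]
    if times is None:
        times = np.arange(T, dtype=float)
    t = np.tile(np.asarray(times, float), C.shape[0])
    y = C.ravel()
    ok = np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(np.unique(t)) < 3:
        return {"fitted": False, "reason": "fewer than 3 census timepoints"}
    X = np.column_stack([np.ones_like(t), t, t**2])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - 3
    rss = float((resid**2).sum())
    a = float(beta[2])
    if dof > 0 and rss > 1e-9 * max(float((y**2).sum()), 1.0):
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.pinv(X.T @ X)
        se = float(np.sqrt(max(cov[2, 2], 0.0)))
        p = 2 * stats.t.sf(abs(a) / se, dof) if se > 0 else 0.0
        exact = False
    else:
        p, exact = np.nan, True
    t_min = -beta[1] / (2 * a) if abs(a) > 1e-12 else np.nan
    interior = np.isfinite(t_min) and (times[0] < t_min < times[-1])
    supported = exact or (np.isfinite(p) and p < 0.05)
    rebound = bool(a > 1e-12 and interior and supported)
    return {
        "fitted": True, "intercept": float(beta[0]), "linear": float(beta[1]),
        "quadratic": a, "p_quadratic": float(p) if np.isfinite(p) else np.nan,
        "t_minimum": float(t_min) if np.isfinite(t_min) else np.nan,
        "rebound": rebound, "n": int(len(y)),
    }
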