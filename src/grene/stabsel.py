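"""Gaussian stabilizing-selection fits to accession frequency trajectories.

Under soft selection in a garden g, an accession's frequency change over one
generation measures its relative fitness, log(p_t+1/p_t) = log(w/ w_bar).
With a Gaussian fitness curve around the accession's climate of origin this
becomes a linear model in squared climate distance:

    log(p_t+1 / p_t) = log W_max,a - Vs_inv,a (z_origin,a - z_garden)^2 - log w_bar_g

The garden mean-fitness terms log w_bar_g are fixed per-garden offsets
(anchored to zero in the first garden for identifiability); the slope on
squared distance is the strength of stabilizing selection Vs_inv, fitted
either globally (one shared slope) or per accession (accession-specific
peak fitness and niche width, the specialist-generalist axis).

Also here: realized climatic optima (frequency-weighted garden climates)
and the adaptation lag z_opt - z_origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "log_fitness_ratios",
    "StabilizingSelectionModel",
    "fit_global_stabilizing",
    "fit_per_accession",
    "niche_tradeoff",
    "realized_optimum",
    "OptimumEstimate",
]


def log_fitness_ratios(
    f_t: np.ndarray,
    f_t1: np.ndarray,
    epsilon: float = 1e-4,
    exclude_below: float = 1e-5,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell log((f_t1 + eps) / (f_t + eps)) fitness proxies.

    ``epsilon`` regularizes boundary frequencies (default ~half of one
    flower in a 5,000-seed pool).  Entries with f_t below
    ``exclude_below`` are returned but flagged True in the second array;
    downstream fits drop them (a lineage essentially absent at t carries no
    usable fitness information).
    """
    f_t = np.asarray(f_t, float)
    f_t1 = np.asarray(f_t1, float)
    ratio = np.log(f_t1 + epsilon) - np.log(f_t + epsilon)
    flagged = f_t < exclude_below
    return ratio, flagged


class StabilizingSelectionModel(RegressorMixin, BaseEstimator):
    """Least-squares fit of the Gaussian stabilizing-selection model.

    Parameters
    ----------
    min_gardens : int
        Minimum number of distinct gardens an accession must appear in for
        an accession-specific fit; accessions below the threshold are
        skipped (with the reason recorded) but still contribute to the
        global fit.
    per_accession : bool
        Fit accession-specific intercepts and slopes (sharing the garden
        offsets) in addition to the global slope.
    truncate : bool
        Clip negative fitted Vs_inv at zero (flagged, raw value retained).

    The design matrix for ``fit(X, y)`` takes ``X`` as a DataFrame with
    columns ``accession``, ``garden`` and ``dist2`` (squared climate
    distance between origin and garden) and ``y`` as the log fitness
    ratios.  One garden's offset is anchored at zero.

    Attributes (fitted)
    -------------------
    global_v_s_inv_, global_se_, global_ci_, global_p_, r2_ : float
        Shared-slope fit and its diagnostics.
    garden_offsets_ : Series
        Fixed per-garden offsets -log w_bar_g (first garden = 0).
    accessions_, log_w_max_, w_max_, v_s_inv_, v_s_inv_raw_, v_s_inv_se_,
    truncated_ : per-accession arrays (only when ``per_accession``).
    skipped_ : dict accession -> reason.
    """

    def __init__(self, min_gardens: int = 3, per_accession: bool = True,
                 truncate: bool = True):
        self.min_gardens = min_gardens
        self.per_accession = per_accession
        self.truncate = truncate

    def fit(self, X: pd.DataFrame, y):
        df = pd.DataFrame(
            {"accession": X["accession"], "garden": X["garden"],
             "dist2": np.asarray(X["dist2"], float), "y": np.asarray(y, float)}
        ).dropna()
        if df.dist2.nunique() < 2:
            raise ValueError("need >= 2 distinct squared climate distances")
        gardens = sorted(df.garden.unique())
        self.gardens_ = gardens
        g_idx = df.garden.map({g: i for i, g in enumerate(gardens)}).to_numpy()
        n, G = len(df), len(gardens)

        # --- global fit: one intercept, shared slope, garden offsets
        Xg = np.zeros((n, 2 + G - 1))
        Xg[:, 0] = 1.0
        Xg[:, 1] = -df.dist2.to_numpy()
        for g in range(1, G):
            Xg[g_idx == g, 1 + g] = 1.0
        beta, res, rank, _ = np.linalg.lstsq(Xg, df.y.to_numpy(), rcond=None)
        fittedg = Xg @ beta
        rss = float(((df.y.to_numpy() - fittedg) ** 2).sum())
        tss = float(((df.y - df.y.mean()) ** 2).sum())
        dof = n - Xg.shape[1]
        sigma2 = rss / dof if dof > 0 else 0.0
        cov = sigma2 * np.linalg.pinv(Xg.T @ Xg)
        se = float(np.sqrt(max(cov[1, 1], 0.0)))
        self.global_v_s_inv_ = float(beta[1])
        self.global_se_ = se
        tq = stats.t.ppf(0.975, dof) if dof > 0 else np.nan
        self.global_ci_ = (beta[1] - tq * se, beta[1] + tq * se)
        tstat = beta[1] / se if se > 0 else np.inf
        self.global_p_ = float(2 * stats.t.sf(abs(tstat), dof)) if dof > 0 else np.nan
        # guard: constant response has no variance to explain
        tss_floor = 1e-12 * max(float((df.y**2).sum()), 1e-30)
        self.r2_ = float(1 - rss / tss) if tss > tss_floor else 0.0
        self.garden_offsets_ = pd.Series(
            np.concatenate([[0.0], beta[2:]]), index=gardens, name="offset"
        )
        self.global_intercept_ = float(beta[0])

        self.skipped_ = {}
        if self.per_accession:
            self._fit_per_accession(df, gardens, g_idx)
        self.n_obs_ = n
        return self

    def _fit_per_accession(self, df, gardens, g_idx):
        counts = df.groupby("accession")["garden"].nunique()
        keep = counts[counts >= self.min_gardens].index
        for acc, c in counts.items():
            if acc not in set(keep):
                self.skipped_[acc] = f"observed in {c} gardens < min_gardens={self.min_gardens}"
        sub = df[df.accession.isin(keep)].reset_index(drop=True)
        accs = sorted(sub.accession.unique())
        a_idx = sub.accession.map({a: i for i, a in enumerate(accs)}).to_numpy()
        gi = sub.garden.map({g: i for i, g in enumerate(gardens)}).to_numpy()
        n, A, G = len(sub), len(accs), len(gardens)
        if A == 0:
            self.accessions_ = []
            return

        X = np.zeros((n, 2 * A + G - 1))
        X[np.arange(n), a_idx] = 1.0  # intercepts = log W_max
        X[np.arange(n), A + a_idx] = -sub.dist2.to_numpy()  # slopes = Vs_inv
        off = gi > 0
        X[np.where(off)[0], 2 * A + gi[off] - 1] = 1.0
        y = sub.y.to_numpy()
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        dof = max(n - X.shape[1], 1)
        sigma2 = rss / dof
        cov_diag = sigma2 * np.diag(np.linalg.pinv(X.T @ X))

        self.accessions_ = accs
        # the joint fit re-estimates the shared garden offsets; they replace
        # the shared-slope fit's offsets so predictions are self-consistent
        self.garden_offsets_ = pd.Series(
            np.concatenate([[0.0], beta[2 * A :]]), index=gardens, name="offset"
        )
        self.log_w_max_ = beta[:A]
        self.w_max_ = np.exp(beta[:A])
        raw = beta[A : 2 * A]
        self.v_s_inv_raw_ = raw
        self.truncated_ = raw < 0
        self.v_s_inv_ = np.where(self.truncated_, 0.0, raw) if self.truncate else raw
        self.v_s_inv_se_ = np.sqrt(np.clip(cov_diag[A : 2 * A], 0, None))
        self.log_w_max_se_ = np.sqrt(np.clip(cov_diag[:A], 0, None))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted log fitness ratio per (accession, garden, dist2) row."""
        check_is_fitted(self, "global_v_s_inv_")
        d2 = np.asarray(X["dist2"], float)
        offs = pd.Series(X["garden"]).map(self.garden_offsets_).fillna(0.0).to_numpy()
        if self.per_accession and getattr(self, "accessions_", None):
            amap = {a: i for i, a in enumerate(self.accessions_)}
            out = np.empty(len(d2))
            for i, (acc, dd, of) in enumerate(zip(X["accession"], d2, offs)):
                j = amap.get(acc)
                if j is None:
                    out[i] = self.global_intercept_ - self.global_v_s_inv_ * dd + of
                else:
                    out[i] = self.log_w_max_[j] - self.v_s_inv_[j] * dd + of
            return out
        return self.global_intercept_ - self.global_v_s_inv_ * d2 + offs

    def summary_frame(self) -> pd.DataFrame:
        check_is_fitted(self, "accessions_")
        return pd.DataFrame(
            {
                "accession": self.accessions_,
                "w_max": self.w_max_,
                "log_w_max": self.log_w_max_,
                "log_w_max_se": self.log_w_max_se_,
                "v_s_inv": self.v_s_inv_,
                "v_s_inv_raw": self.v_s_inv_raw_,
                "v_s_inv_se": self.v_s_inv_se_,
                "truncated": self.truncated_,
            }
        )


def fit_global_stabilizing(
    log_ratios: np.ndarray,
    dist2: np.ndarray,
    gardens: np.ndarray,
    accessions: np.ndarray | None = None,
) -> dict:
    """Shared-slope stabilizing-selection fit; see the estimator class."""
    acc = np.zeros(len(np.ravel(log_ratios)), int) if accessions is None else accessions
    X = pd.DataFrame({"accession": acc, "garden": gardens, "dist2": dist2})
    m = StabilizingSelectionModel(per_accession=False).fit(X, log_ratios)
    return {
        "v_s_inv": m.global_v_s_inv_,
        "se": m.global_se_,
        "ci": m.global_ci_,
        "r2": m.r2_,
        "p": m.global_p_,
        "garden_offsets": m.garden_offsets_,
        "n": m.n_obs_,
    }


def fit_per_accession(
    log_ratios: np.ndarray,
    dist2: np.ndarray,
    gardens: np.ndarray,
    accessions: np.ndarray,
    min_gardens: int = 3,
) -> StabilizingSelectionModel:
    """Accession-specific stabilizing-selection fit with shared garden offsets."""
    X = pd.DataFrame({"accession": accessions, "garden": gardens, "dist2": dist2})
    return StabilizingSelectionModel(min_gardens=min_gardens).fit(X, log_ratios)


def niche_tradeoff(fit: StabilizingSelectionModel) -> dict:
    """Spearman correlation between W_max and Vs_inv across accessions.

    A positive correlation is the specialist-generalist trade-off: high
    peak fitness comes with faster fitness decay away from the optimum.
    """
    check_is_fitted(fit, "accessions_")
    if len(fit.accessions_) < 10:
        raise ValueError("need >= 10 fitted accessions")
    w, v = fit.w_max_, fit.v_s_inv_
    if np.std(v) <= 1e-10 * max(np.abs(v).max(), 1e-30) or np.std(w) <= 1e-10:
        return {"rho": np.nan, "p": np.nan, "defined": False}
    res = stats.spearmanr(w, v)
    return {"rho": float(res.statistic), "p": float(res.pvalue), "defined": True}


@dataclass
class OptimumEstimate:
    """Realized climatic optima and adaptation lags per accession."""

    table: pd.DataFrame  # accession, z_opt, lag, defined


def realized_optimum(
    p0: np.ndarray,
    p1: np.ndarray,
    z_garden: np.ndarray,
    z_origin: np.ndarray,
    accession_ids: list[str] | None = None,
    weight: str = "p1/p0",
    epsilon: float = 1e-4,
) -> OptimumEstimate:
    """Frequency-weighted garden climate as each accession's realized optimum.

    ``p0``/``p1`` are (gardens x accessions) mean frequencies at the start
    and after selection; weights are either the enrichment ratio p1/p0
    (default) or the evolved frequency p1.  z_opt = sum_g w_ag z_g / sum_g
    w_ag; the adaptation lag is z_opt - z_origin.  Accessions with all-zero
    weights are flagged undefined.
    """
    p0 = np.atleast_2d(np.asarray(p0, float))
    p1 = np.atleast_2d(np.asarray(p1, float))
    if p0.shape[0] < 2:
        raise ValueError("need >= 2 gardens")
    z = np.asarray(z_garden, float)
    if weight == "p1/p0":
        w = (p1 + epsilon) / (p0 + epsilon)
    elif weight == "p1":
        w = p1.copy()
    else:
        raise ValueError("weight must be 'p1/p0' or 'p1'")
    w = np.where(np.isfinite(w), w, 0.0)
    tot = w.sum(axis=0)
    defined = tot > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z_opt = (w * z[:, None]).sum(axis=0) / tot
    z_opt[~defined] = np.nan
    lag = z_opt - np.asarray(z_origin, float)
    ids = accession_ids or [f"acc{i}" for i in range(p0.shape[1])]
    return OptimumEstimate(
        table=pd.DataFrame(
            {"accession": ids, "z_opt": z_opt, "lag": lag, "defined": defined}
        )
    )
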