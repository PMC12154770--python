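"""Allele- and accession-frequency reconstruction from pooled sequencing.

Pooled flower samples yield per-SNP ref/alt read counts.  Raw allele
frequencies are simply alt/(ref+alt); because every experimental population
is a mixture of known founder genomes, the pool can additionally be
deconvolved into founder-accession relative frequencies, and the allele
frequencies re-projected through the founder genotypes.  That projection is
the linkage-based error-reduction step: it pools information across all SNPs
carried on each founder haplotype, suppressing the sampling noise of ~10X
coverage.

Deconvolution is simplex-constrained ridge least squares

    f_hat = argmin_f ||G' f - p||^2 + ridge ||f||^2   s.t. f >= 0, sum f = 1

with G the accession x SNP dosage matrix.  It is exposed both as the
scikit-learn transformer :class:`AccessionDeconvolver` and as the
:func:`deconvolve_accessions` convenience function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .panel import FounderPanel

__all__ = [
    "PoolSample",
    "FrequencyTable",
    "AccessionFrequencyTable",
    "estimate_allele_freq",
    "AccessionDeconvolver",
    "deconvolve_accessions",
    "smooth_frequencies",
    "merge_samples",
    "estimate_error",
]


@dataclass
class PoolSample:
    """Per-SNP pooled read counts for one sequenced sample."""

    sample_id: str
    ref_count: np.ndarray
    alt_count: np.ndarray
    garden: str = ""
    replicate: int = 0
    generation: int = 0
    flowers: int = 0
    date: str = ""

    def __post_init__(self) -> None:
        self.ref_count = np.asarray(self.ref_count, dtype=np.int64)
        self.alt_count = np.asarray(self.alt_count, dtype=np.int64)
        if self.ref_count.shape != self.alt_count.shape:
            raise ValueError("ref_count and alt_count must have equal shape")
        if np.any(self.ref_count < 0) or np.any(self.alt_count < 0):
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        return self.ref_count + self.alt_count

    @property
    def n_snps(self) -> int:
        return self.ref_count.shape[0]

    def metadata(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "garden": self.garden,
            "replicate": self.replicate,
            "generation": self.generation,
            "flowers": self.flowers,
            "date": self.date,
        }


@dataclass
class FrequencyTable:
    """Sample x SNP allele frequencies with depths.

    ``freq`` is NaN wherever depth fell below the estimation threshold.
    ``smoothed`` flags whether frequencies are raw counts ratios or have been
    re-projected through the founder panel.
    """

    sample_ids: list[str]
    freq: np.ndarray
    depth: np.ndarray
    smoothed: bool = False
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.freq = np.atleast_2d(np.asarray(self.freq, dtype=float))
        self.depth = np.atleast_2d(np.asarray(self.depth, dtype=float))
        ok = self.freq[~np.isnan(self.freq)]
        if ok.size and (ok.min() < 0 or ok.max() > 1):
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.freq.shape[0]

    @property
    def n_snps(self) -> int:
        return self.freq.shape[1]


@dataclass
class AccessionFrequencyTable:
    """Per-sample simplex of founder-accession relative frequencies."""

    sample_ids: list[str]
    accession_ids: list[str]
    freq: np.ndarray
    residual_rms: np.ndarray

    def __post_init__(self) -> None:
        self.freq = np.atleast_2d(np.asarray(self.freq, dtype=float))
        if np.any(self.freq < -1e-12):
            raise ValueError("accession frequencies must be non-negative")
        sums = self.freq.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("accession frequencies must sum to 1 per sample")

    @property
    def n_samples(self) -> int:
        return self.freq.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.freq, index=self.sample_ids, columns=self.accession_ids
        )


def estimate_allele_freq(
    samples: PoolSample | list[PoolSample], min_depth: int = 1
) -> FrequencyTable:
    """Raw allele frequencies alt/(ref+alt) per sample.

    SNPs with depth below ``min_depth`` are set to NaN (missing).
    """
    if isinstance(samples, PoolSample):
        samples = [samples]
    if not samples:
        raise ValueError("no samples given")
    freq = np.full((len(samples), samples[0].n_snps), np.nan)
    depth = np.zeros_like(freq)
    meta = []
    for i, s in enumerate(samples):
        d = s.depth.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(d > 0, s.alt_count / np.maximum(d, 1), np.nan)
        p[d < min_depth] = np.nan
        freq[i], depth[i] = p, d
        meta.append(s.metadata())
    return FrequencyTable(
        sample_ids=[s.sample_id for s in samples],
        freq=freq,
        depth=depth,
        smoothed=False,
        metadata=pd.DataFrame(meta).set_index("sample_id"),
    )


class AccessionDeconvolver(TransformerMixin, BaseEstimator):
    """Deconvolve pooled allele frequencies into founder-accession frequencies.

    Fit on the founder genotype matrix (accessions x SNPs); transform maps
    each sample's per-SNP allele-frequency vector onto the simplex of founder
    relative abundances by non-negative ridge least squares with a sum-to-one
    constraint.

    Parameters
    ----------
    ridge : float
        L2 penalty on the accession frequencies; a small default keeps the
        solution stable when the panel is near rank-deficient.

    Attributes
    ----------
    genotypes_ : ndarray, shape (n_accessions, n_snps)
        Founder dosages with missing calls mean-imputed per SNP.
    n_features_in_ : int
        Number of SNPs seen at fit time.
    rank_deficient_ : bool
        True when the genotype matrix has numerically deficient row rank
        (a warning is emitted; solutions are still returned, regularized).
    residual_rms_ : ndarray
        Root-mean-square residual ||G'f - p|| per sample of the last
        transform call.
    """

    def __init__(self, ridge: float = 1e-4):
        self.ridge = ridge

    def fit(self, X, y=None):
        geno = X.imputed_genotypes() if isinstance(X, FounderPanel) else np.asarray(X, float)
        if np.isnan(geno).any():
            col = np.nanmean(geno, axis=0)
            idx = np.where(np.isnan(geno))
            geno = geno.copy()
            geno[idx] = np.nan_to_num(col, nan=0.5)[idx[1]]
        if geno.ndim != 2 or geno.shape[0] < 1:
            raise ValueError("genotype matrix must be 2-D, accessions x SNPs")
        self.genotypes_ = geno
        self.n_features_in_ = geno.shape[1]
        sv = np.linalg.svd(geno, compute_uv=False)
        self.rank_deficient_ = bool(np.sum(sv > sv[0] * 1e-10) < geno.shape[0])
        if self.rank_deficient_:
            warnings.warn(
                "founder genotype matrix is rank-deficient; deconvolution is "
                "regularized but accession frequencies may not be unique",
                UserWarning,
                stacklevel=2,
            )
        return self

    def _solve_one(self, p: np.ndarray) -> tuple[np.ndarray, float]:
        mask = np.isfinite(p)
        n_used = int(mask.sum())
        if n_used == 0:
            raise ValueError("all SNPs missing in sample; cannot deconvolve")
        G = self.genotypes_[:, mask]
        n_acc = G.shape[0]
        w_sum = 10.0 * np.sqrt(n_used)
        rows = [G.T, np.full((1, n_acc), w_sum)]
        targets = [p[mask], np.array([w_sum])]
        if self.ridge > 0:
            rows.append(np.sqrt(self.ridge) * np.eye(n_acc))
            targets.append(np.zeros(n_acc))
        A = np.vstack(rows)
        b = np.concatenate(targets)
        f, _ = nnls(A, b)
        total = f.sum()
        f = np.full(n_acc, 1.0 / n_acc) if total <= 0 else f / total
        rms = float(np.sqrt(np.mean((G.T @ f - p[mask]) ** 2)))
        return f, rms

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self)
        P = X.freq if isinstance(X, FrequencyTable) else np.atleast_2d(np.asarray(X, float))
        if P.shape[1] != self.n_features_in_:
            raise ValueError("SNP axis does not match the fitted panel")
        out = np.empty((P.shape[0], self.genotypes_.shape[0]))
        rms = np.empty(P.shape[0])
        for i, p in enumerate(P):
            out[i], rms[i] = self._solve_one(p)
        self.residual_rms_ = rms
        return out


def deconvolve_accessions(
    freqs: FrequencyTable | np.ndarray,
    panel: FounderPanel,
    ridge: float = 1e-4,
) -> AccessionFrequencyTable:
    """Reconstruct founder-accession frequencies for every sample.

    See :class:`AccessionDeconvolver` for the underlying model.
    """
    dec = AccessionDeconvolver(ridge=ridge).fit(panel)
    F = dec.transform(freqs)
    if isinstance(freqs, FrequencyTable):
        ids = freqs.sample_ids
    else:
        ids = [f"s{i}" for i in range(F.shape[0])]
    return AccessionFrequencyTable(
        sample_ids=list(ids),
        accession_ids=list(panel.accession_ids),
        freq=F,
        residual_rms=dec.residual_rms_,
    )


def smooth_frequencies(
    freqs: FrequencyTable,
    accfreq: AccessionFrequencyTable,
    panel: FounderPanel,
) -> FrequencyTable:
    """Linkage-smoothed allele frequencies: project accession frequencies back.

    p_smooth = G' f_hat per sample.  Because f_hat pools evidence across all
    SNPs on each founder haplotype, the projected frequencies have far lower
    sampling error than the raw per-SNP ratios at low coverage.  Applying the
    smoothing twice is a no-op (the projection is already consistent with the
    deconvolution that produced it).
    """
    G = panel.imputed_genotypes()
    smooth = np.clip(accfreq.freq @ G, 0.0, 1.0)
    return FrequencyTable(
        sample_ids=list(freqs.sample_ids),
        freq=smooth,
        depth=freqs.depth.copy(),
        smoothed=True,
        metadata=None if freqs.metadata is None else freqs.metadata.copy(),
    )


def merge_samples(samples: list[PoolSample]) -> PoolSample:
    """Merge repeated samplings of the same tray and season by summing counts."""
    if not samples:
        raise ValueError("no samples to merge")
    keys = {(s.garden, s.replicate, s.generation) for s in samples}
    if len(keys) > 1:
        raise ValueError(f"cannot merge samples with mixed metadata: {sorted(keys)}")
    first = samples[0]
    return PoolSample(
        sample_id="+".join(s.sample_id for s in samples),
        ref_count=np.sum([s.ref_count for s in samples], axis=0),
        alt_count=np.sum([s.alt_count for s in samples], axis=0),
        garden=first.garden,
        replicate=first.replicate,
        generation=first.generation,
        flowers=sum(s.flowers for s in samples),
        date=first.date,
    )


def estimate_error(estimated, truth) -> dict:
    """Error summary (MAE, RMSE, abs-error quantiles) of estimated vs true.

    Accepts arrays, :class:`FrequencyTable` or :class:`AccessionFrequencyTable`
    pairs of identical shape; NaNs in either are dropped pairwise.
    """
    a = estimated.freq if hasattr(estimated, "freq") else np.asarray(estimated, float)
    b = truth.freq if hasattr(truth, "freq") else np.asarray(truth, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    err = np.abs(a - b).ravel()
    err = err[np.isfinite(err)]
    if err.size == 0:
        raise ValueError("no overlapping non-missing entries")
    return {
        "mae": float(err.mean()),
        "rmse": float(np.sqrt(np.mean(err**2))),
        "q50": float(np.quantile(err, 0.5)),
        "q90": float(np.quantile(err, 0.9)),
        "q99": float(np.quantile(err, 0.99)),
        "n": int(err.size),
    }
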