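"""LD-block partition, replicate-consistent selection scan, block overlap.

Because the experimental populations descend from a closed founder panel,
linkage disequilibrium among the founders defines the natural resolution of
any selection signal: SNPs in one founder LD block move together under
lineage sorting.  The partition here chains consecutive SNPs greedily while
they stay correlated (r^2) with the recent SNPs of the growing block.

The selection scan is a per-SNP binomial likelihood-ratio test for a
frequency shift shared by all replicates of a garden: the null holds one
common frequency at both timepoints, the alternative allows a single common
post-selection frequency (one extra parameter, chi-square(1) reference).
Cross-garden consistency of significant blocks is assessed by a permutation
test that resamples each garden's significant set uniformly over blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import FounderPanel

__all__ = [
    "LDBlockPartition",
    "ScanResult",
    "build_ld_blocks",
    "lrt_parallel_selection",
    "scan_genome",
    "block_overlap_permutation",
]

_CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.4549...


@dataclass
class LDBlockPartition:
    """Contiguous, non-overlapping blocks covering every SNP exactly once."""

    block_of: np.ndarray  # (n_snps,) block id per SNP
    blocks: pd.DataFrame  # block_id, chrom, start_idx, end_idx, n_snps, mean_maf

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def snp_indices(self, block_id: int) -> np.ndarray:
        return np.where(self.block_of == block_id)[0]

    def to_bed(self, snp_chrom: np.ndarray, snp_pos: np.ndarray) -> pd.DataFrame:
        """0-based half-open intervals spanning each block's SNP positions."""
        rows = []
        for _, b in self.blocks.iterrows():
            lo, hi = int(b.start_idx), int(b.end_idx)
            rows.append({
                "chrom": snp_chrom[lo],
                "start": int(snp_pos[lo]) - 1,
                "end": int(snp_pos[hi - 1]),
                "name": f"block{int(b.block_id)}",
            })
        return pd.DataFrame(rows)


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        return 0.0
    xs, ys = x[ok], y[ok]
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def build_ld_blocks(
    panel: FounderPanel,
    r2_threshold: float = 0.5,
    max_gap: int = 10,
) -> LDBlockPartition:
    """Greedy chaining of consecutive SNPs into founder LD blocks.

    A block is extended to the next SNP whenever that SNP's r^2 with any of
    the last ``max_gap`` SNPs already in the block reaches ``r2_threshold``;
    otherwise a new block starts.  Blocks never span chromosomes.  The
    procedure is deterministic.
    """
    geno = panel.genotypes
    n_snps = geno.shape[1]
    if n_snps < 2:
        raise ValueError("need >= 2 SNPs")
    block_of = np.empty(n_snps, dtype=int)
    records = []
    bid = -1
    start = 0
    for i in range(n_snps):
        new_block = i == 0 or panel.snp_chrom[i] != panel.snp_chrom[i - 1]
        if not new_block:
            lo = max(start, i - max_gap)
            r2 = max(
                _pairwise_r2(geno[:, j], geno[:, i]) for j in range(lo, i)
            )
            new_block = r2 < r2_threshold
        if new_block:
            if bid >= 0:
                records.append((bid, start, i))
            bid += 1
            start = i
        block_of[i] = bid
    records.append((bid, start, n_snps))

    maf = np.nanmean(geno, axis=0)
    maf = np.minimum(maf, 1 - maf)
    blocks = pd.DataFrame(
        [
            {
                "block_id": b,
                "chrom": panel.snp_chrom[lo],
                "start_idx": lo,
                "end_idx": hi,
                "n_snps": hi - lo,
                "mean_maf": float(np.nanmean(maf[lo:hi])),
            }
            for b, lo, hi in records
        ]
    )
    return LDBlockPartition(block_of=block_of, blocks=blocks)


def _binom_ll(alt: np.ndarray, depth: np.ndarray, p: float) -> float:
    # kernel only; the combinatorial term cancels in the ratio
    alt = np.asarray(alt, float)
    depth = np.asarray(depth, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = alt * np.log(p) + (depth - alt) * np.log1p(-p)
    # 0*log(0) -> 0
    term = np.where((alt == 0) & (p == 0), 0.0, term)
    term = np.where((alt == depth) & (p == 1), 0.0, term)
    return float(np.nansum(term))


def lrt_parallel_selection(
    alt0: np.ndarray,
    depth0: np.ndarray,
    alt1: np.ndarray,
    depth1: np.ndarray,
) -> tuple[float, float]:
    """Replicate-consistent frequency-shift LRT at one SNP.

    Null: one common allele frequency generates all replicates' counts at
    both timepoints.  Alternative: a common starting frequency at t0 and a
    single shared post-selection frequency at t1.  Returns (statistic, p)
    with p from chi-square(1).  Returns (nan, nan) when total depth is zero.
    """
    alt0, depth0 = np.asarray(alt0, float), np.asarray(depth0, float)
    alt1, depth1 = np.asarray(alt1, float), np.asarray(depth1, float)
    if alt0.shape != depth0.shape or alt1.shape != depth1.shape:
        raise ValueError("counts and depths must align")
    d0, d1 = depth0.sum(), depth1.sum()
    if d0 + d1 <= 0:
        return float("nan"), float("nan")
    a0, a1 = alt0.sum(), alt1.sum()
    p_null = (a0 + a1) / (d0 + d1)
    p0 = a0 / d0 if d0 > 0 else p_null
    p1 = a1 / d1 if d1 > 0 else p_null
    ll_null = _binom_ll(alt0, depth0, p_null) + _binom_ll(alt1, depth1, p_null)
    ll_alt = _binom_ll(alt0, depth0, p0) + _binom_ll(alt1, depth1, p1)
    stat = max(2.0 * (ll_alt - ll_null), 0.0)
    return float(stat), float(stats.chi2.sf(stat, 1))


@dataclass
class ScanResult:
    """Genome scan output: per-SNP and per-block statistics."""

    snp: pd.DataFrame  # stat, p, p_adj, significant
    block: pd.DataFrame  # block_id, min_p, p_adj, significant
    lambda_gc: float
    correction: str


def scan_genome(
    alt0: np.ndarray,
    depth0: np.ndarray,
    alt1: np.ndarray,
    depth1: np.ndarray,
    partition: LDBlockPartition | None = None,
    correction: str = "bonferroni",
    alpha: float = 0.05,
) -> ScanResult:
    """Per-SNP parallel-selection LRT across the genome.

    Inputs are (replicates x SNPs) alt counts and depths at the two
    timepoints.  Per-block summaries use the minimum SNP p with a
    within-block Bonferroni factor.  The genomic inflation factor
    lambda_GC (median statistic / chi-square(1) median) is reported as a
    calibration diagnostic.
    """
    from statsmodels.stats.multitest import multipletests

    if correction not in ("bonferroni", "bh"):
        raise ValueError("correction must be 'bonferroni' or 'bh'")
    alt0 = np.atleast_2d(alt0)
    depth0 = np.atleast_2d(depth0)
    alt1 = np.atleast_2d(alt1)
    depth1 = np.atleast_2d(depth1)
    S = alt0.shape[1]
    stat = np.empty(S)
    p = np.empty(S)
    for s in range(S):
        stat[s], p[s] = lrt_parallel_selection(
            alt0[:, s], depth0[:, s], alt1[:, s], depth1[:, s]
        )
    ok = np.isfinite(p)
    p_adj = np.full(S, np.nan)
    if ok.any():
        if correction == "bonferroni":
            p_adj[ok] = np.minimum(p[ok] * ok.sum(), 1.0)
        else:
            p_adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    lam = float(np.nanmedian(stat) / _CHI2_1_MEDIAN) if ok.any() else np.nan
    snp_df = pd.DataFrame(
        {"stat": stat, "p": p, "p_adj": p_adj, "significant": p_adj < alpha}
    )

    block_df = pd.DataFrame()
    if partition is not None:
        rows = []
        for _, b in partition.blocks.iterrows():
            lo, hi = int(b.start_idx), int(b.end_idx)
            pb = p[lo:hi]
            pb = pb[np.isfinite(pb)]
            if len(pb) == 0:
                rows.append({"block_id": int(b.block_id), "min_p": np.nan,
                             "p_block": np.nan})
                continue
            rows.append({
                "block_id": int(b.block_id),
                "min_p": float(pb.min()),
                "p_block": float(min(pb.min() * len(pb), 1.0)),
            })
        block_df = pd.DataFrame(rows)
        ok_b = np.isfinite(block_df.p_block)
        adj = np.full(len(block_df), np.nan)
        if ok_b.any():
            pv = block_df.p_block[ok_b].to_numpy()
            if correction == "bonferroni":
                adj[ok_b.to_numpy()] = np.minimum(pv * ok_b.sum(), 1.0)
            else:
                adj[ok_b.to_numpy()] = multipletests(pv, method="fdr_bh")[1]
        block_df["p_adj"] = adj
        block_df["significant"] = block_df.p_adj < alpha

    return ScanResult(snp=snp_df, block=block_df, lambda_gc=lam, correction=correction)


def block_overlap_permutation(
    significant_sets: list[np.ndarray],
    n_blocks: int,
    k_gardens: int,
    n_perm: int = 10000,
    seed: int | None = None,
) -> tuple[int, float]:
    """Cross-garden overlap of significant blocks vs a uniform resampling null.

    ``significant_sets`` holds each garden's significant block ids over a
    common universe of ``n_blocks`` blocks.  Observed statistic: number of
    blocks significant in >= ``k_gardens`` gardens.  Null: each garden's set
    is redrawn uniformly without replacement, preserving its size.  The
    permutation p has lower bound 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = [len(np.unique(s)) for s in significant_sets]
    hits = np.zeros(n_blocks, dtype=int)
    for s in significant_sets:
        hits[np.unique(np.asarray(s, int))] += 1
    observed = int((hits >= k_gardens).sum())

    exceed = 0
    counts = np.zeros(n_blocks, dtype=np.int32)
    for _ in range(n_perm):
        counts[:] = 0
        for size in sizes:
            if size:
                counts[rng.choice(n_blocks, size=size, replace=False)] += 1
        if int((counts >= k_gardens).sum()) >= observed:
            exceed += 1
    pval = (1 + exceed) / (n_perm + 1)
    return observed, float(pval)
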