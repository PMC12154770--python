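"""Founder panel: genotypes, climates of origin and the starting seed mix.

The panel describes a set of inbred (near-fully homozygous) founder
accessions of a selfing annual plant.  Each accession carries one genome-wide
haplotype, coded as an allele dosage in {0, 1} per biallelic SNP (0.5 marks
residual heterozygosity, NaN missing calls), plus a climate-of-origin vector
and its frequency in the founder seed mix.

The synthetic generator builds panels with block-wise allele sharing (so
linkage-disequilibrium blocks exist) and a genotype-correlated climate of
origin, emulating the structure of a real regional diversity panel without
requiring any sequence download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FounderPanel", "generate_founder_panel"]


@dataclass
class FounderPanel:
    """Accession x SNP genotype panel with climates of origin.

    Parameters
    ----------
    accession_ids : list of str
        Labels of the founder accessions.
    genotypes : ndarray, shape (n_accessions, n_snps)
        Allele dosage in {0, 1} (0.5 = residual heterozygote, NaN = missing).
    snp_chrom : ndarray of str, shape (n_snps,)
        Chromosome label per SNP.
    snp_pos : ndarray of int, shape (n_snps,)
        1-based position, strictly increasing within each chromosome.
    z_origin : DataFrame, shape (n_accessions, n_climate_vars)
        Climate at each accession's geographic origin (e.g. deg C, mm).
    start_freq : ndarray, shape (n_accessions,)
        Founder seed-mix frequency per accession (a simplex).
    """

    accession_ids: list[str]
    genotypes: np.ndarray
    snp_chrom: np.ndarray
    snp_pos: np.ndarray
    z_origin: pd.DataFrame
    start_freq: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.snp_chrom = np.asarray(self.snp_chrom)
        self.snp_pos = np.asarray(self.snp_pos, dtype=int)
        self.start_freq = np.asarray(self.start_freq, dtype=float)
        self.validate()

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def climate_vars(self) -> list[str]:
        return list(self.z_origin.columns)

    def validate(self) -> None:
        n_acc, n_snps = self.genotypes.shape
        if n_acc != len(self.accession_ids):
            raise ValueError("genotypes rows must match accession_ids")
        if len(self.snp_chrom) != n_snps or len(self.snp_pos) != n_snps:
            raise ValueError("snp_chrom/snp_pos must match genotype columns")
        vals = self.genotypes[~np.isnan(self.genotypes)]
        if vals.size and not np.all(np.isin(vals, (0.0, 0.5, 1.0))):
            raise ValueError("genotype dosages must be in {0, 0.5, 1} or NaN")
        if np.any(self.start_freq < 0) or abs(self.start_freq.sum() - 1.0) > 1e-9:
            raise ValueError("start_freq must be a simplex (>=0, sum 1)")
        if len(self.z_origin) != n_acc:
            raise ValueError("z_origin rows must match accessions")
        for chrom in pd.unique(self.snp_chrom):
            pos = self.snp_pos[self.snp_chrom == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    def imputed_genotypes(self) -> np.ndarray:
        """Genotypes with missing calls mean-imputed per SNP.

        Used for deconvolution and allele-frequency projection only; the
        stored panel keeps its missing values.
        """
        geno = self.genotypes.copy()
        col_mean = np.nanmean(np.where(np.isnan(geno), np.nan, geno), axis=0)
        col_mean = np.nan_to_num(col_mean, nan=0.5)
        idx = np.where(np.isnan(geno))
        geno[idx] = col_mean[idx[1]]
        return geno

    def allele_freqs(self, acc_freq: np.ndarray | None = None) -> np.ndarray:
        """Population allele frequencies implied by accession frequencies.

        Defaults to the founder seed mix (``start_freq``).
        """
        f = self.start_freq if acc_freq is None else np.asarray(acc_freq, float)
        return f @ self.imputed_genotypes()


def generate_founder_panel(
    n_accessions: int = 231,
    n_snps: int = 5000,
    n_chroms: int = 5,
    climate_span: dict[str, tuple[float, float]] | None = None,
    ld_decay: float = 20.0,
    n_ancestors: int = 8,
    mutation_rate: float = 0.02,
    climate_noise: float = 0.1,
    mix_concentration: float = 5000.0,
    seed: int | None = None,
) -> FounderPanel:
    """Generate a synthetic founder panel with LD structure and climate clines.

    Parameters
    ----------
    n_accessions, n_snps, n_chroms : int
        Panel dimensions.  Defaults mirror a 231-accession founder set.
    climate_span : dict of variable -> (low, high)
        Range of each climate-of-origin variable; default a single annual
        mean temperature analogue ``bio1`` spanning 4-18 deg C.
    ld_decay : float
        Ancestry-switch scale in SNP-index units.  Larger values give longer
        stretches of shared ancestry, hence stronger/longer LD blocks;
        0 gives mutually independent SNPs.
    n_ancestors : int
        Number of ancestral haplotypes in the mosaic; controls how much
        allele sharing (population structure) the panel carries.
    mutation_rate : float
        Per-SNP probability of flipping the copied ancestral allele.
    climate_noise : float
        Residual (non-genetic) fraction of climate-of-origin variance.
    mix_concentration : float
        Total Dirichlet concentration of the seed-mix jitter around the even
        mix; 5000 gives ~0.1%-scale deviations from 1/n_accessions.
    seed : int
        Seed for reproducibility; identical seeds give identical panels.

    Returns
    -------
    FounderPanel

    Notes
    -----
    The climate of origin is constructed from the accession's genome-wide
    ancestry composition (each ancestral haplotype is assigned a climate
    score), plus ``climate_noise`` residual scatter, then scaled linearly to
    ``climate_span``.  This makes climate of origin heritable in the panel:
    SNPs differentiating ancestors form clines with origin climate, which is
    the substrate both local-adaptation simulation and climate-association
    scans require.
    """
    if n_accessions < 2:
        raise ValueError("n_accessions must be >= 2")
    if n_snps < n_chroms or n_snps < 1 or n_chroms < 1:
        raise ValueError("need n_snps >= n_chroms >= 1")
    if climate_span is None:
        climate_span = {"bio1": (4.0, 18.0)}

    rng = np.random.default_rng(seed)

    # SNP map: chromosomes of ~equal size, strictly increasing positions
    sizes = np.full(n_chroms, n_snps // n_chroms)
    sizes[: n_snps % n_chroms] += 1
    chrom_of = np.repeat([f"chr{i + 1}" for i in range(n_chroms)], sizes)
    pos = np.concatenate([np.cumsum(rng.integers(50, 5000, size=s)) for s in sizes])

    anc_freq = rng.uniform(0.1, 0.9, size=n_snps)
    ancestors = (rng.random((n_ancestors, n_snps)) < anc_freq).astype(float)
    switch = 1.0 if ld_decay <= 0 else float(-np.expm1(-1.0 / ld_decay))
    new_chrom = np.ones(n_snps, dtype=bool)
    new_chrom[1:] = chrom_of[1:] != chrom_of[:-1]

    geno = np.empty((n_accessions, n_snps))
    anc_dosage = np.empty((n_accessions, n_ancestors))
    for a in range(n_accessions):
        switches = (rng.random(n_snps) < switch) | new_chrom
        picks = rng.integers(0, n_ancestors, size=int(switches.sum()))
        path = picks[np.cumsum(switches) - 1]
        row = ancestors[path, np.arange(n_snps)]
        flip = rng.random(n_snps) < mutation_rate
        geno[a] = np.where(flip, 1.0 - row, row)
        anc_dosage[a] = np.bincount(path, minlength=n_ancestors) / n_snps

    # climate of origin from ancestry composition + residual noise
    cols = {}
    for var, (lo, hi) in climate_span.items():
        scores = rng.normal(size=n_ancestors)
        raw = anc_dosage @ scores
        sd = raw.std() or 1.0
        raw = raw / sd + climate_noise * rng.normal(size=n_accessions)
        r0, r1 = raw.min(), raw.max()
        denom = (r1 - r0) or 1.0
        cols[var] = lo + (raw - r0) / denom * (hi - lo)
    z_origin = pd.DataFrame(cols, index=[f"acc{i:04d}" for i in range(n_accessions)])

    start = rng.dirichlet(np.full(n_accessions, mix_concentration / n_accessions))

    return FounderPanel(
        accession_ids=list(z_origin.index),
        genotypes=geno,
        snp_chrom=chrom_of,
        snp_pos=pos,
        z_origin=z_origin,
        start_freq=start,
    )
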