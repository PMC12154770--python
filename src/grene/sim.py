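"""Forward simulator of replicated multi-garden evolution experiments.

Populations of inbred selfing founder lineages reproduce in discrete
non-overlapping generations inside trays of fixed carrying capacity.  An
accession's expected fitness in a garden follows a Gaussian stabilizing
selection curve around its climate of origin,

    w_a = W_max,a * exp(-Vs_inv,a * (z_origin,a - z_garden)^2),

so lineages from climates matching the garden out-reproduce maladapted ones.
Reproduction is soft (density-regulated): every generation the offspring
pool is down-sampled without replacement to the carrying capacity, which
makes mean fitness an implicit normalizer.  Two offspring-number models are
available — "uniform" (minimum-variance seed set: each plant leaves
floor/ceil of its expected count) and "poisson" (overdispersed seed set).
Optional outcrossing creates one-crossover-per-chromosome recombinants;
everything else keeps lineages intact, which is what makes founder
deconvolution from pooled reads well-posed.

Observation is pool sequencing: flowers are drawn multinomially from the
tray, per-SNP read depth is Poisson, and read counts are binomial in the
pool allele frequency with a symmetric substitution error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import FounderPanel
from .poolfreq import PoolSample

__all__ = [
    "GardenDesign",
    "SimParams",
    "PopulationState",
    "TrueTrajectories",
    "accession_fitness",
    "simulate_generation",
    "simulate_experiment",
    "sample_poolseq",
]


@dataclass
class GardenDesign:
    """One experimental garden: its climate and replication scheme."""

    garden_id: str
    z_garden: dict[str, float]
    n_replicates: int = 12
    n_generations: int = 3
    census_schedule: list[int] | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.census_schedule is None:
            self.census_schedule = list(range(self.n_generations + 1))


@dataclass
class SimParams:
    """Generative parameters of the experiment.

    ``w_max`` and ``v_s_inv`` may be scalars (shared by all accessions) or
    per-accession arrays.  ``fecundity`` is the mean seed set per plant at
    average fitness; larger values make density regulation closer to
    hypergeometric sampling from an effectively infinite seed pool.
    """

    w_max: float | np.ndarray = 1.0
    v_s_inv: float | np.ndarray = 0.0
    carrying_capacity: int = 500
    offspring_model: str = "uniform"
    outcross_rate: float = 0.0
    fecundity: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.w_max) < 0):
            raise ValueError("w_max must be >= 0")
        if np.any(np.asarray(self.v_s_inv) < 0):
            raise ValueError("v_s_inv must be >= 0")
        if not 0.0 <= self.outcross_rate <= 1.0:
            raise ValueError("outcross_rate must be in [0, 1]")
        if self.offspring_model not in ("uniform", "poisson"):
            raise ValueError("offspring_model must be 'uniform' or 'poisson'")
        if self.carrying_capacity < 1:
            raise ValueError("carrying_capacity must be >= 1")


@dataclass
class PopulationState:
    """Individuals of one tray at one generation.

    ``accession`` records each individual's maternal founder lineage.
    ``genotypes`` is None while every individual is an exact founder copy;
    once outcrossing creates recombinants it holds explicit per-individual
    dosage rows.
    """

    generation: int
    accession: np.ndarray
    genotypes: np.ndarray | None = None
    extinct: bool = False

    @property
    def census_size(self) -> int:
        return int(self.accession.shape[0])

    def accession_freq(self, n_accessions: int) -> np.ndarray:
        if self.census_size == 0:
            return np.zeros(n_accessions)
        return np.bincount(self.accession, minlength=n_accessions) / self.census_size

    def allele_freq(self, panel: FounderPanel) -> np.ndarray:
        if self.census_size == 0:
            return np.full(panel.n_snps, np.nan)
        if self.genotypes is None:
            return self.accession_freq(panel.n_accessions) @ panel.imputed_genotypes()
        return self.genotypes.mean(axis=0)

    def materialize(self, panel: FounderPanel) -> np.ndarray:
        """Explicit per-individual genotype rows."""
        if self.genotypes is not None:
            return self.genotypes
        return panel.imputed_genotypes()[self.accession]


@dataclass
class TrueTrajectories:
    """Ground-truth record of a simulated experiment.

    Per garden, arrays are indexed (replicate, generation, ...); generation 0
    is the founding composition after establishment in the tray.
    """

    garden_ids: list[str]
    accession_ids: list[str]
    acc_freq: dict[str, np.ndarray]
    allele_freq: dict[str, np.ndarray]
    census: dict[str, np.ndarray]
    extinct: dict[str, np.ndarray]

    def garden_mean_acc_freq(self, garden_id: str, generation: int) -> np.ndarray:
        return self.acc_freq[garden_id][:, generation, :].mean(axis=0)


def accession_fitness(
    panel: FounderPanel,
    params: SimParams,
    z_garden: dict[str, float],
    climate_var: str = "bio1",
) -> np.ndarray:
    """Expected fitness of each accession in a garden.

    w_a = W_max,a * exp(-Vs_inv,a * (z_origin,a - z_garden)^2)
    """
    if climate_var not in panel.z_origin.columns:
        raise KeyError(f"climate variable {climate_var!r} missing from panel climates")
    if climate_var not in z_garden:
        raise KeyError(f"climate variable {climate_var!r} missing from garden climate")
    z0 = panel.z_origin[climate_var].to_numpy(float)
    dist2 = (z0 - float(z_garden[climate_var])) ** 2
    w_max = np.broadcast_to(np.asarray(params.w_max, float), z0.shape)
    v = np.broadcast_to(np.asarray(params.v_s_inv, float), z0.shape)
    return w_max * np.exp(-v * dist2)


def _offspring_counts(
    lam: np.ndarray, model: str, rng: np.random.Generator
) -> np.ndarray:
    if model == "poisson":
        return rng.poisson(lam)
    base = np.floor(lam).astype(np.int64)
    return base + (rng.random(lam.shape) < (lam - base))


def _recombine(
    mother: np.ndarray,
    father: np.ndarray,
    chrom_bounds: list[tuple[int, int]],
    rng: np.random.Generator,
) -> np.ndarray:
    """One crossover uniformly placed per chromosome; random leading parent."""
    child = np.empty_like(mother)
    for lo, hi in chrom_bounds:
        b = lo + int(rng.integers(0, hi - lo + 1))
        if rng.random() < 0.5:
            child[lo:b], child[b:hi] = mother[lo:b], father[b:hi]
        else:
            child[lo:b], child[b:hi] = father[lo:b], mother[b:hi]
    return child


def _chrom_bounds(panel: FounderPanel) -> list[tuple[int, int]]:
    bounds, start = [], 0
    chrom = panel.snp_chrom
    for i in range(1, len(chrom) + 1):
        if i == len(chrom) or chrom[i] != chrom[i - 1]:
            bounds.append((start, i))
            start = i
    return bounds


def simulate_generation(
    state: PopulationState,
    fitness: np.ndarray,
    params: SimParams,
    seed: int | np.random.Generator | None = None,
    panel: FounderPanel | None = None,
) -> PopulationState:
    """Advance one generation of reproduction, selection and regulation.

    Offspring counts are drawn per individual with mean
    fecundity * w / mean(w); selfed offspring copy the parent, outcrossed
    offspring (probability ``outcross_rate``) are one-crossover recombinants
    of two parents (``panel`` is then required to materialize genotypes).
    The offspring pool is down-sampled without replacement to the carrying
    capacity.  An all-zero fitness population returns an extinct state.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if state.census_size == 0:
        return PopulationState(state.generation + 1, np.empty(0, int), None, True)
    w = np.asarray(fitness, float)[state.accession]
    if not np.any(w > 0):
        return PopulationState(state.generation + 1, np.empty(0, int), None, True)
    lam = params.fecundity * w / w.mean()
    counts = _offspring_counts(lam, params.offspring_model, rng)
    total = int(counts.sum())
    if total == 0:
        return PopulationState(state.generation + 1, np.empty(0, int), None, True)

    parent_idx = np.repeat(np.arange(state.census_size), counts)
    # density regulation: sample survivors without replacement
    if total > params.carrying_capacity:
        keep = rng.choice(total, size=params.carrying_capacity, replace=False)
        parent_idx = parent_idx[keep]
    child_acc = state.accession[parent_idx]

    genotypes = None
    if params.outcross_rate > 0:
        if panel is None:
            raise ValueError("panel is required when outcross_rate > 0")
        geno_parents = state.materialize(panel)
        n_children = parent_idx.shape[0]
        outcrossed = rng.random(n_children) < params.outcross_rate
        genotypes = geno_parents[parent_idx].copy()
        if outcrossed.any():
            bounds = _chrom_bounds(panel)
            donors = rng.integers(0, state.census_size, size=int(outcrossed.sum()))
            for j, (ci, di) in enumerate(zip(np.where(outcrossed)[0], donors)):
                genotypes[ci] = _recombine(
                    geno_parents[parent_idx[ci]], geno_parents[di], bounds, rng
                )
    elif state.genotypes is not None:
        genotypes = state.genotypes[parent_idx].copy()

    return PopulationState(state.generation + 1, child_acc, genotypes, False)


def _establish(
    panel: FounderPanel, capacity: int, rng: np.random.Generator
) -> PopulationState:
    counts = rng.multinomial(capacity, panel.start_freq)
    return PopulationState(0, np.repeat(np.arange(panel.n_accessions), counts))


def simulate_experiment(
    panel: FounderPanel,
    gardens: list[GardenDesign],
    params: SimParams,
    seed: int | None = None,
    climate_var: str = "bio1",
    track_alleles: bool = True,
) -> TrueTrajectories:
    """Run the full design: every garden x replicate x generation.

    Replicates within a garden share the garden's fitness landscape and
    differ only in their random draws.  Generation 0 records the composition
    of the established tray (a multinomial draw of the seed mix at carrying
    capacity).
    """
    if not gardens:
        raise ValueError("at least one garden required")
    root = np.random.SeedSequence(seed)
    acc_freq, allele_freq, census, extinct = {}, {}, {}, {}
    n_acc, n_snps = panel.n_accessions, panel.n_snps

    for garden, ss in zip(gardens, root.spawn(len(gardens))):
        w = accession_fitness(panel, params, garden.z_garden, climate_var)
        T = garden.n_generations
        af = np.zeros((garden.n_replicates, T + 1, n_acc))
        pf = np.full((garden.n_replicates, T + 1, n_snps), np.nan)
        cz = np.zeros((garden.n_replicates, T + 1), dtype=int)
        ex = np.zeros(garden.n_replicates, dtype=bool)
        for r, rss in enumerate(ss.spawn(garden.n_replicates)):
            rng = np.random.default_rng(rss)
            state = _establish(panel, params.carrying_capacity, rng)
            for t in range(T + 1):
                af[r, t] = state.accession_freq(n_acc)
                if track_alleles:
                    pf[r, t] = state.allele_freq(panel)
                cz[r, t] = state.census_size
                if t < T:
                    state = simulate_generation(state, w, params, rng, panel)
            ex[r] = state.extinct or state.census_size == 0
        gid = garden.garden_id
        acc_freq[gid], allele_freq[gid], census[gid], extinct[gid] = af, pf, cz, ex

    return TrueTrajectories(
        garden_ids=[g.garden_id for g in gardens],
        accession_ids=list(panel.accession_ids),
        acc_freq=acc_freq,
        allele_freq=allele_freq,
        census=census,
        extinct=extinct,
    )


def sample_poolseq(
    population: PopulationState | np.ndarray,
    panel: FounderPanel,
    n_flowers: int = 100,
    mean_depth: float = 10.0,
    seq_error: float = 0.007,
    seed: int | np.random.Generator | None = None,
    sample_id: str = "sample",
    **metadata,
) -> PoolSample:
    """Pool-sequence a tray: flowers -> Poisson depth -> binomial read counts.

    ``population`` is either a :class:`PopulationState` (flowers drawn
    multinomially over its individuals) or a true accession-frequency vector
    (flowers drawn multinomially over accessions).  ``seq_error`` is a
    symmetric ref<->alt substitution rate.
    """
    if n_flowers < 1:
        raise ValueError("n_flowers must be >= 1")
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if isinstance(population, PopulationState):
        if population.census_size == 0:
            raise ValueError("no reproductive individuals to sample")
        counts = rng.multinomial(n_flowers, np.full(population.census_size, 1.0 / population.census_size))
        geno = population.materialize(panel)
        pool_p = (counts / n_flowers) @ geno
    else:
        f = np.asarray(population, float)
        if f.sum() <= 0:
            raise ValueError("no reproductive individuals to sample")
        counts = rng.multinomial(n_flowers, f / f.sum())
        pool_p = (counts / n_flowers) @ panel.imputed_genotypes()

    depth = rng.poisson(mean_depth, size=panel.n_snps)
    p_obs = pool_p * (1 - seq_error) + (1 - pool_p) * seq_error
    alt = rng.binomial(depth, np.clip(p_obs, 0.0, 1.0))
    return PoolSample(
        sample_id=sample_id,
        ref_count=depth - alt,
        alt_count=alt,
        flowers=int(n_flowers),
        **metadata,
    )
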