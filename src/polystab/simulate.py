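"""Diploid Wright-Fisher forward simulator with Gaussian stabilizing selection.

The population is monoecious, of constant size N, and reproduces by soft
selection: each of the N offspring draws two parents independently,
fitness-proportionally, with replacement (so selfing occurs at rate ~1/N).
Each parent transmits one recombinant gamete, formed by walking the loci in
map order, starting from a fair-coin template haplotype and switching
template between adjacent loci with probability equal to their Haldane
recombination fraction (1/2 across chromosome boundaries, so chromosomes
assort independently).  There is no mutation and no interference.

State is a 2N x L binary haplotype matrix (1 = trait-increasing allele);
individual i owns rows 2i and 2i+1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import numpy.typing as npt

from .maps import LinkageMap
from .model import SelectionRegime, TraitArchitecture

__all__ = [
    "HaplotypePopulation",
    "SimConfig",
    "ReplicateSummary",
    "initialize_population",
    "trait_values",
    "fitness",
    "sample_gametes",
    "reproduce",
    "run_simulation",
    "run_replicates",
]


@dataclass
class HaplotypePopulation:
    """2N x L binary haplotype state plus its map and architecture."""

    haplotypes: npt.NDArray[np.uint8]
    arch: TraitArchitecture
    map: LinkageMap
    generation: int = 0

    def __post_init__(self) -> None:
        H = np.asarray(self.haplotypes)
        if H.ndim != 2 or H.shape[0] % 2:
            raise ValueError("haplotypes must be a 2N x L matrix")
        if H.shape[1] != self.arch.locus_count or H.shape[1] != self.map.locus_count:
            raise ValueError("haplotype, architecture and map locus counts must agree")
        self.haplotypes = H.astype(np.uint8, copy=False)

    @property
    def N(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def locus_count(self) -> int:
        return self.haplotypes.shape[1]

    def allele_freqs(self) -> npt.NDArray[np.float64]:
        """Per-locus frequency of the trait-increasing allele."""
        return self.haplotypes.mean(axis=0)

    def genotypes(self) -> npt.NDArray[np.int8]:
        """Per-individual genotypes g_l in {-1, 0, +1}."""
        H = self.haplotypes
        return (H[0::2].astype(np.int8) + H[1::2].astype(np.int8)) - 1

    def genic_variance(self) -> float:
        p = self.allele_freqs()
        return float(np.sum(2.0 * p * (1.0 - p) * self.arch.effect_sizes**2))

    def genetic_variance(self) -> float:
        """Realized Var(G) across individuals (includes all LD)."""
        return float(np.var(self.genetic_values()))

    def genetic_values(self) -> npt.NDArray[np.float64]:
        return self.genotypes() @ self.arch.effect_sizes

    def pairwise_D(self) -> npt.NDArray[np.float64]:
        """Realized cis (gametic-phase) LD matrix between trait-increasing
        alleles, measured on the 2N haplotypes."""
        H = self.haplotypes.astype(float)
        p = H.mean(axis=0)
        return (H.T @ H) / H.shape[0] - np.outer(p, p)


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.  ``optimum_policy`` fixes the optimum at zero or
    recenters it to the architecture's initial expected mean trait value
    (needed when the architecture is not symmetric)."""

    N: int
    generations: int
    replicates: int = 1
    seed: int = 0
    V_S: float = 1.0
    V_E: float = 0.0
    optimum_policy: Literal["fixed-zero", "recenter-to-initial-mean"] = "fixed-zero"

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")
        if self.V_S <= 0.0:
            raise ValueError("V_S must be positive")

    def regime(self, arch: TraitArchitecture) -> SelectionRegime:
        opt = (
            arch.mean_genetic_value
            if self.optimum_policy == "recenter-to-initial-mean"
            else 0.0
        )
        return SelectionRegime(V_S=self.V_S, V_E=self.V_E, optimum=opt)


def initialize_population(
    arch: TraitArchitecture, linkage_map: LinkageMap, N: int, rng: np.random.Generator
) -> HaplotypePopulation:
    """Draw 2N haplotypes with allele 1 at locus l independently with
    probability p_l — linkage equilibrium, zero expected LD."""
    H = (rng.random((2 * N, arch.locus_count)) < arch.freqs).astype(np.uint8)
    return HaplotypePopulation(H, arch, linkage_map)


def trait_values(
    pop: HaplotypePopulation, V_E: float = 0.0, rng: np.random.Generator | None = None
) -> npt.NDArray[np.float64]:
    """Per-individual trait values Y = sum_l alpha_l g_l, plus an independent
    N(0, V_E) environmental deviate when V_E > 0."""
    Y = pop.genetic_values()
    if V_E > 0.0:
        if rng is None:
            raise ValueError("an rng is required when V_E > 0")
        Y = Y + rng.normal(0.0, np.sqrt(V_E), size=Y.size)
    return Y


def fitness(pop_or_Y, regime: SelectionRegime) -> npt.NDArray[np.float64]:
    """Exact Gaussian relative fitness exp(-(Y - optimum)^2 / (2 V_S))."""
    Y = pop_or_Y.genetic_values() if isinstance(pop_or_Y, HaplotypePopulation) else np.asarray(pop_or_Y, float)
    return np.exp(-((Y - regime.optimum) ** 2) / (2.0 * regime.V_S))


def sample_gametes(
    haplotypes: npt.NDArray[np.uint8],
    parents: npt.NDArray[np.intp],
    switch_probs: npt.NDArray[np.float64],
    map_order: npt.NDArray[np.intp],
    rng: np.random.Generator,
) -> npt.NDArray[np.uint8]:
    """Form one recombinant gamete per entry of ``parents``.

    ``switch_probs`` are the template-switch probabilities between consecutive
    loci *in map order* (``map_order`` indexes columns into map order).  The
    template for the first locus is a fair coin; a cumulative XOR of interval
    switch indicators then selects the template at every locus.  A switch
    probability of 1/2 at chromosome boundaries makes chromosomes assort
    independently.
    """
    n = parents.size
    L = haplotypes.shape[1]
    switches = np.empty((n, L), dtype=bool)
    switches[:, 0] = rng.random(n) < 0.5
    switches[:, 1:] = rng.random((n, L - 1)) < switch_probs
    template_in_map_order = np.logical_xor.accumulate(switches, axis=1)
    template = np.empty((n, L), dtype=bool)
    template[:, map_order] = template_in_map_order
    hapA = haplotypes[2 * parents]
    hapB = haplotypes[2 * parents + 1]
    return np.where(template, hapB, hapA)


def reproduce(
    pop: HaplotypePopulation,
    w: npt.NDArray[np.float64],
    rng: np.random.Generator,
    switch_probs: npt.NDArray[np.float64] | None = None,
    map_order: npt.NDArray[np.intp] | None = None,
) -> HaplotypePopulation:
    """One Wright-Fisher generation: draw 2N parents fitness-proportionally
    with replacement, one gamete from each."""
    total = w.sum()
    if not total > 0.0:
        raise RuntimeError("all fitnesses are zero: cannot sample parents")
    if switch_probs is None:
        switch_probs = pop.map.adjacent_r()
    if map_order is None:
        map_order = pop.map.order()
    N = pop.N
    parents = rng.choice(N, size=2 * N, p=w / total)
    gametes = sample_gametes(pop.haplotypes, parents, switch_probs, map_order, rng)
    # gametes alternate maternal/paternal: rows 2i, 2i+1 form offspring i
    return HaplotypePopulation(gametes, pop.arch, pop.map, pop.generation + 1)


def run_simulation(
    arch: TraitArchitecture,
    linkage_map: LinkageMap,
    regime: SelectionRegime,
    N: int,
    generations: int,
    rng: np.random.Generator,
    V_E: float = 0.0,
    record_sum_D: bool = False,
    neutral: bool = False,
):
    """One replicate.  Returns per-generation arrays (generation 0 = initial
    state, measured before selection): allele frequencies (T+1, L), genic
    variance, genetic variance, and optionally the summed pairwise cis LD."""
    pop = initialize_population(arch, linkage_map, N, rng)
    switch_probs = linkage_map.adjacent_r()
    map_order = linkage_map.order()
    T = generations
    L = arch.locus_count
    freqs = np.empty((T + 1, L))
    vg = np.empty(T + 1)
    vG = np.empty(T + 1)
    sum_D = np.empty(T + 1) if record_sum_D else None
    for t in range(T + 1):
        freqs[t] = pop.allele_freqs()
        vg[t] = pop.genic_variance()
        vG[t] = pop.genetic_variance()
        if record_sum_D:
            D = pop.pairwise_D()
            np.fill_diagonal(D, 0.0)
            sum_D[t] = D.sum()
        if t == T:
            break
        if neutral:
            w = np.ones(N)
        else:
            Y = trait_values(pop, V_E=V_E, rng=rng)
            w = fitness(Y, regime)
        pop = reproduce(pop, w, rng, switch_probs, map_order)
    return freqs, vg, vG, sum_D


@dataclass
class ReplicateSummary:
    """Replicate-averaged simulation output.

    ``mean_minor_freq``: per-generation mean (across loci, then replicates)
    frequency of the initially-minor allele, with its standard error across
    replicates.  Variance components are replicate means; ``d = V_g - V_G``.
    """

    mean_minor_freq: npt.NDArray[np.float64]
    se_minor_freq: npt.NDArray[np.float64]
    V_g: npt.NDArray[np.float64]
    V_G: npt.NDArray[np.float64]
    se_V_g: npt.NDArray[np.float64]
    se_V_G: npt.NDArray[np.float64]
    minor_freq_by_locus: npt.NDArray[np.float64]
    replicates: int
    sum_D: npt.NDArray[np.float64] | None = None
    per_replicate_minor: npt.NDArray[np.float64] | None = field(default=None, repr=False)

    @property
    def d(self) -> npt.NDArray[np.float64]:
        return self.V_g - self.V_G


def run_replicates(
    arch: TraitArchitecture,
    linkage_map: LinkageMap,
    regime: SelectionRegime,
    sim: SimConfig,
    record_sum_D: bool = False,
    neutral: bool = False,
) -> ReplicateSummary:
    """Run ``sim.replicates`` independent replicates (seed = base seed +
    replicate index) and average.  The initially-minor allele at each locus is
    fixed by the architecture (not the realized draw) and tracked throughout.
    """
    T = sim.generations
    L = arch.locus_count
    minor_mask = arch.freqs < 0.5
    reps = sim.replicates
    maf_mean = np.empty((reps, T + 1))
    maf_locus = np.zeros((T + 1, L))
    vg_all = np.empty((reps, T + 1))
    vG_all = np.empty((reps, T + 1))
    sD_all = np.empty((reps, T + 1)) if record_sum_D else None
    for rep in range(reps):
        rng = np.random.default_rng(sim.seed + rep)
        freqs, vg, vG, sD = run_simulation(
            arch, linkage_map, regime, sim.N, T, rng,
            V_E=sim.V_E, record_sum_D=record_sum_D, neutral=neutral,
        )
        minor = np.where(minor_mask[None, :], freqs, 1.0 - freqs)
        maf_mean[rep] = minor.mean(axis=1)
        maf_locus += minor
        vg_all[rep] = vg
        vG_all[rep] = vG
        if record_sum_D:
            sD_all[rep] = sD
    sqrt_reps = np.sqrt(reps)
    return ReplicateSummary(
        mean_minor_freq=maf_mean.mean(axis=0),
        se_minor_freq=maf_mean.std(axis=0, ddof=1) / sqrt_reps if reps > 1 else np.zeros(T + 1),
        V_g=vg_all.mean(axis=0),
        V_G=vG_all.mean(axis=0),
        se_V_g=vg_all.std(axis=0, ddof=1) / sqrt_reps if reps > 1 else np.zeros(T + 1),
        se_V_G=vG_all.std(axis=0, ddof=1) / sqrt_reps if reps > 1 else np.zeros(T + 1),
        minor_freq_by_locus=maf_locus / reps,
        replicates=reps,
        sum_D=sD_all.mean(axis=0) if record_sum_D else None,
        per_replicate_minor=maf_mean,
    )
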