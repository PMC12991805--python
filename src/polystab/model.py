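"""Domain types for an additive polygenic trait under Gaussian stabilizing selection.

The model: L autosomal biallelic loci; at locus ``l`` the trait-increasing
allele has frequency ``p_l`` and haploid effect ``+alpha_l/2`` (the
trait-decreasing allele ``-alpha_l/2``), so a homozygote swap changes the
trait by ``2*alpha_l``.  An individual's trait value is ``Y = G + E`` with
``G = sum_l alpha_l * g_l`` and genotype ``g_l`` coded -1/0/+1.  Relative
fitness is Gaussian about an optimum: ``phi(Y) = exp(-(Y-opt)^2 / (2 V_S))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

__all__ = [
    "TraitArchitecture",
    "SelectionRegime",
    "VarianceComponents",
    "LDSpec",
    "AssortParams",
    "Trajectory",
]


@dataclass(frozen=True)
class TraitArchitecture:
    """Per-locus effect sizes and trait-increasing-allele frequencies.

    Parameters
    ----------
    effect_sizes
        Diploid effect sizes ``alpha_l`` (trait units); the haploid allelic
        effect is ``±alpha_l/2``.
    freqs
        Frequencies ``p_l`` of the trait-increasing allele, strictly in (0, 1).
    """

    effect_sizes: npt.NDArray[np.float64]
    freqs: npt.NDArray[np.float64]

    def __post_init__(self) -> None:
        alpha = np.atleast_1d(np.asarray(self.effect_sizes, dtype=float))
        p = np.atleast_1d(np.asarray(self.freqs, dtype=float))
        if alpha.shape != p.shape or alpha.ndim != 1 or alpha.size < 1:
            raise ValueError("effect_sizes and freqs must be equal-length 1-D arrays")
        if not np.all(np.isfinite(alpha)):
            raise ValueError("effect sizes must be finite")
        if not (np.all(p > 0.0) and np.all(p < 1.0)):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
        object.__setattr__(self, "effect_sizes", alpha)
        object.__setattr__(self, "freqs", p)

    @property
    def locus_count(self) -> int:
        return self.freqs.size

    @property
    def genic_variance(self) -> float:
        """V_g = sum_l 2 p_l (1-p_l) alpha_l^2, the LD-free additive variance."""
        p = self.freqs
        return float(np.sum(2.0 * p * (1.0 - p) * self.effect_sizes**2))

    @property
    def mean_genetic_value(self) -> float:
        """Population mean of G, sum_l (2 p_l - 1) alpha_l."""
        return float(np.sum((2.0 * self.freqs - 1.0) * self.effect_sizes))

    @property
    def minor_mask(self) -> npt.NDArray[np.bool_]:
        """True where the trait-increasing allele is the minor allele."""
        return self.freqs < 0.5

    def minor_allele_freqs(self) -> npt.NDArray[np.float64]:
        return np.minimum(self.freqs, 1.0 - self.freqs)

    @classmethod
    def symmetric(cls, L: int, p_minor: float = 0.2, alpha: float = 1.0) -> "TraitArchitecture":
        """Fully symmetric architecture: equal effects, half the loci with the
        trait-increasing allele at ``p_minor`` and half at ``1 - p_minor``, so
        the mean genetic value is zero.  ``L`` must be even.
        """
        if L % 2:
            raise ValueError("symmetric architecture requires an even locus count")
        p = np.full(L, p_minor, dtype=float)
        p[L // 2:] = 1.0 - p_minor
        return cls(np.full(L, alpha, dtype=float), p)


@dataclass(frozen=True)
class SelectionRegime:
    """Gaussian stabilizing selection of width ``V_S`` around ``optimum``,
    plus environmental variance ``V_E`` added to the trait."""

    V_S: float
    V_E: float = 0.0
    optimum: float = 0.0

    def __post_init__(self) -> None:
        if not self.V_S > 0.0:
            raise ValueError("V_S must be positive")
        if self.V_E < 0.0:
            raise ValueError("V_E must be non-negative")


@dataclass(frozen=True)
class VarianceComponents:
    """One consistent record of the trait's variance decomposition.

    ``d`` is the (positive) reduction of the genetic variance below the genic
    variance caused by negative LD between like-effect alleles, so
    ``V_G = V_g - d``, ``V_P = V_G + V_E``, ``h2 = V_G / V_P`` and
    ``X = (V_S + V_E) / V_g``.
    """

    V_g: float
    V_G: float
    V_P: float
    V_E: float
    d: float
    h2: float
    X: float

    def __post_init__(self) -> None:
        if min(self.V_g, self.V_G, self.V_P, self.V_E) < 0.0:
            raise ValueError("variance components must be non-negative")
        if not (0.0 <= self.d <= self.V_g + 1e-12):
            raise ValueError("d must lie in [0, V_g]")
        if abs(self.V_G - (self.V_g - self.d)) > 1e-9 * max(1.0, self.V_g):
            raise ValueError("V_G must equal V_g - d")
        if abs(self.V_P - (self.V_G + self.V_E)) > 1e-9 * max(1.0, self.V_P):
            raise ValueError("V_P must equal V_G + V_E")

    @classmethod
    def at_quasi_equilibrium(
        cls, V_g: float, V_S: float, V_E: float = 0.0, rbar_h: float = 0.5
    ) -> "VarianceComponents":
        """Variance components after Bulmer LD has equilibrated, for a trait
        of genic variance ``V_g`` under selection width ``V_S`` on a map with
        harmonic-mean recombination rate ``rbar_h``."""
        # local import: predictors depends on this module
        from .predictors import d_over_Vg_equilibrium

        X = (V_S + V_E) / V_g
        d = d_over_Vg_equilibrium(X, rbar_h) * V_g
        V_G = V_g - d
        V_P = V_G + V_E
        return cls(V_g=V_g, V_G=V_G, V_P=V_P, V_E=V_E, d=d, h2=V_G / V_P, X=X)


@dataclass(frozen=True)
class LDSpec:
    """Symmetric matrix of gametic-phase (cis) LD coefficients ``D_ll'``
    between trait-increasing alleles; the diagonal is unused and must be 0."""

    pairwise_D: npt.NDArray[np.float64]

    def __post_init__(self) -> None:
        D = np.asarray(self.pairwise_D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("pairwise_D must be a square matrix")
        if not np.allclose(D, D.T):
            raise ValueError("pairwise_D must be symmetric")
        if np.any(np.diag(D) != 0.0):
            raise ValueError("diagonal of pairwise_D must be zero")
        object.__setattr__(self, "pairwise_D", D)

    def validate_bounds(self, arch: TraitArchitecture) -> None:
        """Check |D_ll'| against the frequency bounds implied by ``arch``."""
        p = arch.freqs
        q = 1.0 - p
        bound = np.minimum.reduce(
            [np.outer(p, p), np.outer(q, q), np.outer(p, q), np.outer(q, p)]
        )
        np.fill_diagonal(bound, np.inf)
        if np.any(np.abs(self.pairwise_D) > bound + 1e-12):
            raise ValueError("some |D_ll'| exceed the admissible haplotype-frequency bounds")

    def row_sums(self, arch: TraitArchitecture) -> npt.NDArray[np.float64]:
        """Per-locus effect-weighted LD sums S_l = sum_{l'!=l} D_ll' alpha_l'."""
        return self.pairwise_D @ arch.effect_sizes


@dataclass(frozen=True)
class AssortParams:
    """Assortative mating: phenotypic correlation ``rho`` among mates and the
    trait heritability ``h2`` entering the assortment algebra."""

    rho: float
    h2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must lie in [0, 1]")
        if self.h2 * self.rho >= 1.0:
            raise ValueError("h2 * rho must be < 1")

    @property
    def ld_prefactor(self) -> float:
        """h2*rho / (1 - h2*rho), the strength of assortment-generated LD."""
        x = self.h2 * self.rho
        return x / (1.0 - x)


@dataclass
class Trajectory:
    """Per-generation per-locus frequencies of the trait-increasing allele.

    ``freqs[t]`` is the length-L frequency vector at generation ``t``
    (generation 0 is the initial state), so ``freqs`` has shape
    ``(generations + 1, L)``.
    """

    freqs: npt.NDArray[np.float64]
    variance_by_generation: list[VarianceComponents] | None = None
    label: str = ""
    minor_mask: npt.NDArray[np.bool_] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 2:
            raise ValueError("freqs must have shape (generations + 1, L)")
        if np.any(f < -1e-12) or np.any(f > 1.0 + 1e-12):
            raise ValueError("frequencies must stay in [0, 1]")
        self.freqs = np.clip(f, 0.0, 1.0)

    @property
    def generations(self) -> int:
        return self.freqs.shape[0] - 1

    @property
    def locus_count(self) -> int:
        return self.freqs.shape[1]

    def minor_freqs(self) -> npt.NDArray[np.float64]:
        """Frequency of the initially-minor allele, per generation and locus."""
        mask = self.minor_mask
        if mask is None:
            mask = self.freqs[0] < 0.5
        return np.where(mask[None, :], self.freqs, 1.0 - self.freqs)

    def mean_minor_freq(self) -> npt.NDArray[np.float64]:
        """Across-locus mean frequency of the initially-minor allele."""
        return self.minor_freqs().mean(axis=1)
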