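"""Closed-form predictors of allele-frequency change under stabilizing selection.

Three nested levels of approximation are provided for the expected
per-generation change in the frequency of the trait-increasing allele at a
locus of effect size ``alpha`` and frequency ``p``:

* ``naive``       E[dp] = p(1-p)(p-1/2) alpha^2 / V_S
                  (ignores background phenotypic variance and LD);
* ``background``  E[dp] = p(1-p)(p-1/2) alpha^2 / (V_S + V_P)
                  (dilutes selection by the phenotypic variance);
* ``bulmer``      as ``background`` but with alpha replaced by an *effective*
                  effect size alpha_eff = alpha (1 - (d/V_g) rbar_h/rbar_h(l)),
                  accounting for the negative LD that stabilizing selection
                  builds between like-effect alleles (the Bulmer effect).

The Bulmer variance deficit ``d`` at quasi-equilibrium depends on the linkage
map only through the harmonic-mean recombination rate ``rbar_h``; its
apportionment to a particular locus depends on the locus-specific harmonic
mean ``rbar_h(l)``.  A non-equilibrium predictor tracks the build-up of
pairwise LD from linkage equilibrium via the recursion
``D <- K + (1 - r) D`` and feeds the resulting per-locus effective effect
sizes into the same frequency-change formula.

All background-variance-aware predictors share a single frozen phenotypic
variance, taken at its quasi-equilibrium value ``V_P = V_g(0) - d + V_E``:
the realized variance of a trait under selection already carries the Bulmer
deficit, and the LD correction enters the dynamics only through alpha_eff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import numpy.typing as npt

from .model import AssortParams, LDSpec, SelectionRegime, TraitArchitecture, Trajectory

__all__ = [
    "mean_trait_given_allele",
    "marginal_fitness_gaussian",
    "effective_selection_coefficient",
    "expected_delta_p",
    "d_over_Vg_equilibrium",
    "d_over_Vg_implicit",
    "expected_pairwise_D",
    "effective_effect_size",
    "assort_D_row_sum",
    "delta_genic_variance",
    "K_increment",
    "nonequilibrium_D",
    "MapSummary",
    "iterate_equilibrium_trajectory",
    "iterate_nonequilibrium_trajectory",
    "portability_variance_fraction",
]

PredictorMode = Literal["naive", "background", "bulmer"]


def mean_trait_given_allele(
    arch: TraitArchitecture, locus: int, ld: LDSpec | None = None
) -> tuple[float, float]:
    """Mean trait values experienced by the trait-increasing and
    trait-decreasing alleles at ``locus``, with the population mean at the
    optimum.

    Returns ``(E[Y | I_l = 1], E[Y | I_l = 0])`` where ``I_l`` indicates a
    trait-increasing allele on a random gamete.  LD with other causal loci
    shifts both conditional means by the effect-weighted LD sum
    ``S_l = sum_{l'!=l} D_ll' alpha_l'``:

        E[Y | I_l = 1] = (1 - p_l) (alpha_l + S_l / (p_l (1 - p_l)))
        E[Y | I_l = 0] =      -p_l (alpha_l + S_l / (p_l (1 - p_l)))
    """
    p = float(arch.freqs[locus])
    alpha = float(arch.effect_sizes[locus])
    S_l = 0.0
    if ld is not None:
        ld.validate_bounds(arch)
        S_l = float(ld.row_sums(arch)[locus])
    shifted = alpha + S_l / (p * (1.0 - p))
    return (1.0 - p) * shifted, -p * shifted


def marginal_fitness_gaussian(
    mu: float, V_P: float, V_S: float, quadratic: bool = False
) -> float:
    """Average relative fitness of the bearer of an allele whose carriers'
    trait values are Normal(mu, V_P) under Gaussian selection of width V_S.

    The background variance dilutes selection: the fitness is
    ``exp(-mu^2 / (2 (V_S + V_P)))``.  With ``quadratic=True`` the
    first-order Taylor expansion ``1 - mu^2 / (2 (V_S + V_P))`` is returned
    instead (the form used throughout the analytic derivations).
    """
    if V_S <= 0.0:
        raise ValueError("V_S must be positive")
    if V_P < 0.0:
        raise ValueError("V_P must be non-negative")
    z = mu**2 / (2.0 * (V_S + V_P))
    return 1.0 - z if quadratic else float(np.exp(-z))


def effective_selection_coefficient(p, alpha_eff, V_S: float, V_P: float = 0.0):
    """Effective selection coefficient of the trait-increasing allele,
    ``s_eff = (p - 1/2) alpha_eff^2 / (V_S + V_P)``.

    Negative when the trait-increasing allele is minor: stabilizing selection
    acts against the rarer allele.  Accepts scalars or arrays.
    """
    return (np.asarray(p) - 0.5) * np.asarray(alpha_eff) ** 2 / (V_S + V_P)


def expected_delta_p(p, alpha_eff, V_S: float, V_P: float = 0.0):
    """Expected one-generation change in trait-increasing allele frequency,
    ``E[dp] = p(1-p)(p - 1/2) alpha_eff^2 / (V_S + V_P)``.

    Passing the raw effect size with ``V_P=0`` gives the naive predictor;
    a nonzero ``V_P`` the background predictor; and an attenuated
    ``alpha_eff`` from :func:`effective_effect_size` the Bulmer predictor.
    """
    p = np.asarray(p)
    return p * (1.0 - p) * effective_selection_coefficient(p, alpha_eff, V_S, V_P)


def d_over_Vg_equilibrium(X: float, rbar_h: float = 0.5) -> float:
    """Quasi-equilibrium Bulmer variance deficit d/V_g.

    ``X = (V_S + V_E)/V_g`` measures the (inverse) strength of selection and
    ``rbar_h`` is the harmonic-mean recombination rate across causal locus
    pairs.  For unlinked loci (``rbar_h = 1/2``) this reduces to the classic
    ``(3 + X - sqrt(1 + 6X + X^2)) / 4``; tighter maps (smaller ``rbar_h``)
    retain more LD and give a larger deficit.
    """
    if X < 0.0:
        raise ValueError("X must be non-negative")
    if not (0.0 < rbar_h <= 0.5):
        raise ValueError("rbar_h must lie in (0, 1/2]")
    root = np.sqrt(1.0 + 2.0 * (1.0 + 1.0 / rbar_h) * X + X**2)
    return float((1.0 + rbar_h * ((1.0 + X) - root)) / (1.0 + 2.0 * rbar_h))


def d_over_Vg_implicit(h2: float, VS_over_VP: float, rbar_h: float = 0.5) -> float:
    """Quasi-equilibrium d/V_g expressed in observable quantities.

    Uses the trait's (quasi-equilibrium) heritability ``h2`` and the ratio
    ``V_S/V_P``, avoiding any estimate of the genic variance:
    ``d/V_g = h2 / (2 rbar_h (1 + V_S/V_P) + h2)``.
    """
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("h2 must lie in [0, 1]")
    if VS_over_VP <= 0.0:
        raise ValueError("VS_over_VP must be positive")
    if not (0.0 < rbar_h <= 0.5):
        raise ValueError("rbar_h must lie in (0, 1/2]")
    return h2 / (2.0 * rbar_h * (1.0 + VS_over_VP) + h2)


def expected_pairwise_D(
    d: float, alpha: float, L: int, rbar_h: float = 0.5, r_llprime: float = 0.5
):
    """Expected quasi-equilibrium LD between the trait-increasing alleles of
    one locus pair, ``E[D_ll'] = -d rbar_h / (2 alpha^2 L (L-1) r_ll')``.

    The total deficit is shared across pairs in proportion to ``1/r_ll'``:
    tightly linked pairs carry more of the negative LD.  The approximation
    degrades for very small ``r_ll'`` (the per-pair share would exceed the
    admissible range), which is the caller's concern, not an error.
    """
    if d < 0.0:
        raise ValueError("d must be non-negative")
    if L < 2:
        raise ValueError("at least two loci are required")
    r = np.asarray(r_llprime, dtype=float)
    if np.any(r <= 0.0) or np.any(r > 0.5):
        raise ValueError("recombination fractions must lie in (0, 1/2]")
    return -d * rbar_h / (2.0 * alpha**2 * L * (L - 1) * r)


def effective_effect_size(
    alpha,
    d_over_Vg: float,
    rbar_h_ratio=1.0,
    assort: AssortParams | None = None,
):
    """Effective effect size summarizing how long-range LD rescales a locus's
    contribution to its own frequency dynamics:

        alpha_eff = alpha (1 + h2 rho / (2 (1 - h2 rho))
                            - (d/V_g) * rbar_h / rbar_h(l))

    Stabilizing selection attenuates (negative LD); assortative mating, when
    present, amplifies (positive LD).  ``rbar_h_ratio`` is the per-locus
    linkage weighting ``rbar_h / rbar_h(l)`` (1 for unlinked loci).
    """
    if not (0.0 <= d_over_Vg <= 1.0):
        raise ValueError("d_over_Vg must lie in [0, 1]")
    ratio = np.asarray(rbar_h_ratio, dtype=float)
    if np.any(ratio <= 0.0):
        raise ValueError("rbar_h_ratio must be positive")
    assort_term = 0.0 if assort is None else assort.ld_prefactor / 2.0
    return np.asarray(alpha) * (1.0 + assort_term - d_over_Vg * ratio)


def assort_D_row_sum(
    p: float, alpha: float, L: int, assort: AssortParams
) -> float:
    """Expected per-locus LD row sum generated by assortative mating alone,
    for a symmetric architecture: ``h2 rho/(1 - h2 rho) * p(1-p)/2``
    (equivalently the same prefactor times ``V_g / (4 L alpha^2)``).

    Unlike selection-generated LD this does not depend on the linkage map.
    """
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie in (0, 1)")
    return assort.ld_prefactor * p * (1.0 - p) / 2.0


def delta_genic_variance(arch: TraitArchitecture, delta_p, Ne: float | None = None) -> float:
    """Expected one-generation change in the genic variance,
    ``sum_l 2 alpha_l^2 [(1 - 2 p_l) dp_l - dp_l^2 - p_l(1-p_l)/(2 Ne)]``.

    The first term is the systematic erosion by selection against minor
    alleles, the second a second-order correction, the last the loss of
    heterozygosity to drift (omitted when ``Ne`` is None).
    """
    dp = np.asarray(delta_p, dtype=float)
    p = arch.freqs
    terms = (1.0 - 2.0 * p) * dp - dp**2
    if Ne is not None:
        if Ne <= 0.0:
            raise ValueError("Ne must be positive")
        terms = terms - p * (1.0 - p) / (2.0 * Ne)
    return float(np.sum(2.0 * arch.effect_sizes**2 * terms))


def K_increment(d: float, alpha: float, L: int, rbar_h: float = 0.5) -> float:
    """Per-generation cis-LD increment K = -d rbar_h / (2 alpha^2 L (L-1))
    that stabilizing selection contributes to every locus pair."""
    if L < 2:
        raise ValueError("at least two loci are required")
    return -d * rbar_h / (2.0 * alpha**2 * L * (L - 1))


def nonequilibrium_D(t, r, K):
    """Expected pairwise LD t generations after the onset of selection,
    starting from linkage equilibrium: ``D(t) = (K/r)(1 - (1-r)^t)``.

    Closed form of the recursion ``D(t+1) = K + (1-r) D(t)``; converges at
    rate ``r`` to the quasi-equilibrium value ``K/r``.
    """
    t = np.asarray(t)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0.0) or np.any(r > 0.5):
        raise ValueError("recombination fractions must lie in (0, 1/2]")
    return (K / r) * (1.0 - (1.0 - r) ** t)


@dataclass(frozen=True)
class MapSummary:
    """Linkage-map summary sufficient for the equilibrium predictors: the
    global harmonic-mean recombination rate and, optionally, the per-locus
    harmonic means (None means all loci unlinked, every rbar_h(l) = 1/2)."""

    rbar_h: float = 0.5
    rbar_h_l: npt.NDArray[np.float64] | None = None

    def ratio(self, L: int) -> npt.NDArray[np.float64]:
        """Per-locus weighting rbar_h / rbar_h(l)."""
        if self.rbar_h_l is None:
            return np.full(L, self.rbar_h / 0.5)
        return self.rbar_h / np.asarray(self.rbar_h_l, dtype=float)


def _frozen_denominator(
    arch: TraitArchitecture, regime: SelectionRegime, mode: PredictorMode, d: float
) -> float:
    """V_S + V_P with the frozen quasi-equilibrium V_P (0 for naive mode)."""
    if mode == "naive":
        return regime.V_S
    V_P = arch.genic_variance - d + regime.V_E
    return regime.V_S + V_P


def iterate_equilibrium_trajectory(
    arch: TraitArchitecture,
    regime: SelectionRegime,
    map_summary: MapSummary | None = None,
    generations: int = 1,
    mode: PredictorMode = "bulmer",
    freeze: bool = True,
) -> Trajectory:
    """Iterate the expected per-locus frequency change for ``generations``
    generations under one of the three predictors.

    ``V_P`` and ``d/V_g`` are frozen at their generation-0 (quasi-equilibrium)
    values by default; ``freeze=False`` recomputes both from the current
    frequencies each generation, for exploration.  Frequencies are clamped to
    [0, 1]; a locus that reaches a boundary stays there.
    """
    if generations < 0:
        raise ValueError("generations must be non-negative")
    if map_summary is None:
        map_summary = MapSummary()
    L = arch.locus_count
    ratio = map_summary.ratio(L)

    def step_params(current: TraitArchitecture):
        # the QE variance deficit enters the shared V_P for both
        # background-aware modes, but attenuates alpha only in bulmer mode
        X = (regime.V_S + regime.V_E) / current.genic_variance
        dvg = d_over_Vg_equilibrium(X, map_summary.rbar_h)
        denom = _frozen_denominator(current, regime, mode, dvg * current.genic_variance)
        alpha_eff = effective_effect_size(
            current.effect_sizes, dvg if mode == "bulmer" else 0.0, ratio
        )
        return alpha_eff, denom

    alpha_eff, denom = step_params(arch)
    p = arch.freqs.copy()
    out = np.empty((generations + 1, L))
    out[0] = p
    for t in range(1, generations + 1):
        if not freeze:
            interior = (p > 0.0) & (p < 1.0)
            if interior.any():
                # recompute d/Vg and V_P from the surviving polymorphic loci
                cur = TraitArchitecture(arch.effect_sizes[interior], p[interior])
                X = (regime.V_S + regime.V_E) / cur.genic_variance
                dvg = d_over_Vg_equilibrium(X, map_summary.rbar_h)
                denom = _frozen_denominator(cur, regime, mode, dvg * cur.genic_variance)
                alpha_full = np.zeros(L)
                alpha_full[interior] = effective_effect_size(
                    arch.effect_sizes[interior],
                    dvg if mode == "bulmer" else 0.0,
                    ratio[interior],
                )
                alpha_eff = alpha_full
        dp = p * (1.0 - p) * (p - 0.5) * np.asarray(alpha_eff) ** 2 / denom
        p = np.clip(p + dp, 0.0, 1.0)
        out[t] = p
    return Trajectory(out, label=mode, minor_mask=arch.freqs < 0.5)


def iterate_nonequilibrium_trajectory(
    arch: TraitArchitecture,
    regime: SelectionRegime,
    linkage_map,
    generations: int,
) -> Trajectory:
    """Trajectory prediction that tracks the build-up of pairwise LD from
    linkage equilibrium instead of assuming it equilibrated instantly.

    Each generation the full pairwise LD matrix is advanced by
    ``D <- K + (1 - r) D`` (elementwise in the recombination-fraction matrix
    ``r``), per-locus effective effect sizes are formed as
    ``alpha_eff,l(t) = alpha (1 + sum_{l'} E[D_ll'(t)] / (p_l(t)(1-p_l(t))))``,
    and frequencies are stepped with the shared frozen ``V_S + V_P``
    denominator.  At t=0 (zero LD) the step equals the background predictor;
    as t grows it converges to the equilibrium Bulmer predictor.

    Requires (near-)equal effect sizes across loci, as the per-pair LD
    increment K is derived under that symmetry.
    """
    alpha_arr = arch.effect_sizes
    if not np.allclose(alpha_arr, alpha_arr[0]):
        raise ValueError("non-equilibrium predictor requires equal effect sizes")
    alpha = float(alpha_arr[0])
    L = arch.locus_count
    R = linkage_map.pairwise_r_matrix()
    rbar_h = linkage_map.rbar_h()

    Vg0 = arch.genic_variance
    X = (regime.V_S + regime.V_E) / Vg0
    dvg = d_over_Vg_equilibrium(X, rbar_h)
    d = dvg * Vg0
    K = K_increment(d, alpha, L, rbar_h)
    denom = regime.V_S + (Vg0 - d + regime.V_E)

    D = np.zeros((L, L))
    offdiag = ~np.eye(L, dtype=bool)
    p = arch.freqs.copy()
    out = np.empty((generations + 1, L))
    out[0] = p
    for t in range(1, generations + 1):
        interior = (p > 0.0) & (p < 1.0)
        sum_D = D.sum(axis=1)  # diagonal stays zero
        het = np.where(interior, p * (1.0 - p), np.nan)
        alpha_eff = alpha * (1.0 + np.where(interior, sum_D / het, 0.0))
        dp = np.where(
            interior, p * (1.0 - p) * (p - 0.5) * alpha_eff**2 / denom, 0.0
        )
        p = np.clip(p + dp, 0.0, 1.0)
        out[t] = p
        D[offdiag] = K + (1.0 - R[offdiag]) * D[offdiag]
    return Trajectory(out, label="nonequilibrium", minor_mask=arch.freqs < 0.5)


def portability_variance_fraction(
    F_ST: float, N: float, alpha_eff: float, V_S: float
) -> float:
    """Fraction of ancestral trait variance from standing polymorphisms of
    effect ``alpha_eff`` still segregating in a descendant population at
    divergence ``F_ST``: ``exp(-F_ST (1 + S/4))`` with
    ``S = 2 N alpha_eff^2 / V_S``.

    Passing an effective effect size from :func:`effective_effect_size`
    folds the Bulmer slowdown (or assortment speed-up) of allelic turnover
    into this polygenic-score portability calculation.
    """
    if F_ST < 0.0:
        raise ValueError("F_ST must be non-negative")
    if N <= 0.0 or V_S <= 0.0:
        raise ValueError("N and V_S must be positive")
    S = 2.0 * N * alpha_eff**2 / V_S
    return float(np.exp(-F_ST * (1.0 + S / 4.0)))
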