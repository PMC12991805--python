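# Methods

## Model and assumptions

An additive trait is controlled by `L` autosomal biallelic loci. The
trait-increasing allele at locus `l` has frequency `p_l` and haploid effect
`+α_l/2`; genotypes are coded `g_l ∈ {−1, 0, +1}` and the genetic value is
`G = Σ_l α_l g_l`. The trait `Y = G + E` is under Gaussian stabilizing
selection `φ(Y) = exp(−(Y−opt)²/2V_S)`; mating is random (assortative mating
enters only through a closed-form LD term, below); mutation is ignored, so
these are the dynamics of standing variants over hundreds of generations,
not a mutation–selection equilibrium. The population mean is assumed to sit
at the optimum — architectures that do not satisfy `Σ(2p_l−1)α_l = 0` must
recenter the optimum to the initial mean (the simulator's
`recenter-to-initial-mean` policy).

The analytic predictors use the quadratic expansion of the Gaussian fitness
(valid because `α² ≪ V_S + V_P` for a polygenic trait); the exact
exponential is available via `marginal_fitness_gaussian(..., quadratic=False)`
and is what the simulator uses. The predictors assume high polygenicity:
each locus contributes a vanishing share of the variance, so the trait
distribution among carriers of either allele is Normal with variance ≈ `V_P`.

## Predictors and the shared V_P convention

Three nested equilibrium predictors step `p_l` forward with
`Δp = p(1−p)(p−½)α_eff²/(V_S+V_P)`:

| mode | α_eff | V_P |
|---|---|---|
| `naive` | α | 0 |
| `background` | α | `V_g(0) − d + V_E` |
| `bulmer` | `α(1 − (d/V_g)·r̄h/r̄h(l))` | `V_g(0) − d + V_E` |

with `d` the quasi-equilibrium Bulmer deficit at generation 0. Two choices
here were genuinely open:

* **Which V_P to freeze.** The realized phenotypic variance of a trait under
  stabilizing selection already carries the LD deficit (`V_P = V_g − d + V_E`
  within a few tens of generations), so every background-variance-aware
  predictor uses that value and the LD correction enters *only* through
  `α_eff`. This also makes the three predictors mutually consistent: the
  non-equilibrium predictor (below) coincides with `background` exactly at
  t=0 (when LD is zero) and converges to `bulmer` as LD equilibrates, which
  would be impossible if the modes used different denominators.
* **Freezing over time.** `V_P` and `d/V_g` are held at their generation-0
  values during iteration (both decay only on the slow allele-frequency
  timescale, and freezing keeps predictions reproducible and interpretable);
  `freeze=False` recomputes both each generation from the current `V_g` for
  exploration.

Frequencies are clamped to [0, 1]; a locus at a boundary has `p(1−p) = 0`
and stays fixed — the predictors are not meant to be iterated to fixation.

Heterogeneous architectures apply the per-locus formula with locus-specific
`α_l, p_l` and the global `d/V_g`; this is a close approximation, not exact,
when effects vary.

The quasi-equilibrium deficit itself is available in two forms: explicit in
`X = (V_S+V_E)/V_g` and `r̄h` (`d_over_Vg_equilibrium`), and implicit in
observables `h²` and `V_S/V_P` (`d_over_Vg_implicit`); the two are verified
to be mutually consistent to 1e−8 relative in the test suite. At `r̄h = ½`
the explicit form reduces exactly to the classic unlinked result
`(3+X−√(1+6X+X²))/4`.

## Non-equilibrium LD predictor

Starting from linkage equilibrium, each generation of selection adds an
equal increment `K = −d·r̄h/(2α²L(L−1))` of cis LD to every pair, while
recombination destroys a fraction `r_ll'`:
`D_ll'(t+1) = K + (1−r_ll')D_ll'(t)`, giving the closed form
`D(t) = (K/r)(1−(1−r)^t)` with asymptote `K/r`. Per-locus effective effects
are rebuilt each generation as
`α_eff,l(t) = α(1 + Σ_{l'≠l} E[D_ll'(t)] / (p_l(t)(1−p_l(t))))`. The
increment `K` uses the generation-0 equilibrium `d` and requires equal
effect sizes (the symmetry under which the equal-apportionment argument
holds); the cis/trans split of the selection increment is not modeled
separately — the recursion above is used as stated. This predictor corrects
the equilibrium predictor's main bias: for tightly linked loci LD
equilibrates slowly, selection is less masked early on, and cumulative
frequency change is larger than the equilibrium formula predicts.

## Assortative mating

Phenotypic correlation `ρ` among mates with trait heritability `h²`
generates positive LD between like-effect alleles, independent of the map:
per-locus row sum `h²ρ/(1−h²ρ)·p(1−p)/2`. Combined with selection-generated
LD additively (a stated simplification, not a derived result), the effective
effect becomes `α(1 + h²ρ/(2(1−h²ρ)) − (d/V_g)·r̄h/r̄h(l))`: assortment
amplifies where the Bulmer term attenuates. For a height-like trait
(`h²=0.8, ρ=0.25, V_S/V_P=30, r̄h=0.464`) the assortment prefactor 0.25
dwarfs `2d/V_g ≈ 0.054`, so dynamics are *accelerated* despite the Bulmer
effect.

## Linkage maps

Pairwise recombination fractions are ½ across chromosomes and Haldane's
`r(d) = (1−e^{−2d})/2` of the Morgan distance within one (no interference;
no alternative map functions). Maps come from either a chromosome table
(id, bp length, cM length) with loci apportioned to chromosomes
proportionally to bp (largest-remainder rounding, ties by table order) and
spaced at genetic midpoints `(i−½)/k` of the chromosome length — midpoint
spacing avoids coincident loci, which would make the harmonic means
undefined — or a per-locus PLINK-like `.map` file. Sex-specific cM columns
are averaged before use; everything downstream, including the simulator,
operates on the sex-averaged map. Real-genome tables (e.g., human or
Drosophila maps) are optional user-supplied inputs; the packaged fixtures
are synthetic presets chosen to bracket the two LD regimes
(`high-recombination`: 20 chromosomes, 32 Morgans, r̄h ≈ 0.48;
`low-recombination`: 3 chromosomes, 0.9 Morgans, r̄h ≈ 0.10).

## Simulator

Diploid, monoecious, constant N, soft selection: each of N offspring draws
two parents independently, fitness-proportionally, with replacement (selfing
at rate ~1/N, negligible at simulated sizes). Gametes walk loci in map
order, starting each chromosome from a fair-coin template and switching
template between adjacent loci with probability equal to their Haldane
fraction; a switch probability of ½ at chromosome boundaries implements
independent assortment. Fitness uses the exact Gaussian on genetic values
(V_E = 0 by default: a fully heritable trait; nonzero V_E adds a Normal
deviate). Initial haplotypes are drawn independently per locus at the
architecture frequencies (linkage equilibrium). Replicate `i` uses seed
`base + i`, so any replicate is independently reproducible. Per generation
the simulator records allele frequencies, `V_g` from frequencies, `V_G` as
the variance of `G` across individuals, and `d = V_g − V_G` (which includes
cis and trans LD, matching the genic-vs-genetic comparison the predictors
target). `Ne` is taken equal to census `N` in drift terms.

## What the synthetic data does and does not emulate

The generator reproduces the study conditions: the fully symmetric design
(equal effects, minor alleles at 0.2, half trait-increasing-minor), the
heterogeneous design (minor-allele frequency ~ U[0.1,0.3], minor-allele
effect ~ N(0,1), optimum recentered per architecture), `V_S` set as a
multiple (default 5) of the initial genic variance, and linkage-equilibrium
initialization. It does not emulate mutation, demography, sex chromosomes,
crossover interference, pleiotropy, dominance/epistasis, or realistic
effect-size–frequency coupling — so passing tests validate the predictor
algebra and its regime of applicability, not the full complexity of real
trait architectures.

## Problem sizes and numerical choices

The standard comparison runs at N=1000, L=200, 50 replicates, 200
generations (V_S/V_g = 5), chosen so that across-locus and across-replicate
averaging leaves the drift-induced standard error of the mean minor-allele
frequency near 1e−3 — small enough to separate the three predictors
cleanly. The full-scale design (N=10⁴, L=10³, 10³ replicates, 500
generations) is reachable via `ExperimentSpec` overrides. Monte-Carlo
acceptance bands in tests are ±4 standard errors estimated from the data.
Binning by `r̄h(l)` uses half-open intervals; bins with fewer than 20 loci
are flagged unreliable and excluded from predictor ranking. Averages of the
Bulmer predictor across loci square the per-locus attenuation factor before
averaging. Trajectory comparisons require identical generation grids and
report RMSE and ±2 SE coverage.

## Known limitations

* The per-pair LD apportionment `∝ 1/r_ll'` breaks down for very small
  `r_ll'` (the implied |D| can exceed admissible bounds); the non-equilibrium
  predictor mitigates but does not remove this.
* The non-equilibrium predictor and the variance-trajectory prediction
  require equal effect sizes.
* Predictors treat loci as exchangeable given `(α_l, p_l, r̄h(l))`; realized
  per-locus trajectories in any one population deviate by drift.
* No inference: the package predicts dynamics given `(V_S, V_E, α, p)`;
  it does not estimate them from data.
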