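"""Scripted prediction-vs-simulation experiments at configurable scale.

Each experiment builds a trait architecture and linkage map, runs the
Wright-Fisher simulator for a number of replicates, evaluates the analytic
predictors on the same configuration, and reports comparison metrics
(per-generation coverage within +/-2 SE and RMSE).  Default scales are
desk-sized: N=1000, L=200, 50 replicates, 200 generations; the full-scale
study design (N=10^4, L=10^3, 10^3 replicates, 500 generations) is reachable
through the same overrides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt
import pandas as pd

from .maps import LinkageMap, place_loci, unlinked_map
from .model import SelectionRegime, TraitArchitecture, Trajectory
from .predictors import (
    d_over_Vg_equilibrium,
    delta_genic_variance,
    iterate_equilibrium_trajectory,
    iterate_nonequilibrium_trajectory,
    K_increment,
    nonequilibrium_D,
)
from .simulate import ReplicateSummary, SimConfig, run_replicates

__all__ = [
    "ExperimentSpec",
    "ExperimentResult",
    "BinSummary",
    "heterogeneous_architecture",
    "heterogeneous_expected_vg",
    "run_experiment",
    "compare_trajectories",
    "bin_by_rhl",
    "variance_trajectories",
]

KNOWN_EXPERIMENTS = (
    "symmetric_unlinked",
    "linked_high_recomb",
    "linked_low_recomb",
    "linkage_binned_maf",
    "timescales",
    "heterogeneous",
)


@dataclass(frozen=True)
class ExperimentSpec:
    """Named experiment plus scale overrides.

    ``vs_over_vg``: V_S is set to this multiple of the initial genic
    variance (the study design uses 5; 25 probes weak selection).
    ``map_source``: None uses the experiment's default (unlinked, or a
    fixture chromosome table for map experiments); otherwise a
    ChromosomeTable to place loci on.
    """

    name: str
    N: int = 1000
    L: int = 200
    replicates: int = 50
    generations: int = 200
    vs_over_vg: float = 5.0
    seed: int = 0
    p_minor: float = 0.2
    alpha: float = 1.0
    map_source: object | None = None
    predictors: tuple[str, ...] = ("naive", "background", "bulmer")

    def __post_init__(self) -> None:
        if self.name not in KNOWN_EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.name!r}; choose from {KNOWN_EXPERIMENTS}")
        if min(self.N, self.L, self.replicates, self.generations) <= 0:
            raise ValueError("scale overrides must be positive")


@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    arch: TraitArchitecture
    linkage_map: LinkageMap
    regime: SelectionRegime
    sim: ReplicateSummary
    predictions: dict[str, Trajectory]
    metrics: pd.DataFrame | None = None

    def tidy(self) -> pd.DataFrame:
        """Long-format table: generation, locus ('mean'), quantity, value,
        predictor tag."""
        rows = []
        gens = np.arange(self.sim.mean_minor_freq.size)
        for tag, values in [
            ("simulation", self.sim.mean_minor_freq),
            ("simulation_se", self.sim.se_minor_freq),
        ]:
            rows.append(pd.DataFrame(
                {"generation": gens, "locus": "mean", "quantity": "p_minor",
                 "value": values, "predictor": tag}
            ))
        rows.append(pd.DataFrame(
            {"generation": gens, "locus": "mean", "quantity": "Vg",
             "value": self.sim.V_g, "predictor": "simulation"}
        ))
        rows.append(pd.DataFrame(
            {"generation": gens, "locus": "mean", "quantity": "VG",
             "value": self.sim.V_G, "predictor": "simulation"}
        ))
        for tag, traj in self.predictions.items():
            rows.append(pd.DataFrame(
                {"generation": np.arange(traj.generations + 1), "locus": "mean",
                 "quantity": "p_minor", "value": traj.mean_minor_freq(),
                 "predictor": tag}
            ))
        return pd.concat(rows, ignore_index=True)


def heterogeneous_architecture(
    L: int,
    rng: np.random.Generator,
    maf_low: float = 0.1,
    maf_high: float = 0.3,
    alpha_sd: float = 1.0,
) -> TraitArchitecture:
    """Heterogeneous architecture: minor-allele frequencies drawn from
    Uniform[maf_low, maf_high] and minor-allele effects from Normal(0,
    alpha_sd^2), independently per locus.  Canonicalized so that stored
    frequencies refer to the trait-increasing allele (with effect |alpha|);
    the mean genetic value is generally nonzero, so the optimum should be
    recentered to it."""
    maf = rng.uniform(maf_low, maf_high, size=L)
    a = rng.normal(0.0, alpha_sd, size=L)
    # if the minor allele decreases the trait, the major allele is the
    # trait-increasing one
    p = np.where(a >= 0.0, maf, 1.0 - maf)
    return TraitArchitecture(np.abs(a), p)


def heterogeneous_expected_vg(
    L: int, maf_low: float = 0.1, maf_high: float = 0.3, alpha_sd: float = 1.0
) -> float:
    """Expected initial genic (= genetic, at linkage equilibrium) variance of
    the heterogeneous architecture: L * 2 E[p(1-p)] * E[alpha^2]."""
    mean_p = (maf_low + maf_high) / 2.0
    ep2 = mean_p**2 + (maf_high - maf_low) ** 2 / 12.0
    return L * 2.0 * (mean_p - ep2) * alpha_sd**2


def _build_inputs(spec: ExperimentSpec):
    rng = np.random.default_rng(spec.seed)
    if spec.name == "heterogeneous":
        arch = heterogeneous_architecture(spec.L, rng)
        optimum_policy = "recenter-to-initial-mean"
    else:
        arch = TraitArchitecture.symmetric(spec.L, spec.p_minor, spec.alpha)
        optimum_policy = "fixed-zero"
    if spec.map_source is not None:
        lmap = place_loci(spec.map_source, spec.L)
    elif spec.name in ("linked_high_recomb", "timescales"):
        from .io import FixtureMapSpec, make_fixture_chromosome_table

        lmap = place_loci(make_fixture_chromosome_table(
            FixtureMapSpec.preset("high-recombination")), spec.L)
    elif spec.name in ("linked_low_recomb", "linkage_binned_maf"):
        from .io import FixtureMapSpec, make_fixture_chromosome_table

        lmap = place_loci(make_fixture_chromosome_table(
            FixtureMapSpec.preset("low-recombination")), spec.L)
    else:
        lmap = unlinked_map(spec.L)
    V_S = spec.vs_over_vg * arch.genic_variance
    return arch, lmap, V_S, optimum_policy


def run_experiment(spec: ExperimentSpec) -> ExperimentResult:
    """Build the experiment's architecture and map, run the simulator and all
    requested predictors, and attach comparison metrics."""
    arch, lmap, V_S, optimum_policy = _build_inputs(spec)
    sim_cfg = SimConfig(
        N=spec.N, generations=spec.generations, replicates=spec.replicates,
        seed=spec.seed, V_S=V_S, optimum_policy=optimum_policy,
    )
    regime = sim_cfg.regime(arch)
    record_sum_D = spec.name == "timescales"
    summary = run_replicates(arch, lmap, regime, sim_cfg, record_sum_D=record_sum_D)
    map_summary = lmap.summary()
    predictions: dict[str, Trajectory] = {}
    for mode in spec.predictors:
        if mode == "nonequilibrium":
            predictions[mode] = iterate_nonequilibrium_trajectory(
                arch, regime, lmap, spec.generations
            )
        else:
            predictions[mode] = iterate_equilibrium_trajectory(
                arch, regime, map_summary, spec.generations, mode=mode
            )
    metrics = pd.DataFrame([
        {"predictor": tag,
         **compare_trajectories(summary.mean_minor_freq, summary.se_minor_freq,
                                traj.mean_minor_freq())}
        for tag, traj in predictions.items()
    ]).sort_values("rmse", ignore_index=True)
    return ExperimentResult(spec, arch, lmap, regime, summary, predictions, metrics)


def compare_trajectories(
    sim_mean: npt.NDArray[np.float64],
    sim_se: npt.NDArray[np.float64],
    pred: npt.NDArray[np.float64],
) -> dict[str, float]:
    """RMSE over generations, coverage fraction of generations with
    |sim - pred| <= 2 SE, and mean z-score."""
    sim_mean = np.asarray(sim_mean, float)
    pred = np.asarray(pred, float)
    if sim_mean.shape != pred.shape:
        raise ValueError("simulation and prediction must share the generation grid")
    resid = sim_mean - pred
    se = np.asarray(sim_se, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, np.abs(resid) / se, np.where(resid == 0, 0.0, np.inf))
    return {
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "coverage_2se": float(np.mean(z <= 2.0)),
        "mean_abs_z": float(np.mean(z[np.isfinite(z)])) if np.isfinite(z).any() else float("inf"),
    }


@dataclass
class BinSummary:
    """Loci binned by their locus-specific harmonic-mean recombination rate
    rbar_h(l), with per-bin mean simulated minor-allele frequency at a target
    generation and the matching predictions."""

    table: pd.DataFrame
    edges: npt.NDArray[np.float64]

    @property
    def counts(self) -> npt.NDArray[np.int64]:
        return self.table["n_loci"].to_numpy()


def bin_by_rhl(
    linkage_map: LinkageMap,
    maf_by_locus: npt.NDArray[np.float64],
    edges,
    predictions: dict[str, npt.NDArray[np.float64]] | None = None,
    min_loci: int = 20,
) -> BinSummary:
    """Assign each locus to the half-open bin [lo, hi) containing its
    rbar_h(l); loci outside every bin land in an 'overflow' row rather than
    being dropped.  Bins with fewer than ``min_loci`` loci are flagged
    (too noisy to rank predictors on)."""
    edges = np.asarray(edges, float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing with at least two values")
    rhl = linkage_map.rbar_h_per_locus()
    maf_by_locus = np.asarray(maf_by_locus, float)
    if maf_by_locus.size != rhl.size:
        raise ValueError("need one minor-allele frequency per locus")
    idx = np.digitize(rhl, edges, right=False) - 1
    in_range = (idx >= 0) & (rhl < edges[-1])
    rows = []
    for b in range(edges.size - 1):
        sel = in_range & (idx == b)
        row = {
            "bin_lo": edges[b], "bin_hi": edges[b + 1], "n_loci": int(sel.sum()),
            "mean_rhl": float(rhl[sel].mean()) if sel.any() else np.nan,
            "sim_maf": float(maf_by_locus[sel].mean()) if sel.any() else np.nan,
            "reliable": bool(sel.sum() >= min_loci),
        }
        if predictions:
            for tag, vals in predictions.items():
                row[f"pred_{tag}"] = float(np.asarray(vals)[sel].mean()) if sel.any() else np.nan
        rows.append(row)
    overflow = ~in_range
    if overflow.any():
        row = {
            "bin_lo": np.nan, "bin_hi": np.nan, "n_loci": int(overflow.sum()),
            "mean_rhl": float(rhl[overflow].mean()),
            "sim_maf": float(maf_by_locus[overflow].mean()),
            "reliable": bool(overflow.sum() >= min_loci),
        }
        if predictions:
            for tag, vals in predictions.items():
                row[f"pred_{tag}"] = float(np.asarray(vals)[overflow].mean())
        rows.append(row)
    return BinSummary(pd.DataFrame(rows), edges)


def variance_trajectories(
    arch: TraitArchitecture,
    regime: SelectionRegime,
    linkage_map: LinkageMap,
    trajectory: Trajectory,
    Ne: float,
) -> pd.DataFrame:
    """Predicted genic and genetic variance along a predictor's frequency
    trajectory: V_g(t) accumulates the per-generation genic-variance change
    (selection + drift terms), the LD deficit d(t) sums the non-equilibrium
    pairwise LD over locus pairs, and V_G(t) = V_g(t) - d(t)."""
    freqs = trajectory.freqs
    T = trajectory.generations
    alpha = arch.effect_sizes
    if not np.allclose(alpha, alpha[0]):
        raise ValueError("variance prediction requires equal effect sizes")
    a = float(alpha[0])
    L = arch.locus_count
    rbar_h = linkage_map.rbar_h()
    R = linkage_map.pairwise_r_matrix()
    off = ~np.eye(L, dtype=bool)
    Vg0 = arch.genic_variance
    dvg = d_over_Vg_equilibrium((regime.V_S + regime.V_E) / Vg0, rbar_h)
    K = K_increment(dvg * Vg0, a, L, rbar_h)

    vg_pred = np.empty(T + 1)
    vg_pred[0] = Vg0
    for t in range(T):
        cur = TraitArchitecture(alpha, np.clip(freqs[t], 1e-12, 1 - 1e-12))
        dp = freqs[t + 1] - freqs[t]
        vg_pred[t + 1] = vg_pred[t] + delta_genic_variance(cur, dp, Ne)
    t_grid = np.arange(T + 1)
    # -2 a^2 * sum of pairwise D(t) over ordered pairs = d(t)
    d_pred = np.array([
        -2.0 * a**2 * nonequilibrium_D(t, R[off], K).sum() for t in t_grid
    ])
    return pd.DataFrame({
        "generation": t_grid,
        "Vg_pred": vg_pred,
        "d_pred": d_pred,
        "VG_pred": vg_pred - d_pred,
    })
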