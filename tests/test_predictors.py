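import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import polystab as ps


def enumerate_conditional_mean(p1, p2, a1, a2, D):
    """Oracle for the two-locus conditional trait mean: enumerate the four
    haplotype frequencies consistent with (p1, p2, D), average the haploid
    genetic value given the focal allele, and subtract the population haploid
    mean (the population is centered on its optimum)."""
    f = {
        (1, 1): p1 * p2 + D,
        (1, 0): p1 * (1 - p2) - D,
        (0, 1): (1 - p1) * p2 - D,
        (0, 0): (1 - p1) * (1 - p2) + D,
    }
    assert all(v >= -1e-12 for v in f.values())
    value = lambda g: (a1 / 2 if g[0] else -a1 / 2) + (a2 / 2 if g[1] else -a2 / 2)
    pop_mean = sum(f[g] * value(g) for g in f)
    cond = sum(f[g] * value(g) for g in f if g[0] == 1) / p1
    return cond - pop_mean


class TestMeanTraitGivenAllele:
    def test_no_ld_recovers_simple_means(self):
        arch = ps.TraitArchitecture(np.array([1.0]), np.array([0.2]))
        assert ps.mean_trait_given_allele(arch, 0) == pytest.approx((0.8, -0.2))
        arch = ps.TraitArchitecture(np.array([2.0]), np.array([0.5]))
        up, down = ps.mean_trait_given_allele(arch, 0)
        assert (up, down) == pytest.approx((1.0, -1.0))
        assert up == -down  # symmetric about the optimum at p = 1/2

    def test_negative_ld_masks_the_allele(self):
        arch = ps.TraitArchitecture(np.ones(2), np.array([0.2, 0.2]))
        ld = ps.LDSpec(np.array([[0.0, -0.04], [-0.04, 0.0]]))
        up, down = ps.mean_trait_given_allele(arch, 0, ld)
        assert up == pytest.approx(0.6)
        assert up == pytest.approx(enumerate_conditional_mean(0.2, 0.2, 1, 1, -0.04))

    @given(
        p1=st.floats(0.05, 0.95), p2=st.floats(0.05, 0.95),
        a2=st.floats(-2.0, 2.0), frac=st.floats(-0.9, 0.9),
    )
    @settings(max_examples=100, derandomize=True)
    def test_matches_enumeration_oracle(self, p1, p2, a2, frac):
        # symmetric admissible bound (stricter than the one-sided bounds)
        bound = min(p1 * p2, (1 - p1) * (1 - p2), p1 * (1 - p2), (1 - p1) * p2)
        D = frac * bound
        arch = ps.TraitArchitecture(np.array([1.0, a2]), np.array([p1, p2]))
        ld = ps.LDSpec(np.array([[0.0, D], [D, 0.0]]))
        up, _ = ps.mean_trait_given_allele(arch, 0, ld)
        assert up == pytest.approx(enumerate_conditional_mean(p1, p2, 1.0, a2, D), abs=1e-10)


class TestMarginalFitness:
    def test_reference_points(self):
        assert ps.marginal_fitness_gaussian(0.0, 10.0, 1.0) == 1.0
        assert ps.marginal_fitness_gaussian(np.sqrt(2 * 50.0), 0.0, 50.0) == pytest.approx(np.exp(-1))
        w = ps.marginal_fitness_gaussian(1.0, 320.0, 1600.0)
        assert w == pytest.approx(np.exp(-1 / 3840))
        wq = ps.marginal_fitness_gaussian(1.0, 320.0, 1600.0, quadratic=True)
        assert wq == pytest.approx(1 - 1 / 3840)
        assert abs(w - wq) < 1e-7  # expansions agree for a polygenic locus


class TestExpectedDeltaP:
    def test_hand_evaluations(self):
        assert ps.expected_delta_p(0.2, 1.0, 1600.0, 0.0) == pytest.approx(-3.0e-5)
        assert ps.expected_delta_p(0.2, 1.0, 1600.0, 320.0) == pytest.approx(-2.5e-5)
        dvg = ps.d_over_Vg_equilibrium(5.0)
        a_eff = ps.effective_effect_size(1.0, dvg)
        dp = ps.expected_delta_p(0.2, a_eff, 1600.0, 320.0)
        assert dp == pytest.approx(-0.048 * (1 - dvg) ** 2 / 1920, rel=1e-9)
        assert abs(dp) < 2.5e-5 < 3.0e-5  # strictly smaller at each refinement

    def test_selection_coefficient_antisymmetry(self):
        s_minor = ps.effective_selection_coefficient(0.2, 1.0, 1600.0)
        s_major = ps.effective_selection_coefficient(0.8, 1.0, 1600.0)
        assert s_minor == pytest.approx(-0.3 / 1600)
        assert s_major == pytest.approx(-s_minor)
        assert ps.effective_selection_coefficient(0.5, 3.0, 100.0) == 0.0

    @given(p=st.floats(0.01, 0.99), vp=st.floats(0.0, 1000.0), dvg=st.floats(0.0, 1.0))
    @settings(max_examples=200, derandomize=True)
    def test_slowdown_ordering_and_fixed_point(self, p, vp, dvg):
        V_S = 100.0
        naive = ps.expected_delta_p(p, 1.0, V_S, 0.0)
        background = ps.expected_delta_p(p, 1.0, V_S, vp)
        bulmer = ps.expected_delta_p(p, ps.effective_effect_size(1.0, dvg), V_S, vp)
        assert abs(bulmer) <= abs(background) + 1e-18
        assert abs(background) <= abs(naive) + 1e-18
        # antisymmetry under p <-> 1-p, zero at p = 1/2
        assert ps.expected_delta_p(1 - p, 1.0, V_S, vp) == pytest.approx(-background, rel=1e-9)
        assert ps.expected_delta_p(0.5, 1.0, V_S, vp) == 0.0


class TestBulmerDeficit:
    def test_unlinked_reduction_identity(self):
        rng = np.random.default_rng(0)
        for X in rng.uniform(0.0, 100.0, size=1000):
            full = ps.d_over_Vg_equilibrium(X, 0.5)
            reduced = (3 + X - np.sqrt(1 + 6 * X + X**2)) / 4
            assert full == pytest.approx(reduced, rel=1e-12, abs=1e-15)

    def test_reference_values(self):
        assert ps.d_over_Vg_equilibrium(5.0, 0.5) == pytest.approx((8 - np.sqrt(56)) / 4)
        assert ps.d_over_Vg_equilibrium(5.0, 0.0744) == pytest.approx(0.4136, abs=5e-4)

    def test_weak_selection_limit(self):
        # d/Vg -> Vg/(VS+VE) = 1/X as X grows
        for X in (1e2, 1e4, 1e6):
            assert ps.d_over_Vg_equilibrium(X, 0.5) * X == pytest.approx(1.0, rel=20 / X)

    def test_oracle_bulmer_recursion(self):
        # independent oracle for the unlinked deficit: free recombination
        # halves the LD deficit each generation while Gaussian selection on a
        # fully heritable trait regenerates half of V_G^2/(V_G+V_S+V_E);
        # iterate d' = d/2 + (1/2) V_G^2/(V_G+V_S) to the fixed point
        X, Vg = 5.0, 320.0
        VS = X * Vg
        d = 0.0
        for _ in range(200):
            V = Vg - d
            d = 0.5 * d + 0.5 * V**2 / (V + VS)
        assert ps.d_over_Vg_equilibrium(X, 0.5) == pytest.approx(d / Vg, rel=1e-10)

    def test_implicit_form_height_example(self):
        dvg = ps.d_over_Vg_implicit(0.8, 30.0, 0.464)
        assert 2 * dvg == pytest.approx(0.054, abs=5e-4)
        assert ps.d_over_Vg_implicit(0.0, 30.0, 0.464) == 0.0

    @given(
        vg=st.floats(10.0, 1000.0),
        x=st.floats(0.1, 50.0),
        ve_frac=st.floats(0.0, 2.0),
        rbar=st.floats(0.01, 0.5),
    )
    @settings(max_examples=200, derandomize=True)
    def test_explicit_implicit_self_consistency(self, vg, x, ve_frac, rbar):
        # d from the explicit form, plugged into the implicit form through the
        # quasi-equilibrium V_G, V_P, h2, must return the same d/Vg
        ve = ve_frac * vg
        vs = x * vg - ve
        if vs <= 0:
            return
        dvg = ps.d_over_Vg_equilibrium(x, rbar)
        d = dvg * vg
        vG = vg - d
        vP = vG + ve
        assert ps.d_over_Vg_implicit(vG / vP, vs / vP, rbar) == pytest.approx(dvg, rel=1e-8)


class TestPairwiseLD:
    def test_total_and_row_sums(self):
        L, alpha, d = 40, 1.3, 2.7
        lmap = ps.place_loci(
            ps.make_fixture_chromosome_table(ps.FixtureMapSpec(3, 1.2, (1e6, 2e6, 3e6))), L
        )
        R = lmap.pairwise_r_matrix()
        off = ~np.eye(L, dtype=bool)
        rbar = lmap.rbar_h()
        D = ps.expected_pairwise_D(d, alpha, L, rbar, R[off])
        # ordered-pair total is exactly -d/(2 alpha^2)
        assert D.sum() == pytest.approx(-d / (2 * alpha**2), rel=1e-12)
        # per-locus row sums follow the rbar_h/rbar_h(l) apportionment
        Dm = np.zeros((L, L))
        Dm[off] = D
        row = Dm.sum(axis=1)
        expected = -d / (2 * alpha**2 * L) * rbar / lmap.rbar_h_per_locus()
        assert row == pytest.approx(expected, rel=1e-10)

    def test_unlinked_and_degenerate_cases(self):
        assert ps.expected_pairwise_D(0.0, 1.0, 10) == 0.0
        assert ps.expected_pairwise_D(2.0, 1.0, 10) == pytest.approx(-2.0 / (2 * 90))


class TestEffectiveEffectSize:
    def test_attenuation_and_amplification(self):
        assert ps.effective_effect_size(1.0, 0.0) == 1.0
        assert ps.effective_effect_size(1.0, 0.1291713) == pytest.approx(0.8708287)
        assort = ps.AssortParams(rho=0.25, h2=0.8)
        a_eff = ps.effective_effect_size(1.0, 0.02706, 1.0, assort)
        assert a_eff == pytest.approx(1.0 + 0.125 - 0.02706)
        assert a_eff > 1.0  # assortment outweighs the Bulmer attenuation

    def test_assort_row_sum(self):
        assort = ps.AssortParams(rho=0.25, h2=0.8)
        assert ps.assort_D_row_sum(0.2, 1.0, 100, assort) == pytest.approx(0.25 * 0.16 / 2)
        assert ps.assort_D_row_sum(0.2, 1.0, 100, ps.AssortParams(rho=0.0, h2=0.8)) == 0.0


class TestDeltaGenicVariance:
    def test_pure_drift_and_hand_value(self):
        arch = ps.TraitArchitecture(np.ones(3), np.array([0.2, 0.5, 0.7]))
        assert ps.delta_genic_variance(arch, np.zeros(3), Ne=50.0) == pytest.approx(
            -arch.genic_variance / 100.0
        )
        single = ps.TraitArchitecture(np.array([1.0]), np.array([0.2]))
        dv = ps.delta_genic_variance(single, np.array([-3e-5]), Ne=10_000.0)
        assert dv == pytest.approx(2 * (0.6 * -3e-5 - 9e-10 - 0.16 / 20_000))
        # without drift, selection against the minor allele erodes V_g
        assert ps.delta_genic_variance(single, np.array([-3e-5])) < 0.0


class TestNonequilibriumLD:
    @pytest.mark.parametrize("r", [1e-3, 0.01, 0.1, 0.5])
    def test_closed_form_equals_recursion(self, r):
        K = -0.37
        D = 0.0
        checkpoints = {0, 1, 2, 10, 100, 1000, 10_000}
        for t in range(10_001):
            if t in checkpoints:
                assert ps.nonequilibrium_D(t, r, K) == pytest.approx(D, abs=1e-10)
            D = K + (1 - r) * D

    def test_initial_and_asymptotic_values(self):
        K = ps.K_increment(2.0, 1.0, 50, 0.3)
        assert K == pytest.approx(-2.0 * 0.3 / (2 * 50 * 49))
        assert ps.nonequilibrium_D(0, 0.2, K) == 0.0
        assert ps.nonequilibrium_D(10_000, 0.2, K) == pytest.approx(K / 0.2)
        assert ps.nonequilibrium_D(2, 0.5, K) == pytest.approx(1.5 * K)


class TestTrajectoryIteration:
    def test_zero_generations_is_identity(self):
        arch = ps.TraitArchitecture.symmetric(10, 0.2)
        traj = ps.iterate_equilibrium_trajectory(
            arch, ps.SelectionRegime(V_S=100.0), generations=0
        )
        assert traj.freqs[0] == pytest.approx(arch.freqs)

    def test_naive_two_generation_hand_iteration(self):
        arch = ps.TraitArchitecture(np.array([1.0]), np.array([0.2]))
        traj = ps.iterate_equilibrium_trajectory(
            arch, ps.SelectionRegime(V_S=1600.0), generations=2, mode="naive"
        )
        p1 = 0.2 + 0.2 * 0.8 * (0.2 - 0.5) / 1600
        p2 = p1 + p1 * (1 - p1) * (p1 - 0.5) / 1600
        assert traj.freqs[:, 0] == pytest.approx([0.2, p1, p2], rel=1e-12)
        assert p1 == pytest.approx(0.19997)

    def test_mode_ordering_every_generation(self, symmetric_arch):
        arch = symmetric_arch
        regime = ps.SelectionRegime(V_S=5 * arch.genic_variance)
        trajs = {
            m: ps.iterate_equilibrium_trajectory(arch, regime, None, 100, mode=m)
            for m in ("naive", "background", "bulmer")
        }
        maf = {m: t.mean_minor_freq() for m, t in trajs.items()}
        assert np.all(maf["naive"][1:] < maf["background"][1:])
        assert np.all(maf["background"][1:] < maf["bulmer"][1:])

    def test_nonequilibrium_limits(self, symmetric_arch, low_recomb_map):
        arch, lmap = symmetric_arch, low_recomb_map
        regime = ps.SelectionRegime(V_S=5 * arch.genic_variance)
        noneq = ps.iterate_nonequilibrium_trajectory(arch, regime, lmap, 1)
        background = ps.iterate_equilibrium_trajectory(
            arch, regime, lmap.summary(), 1, mode="background"
        )
        # zero LD at the onset: first step identical to the background predictor
        assert noneq.freqs[1] == pytest.approx(background.freqs[1], abs=1e-16)


def test_portability_variance_fraction():
    assert ps.portability_variance_fraction(0.0, 1000, 1.0, 100.0) == 1.0
    assert ps.portability_variance_fraction(0.1, 1000, 0.0, 100.0) == pytest.approx(np.exp(-0.1))
    # S = 4 when 2 N alpha^2 / V_S = 4
    assert ps.portability_variance_fraction(0.1, 2000, 1.0, 1000.0) == pytest.approx(np.exp(-0.2))
    # the Bulmer-corrected effect size slows turnover (larger retained fraction)
    a_eff = ps.effective_effect_size(1.0, 0.3)
    assert ps.portability_variance_fraction(0.1, 2000, a_eff, 1000.0) > \
        ps.portability_variance_fraction(0.1, 2000, 1.0, 1000.0)
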