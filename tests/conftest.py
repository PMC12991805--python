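import pytest

import polystab as ps


@pytest.fixture(scope="session")
def symmetric_arch():
    """Desk-scale symmetric architecture: 200 loci, alpha=1, minor allele at
    0.2 (trait-increasing minor at half the loci, major at the other half)."""
    return ps.TraitArchitecture.symmetric(200, 0.2, 1.0)


@pytest.fixture(scope="session")
def low_recomb_map():
    """Fixture linkage map in the strong-LD regime (rbar_h ~ 0.1)."""
    table = ps.make_fixture_chromosome_table(
        ps.FixtureMapSpec.preset("low-recombination")
    )
    return ps.place_loci(table, 200)


@pytest.fixture(scope="session")
def symmetric_unlinked_desk(symmetric_arch):
    """Shared desk-scale replication of the fully symmetric unlinked design:
    N=1000, L=200, V_S/V_g=5, 50 replicates, 200 generations, plus the three
    equilibrium predictors evaluated on the same configuration."""
    arch = symmetric_arch
    lmap = ps.unlinked_map(arch.locus_count)
    cfg = ps.SimConfig(
        N=1000, generations=200, replicates=50, seed=1,
        V_S=5.0 * arch.genic_variance,
    )
    regime = cfg.regime(arch)
    summary = ps.run_replicates(arch, lmap, regime, cfg)
    ms = lmap.summary()
    predictions = {
        mode: ps.iterate_equilibrium_trajectory(
            arch, regime, ms, cfg.generations, mode=mode
        )
        for mode in ("naive", "background", "bulmer")
    }
    return {
        "arch": arch, "map": lmap, "config": cfg, "regime": regime,
        "summary": summary, "predictions": predictions,
    }
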