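"""Linkage maps and harmonic-mean recombination rates.

Places 200 loci on two fixture genomes — one with many long chromosomes
(high recombination) and one with few, genetically short chromosomes (low
recombination) — and prints the map summaries that drive the strength of
Bulmer LD.  The variance deficit d/V_g grows sharply as rbar_h falls.
"""

import polystab as ps

for preset in ("high-recombination", "low-recombination"):
    table = ps.make_fixture_chromosome_table(ps.FixtureMapSpec.preset(preset))
    lmap = ps.place_loci(table, 200)
    rhl = lmap.rbar_h_per_locus()
    dvg = ps.d_over_Vg_equilibrium(X=5.0, rbar_h=lmap.rbar_h())
    print(f"{preset}: {len(table.ids)} chromosomes")
    print(f"  rbar_h = {lmap.rbar_h():.4f}, rbar_h(l) in [{rhl.min():.4f}, {rhl.max():.4f}]")
    print(f"  equilibrium d/V_g at X=5: {dvg:.4f}")
# loci with small rbar_h(l) sit in tight linkage with many causal partners,
# accumulate more negative LD, and have their dynamics slowed the most
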