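"""Pooling, pivot matching, classification, sharing percentages, z tests,
bootstrap CIs — checked against the synthetic generator's ledger."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from neolith import fixtures, synth
from neolith.haplotypes import Haplotype, Individual, PopulationSample, Variant
from neolith.sharing import (
    bootstrap_sharing_ci,
    build_pivot,
    classify_haplotypes,
    pool_and_subsample,
    sharing_percentages,
    sharing_z_tests,
    two_prop_z,
)


def _uniform_recipes(names, n=120, seed=0):
    freqs = fixtures.table2_frequencies()
    return [
        synth.recipe_from_frequencies(name, freqs["European"], n=n, seed=seed + i)
        for i, name in enumerate(names)
    ]


def _query_pop(haps, name="query"):
    inds = [Individual(id=f"q{k}", haplotype=h) for k, h in enumerate(haps)]
    return PopulationSample(name, inds)


def test_pool_and_subsample_size_rule(rng):
    recipes = [
        synth.recipe_from_frequencies(f"P{i}", fixtures.table2_frequencies()["European"],
                                      n=n, seed=i)
        for i, n in enumerate((600, 500, 120))
    ]
    pops = [synth.generate_pool(r)[0] for r in recipes]
    panel = pool_and_subsample(pops, target_n=500, seed=1)
    assert panel.names == ["P0", "P1"]  # the 120-member pool is excluded
    assert all(p.size == 500 for p in panel.pools)
    panel2 = pool_and_subsample(pops, target_n=500, seed=1)
    assert [
        [i.id for i in a.individuals] for a in panel.pools
    ] == [[i.id for i in b.individuals] for b in panel2.pools]
    # below-minimum pools are retained when the minimum is relaxed
    panel3 = pool_and_subsample(pops, target_n=500, seed=1, min_size=100)
    assert panel3.names == ["P0", "P1", "P2"]


def test_pivot_cells_equal_ledger_counts():
    recipes = _uniform_recipes(["A", "B", "C"], n=80)
    hap = Haplotype(frozenset({Variant(16360, "C")}))
    panel, ledger = synth.generate_panel(
        recipes, planted={"B": [(hap, 7)]}, seed=3
    )
    query = _query_pop([hap])
    pivot = build_pivot(panel, query)
    key = hap.trim(pivot.window).canonical_key()
    assert pivot.counts.loc[key, "B"] == 7
    assert ledger.key_count("B", key) == 7
    assert pivot.presence.loc[key, "B"] == 1
    # every pivot cell equals the ledger's direct count
    for pool in panel.names:
        counts = ledger.pool_ledgers[pool].key_counts
        for k in pivot.counts.index:
            assert pivot.counts.loc[k, pool] == counts.get(k, 0)


def test_absent_query_haplotype_has_zero_row():
    recipes = _uniform_recipes(["A", "B"], n=50)
    panel, _ = synth.generate_panel(recipes, seed=4)
    novel = Haplotype(frozenset({Variant(16364, "G"), Variant(16365, "G")}))
    pivot = build_pivot(panel, _query_pop([novel]))
    key = novel.canonical_key()
    assert (pivot.counts.loc[key] == 0).all()


def test_classification_partitions_query():
    recipes = _uniform_recipes([f"P{i}" for i in range(8)], n=60)
    widespread = Haplotype(frozenset({Variant(16350, "C")}))
    limited = Haplotype(frozenset({Variant(16351, "C")}))
    absent = Haplotype(frozenset({Variant(16352, "C")}))
    planted = {f"P{i}": [(widespread, 2)] for i in range(8)}
    planted["P0"].append((limited, 3))
    panel, _ = synth.generate_panel(recipes, planted=planted, seed=5)
    query = _query_pop([widespread, limited, absent])
    pivot = build_pivot(panel, query)
    cls = classify_haplotypes(pivot)
    assert cls.noninformative == [widespread.canonical_key()]
    assert cls.informative == [limited.canonical_key()]
    assert cls.unique == [absent.canonical_key()]
    total = len(cls.noninformative) + len(cls.informative) + len(cls.unique)
    assert total == len(pivot.query_keys)


def test_sharing_percentages_additive_and_ledger_exact():
    recipes = _uniform_recipes([f"P{i}" for i in range(4)], n=50)
    wide = Haplotype(frozenset({Variant(16350, "C")}))
    info = Haplotype(frozenset({Variant(16351, "C")}))
    planted = {f"P{i}": [(wide, 5)] for i in range(4)}
    planted["P2"].append((info, 9))
    panel, ledger = synth.generate_panel(recipes, planted=planted, seed=6)
    query = _query_pop([wide, info])
    pivot = build_pivot(panel, query)
    cls = classify_haplotypes(pivot)
    pct = sharing_percentages(pivot, cls)
    np.testing.assert_allclose(
        pct["all"], pct["informative"] + pct["noninformative"]
    )
    assert pct.loc["P2", "informative"] == pytest.approx(100 * 9 / 50)
    assert pct.loc["P1", "informative"] == 0.0
    assert pct.loc["P1", "noninformative"] == pytest.approx(100 * 5 / 50)
    assert (pct["all"] >= pct["noninformative"] - 1e-12).all()


def test_planted_iranian_style_pool_hits_7_2_percent():
    """A pool of 500 with 36 planted informative carriers shares 7.2%."""
    recipes = _uniform_recipes(["Target", "Other"], n=500)
    info = Haplotype(frozenset({Variant(16355, "C")}))
    panel, _ = synth.generate_panel(recipes, planted={"Target": [(info, 36)]},
                                    seed=7)
    query = _query_pop([info])
    pivot = build_pivot(panel, query)
    cls = classify_haplotypes(pivot)
    pct = sharing_percentages(pivot, cls)
    assert pct.loc["Target", "informative"] == pytest.approx(7.2)


def _z_oracle(x1, n1, x2, n2):
    p1, p2 = x1 / n1, x2 / n2
    p = (x1 + x2) / (n1 + n2)
    z = (p1 - p2) / math.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
    return z, 2 * (1 - norm.cdf(abs(z)))


@pytest.mark.parametrize(
    "x1,n1,x2,n2",
    [(30, 500, 10, 500), (1, 50, 5, 60), (250, 500, 250, 500), (7, 36, 2, 500)],
)
def test_two_prop_z_matches_closed_form(x1, n1, x2, n2):
    z, p = two_prop_z(x1, n1, x2, n2)
    ez, ep = _z_oracle(x1, n1, x2, n2)
    assert z == pytest.approx(ez, abs=1e-12)
    assert p == pytest.approx(ep, abs=1e-12)


def test_two_prop_z_properties():
    z, p = two_prop_z(10, 100, 10, 100)
    assert (z, p) == (0.0, 1.0)
    assert two_prop_z(0, 500, 0, 500) == (0.0, 1.0)
    assert two_prop_z(500, 500, 500, 500) == (0.0, 1.0)
    z1, p1 = two_prop_z(30, 500, 10, 500)
    z2, p2 = two_prop_z(10, 500, 30, 500)
    assert z1 == pytest.approx(-z2)
    assert p1 == pytest.approx(p2)


def test_z_table_flags_planted_enrichment():
    recipes = _uniform_recipes([f"P{i}" for i in range(6)], n=200)
    info = Haplotype(frozenset({Variant(16356, "C")}))
    planted = {"P3": [(info, 30)], "P0": [(info, 2)]}
    panel, _ = synth.generate_panel(recipes, planted=planted, seed=8)
    pivot = build_pivot(panel, _query_pop([info]))
    cls = classify_haplotypes(pivot)
    table = sharing_z_tests(pivot, cls, "informative")
    assert table.loc["P3", "p"] < 0.01
    assert table.loc["P3", "z"] > 0
    # P0 carries a couple of copies: not significantly different
    assert table.loc["P0", "p"] > 0.05
    # pools with zero hits sit significantly below the pooled rate
    assert table.loc["P1", "z"] < 0


def test_bootstrap_ci_degenerate_pools():
    hap = Haplotype(frozenset({Variant(16357, "C")}))
    full = PopulationSample(
        "full", [Individual(id=f"i{k}", haplotype=hap) for k in range(20)]
    )
    other = Haplotype(frozenset({Variant(16358, "C")}))
    none = PopulationSample(
        "none", [Individual(id=f"j{k}", haplotype=other) for k in range(20)]
    )
    pivot = build_pivot(
        synth.generate_panel(_uniform_recipes(["X"], n=30), seed=9)[0],
        _query_pop([hap]),
    )
    cls = classify_haplotypes(pivot, widespread_min_pools=1)
    # classification: hap unique in that panel; force it informative instead
    cls.informative.extend(cls.unique)
    cls.unique.clear()
    assert bootstrap_sharing_ci(full, cls, reps=50, seed=1)["informative"] == (
        100.0, 100.0
    )
    assert bootstrap_sharing_ci(none, cls, reps=50, seed=1)["informative"] == (
        0.0, 0.0
    )


def test_bootstrap_ci_coverage_matches_binomial():
    """Percentile CI of a planted 10% sharing fraction covers the truth at
    roughly the nominal 95% rate when pools are binomial draws."""
    from neolith.sharing import HaplotypeClassification

    n, frac, reps, trials = 400, 0.10, 400, 60
    hap = Haplotype(frozenset({Variant(16359, "C")}))
    other = Haplotype(frozenset({Variant(16360, "T")}))
    cls = HaplotypeClassification(
        noninformative=[], informative=[hap.canonical_key()], unique=[],
        widespread_fraction=0.75, widespread_min_pools=1,
    )
    draw = np.random.default_rng(99)
    covered = 0
    for t in range(trials):
        k = draw.binomial(n, frac)
        members = [
            Individual(id=f"i{j:03d}", haplotype=hap if j < k else other)
            for j in range(n)
        ]
        pool = PopulationSample("pool", members)
        lo, hi = bootstrap_sharing_ci(pool, cls, reps=reps, seed=t,
                                      level=0.95)["informative"]
        covered += lo <= 100 * frac <= hi
    se = math.sqrt(0.95 * 0.05 / trials)
    assert covered / trials > 0.95 - 4 * se - 0.02
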