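"""Diversity, F-statistics, exact tests and FDR."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

import oracles
from mesoped import popgen
from mesoped.genotype_data import Origin
from mesoped.popgen import McTestConfig
from conftest import make_table, random_table

FAST_MC = McTestConfig(1_000, 100, 500, seed=3)


# ---------------------------------------------------------------------------
# allele frequencies and heterozygosity
# ---------------------------------------------------------------------------

def test_allele_freqs_simple_counts():
    table = make_table({"L": [(1, 1), (1, 2)]})
    freqs = popgen.allele_freqs(table)
    assert freqs["L"] == {1: 0.75, 2: 0.25}


def test_allele_freqs_monomorphic_and_brute_force():
    table = make_table({"L": [(5, 5), (5, 5)]})
    assert popgen.allele_freqs(table)["L"] == {5: 1.0}
    rng = np.random.default_rng(11)
    for _ in range(10):
        t = random_table(rng, n_ind=12, n_loci=3, n_alleles=4,
                         missing_rate=0.2)
        freqs = popgen.allele_freqs(t)
        for l, loc in enumerate(t.panel):
            col = t.calls[:, l, :].ravel()
            col = col[col != 0]
            for a, f in freqs[loc.name].items():
                assert f == pytest.approx(np.mean(col == a))
            if len(col):
                assert sum(freqs[loc.name].values()) == pytest.approx(1.0)


def test_heterozygosity_limits_and_oracle():
    all_het = make_table({"L": [(1, 2)] * 6})
    het = popgen.observed_expected_het(all_het)
    assert het.loc["L", "Ho"] == 1.0
    mono = make_table({"L": [(1, 1)] * 6})
    assert popgen.observed_expected_het(mono).loc["L", "He"] == 0.0
    # 10-individual two-allele sample against the direct unbiased formula
    genos = [(1, 1)] * 3 + [(1, 2)] * 4 + [(2, 2)] * 3
    table = make_table({"L": genos})
    he = popgen.observed_expected_het(table).loc["L", "He"]
    assert he == pytest.approx(float(oracles.unbiased_he(genos)), abs=1e-12)


# ---------------------------------------------------------------------------
# allelic richness
# ---------------------------------------------------------------------------

def test_allelic_richness_limits():
    table = make_table({"L": [(1, 2), (2, 3), (3, 3)]})
    ar_full = popgen.allelic_richness(table, g=6)
    assert ar_full["L"] == pytest.approx(3.0)
    mono = make_table({"L": [(7, 7)] * 4})
    assert popgen.allelic_richness(mono, g=2)["L"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        popgen.allelic_richness(table, g=7)


def test_allelic_richness_exhaustive_oracle():
    """Rarefaction equals the mean allele count over ALL g-subsets of a
    6-copy toy locus (exact rational enumeration)."""
    genos = [(1, 1), (1, 2), (2, 3)]
    copies = [a for g in genos for a in g]
    table = make_table({"L": genos})
    for g in (1, 2, 3, 4, 5, 6):
        expected = oracles.allelic_richness_exhaustive(copies, g)
        got = popgen.allelic_richness(table, g=g)["L"]
        assert got == pytest.approx(float(expected), abs=1e-12)


# ---------------------------------------------------------------------------
# Weir–Cockerham statistics
# ---------------------------------------------------------------------------

def _pops_from_table(table, locus_idx):
    pops = []
    for origin in (Origin.SOUTH, Origin.WEST, Origin.OFFSPRING):
        sub = table.subset(origin=origin)
        if sub.n_individuals == 0:
            continue
        genos = [
            (int(a), int(b))
            for a, b in sub.calls[:, locus_idx, :]
            if a != 0 and b != 0
        ]
        pops.append(genos)
    return pops


def test_theta_complete_fixation():
    table = make_table(
        {"L": [(1, 1)] * 4 + [(2, 2)] * 4},
        origins=[Origin.SOUTH] * 4 + [Origin.WEST] * 4,
    )
    res = popgen.fst_weir_cockerham(table)
    assert res.theta == pytest.approx(1.0)


def test_theta_identical_samples_near_zero():
    genos = [(1, 1), (1, 2), (2, 2), (1, 2)]
    table = make_table(
        {"L": genos + genos},
        origins=[Origin.SOUTH] * 4 + [Origin.WEST] * 4,
    )
    assert popgen.fst_weir_cockerham(table).theta <= 0.0 + 1e-12


def test_fis_sign_and_limits():
    all_het = make_table({"L": [(1, 2)] * 8})
    per_locus, multi = popgen.fis_weir_cockerham(all_het)
    assert multi < 0
    rng = np.random.default_rng(5)
    # large sample at HW proportions -> Fis near 0
    genos = [(1, 1)] * 250 + [(1, 2)] * 500 + [(2, 2)] * 250
    table = make_table({"L": genos})
    _, fis = popgen.fis_weir_cockerham(table)
    assert abs(fis) < 0.01


@pytest.mark.parametrize("seed", range(12))
def test_wc_statistics_match_rational_anova_oracle(seed):
    """theta and Fis agree with an independently coded exact
    variance-component computation on random small instances."""
    rng = np.random.default_rng(seed)
    n_pops = int(rng.integers(2, 4))
    table = random_table(
        rng,
        n_ind=int(rng.integers(2 * n_pops, 21)),
        n_loci=int(rng.integers(1, 4)),
        n_alleles=int(rng.integers(2, 4)),
        n_pops=n_pops,
    )
    groups = [Origin.SOUTH, Origin.WEST, Origin.OFFSPRING][:n_pops]
    pops_by_locus = [_pops_from_table(table, l) for l in range(table.n_loci)]
    if all(oracles.wc_components(p) is None for p in pops_by_locus):
        pytest.skip("all loci monomorphic in this draw")
    res = popgen.fst_weir_cockerham(table, groups)
    assert res.theta == pytest.approx(
        oracles.theta_oracle(pops_by_locus), abs=1e-12
    )
    single = table.subset(origin=Origin.SOUTH)
    single_genos = [
        [
            (int(a), int(b))
            for a, b in single.calls[:, l, :]
            if a != 0 and b != 0
        ]
        for l in range(table.n_loci)
    ]
    if any(oracles.wc_components([g]) is not None for g in single_genos):
        _, fis = popgen.fis_weir_cockerham(table, Origin.SOUTH)
        assert fis == pytest.approx(oracles.fis_oracle(single_genos), abs=1e-12)


def test_multilocus_theta_is_ratio_of_sums_not_mean():
    rng = np.random.default_rng(42)
    table = random_table(rng, n_ind=16, n_loci=3, n_alleles=3, n_pops=2)
    res = popgen.fst_weir_cockerham(table)
    per_locus_mean = np.nanmean(list(res.per_locus_theta.values()))
    # the two differ in general; the multilocus value must equal the oracle
    pops_by_locus = [_pops_from_table(table, l) for l in range(3)]
    assert res.theta == pytest.approx(
        oracles.theta_oracle(pops_by_locus), abs=1e-12
    )
    assert res.theta != pytest.approx(per_locus_mean, abs=1e-6)


# ---------------------------------------------------------------------------
# Hardy–Weinberg Markov-chain test
# ---------------------------------------------------------------------------

def test_hw_chain_matches_enumeration():
    genos = [(1, 1)] * 6 + [(1, 2)] * 3 + [(2, 2)] * 5
    table = make_table({"L": genos})
    exact = oracles_hw_exact(genos)
    res = popgen.hw_exact_test(table, None, "L", FAST_MC)
    assert abs(res.p_value - exact) < 3 * max(res.mc_se, 1e-3)


def oracles_hw_exact(genos):
    counts = {}
    for g in genos:
        counts[g] = counts.get(g, 0) + 1
    return popgen.hw_exact_p_enumerated(counts)


def test_hw_null_case_and_determinism():
    genos = [(1, 1)] * 25 + [(1, 2)] * 50 + [(2, 2)] * 25
    table = make_table({"L": genos})
    res1 = popgen.hw_exact_test(table, None, "L", FAST_MC)
    res2 = popgen.hw_exact_test(table, None, "L", FAST_MC)
    assert res1.p_value == res2.p_value  # same seed, same chain
    assert res1.p_value > 0.5


def test_hw_monomorphic_convention():
    table = make_table({"L": [(1, 1)] * 5})
    res = popgen.hw_exact_test(table, None, "L", FAST_MC)
    assert res.p_value == 1.0 and res.monomorphic


def test_hw_chain_convergence_under_doubling():
    genos = [(1, 1)] * 8 + [(1, 2)] * 2 + [(2, 2)] * 6
    table = make_table({"L": genos})
    short = popgen.hw_exact_test(table, None, "L", FAST_MC)
    long_cfg = McTestConfig(1_000, 100, 1_000, seed=17)
    longer = popgen.hw_exact_test(table, None, "L", long_cfg)
    se = math.hypot(short.mc_se, longer.mc_se)
    assert abs(short.p_value - longer.p_value) < 3 * max(se, 1e-3)


# ---------------------------------------------------------------------------
# linkage-disequilibrium test
# ---------------------------------------------------------------------------

def test_ld_perfect_association_small_p():
    rng = np.random.default_rng(0)
    genos = [tuple(sorted(rng.integers(1, 4, 2))) for _ in range(40)]
    table = make_table({"A": genos, "B": genos})
    res = popgen.ld_exact_test(table, None, "A", "B", FAST_MC)
    assert res.p_value < 0.01


def test_ld_determinism_and_monomorphic():
    rng = np.random.default_rng(1)
    ga = [tuple(sorted(rng.integers(1, 4, 2))) for _ in range(30)]
    gb = [tuple(sorted(rng.integers(1, 4, 2))) for _ in range(30)]
    table = make_table({"A": ga, "B": gb})
    r1 = popgen.ld_exact_test(table, None, "A", "B", FAST_MC)
    r2 = popgen.ld_exact_test(table, None, "A", "B", FAST_MC)
    assert r1.p_value == r2.p_value
    mono = make_table({"A": [(1, 1)] * 5, "B": [(2, 3)] * 5})
    assert popgen.ld_exact_test(mono, None, "A", "B", FAST_MC).monomorphic


# ---------------------------------------------------------------------------
# null alleles and FDR
# ---------------------------------------------------------------------------

def test_null_allele_estimator():
    # Ho = He -> 0; direct formula value on He=0.5, Ho=0.4
    assert (0.5 - 0.4) / (0.5 + 0.4) == pytest.approx(1 / 9)
    genos = [(1, 1)] * 5 + [(1, 2)] * 4 + [(2, 2)] * 1
    table = make_table({"L": genos})
    het = popgen.observed_expected_het(table)
    expected = (het.loc["L", "He"] - het.loc["L", "Ho"]) / (
        het.loc["L", "He"] + het.loc["L", "Ho"]
    )
    assert popgen.null_allele_freq(table, None, "L") == pytest.approx(expected)
    all_hom = make_table({"L": [(1, 1)] * 5 + [(2, 2)] * 5})
    assert popgen.null_allele_freq(all_hom, None, "L") == pytest.approx(1.0)


def test_fdr_step_up_rules():
    # by hand at alpha=0.05, m=4: k=3 needs p<=0.0375 but p3=0.04, so the
    # step-up stops at k=2
    res = popgen.fdr_adjust([0.01, 0.02, 0.04, 0.8], "bh", alpha=0.05)
    assert list(res["reject"]) == [True, True, False, False]
    res2 = popgen.fdr_adjust([0.01, 0.02, 0.037, 0.8], "bh", alpha=0.05)
    assert list(res2["reject"]) == [True, True, True, False]
    assert popgen.fdr_adjust([0.03], "bh")["p_adjusted"][0] == pytest.approx(0.03)
    res0 = popgen.fdr_adjust([0.0, 0.0, 0.0], "by")
    assert res0["reject"].all()
    assert popgen.fdr_adjust([], "bh").empty
    with pytest.raises(ValueError):
        popgen.fdr_adjust([0.5], "bonferroni")


def test_fdr_order_invariance():
    rng = np.random.default_rng(3)
    p = rng.random(20)
    perm = rng.permutation(20)
    a = popgen.fdr_adjust(p, "by")["p_adjusted"].to_numpy()
    b = popgen.fdr_adjust(p[perm], "by")["p_adjusted"].to_numpy()
    assert np.allclose(a[perm], b)


def test_by_uses_harmonic_inflation():
    p = [0.01, 0.04, 0.2]
    bh = popgen.fdr_adjust(p, "bh")["p_adjusted"].to_numpy()
    by = popgen.fdr_adjust(p, "by")["p_adjusted"].to_numpy()
    c3 = 1 + 1 / 2 + 1 / 3
    assert np.allclose(np.minimum(bh * c3, 1.0), by)


def test_flagged_locus_excluded_from_multilocus():
    rng = np.random.default_rng(9)
    table = random_table(rng, n_ind=16, n_loci=3, n_alleles=3, n_pops=2)
    full = popgen.fst_weir_cockerham(table).theta
    table.flag_locus("L2")
    without = popgen.fst_weir_cockerham(table).theta
    with_flag = popgen.fst_weir_cockerham(table, include_flagged=True).theta
    assert with_flag == pytest.approx(full)
    assert without != pytest.approx(full)
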