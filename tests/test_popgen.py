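import math

import numpy as np
import pytest

from matesel import popgen
from matesel.panel import HGAMMARUS_EXP, Locus, LocusPanel
from matesel.records import Individual


# ---------------------------------------------------------------------------
# Exclusion probability


def brute_exclusion(p):
    """O(k^6) oracle: enumerate mother, true father, egg and random male.

    Uses the Mendelian deduction rule directly (alleles of the egg whose
    partner allele occurs in the mother), independently of the closed-form
    enumeration in the implementation.
    """
    k = len(p)
    total = 0.0
    for i in range(k):  # maternal transmitted allele
        for j in range(k):  # other maternal allele (ordered genotype)
            wm = p[i] * p[j]
            for c in range(k):  # paternal transmitted allele
                egg = (i, c)
                mother = (i, j)
                s = {
                    x
                    for x, other in ((egg[0], egg[1]), (egg[1], egg[0]))
                    if other in mother
                }
                excl = sum(
                    p[x] * p[y]
                    for x in range(k)
                    for y in range(k)
                    if not ({x, y} & s)
                )
                total += wm * p[c] * excl
    return total


@pytest.mark.parametrize(
    "freqs, expected",
    [
        ([0.5, 0.5], 0.1875),
        ([1 / 3] * 3, 10 / 27),
        ([0.25] * 4, 0.50390625),
        ([0.5, 0.3, 0.2], None),  # uneven: oracle only
    ],
)
def test_exclusion_probability_matches_brute_force(freqs, expected):
    got = popgen.exclusion_probability(np.array(freqs))
    assert got == pytest.approx(brute_exclusion(freqs), abs=1e-12)
    if expected is not None:
        assert got == pytest.approx(expected, abs=1e-9)


def test_exclusion_probability_monotone_in_allele_count():
    values = [
        popgen.exclusion_probability(np.full(k, 1.0 / k)) for k in range(2, 12)
    ]
    assert all(b > a for a, b in zip(values, values[1:]))
    assert popgen.exclusion_probability(np.array([1.0])) == 0.0


def test_exclusion_probability_rejects_bad_input():
    with pytest.raises(ValueError):
        popgen.exclusion_probability(np.array([0.5, 0.4]))


def test_combined_exclusion():
    assert popgen.combined_exclusion([0.5, 0.5]) == pytest.approx(0.75)
    assert popgen.combined_exclusion([0.0, 0.0]) == 0.0
    with pytest.raises(ValueError):
        popgen.combined_exclusion([1.2])


def test_combined_exclusion_of_published_panel_is_9998():
    combined = popgen.combined_exclusion(HGAMMARUS_EXP.values())
    assert round(combined, 4) == 0.9998


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def levene_p_two_alleles(n_aa, n_ab, n_bb):
    """Closed-form Levene exact p for a biallelic sample (oracle)."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab

    def prob(nab):
        naa = (na - nab) // 2
        nbb = (nb - nab) // 2
        return math.exp(
            math.lgamma(n + 1)
            - math.lgamma(naa + 1)
            - math.lgamma(nab + 1)
            - math.lgamma(nbb + 1)
            + nab * math.log(2.0)
            + math.lgamma(na + 1)
            + math.lgamma(nb + 1)
            - math.lgamma(2 * n + 1)
        )

    obs = prob(n_ab)
    return sum(
        prob(h)
        for h in range(na % 2, min(na, nb) + 1, 2)
        if prob(h) <= obs + 1e-12
    )


@pytest.mark.parametrize(
    "n_aa, n_ab, n_bb",
    [(3, 5, 2), (10, 1, 10), (0, 10, 0), (7, 0, 3), (20, 30, 12)],
)
def test_hwe_exact_matches_biallelic_closed_form(n_aa, n_ab, n_bb):
    counts = {}
    if n_aa:
        counts[(1, 1)] = n_aa
    if n_ab:
        counts[(1, 2)] = n_ab
    if n_bb:
        counts[(2, 2)] = n_bb
    p = popgen.hwe_exact_test(counts)
    assert p == pytest.approx(levene_p_two_alleles(n_aa, n_ab, n_bb), abs=1e-9)


def test_hwe_monomorphic_and_errors():
    assert popgen.hwe_exact_test({(1, 1): 10}) == 1.0
    with pytest.raises(ValueError):
        popgen.hwe_exact_test({})


def test_hwe_monte_carlo_agrees_with_enumeration():
    counts = {(1, 1): 6, (1, 2): 9, (2, 2): 4, (1, 3): 2, (3, 3): 1}
    exact = popgen.hwe_exact_test(counts)
    mc = popgen.hwe_exact_test(
        counts, max_arrays=1, mc_reps=20000, rng=np.random.default_rng(0)
    )
    assert mc == pytest.approx(exact, abs=0.02)


# ---------------------------------------------------------------------------
# Weir-Cockerham F-statistics


def _pop(ids, genos, area="a"):
    return [
        Individual(
            id=f"{area}{i}", sex="M", area=area, year=0, cl=1.0, genotype={"L": g}
        )
        for i, g in zip(ids, genos)
    ]


BIALLELIC = LocusPanel(
    (Locus("L", np.array([1, 2]), np.array([0.5, 0.5])),)
)


def test_theta_hand_computed_components():
    # pop1: 3 AA, 1 Aa, 1 aa (p=0.7, h=0.2); pop2: 1 AA, 2 Aa, 2 aa (p=0.4, h=0.4)
    # By hand (per allele A): nbar=5, nc=5, pbar=0.55, s2=0.045, hbar=0.3
    # a = 0.045 - (1/4)(0.2475 - 0.0225 - 0.075) = 0.0075
    # b = 1.25 (0.2475 - 0.0225 - 0.45*0.3) = 0.1125 ; c = 0.15
    # theta = a / (a + b + c) = 0.0075 / 0.27
    g1 = [(1, 1)] * 3 + [(1, 2)] + [(2, 2)]
    g2 = [(1, 1)] + [(1, 2)] * 2 + [(2, 2)] * 2
    pops = [_pop(range(5), g1, "a"), _pop(range(5), g2, "b")]
    theta = popgen.weir_cockerham_theta(pops, BIALLELIC)
    assert theta == pytest.approx(0.0075 / 0.27, abs=1e-12)


def test_theta_fixed_difference_is_one():
    pops = [
        _pop(range(5), [(1, 1)] * 5, "a"),
        _pop(range(5), [(2, 2)] * 5, "b"),
    ]
    assert popgen.weir_cockerham_theta(pops, BIALLELIC) == pytest.approx(1.0)


def test_theta_requires_two_groups():
    with pytest.raises(ValueError):
        popgen.weir_cockerham_theta([_pop(range(5), [(1, 2)] * 5)], BIALLELIC)


def test_fis_all_heterozygotes_is_minus_one():
    sample = _pop(range(10), [(1, 2)] * 10)
    fis = popgen.fis_single_sample(sample, BIALLELIC["L"])
    assert fis == pytest.approx(-1.0)


def test_fis_near_zero_under_hwe(dataset):
    # large simulated sample drawn in HWE: F_IS should be near zero
    locus = dataset.panel["C120"]
    fis = popgen.fis_single_sample(dataset.adults, locus)
    assert abs(fis) < 0.05


def test_pairwise_fst_same_distribution_is_null(dataset):
    rng = np.random.default_rng(5)
    adults = dataset.adults
    res = popgen.pairwise_fst(
        adults[:150],
        adults[150:300],
        dataset.panel,
        permutations=100,
        rng=rng,
        labels=("x", "y"),
    )
    # both halves drawn from the same frequencies: tiny theta, null p
    assert abs(res.theta) < 0.01
    assert res.p_value > 0.05
    assert res.groups == ("x", "y")


def test_pairwise_fst_detects_differentiation():
    rng = np.random.default_rng(6)
    a = _pop(range(30), [(1, 1)] * 25 + [(1, 2)] * 5, "a")
    b = _pop(range(30), [(2, 2)] * 25 + [(1, 2)] * 5, "b")
    res = popgen.pairwise_fst(a, b, BIALLELIC, permutations=200, rng=rng)
    assert res.theta > 0.5
    assert res.p_value < 0.05


# ---------------------------------------------------------------------------
# LD, BH, null alleles, summaries


def test_ld_detects_duplicated_locus(dataset):
    panel = dataset.panel
    dup = Locus("DUP", panel[0].alleles, panel[0].freqs)
    adults = []
    for a in dataset.adults[:100]:
        g = dict(a.genotype)
        g["DUP"] = g[panel[0].name]
        adults.append(
            Individual(id=a.id, sex=a.sex, area=a.area, year=a.year, cl=a.cl, genotype=g)
        )
    p = popgen.ld_test(
        adults, panel[0], dup, permutations=200, rng=np.random.default_rng(1)
    )
    assert p < 0.02


def test_ld_independent_loci_is_null(dataset):
    p = popgen.ld_test(
        dataset.adults,
        dataset.panel[0],
        dataset.panel[1],
        permutations=200,
        rng=np.random.default_rng(2),
    )
    assert p > 0.01


def test_bh_adjust_hand_example_and_statsmodels():
    adj = popgen.bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(3)
    p = rng.random(25)
    ours = popgen.bh_adjust(p)
    _, theirs, _, _ = multipletests(p, method="fdr_bh")
    assert ours == pytest.approx(theirs, abs=1e-12)
    with pytest.raises(ValueError):
        popgen.bh_adjust([1.5])


def test_null_allele_frequency():
    assert popgen.null_allele_frequency(0.8, 0.6) == pytest.approx(1 / 7)
    assert math.isnan(popgen.null_allele_frequency(0.0, 0.0))


def test_locus_summaries_structure_and_ranges(dataset):
    df = popgen.locus_summaries(
        dataset.adults, dataset.panel, mc_reps=500, rng=np.random.default_rng(4)
    )
    assert list(df["locus"]) == dataset.panel.names
    assert (df["n"] > 600).all()
    for col in ("h_o", "h_e", "hwe_p", "exp"):
        assert df[col].between(0, 1).all(), col
    # BH-adjusted p-values never smaller than the raw ones
    assert (df["hwe_p_bh"] >= df["hwe_p"] - 1e-12).all()
    # combined exclusion over the sample-frequency EXPs is high for 10 loci
    assert popgen.combined_exclusion(df["exp"]) > 0.999
    t, p = popgen.fis_t_test(df)
    assert np.isfinite(t) and 0 <= p <= 1
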