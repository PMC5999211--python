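import dataclasses

import numpy as np
import pytest

from matesel.parentage import candidate_mismatch_loci, deduce_paternal_alleles
from matesel.simulate import (
    GroupConfig,
    PopulationConfig,
    error_free,
    fit_preference,
    simulate_adults,
    simulate_dataset,
    simulate_matings,
)


def test_config_validation():
    with pytest.raises(ValueError):
        PopulationConfig(skew=(0.7, 0.2, 0.3))  # sums to 1.2
    with pytest.raises(ValueError):
        PopulationConfig(eggs_per_brood=0)
    with pytest.raises(ValueError):
        PopulationConfig(p_multiple=1.5)


def test_seed_determinism():
    a = simulate_dataset(PopulationConfig(), seed=42)
    b = simulate_dataset(PopulationConfig(), seed=42)
    assert [x.id for x in a.adults] == [x.id for x in b.adults]
    assert [x.cl for x in a.adults] == [x.cl for x in b.adults]
    assert all(
        x.genotype == y.genotype for x, y in zip(a.adults, b.adults)
    )
    assert a.egg_sires == b.egg_sires
    c = simulate_dataset(PopulationConfig(), seed=43)
    assert [x.cl for x in a.adults] != [x.cl for x in c.adults]


def test_group_sizes_and_realized_means(dataset):
    cfg = dataset.config
    for (area, sex), grp in cfg.groups.items():
        members = [
            a for a in dataset.adults if a.area == area and a.sex == sex
        ]
        assert len(members) == grp.n
        mean = np.mean([a.cl for a in members])
        se = grp.cv_cl * grp.mean_cl / np.sqrt(grp.n)
        assert abs(mean - grp.mean_cl) < 3 * se, (area, sex)
        assert all(a.cl > 0 for a in members)


def test_male_claw_allometry(dataset):
    males = dataset.males
    cl = np.array([m.cl for m in males])
    cw = np.array([m.cw for m in males])
    assert all(m.cw is not None for m in males)
    assert all(f.cw is None for f in dataset.females)
    slope, intercept = np.polyfit(cl, cw, 1)
    cfg = dataset.config
    assert slope == pytest.approx(cfg.claw_slope, abs=0.05)
    resid = cw - (intercept + slope * cl)
    assert resid.std(ddof=1) == pytest.approx(cfg.claw_resid_sd, rel=0.2)


def test_harvest_truncation_removes_large_fished():
    cfg = PopulationConfig(harvest_prob=1.0)
    adults = simulate_adults(cfg, np.random.default_rng(0))
    fished = [a for a in adults if a.area == "fished"]
    assert fished and all(a.cl <= cfg.harvest_threshold for a in fished)
    reserve_large = [
        a for a in adults if a.area == "reserve" and a.cl > cfg.harvest_threshold
    ]
    assert reserve_large  # the reserve is untouched


def test_matings_respect_area_and_multiplicity():
    rng = np.random.default_rng(1)
    cfg = PopulationConfig(p_multiple=0.0)
    adults = simulate_adults(cfg, rng)
    by_id = {a.id: a for a in adults}
    matings = simulate_matings(adults, cfg, rng)
    assert len(matings) == len([a for a in adults if a.sex == "F"])
    for m in matings:
        assert len(m.sires) == 1
        assert by_id[m.sires[0]].area == by_id[m.mother_id].area
    cfg2 = PopulationConfig(p_multiple=1.0)
    matings2 = simulate_matings(adults, cfg2, np.random.default_rng(2))
    assert all(len(m.sires) == 2 for m in matings2)
    assert all(len(set(m.sires)) == 2 for m in matings2)
    assert all(m.contributions == [0.9, 0.1] for m in matings2)


def test_error_free_eggs_are_mendelian(ef_dataset):
    ds = ef_dataset
    mothers = {a.id: a for a in ds.females}
    by_id = {a.id: a for a in ds.adults}
    for brood in ds.broods[:30]:
        mother = mothers[brood.mother_id]
        for egg in brood.eggs:
            sire = by_id[ds.egg_sires[egg.id]]
            psets = deduce_paternal_alleles(egg.genotype, mother.genotype, ds.panel)
            # no mother mismatch, and the true sire is never excluded
            assert all(s is None or s for s in psets.values())
            assert candidate_mismatch_loci(psets, sire.genotype) == []


def test_missingness_rate_close_to_configured(dataset):
    calls = [
        pair
        for a in dataset.adults
        for pair in a.genotype.values()
    ]
    frac = np.mean([p == (0, 0) for p in calls])
    # missing_rate 0.01 over ~6600 locus calls
    assert 0.004 < frac < 0.02


def test_observed_genotypes_differ_from_truth_at_error_rate(dataset):
    # with published error rates a few percent of calls are perturbed
    diffs = total = 0
    for a in dataset.adults:
        truth = dataset.true_genotypes[a.id]
        for name, pair in a.genotype.items():
            if pair == (0, 0):
                continue
            total += 1
            diffs += pair != truth[name]
    assert 0.005 < diffs / total < 0.08


def test_error_free_observation_is_exact(ef_dataset):
    for a in ef_dataset.adults:
        assert a.genotype == ef_dataset.true_genotypes[a.id]


def test_brood_sizes(dataset):
    assert all(len(b.eggs) == dataset.config.eggs_per_brood for b in dataset.broods)
    assert len(dataset.broods) == len(dataset.females)


def test_larger_males_mate_more():
    # the preference model must yield positive size selection in the reserve
    rng = np.random.default_rng(3)
    cfg = PopulationConfig()
    adults = simulate_adults(cfg, rng)
    matings = simulate_matings(adults, cfg, rng)
    sires = {s for m in matings for s in m.sires}
    males = [a for a in adults if a.sex == "M" and a.area == "reserve"]
    succ = [m.cl for m in males if m.id in sires]
    rest = [m.cl for m in males if m.id not in sires]
    assert np.mean(succ) > np.mean(rest)


def test_fit_preference_recovers_coefficients():
    cfg = PopulationConfig()
    ds = simulate_dataset(cfg, seed=11)
    fit = fit_preference(ds.adults, ds.matings, cfg)
    assert fit.names == ("b_size", "b_claw_res")
    ci = fit.ci()
    assert ci[0, 0] <= cfg.b_size <= ci[0, 1]
    assert ci[1, 0] <= cfg.b_claw_res <= ci[1, 1]
    assert np.isfinite(fit.loglik)


def test_error_free_helper():
    cfg = error_free(PopulationConfig(missing_rate=0.05))
    assert cfg.missing_rate == 0.0


def test_growth_records_generated(dataset):
    recs = dataset.growth_records
    assert len(recs) == dataset.config.growth.n_records
    cls = np.array([r.cl_first for r in recs])
    assert cls.min() >= dataset.config.growth.cl_min
    assert cls.max() <= dataset.config.growth.cl_max
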