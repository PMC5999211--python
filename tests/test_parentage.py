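import math

import numpy as np
import pytest

from matesel import parentage
from matesel.panel import Locus, LocusPanel
from matesel.records import Brood, Egg, Individual
from matesel.simulate import draw_genotype

TRI = LocusPanel(
    (Locus("L", np.array([1, 2, 3]), np.array([0.45, 0.45, 0.10])),)
)


def test_deduce_paternal_alleles_cases():
    mother = {"L": (1, 2)}
    assert parentage.deduce_paternal_alleles({"L": (1, 3)}, mother, TRI)["L"] == {3}
    # egg carries both maternal alleles: paternal allele ambiguous
    assert parentage.deduce_paternal_alleles({"L": (1, 2)}, mother, TRI)["L"] == {1, 2}
    # mother-offspring mismatch: empty set
    assert parentage.deduce_paternal_alleles({"L": (3, 3)}, mother, TRI)["L"] == frozenset()
    # untyped egg or mother: None
    assert parentage.deduce_paternal_alleles({"L": (0, 0)}, mother, TRI)["L"] is None
    assert parentage.deduce_paternal_alleles({"L": (1, 3)}, {"L": (0, 1)}, TRI)["L"] is None


def test_mismatch_helpers():
    psets = {"a": frozenset({3}), "b": frozenset(), "c": None}
    assert parentage.mother_mismatch_loci(psets) == ["b"]
    cand = {"a": (1, 2), "b": (3, 3), "c": (3, 3)}
    # only locus "a" is checkable and the candidate misses allele 3 there
    assert parentage.candidate_mismatch_loci(psets, cand) == ["a"]
    # candidate missing at "a": skipped
    assert parentage.candidate_mismatch_loci(psets, {"a": (0, 0)}) == []


def test_paternity_llr_frozen_example():
    # mother (1,2), egg (1,3), candidate (3,3), freq(3) = 0.10, no errors:
    # candidate transmits 3 with certainty, a random father with p 0.10,
    # so the likelihood ratio is exactly 10.
    llr = parentage.paternity_likelihood(
        {"L": (1, 3)}, {"L": (1, 2)}, {"L": (3, 3)}, TRI
    )
    assert llr == pytest.approx(math.log(10.0), abs=1e-12)
    # a heterozygous candidate (1,3) transmits 3 only half the time: LR = 5
    llr_het = parentage.paternity_likelihood(
        {"L": (1, 3)}, {"L": (1, 2)}, {"L": (1, 3)}, TRI
    )
    assert llr_het == pytest.approx(math.log(5.0), abs=1e-12)


def test_incompatible_candidate_excluded_without_errors():
    llr = parentage.paternity_likelihood(
        {"L": (1, 1)}, {"L": (1, 1)}, {"L": (2, 2)}, TRI
    )
    assert llr == float("-inf")


def test_dropout_rescues_compatible_trio():
    # true egg (1,2) from candidate (2,2) observed as homozygote (1,1):
    # impossible without error, possible with allelic dropout
    noisy = LocusPanel(
        (Locus("L", np.array([1, 2, 3]), np.array([0.45, 0.45, 0.10]), e1=0.1),)
    )
    egg, mother, cand = {"L": (1, 1)}, {"L": (1, 1)}, {"L": (2, 2)}
    assert parentage.paternity_likelihood(egg, mother, cand, TRI) == float("-inf")
    assert math.isfinite(parentage.paternity_likelihood(egg, mother, cand, noisy))


def test_missing_loci_contribute_zero():
    llr = parentage.paternity_likelihood(
        {"L": (0, 0)}, {"L": (1, 2)}, {"L": (3, 3)}, TRI
    )
    assert llr == 0.0


def test_trioscorer_matches_scalar_likelihood(panel):
    rng = np.random.default_rng(11)
    candidates = [draw_genotype(panel, rng) for _ in range(12)]
    mother = draw_genotype(panel, rng)
    father = candidates[0]
    egg = {
        loc.name: tuple(
            sorted(
                (
                    mother[loc.name][int(rng.integers(2))],
                    father[loc.name][int(rng.integers(2))],
                )
            )
        )
        for loc in panel
    }
    scorer = parentage.TrioScorer(candidates, panel)
    vec = scorer.llrs(egg, mother)
    for i, cand in enumerate(candidates):
        scalar = parentage.paternity_likelihood(egg, mother, cand, panel)
        if scalar == float("-inf"):
            assert vec[i] == float("-inf")
        else:
            assert vec[i] == pytest.approx(scalar, abs=1e-9)


def test_best_and_delta():
    best, top, delta = parentage._best_and_delta(np.array([1.0, 3.0, 2.5]))
    assert (best, top) == (1, 3.0)
    assert delta == pytest.approx(0.5)
    best, top, delta = parentage._best_and_delta(np.array([2.0]))
    assert delta == float("inf")
    best, top, delta = parentage._best_and_delta(np.array([4.0, float("-inf")]))
    assert delta == float("inf")


def test_calibrate_confidence_threshold_properties(ef_panel):
    thr = parentage.calibrate_confidence(
        ef_panel, pool_size=50, sampled_fraction=1.0, reps=200, seed=1
    )
    # fully sampled error-free pool: assignments are near-perfect, so some
    # finite threshold achieves 95% precision
    assert math.isfinite(thr)
    assert parentage.calibrate_confidence(ef_panel, 50, 0.0, reps=10, seed=1) == float("inf")
    with pytest.raises(ValueError):
        parentage.calibrate_confidence(ef_panel, 50, 1.0, reps=0)


def test_assign_fathers_recovers_true_sires(ef_dataset):
    ds = ef_dataset
    males = ds.males
    mothers = {a.id: a for a in ds.females}
    broods = ds.broods[:20]
    results, matings = parentage.assign_fathers(broods, mothers, males, ds.panel, 0.0)
    assert len(results) == sum(len(b.eggs) for b in broods)
    assigned = [r for r in results if r.father_id is not None]
    assert len(assigned) > 0.5 * len(results)
    correct = sum(r.father_id == ds.egg_sires[r.egg_id] for r in assigned)
    assert correct / len(assigned) > 0.95
    # matings aggregate distinct mother-father pairs with egg counts
    assert sum(m.n_eggs for m in matings) == len(assigned)
    assert all(m.mother_id in mothers for m in matings)
    # error-free data: no mother mismatches anywhere
    assert all(r.mother_mismatches == 0 for r in results)


def _brood_from(mother_g, sires, counts, panel, prefix="m1"):
    eggs = []
    k = 0
    for sire_g, n in zip(sires, counts):
        for _ in range(n):
            k += 1
            egg = {
                name: tuple(sorted((mother_g[name][0], sire_g[name][0])))
                for name in mother_g
            }
            eggs.append(Egg(id=f"{prefix}-e{k}", genotype=egg))
    return Brood(mother_id=prefix, eggs=eggs)


def _homozygous_panel_setup():
    loci = tuple(
        Locus(f"L{i}", np.array([1, 2, 3, 4]), np.array([0.4, 0.3, 0.2, 0.1]))
        for i in range(6)
    )
    panel = LocusPanel(loci)
    mk = lambda allele: {loc.name: (allele, allele) for loc in panel}
    return panel, mk


def test_classify_brood_single_and_multiple():
    panel, mk = _homozygous_panel_setup()
    mother = Individual(id="m1", sex="F", area="reserve", year=2011, cl=95.0,
                        genotype=mk(1))
    sire_a = Individual(id="A", sex="M", area="reserve", year=2011, cl=100.0,
                        genotype=mk(2))
    sire_b = Individual(id="B", sex="M", area="reserve", year=2011, cl=100.0,
                        genotype=mk(3))
    cands = {"A": sire_a, "B": sire_b}
    # single-sire brood
    brood1 = _brood_from(mk(1), [mk(2)], [10], panel)
    res1, _ = parentage.assign_fathers([brood1], {"m1": mother},
                                       [sire_a, sire_b], panel, 0.0)
    c1 = parentage.classify_brood(brood1, mother, cands, res1, panel)
    assert c1.classification == "single"
    assert c1.primary_sire == "A" and c1.secondary_sire is None
    # 8:2 mixture: B's eggs mismatch A at all six loci (>= 5 required)
    brood2 = _brood_from(mk(1), [mk(2), mk(3)], [8, 2], panel)
    res2, _ = parentage.assign_fathers([brood2], {"m1": mother},
                                       [sire_a, sire_b], panel, 0.0)
    c2 = parentage.classify_brood(brood2, mother, cands, res2, panel)
    assert c2.classification == "multiple"
    assert c2.primary_sire == "A" and c2.secondary_sire == "B"
    # raising the evidence bar beyond the panel size blocks the call
    c3 = parentage.classify_brood(brood2, mother, cands, res2, panel,
                                  min_mismatch_loci=7)
    assert c3.classification == "ambiguous"


def test_classify_brood_no_assignments_is_ambiguous():
    panel, mk = _homozygous_panel_setup()
    mother = Individual(id="m1", sex="F", area="reserve", year=2011, cl=95.0,
                        genotype=mk(1))
    brood = _brood_from(mk(1), [mk(2)], [10], panel)
    results = [
        parentage.AssignmentResult(e.id, "m1", None, 0.0, 0.0, 0, 0, False)
        for e in brood.eggs
    ]
    c = parentage.classify_brood(brood, mother, {}, results, panel)
    assert c.classification == "ambiguous" and c.primary_sire is None
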