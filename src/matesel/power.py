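"""Monte-Carlo power to detect multiple paternity (prDM).

Given a locus panel, brood size and sire-contribution skew, estimates the
probability that a brood truly sired by several males is detectably
incompatible with every possible single father.  Detection is the
error-free Mendelian criterion: at one or more loci, no two alleles can
jointly account for the deduced paternal allele of every egg.  Detection
can never beat the sampling bound ``1 - sum_k c_k^n`` — a minor sire is
invisible unless one of his eggs is among those sampled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import LocusPanel
from .records import Genotype

__all__ = [
    "PowerConfig",
    "PowerResult",
    "detect_multiple",
    "prdm",
    "skew_table",
    "sampling_bound",
]


@dataclass(frozen=True)
class PowerConfig:
    panel: LocusPanel
    brood_size: int = 10
    contributions: tuple[float, ...] = (0.5, 0.5)
    replicates: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.brood_size < 1:
            raise ValueError("brood size must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        c = np.asarray(self.contributions, dtype=float)
        if np.any(c <= 0) or abs(c.sum() - 1.0) > 1e-9:
            raise ValueError("contributions must be positive and sum to 1")


@dataclass(frozen=True)
class PowerResult:
    estimate: float
    se: float
    replicates: int


def sampling_bound(contributions, n: int) -> float:
    """P(the sampled eggs do not all share one sire) = 1 - sum_k c_k^n."""
    c = np.asarray(list(contributions), dtype=float)
    return float(1.0 - np.sum(c**n))


def _single_father_possible(sets: list[frozenset[int]]) -> bool:
    """Can one diploid father cover every egg's paternal allele set?"""
    forced = {next(iter(s)) for s in sets if len(s) == 1}
    if len(forced) > 2:
        return False
    union = sorted(set().union(*sets))
    if len(union) <= 2:
        return True
    candidates = (
        [tuple(sorted(forced))]
        if len(forced) == 2
        else [
            tuple(sorted(pair))
            for pair in itertools.combinations_with_replacement(union, 2)
            if forced <= set(pair)
        ]
    )
    for pair in candidates:
        if all(s & set(pair) for s in sets):
            return True
    return False


def detect_multiple(
    brood_genotypes: list[Genotype], mother: Genotype, panel: LocusPanel
) -> bool:
    """True iff no single father is Mendelian-compatible with all eggs.

    Error-free check: per locus, deduce each egg's possible paternal
    allele(s) given the mother and test whether any two alleles cover them
    all.  Since loci are independent, the brood is single-father-compatible
    exactly when every locus is.
    """
    for locus in panel:
        m = mother.get(locus.name, (0, 0))
        if m[0] == 0 or m[1] == 0:
            continue
        sets: list[frozenset[int]] = []
        incompatible = False
        for egg in brood_genotypes:
            e = egg.get(locus.name, (0, 0))
            if e[0] == 0 or e[1] == 0:
                continue
            s = frozenset(
                x for x, other in ((e[0], e[1]), (e[1], e[0])) if other in m
            )
            if not s:  # mother-incompatible egg: no single father either
                incompatible = True
                break
            sets.append(s)
        if incompatible:
            return True
        if sets and not _single_father_possible(sets):
            return True
    return False


def _detect_one_locus(
    mother: np.ndarray, mat: np.ndarray, pat: np.ndarray
) -> bool:
    """Detection at one locus from allele-index arrays (mat drawn from mother).

    The deduced paternal set for egg i is {pat_i}, plus {mat_i} when pat_i
    is itself a maternal allele (the egg then carries both maternal alleles
    and the transmitted one is ambiguous).
    """
    m = set(int(a) for a in mother)
    sets = []
    for ma, pa in zip(mat, pat):
        s = {int(pa)}
        if int(pa) in m:
            s.add(int(ma))
        sets.append(frozenset(s))
    return not _single_father_possible(sets)


def prdm(config: PowerConfig) -> PowerResult:
    """Monte-Carlo estimate of the multiple-paternity detection probability.

    Deterministic given the seed.  A single-sire configuration
    short-circuits to exactly zero (nothing to detect).
    """
    if len(config.contributions) == 1:
        return PowerResult(estimate=0.0, se=0.0, replicates=config.replicates)
    rng = np.random.default_rng(config.seed)
    contributions = np.asarray(config.contributions, dtype=float)
    n_sires = len(contributions)
    n = config.brood_size
    reps = config.replicates
    cums = [np.cumsum(loc.freqs) for loc in config.panel.loci]
    hits = 0
    for _ in range(reps):
        sire_idx = np.searchsorted(np.cumsum(contributions), rng.random(n))
        detected = False
        for cum in cums:
            mother = np.searchsorted(cum, rng.random(2))
            sires = np.searchsorted(cum, rng.random((n_sires, 2)))
            mat = mother[rng.integers(0, 2, size=n)]
            pat = sires[sire_idx, rng.integers(0, 2, size=n)]
            if _detect_one_locus(mother, mat, pat):
                detected = True
                break
        hits += detected
    p = hits / reps
    se = float(np.sqrt(p * (1 - p) / reps))
    return PowerResult(estimate=float(p), se=se, replicates=reps)


def skew_table(
    panel: LocusPanel,
    brood_sizes: list[int],
    skews: list[tuple[float, ...]],
    replicates: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """prDM over a grid of brood sizes × contribution skews."""
    rows = []
    for i, (n, skew) in enumerate(itertools.product(brood_sizes, skews)):
        res = prdm(
            PowerConfig(
                panel=panel,
                brood_size=n,
                contributions=tuple(skew),
                replicates=replicates,
                seed=seed + i,
            )
        )
        rows.append(
            {
                "brood_size": n,
                "skew": ":".join(f"{c:g}" for c in skew),
                "n_sires": len(skew),
                "prdm": res.estimate,
                "se": res.se,
                "replicates": res.replicates,
                "sampling_bound": sampling_bound(skew, n),
            }
        )
    return pd.DataFrame(rows)
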