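"""Descriptive and inferential population genetics on the adult sample.

Per-locus diversity (allele counts, observed and unbiased expected
heterozygosity), Hardy–Weinberg exact tests (complete enumeration of
genotype arrays when feasible, Monte-Carlo otherwise), Weir–Cockerham
F-statistics, genotypic linkage-disequilibrium permutation tests, the
Chakraborty moment estimator of null-allele frequency, second-parent
(known mother) exclusion probabilities, and Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import Locus, LocusPanel
from .records import Individual, is_missing

__all__ = [
    "exclusion_probability",
    "combined_exclusion",
    "hwe_exact_test",
    "weir_cockerham_theta",
    "fis_single_sample",
    "pairwise_fst",
    "PairwiseFst",
    "ld_test",
    "bh_adjust",
    "locus_summaries",
    "fis_t_test",
]


# ---------------------------------------------------------------------------
# Exclusion probability (second parent, mother known)


def exclusion_probability(freqs: np.ndarray) -> float:
    """Probability of excluding a random non-father when the mother is known.

    Averages, over HWE mother genotypes and offspring (sire drawn from the
    same allele frequencies), the probability that a random male carries no
    allele consistent with the offspring's deduced paternal allele set.
    With maternal transmitted allele i (mother {i, j}) and paternal allele c,
    the deducible paternal set is {c} when c is not a maternal allele,
    {i, c} when c equals j, and {i} when c equals i; a random male is
    excluded when both his alleles miss that set.
    """
    p = np.asarray(freqs, dtype=float)
    if p.ndim != 1 or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("freqs must be a probability vector")
    k = len(p)
    if k == 1:
        return 0.0
    total = 0.0
    for i in range(k):
        for j in range(k):
            w_m = p[i] * p[j]  # ordered mother genotype; transmits allele i
            # paternal allele c = i  -> set {i}
            acc = p[i] * (1.0 - p[i]) ** 2
            # paternal allele c = j (j != i) -> set {i, j}
            if j != i:
                acc += p[j] * (1.0 - p[i] - p[j]) ** 2
            # paternal allele outside the mother -> set {c}
            for c in range(k):
                if c != i and c != j:
                    acc += p[c] * (1.0 - p[c]) ** 2
            total += w_m * acc
    return float(total)


def combined_exclusion(exps) -> float:
    """Combine per-locus exclusion probabilities: 1 - prod(1 - EXP_l)."""
    exps = np.asarray(list(exps), dtype=float)
    if np.any((exps < 0) | (exps > 1)):
        raise ValueError("exclusion probabilities must be in [0, 1]")
    return float(1.0 - np.prod(1.0 - exps))


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def genotype_counts(individuals: list[Individual], locus: Locus) -> dict[tuple[int, int], int]:
    counts: dict[tuple[int, int], int] = {}
    for ind in individuals:
        pair = ind.genotype.get(locus.name, (0, 0))
        if is_missing(pair):
            continue
        counts[pair] = counts.get(pair, 0) + 1
    return counts


def _array_log_prob(counts: dict[tuple[int, int], int]) -> float:
    """Levene conditional probability of a genotype array given allele counts."""
    n = sum(counts.values())
    allele: dict[int, int] = {}
    het = 0
    log_nij = 0.0
    for (a, b), c in counts.items():
        allele[a] = allele.get(a, 0) + c
        allele[b] = allele.get(b, 0) + c
        if a != b:
            het += c
        log_nij += math.lgamma(c + 1)
    logp = (
        math.lgamma(n + 1)
        + sum(math.lgamma(m + 1) for m in allele.values())
        + het * math.log(2.0)
        - math.lgamma(2 * n + 1)
        - log_nij
    )
    return logp


def _enumerate_arrays(allele_counts: list[int], max_arrays: int):
    """Yield every genotype array (dict over index pairs) with the given
    allele-copy margins; raises OverflowError past ``max_arrays``."""
    k = len(allele_counts)
    seen = 0
    array: dict[tuple[int, int], int] = {}

    def rec_allele(i: int, rem: list[int]):
        nonlocal seen
        if i == k:
            seen += 1
            if seen > max_arrays:
                raise OverflowError("too many genotype arrays")
            yield dict(array)
            return
        yield from rec_pair(i, i + 1, rem, rem[i])

    def rec_pair(i: int, j: int, rem: list[int], left: int):
        # distribute allele i's remaining copies into hets (i,j), j>i, then homs
        if j == k:
            if left % 2 == 0:
                nii = left // 2
                if nii:
                    array[(i, i)] = nii
                rem2 = rem.copy()
                rem2[i] = 0
                yield from rec_allele(i + 1, rem2)
                array.pop((i, i), None)
            return
        for nij in range(0, min(left, rem[j]) + 1):
            if nij:
                array[(i, j)] = nij
            rem[j] -= nij
            yield from rec_pair(i, j + 1, rem, left - nij)
            rem[j] += nij
            array.pop((i, j), None)

    yield from rec_allele(0, list(allele_counts))


def hwe_exact_test(
    counts: dict[tuple[int, int], int],
    mc_reps: int = 10000,
    max_arrays: int = 200_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Exact conditional test of Hardy-Weinberg proportions.

    Sums Levene probabilities over all genotype arrays with the observed
    allele counts when the enumeration is small enough; otherwise
    Monte-Carlo: random pairings of the observed allele copies.
    The p-value is the total probability of arrays no more probable than
    the observed one.
    """
    if not counts:
        raise ValueError("need at least one genotype")
    alleles = sorted({a for pair in counts for a in pair})
    if len(alleles) == 1:
        return 1.0
    index = {a: i for i, a in enumerate(alleles)}
    icounts = {(index[a], index[b]): c for (a, b), c in counts.items()}
    margins = [0] * len(alleles)
    for (a, b), c in icounts.items():
        margins[a] += c
        margins[b] += c
    log_obs = _array_log_prob(icounts)
    tol = 1e-9
    try:
        p_sum = 0.0
        for array in _enumerate_arrays(margins, max_arrays):
            lp = _array_log_prob(array)
            if lp <= log_obs + tol:
                p_sum += math.exp(lp)
        return float(min(p_sum, 1.0))
    except OverflowError:
        pass
    # Monte-Carlo: shuffle the 2n allele copies and re-pair
    rng = rng or np.random.default_rng()
    pool = np.repeat(np.arange(len(alleles)), margins)
    hits = 0
    for _ in range(mc_reps):
        rng.shuffle(pool)
        arr: dict[tuple[int, int], int] = {}
        for a, b in pool.reshape(-1, 2):
            key = (int(min(a, b)), int(max(a, b)))
            arr[key] = arr.get(key, 0) + 1
        if _array_log_prob(arr) <= log_obs + tol:
            hits += 1
    return float((hits + 1) / (mc_reps + 1))


# ---------------------------------------------------------------------------
# Weir-Cockerham F-statistics


def _locus_matrix(
    individuals: list[Individual], locus: Locus
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Allele-index pairs per individual (-1 = missing) and the allele list."""
    alleles = sorted(
        {a for ind in individuals for a in ind.genotype.get(locus.name, (0, 0)) if a != 0}
    )
    idx = {a: i for i, a in enumerate(alleles)}
    pairs = np.full((len(individuals), 2), -1, dtype=int)
    for row, ind in enumerate(individuals):
        pair = ind.genotype.get(locus.name, (0, 0))
        if not is_missing(pair):
            pairs[row, 0] = idx[pair[0]]
            pairs[row, 1] = idx[pair[1]]
    return pairs[:, 0], pairs[:, 1], alleles


def _group_stats(
    a1: np.ndarray, a2: np.ndarray, k: int, masks: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per group: typed sample size, allele freqs, het-carrier freqs."""
    r = len(masks)
    n = np.zeros(r)
    p = np.zeros((r, k))
    h = np.zeros((r, k))
    typed = a1 >= 0
    het = typed & (a1 != a2)
    for g, mask in enumerate(masks):
        m = mask & typed
        n[g] = m.sum()
        if n[g] == 0:
            continue
        p[g] = np.bincount(a1[m], minlength=k) + np.bincount(a2[m], minlength=k)
        hm = mask & het
        h[g] = np.bincount(a1[hm], minlength=k) + np.bincount(a2[hm], minlength=k)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = p / (2 * n[:, None])
        h = h / n[:, None]
    return n, p, h


def _locus_allele_stats(
    groups: list[list[Individual]], locus: Locus
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]:
    """Per group: sample size, and per allele freq and het-carrier freq."""
    pooled = [ind for grp in groups for ind in grp]
    a1, a2, alleles = _locus_matrix(pooled, locus)
    masks = []
    start = 0
    for grp in groups:
        mask = np.zeros(len(pooled), dtype=bool)
        mask[start : start + len(grp)] = True
        masks.append(mask)
        start += len(grp)
    n, p, h = _group_stats(a1, a2, len(alleles), masks)
    return n, p, h, alleles


def _wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray) -> tuple[float, float, float]:
    """Summed Weir-Cockerham variance components (a, b, c) over alleles."""
    r = len(n)
    nbar = n.mean()
    nc = (r * nbar - np.sum(n**2) / (r * nbar)) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for al in range(p.shape[1]):
        pbar = np.sum(n * p[:, al]) / (r * nbar)
        s2 = np.sum(n * (p[:, al] - pbar) ** 2) / ((r - 1) * nbar)
        hbar = np.sum(n * h[:, al]) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def weir_cockerham_theta(
    groups: list[list[Individual]], panel: LocusPanel
) -> float:
    """Multilocus Weir-Cockerham θ: ratio of summed variance components."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 individuals each")
    num = den = 0.0
    for locus in panel:
        n, p, h, alleles = _locus_allele_stats(groups, locus)
        if len(alleles) < 2 or np.any(n < 2):
            continue
        a, b, c = _wc_components(n, p, h)
        num += a
        den += a + b + c
    return float(num / den) if den != 0 else 0.0


def fis_single_sample(individuals: list[Individual], locus: Locus) -> float:
    """Weir-Cockerham within-sample inbreeding coefficient f = 1 - c/(b + c)."""
    n, p, h, alleles = _locus_allele_stats([individuals], locus)
    n0 = n[0]
    if n0 < 2 or len(alleles) < 2:
        return float("nan")
    b_sum = c_sum = 0.0
    for al in range(p.shape[1]):
        pa, ha = p[0, al], h[0, al]
        b_sum += (n0 / (n0 - 1)) * (pa * (1 - pa) - (2 * n0 - 1) / (4 * n0) * ha)
        c_sum += ha / 2
    if b_sum + c_sum == 0:
        return float("nan")
    return float(1.0 - c_sum / (b_sum + c_sum))


@dataclass(frozen=True)
class PairwiseFst:
    groups: tuple[str, str]
    theta: float
    p_value: float
    permutations: int


def pairwise_fst(
    group_a: list[Individual],
    group_b: list[Individual],
    panel: LocusPanel,
    permutations: int = 1000,
    rng: np.random.Generator | None = None,
    labels: tuple[str, str] = ("A", "B"),
) -> PairwiseFst:
    """Weir-Cockerham θ between two samples with a permutation p-value.

    The null distribution permutes individuals across group labels; the
    p-value is the fraction of permuted θ at least as large as observed.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    theta = weir_cockerham_theta([group_a, group_b], panel)
    rng = rng or np.random.default_rng()
    pooled = list(group_a) + list(group_b)
    na = len(group_a)
    matrices = [_locus_matrix(pooled, locus) for locus in panel]

    def theta_for(mask_a: np.ndarray) -> float:
        num = den = 0.0
        for a1, a2, alleles in matrices:
            if len(alleles) < 2:
                continue
            n, p, h = _group_stats(a1, a2, len(alleles), [mask_a, ~mask_a])
            if np.any(n < 2):
                continue
            a, b, c = _wc_components(n, p, h)
            num += a
            den += a + b + c
        return num / den if den != 0 else 0.0

    hits = 0
    base = np.zeros(len(pooled), dtype=bool)
    base[:na] = True
    for _ in range(permutations):
        if theta_for(rng.permutation(base)) >= theta - 1e-12:
            hits += 1
    return PairwiseFst(
        groups=labels,
        theta=theta,
        p_value=float((hits + 1) / (permutations + 1)),
        permutations=permutations,
    )


# ---------------------------------------------------------------------------
# Linkage disequilibrium


def ld_test(
    individuals: list[Individual],
    locus_a: Locus,
    locus_b: Locus,
    permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Genotypic LD: G statistic on the two-locus genotype table, null by
    permuting one locus's genotypes across individuals."""
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    pairs = [
        (ind.genotype.get(locus_a.name, (0, 0)), ind.genotype.get(locus_b.name, (0, 0)))
        for ind in individuals
    ]
    pairs = [(ga, gb) for ga, gb in pairs if not is_missing(ga) and not is_missing(gb)]
    if len(pairs) < 10:
        raise ValueError("need >= 10 individuals typed at both loci")
    ga = [p[0] for p in pairs]
    gb = [p[1] for p in pairs]
    if len(set(ga)) < 2 or len(set(gb)) < 2:
        return 1.0
    # integer-code the genotype classes at each locus
    levels_a = {g: i for i, g in enumerate(sorted(set(ga)))}
    levels_b = {g: i for i, g in enumerate(sorted(set(gb)))}
    xa = np.array([levels_a[g] for g in ga])
    xb = np.array([levels_b[g] for g in gb])
    ka, kb = len(levels_a), len(levels_b)

    def g_stat(xs, ys) -> float:
        tab = np.bincount(xs * kb + ys, minlength=ka * kb).reshape(ka, kb).astype(float)
        n = tab.sum()
        exp = tab.sum(1)[:, None] * tab.sum(0)[None, :] / n
        mask = tab > 0
        return float(2.0 * np.sum(tab[mask] * np.log(tab[mask] / exp[mask])))

    g_obs = g_stat(xa, xb)
    rng = rng or np.random.default_rng()
    hits = 0
    for _ in range(permutations):
        if g_stat(xa, rng.permutation(xb)) >= g_obs - 1e-12:
            hits += 1
    return float((hits + 1) / (permutations + 1))


# ---------------------------------------------------------------------------
# Multiple testing and summaries


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(pvals), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def null_allele_frequency(h_e: float, h_o: float) -> float:
    """Chakraborty moment estimator (H_E - H_O)/(H_E + H_O)."""
    if h_e + h_o == 0:
        return float("nan")
    return (h_e - h_o) / (h_e + h_o)


def locus_summaries(
    individuals: list[Individual],
    panel: LocusPanel,
    mc_reps: int = 10000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-locus diversity and QC statistics (one row per locus).

    Columns: n (typed individuals), n_a, h_o, h_e (unbiased), hwe_p,
    hwe_p_bh, f_is, f_null, exp (second-parent exclusion from the sample
    allele frequencies).
    """
    if len(individuals) < 2:
        raise ValueError("need at least two typed individuals")
    rng = rng or np.random.default_rng()
    rows = []
    for locus in panel:
        counts = genotype_counts(individuals, locus)
        n = sum(counts.values())
        if n == 0:
            rows.append([locus.name, 0, 0, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan])
            continue
        allele_count: dict[int, int] = {}
        het = 0
        for (a, b), c in counts.items():
            allele_count[a] = allele_count.get(a, 0) + c
            allele_count[b] = allele_count.get(b, 0) + c
            if a != b:
                het += c
        freqs = np.array(list(allele_count.values()), dtype=float) / (2 * n)
        n_a = len(allele_count)
        h_o = het / n
        h_e = (2 * n / (2 * n - 1)) * (1 - np.sum(freqs**2)) if n > 1 else np.nan
        if n_a == 1:
            rows.append([locus.name, n, 1, h_o, 0.0, np.nan, np.nan, np.nan, 0.0])
            continue
        hwe_p = hwe_exact_test(counts, mc_reps=mc_reps, rng=rng)
        f_is = fis_single_sample(individuals, locus)
        f_null = null_allele_frequency(h_e, h_o)
        exp = exclusion_probability(freqs)
        rows.append([locus.name, n, n_a, h_o, h_e, hwe_p, f_is, f_null, exp])
    df = pd.DataFrame(
        rows,
        columns=["locus", "n", "n_a", "h_o", "h_e", "hwe_p", "f_is", "f_null", "exp"],
    )
    valid = df["hwe_p"].notna()
    df["hwe_p_bh"] = np.nan
    if valid.any():
        df.loc[valid, "hwe_p_bh"] = bh_adjust(df.loc[valid, "hwe_p"].to_numpy())
    return df


def fis_t_test(summaries: pd.DataFrame) -> tuple[float, float]:
    """One-sample t test of mean F_IS across loci against zero."""
    vals = summaries["f_is"].dropna().to_numpy()
    if len(vals) < 2:
        return float("nan"), float("nan")
    t, p = stats.ttest_1samp(vals, 0.0)
    return float(t), float(p)
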