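"""Synthetic lobster populations with size-biased mating and genotyping error.

Generates complete datasets — adults, matings, egg broods, genotypes and
mark-recapture growth records — with the statistical structure the downstream
analysis assumes, so every pipeline stage is testable without field data.

The default configuration mirrors the Flødevigen study system: per-area and
per-sex size distributions (reserve males are larger and more variable than
fished males), a 10-locus microsatellite panel, occasional multiple paternity
with a strongly skewed paternal contribution, and an annual moult/growth
process for back-adjusting male size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .panel import Locus, LocusPanel, reference_panel
from .records import Brood, Egg, Genotype, GrowthRecord, Individual, sort_pair

__all__ = [
    "GroupConfig",
    "GrowthConfig",
    "PopulationConfig",
    "Mating",
    "SimulatedDataset",
    "simulate_adults",
    "simulate_matings",
    "simulate_genotypes",
    "simulate_growth_records",
    "simulate_dataset",
    "draw_genotype",
    "observe_genotype",
]


@dataclass(frozen=True)
class GroupConfig:
    """Size distribution of one area × sex group: N(mean, (cv·mean)^2), CL > 0."""

    n: int
    mean_cl: float
    cv_cl: float

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("group count must be positive")
        if self.cv_cl <= 0:
            raise ValueError("CV must be positive")
        if self.mean_cl <= 0:
            raise ValueError("mean CL must be positive")


@dataclass(frozen=True)
class GrowthConfig:
    """Mark-recapture growth process for males captured in consecutive years.

    Moult probability is logistic in CL at first capture; defaults give
    p ≈ 1 below 90 mm (annual moulting below the minimum legal size) falling
    under 0.75 above ~113 mm.  The yearly increment declines gently with size
    and stays above the 5 mm moult-detection threshold across the sampled
    range, so a true moult is always recognisable.
    """

    n_records: int = 300
    cl_min: float = 60.0
    cl_max: float = 140.0
    moult_intercept: float = 12.78
    moult_slope: float = -0.1034
    growth_intercept: float = 12.0  # mm at CL = 0
    growth_slope: float = -0.04  # mm per mm CL
    growth_sd: float = 1.0
    measure_sd: float = 1.2  # non-moult remeasurement noise, |noise| < 5 mm

    def moult_prob(self, cl: np.ndarray | float) -> np.ndarray | float:
        eta = self.moult_intercept + self.moult_slope * np.asarray(cl, dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))

    def increment(self, cl: np.ndarray | float) -> np.ndarray | float:
        return self.growth_intercept + self.growth_slope * np.asarray(cl, dtype=float)


# Observed (post-harvest) pooled group sizes and size distributions of the
# study system: (area, sex) -> (count, mean CL mm, CV).
DEFAULT_GROUPS: dict[tuple[str, str], GroupConfig] = {
    ("reserve", "M"): GroupConfig(274, 99.0, 0.18),
    ("fished", "M"): GroupConfig(287, 88.0, 0.15),
    ("reserve", "F"): GroupConfig(51, 97.0, 0.12),
    ("fished", "F"): GroupConfig(46, 92.0, 0.11),
}


@dataclass(frozen=True)
class PopulationConfig:
    """Everything needed to generate one synthetic dataset.

    Mating preference: a male's weight for a given female is
    ``exp(b_size·z_CL + b_claw_res·z_CWres)`` times a half-Gaussian
    assortative kernel centred at the preferred male size
    ``delta_assort · CL_female``: males smaller than the preferred size are
    penalised with scale ``assort_sd`` (mm), males at or above it are not
    discriminated further (sperm-limitation logic — a female avoids mates
    too small to fertilise her clutch but gains little above that).  Set
    ``delta_assort`` to None to disable the kernel.  ``z`` are standardised
    over the whole male population, so per-SD preference coefficients
    express more weakly in an area whose trait variance harvest has
    truncated.
    """

    groups: dict[tuple[str, str], GroupConfig] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )
    # crusher-claw allometry on CL (males)
    claw_slope: float = 0.82
    claw_intercept: float = -27.0
    claw_resid_sd: float = 6.0
    # mating preference
    b_size: float = 0.6  # log-odds per SD of CL
    b_claw_res: float = 1.3  # log-odds per SD of residual claw width
    delta_assort: float | None = 1.2  # preferred male/female CL ratio
    assort_sd: float = 20.0  # half-Gaussian kernel scale on male CL, mm
    # multiple paternity
    p_multiple: float = 0.02
    skew: tuple[float, ...] = (0.9, 0.1)  # paternal contributions when multiple
    eggs_per_brood: int = 10
    # optional extra harvest truncation of the fished area
    harvest_threshold: float = 90.0
    harvest_prob: float = 0.0
    # sampling-year structure (males fished over several seasons)
    male_years: tuple[int, ...] = (2010, 2011, 2012)
    female_years: tuple[int, ...] = (2011, 2012)
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    missing_rate: float = 0.01

    def __post_init__(self) -> None:
        if abs(sum(self.skew) - 1.0) > 1e-9 or any(c <= 0 for c in self.skew):
            raise ValueError("skew contributions must be positive and sum to 1")
        if self.eggs_per_brood < 1:
            raise ValueError("eggs per brood must be >= 1")
        if not 0 <= self.p_multiple <= 1:
            raise ValueError("p_multiple must be a probability")


@dataclass
class Mating:
    """A mother and her true sires with fertilisation contributions."""

    mother_id: str
    sires: list[str]
    contributions: list[float]


@dataclass
class SimulatedDataset:
    """One complete synthetic dataset plus the generating truth."""

    adults: list[Individual]
    broods: list[Brood]
    matings: list[Mating]
    true_genotypes: dict[str, Genotype]
    egg_sires: dict[str, str]
    growth_records: list[GrowthRecord]
    panel: LocusPanel
    config: PopulationConfig
    seed: int

    @property
    def males(self) -> list[Individual]:
        return [a for a in self.adults if a.sex == "M"]

    @property
    def females(self) -> list[Individual]:
        return [a for a in self.adults if a.sex == "F"]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal draws truncated at > 0 by redrawing (negligible mass for our CVs)."""
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def simulate_adults(
    config: PopulationConfig, rng: np.random.Generator
) -> list[Individual]:
    """Draw the adult population group by group.

    Sizes are normal with the configured mean and CV, truncated at zero;
    male claw width follows the linear allometry plus normal residual.
    Fished-area individuals above the harvest threshold are removed with
    probability ``harvest_prob`` (default 0: the configured distributions
    are already the observed, post-harvest ones).
    """
    adults: list[Individual] = []
    counter = 0
    for (area, sex), grp in sorted(config.groups.items()):
        cls = _truncated_normal(rng, grp.mean_cl, grp.cv_cl * grp.mean_cl, grp.n)
        years = config.male_years if sex == "M" else config.female_years
        year_draws = rng.choice(np.asarray(years), size=grp.n)
        for cl, year in zip(cls, year_draws):
            counter += 1
            cw = None
            if sex == "M":
                cw = config.claw_intercept + config.claw_slope * cl
                cw += rng.normal(0.0, config.claw_resid_sd)
                cw = max(cw, 1.0)
            adults.append(
                Individual(
                    id=f"{area[0].upper()}{sex}{counter:04d}",
                    sex=sex,
                    area=area,
                    year=int(year),
                    cl=float(cl),
                    cw=cw,
                )
            )
    if config.harvest_prob > 0:
        kept = []
        for a in adults:
            if (
                a.area == "fished"
                and a.cl > config.harvest_threshold
                and rng.random() < config.harvest_prob
            ):
                continue
            kept.append(a)
        adults = kept
    return adults


def male_preference_scores(
    males: list[Individual], config: PopulationConfig
) -> np.ndarray:
    """Per-male log-preference from the trait terms (kernel excluded).

    Traits are standardised over the WHOLE male population, not per area:
    the preference coefficients are per population-SD, so an area whose
    trait variance has been truncated by harvest expresses a weaker
    realised preference — the mechanism behind area contrasts in selection.
    """
    cl = np.array([m.cl for m in males])
    cw = np.array([m.cw for m in males], dtype=float)
    sd_cl = cl.std(ddof=1)
    z_cl = (cl - cl.mean()) / sd_cl if sd_cl > 0 else np.zeros_like(cl)
    if len(males) >= 3 and sd_cl > 0:
        beta = np.polyfit(cl, cw, 1)
        res = cw - np.polyval(beta, cl)
        sd = res.std(ddof=1)
        z_res = res / sd if sd > 0 else np.zeros_like(res)
    else:
        z_res = np.zeros_like(cl)
    return config.b_size * z_cl + config.b_claw_res * z_res


def _female_weights(
    pool_cl: np.ndarray,
    pool_scores: np.ndarray,
    female_cl: float,
    config: PopulationConfig,
) -> np.ndarray:
    logw = pool_scores.copy()
    if config.delta_assort is not None:
        shortfall = np.minimum(pool_cl - config.delta_assort * female_cl, 0.0)
        logw = logw - 0.5 * (shortfall / config.assort_sd) ** 2
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def simulate_matings(
    adults: list[Individual],
    config: PopulationConfig,
    rng: np.random.Generator,
) -> list[Mating]:
    """Assign each female one sire (or more, with the configured skew).

    Sires are sampled from the female's area with probability proportional
    to the preference weight; with probability ``p_multiple`` additional
    sires are drawn (without replacement) to fill the skew vector.
    """
    males = [a for a in adults if a.sex == "M"]
    females = [a for a in adults if a.sex == "F"]
    if not males:
        raise ValueError("no males available for mating")
    if not females:
        raise ValueError("no females available for mating")
    scores = male_preference_scores(males, config)
    by_area: dict[str, tuple[list[Individual], np.ndarray, np.ndarray]] = {}
    for area in {m.area for m in males}:
        idx = [i for i, m in enumerate(males) if m.area == area]
        by_area[area] = (
            [males[i] for i in idx],
            np.array([males[i].cl for i in idx]),
            scores[idx],
        )
    all_pool = (males, np.array([m.cl for m in males]), scores)
    matings = []
    for f in females:
        pool, pool_cl, pool_scores = by_area.get(f.area, all_pool)
        w = _female_weights(pool_cl, pool_scores, f.cl, config)
        n_sires = len(config.skew) if rng.random() < config.p_multiple else 1
        n_sires = min(n_sires, len(pool))
        idx = rng.choice(len(pool), size=n_sires, replace=False, p=w)
        contributions = list(config.skew[:n_sires])
        total = sum(contributions)
        contributions = [c / total for c in contributions]
        matings.append(
            Mating(
                mother_id=f.id,
                sires=[pool[i].id for i in idx],
                contributions=contributions,
            )
        )
    return matings


def draw_genotype(panel: LocusPanel, rng: np.random.Generator) -> Genotype:
    """A multilocus genotype drawn from panel frequencies in HWE."""
    g: Genotype = {}
    for loc in panel:
        pair = rng.choice(loc.alleles, size=2, p=loc.freqs)
        g[loc.name] = sort_pair(int(pair[0]), int(pair[1]))
    return g


def _observe_locus(
    pair: tuple[int, int],
    locus: Locus,
    rng: np.random.Generator,
    missing_rate: float,
) -> tuple[int, int]:
    a, b = pair
    # allelic dropout: heterozygote scored as a homozygote for one allele
    if a != b and rng.random() < locus.e1:
        kept = a if rng.random() < 0.5 else b
        a = b = kept
    # false allele: each scored allele replaced by a random panel allele
    obs = [a, b]
    for i in range(2):
        if rng.random() < locus.e2:
            obs[i] = int(rng.choice(locus.alleles, p=locus.freqs))
    if missing_rate > 0 and rng.random() < missing_rate:
        return (0, 0)
    return sort_pair(obs[0], obs[1])


def observe_genotype(
    true: Genotype,
    panel: LocusPanel,
    rng: np.random.Generator,
    missing_rate: float = 0.0,
) -> Genotype:
    """Apply the dropout / false-allele / missingness observation layer."""
    return {
        loc.name: _observe_locus(true[loc.name], loc, rng, missing_rate)
        for loc in panel
    }


def simulate_genotypes(
    adults: list[Individual],
    matings: list[Mating],
    panel: LocusPanel,
    rng: np.random.Generator,
    missing_rate: float = 0.0,
    eggs_per_brood: int = 10,
) -> tuple[list[Brood], dict[str, Genotype], dict[str, str]]:
    """Draw parental genotypes in HWE, inherit eggs Mendelianly, observe.

    Mutates ``adults`` in place by setting their observed genotypes, and
    returns ``(broods, true_genotypes, egg_sires)``.  Egg sires are drawn
    per egg from the mating's contribution vector, so a multiply-mated
    female's brood is a multinomial mixture of her sires.
    """
    true: dict[str, Genotype] = {}
    by_id = {a.id: a for a in adults}
    for a in adults:
        g = draw_genotype(panel, rng)
        true[a.id] = g
        a.genotype = observe_genotype(g, panel, rng, missing_rate)
    broods: list[Brood] = []
    egg_sires: dict[str, str] = {}
    for mating in matings:
        mother_true = true[mating.mother_id]
        eggs = []
        for k in range(eggs_per_brood):
            sire_id = mating.sires[
                int(rng.choice(len(mating.sires), p=mating.contributions))
            ]
            if sire_id not in true:
                raise KeyError(f"sire {sire_id} has no genotype")
            sire_true = true[sire_id]
            egg_true: Genotype = {}
            for loc in panel:
                mat = mother_true[loc.name][int(rng.integers(2))]
                pat = sire_true[loc.name][int(rng.integers(2))]
                egg_true[loc.name] = sort_pair(mat, pat)
            egg_id = f"{mating.mother_id}-e{k + 1:02d}"
            true[egg_id] = egg_true
            egg_sires[egg_id] = sire_id
            eggs.append(
                Egg(id=egg_id, genotype=observe_genotype(egg_true, panel, rng, missing_rate))
            )
        broods.append(Brood(mother_id=mating.mother_id, eggs=eggs))
    # sanity: all mothers exist
    for b in broods:
        if b.mother_id not in by_id:
            raise KeyError(f"unknown mother {b.mother_id}")
    return broods, true, egg_sires


def simulate_growth_records(
    config: GrowthConfig, rng: np.random.Generator
) -> list[GrowthRecord]:
    """Males measured in two consecutive years under the moult/growth process."""
    records = []
    cls = rng.uniform(config.cl_min, config.cl_max, size=config.n_records)
    p = np.asarray(config.moult_prob(cls))
    moulted = rng.random(config.n_records) < p
    for i, (cl, m) in enumerate(zip(cls, moulted)):
        if m:
            delta = config.increment(cl) + rng.normal(0.0, config.growth_sd)
        else:
            delta = float(np.clip(rng.normal(0.0, config.measure_sd), -4.9, 4.9))
        records.append(
            GrowthRecord(male_id=f"G{i:04d}", cl_first=float(cl), cl_second=float(cl + delta))
        )
    return records


def simulate_dataset(
    config: PopulationConfig | None = None,
    panel: LocusPanel | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Generate one full dataset: adults, matings, broods, genotypes, growth."""
    config = config or PopulationConfig()
    panel = panel or reference_panel()
    rng = np.random.default_rng(seed)
    adults = simulate_adults(config, rng)
    matings = simulate_matings(adults, config, rng)
    broods, true, egg_sires = simulate_genotypes(
        adults,
        matings,
        panel,
        rng,
        missing_rate=config.missing_rate,
        eggs_per_brood=config.eggs_per_brood,
    )
    growth = simulate_growth_records(config.growth, rng)
    return SimulatedDataset(
        adults=adults,
        broods=broods,
        matings=matings,
        true_genotypes=true,
        egg_sires=egg_sires,
        growth_records=growth,
        panel=panel,
        config=config,
        seed=seed,
    )


@dataclass(frozen=True)
class PreferenceFit:
    """Conditional-logit estimates of the mating-preference coefficients."""

    params: np.ndarray  # (b_size, b_claw_res[, delta_assort])
    se: np.ndarray
    names: tuple[str, ...]
    loglik: float

    def ci(self, level: float = 0.95) -> np.ndarray:
        from scipy import stats as _st

        zq = _st.norm.ppf(0.5 + level / 2)
        return np.column_stack([self.params - zq * self.se, self.params + zq * self.se])


def fit_preference(
    adults: list[Individual],
    matings: list[Mating],
    config: PopulationConfig,
    estimate_delta: bool = False,
) -> PreferenceFit:
    """Recover the generating preference coefficients by conditional logit.

    Each mating contributes the softmax likelihood of the primary sire
    among the female's area pool, exactly matching the generating choice
    model; this is the natural estimator for validating the generator.
    ``assort_sd`` is held at its configured value; ``delta_assort`` is
    estimated too when requested (ignored if the kernel is disabled).
    """
    from scipy.optimize import minimize
    from scipy.special import logsumexp
    from statsmodels.tools.numdiff import approx_hess

    males = [a for a in adults if a.sex == "M"]
    cl = np.array([m.cl for m in males])
    cw = np.array([m.cw for m in males], dtype=float)
    z_cl = (cl - cl.mean()) / cl.std(ddof=1)
    beta = np.polyfit(cl, cw, 1)
    res = cw - np.polyval(beta, cl)
    z_res = res / res.std(ddof=1)
    idx_of = {m.id: i for i, m in enumerate(males)}
    by_area: dict[str, np.ndarray] = {}
    for area in {m.area for m in males}:
        by_area[area] = np.array([i for i, m in enumerate(males) if m.area == area])
    mothers = {a.id: a for a in adults if a.sex == "F"}
    choice_sets = []
    for mating in matings:
        f = mothers[mating.mother_id]
        pool = by_area.get(f.area)
        if pool is None:
            continue
        chosen = idx_of[mating.sires[0]]
        pos = int(np.flatnonzero(pool == chosen)[0])
        choice_sets.append((pool, pos, f.cl))

    use_kernel = config.delta_assort is not None
    est_delta = estimate_delta and use_kernel

    def nll(theta: np.ndarray) -> float:
        b1, b2 = theta[0], theta[1]
        delta = theta[2] if est_delta else (config.delta_assort or 0.0)
        total = 0.0
        for pool, pos, fcl in choice_sets:
            logw = b1 * z_cl[pool] + b2 * z_res[pool]
            if use_kernel:
                shortfall = np.minimum(cl[pool] - delta * fcl, 0.0)
                logw = logw - 0.5 * (shortfall / config.assort_sd) ** 2
            total -= logw[pos] - logsumexp(logw)
        return total

    x0 = np.array([0.0, 0.0] + ([config.delta_assort] if est_delta else []))
    opt = minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-8})
    hess = approx_hess(opt.x, nll)
    cov = np.linalg.inv(hess)
    names = ("b_size", "b_claw_res") + (("delta_assort",) if est_delta else ())
    return PreferenceFit(
        params=opt.x,
        se=np.sqrt(np.maximum(np.diag(cov), 0.0)),
        names=names,
        loglik=-float(opt.fun),
    )


def error_free(config: PopulationConfig | None = None) -> PopulationConfig:
    """A copy of ``config`` suited to error-free runs (no missing data)."""
    config = config or PopulationConfig()
    return replace(config, missing_rate=0.0)
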