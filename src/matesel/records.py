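"""Core record types: individuals, broods, mark-recapture growth records.

Genotypes are per-locus ordered allele pairs of integer fragment lengths;
``0`` codes a missing allele (GenePop convention).  A locus with either
allele missing counts as a missing locus throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

Genotype = dict[str, tuple[int, int]]

MISSING: tuple[int, int] = (0, 0)


def is_missing(pair: tuple[int, int]) -> bool:
    """A locus is missing if either allele is uncalled (coded 0)."""
    return pair[0] == 0 or pair[1] == 0


def n_missing(genotype: Genotype) -> int:
    return sum(1 for pair in genotype.values() if is_missing(pair))


def sort_pair(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a <= b else (b, a)


@dataclass
class Individual:
    """An adult lobster: phenotype, metadata and multilocus genotype.

    ``cl`` is carapace length (mm); ``cw`` is crusher-claw width (mm),
    recorded for males only (None otherwise).
    """

    id: str
    sex: str  # "M" | "F"
    area: str  # "reserve" | "fished"
    year: int
    cl: float
    cw: float | None = None
    genotype: Genotype = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"{self.id}: sex must be 'M' or 'F'")
        if self.cl <= 0:
            raise ValueError(f"{self.id}: carapace length must be positive")


@dataclass
class Egg:
    """One sampled egg from a brood, with its observed genotype."""

    id: str
    genotype: Genotype = field(default_factory=dict)


@dataclass
class Brood:
    """A mother and her sampled eggs (ten per female by design)."""

    mother_id: str
    eggs: list[Egg] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.eggs)


@dataclass(frozen=True)
class GrowthRecord:
    """A male captured in two consecutive years: CL at both captures (mm)."""

    male_id: str
    cl_first: float
    cl_second: float

    def __post_init__(self) -> None:
        if self.cl_first <= 0 or self.cl_second <= 0:
            raise ValueError("carapace lengths must be positive")

    @property
    def delta(self) -> float:
        return self.cl_second - self.cl_first
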