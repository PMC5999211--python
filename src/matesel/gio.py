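"""Reading, writing and QC of genotype/phenotype tables.

Two on-disk dialects are supported: a tab-separated table with one row per
individual and two columns per locus, and GenePop (3-digit allele codes,
``POP`` blocks by area, missing = 000).  QC covers the missing-loci exclusion
rule (individuals untyped at five or more loci are dropped) and duplicate-
genotype detection, which flags re-sampled individuals after tag loss.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import pandas as pd

from .panel import LocusPanel
from .records import Brood, Egg, Genotype, GrowthRecord, Individual, is_missing, n_missing

__all__ = [
    "write_adults",
    "read_adults",
    "write_broods",
    "read_broods",
    "write_growth",
    "read_growth",
    "write_genepop",
    "read_genepop",
    "filter_missing",
    "find_duplicates",
    "resolve_duplicates",
]

_META_COLS = ["id", "sex", "area", "year", "cl", "cw"]


def _locus_cols(panel: LocusPanel) -> list[str]:
    return [f"{name}.{i}" for name in panel.names for i in (1, 2)]


def _genotype_row(genotype: Genotype, panel: LocusPanel) -> list[int]:
    row = []
    for name in panel.names:
        pair = genotype.get(name, (0, 0))
        row.extend(pair)
    return row


def _parse_genotype(row: pd.Series, panel: LocusPanel, line_no: int, errors: list[str]) -> Genotype:
    g: Genotype = {}
    for name in panel.names:
        try:
            a = int(row[f"{name}.1"])
            b = int(row[f"{name}.2"])
        except (KeyError, ValueError):
            errors.append(f"line {line_no}: malformed alleles at locus {name}")
            a = b = 0
        if a and b:
            locus = panel[name]
            for allele in (a, b):
                if allele not in locus.alleles:
                    errors.append(
                        f"line {line_no}: unknown allele {allele} at locus {name}"
                    )
        # a half-missing call is treated as a fully missing locus
        g[name] = (min(a, b), max(a, b)) if (a and b) else (0, 0)
    return g


def write_adults(adults: list[Individual], path: str | Path, panel: LocusPanel) -> None:
    rows = []
    for a in adults:
        rows.append(
            [a.id, a.sex, a.area, a.year, a.cl, "" if a.cw is None else a.cw]
            + _genotype_row(a.genotype, panel)
        )
    df = pd.DataFrame(rows, columns=_META_COLS + _locus_cols(panel))
    df.to_csv(path, sep="\t", index=False)


def read_adults(path: str | Path, panel: LocusPanel) -> list[Individual]:
    df = pd.read_csv(path, sep="\t")
    missing_cols = [c for c in _META_COLS[:5] + _locus_cols(panel) if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: header missing columns {missing_cols}")
    errors: list[str] = []
    adults = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        g = _parse_genotype(row, panel, line_no, errors)
        cw = row.get("cw")
        adults.append(
            Individual(
                id=str(row["id"]),
                sex=str(row["sex"]),
                area=str(row["area"]),
                year=int(row["year"]),
                cl=float(row["cl"]),
                cw=None if pd.isna(cw) else float(cw),
                genotype=g,
            )
        )
    if errors:
        raise ValueError("malformed rows:\n" + "\n".join(errors))
    return adults


def write_broods(broods: list[Brood], path: str | Path, panel: LocusPanel) -> None:
    rows = []
    for b in broods:
        for egg in b.eggs:
            rows.append([egg.id, b.mother_id] + _genotype_row(egg.genotype, panel))
    df = pd.DataFrame(rows, columns=["egg_id", "mother_id"] + _locus_cols(panel))
    df.to_csv(path, sep="\t", index=False)


def read_broods(path: str | Path, panel: LocusPanel) -> list[Brood]:
    df = pd.read_csv(path, sep="\t")
    errors: list[str] = []
    by_mother: dict[str, Brood] = {}
    for i, row in df.iterrows():
        g = _parse_genotype(row, panel, i + 2, errors)
        mother = str(row["mother_id"])
        by_mother.setdefault(mother, Brood(mother_id=mother)).eggs.append(
            Egg(id=str(row["egg_id"]), genotype=g)
        )
    if errors:
        raise ValueError("malformed rows:\n" + "\n".join(errors))
    return list(by_mother.values())


def write_growth(records: list[GrowthRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [[r.male_id, r.cl_first, r.cl_second] for r in records],
        columns=["male_id", "cl_first", "cl_second"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_growth(path: str | Path) -> list[GrowthRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        GrowthRecord(str(r.male_id), float(r.cl_first), float(r.cl_second))
        for r in df.itertuples()
    ]


def write_genepop(
    adults: list[Individual],
    path: str | Path,
    panel: LocusPanel,
    title: str = "matesel export",
) -> None:
    """GenePop export: 3-digit allele codes, one POP block per area."""
    for loc in panel:
        if any(a > 999 for a in loc.alleles):
            raise ValueError(f"{loc.name}: allele labels exceed 3-digit GenePop codes")
    lines = [title]
    lines.extend(panel.names)
    by_area: dict[str, list[Individual]] = {}
    for a in adults:
        by_area.setdefault(a.area, []).append(a)
    for area in sorted(by_area):
        lines.append("POP")
        for ind in by_area[area]:
            codes = []
            for name in panel.names:
                a1, a2 = ind.genotype.get(name, (0, 0))
                codes.append(f"{a1:03d}{a2:03d}")
            lines.append(f"{area}:{ind.id} ,  " + " ".join(codes))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(path: str | Path, panel: LocusPanel) -> list[Individual]:
    """Re-import a GenePop export (metadata other than area is not stored)."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2 + len(panel):
        raise ValueError(f"{path}: truncated GenePop file")
    locus_names = [ln.strip() for ln in lines[1 : 1 + len(panel)]]
    if locus_names != panel.names:
        raise ValueError(f"{path}: locus list does not match panel")
    adults = []
    pop_index = -1
    for line_no, line in enumerate(lines[1 + len(panel) :], start=2 + len(panel)):
        if line.strip().upper() == "POP":
            pop_index += 1
            continue
        if not line.strip():
            continue
        if pop_index < 0:
            raise ValueError(f"line {line_no}: genotype row before first POP")
        ident, _, geno = line.partition(",")
        ident = ident.strip()
        area, _, ind_id = ident.partition(":")
        codes = geno.split()
        if len(codes) != len(panel):
            raise ValueError(f"line {line_no}: expected {len(panel)} loci, got {len(codes)}")
        g: Genotype = {}
        for name, code in zip(panel.names, codes):
            if len(code) != 6 or not code.isdigit():
                raise ValueError(f"line {line_no}: bad allele code '{code}' at {name}")
            a, b = int(code[:3]), int(code[3:])
            g[name] = (0, 0) if (a == 0 or b == 0) else (min(a, b), max(a, b))
        adults.append(
            Individual(
                id=ind_id or ident,
                sex="M",
                area=area or f"pop{pop_index}",
                year=0,
                cl=1.0,
                genotype=g,
            )
        )
    return adults


def filter_missing(
    adults: list[Individual], max_missing: int = 5
) -> tuple[list[Individual], list[str]]:
    """Drop individuals untyped at ``max_missing`` or more loci.

    Returns (kept, removal log).  Idempotent.
    """
    kept, log = [], []
    for a in adults:
        nm = n_missing(a.genotype)
        if nm >= max_missing:
            log.append(f"{a.id}: excluded, missing at {nm} loci")
        else:
            kept.append(a)
    return kept, log


def _pair_mismatches(g1: Genotype, g2: Genotype) -> tuple[int, int]:
    """(number of compared loci, number of mismatching loci); missing skipped."""
    compared = mismatched = 0
    for name, p1 in g1.items():
        p2 = g2.get(name, (0, 0))
        if is_missing(p1) or is_missing(p2):
            continue
        compared += 1
        if p1 != p2:
            mismatched += 1
    return compared, mismatched


def find_duplicates(
    adults: list[Individual], max_mismatch: int = 0
) -> list[tuple[str, str]]:
    """All pairs whose genotypes agree at every compared locus up to
    ``max_mismatch`` mismatches.  Output sorted, each pair (id_a < id_b) once.
    """
    if len(adults) < 2:
        return []
    pairs = []
    for a, b in itertools.combinations(sorted(adults, key=lambda x: x.id), 2):
        compared, mismatched = _pair_mismatches(a.genotype, b.genotype)
        if compared > 0 and mismatched <= max_mismatch:
            pairs.append((a.id, b.id))
    return sorted(pairs)


def resolve_duplicates(
    adults: list[Individual], pairs: list[tuple[str, str]]
) -> list[Individual]:
    """Drop one member of each duplicate pair: keep the record with fewer
    missing loci, then the later capture year (the fresher sample)."""
    by_id = {a.id: a for a in adults}
    drop: set[str] = set()
    for ia, ib in pairs:
        a, b = by_id[ia], by_id[ib]
        key_a = (n_missing(a.genotype), -a.year)
        key_b = (n_missing(b.genotype), -b.year)
        drop.add(ib if key_a <= key_b else ia)
    return [a for a in adults if a.id not in drop]
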