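"""End-to-end pipeline: simulate → QC → assign → power → adjust → select.

`run_pipeline` executes every stage on one seeded synthetic dataset and
returns a report bundle of tables; `summarize_matings` produces the
bookkeeping table (assignment fractions, father counts, polygamy, multiple
paternity, interarea pairs) from assignment results, and is equally usable
on externally supplied tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gio, popgen, selection
from .growth import adjust_cl, fit_growth_model
from .panel import LocusPanel
from .parentage import (
    AssignmentResult,
    BroodPaternity,
    MatingRecord,
    assign_fathers,
    calibrate_confidence,
    classify_brood,
)
from .power import PowerConfig, prdm, sampling_bound
from .records import Individual
from .simulate import PopulationConfig, simulate_dataset

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "summarize_matings"]


@dataclass
class RunConfig:
    """Thresholds and replicate counts for one pipeline run.

    Defaults follow the field protocol: exclusion at >= 5 missing loci,
    5 mm moult detection, candidate males at >= 80 mm CL, 95% assignment
    confidence, and >= 5 mismatching loci to accept a second sire.
    """

    population: PopulationConfig = field(default_factory=PopulationConfig)
    seed: int = 0
    max_missing_loci: int = 5
    moult_threshold_mm: float = 5.0
    candidate_min_cl: float = 80.0
    confidence: float = 0.95
    min_mismatch_loci: int = 5
    sampled_father_fraction: float = 0.9
    calibration_reps: int = 400
    fst_permutations: int = 200
    power_reps: int = 2000
    hwe_mc_reps: int = 2000
    gradient_year: int | None = 2010
    duplicate_mismatch: int = 0


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def summarize_matings(
    assignments: list[AssignmentResult],
    matings: list[MatingRecord],
    candidates: list[Individual],
    mothers: dict[str, Individual],
    brood_classes: list[BroodPaternity] | None = None,
) -> dict:
    """Bookkeeping counts and percentages of the assignment stage.

    Every percentage is computed from the counts in the same structure, so
    report numbers are traceable: offspring assigned / offspring total,
    distinct fathers / candidates, per-area share of known matings,
    polygamous males, multiply-sired broods and interarea pairs.
    """
    cand_by_id = {c.id: c for c in candidates}
    areas = sorted({c.area for c in candidates} | {m.area for m in mothers.values()})
    per_area = {
        a: {
            "offspring_total": 0,
            "offspring_assigned": 0,
            "candidates": 0,
            "fathers": 0,
            "matings": 0,
            "polygamous_males": 0,
        }
        for a in areas
    }
    for a in assignments:
        area = mothers[a.mother_id].area
        per_area[area]["offspring_total"] += 1
        if a.father_id is not None:
            per_area[area]["offspring_assigned"] += 1
    for c in candidates:
        per_area[c.area]["candidates"] += 1
    fathers_by_area: dict[str, set[str]] = {a: set() for a in areas}
    mates_per_father: dict[str, set[str]] = {}
    interarea = 0
    for m in matings:
        father = cand_by_id.get(m.father_id)
        area = father.area if father else mothers[m.mother_id].area
        per_area[area]["matings"] += 1
        fathers_by_area[area].add(m.father_id)
        mates_per_father.setdefault(m.father_id, set()).add(m.mother_id)
        if father is not None and father.area != mothers[m.mother_id].area:
            interarea += 1
    for a in areas:
        per_area[a]["fathers"] = len(fathers_by_area[a])
        per_area[a]["polygamous_males"] = sum(
            1
            for f in fathers_by_area[a]
            if len(mates_per_father.get(f, ())) > 1
        )
    table = pd.DataFrame(per_area).T
    table.index.name = "area"

    total_offspring = int(table["offspring_total"].sum())
    total_assigned = int(table["offspring_assigned"].sum())
    total_candidates = int(table["candidates"].sum())
    distinct_fathers = len(mates_per_father)
    total_matings = int(table["matings"].sum())
    n_broods = len({a.mother_id for a in assignments})
    n_multiple = (
        sum(1 for b in brood_classes if b.classification == "multiple")
        if brood_classes is not None
        else None
    )

    def pct(num, den):
        return 100.0 * num / den if den else 0.0

    summary = {
        "offspring_total": total_offspring,
        "offspring_assigned": total_assigned,
        "pct_assigned": pct(total_assigned, total_offspring),
        "candidates": total_candidates,
        "distinct_fathers": distinct_fathers,
        "pct_fathers": pct(distinct_fathers, total_candidates),
        "matings": total_matings,
        "pct_matings_by_area": {
            a: pct(per_area[a]["matings"], total_matings) for a in areas
        },
        "polygamous_males": int(table["polygamous_males"].sum()),
        "broods": n_broods,
        "interarea_pairs": interarea,
    }
    if n_multiple is not None:
        summary["multiple_broods"] = n_multiple
        summary["pct_multiple_broods"] = pct(n_multiple, n_broods)
    return {"per_area": table, "summary": summary}


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # abort with the stage name
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig | None = None, out_dir: str | Path | None = None) -> dict:
    """Run every stage on one seeded synthetic dataset.

    Returns a report dict; when ``out_dir`` is given, intermediate tables
    are written there as TSV as each stage completes, so a failing stage
    leaves partial outputs behind.  Re-running with the same config is
    reproducible (single seed feeds every stage).
    """
    config = config or RunConfig()
    report: dict = {"seed": config.seed}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def emit(name: str, df: pd.DataFrame) -> None:
        if out is not None:
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)

    rng = np.random.default_rng(config.seed + 1)

    @_stage("simulate")
    def stage_simulate():
        return simulate_dataset(config.population, seed=config.seed)

    ds = stage_simulate()
    panel: LocusPanel = ds.panel
    if out is not None:
        gio.write_adults(ds.adults, out / "adults.tsv", panel)
        gio.write_broods(ds.broods, out / "broods.tsv", panel)
        gio.write_growth(ds.growth_records, out / "growth.tsv")

    @_stage("qc")
    def stage_qc():
        adults, removal_log = gio.filter_missing(ds.adults, config.max_missing_loci)
        dup_pairs = gio.find_duplicates(adults, config.duplicate_mismatch)
        adults = gio.resolve_duplicates(adults, dup_pairs)
        summaries = popgen.locus_summaries(
            adults, panel, mc_reps=config.hwe_mc_reps, rng=rng
        )
        areas = sorted({a.area for a in adults})
        fst = None
        if len(areas) == 2:
            ga = [a for a in adults if a.area == areas[0]]
            gb = [a for a in adults if a.area == areas[1]]
            if len(ga) >= 2 and len(gb) >= 2:
                fst = popgen.pairwise_fst(
                    ga, gb, panel, permutations=config.fst_permutations,
                    rng=rng, labels=(areas[0], areas[1]),
                )
        t, p = popgen.fis_t_test(summaries)
        return adults, removal_log, dup_pairs, summaries, fst, (t, p)

    adults, removal_log, dup_pairs, summaries, fst, fis_test = stage_qc()
    report["qc"] = {
        "locus_summaries": summaries,
        "removed_missing": removal_log,
        "duplicates": dup_pairs,
        "fst": fst,
        "fis_t_test": fis_test,
        "combined_exclusion": popgen.combined_exclusion(summaries["exp"].dropna()),
    }
    emit("locus_summaries", summaries)

    @_stage("assign")
    def stage_assign():
        males = [a for a in adults if a.sex == "M"]
        mothers = {a.id: a for a in adults if a.sex == "F"}
        broods = [b for b in ds.broods if b.mother_id in mothers]
        threshold = calibrate_confidence(
            panel,
            pool_size=min(len(males), 200),
            sampled_fraction=config.sampled_father_fraction,
            reps=config.calibration_reps,
            seed=config.seed + 2,
            confidence=config.confidence,
            missing_rate=config.population.missing_rate,
        )
        assignments, matings = assign_fathers(broods, mothers, males, panel, threshold)
        cand_by_id = {m.id: m for m in males}
        classes = [
            classify_brood(
                b, mothers[b.mother_id], cand_by_id, assignments, panel,
                min_mismatch_loci=config.min_mismatch_loci,
            )
            for b in broods
        ]
        return males, mothers, broods, threshold, assignments, matings, classes

    males, mothers, broods, threshold, assignments, matings, classes = stage_assign()
    assignment_df = pd.DataFrame(
        {
            "egg_id": [a.egg_id for a in assignments],
            "mother_id": [a.mother_id for a in assignments],
            "father_id": [a.father_id or "" for a in assignments],
            "llr": [a.llr for a in assignments],
            "delta": [a.delta for a in assignments],
            "mismatches": [a.mismatches for a in assignments],
            "confident": [a.confident for a in assignments],
        }
    )
    emit("assignments", assignment_df)
    report["assignment"] = {
        "threshold": threshold,
        "assignments": assignments,
        "matings": matings,
        "brood_classes": classes,
    }

    @_stage("summarize")
    def stage_summarize():
        return summarize_matings(assignments, matings, males, mothers, classes)

    report["mating_summary"] = stage_summarize()
    if out is not None:
        report["mating_summary"]["per_area"].to_csv(out / "mating_summary.tsv", sep="\t")

    @_stage("power")
    def stage_power():
        rows = []
        for skew in ((0.5, 0.5), tuple(config.population.skew)):
            res = prdm(
                PowerConfig(
                    panel=panel,
                    brood_size=config.population.eggs_per_brood,
                    contributions=skew,
                    replicates=config.power_reps,
                    seed=config.seed + 3,
                )
            )
            rows.append(
                {
                    "skew": ":".join(f"{c:g}" for c in skew),
                    "prdm": res.estimate,
                    "se": res.se,
                    "sampling_bound": sampling_bound(skew, config.population.eggs_per_brood),
                }
            )
        return pd.DataFrame(rows)

    power_table = stage_power()
    emit("power", power_table)
    report["power"] = power_table

    @_stage("growth")
    def stage_growth():
        model = fit_growth_model(ds.growth_records, config.moult_threshold_mm)
        male_by_id = {m.id: m for m in males}
        pairs = []
        for m in matings:
            male = male_by_id.get(m.father_id)
            if male is None:
                continue
            mother = mothers[m.mother_id]
            pairs.append(
                selection.MatedPair(
                    mother_id=m.mother_id,
                    father_id=m.father_id,
                    female_cl=mother.cl,
                    male_cl_adjusted=adjust_cl(male, mother.year, model),
                    male_cw=male.cw,
                    female_area=mother.area,
                    male_area=male.area,
                    year=mother.year,
                )
            )
        return model, pairs

    growth_model, mated_pairs = stage_growth()
    pairs_df = selection.pairs_frame(mated_pairs, drop_interarea=True)
    emit("pairs", pairs_df)
    report["growth_model"] = growth_model
    report["pairs"] = pairs_df

    @_stage("select")
    def stage_select():
        father_ids = {m.father_id for m in matings}
        cand = [m for m in males if m.cl >= config.candidate_min_cl]
        mdf = pd.DataFrame(
            {
                "id": [m.id for m in cand],
                "area": [m.area for m in cand],
                "year": [m.year for m in cand],
                "cl": [m.cl for m in cand],
                "cw": [m.cw for m in cand],
                "success": [int(m.id in father_ids) for m in cand],
            }
        )
        mdf["cw_res"] = selection.residual_claw(mdf["cw"], mdf["cl"])
        # differentials per area (years pooled), standardized within area
        diff_rows = []
        for area, sub in mdf.groupby("area"):
            if sub["cl"].nunique() < 2 or len(sub) < 3:
                continue
            for trait, col in (("CL", "cl"), ("CW", "cw")):
                z = selection.standardize(sub[col])
                s, p = selection.selection_differential(z, sub["success"].astype(bool))
                diff_rows.append({"area": area, "trait": trait, "s": s, "p": p})
        differentials = pd.DataFrame(diff_rows)

        # gradients on the focal cohort
        sub = mdf if config.gradient_year is None else mdf[mdf["year"] == config.gradient_year]
        gradient_tables = None
        if len(sub) >= 20 and sub["success"].sum() >= 3:
            sub = sub.copy()
            sub["z_cl"] = selection.standardize(sub["cl"], sub["area"])
            sub["z_cw"] = selection.standardize(sub["cw"], sub["area"])
            sub["z_cwres"] = selection.standardize(sub["cw_res"], sub["area"])
            ranking, fits = selection.fit_selection_models(sub)
            grad_rows = []
            for model_name, traits in (
                ("CL + CW_res", ["CW_res", "CL"]),
                ("CL", ["CL"]),
                ("CW", ["CW"]),
                ("CW_res", ["CW_res"]),
            ):
                fit = fits.get(model_name)
                if fit is None:
                    continue
                grads = selection.janzen_stern_gradient(fit)
                order = (
                    ["z_cl", "z_cwres"] if model_name == "CL + CW_res" else None
                )
                for j, trait in enumerate(traits):
                    col = {"CL": "z_cl", "CW": "z_cw", "CW_res": "z_cwres"}[trait]
                    idx = order.index(col) if order else 0
                    raw = {"CL": "cl", "CW": "cw", "CW_res": "cw_res"}[trait]
                    beta = float(np.asarray(fit.params)[idx + 1])
                    row = {
                        "model": model_name,
                        "trait": trait,
                        "beta": beta,
                        "se": float(np.asarray(fit.bse)[idx + 1]),
                        "beta_avggrad": float(np.asarray(grads)[idx]),
                    }
                    if trait in ("CL", "CW"):
                        row["beta_mu"] = selection.mean_standardized_gradient(
                            row["beta_avggrad"],
                            float(sub[raw].mean()),
                            float(sub[raw].std(ddof=1)),
                            trait,
                        )
                    grad_rows.append(row)
            gradient_tables = {"ranking": ranking, "gradients": pd.DataFrame(grad_rows)}

        assortative = None
        gaps = {}
        if len(pairs_df) >= 6 and pairs_df["area"].nunique() >= 1:
            try:
                assortative = selection.assortative_model(pairs_df)
            except ValueError:
                assortative = None
            for area in pairs_df["area"].unique():
                if (pairs_df["area"] == area).sum() >= 2:
                    gaps[area] = selection.pair_size_gap(pairs_df, area)
        return mdf, differentials, gradient_tables, assortative, gaps

    mdf, differentials, gradient_tables, assortative, gaps = stage_select()
    emit("differentials", differentials)
    if gradient_tables is not None:
        emit("model_ranking", gradient_tables["ranking"])
        emit("gradients", gradient_tables["gradients"])
    report["selection"] = {
        "males": mdf,
        "differentials": differentials,
        "gradients": gradient_tables,
        "assortative": assortative,
        "pair_gaps": gaps,
    }
    return report
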