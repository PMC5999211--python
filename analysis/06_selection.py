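"""Selection differentials, logistic selection models, gradients and the
size-assortative mating model."""

import numpy as np
import pandas as pd
from common import DATA, RESULTS

from matesel import gio, selection
from matesel.growth import GrowthModel, adjust_cl
from matesel.panel import reference_panel

GRADIENT_YEAR = 2010
MIN_CL = 80.0


def main() -> None:
    panel = reference_panel()
    adults, _ = gio.filter_missing(gio.read_adults(DATA / "adults.tsv", panel))
    males = {a.id: a for a in adults if a.sex == "M"}
    mothers = {a.id: a for a in adults if a.sex == "F"}
    matings = pd.read_csv(RESULTS / "03_parentage" / "matings.tsv", sep="\t")
    model = GrowthModel.from_text(RESULTS / "05_growth" / "growth_model.txt")

    pairs = []
    for row in matings.itertuples():
        male = males.get(row.father_id)
        mother = mothers.get(row.mother_id)
        if male is None or mother is None:
            continue
        pairs.append(
            selection.MatedPair(
                mother_id=row.mother_id, father_id=row.father_id,
                female_cl=mother.cl,
                male_cl_adjusted=adjust_cl(male, mother.year, model),
                male_cw=male.cw, female_area=mother.area, male_area=male.area,
                year=mother.year,
            )
        )
    pairs_df = selection.pairs_frame(pairs)

    father_ids = set(matings["father_id"])
    cand = [m for m in males.values() if m.cl >= MIN_CL]
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

    diff_rows = []
    for area, sub in mdf.groupby("area"):
        for trait, col in (("CL", "cl"), ("CW", "cw"), ("CW_res", "cw_res")):
            z = selection.standardize(sub[col])
            s, p = selection.selection_differential(z, sub["success"].astype(bool))
            diff_rows.append({"area": area, "trait": trait, "s": s, "p": p})
    differentials = pd.DataFrame(diff_rows)

    cohort = mdf[mdf["year"] == GRADIENT_YEAR].copy()
    cohort["z_cl"] = selection.standardize(cohort["cl"], cohort["area"])
    cohort["z_cw"] = selection.standardize(cohort["cw"], cohort["area"])
    cohort["z_cwres"] = selection.standardize(cohort["cw_res"], cohort["area"])
    ranking, fits = selection.fit_selection_models(cohort)
    grad_rows = []
    for model_name, cols in (("CL", ["z_cl"]), ("CW", ["z_cw"]),
                             ("CW_res", ["z_cwres"])):
        fit = fits.get(model_name)
        if fit is None:
            continue
        grad = selection.janzen_stern_gradient(fit, coef_index=0)
        row = {
            "model": model_name,
            "beta": float(np.asarray(fit.params)[1]),
            "se": float(np.asarray(fit.bse)[1]),
            "beta_avggrad": grad,
        }
        raw = {"CL": "cl", "CW": "cw"}.get(model_name)
        if raw:
            row["beta_mu"] = selection.mean_standardized_gradient(
                grad, float(cohort[raw].mean()), float(cohort[raw].std(ddof=1)),
                model_name,
            )
        grad_rows.append(row)

    assort = selection.assortative_model(pairs_df)
    gap_rows = []
    for area in ("reserve", "fished"):
        gap, t, p = selection.pair_size_gap(pairs_df, area)
        gap_rows.append({"area": area, "gap_pct": gap, "t": t, "p": p})

    out = RESULTS / "06_selection"
    out.mkdir(parents=True, exist_ok=True)
    pairs_df.to_csv(out / "pairs.tsv", sep="\t", index=False)
    differentials.to_csv(out / "differentials.tsv", sep="\t", index=False)
    ranking.to_csv(out / "model_ranking.tsv", sep="\t", index=False)
    pd.DataFrame(grad_rows).to_csv(out / "gradients.tsv", sep="\t", index=False)
    pd.DataFrame(gap_rows).to_csv(out / "pair_gaps.tsv", sep="\t", index=False)
    with open(out / "assortative.txt", "w") as fh:
        fh.write(
            f"slope {assort.slope:.3f} (SE {assort.slope_se:.3f}), "
            f"area effect {assort.area_effect:.2f} mm, R^2 {assort.r_squared:.3f}, "
            f"interaction LRT chi2 {assort.lrt_chi2:.2f} p {assort.lrt_p:.3f}, "
            f"n {assort.n}\n"
        )
    print("differentials:\n", differentials.to_string(index=False))
    print("model ranking (top 5):\n", ranking.head(5).to_string(index=False))
    print("gradients:\n", pd.DataFrame(grad_rows).to_string(index=False))
    print(
        f"assortative: slope {assort.slope:.3f} +- {assort.slope_se:.3f}, "
        f"area effect {assort.area_effect:.2f} mm, R2 {assort.r_squared:.3f}"
    )
    print("pair gaps:\n", pd.DataFrame(gap_rows).to_string(index=False))


if __name__ == "__main__":
    main()
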