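"""Paternity assignment, brood classification and mating bookkeeping."""

import json

import pandas as pd
from common import DATA, RESULTS, SEED

from matesel import gio
from matesel.panel import reference_panel
from matesel.parentage import assign_fathers, calibrate_confidence, classify_brood
from matesel.pipeline import summarize_matings


def main() -> None:
    panel = reference_panel()
    adults, _ = gio.filter_missing(gio.read_adults(DATA / "adults.tsv", panel))
    broods = gio.read_broods(DATA / "broods.tsv", panel)
    males = [a for a in adults if a.sex == "M"]
    mothers = {a.id: a for a in adults if a.sex == "F"}
    broods = [b for b in broods if b.mother_id in mothers]

    threshold = calibrate_confidence(
        panel, pool_size=200, sampled_fraction=0.9, reps=400,
        seed=SEED + 2, confidence=0.95, missing_rate=0.01,
    )
    assignments, matings = assign_fathers(broods, mothers, males, panel, threshold)
    cand_by_id = {m.id: m for m in males}
    classes = [
        classify_brood(b, mothers[b.mother_id], cand_by_id, assignments, panel)
        for b in broods
    ]
    summary = summarize_matings(assignments, matings, males, mothers, classes)

    out = RESULTS / "03_parentage"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "egg_id": [a.egg_id for a in assignments],
            "mother_id": [a.mother_id for a in assignments],
            "father_id": [a.father_id or "" for a in assignments],
            "llr": [a.llr for a in assignments],
            "delta": [a.delta for a in assignments],
            "confident": [a.confident for a in assignments],
        }
    ).to_csv(out / "assignments.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "mother_id": [m.mother_id for m in matings],
            "father_id": [m.father_id for m in matings],
            "n_eggs": [m.n_eggs for m in matings],
        }
    ).to_csv(out / "matings.tsv", sep="\t", index=False)
    summary["per_area"].to_csv(out / "mating_summary.tsv", sep="\t")
    (out / "summary.json").write_text(json.dumps(summary["summary"], indent=2) + "\n")
    s = summary["summary"]
    print(
        f"Delta threshold {threshold:.2f}; assigned "
        f"{s['offspring_assigned']}/{s['offspring_total']} eggs "
        f"({s['pct_assigned']:.1f}%); {s['distinct_fathers']} fathers of "
        f"{s['candidates']} candidates ({s['pct_fathers']:.1f}%); "
        f"{s['matings']} matings; {s['multiple_broods']}/{s['broods']} "
        f"multiply-sired broods ({s['pct_multiple_broods']:.1f}%)"
    )


if __name__ == "__main__":
    main()
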