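"""Genotype QC and population genetics on the adult sample."""

import numpy as np
from common import DATA, RESULTS, SEED

from matesel import gio, popgen
from matesel.panel import reference_panel


def main() -> None:
    panel = reference_panel()
    adults = gio.read_adults(DATA / "adults.tsv", panel)
    kept, removal_log = gio.filter_missing(adults, max_missing=5)
    dup_pairs = gio.find_duplicates(kept)
    kept = gio.resolve_duplicates(kept, dup_pairs)

    rng = np.random.default_rng(SEED + 100)
    summaries = popgen.locus_summaries(kept, panel, mc_reps=5000, rng=rng)
    reserve = [a for a in kept if a.area == "reserve"]
    fished = [a for a in kept if a.area == "fished"]
    fst = popgen.pairwise_fst(
        reserve, fished, panel, permutations=500, rng=rng,
        labels=("reserve", "fished"),
    )
    t, p = popgen.fis_t_test(summaries)

    out = RESULTS / "02_popgen"
    out.mkdir(parents=True, exist_ok=True)
    summaries.to_csv(out / "locus_summaries.tsv", sep="\t", index=False)
    lines = [
        f"individuals read: {len(adults)}",
        f"removed for missing loci: {len(removal_log)}",
        f"duplicate pairs resolved: {len(dup_pairs)}",
        f"individuals analysed: {len(kept)}",
        f"combined exclusion: {popgen.combined_exclusion(summaries['exp']):.4f}",
        f"pairwise Fst (reserve vs fished): theta={fst.theta:.4f} p={fst.p_value:.3f}",
        f"mean F_IS t-test vs 0: t={t:.3f} p={p:.3f}",
    ]
    (out / "qc_log.txt").write_text("\n".join(lines) + "\n")
    print("\n".join(lines))


if __name__ == "__main__":
    main()
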