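"""Fit the moult-probability and growth-increment models."""

from common import DATA, RESULTS

from matesel import gio
from matesel.growth import fit_growth_model


def main() -> None:
    records = gio.read_growth(DATA / "growth.tsv")
    model = fit_growth_model(records)
    out = RESULTS / "05_growth"
    out.mkdir(parents=True, exist_ok=True)
    model.to_text(out / "growth_model.txt")
    print(
        f"n={model.n_records}; moult logit: {model.moult_intercept:.3f} "
        f"{model.moult_slope:+.4f}*CL (SE {model.moult_se[0]:.3f}, "
        f"{model.moult_se[1]:.4f}); increment: {model.growth_intercept:.2f} "
        f"{model.growth_slope:+.4f}*CL mm/moult"
    )
    for cl in (80, 90, 100, 113):
        print(f"  p_moult({cl} mm) = {model.p_moult(float(cl)):.3f}")


if __name__ == "__main__":
    main()
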