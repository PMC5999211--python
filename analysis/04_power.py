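"""Multiple-paternity detection power (prDM) over contribution skews."""

from common import RESULTS, SEED

from matesel.panel import reference_panel
from matesel.power import skew_table


def main() -> None:
    panel = reference_panel(with_errors=False)
    table = skew_table(
        panel,
        brood_sizes=[5, 10],
        skews=[(0.5, 0.5), (0.7, 0.3), (0.9, 0.1), (1 / 3, 1 / 3, 1 / 3)],
        replicates=10_000,
        seed=SEED + 3,
    )
    out = RESULTS / "04_power"
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "power.tsv", sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
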