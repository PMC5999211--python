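"""Generate the study dataset: adults, broods, growth records, GenePop export."""

from common import DATA, SEED

from matesel import gio
from matesel.simulate import PopulationConfig, simulate_dataset


def main() -> None:
    ds = simulate_dataset(PopulationConfig(), seed=SEED)
    DATA.mkdir(parents=True, exist_ok=True)
    gio.write_adults(ds.adults, DATA / "adults.tsv", ds.panel)
    gio.write_broods(ds.broods, DATA / "broods.tsv", ds.panel)
    gio.write_growth(ds.growth_records, DATA / "growth.tsv")
    gio.write_genepop(ds.adults, DATA / "adults.genepop", ds.panel)
    (DATA / "seed.txt").write_text(f"{SEED}\n")
    print(
        f"wrote {len(ds.adults)} adults ({len(ds.males)} M / {len(ds.females)} F), "
        f"{len(ds.broods)} broods, {len(ds.growth_records)} growth records"
    )


if __name__ == "__main__":
    main()
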