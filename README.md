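# matesel

Parentage-based analysis of mating patterns and sexual selection in a
harvested European lobster (*Homarus gammarus*) population.

Lobsters are harvested above a legal size, which truncates the male size
distribution on fished grounds while marine reserves keep the natural size
structure intact. Because female lobsters prefer large-clawed, large-bodied
mates, harvest is expected to weaken sexual selection on male size and
shrink the size gap between mated males and their females. `matesel`
implements the full inferential chain needed to study this from genetic
data:

* **Synthetic population generator** — adults in two areas ("reserve" with an
  intact size structure, "fished" with a truncated one), preference-driven
  mating, Mendelian egg genotypes under a realistic genotyping-error model
  (allelic dropout, false alleles, missing calls), and mark–recapture growth
  records.
* **Genotype I/O and QC** — TSV and GenePop formats, missing-loci exclusion,
  duplicate-genotype detection.
* **Population genetics** — per-locus diversity, Hardy–Weinberg exact tests
  (full enumeration with Monte-Carlo fallback), Weir–Cockerham F-statistics
  with permutation tests, genotypic linkage disequilibrium, null-allele
  estimation, Benjamini–Hochberg correction, and second-parent (known
  mother) exclusion probabilities.
* **Paternity assignment** — error-aware trio likelihoods, simulation-
  calibrated Δ confidence thresholds (95% precision), conservative
  multiple-paternity classification of broods.
* **Detection power (prDM)** — Monte-Carlo probability of detecting multiple
  paternity for a brood, with the analytic sampling bound as cross-check.
* **Growth back-adjustment** — moult-probability logistic and growth-
  increment regressions from mark–recapture records, used to express male
  size in the mating year.
* **Selection analysis** — standardized selection differentials, a ranked
  set of logistic selection models (AICc), Janzen–Stern selection gradients
  (β_avggrad, β_μ), and the size-assortative mating model with area effects.

## Worked example

The bundled 10-locus panel reproduces the published per-locus second-parent
exclusion probabilities; combined they give near-certain exclusion of a
random non-father when the mother is known:

```python
>>> from matesel.panel import HGAMMARUS_EXP
>>> from matesel.popgen import combined_exclusion
>>> round(combined_exclusion(HGAMMARUS_EXP.values()), 4)
0.9998
```

Multiple-paternity detection power for a 10-egg brood on the same panel
(`matesel prdm --n 10 --skew 9:1 --reps 10000`):

| sire contributions | prDM (10,000 reps) | analytic sampling bound |
| ------------------ | ------------------ | ----------------------- |
| 5:5                | 99.8%              | 99.8%                   |
| 9:1                | 65.5%              | 65.1%                   |

With two equally contributing sires a brood of ten is essentially always
detectably multi-sired; at 9:1 skew the minor sire is often simply absent
from the ten sampled eggs, so power drops to the sampling bound.

Running the full pipeline on one synthetic dataset (seed 1, default
configuration; `python analysis/01_simulate.py` … `06_selection.py`) gives:

* 658 adults (561 candidate males, 97 ovigerous females), 97 broods of 10
  eggs; combined exclusion from sample allele frequencies 0.9997; pairwise
  F<sub>ST</sub> between areas −0.0002 (p = 0.71).
* Calibrated Δ threshold 2.26; 629/970 eggs assigned a father (64.8%);
  78 of 561 candidates (13.9%) fathered offspring in 109 inferred matings.
* Moult logistic 11.9 − 0.096·CL (p_moult ≈ 0.99 at 80 mm, 0.75 at 113 mm);
  growth increment 11.8 − 0.038·CL mm per moult.
* Standardized selection differentials on male carapace length:
  S = 0.60 (reserve) vs 0.43 (fished); the best-supported selection model by
  AICc is carapace length + residual claw width.
* Size-assortative mating: male size increases with female size
  (slope 0.28 ± 0.13) with a +17.4 mm reserve area effect; mated males
  exceed their females by 25.7% (reserve) vs 11.0% (fished).

Numbers for stochastic steps vary slightly with the seed; the qualitative
contrasts (stronger selection and larger pair gaps in the reserve) are
stable and are enforced by the acceptance tests.

## Command-line interface

```sh
matesel simulate --seed 1 --out data/       # generate a synthetic dataset
matesel prdm --n 10 --skew 9:1 --reps 10000 # detection power
matesel run --seed 1 --out run/             # full pipeline, TSV outputs
```

`--config cfg.yaml` overrides the population configuration (group sizes and
size distributions, preference coefficients, error rates, …).

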