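# Methods

This note documents the statistical models implemented in `matesel`, the
design of the synthetic population generator, the numerical choices made,
and the known limits of both.

## 1. Locus panels

A `LocusPanel` holds, per microsatellite locus, the allele labels,
population allele frequencies and two genotyping-error rates: `e1`, the
allelic-dropout rate (a heterozygote scored as a homozygote for one of its
alleles, chosen uniformly), and `e2`, the per-allele false-allele rate (the
scored allele replaced by a random allele drawn from the panel
frequencies).

The bundled reference panel reproduces a published 10-locus description of
the study system: for each locus the allele count N_a and expected
heterozygosity H_E are published, but the raw allele frequencies are not.
`matched_locus` therefore builds synthetic frequencies as a geometric
series p_i ∝ r^i whose ratio r is tuned by bisection until
1 − Σ p_i² equals the published H_E (within 5·10⁻⁴). H_E is strictly
increasing in r with supremum 1 − 1/k at the equifrequent limit, so the
bisection is well posed whenever the target is attainable. This matching
preserves the two quantities that drive exclusion and detection power
(allele count and heterozygosity) while the detailed frequency spectrum
remains synthetic.

## 2. Second-parent exclusion probability

With the mother known, an offspring's paternal allele is deducible up to
the usual ambiguity (when the egg carries both maternal alleles). For a
mother with ordered genotype (i, j) transmitting i and a true paternal
allele c, the deducible paternal set is {c} if c is not maternal, {i, c}
if c = j, and {i} if c = i; a random male is excluded when neither of his
alleles intersects that set. `exclusion_probability` enumerates this in
O(k³) per locus; the test suite checks it exactly against an O(k⁶)
brute-force enumeration. Loci combine as EXP = 1 − Π(1 − EXP_l).

## 3. Population genetics

* **Hardy–Weinberg**: the exact conditional test sums Levene probabilities
  over all genotype arrays with the observed allele-count margins. Arrays
  are enumerated recursively (capped at 200,000); beyond the cap the test
  falls back to Monte-Carlo re-pairing of the observed allele copies. The
  p-value is the total probability of arrays no more probable than the
  observed one (ties included, tolerance 10⁻⁹ in log space).
* **F-statistics**: Weir–Cockerham variance components a, b, c per allele,
  summed over alleles and loci; θ = Σa / Σ(a+b+c). The within-sample
  inbreeding coefficient uses the single-sample components,
  f = 1 − c/(b+c). Pairwise θ significance comes from permuting
  individuals across group labels; p = (hits + 1)/(permutations + 1).
* **Linkage disequilibrium**: G-test on the two-locus genotype contingency
  table with a permutation null (one locus's genotypes shuffled across
  individuals).
* **Null alleles**: Chakraborty moment estimator (H_E − H_O)/(H_E + H_O),
  with unbiased H_E = (2n/(2n−1))(1 − Σ p̂²).
* **Multiple testing**: Benjamini–Hochberg step-up, implemented directly
  and cross-checked against `statsmodels` in the tests.

## 4. Paternity assignment

Each egg is scored against every candidate male with a multilocus
log-likelihood ratio: P(egg observation | mother, candidate) over
P(egg observation | mother, random father from panel frequencies). The
observation model integrates allelic dropout and false alleles over the
possible true egg genotypes — the same layer the generator applies — so a
single-locus mismatch does not exclude a candidate when the error rates
can explain it. Missing loci contribute zero. With all error rates zero
the likelihood degenerates to Mendelian exclusion (−∞ for incompatible
candidates).

Confidence follows a Δ-calibration: the difference between the best and
second-best candidate's log-likelihood must exceed a threshold chosen by
simulation (eggs with known true fathers inside/outside the candidate
pool at the assumed sampled fraction) such that accepted assignments are
at least 95% correct. Assignments are refused outright when the egg
mismatches its mother at any locus.

Broods are classified single- or multiply-sired conservatively: a second
sire is accepted only when some egg is fully mother-compatible and
mismatches the primary sire at five or more fully observed loci; eggs
mismatching at one to four loci leave the brood "ambiguous".

## 5. Multiple-paternity detection power (prDM)

Detection uses the error-free Mendelian criterion: at some locus, no two
alleles can jointly cover the deduced paternal allele set of every egg.
Because loci are independent, the per-locus check suffices. The hitting-
set question is answered by enumerating candidate father genotypes over
the union of deduced alleles (forced singletons first). The Monte-Carlo
estimate draws mother and sires from panel frequencies, assigns eggs to
sires multinomially by the contribution vector, and reports the detected
fraction; its analytic ceiling is the sampling bound 1 − Σ c_k^n (the
minor sire must appear among the n sampled eggs at all). The brute-force
father enumeration doubles as the test oracle.

## 6. Growth back-adjustment

Males are captured in seasons before the females' brood sampling, so male
size is expressed in the female's year by
CL_adj = CL_meas + (Year_f − Year_m) · g(CL) · p_moult(CL), evaluated once
at the measured size. p_moult is a logistic regression of moult occurrence
on CL from records of males measured in two consecutive years, with a
moult inferred when the difference is ≥ 5 mm (smaller differences are
treated as measurement error; shrinkage beyond −5 mm flags a suspect
record, which is excluded). g(CL) is the OLS regression of the increment
on CL over the moulted subset. Complete separation in the logistic fit
falls back to a ridge-penalised fit and sets a flag. The single-step
evaluation (rather than iterating moult by moult) is a deliberate
simplification; over the 1–2 year gaps in the data the difference is
small relative to the increment noise.

## 7. Selection analysis

* **Differentials**: S = mean standardized trait of successful fathers
  minus all candidate males (candidates filtered to CL ≥ 80 mm, a maturity
  proxy), with Welch t-tests; standardization is within group.
* **Models**: logistic regressions of mating success on standardized CL,
  CW and residual claw width (OLS residuals of CW on CL), with and without
  area main effects and interactions plus quadratic variants, ranked by
  AICc = AIC + 2p(p+1)/(n−p−1). Non-converged models are flagged and
  ranked last.
* **Gradients**: Janzen–Stern transformation
  β_avggrad = b · mean[ŵ(1−ŵ)] / w̄ of the logistic coefficients, and the
  mean-standardized form β_μ = β_avggrad · mean/SD for absolute traits
  (undefined for residual claw size, which has no natural zero). In the
  weak-selection limit β_avggrad converges to the OLS regression of
  relative fitness on the trait, which the tests verify numerically.
* **Assortative mating**: OLS of male adjusted CL on female CL with an
  additive area term, tested against the interaction model by a 1-df
  likelihood ratio; plus the mean within-pair relative size gap
  (male − female)/female per area. Inter-area mother–father pairs are
  excluded from pair-level analyses.

## 8. Synthetic population generator

Group sizes and size distributions (normal, truncated at zero) are
configured per area × sex; the defaults describe the observed, post-harvest
population, so no additional harvest truncation is applied by default
(`harvest_prob` exists for experiments that remove large fished males
explicitly). Male claw width follows a linear allometry on CL with normal
residuals.

Mating: each female draws her sire(s) from her area's males with
probability proportional to
exp(b_size·z_CL + b_claw_res·z_CWres) · K(CL_male; CL_female), where the
preference z-scores are standardized over the **whole** male population.
This is the mechanism behind the area contrast: the per-SD preference
coefficients express more weakly in an area whose trait variance harvest
has truncated. K is a **one-sided** half-Gaussian kernel on the male-size
shortfall below the preferred size δ·CL_female (scale in mm): males
smaller than the preferred size are penalised, males at or above it are
not discriminated further. The one-sided form reflects sperm-limitation
logic (a female avoids males too small to fertilise her clutch, gains
little above that) and is what lets the intact reserve population express
both stronger size selection and larger pair size gaps than the truncated
fished population; a symmetric kernel penalises the reserve's largest
males and washes the contrast out.

With probability `p_multiple` a female mates additional males filling a
contribution vector (default 9:1). Egg genotypes are Mendelian draws from
the true parental genotypes with the sire drawn per egg from the
contribution vector; all observed genotypes (adults and eggs) pass through
the dropout / false-allele / missingness layer.

Growth records are generated from the same moult-logistic and increment
models the fitting code assumes, plus measurement noise bounded below the
5 mm moult threshold.

### Realism limits

* Allele frequencies are geometric-series surrogates matched to published
  allele counts and heterozygosities, not the real frequency spectra.
* The generator mates every female and samples exactly ten eggs per brood;
  there is no sampling failure, female refusal, or brood loss.
* Sperm storage across seasons, repeated female spawning, and male mate
  guarding are not modelled; the "sampled fraction" of true fathers in
  the candidate pool is an assumption of the confidence calibration, not
  an emergent property.
* Population structure is absent by construction (both areas share one
  gene pool), so F_ST between areas is near zero by design.
* Growth records are error-in-equation only; real mark–recapture data have
  size-dependent recapture probabilities the generator ignores.

## 9. Numerical choices

* All stochastic components take explicit seeds (`numpy.random.default_rng`)
  and are deterministic given them.
* Likelihood scoring is vectorised per locus over the candidate pool
  (`TrioScorer`), making ~10³ eggs × ~500 candidates tractable in seconds.
* HWE enumeration caps at 200,000 arrays before the Monte-Carlo fallback;
  permutation p-values use the (hits+1)/(n+1) estimator, so they are never
  exactly zero.
* Logistic fits use `statsmodels` with a 200-iteration cap; separation and
  non-convergence are detected and surfaced rather than silently accepted.
* The preference-recovery estimator (`fit_preference`) maximises the exact
  conditional-logit (softmax) likelihood of each observed sire among the
  female's area pool — matching the generating choice model — with
  standard errors from the numerical Hessian.

## 10. Limitations

* Paternity is assigned egg by egg; a brood-level joint model (full-
  pedigree reconstruction) would share information across eggs and reduce
  the ~5% of single-egg misassignments the Δ-calibration tolerates at 95%
  precision. Those misassignments inflate apparent polygamy and can create
  spurious inter-area pairs, which is why brood classification applies the
  conservative ≥5-locus rule instead of trusting lone egg assignments.
* The Janzen–Stern gradient is an approximation whose quality degrades as
  mean success departs from the weak-selection regime.
* AICc ranking assumes independent male outcomes; non-independence through
  shared females is ignored, as in the standard analysis it mirrors.
* The generator's area contrast is a design choice (global-population
  standardization plus one-sided kernel), not a fitted model of real
  behaviour; parameter-recovery tests validate internal consistency, not
  field realism.
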