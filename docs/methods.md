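# Methods

## The triad log-linear model

A case-parent trio consists of an affected child and both biological
parents, genotyped at a biallelic SNP. Writing M, P, C for the number of
risk-allele copies carried by mother, father and child, only 15 of the 27
ordered (M, P, C) triples are Mendelian-compatible. `triopoo` uses a fixed
cell order:

| cell | (M,P,C) | stratum | origin | cell | (M,P,C) | stratum | origin |
|---|---|---|---|---|---|---|---|
| 1 | 2,2,2 | 2×2 | – | 9 | 1,1,1 | 1×1 | ambiguous |
| 2 | 2,1,2 | 2×1 | – | 10 | 1,1,0 | 1×1 | – |
| 3 | 2,1,1 | 2×1 | maternal | 11 | 1,0,1 | 1×0 | maternal |
| 4 | 1,2,2 | 2×1 | – | 12 | 1,0,0 | 1×0 | – |
| 5 | 1,2,1 | 2×1 | paternal | 13 | 0,1,1 | 1×0 | paternal |
| 6 | 2,0,1 | 2×0 | maternal | 14 | 0,1,0 | 1×0 | – |
| 7 | 0,2,1 | 2×0 | paternal | 15 | 0,0,0 | 0×0 | – |
| 8 | 1,1,2 | 1×1 | – | | | | |

Counts over the 15 cells are modelled with a Poisson log-linear mean

    m_i = exp( mu_s(i) + c1·1(C=1) + c2·1(C=2)
               + alpha·1(origin maternal) + beta·1(M=2) + gamma·1(M=1) ),

one free intercept per unordered parental mating type
{2×2, 2×1, 2×0, 1×1, 1×0, 0×0}. The child-dose terms c1, c2 absorb any
ordinary allelic association, so the POO terms are identified only by
asymmetries within mating types. The model assumes Mendelian transmission,
parental symmetry within mating types in the source population, one
affected child per family, and no linkage disequilibrium with another
causal locus.

A heterozygous child's single copy has a known parent whenever the parents
carry unequal doses (cells 3, 6, 11 maternal; 5, 7, 13 paternal). In the
double-heterozygote cell 9 the origin is latent and the two transmission
paths are merged directly in the likelihood:

    m_9 = exp(mu_{1×1} + c1 + gamma) · (exp(alpha) + 1).

With all coefficients zero this reduces to the factor-2 Mendelian path
multiplicity of that cell. The merged-cell form was chosen over an EM
formulation because it is exact, keeps the likelihood an explicit function
of the parameters, and is directly comparable with the brute-force grid
oracle used in the tests; EM would converge to the same maximum.

Interpretation of the exponentiated terms: exp(alpha) is the
maternal:paternal transmission odds ratio among origin-informative
heterozygous affected children (imprinting); exp(beta) and exp(gamma) the
risk multipliers for children of mothers carrying two and one copies
(maternal effects), irrespective of transmission.

## Fitting

Because every stratum has a free intercept, maximising the Poisson
likelihood is equivalent — for likelihood-ratio purposes — to the 15-cell
multinomial conditional on the stratum totals; the fit enforces
`sum(fitted means) = sum(counts)` within every stratum (asserted in the
test suite). The intercepts are profiled out analytically
(`exp(mu_s) = N_s / Σ_{i∈s} w_i`), leaving at most five coefficients that
are maximised by L-BFGS-B with the analytic envelope-theorem gradient, from
two deterministic starts (all zeros, and crude log-count-ratio moment
estimates). Convergence uses a relative likelihood tolerance of 1e-13 and
a gradient-norm check of 1e-4; fitting involves no randomness.

Numerical choices:

* Coefficients are bounded at |coef| ≤ 12 (odds ratio ≈ 1.6e5). When a
  contrast class is empty the MLE diverges; the cap keeps the likelihood
  finite and such coefficients are flagged (`capped_terms`). Near-boundary
  odds ratios are expected in small tables.
* Strata with zero total count are excluded from the likelihood and
  reported (`excluded_strata`).
* A term with no informative counts at all is *inestimable* and is
  excluded from the fit with a reason, rather than returned at a boundary:
  alpha when no origin-determinate heterozygous children exist (cells
  3, 5, 6, 7, 11, 13 all empty); beta when cells 2, 3, 6 are empty (the
  2×2 stratum alone carries no beta contrast — its intercept absorbs it);
  gamma when cells 4, 5, 11, 12 are empty (similarly, the 1×1 stratum is
  absorbed). This reproduces the practical reporting convention for trios
  with, e.g., no homozygous mothers.
* When alpha is excluded or inestimable, cell 9 keeps its factor-2 path
  multiplicity.

Each term is tested by a 1-df likelihood-ratio chi-square. By default the
term is dropped from the *jointly* fitted model (all included terms as the
alternative); the simpler convention — the term as the sole POO term over
the strata + child-dose baseline — is available via `baseline="single"`.
Joint fitting is the default because handling imprinting and maternal
effects simultaneously is the point of the method: a pure transmission
asymmetry test is biased when maternal effects are present. LRT statistics
are clamped to zero when within numerical noise (< 1e-8), and an exactly
zero statistic reports p = 1.0. The reported odds ratio is the
exponentiated coefficient from the full fit; Wald confidence intervals are
not printed by default.

## QC

Call-rate QC removes individuals below 95% first, then SNPs below 98%
recomputed on the survivors — this order matters because removing
individuals changes SNP call rates; the reverse order is not implemented.
Removing any member removes the whole trio; every removal is reported with
its reason and the operation is idempotent. Trios with a missing genotype
at a given SNP are excluded for that SNP only, since tabulation is
per-SNP. A complete but Mendelian-inconsistent dose triple is never
counted; it increments the table's error tally. As a coarse screen for
wrong family relationships, trios whose Mendelian-error rate across SNPs
exceeds 5% are flagged; this catches gross errors (sample swaps,
non-paternity) without requiring genome-wide identity-by-descent
estimation. Sex checks are limited to pedigree-role consistency (a
recorded mother must not be male), since autosomal PED input carries no
intensity data to infer genetic sex from.

## Simulator

Parental doses are drawn independently from Hardy-Weinberg proportions at
the risk-allele frequency (so mating symmetry holds by construction);
children receive one allele from each parent by fair Mendelian
transmission with the origin of each allele recorded. The child is
affected with probability

    baseline · R1^1(C=1) · R2^1(C=2) · Im^1(C=1 ∧ maternal copy)
             · S1^1(M=1) · S2^1(M=2),

and trios are retained by rejection sampling on an affected child. The
exact acceptance probability is computed by enumeration (it also sizes the
sampling batches); configurations below 1e-6 are rejected rather than
looped on. Rejection sampling was preferred to inverting the analytic
triad distribution because it is transparent and makes origin tracking
trivial; the analytic cell probabilities are still derived independently
in the tests and used as the oracle for the simulator's null distribution.

`baseline_risk` defaults to 0.005: in this rare-disease regime the
simulator's relative risks coincide with the log-linear model's odds-ratio
parameters (Im ↔ exp(alpha), S1 ↔ exp(gamma), S2 ↔ exp(beta)), which the
test suite verifies by parameter recovery. Genotype dropout and
single-child-allele corruption can be injected after ascertainment to
exercise the QC path; corruption of parental genotypes and more elaborate
error models are out of scope.

What the simulator does *not* emulate: linkage disequilibrium between
SNPs, population stratification or admixture, genotyping-intensity cluster
artefacts, relatedness between families, or phenotype heterogeneity.
Passing tests therefore demonstrate correctness of the estimator and its
calibration under the model's own assumptions, not robustness to these
real-data complications.

## Power, and the gap to analytic power calculators

`estimate_power` simulates replicate cohorts, runs the term's LRT on each,
and reports the fraction of estimable replicates with p below the nominal
level, with a binomial Monte-Carlo standard error. Replicate seeds derive
deterministically from one master seed. Replicates with an inestimable
term are excluded from the denominator and counted separately (a warning
fires if they exceed 10%).

The two shipped cohort-sized scenarios give, at imprinting OR 3 and level
0.05 with 1000 replicates:

* 181 trios, risk-allele frequency 0.025: power ≈ 0.22 (MC s.e. 0.013);
* 62 trios, frequency 0.075: power ≈ 0.19 (MC s.e. 0.013).

These sit far below the ≥80% figures that analytic power software reports
for similar-sounding "POO effect of OR 3" scenarios, and the gap is
structural, not a bug. At frequency 0.025 a trio contains an
origin-determinate heterozygous child with probability ≈ 5%, so a 181-trio
cohort carries roughly nine origin-informative trios; a 3:1 transmission
asymmetry on nine observations cannot approach 80% power for a 1-df test
at 0.05 (the expected LRT non-centrality is ≈ 2.6). Analytic calculators
reach high power for such scenarios by computing a different quantity —
typically a child-genotype relative-risk test using all transmissions, not
the origin-resolved imprinting contrast in a model that simultaneously
adjusts for maternal-genotype effects, which is well known to cost power
relative to a pure parental-asymmetry test. The package therefore ships
its simulation-based estimates, with their Monte-Carlo uncertainty, as the
regression values for these scenarios. A third named scenario (62 trios,
OR 4 at frequency 0.04) is provided because both parameterisations
circulate for the smaller-cohort setting; it is shipped as-is rather than
reconciled.

Problem sizes used by the shipped checks, chosen to give decisive
Monte-Carlo resolution: 1000 replicates for each power scenario
(s.e. ≈ 1.3%), 2000 null replicates of 500 trios at frequency 0.3 for
type-I-error calibration (each term's empirical size must fall in
[0.035, 0.065]), and 500 replicates of 1000 trios for parameter recovery
(mean exp(alpha) within 15% of the simulated OR 3, central 95% of
estimates bracketing it).

## Pipeline conventions

One report row per configured SNP. Doses count copies of the per-SNP risk
allele declared in the SNP configuration, so odds-ratio directions follow
the declared risk allele; flipping the declaration maps every dose d to
2−d and inverts the odds ratios. Bonferroni correction is applied within
user-declared analysis families; the family size counts SNPs (the
`snp_terms` convention, counting SNP × term pairs, is available as an
option). Raw p-values are always reported; the flag marks
`p × family size ≤ level`. A SNP whose trios all fall in the 2×2 or 0×0
mating types (or with no complete trios) is flagged `uninformative`;
inestimable terms render as `N/A` in the markdown view. TSV reports keep
full precision and re-read losslessly; the markdown view rounds odds
ratios to one decimal and p-values to two significant figures. Reports are
byte-identical on re-runs; nothing in the analysis path is random.

## Known limitations

* Incomplete trios (dyads) are reported and excluded; no missing-parent
  likelihood is implemented.
* Single-SNP analyses only: no haplotypes, no X-linked models, no
  imputation.
* The estimability screen is count-based; pathological tables in which a
  term is formally identified only through cross-stratum coupling can
  still produce capped (boundary) estimates, which are flagged but not
  suppressed.
* Power estimates inherit the simulator's idealisations listed above.
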