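# Methods

This note documents the statistical models implemented in `gwcausal`, the
design choices that were genuinely open, the defaults and their rationale,
and the limitations we know about. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Discrete and cyclic additive-noise models

An additive-noise model (ANM) from `X` to `Y` is `Y = f(X) + N` with
`N ⫫ X`. Two arithmetic conventions are supported through `DomainSpec`:

* **cyclic** — values live in ℤ/mℤ and subtraction is modulo `m`. Genetics
  convention: genotype `X` is 3-cyclic, binary trait `Y` is 2-cyclic.
* **integer** — ordinary subtraction; the residual support widens with the
  range of `f`.

Fitting minimizes a dependence measure (DM) between regressor and residuals
over function tables `f : supp(X) → supp(Y)`:

* `chi2_p` (default): 1 − (Pearson χ² p-value) of the regressor × residual
  contingency table. For a fixed table shape, minimizing this is the same as
  minimizing the χ² statistic itself.
* `distance_correlation`: squared sample distance correlation between
  regressor and residual values, evaluated directly from the table with
  probability weights.
* `shannon_entropy`: the mutual information I(X; N) in bits — zero exactly
  at empirical independence.

Search is **exhaustive** over all `|Y|^|X|` tables when that family is small
(≤ 10⁵; the genotype→trait case has only 2³ = 8), otherwise **iterative**
coordinate descent from the conditional-mode table `f(x) = argmax_y P̂(y|x)`.
On supports with `|X|·|Y| ≤ 32` the descent is restarted from the constant
functions and (for cyclic responses) the constant shifts of the mode table;
these deterministic extra starts remove the single-coordinate local optima
that one fixed start occasionally hits, and the test suite asserts equality
with exhaustive search on random instances. Ties are broken toward the
lexicographically smallest `f`, making every fit deterministic. Regressor
states never observed get `f` set to the majority response, with a warning.

Residual independence is tested with the Pearson χ² test on the
regressor × residual table (columns with zero total contribute nothing; the
degrees of freedom stay at the full-table value, which for the
2 × 3^q genotype layout is 3^q − 1 — identical to the classical
(rows−1)(cols−1) there; a `df_convention` switch exposes both). When any
retained expected count is below 5, Fisher's exact test is used instead
(exact enumeration for 2 × 2; a seeded Monte-Carlo exact test conditioning
on both margins, 10⁵ draws, for wider tables).

**Direction decision (accept/reject rule).** Fit both directions; accept a
direction when its residual-independence p-value exceeds ε (default 0.05).
Only forward accepted → `X_causes_Y`; only backward → `Y_causes_X`; both →
`reversible`; neither → `no_decision`.

**Permutation causal test.** The statistic is the *directional DM contrast*

    T = min_g χ²(Y-residual table) − min_f χ²(X-residual table),

i.e. backward best-fit dependence minus forward best-fit dependence, on the
χ²-statistic scale. Two numerical facts shaped this definition. First, on
the 1 − p scale the contrast saturates: under strong dependence both
directions' best p-values underflow to zero and the contrast carries no
signal. Second, under independence the identity relabeling is almost surely
the best fit in *both* directions, and the χ² statistic is invariant to
transposition, so the contrast has an atom at exactly zero; a conventional
"count ties as exceedances" rule would make the test absurdly conservative
(type-I error near 0). We therefore use the classical randomized-test
device: the observed statistic is ranked among the permutation draws with
iid uniform tie-splitting, which makes the p-value exactly uniform under
exchangeability. All randomization is seeded.

**Permutation nulls are sampled, not shuffled.** Every statistic above is a
function of the joint count table alone, and permuting `y` against `x`
leaves both margins fixed while making all assignments equally likely — so
the permutation null *is* the multivariate hypergeometric distribution over
tables with the observed margins. The tests draw null tables directly
(vectorized, one `multivariate_hypergeometric` call for a binary response)
and evaluate batch statistics; this is an exact realization of the
permutation null, not an approximation, and the suite checks the two
routes agree in distribution. The generic `permutation_pvalue` engine still
shuffles literally for arbitrary statistics.

**Multivariate (multi-SNP) models** encode the q-tuple of genotypes as one
3^q-state regressor (q ≤ 8 enforced) and reduce to the single-regressor fit.

## Minimal-entropy exogenous construction

Any discrete conditional `P(Y|X)` can be generated as `Y = f(X, E)` with
`E ⫫ X`. The greedy construction peels mass blocks from the conditional
matrix `M` (row i = `P̂(Y | X = x_i)`): repeatedly take α = min over rows of
the current row maximum, record α as one state of `E` together with the
per-row output labels (the argmax columns), subtract α from each row's
maximum, and stop when the remaining mass is below tolerance (10⁻¹²;
leftover mass is discarded and `e` renormalized). The construction works
for any r × c row-stochastic matrix — squareness is not required — and an
allele-level 2 × 2 reduction (genotype collapsed to allele counts) is
available for users who want the square-matrix setting. Properties the
suite asserts: the recorded assignment reconstructs every row of `M` to
10⁻⁶; `H₁(e)` is at least the largest row entropy; the block count is at
most r(c−1)+1; the output is deterministic and invariant to row order (ties
resolve to the smallest column, then row, index).

Direction rule: `X → Y` when `H₁(E) < H₁(Ẽ)` (forward vs backward
construction), tie within 10⁻⁹.

**Permutation test.** The statistic is `H₁(Ẽ) − H₁(E)`. Under independence
it concentrates at the baseline `H₁(X) − H₁(Y)` (both constructions then
return the corresponding marginal), *not* at zero, and departures caused by
real structure can go either way: measured on genotype–trait data,
latent-confounder association and moderate dominant causation push the
contrast below baseline, while strong near-deterministic mechanisms push it
above. The test is therefore two-sided (equal-tail, randomized
tie-splitting). This choice reproduces the characteristic inflation of the
entropy-based test under association-without-causation that motivates
treating it as unreliable for genetic causal testing.

## Distance correlation and the T_C contrast

Sample distance covariance of paired point sets uses the double-centered
Euclidean distance matrices `A`, `B`:
`V² = (1/n²) ΣΣ A_kl B_kl`, `R² = V²_xy / √(V²_x V²_y)` with `R² = 0` when a
marginal distance variance vanishes. The implementation is vectorized and
the suite pins it to a literal four-loop evaluation at 10⁻¹² on random
instances; `T_IND = n V²_xy / (ā‥ b̄‥)` gives a permutation independence
test for ordinary samples.

For causal contrasts the dependence is measured between *distributions*:
each observed level `x_i` is one point pairing the scalar `P̂(X = x_i)` with
the vector `P̂(Y | X = x_i)` (one group per level — genetics supports are
tiny, no binning). With m such points,
`Δ_{X→Y} = m V²_m / (ā‥ b̄‥)` (zero when the normalizer degenerates, e.g.
an exact product joint), `Δ_{Y→X}` analogously from k groups of `Y`, and
`T_C = |Δ_{X→Y} − Δ_{Y→X}|` with an upper-tail randomized permutation
p-value. A direction is declared only at `p ≤ α`, named by the larger Δ;
this direction convention is recorded in the output metadata because the
two candidate readings differ only by a verdict label swap.

**Degeneracy on small supports.** With a binary variable on one side, that
side's embedding has two points and its Δ is identically 2 whenever the
points differ — so for genotype (3 states) × trait (2 states) data,
`T_C = |Δ_{X→Y} − 2|` and the contrast carries almost no causal signal. The
test keeps exact level (the null is permutation-calibrated) but has little
power, and the scan marks DC output as advisory for causes with ≤ 3 states.
This degeneracy is intrinsic to the construction, consistent with the
method's published real-data behavior on SNPs, and is the reason the power
study below shows near-zero DC power.

## Scenario generators

* `anm_pair` — cyclic ANM pairs on ℤ/7ℤ (7 states hold every studied noise
  support |N| ∈ {2,3,5,7}): cause pmf ~ flat Dirichlet, `f` uniform random
  excluding constants (which make the pair trivially symmetric), noise pmf
  ~ flat Dirichlet on |N| states with its largest mass swapped to 0 so the
  mode-at-zero convention holds. Ground truth X → Y.
* `random_joint` — `P(X)` and each row of `P(Y|X)` from flat Dirichlets
  over configurable state sizes (default (12, 12)). Ground truth X → Y.
* `geno_null` — genotype from Hardy–Weinberg equilibrium (MAF fixed, or
  drawn U(0.1, 0.5) per sample when `maf=None`, emulating SNPs spread
  across the genome); trait ~ Bernoulli(prevalence 0.3), independent.
* `geno_assoc_only` — a latent binary confounder `U` shifts both the MAF
  and the trait risk by ± `confounder_strength` (default 0.135, chosen
  analytically so the marginal allele–disease odds ratio is ≈ 1.5: with
  U = ±1 equiprobable, MAF 0.3 ± 0.135 and risk 0.3 ± 0.135 the 2 × 2
  allele table gives OR ≈ 1.50). No genotype→trait mechanism exists.
* `geno_assoc_causal` — trait ~ Bernoulli(penetrance[genotype]); default
  penetrance (0.1, 0.3, 0.6), a moderate additive effect. Note an exact
  2-cyclic ANM constrains penetrance values to {p, 1−p}; the default is
  deliberately not exactly ANM-representable, which makes the power study
  conservative for the ANM test.

Every generator is a pure function of its `ScenarioConfig` (including the
seed). The benchmark harness reuses the same replicate seed streams across
the scenario list (common random numbers), so curves over sample sizes share
their MAF/effect draws and monotone trends are not drowned in independent
Monte-Carlo noise. Accuracy benchmarks score forced-choice direction calls
(ANM: smaller best-fit DM; entropy: smaller exogenous entropy; DC: larger
Δ), the way cause-effect-pair benchmarks are conventionally scored; the
ε-threshold accept/reject verdict is reserved for the scan, where "no
decision" is a meaningful outcome.

## Problem sizes and defaults

| parameter | default | notes |
|---|---|---|
| ε (residual-independence acceptance) | 0.05 | direction rule |
| T_iter (descent sweeps) | 20 | convergence typically ≤ 3 |
| B (permutations) | 1000 library / 999 benchmarks / 10⁴ scan | 10⁶ reachable by flag |
| reps (benchmark) | 1000 (`--fast`: 200, B = 499) | MC SE reported per rate |
| scan QC | > 5% missing excluded | remaining missing dropped pairwise |
| multiple testing | Bonferroni α/V (FDR optional) | across scanned variants |

The type-I study runs 1,000 replicates per cell with B = 999; the power
study uses 200 replicates per sample size over n ∈ {200, 500, 1000, 2000,
5000}; the accuracy studies use 200–1000 replicates at n = 4000. These sizes
keep every published-scale check reproducible on a laptop-class single CPU.

## What the synthetic data does and does not emulate

The genotype generators produce a single biallelic SNP in HWE with a binary
trait — no linkage disequilibrium, population structure, covariates,
genotyping error, or case-control ascertainment. Passing the simulation
checks therefore demonstrates the statistical operating characteristics of
the tests under the stated generative families, not robustness to the full
messiness of real cohort data. The association-without-causation mechanism
is a marginal latent confounder; real confounding (e.g. stratification,
LD with an untyped causal variant) can differ in ways that matter, and the
original effect-size configurations behind the published validity/power
tables are not public, so those comparisons are qualitative.

## Known limitations

* **Confounding vs weak causation.** A marginal confounder at OR ≈ 1.5
  induces a smooth penetrance-like gradient `P(y|g)` that is observationally
  close to a weak additive causal effect; the ANM contrast test rejects at
  ≈ 0.15–0.17 there, well above nominal. No bivariate method can separate
  the two from `(X, Y)` data alone unless the functional forms differ; the
  published near-nominal behavior under association is not reproduced by
  this construction.
* **DC power on genotype data** is near zero (degeneracy above); the
  published power ordering ANM > DC > entropy is not reproduced — here the
  two-sided entropy test is the more powerful of the two under causation,
  precisely because confounding-style and causal signals move its statistic
  the same way.
* **Entropy direction on flat random joints** (the (12, 12) family)
  systematically prefers the backward direction: backward conditionals
  `P(X|Y)` are homogenized by the shared cause marginal and admit a
  lower-entropy exogenous variable. Its forced-choice accuracy there is
  near zero, unlike on genuinely ANM-generated data where it exceeds 0.95.
* **Power curves need not be monotone** for the contrast tests: replicates
  whose population contrast is negative stop rejecting as n grows, so power
  can decline slightly toward its asymptotic plateau.
* The exact minimum-entropy coupling is NP-hard; only the greedy
  construction is implemented. No continuous-variable methods, no latent
  confounder modelling, no imputation/phasing/covariate adjustment in the
  scan.
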