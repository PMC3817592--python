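# Methods

## Model

All calculations assume the phenotypes truly follow the polygenic mixed
model

    y = 1 mu + x beta + u + e,
    V(u) = A sigma_u^2,   V(e) = I sigma_e^2,
    h2 = sigma_u^2 / (sigma_u^2 + sigma_e^2),   sigma_y^2 = sigma_u^2 + sigma_e^2,

on the set of phenotyped-and-genotyped animals. `A` is the numerator
relationship matrix (tabular recursion `a_ij = (a_{j,s_i} + a_{j,d_i})/2`,
`a_ii = 1 + a_{s_i d_i}/2`), built from the full pedigree and then restricted
to the analyzed animals; parents influence the analysis only through the
structure of `A` and, for the QTDT, through their genotypes. `D` is the
diagonal of Mendelian-sampling coefficients
`d_ii = a_ii - a_ss/4 - a_dd/4 - a_sd/2`; for an animal with one recorded
parent the other is treated as an unrelated non-inbred founder
(`d_ii = a_ii - a_ss/4 - 1/4`), and for founders the entire genotype is
Mendelian sampling (`d_ii = a_ii`). Genotypes are coded in standardized form
(`w` has mean 0 and variance 1 under Hardy-Weinberg) and centred,
`x = w - mean(w)`, so `beta` is in units of phenotypic SD per standardized
allele dose when `sigma_y^2 = 1`; `beta_allele = beta / sqrt(2pq)` converts
to an allele-substitution effect and `beta / r` to the effect of a QTL in LD
`r^2` with the SNP.

## Conditional moments

Each analyzed statistic is a t-type ratio `tau = beta_hat / sqrt(c q / df)`
with a method-specific estimator, naive variance coefficient `c` and
residual quadratic `q`:

* regression: `beta_hat = x'y / x'x`, `c = (x'x)^-1`, `q = e'e`, df = n-2;
* GRAMMAR: OLS of the SNP-free random-model BLUP residuals on `x`
  (`e_hat = lambda A^-1 u_hat`), same `c`, `q` from the second-stage OLS;
* FASTA: GLS of `y` on `[1, x]` with covariance `A sigma_u^2_hat + I
  sigma_e^2_hat` pre-estimated in the SNP-free random model;
  `c = (x'x - x'Cuu x)^-1`, `q = e_hat'y`, df = n-2;
* QTDT: OLS of `y` on `Q = [1, z - mean(z), x - z]` with
  `z = (x_s + x_d)/2`; the tested coefficient is the within-family one,
  `c = [(Q'Q)^-1]_33`, `q = e'e`, df = n-3;
* exact GLS ("true"): FASTA with the true variance components.

`Cuu` is the random-effect block of the inverted mixed-model-equation
coefficient matrix `[[n, 1'], [1, I + lambda A^-1]]` of the SNP-free random
model, equivalently `Cuu = (I + lambda A^-1 - 11'/n)^-1`. Two block-inverse
identities carry the whole derivation: `Cu1 = -Cuu 1 / n` and
`lambda Cuu A^-1 Cuu = Cuu - Cuu Cuu + Cuu 11' Cuu / n` (the latter holds for
any invertible `A`, and is kept as a cross-check in the tests while the
direct `A^-1` form is the computation path). With them, every estimator's
exact mean and variance under the true model, and the exact expectation of
every residual quadratic, reduce to rational functions of the forms `x'x`,
`x'Ax`, `x'Cuu x`, `x'Cuu Cuu x`, `x'Cuu A^-1 Cuu x`, `(x'Cuu 1)^2` and the
scalars `tr(Cuu)`, `1'Cuu 1`, `tr(Cuu A^-1 Cuu)`, `1'Cuu A^-1 Cuu 1` (for the
QTDT: the 3x3 blocks `Q'Q`, `Q'x`, `Q'1`, `Q'AQ`). The expressions were
derived from these definitions rather than transcribed, and the unit tests
verify them to 1e-8 against brute-force dense projections on balanced and
irregular pedigrees. The moments of the statistic itself then use two
approximations, stated once and shared by every method: the t ratio is
treated as normal (adequate from roughly a hundred animals), and
expectations of ratios/products are replaced by ratios/products of
expectations at the outermost level:

    E(tau) = E(beta_hat) / sqrt(c E(q)/df),
    V(tau) = V(beta_hat) / (c E(q)/df).

The QTDT design matrix uses `w - z` bookkeeping for the within-family
column: it differs from `x - z` by a multiple of the intercept column, so
the fitted statistic is identical, while the marginal expectations below
become exact.

## Marginal moments

Under gene dropping from Hardy-Weinberg founders, `E(w w') = A` exactly, so
for `x = Hw` (`H = I - 11'/n`) every quadratic form marginalizes as an exact
trace, `E(x'Mx) = tr(M H A H)`, and `E((x'Cuu 1)^2) = 1'Cuu H A H Cuu 1`.
For the QTDT blocks, `E(z z') = E(w z') = A - D` when no tested animal is a
parent of another tested animal (a terminal tested generation — the designs
this machinery targets); all printed blocks of `E(Q'Q)`, `E(Q'x)` and
`E(Q'AQ)` follow exactly, and the tests pin each one against gene-dropping
averages. One consequence worth stating: marginally
`V(beta_w) = 2 sigma_y^2 / n` without inbreeding — the polygenic effect
drops out of the QTDT estimator variance entirely.

The variance components entering the two-step methods are handled by the
plug-in rule: the SNP-free random model absorbs the SNP variance into the
polygenic term, so `E(sigma_u^2_hat) = sigma_u^2 + beta^2`,
`E(sigma_e^2_hat) = sigma_e^2`, and the shrinkage ratio used for `Cuu` and
the `(sigma_e^2 - lambda sigma_u^2)` correction factors is
`lambda = sigma_e^2 / (sigma_u^2 + beta^2)` under the alternative and the
true ratio under the null. When the user supplies `h2_used`
(misspecification analysis), `lambda = (1 - h2_used)/h2_used` everywhere the
two-step models reference estimated components, while the true `h2` governs
the distribution of `y`.

## Rates, bias and design

With `E0 = 0` and `V0` the null moments and `t = Phi^-1(1 - alpha/2)`,

    alpha_true = 2 (1 - Phi(t / sqrt(V0)))            (two-sided, as used)
    power      = 1 - Phi((threshold - E1)/sqrt(V1))   (upper tail; the lower
                                                       rejection mass is
                                                       negligible at
                                                       realistic effects)

Power "at the true type-1 error" recalibrates `threshold = sqrt(V0) t`. The
GRAMMAR relative bias is `E(beta_hat)/b - 1 = -E(x'Cuu x)/E(x'x)`; `V0`
doubles as the genomic-control inflation factor. Sample-size search
increments whole half-sib families (geometric bracket + bisection, capped at
1e6 animals, minimum 8 animals) using the closed-form half-sib backend: for
f equal families of d half-sibs every matrix involved lies in the
commutative algebra spanned by {I, within-family blocks, 11'}, is
diagonalized by three invariant subspaces (multiplicities n-f, f-1, 1), and
all traces and quadratic forms are O(1) in n. The dense backend handles
arbitrary `A`/`D` and agrees with the structured one to 1e-8 in tests.

## Defaults

* `sigma_y2 = 1` (all outputs scale-free; tested), `mu = 0`, `p = 0.5`,
  `r2 = 1`.
* SNP variance fraction 0.02 of `sigma_y^2` (`beta = 0.1414 sigma_y`,
  allele-substitution effect 0.20 at MAF 0.5) — the CLI default effect.
* nominal `alpha = 0.01` for the analytic subcommands, 0.05 for the
  validation simulator, mirroring their typical uses.
* heritability is clipped to `[1e-6, 1 - 1e-6]` before forming
  `lambda = (1-h2)/h2`; the exact endpoints are answered by this continuity
  limit (at `h2 = 0` all methods collapse to a calibrated test). Values of
  `h2` very close to 1 stress the shrinkage algebra and the normal
  approximation; the validation grid stops at 0.9.

## Validation simulator

The simulator exists to check the algebra, and emulates exactly the model
above: founder genotypes drawn in Hardy-Weinberg proportions, one allele
transmitted per parent down the pedigree (so `E(ww') = A` by construction),
polygenic values by the recursion `u_i = (u_s + u_d)/2 + m_i` with
`V(m_i) = d_ii sigma_u^2`, residuals iid normal. Each replicate produces a
null and an alternative phenotype sharing genotypes, polygenic values and
residuals. Variance components are re-estimated per replicate by REML on
the SNP-free random model — a 1-D profile likelihood in `h2` over the
eigendecomposition of `A` (O(n) per evaluation after one rotation;
convergence 1e-9 in `h2`; verified against a 2001-point grid search) — and
shared by GRAMMAR and FASTA within a replicate. Statistics are computed as a
practitioner would compute them. Monomorphic-SNP replicates are skipped and
counted. One master seed drives everything; identical seeds give
byte-identical result tables.

What the simulator does *not* emulate — and hence what passing tests do not
establish about field data: selection and assortative mating (founders are
unrelated and matings random), genotyping error, non-normal residuals,
multiple causal loci per tested SNP, marker-based (realized) relationship
matrices, and population admixture.

## Numerical and testing choices

* Monte-Carlo comparisons of E(tau), V(tau) first map the
  normal-approximation moments to noncentral-t moments with df denominator
  degrees of freedom (`E(t) = delta c1(df)`,
  `V(t) = (V + E^2) df/(df-2) - E(t)^2`): the statistic has an estimated
  denominator, and at validation-sized samples the df/(df-2) spread alone
  exceeds Monte-Carlo resolution.
* The ratio-of-expectations step leaves an irreducible O(Var(q)/E(q)^2)
  residual in V(tau), measured at 0.5-1.3% on 12-600-animal designs and
  largest for GRAMMAR under the alternative and at extreme heritability;
  Monte-Carlo assertions therefore carry 1-3% relative floors on variances.
  The same step makes the marginal QTDT null variance exceed the (exactly
  calibrated) conditional one by up to 0.035 for ten families of 60 at
  `h2 = 0.9`, shrinking quickly with the number of families.
* The equal-power identity of GRAMMAR and FASTA at equal true type-1 error
  is a statement about the statistics given the variance components (they
  share their numerator); it holds to 6e-4 with a common shrinkage ratio.
  Under the plug-in rule the component expectation affects the two methods
  asymmetrically, adding up to 0.006 at `h2 = 0.1` on large-family designs.
* Replicated validation runs at 2000 replicates per scenario over three
  designs (120x5, 20x30, 10x60) and `h2` in {0, 0.3, 0.6, 0.9}; fixed-x
  Monte-Carlo oracles use 200 000 trait replicates on 12-300-animal
  designs; gene-dropping form checks use 200 000-400 000 drops. These sizes
  resolve the approximations discussed above while keeping the full suite
  around two minutes.
* Singular `A` raises with guidance (analyze the phenotyped subset, or add a
  small ridge); a monomorphic SNP, a missing parental genotype for the QTDT
  and a design without within-family genotype variation raise explicit
  errors rather than returning degenerate numbers.

## Known limitations

* The QTDT marginalization assumes the tested animals form a terminal
  generation; with phenotyped parents of phenotyped offspring the `A - D`
  bookkeeping for mid-parent codes no longer holds (conditional moments
  remain exact for any pedigree).
* Moments integrate over genotypes and plug in component expectations, but
  ignore the sampling variance of the variance-component estimators
  themselves; REML validation shows this is adequate at hundreds of animals
  and a single SNP of small effect.
* One SNP at a time, no additional fixed effects, no genome-wide threshold
  logic, pedigree-based relationships only.
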