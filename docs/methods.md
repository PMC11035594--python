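# Methods

## The model

A genome-wide interaction study (GWIS) fits, per variant,

    Y = b0 + b1*G + b2*E + b3*(G*E) + eps                    (interaction model)

while a GWAS fits the marginal model

    Y = a0 + alpha*G + eps.                                  (marginal model)

Writing `rho` for the mediation contribution of G acting through E, the
population gap between the marginal and main effects is

    alpha - b1 = (rho*sE1/sG1)*b2 + (muE1 + rho*sE1/sG1)*b3,

where `muE1`, `sE1` are the environment mean and SD in the GWAS cohort and
`sG1` the genotype SD. A variant with neither interaction (`b3 = 0`) nor
mediation (`rho = 0`) therefore has `alpha = b1`; in practice the two
consortia measure the phenotype differently, so the estimates satisfy
`alpha_hat ≈ theta*beta1_hat` with a slope `theta` that is 1 only under
homogeneous measurement. `theta` is estimated by inverse-variance-weighted
(IVW) regression of marginal on main effects over strong, LD-independent
instruments — exactly the slope-fitting step of summary-statistics
Mendelian randomization with the trait's own polygenic signal playing the
role of the exposure. Variants departing from the fitted line carry
interaction and/or mediation signal, the analogue of horizontal pleiotropy;
the screen statistic is

    T = (alpha_hat - theta_hat*beta1_hat)^2 / var(alpha_hat - theta_hat*beta1_hat) ~ chi2(1),
    var(...) = se_a^2 + theta^2*se_b1^2 - 2*theta*r*se_a*se_b1,

with `r` the estimator correlation induced by sample overlap, estimated
from the z-score correlation of variants null in both sources (two-sided
p > 0.05). `theta_hat` is treated as fixed inside the variance: it is
fitted on ~100 instruments, so its noise is an order of magnitude below a
single variant's. The slope fit iterates IVW refitting with removal of
instruments whose screen p falls below a Bonferroni bound (0.05/|set|,
at most 50 iterations, deterministic) so that contaminated instruments do
not drag the line.

The two-step procedure screens the genome with `T` at 5e-8, clusters
significant variants into loci (±1 Mb around successive leads) and
LD-independent signals (pairwise r² < 0.1), then confirms the X surviving
signals with the GWIS direct interaction test `b3_hat^2/var(b3_hat)` at
`0.05/(X*n_exposures)`. X counts signals, not loci (a config flag flips
this). Step-2 results computed in data overlapping step 1 are labelled
"non-independent confirmation"; only a separate dataset earns
"replication". Discovery and replication direct-test p-values are combined
by Fisher's method (−2·(ln p1 + ln p2) on chi-square(4)); a sum-of-squared-z
chi-square(2) combination is available as `method="sum_z2"` because both
rules appear in published replication tables and they differ numerically.

## Tunable parameters that matter

| parameter | default | why |
|---|---|---|
| screen threshold | 5e-8 | genome-wide significance |
| instrument p-threshold | 5e-8 after genomic-control correction | strong instruments only |
| LD pruning | 500 kb window, r² < 0.1 | standard clumping of independent instruments |
| IMRP removal level | 0.05/set size, ≤ 50 iterations | Bonferroni outlier removal, deterministic |
| overlap-r null set | two-sided p > 0.05, ≥ 200 variants | null z-scores isolate estimator correlation |
| MAF concordance | diff ≤ 0.15 (0.01 for positional joins) | cross-consortium QC |
| effective-n floors | 100 K (GWAS) / 30 K (GWIS) | excludes poorly-imputed or small-subset variants |
| environment-locus exclusion | p < 5e-7, ±1 Mb closed window | limits mediation contamination |
| standardization | b* = z/√n, SE* = 1/√n | removes trait-scale differences; the z/√(n+z²) variant is a config switch and differs only when z ~ √n |
| genomic control | divide chi-squares by λ only when λ > 1 | deflation-only, the usual convention |

Coordinates are 1-based and exclusion windows closed. "MAF difference" is
computed on minor-allele frequencies after alignment, making it invariant
to strand and allele-order flips. Rows missing EAF in one source are
retained but flagged and exempted from MAF filters (conservative
retention). An `adjusted_for_env` flag records whether the marginal
effects were estimated with the environment as a covariate; it is carried
as metadata only, since the screen's contrast is valid either way and the
available real-data documentation is ambiguous on this point.

## Synthetic cohort designs

Design A emulates a GWAS/GWIS pair with no mediation: m = 102 independent
variants, allele frequencies Uniform(0.05, 0.5), genotypes divided by
√(2p(1−p)) so their variance is 1 (the expected-slope theory assumes unit
genotype variance; an alternative reading of the generative recipe divides
by 2p(1−p) itself, which we treat as a typo since it breaks that
normalization). Main effects are drawn N(0, σβ²) per replicate
(σβ² = 0.005 by default: each instrument explains 0.5% of trait variance,
102 variants ≈ half the unit-residual phenotype variance); the trait adds
an environment effect 0.1, an interaction 0.05 on variant 1 only, and unit
residual noise. Cohorts of n1 = n2 = 20,000 may overlap by any fraction
and carry different environment means; the slope is fitted on the last 100
variants, power is read off variant 1 and type-I error off variant 2. A
sign scenario `s ∈ {−1, 0, 1}` sets the direction of variant 1's main
effect relative to its interaction.

Design B stresses mediation: 20 variants at allele frequency 0.3,
standardized by SD *without centering* (the nonzero genotype mean is what
lets mediation leak into the marginal effect), one variant carrying
`E = 0.05*G + N(mu, 0.9975)` — G explains exactly 0.25% of E's variance —
and/or an interaction of 0.1 in `Y = 0.1*G + gamma*E + 0.1*G*E + N(0, 10)`
with `gamma ∈ {1, √5}`. The GWIS cohort (20,000) is nested in the GWAS
cohort (up to 300,000) and non-overlapping GWAS samples have a 1.5×
environment mean. The generative recipe states the mediation residual mean
inconsistently (2 in one place, 1 in the model listing); the default is 1
with `env_mean` as an explicit knob, since the environment mean is plainly
a swept parameter of the original design.

A fast generator draws `(alpha_hat, beta1_hat, beta3_hat)` directly from
their asymptotic trivariate normal laws, including the G/G×E collinearity
structure (`corr(beta1_hat, beta3_hat) = −muE/√(muE²+sE²)`) and the
overlap covariance. For the overlap cross-moments we use the
influence-function results

    n*cov(alpha_hat, beta1_hat) = s²*(sE2² + muE2² − muE2*muE0)/sE2² * n0/n2,
    n*cov(alpha_hat, beta3_hat) = s²*(muE0 − muE2)/sE2² * n0/n2,

which Monte-Carlo experiments confirm (full overlap, equal environments:
estimator correlation 1/√2). The closed-form expected slope implemented in
`theory.expected_theta` uses a larger published overlap term,
`n0/(n1*n2)*(1+muE0²/sE0²)`; the two coincide for disjoint cohorts
(n0 = 0) and both give E(theta_hat) = 1 at complete overlap, but they
differ at intermediate overlap, where the closed form should be read as an
upper-bound-preserving approximation. Simulation-vs-theory consistency is
therefore asserted on disjoint-cohort grids. At complete overlap the three
estimators become linearly dependent (`alpha_hat = beta1_hat +
muE*beta3_hat`), so the generator takes an eigenvalue square root of the
(then singular) covariance rather than a Cholesky factor.

What the generators deliberately omit: LD between variants (the designs
use independent variants, so LD pruning and locus definition are exercised
on constructed fixtures, not on these cohorts), binary traits, covariates,
population stratification, and meta-analysis heterogeneity. Passing tests
therefore demonstrate calibration and power of the statistics under clean
sampling noise and overlap structure, not robustness to confounding —
which is the screen's selling point in theory (the outlier step is
unaffected by a mis-fitted line) but is not what the suite measures.

## Residual-effect heritability

`alpha_hat − theta_hat*beta1_hat` isolates the interaction + mediation
contribution to the marginal effect; its chi-squares regressed on LD
scores (`E[chi2] = a + n*h²*l/M`, weights 1/max(l, 1) times the inverse
squared first-pass fitted mean, two passes, all chromosomes pooled,
jackknife SE over 200 contiguous blocks) give a lower bound on the
phenotype variance from G×E and mediation — a sub-component of the
marginal-effect (SNP) heritability. The intercept is unconstrained by
default; on panels of independent variants every LD score is 1 and the
slope is only identifiable with the intercept pinned (at 1, the
no-confounding value), which is how the recovery tests run.

## Numerical choices and problem sizes

The IVW slope is the closed-form weighted ratio and equals the exact
parabola minimizer of its objective to ~1e-12; instrument pruning breaks
ties by ascending p then position, so outputs are deterministic. All
randomness flows from a single integer seed through numpy Generators.
The test suite runs design A at 500 replicates (n = 20,000), design B at
1000 replicates (n1 up to 300,000), and fast-path calibration at 2000
replicates — sizes chosen so Monte-Carlo error is small against the
effects being measured while the whole suite stays comfortably
desk-scale. The same-sample equivalence of the marginal-vs-main contrast
with the direct test is verified with the environment orthogonalized
in-sample against the genotype, which makes the finite-sample identity
`alpha_hat − beta1_hat = delta_ge*beta3_hat` exact; on natural data the
equivalence is asymptotic and the two tests' z-scores correlate ≈ 0.98.

## Known limitations

Real applications of the screen (cross-consortium lipid × smoking/alcohol
analyses) involve meta-analyzed, partially-overlapping, multi-ancestry
summary statistics whose idiosyncrasies (trait transformations, PC
corrections, per-variant sample-size heterogeneity) the generators do not
model; the departure of fitted slopes from 1 in such data is expected and
handled, but not simulated. The LD-score regression here consumes
externally computed LD scores; computing them from a reference panel is
out of scope. The screen tests the *combined* interaction + mediation
signal: separating the two requires the step-2 direct test and, for
mediation specifically, exclusion of environment-associated loci.
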