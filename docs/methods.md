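# Methods

## The models

### Univariate animal model

The central model for a titer record of animal *k* on ELISA plate *i* is

    y = μ + Plate_i + Sex_j + a_k + d_l + e,

with plate and sex fixed, additive genetic effects `a ~ N(0, A σ²A)` (A the
pedigree numerator relationship matrix), maternal environmental (dam)
effects `d ~ N(0, I σ²m)` shared by full sibs, and residual
`e ~ N(0, I σ²e)`.  Heritability and the maternal ratio are defined against
the phenotypic variance net of plate effects, `h² = σ²A/(σ²A+σ²m+σ²e)` and
`m² = σ²m/(σ²A+σ²m+σ²e)`.  Generation is never added as a separate fixed
effect: each generation is assayed as one batch, so generation is confounded
with plate, and the design builder raises a singularity error naming the
aliased columns if both are requested.

Variants: dropping the dam term (for the 1-df maternal LRT); adding a
maternal *genetic* effect with covariance structure
`Var(a, g) = [[σ²A, σ_a,mg], [σ_a,mg, σ²mg]] ⊗ A` (2-df LRT against the
base model); replacing fixed plates by a random plate term to quantify the
fraction of variance that plates absorb; and a fixed-component mode in which
the components are held at previously estimated values and the fit reduces
to one generalised-least-squares solve — the major-locus model (plate, sex,
line and 3-class genotype fixed) is run this way, as estimating components
on the genotyped subset alone would be both noisy and circular.

### Estimation

REML is computed through the mixed-model equations with the sparse inverse
of A (Henderson's rules, inbreeding-corrected; `log|A|` is the sum of log
Mendelian-sampling variances).  The restricted log-likelihood is the full
definition with constants,

    llf = −½[(n−p) log 2π + log|V| + log|X'V⁻¹X| + y'Py],

evaluated via `log|R| + log|G| + log|C|` with one sparse LU factorisation of
the MME coefficient matrix per evaluation (symmetric-mode minimum-degree
ordering, which keeps fill-in roughly an order of magnitude below the
default column ordering on pedigree-structured systems).  Free variances
are optimised as log-ratios to the residual variance, which is profiled out
in closed form; the direct–maternal covariance is parameterised through a
tanh-bounded correlation.  Nelder–Mead drives the (2–4 parameter)
univariate problems; convergence uses absolute tolerances 1e−6 (parameters,
log scale) and 1e−8 (objective).  Standard errors of components come from a
central-difference Hessian of the unprofiled likelihood at the optimum;
ratio and correlation SEs use the delta method.

Correlations live on a tanh scale and therefore cannot numerically leave
[−1, 1]; estimates pinned against the boundary (|r| > 0.99) are flagged as
at/outside the edge of the parameter space rather than raised as errors,
because boundary maternal-genetic correlations are an expected outcome on
data of this structure.  Likelihood-ratio statistics are referred to plain
chi-square distributions (1 df for the dam term, 2 df for the maternal
genetic block) without boundary mixtures, matching standard practice for
these tests in animal breeding.

### Bivariate model

Two traits (or one trait sex-split into two) are fitted jointly with
trait-specific fixed effects, additive covariance `G_A ⊗ A`, maternal
covariance `G_M ⊗ I`, and a per-animal 2×2 residual covariance for animals
carrying both traits.  In the sex-split analysis each animal carries exactly
one trait, so the residual covariance is not estimable and is fixed at 0
(documented as this package's choice; with records on both traits it is
free).  The additive correlation can be fixed (0.999) for the boundary LRT
that r_a = 1.

Optimisation is staged: univariate REML fits of each trait seed the
variance ratios; a bounded quasi-Newton pass moves all parameters jointly;
and each correlation coordinate is then refined by a one-dimensional
bounded search (correlations sit in flat likelihood directions, where a
dedicated line search is far more reliable than finite-difference
quasi-Newton steps), alternating once more with a joint pass.  On replicate
datasets of the recovery design a subsequent 1,500-evaluation Nelder–Mead
polish improves the restricted log-likelihood by under 0.1 units and moves
r_a by under 0.005, so the staged optimum is effectively converged.  The
bound |r| ≤ 0.9989 keeps the Kronecker precision matrices numerically
regular.

## Selection theory

Truncation intensity is `i = φ(z)/p`; sexes are averaged as
`ī = (i_m + i_f)/2` since each parent contributes half the genes.  The
major-locus frequency iteration is the classical mass-selection
approximation `Δp = i p q α/σ_P` with average effect `α = a + d(q − p)`,
re-imposing Hardy–Weinberg proportions each generation and holding σ_P at
its base value (the approximation supplies no update rule; an eroding-σ_P
option would be a one-line change but is deliberately not default).  Locus
variances are `σ²A,locus = 2pqα²` and `σ²D,locus = (2pq d)²`; the locus part
of a realized trend between frequencies p₀ and p_t is
`M(p_t) − M(p₀)` with `M(p) = p²v_CC + 2pq v_CG + q²v_GG`, and the
polygenic part is the remainder, so the split is conservative by
construction.

The default intensity schedule derives from the reference design: 25 sires
and 50 dams selected per line and sex from per-generation candidate counts
(4855, 946, 820, 526, 915, 1135, 707), a quarter of each total per line and
sex.  The exact intensities behind the study's expected trajectory are not
printed anywhere, so this reconstruction carries a stated ±0.05 band on the
generation-7 prediction (≈0.75 for the High line against the reported
expectation 0.77).

## The synthetic-data generator

The simulator reproduces the statistical structure the estimators assume:

- **Design.** A base population (default 4,855; 63.8 % female) and 7
  generations of two divergently mass-selected lines; 25 sires and 50 dams
  per line selected on own IgTotal phenotype (High: top; Low: bottom; ties
  broken by animal id); each sire mated to ≤2 dams, full- and half-sib
  matings avoided by maximum bipartite matching with a least-related
  fallback; per-generation totals default to (946, 820, 526, 915, 1135,
  707, 974) split equally between lines.  The base round selects with the
  same 25/50 counts (the study used 24/44–48; the difference is immaterial
  to every implemented estimator).
- **Traits.** IgM, IgG, IgTotal with polygenic variances chosen so that
  σ²A+σ²m+σ²e equals the reported phenotypic variances (1.15, 1.95, 1.85)
  at h² = 0.30/0.12/0.12 and m² = 0.03/0.02/0.03; plate variances derive
  from the reported fractions of variance a random plate effect explains
  (18/14/22 %), giving σ²plate = f/(1−f)·σ²P; a −0.13 titer-point male
  effect on IgM.  Additive, maternal and residual effects are sampled from
  the reported correlation matrices; the two unreported residual
  correlations (IgM–IgTotal, IgG–IgTotal) are implied by the phenotypic
  correlation identity cov_P = cov_A + cov_M + cov_E, giving 0.461 and
  0.826.
- **Major locus.** Hardy–Weinberg founders at p₀ = 0.45; genotype values
  per trait (IgM 0/1.01/1.12, IgG 0/0.22/0.07, IgTotal 0/0.49/0.44);
  Mendelian transmission of one allele per parent.
- **Transmission.** Polygenic offspring values are midparent plus a
  Mendelian-sampling deviation with variance ½σ²A(1 − (F_s+F_d)/2)
  (correlated across traits), keeping the polygenic covariance consistent
  with A as inbreeding accumulates.  Parental inbreeding comes from a
  memoised kinship cache over the ancestor graph.
- **Assay structure.** Animals are plated in shuffled blocks of 20, mixing
  lines and sexes within plate from generation 1 on (the estimable layout);
  a flag reproduces the base population's confounded single-sex plates, and
  a per-generation plate-mean drift option exists (default off) to
  demonstrate how batch effects divert the phenotypic trend from the
  genetic trend.
- **Maternal families.** With no ancestral generations (default), founders
  receive pseudo maternal-family labels in blocks of 6 — environment-only
  dam groups among genetically unrelated founders — so σ²m is defined and
  estimable in the base.  With `n_ancestral_generations ≥ 1` the base is
  bred from an unphenotyped ancestral cohort and has real pedigree dams,
  which the maternal-genetic model requires.
- **Determinism.** One root seed; every stage draws from a named spawned
  stream, and all graph computations use integer node keys, so identical
  seed and configuration give byte-identical outputs across processes.

What the generator does **not** emulate: the two-batch base population with
overlapping animals (one founder cohort suffices for every implemented
estimator); genotype imputation error in the base; titer measurement as an
explicit dilution series per bird (phenotypes are drawn on the titer scale
directly; the endpoint rule `log2` of the dilution closest to 50 % of E_MAX
is implemented as a standalone operation with a lower-dilution tie rule and
endpoint flag); survival or challenge outcomes; overlapping generations.
Passing recovery tests on these data therefore show the estimators are
correct and calibrated for the assumed generative structure, not that real
titer data meet those assumptions.

## Replication experiments

`nabsel.experiments` fixes the study conditions for the quantitative
checks.  Parameter-recovery runs (h², m², r_a) use a reduced design — 600
founders plus three 900-bird generations (≈3,300 records), locus effects
zero and parents drawn at random — because the recovery targets are the
*polygenic* generating values (h² = 0.30 would not be the generating ratio
with a segregating major locus on top, and random mating avoids
selection-induced drift of the realized parameters).  The genotype-effect
recovery runs the full divergent design, estimates Model-1-style components
on the genotyped generations 5–7 (pedigree pruned to those animals and
their ancestors), and solves the fixed-component locus model there.  The
endpoint experiment runs the complete design; its reduced variant shrinks
only the base population (the bulk of the records) and keeps the selected
lines intact.  Replicate counts (10 for recoveries, 100 for the endpoint)
balance Monte-Carlo error against the single-CPU runtime of the whole
battery.

## Numerical notes and limitations

- The MME path materialises no dense A; dense relationship matrices are
  guarded to ≤2,000 animals (oracle/test use).
- Profiled-scale and absolute likelihood paths agree to ~1e−10 and both are
  validated against dense Kronecker GLS computations in the tests.
- The Welch t-test in the descriptive tables degenerates when both groups
  have zero variance; the implementation then reports p = 1 for equal means
  and p = 0 otherwise.
- REML fixed-effect SEs are Wald (from the MME inverse); no Kenward–Roger
  style small-sample correction is applied.
- The bivariate fitter handles exactly two traits; the three pairwise
  correlations of a trait trio are obtained from the three pairwise fits.
- Likelihood surfaces with near-boundary correlations are flat; the
  correlation refinement stage pins them to ~1e−3, which is an order of
  magnitude below the Monte-Carlo spread of the recovery experiments.
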