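# Methods

`rvth` implements gene-level association tests between rare variants (RVs)
and a binary trait, together with the liability-threshold case-control
simulator used to study their operating characteristics. This note records
the model, the parameter conventions, the numerical choices, and the
limitations a user should know before trusting a number.

## The tests

All tests operate on a subjects × variants carriage matrix for one gene and
a binary phenotype, optionally with covariates.

**Trend-and-heterogeneity (TH).** Because E[X²] = μ² + σ², the sum of
squared phenotypes of RV carriers responds both to a mean shift (trend) and
to a variance inflation (heterogeneity) — the latter is what a gene with a
mixture of risk-increasing and risk-decreasing alleles produces. For a
binary trait the quantitative phenotype is replaced by the Pearson residual
(y − μ̂)/√(μ̂(1−μ̂)) from a logistic regression of the trait on the
covariates (intercept-only when there are none). The statistic is
TH = Σᵢ∈carriers (rᵢ − r̄)², and its null distribution is obtained by
resampling carrier-sized subsets (without replacement by default; with
replacement available) from all n residuals; the reported p-value is
(1 + #{TH* ≥ TH})/(B + 1), one-sided. Centering at the full-sample mean
residual is a numerical nicety — for a fitted logistic model the residual
mean is already ≈ 0. One-sidedness is a design choice: association inflates
carrier squared deviations under trend and under heterogeneity alike.

**Collapsing logistic regression (RCS / RCS-C).** Logistic regression of
the trait on carriage status G = I[any RV carried], without (RCS) or with
(RCS-C) covariates; inference by the 1-df likelihood-ratio test, chosen
over the Wald test for stability with few carriers. Separation or
non-convergence falls back to the largest finite-likelihood iterate with a
warning, never a silent drop.

**C-alpha (CA / CA-P).** A test of extra-binomial variance in the
proportion of cases among the nⱼ carriers of each variant j:
T = Σⱼ (yⱼ − nⱼp₀)² − nⱼp₀(1−p₀) with p₀ the sample case fraction. The
null variance c sums exact per-variant variances of the bracketed term
under Binomial(nⱼ, p₀), enumerated over all copy configurations.
Asymptotic inference uses Z = T/√c against the upper normal tail;
permutation inference permutes case labels and recomputes T. Both p₀ and c
depend only on the copy counts nⱼ and the case total, which label
permutations leave unchanged, so holding them fixed during permutation is
exact, not an approximation. Singletons contribute nothing when p₀ = 0.5.

**SKAT (SK / SK-R).** The variance-component score statistic
Q = (y − μ̂)ᵀ G W Gᵀ (y − μ̂) with a linear kernel and diagonal weights
W = diag(w(mⱼ)²), where w is the beta(1,25) density at the variant's
sample minor-allele frequency (identity when unweighted). The asymptotic
null is Σ λₖ χ²₁ with λₖ the eigenvalues of W^{1/2}Gᵀ P₀ G W^{1/2},
P₀ = V − VX(XᵀVX)⁻¹XᵀV, V = diag(μ̂(1−μ̂)). The tail probability is
computed by numerical inversion of the characteristic function (Imhof's
integral, quad tolerance 1e-9, exact scaled-χ² shortcut for equal
eigenvalues) with the Liu moment-matching approximation as fallback when
the inversion fails or leaves [0,1]. The resampling mode draws
y* ~ Bernoulli(μ̂) and recomputes the score with a one-step
covariate-projection correction r* → r* − VX(XᵀVX)⁻¹Xᵀr* in place of a
per-replicate GLM refit; the correction reproduces the refit's first-order
effect (for an intercept-only model it equals the exact refit) and was
checked against a full per-replicate refit on simulated cohorts.

All resampling p-values use (1 + k)/(B + 1) and therefore respect the floor
1/(B + 1). Ties are counted with a 1e-9 relative tolerance so degenerate
reference distributions yield p = 1 rather than an artifact of float
summation order.

## The simulator

One simulated gene is a set of variant sites. Frequencies are drawn from
Wright's stationary distribution ψ(p) ∝ p^{β₁−1}(1−p)^{β₂−1}e^{σ(1−p)},
truncated to the rare-variant window [1/20000, 0.005); σ = 0 with
probability 0.5 and otherwise uniform on (0, 20); β₁ ~ U(0.001, 0.003) and
β₂ ~ U(1, 5) by default, both configurable. Sampling is by normalized
weights on a 512-point uniform grid of the window — deterministic, exact up
to discretization, and trivially truncated. Sites are added until the
expected per-subject carriage 1 − Π(1 − qⱼ) is as close as achievable to
the calibration target of 1% per 500 coding base pairs; the first site is
always kept, and drawing stops at the first site whose inclusion would move
the expected carriage farther from the target than leaving it out. Each
sampled frequency is used directly as the per-subject carriage probability
(effectively haploid carriage), which preserves the printed calibration
exactly; a diploid Hardy–Weinberg reading (carriage 2q − q²) would double
gene-level carriage relative to the same target. Each site independently
receives a deleteriousness class D ∈ {0,1,2,3} with marginal probabilities
(0.26, 0.16, 0.36, 0.22) and an effect sign, +1 with probability ζ
(ζ = 1 homogeneity, ζ = 0.5 complete heterogeneity).

Per subject, carriage of each site is Bernoulli(qⱼ); when several sites are
carried only the most deleterious is retained (ties broken by gene order,
deterministically). A carried class-0 site still sets carriage G = 1 —
G is what the tests observe — but contributes no effect. The latent trait
is Z = δ·s·d + γC + ε with d the retained class (linear scenario) or its
indicator (magnitude scenario), C ~ N(0,1), ε ~ N(0, 1−γ²), so Var(Z) = 1
for non-carriers. A subject is a case iff Z exceeds the (1−K) quantile of
N(0,1); rare carriers perturb the marginal of Z negligibly (carriage ≤ ~8%,
effects ≤ 3δ), so the null-distribution threshold matches the marginal
quantile to within Monte-Carlo noise while staying closed-form and
reproducible. Subjects are generated (vectorised in fixed batches,
equivalent to one at a time) until the case and control quotas fill;
a configurable cap of 200·(n_cases+n_controls)/min(K, 1−K) generated
subjects guards against non-termination.

**The Rsq convention.** `rsq` states the fraction of *observed binary
trait* variance explained by the covariate (default `rsq_scale="binary"`).
For a threshold model, corr(y, C) = γφ(τ)/√(K(1−K)), so the latent-scale
coefficient is γ² = rsq·K(1−K)/φ(τ)² — 0.44 and 0.88 for rsq = 15% and 30%
at K = 10%. The alternative latent-scale reading (γ² = rsq directly,
`rsq_scale="liability"`) is retained as an option. The observed-scale
default was adopted because only under it does the simulator reproduce the
documented qualitative behaviour of the tests at the stated Rsq levels —
most sharply, TH overtaking permutation C-alpha under heterogeneity at
Rsq = 30%, which fails at every CDS/δ cell under the liability-scale
reading; it is also the literal reading of "fraction of binary trait
variability". Note the observed scale bounds rsq ≤ φ(τ)²/(K(1−K)) ≈ 0.34
at K = 10%; larger values raise an error.

## The evaluation harness

`estimate_size` and `estimate_power` sweep a grid over (δ, ζ, Rsq, CDS,
scenario). Every replicate draws a *fresh* gene, so between-gene
variability is part of the Monte-Carlo error; a fixed-gene analysis can be
had by calling `simulate_cohort` directly in a loop. Default design levels
follow the study design: 1000 cases + 1000 controls, K = 0.1, δ from 0 to 1
in steps of 0.05, ζ ∈ {0.5, 0.8, 1}, Rsq ∈ {0, 0.15, 0.30} (the
Methods-text grid; the alternative {0, 0.10, 0.20} appears only in figure
captions and is configurable), CDS ∈ {361, 1209, 4057} bp (the 10/50/90
percentiles of human coding-sequence length), 25,000 replicates for size at
α = 10⁻³ and 250 for power. Resample counts default to 10/α so the p-value
floor sits a decade below the significance level. Seeds derive from a
single master seed through `numpy` SeedSequence spawning: reruns are
bit-identical, and per-replicate failures are logged and counted, never
silently skipped.

Full-scale grids with permutation inference are hours-scale on one core;
the test suite therefore runs a scaled-down profile — 5000 null replicates
at α = 0.01 for size, 500 replicates per cell at δ ∈ {0.4, 0.8} for the
power-ordering checks — chosen so that binomial Monte-Carlo error is small
against the effects being asserted. The ordering checks run at CDS = 1209
except TH-vs-CA-P, which uses CDS = 361 because at long genes both tests
saturate near power 1 and no ordering is measurable.

## What the simulator does and does not emulate

It emulates a rare-variant site-frequency spectrum truncated below 0.5%
MAF, deleteriousness classes with the population-genetics marginal above,
signed heterogeneous effects, a normal covariate acting on liability, and
retrospective case-control ascertainment. It does **not** model linkage
disequilibrium (sites are independent), diploid dosage effects, population
structure, genotyping error, or annotation-conditional deleteriousness.
Passing tests therefore certify the statistical machinery and its
calibration under this generative model, not performance on any particular
real sequencing study.

## Known limitations

* The asymptotic SKAT p-value is a Gaussian-limit approximation; with
  per-variant carrier counts of ~0.1–10 at n = 2000 it deviates from the
  (exact, conditional) parametric bootstrap by ~0.01 in p on typical null
  cohorts. The bootstrap mode is the reference when they disagree.
* The C-alpha permutation p-value is conservative (super-uniform) because
  its statistic is discrete and ties are counted as exceedances; this is
  visible as below-nominal empirical size at short genes.
* The β₁, β₂ hyper-prior ranges shape only the within-gene frequency
  spectrum; gene-level carriage is pinned by the stopping rule and is
  insensitive to them.
* Missing genotypes read from VCF are imputed as non-carriers (logged);
  use `missing_drop` to exclude incomplete samples instead.
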