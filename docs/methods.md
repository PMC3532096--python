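# Methods

This note documents the models implemented in `bdsmap`, their assumptions,
the defaults and why they were chosen, the numerical decisions that affect
results, and what the built-in simulator does and does not emulate. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. The inverted regression

The core idea: under directional selection an allele's frequency changes
consistently in time, so genotype becomes *predictive of birth date*. All
mapping models therefore fit birth date (decimal years; month and day as a
fraction of a year) as the dependent variable over SNP genotypes. The
payoff of the inversion is that kinship and family structure — which fatally
confound the forward regression of allele count on time under unequal
family sampling — can be absorbed by a single random animal effect on the
*dependent*-variable side, where mixed-model machinery handles it exactly.

Assumptions shared by all three mapping models: autosomal-style additive
gene action (ASEs are defined with zero dominance deviation, so the allele
substitution effect equals the genotypic value), a closed population
sampled across the time span, and complete genotypes (QC and imputation run
first).

## 2. Relationship structures

* **VanRaden GRM (method 1)**: `G = ZZ′/(2Σpᵢ(1−pᵢ))`, `Z = M − 2p`, with
  `p` the *base-generation* allele frequencies. The base cohort is a
  user-supplied id list or the earliest-born m animals; frequencies are
  clamped to `[1/(4n_base), 1 − 1/(4n_base)]` so loci fixed in a small base
  cohort cannot blow up the scaling. Two consequences worth knowing:
  (i) if `p` is taken at the *full-sample* mean, `Z′1 = 0` makes `G`
  exactly singular (the ones vector is a null vector) — inversions use a
  configurable diagonal ridge (default 1e-8); (ii) with a base-cohort
  reference the fitted animal effects have a nonzero mean, which is real
  signal (the cohort-to-present genetic trend), not a defect.
* **Balding–Nichols kinship** (EMMAX stage): per-SNP centering by `2p` and
  scaling by `2p(1−p)` at sample frequencies, averaged over SNPs.
  Monomorphic SNPs are rejected rather than silently skipped — they belong
  to QC.
* **Pedigree inbreeding**: Meuwissen–Luo recursion (the algorithm
  underlying the rapid numerator-relationship-matrix inverse), founders
  assumed non-inbred and unrelated; compiled with numba, O(n·depth) per
  animal. Genomic F is the GRM diagonal minus one and is
  frequency-referenced, hence legitimately negative for animals less
  homozygous than the base.

## 3. REML and GBLUP

Variance components of `y = Xβ + g + e`, `g ~ N(0, Kσ²_g)`,
`e ~ N(0, D σ²_e)` (D = diag(1/w) for deregression weights) are estimated
by restricted maximum likelihood, profiled over
`h = σ²_g/(σ²_g+σ²_e)`: after the weight transform and a projection onto
the null space of X, one eigendecomposition reduces the problem to a 1-D
bounded Brent search (tolerance 1e-8, endpoints checked explicitly against
the interior optimum). This is exact and deterministic; a near-isotropic
kernel (K ≈ I) triggers a weak-identifiability warning because h is then
barely informed by the data.

GBLUP solves the GLS/BLUP system through the phenotypic covariance
`V = σ²_g K + σ²_e D` (Cholesky), which is algebraically identical to
Henderson's mixed-model equations. ASEs are backsolved as
`α = Z′G⁻¹ĝ/(2Σpq)` and converted to per-SNP additive variances
`2p(1−p)α²` for ranking. The identity with ridge SNP-BLUP
(`λ = σ²_e·2Σpq/σ²_g`) is exploited by `snp_blup_ase`, an m×m route used
when animals outnumber markers; the test suite verifies both routes agree
to < 1e-6 against an independently assembled joint solve.

Ranking ties (equal variance or p) break by map order (chromosome,
position) so top-k sets are reproducible. The fraction entry point of
`rank_top_snps` rounds `fraction·m` to the nearest integer; an explicit k
is also accepted because a published count and a rounded fraction can
disagree by a couple of SNPs.

## 4. EMMAX scan and the Poisson baseline

The two-stage scheme: REML once under the null (no SNP), then V held fixed
and every SNP tested as a fixed effect by GLS in the whitened basis
(eigendecomposition of K; covariates projected out; per-SNP t-tests with
n − p − 1 df). Covariates beyond the intercept are supported but the
default is intercept-only. P-values go through Benjamini–Hochberg
(step-up, ties stable, NaNs passed through and excluded from the
multiplicity count).

The genomic-inflation factor λ_GC = median(χ²)/0.4549 operationalizes
"calibrated": the package's validation requires λ ≈ 1 for EMMAX on
confounded neutral data and λ > 1.5 for the Poisson baseline on the same
data. One caveat measured during development: 0/1/2 allele counts are
*underdispersed* relative to Poisson (binomial variance 2pq below the
mean), so on *unconfounded* data the baseline runs conservative (λ < 1)
rather than uniform — the baseline's failure mode is confounding-driven
inflation, not generic miscalibration.

## 5. BayesCπ

Spike-and-slab regression with a common slab variance and estimated π
(probability a SNP has no effect): per sweep, a joint Bernoulli–normal
update per locus, scaled-inverse-χ² updates for slab and residual
variances, a normal update for the intercept, and `π ~ Beta(1+m−k, 1+k)`
(uniform prior). Defaults follow the standard run protocol: 160,000
iterations, 1,000 burn-in, π₀ = 0.9. The kernel is numba-compiled,
single-threaded, and bit-reproducible for a fixed seed; the running
residual is refreshed from scratch every 1,000 sweeps and the maximum
drift is reported (tested < 1e-8).

**Prior convention (a deliberate design decision).** The slab scale is
derived from the *phenotypic* variance, `S²_b ∝ var(y)/((1−π₀)·Σ2pq)`,
with ν_b = 10 degrees of freedom; the residual prior uses ν_e = 4 with a
scale from the starting residual variance (typically the GBLUP REML
estimate). The more obvious convention — deriving the slab scale from the
starting *genetic* variance — degenerates exactly when it matters most:
on data with no signal the REML genetic variance is near zero, the slab
prior collapses below the per-locus noise resolution σ²_e/x′x, spike and
slab merge, and the chain ratchets into an overfitting state in which π
drifts far from 1. Anchoring the scale to var(y) keeps the slab resolvable
against the residual noise at any signal level, and the stiffer ν_b = 10
prevents the sampled slab variance from being dragged into the merge by
occasional spurious inclusions. With this convention the sampler excludes
essentially everything on pure-noise data (π near 1) and still recovers a
5%-causal architecture (π ≈ 0.9–0.95, causal inclusion far above null),
as the acceptance suite verifies.

Reported summaries: posterior mean π (all post-burn-in samples; a thinned
trace is kept for diagnostics), per-SNP posterior mean effects (shrunk by
inclusion frequency), inclusion probabilities, posterior variance
components, the proportion of var(y) explained (per-sweep genetic variance
over genetic-plus-residual), and `k = round((1−π̄)·m)` — numpy's
round-half-to-even, documented because a published k and a rounded
fraction can differ by a few SNPs. Locus update order is map order by
default (reproducibility); a shuffle flag exists.

## 6. Effective population size and the drift test

Generation number is `(birth_year − 1950)/5` — a 5-year generation
interval anchored at 1950; fractional and negative values are allowed.
`ΔF` is the OLS slope of individual inbreeding on generation number;
`N_e = 1/(2ΔF)`, `SE(N_e) ≈ 2·N_e·SE(ΔF)` (delta method). A non-positive
slope raises (no inbreeding accumulation ⇒ N_e undefined). Either
pedigree-derived or birth-year-derived generations can be supplied; the
estimate records which subset was used.

The drift test compares cohort frequencies `p₁` (earlier — it supplies the
drift variance) and `p₂`: `z = (p₂−p₁)/√(p₁(1−p₁)·t/(2N_e))`, two-sided
normal p, flagged when −log₁₀p exceeds the threshold (default 8, i.e. a
99.999999% interval); X-linked SNPs use `1.5N_e`. Two fidelity choices:
binomial sampling noise of finite cohorts is *not* added to the drift
variance (the classical test omits it; consequently calibration checks use
exact post-drift frequencies), and `t` (generations separating the
cohorts, default 1) scales the per-generation variance linearly — adequate
for t ≪ N_e. Loci fixed in the earlier cohort are skipped with a warning
(zero drift variance). −log₁₀p is computed via `logsf`, so z well beyond 8
does not underflow. Note the direction of the N_e sensitivity: at fixed
data, a larger N_e shrinks the drift envelope and can only *increase* the
flagged fraction.

## 7. Selection intensities, trends, genes

From `Δq = i·p·q·a/σ` with the ASE standing in for the genotypic value a,
each trait's regressor over the selected SNP set is
`x_j = p_j(1−p_j)·ASE_j/σ_ASE`, where σ_ASE is the standard deviation of
that trait's ASEs *over the SNP set entering the regression* (computed
after pruning). Birth-date ASEs are regressed on x by GLS with error
covariance ∝ V, the signed dosage correlation matrix; runs of
map-consecutive SNPs with |r| = 1 are pruned to their first member
beforehand (V must be nonsingular; smallest eigenvalue checked). Sign
convention: a trait selected upward yields a positive intensity. The
single-trait fits report î, SE, p (Bonferroni α = 0.05/16 in the summary,
matching a 16-trait panel); the joint multi-trait fit reports only its
adjusted R² and condition number — its coefficients are retained but
flagged unreliable under multicollinearity.

Two caveats established on simulation: the GLS is coherent when the birth
ASEs come from a *mixed-model* fit (GBLUP/SNP-BLUP). Feeding it marginal
per-SNP regression slopes breaks it — family structure then lives in the
leading eigenvector of V, exactly where the selection signal lives, and
whitening destroys the inference. And at small n the per-SNP ASE noise,
not drift, limits how finely two traits' intensities can be separated —
the validation scenario uses whole-register SNP-BLUP ASEs for that reason.

Genetic trends are linear and quadratic OLS of (deregressed) EBV on birth
date (centered for conditioning), reporting slope/curvature, AIC, adjusted
R² and model p-values. Gene windows: a gene is reported if its 1-based
inclusive interval lies within 100 kb (default) of the SNP position,
distance 0 inside the gene, strand ignored; BED input (0-based half-open)
is converted on read, GFF3 is used as-is, and unmatched chromosome names
raise rather than silently dropping hits.

## 8. Deregression

`simple` mode: `dEBV = EBV/r²` with weight
`w = (1−h²)/((c + (1−r²)/r²)·h²)`, where c is the fraction of genetic
variance not captured by markers. The weight diverges as r² → 1 with
c = 0; it is capped at 1e4 with a warning. `parent_adjusted` mode removes
the parent-average contribution by solving the 2×2 mixed-model system for
(PA, individual) implied by the reliabilities, using the relationship
precision `[[4, −2], [−2, 2]]` between an animal and its parent average;
information contents are recovered from `r²_PA = (r²_sire + r²_dam)/4` and
the animal's own r², the deregressed reliability is re-derived from the
individual's information content, and the weight uses it. An EBV whose
reliability does not exceed what the parent average alone provides cannot
be deregressed and raises. The simple mode is the default; the
parent-average algebra admits variants and the adjusted mode documents the
one implemented.

## 9. The simulator

`simulate_selected_population` emulates the data structure the mapping
methods presuppose: a pedigreed population spanning ~50 years (default
1950–2000) with a 5-year generation interval, yearly overlapping
generations (parents usable at 2–10 years; a discrete-generation switch
restricts parentage to the previous cohort), truncation selection on an
era-dependent index of EBV proxies (era weights may flip sign mid-span,
emulating historical reversals such as birth weight), geometric "AI sire"
usage skew, pleiotropic QTL effects drawn from a configurable across-trait
correlation, and a per-family genotyping-depth schedule over decades — the
confounder the method exists to defeat. Genomes are `n_chromosomes`
1-Morgan chromosomes with evenly spaced SNPs; meiosis is the exact Haldane
(no-interference) model implemented as a two-state Markov chain along each
chromosome (switch probability `(1−e^{−2d})/2` between adjacent loci),
vectorized over whole cohorts. EBV proxies are true breeding values plus
noise calibrated to a target accuracy r² against founder genetic variance —
a deliberate stand-in for running a full genetic evaluation inside the
simulator, because the package tests mapping methods, not evaluation
systems.

What it does **not** emulate: genotyping error and missingness mechanisms
beyond uniform random, mutation, dominance/epistasis, age-dependent
fertility, assortative mating, migration, real marker ascertainment, or
LD at founders (founder haplotypes are drawn in linkage equilibrium; LD
accrues only through drift and selection). Passing tests therefore show
the methods behave correctly under the stated population-genetic
mechanisms, not that they are robust to every artefact of real data.

Named validation scenarios (in `bdsmap.scenarios`) fix the study
conditions: the confounded-families contrast (n = 300, m = 1000, six
Balding–Nichols families at F_ST = 0.1 whose sampling depth tracks the
era), the single-QTL sweep (10 discrete generations, all loci started at
0.5 so the sweep has room and the drift envelope is homogeneous, parent
numbers giving N_e of a few hundred so the envelope stays narrow), the
three-trait intensity recovery (index weights (1, 0.3, 0); cohorts of 600
so ASE noise sits below the 0.3-vs-0 contrast), N_e = 50 random mating
(uniform sire usage — any usage skew lowers realized N_e below census),
and a null-REML panel of m = 200 markers at n = 500, sized from the null
sampling SD of the REML ratio (≈ √(2m)/n) so "near zero" is a
several-sigma statement. These sizes were chosen once, from the mechanisms
above, and run in seconds to about two minutes each on one CPU.

## 10. Known limitations

* Dense linear algebra throughout: n in the low thousands (animals) and m
  to ~50k markers via the marker-space route are comfortable; beyond that
  an iterative or out-of-core solver would be needed.
* The EMMAX scan refits no variance components per SNP (that is its
  definition); strong single-locus effects on birth date slightly deflate
  its test statistics.
* The drift test treats loci independently; linked loci share drift noise
  and their flags are correlated.
* BayesCπ's π is weakly identified when the slab cannot be resolved
  against noise (tiny n·slab/σ²_e); the prior convention above mitigates
  but cannot remove this.
* QC applies Hardy–Weinberg filtering to autosomes only and treats
  pseudoautosomal markers as autosomal.
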