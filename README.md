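# bdsmap — Birth Date Selection Mapping

`bdsmap` detects loci under **ongoing selection** in populations sampled over
time — livestock breeds with decades of pedigree and DNA archives being the
motivating case — by *inverting* the usual regression: instead of asking how
allele frequency changes with time, it fits **birth date as the dependent
variable** in genome-wide mixed models. A neutral allele drifting at large
N<sub>e</sub> says nothing about when its carrier was born; an allele driven
by directional selection becomes predictive of birth date, because carriers
of the rising allele are increasingly likely to be born recently.

The naive alternative — regressing allele counts on birth date with a
Poisson model — collapses under real sampling designs: families are
genotyped to different depths at different times, so between-family
frequency differences masquerade as frequency change in time. The mixed
models here (GBLUP with a VanRaden genomic relationship matrix, an
EMMAX-style two-stage scan with a Balding–Nichols kinship, and a BayesCπ
variable-selection regression) absorb that structure; the package keeps the
Poisson scan as a diagnostic baseline so the contrast is measurable
(genomic-inflation factor λ<sub>GC</sub> ≫ 1 versus ≈ 1).

## What it computes

* **Birth-date GBLUP** — animal model `y = Xβ + g + e`, `g ~ N(0, G σ²_g)`,
  REML variance components, and per-SNP allele substitution effects (ASEs)
  backsolved as `α = Z′G⁻¹ĝ / (2Σp(1−p))`, ranked by the additive variance
  `2p(1−p)α²`. An exact marker-space route (`snp_blup_ase`) solves the
  equivalent ridge system `(Z′Z + λI)α = Z′y`, `λ = σ²_e·2Σpq/σ²_g`.
* **EMMAX scan** — variance components estimated once under the null, then
  per-SNP GLS tests in the whitened basis; Benjamini–Hochberg q-values;
  λ<sub>GC</sub> diagnostics.
* **BayesCπ** — spike-and-slab Gibbs sampler in which a fraction π of SNPs
  has no effect and π is estimated from the data (numba-compiled,
  bit-reproducible for a fixed seed).
* **Effective population size** — pedigree inbreeding F by the
  Meuwissen–Luo recursion, generation number `(birth_year − 1950)/5`, and
  `N_e = 1/(2ΔF)` from the regression of F on generation, with
  `SE(N_e) ≈ 2·N_e·SE(ΔF)`.
* **Drift test** — per SNP, is the observed frequency change between two
  cohorts larger than drift can explain?
  `Δp ~ N(0, p₁(1−p₁)·t/(2N_e))` (autosomes; `1.5N_e` on X), flagged when
  −log₁₀p exceeds a threshold (default 8).
* **Selection-intensity reconstruction** — from Falconer's
  `Δq = i·p·q·a/σ`, birth-date ASEs are regressed on `p(1−p)·ASE_trait/σ_ASE`
  by GLS with the signed LD correlation matrix as error structure, yielding
  a signed relative selection intensity per trait.
* **Support machinery** — PLINK PED/MAP and allele-count CSV readers/writers,
  SNP QC (call rate, MAF, Hardy–Weinberg χ² cap), imputation, deregression
  of EBVs with information weights, genetic-trend regressions, gene-window
  reports (BED/GFF3), Manhattan plots.
* **Forward simulator** — overlapping-generation pedigrees under
  era-dependent multi-trait index selection with pleiotropic QTLs, AI-sire
  usage skew, biased temporal family sampling, and neutral Wright–Fisher
  controls. Every analysis above is validated against it.

## Worked example

Simulate ten generations of truncation selection on a trait controlled by a
single QTL, then map it from birth dates alone:

```python
from bdsmap.simulate import simulate_selected_population, sweep_config
from bdsmap.relationship import grm_vanraden, base_allele_freqs, earliest_cohort
from bdsmap.gblup import GBLUP

pop = simulate_selected_population(sweep_config(seed=1))
g = pop.genotypes                       # 660 animals x 500 SNPs
p = base_allele_freqs(g, earliest_cohort(g, 60))
fit = GBLUP(g.birth_date, grm_vanraden(g, p)).fit()
print(fit.summary())
```

```
GBLUP animal model
==================
n animals:        660
sigma2_g:         128.217
sigma2_e:         77.2322
variance ratio:   0.6241
fixed effects (estimate +/- se):
  beta[0] = 1958.29 +/- 0.863
animal effects:   mean 17.2, sd 11.92
```

Multilocus genotypes explain 62% of the variance in *birth date* — the
genomic signature of a population reshaped by selection. The backsolved
per-SNP variances point at the causal locus:

```python
fit.snp_effects(g).top(3)
```

```
     snp chrom      pos     freq       ase  var_2pqa2  rank
snp00365     4 65500000 0.525000  3.910281   7.626036     1
snp00104     2  4500000 0.591667 -1.918278   1.778055     2
snp00052     1 52500000 0.550000 -1.466089   1.063962     3
```

`snp00365` is the simulated QTL (`pop.qtl_ids == ['snp00365']`); an ASE of
3.9 years per allele copy means carriers of two copies are born, on
average, almost eight years later than non-carriers. The companion drift
test agrees:

```python
from bdsmap.relationship import pedigree_inbreeding
from bdsmap.drift import generation_number, ne_from_inbreeding_regression, drift_test

F = pedigree_inbreeding(pop.pedigree)
gens = generation_number(pop.pedigree.birth_dates().to_numpy())
ne = ne_from_inbreeding_regression(F.F.to_numpy(), gens)
traj = pop.trajectories
drift = drift_test(traj.iloc[0], traj.iloc[-1], ne.Ne, n_generations=10,
                   snp_ids=list(traj.columns))
print(ne.Ne)            # 331.8  (from dF/generation = 0.0015)
print(drift.summary())
```

```
drift test: 500 SNPs, Ne = 331.82, threshold -log10 p = 8; 0.20% flagged as selected (0 fixed loci skipped)
```

The one flagged locus (0.20% of 500) is again the QTL.

A thin CLI mirrors the library (`bdsmap qc|gblup|emmax|bayescpi|drift|ne|
deregress|intensity|trend|genes-near|fixture`).

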