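"""End-to-end validation scenarios exercised on the built-in simulator.

Each function runs one self-contained experiment — simulate data under known
truth, run the corresponding analysis, and report the quantities a user
would check — and is shared by the test suite, the reproduction script and
the documentation examples.  Problem sizes are chosen to finish in seconds
to a few minutes on one CPU while leaving clear margins between the
behaviors being contrasted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayescpi import BayesCPi, BayesCPiConfig
from .drift import drift_test, generation_number, ne_from_inbreeding_regression
from .emmax import EMMAXScan, PoissonBirthDateScan
from .gblup import GBLUP, reml_single_kernel, snp_blup_ase
from .io import GenotypeDataset
from .relationship import (base_allele_freqs, earliest_cohort, grm_vanraden,
                           pedigree_inbreeding)
from .selection import (SelectionIntensityGLS, ld_signed_correlation,
                        prune_perfect_ld)
from .simulate import (SimConfig, simulate_confounded_families,
                       simulate_neutral_drift, simulate_selected_population,
                       sweep_config)

__all__ = [
    "bayescpi_null_pi",
    "bayescpi_sparse_recovery",
    "confounded_scan_contrast",
    "sweep_detection",
    "intensity_recovery_replicate",
    "intensity_recovery_rate",
    "ne_recovery",
    "null_reml_ratio",
    "drift_calibration",
    "neutral_genotypes",
    "sparse_trait",
]


def neutral_genotypes(n: int, m: int, seed: int,
                      freq_range=(0.1, 0.9)) -> GenotypeDataset:
    """Unstructured neutral genotypes with uniform random birth dates."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(*freq_range, m)
    calls = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    mono = calls.std(axis=0) == 0
    calls[0, mono] = 1  # keep every column polymorphic in-sample
    loci = pd.DataFrame({"snp": [f"s{j:05d}" for j in range(m)],
                         "chrom": "1", "pos": np.arange(1, m + 1) * 500})
    return GenotypeDataset([f"A{i:05d}" for i in range(n)],
                           1950 + rng.uniform(0, 50, n), loci, calls)


def sparse_trait(g: GenotypeDataset, causal_fraction: float, h2: float,
                 seed: int):
    """A trait with the given causal fraction and heritability on ``g``.

    Returns ``(y, causal_indices)``; effects are standard normal on the
    causal dosage columns, rescaled so the genetic share of var(y) is h2.
    """
    rng = np.random.default_rng(seed)
    m = g.n_snps
    nc = max(1, int(round(causal_fraction * m)))
    idx = np.sort(rng.choice(m, nc, replace=False))
    gv = g.dosages()[:, idx] @ rng.normal(0, 1, nc)
    gv = (gv - gv.mean()) / gv.std() * np.sqrt(h2)
    y = gv + rng.normal(0, np.sqrt(1 - h2), g.n_animals)
    return y, idx


# ---------------------------------------------------------------------------

def confounded_scan_contrast(seed: int = 0) -> dict:
    """Poisson baseline vs EMMAX on neutral, family-time-confounded data.

    Returns the genomic-inflation factors of both scans on the same
    dataset (n=300, m=1000, six drift-diverged families whose sampling
    depth tracks the era).
    """
    g = simulate_confounded_families(seed=seed)
    emmax = EMMAXScan(g.birth_date, g).fit()
    pois = PoissonBirthDateScan(g).fit()
    return {"lambda_poisson": pois.lambda_gc,
            "lambda_emmax": emmax.lambda_gc,
            "n": g.n_animals, "m": g.n_snps}


def sweep_detection(seed: int = 0, threshold_log10_p: float = 8.0) -> dict:
    """Detect a single-QTL sweep by GBLUP backsolve and the drift test.

    Simulates 10 generations of truncation selection on a one-QTL trait,
    estimates Ne from the pedigree inbreeding regression, tests each locus's
    frequency change between the founder and final cohorts against the
    10-generation drift envelope, and ranks loci by birth-date 2p(1-p)a^2.
    """
    pop = simulate_selected_population(sweep_config(seed))
    g = pop.genotypes
    qtl = pop.qtl_ids[0]

    F = pedigree_inbreeding(pop.pedigree)
    gens = generation_number(pop.pedigree.birth_dates().to_numpy())
    ne = ne_from_inbreeding_regression(F.F.to_numpy(), gens,
                                       subset="sweep pedigree")

    traj = pop.trajectories
    n_gen = len(traj) - 1
    res = drift_test(traj.iloc[0].to_numpy(), traj.iloc[-1].to_numpy(),
                     ne.Ne, threshold_log10_p=threshold_log10_p,
                     n_generations=n_gen, snp_ids=list(traj.columns))
    tab = res.table.set_index("snp")
    neutral = tab.drop(qtl, errors="ignore")

    p = base_allele_freqs(g, earliest_cohort(g, 60))
    G = grm_vanraden(g, p)
    fit = GBLUP(g.birth_date, G).fit()
    scan = fit.snp_effects(g)
    rank = int(scan.table.set_index("snp").loc[qtl, "rank"])
    return {
        "ne_estimate": ne.Ne,
        "qtl_flagged": bool(tab.loc[qtl, "flagged"]) if qtl in tab.index else True,
        "neutral_flag_rate": float(neutral["flagged"].mean()),
        "qtl_rank": rank,
        "m": len(scan),
        "qtl_rank_percentile": 100.0 * (1 - (rank - 1) / len(scan)),
        "variance_ratio": fit.variance_components.ratio,
    }


def _intensity_config(seed: int) -> SimConfig:
    """Three uncorrelated traits under index selection with weights
    (1, 0.3, 0) -> relative selection intensities proportional to the
    weights.  Every SNP is a (pleiotropic) QTL so the intensity regression
    has a regressor at each locus.  Cohorts of 600 keep the marker-space
    GBLUP's per-SNP ASE noise below the trait-2 vs trait-3 contrast."""
    return SimConfig(
        n_founders=600, births_per_year=600, start_year=1950, end_year=2000,
        generation_interval=5.0, discrete_generations=True,
        n_chromosomes=45, n_snps_per_chromosome=10, n_qtl=450, n_traits=3,
        heritabilities=(0.4, 0.4, 0.4), ebv_accuracy_r2=(0.7, 0.7, 0.7),
        index_eras=[(1950, np.array([1.0, 0.3, 0.0]))],
        proportion_sires=0.15, proportion_dams=0.50, sire_usage_skew=0.0,
        seed=seed)


def intensity_recovery_replicate(seed: int = 0) -> tuple[float, float, float]:
    """One replicate of the selection-intensity recovery experiment.

    Simulates index selection with per-trait intensities proportional to
    (1, 0.3, 0), estimates birth-date ASEs by marker-space GBLUP over the
    whole simulated register (variance components from REML on a 600-animal
    subsample), prunes perfect LD, and runs the GLS intensity regression
    against the true per-trait allele effects.  Returns the three estimated
    relative intensities.
    """
    pop = simulate_selected_population(_intensity_config(seed))
    g = pop.genotypes
    p = base_allele_freqs(g, earliest_cohort(g, 150))
    rng = np.random.default_rng(seed)
    sub = np.sort(rng.choice(g.n_animals, 600, replace=False))
    gs = g.subset(animal_idx=sub)
    vc = reml_single_kernel(gs.birth_date, None, grm_vanraden(gs, p))
    scan = snp_blup_ase(g.birth_date, g, p, vc)
    tab = scan.table.set_index("snp")
    keep = [s for s in tab.index if 0.02 < tab.loc[s, "freq"] < 0.98]
    keep = prune_perfect_ld(g, keep)
    tab = tab.loc[keep]
    traits = pop.qtl_effects.loc[keep]
    V = ld_signed_correlation(g, keep)
    res = SelectionIntensityGLS(tab["ase"], traits, tab["freq"], V).fit()
    return tuple(res[t].i_hat for t in ("trait1", "trait2", "trait3"))


def intensity_recovery_rate(n_replicates: int = 100, seed: int = 0) -> dict:
    """Fraction of replicates with correct signs and ordering i1 > i2 > i3."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_replicates)
    ok = 0
    for s in seeds:
        i1, i2, i3 = intensity_recovery_replicate(int(s) % (2 ** 31))
        ok += (i1 > i2 > i3) and (i1 > 0) and (i2 > 0)
    return {"recovery_rate": ok / n_replicates, "n": n_replicates}


def bayescpi_null_pi(n: int = 300, m: int = 500, iterations: int = 30_000,
                     seed: int = 0) -> dict:
    """Posterior mean pi when nothing predicts the dependent variable.

    With no associated SNPs the sampler should keep (nearly) all loci out of
    the model and drive pi towards 1.
    """
    g = neutral_genotypes(n, m, seed)
    rng = np.random.default_rng(seed + 1)
    y = rng.normal(0, 1, n)
    cfg = BayesCPiConfig(iterations=iterations, burn_in=1_000, seed=seed)
    res = BayesCPi(y, g, cfg).fit()
    return {"pi_mean": res.pi_mean, "pve": res.pve_mean, "n": n, "m": m}


def bayescpi_sparse_recovery(n: int = 500, m: int = 1000,
                             causal_fraction: float = 0.05, h2: float = 0.5,
                             iterations: int = 50_000, seed: int = 0) -> dict:
    """pi and inclusion-probability separation on a 5%-causal trait."""
    g = neutral_genotypes(n, m, seed)
    y, causal = sparse_trait(g, causal_fraction, h2, seed + 1)
    cfg = BayesCPiConfig(iterations=iterations, burn_in=1_000, seed=seed)
    res = BayesCPi(y, g, cfg).fit()
    inc = res.inclusion_prob.to_numpy()
    null = np.delete(inc, causal)
    return {"pi_mean": res.pi_mean,
            "causal_inclusion": float(inc[causal].mean()),
            "null_inclusion": float(null.mean()),
            "pve": res.pve_mean, "n": n, "m": m}


def ne_recovery(true_ne: int = 50, generations: int = 20,
                seed: int = 0) -> dict:
    """Estimate Ne from pedigree F in a random-mating population of known size.

    A closed population of ``true_ne`` animals per discrete generation mates
    at random (index weights zero); the pedigree-F-on-generation regression
    should recover Ne up to the usual factor reflecting unequal family sizes.
    """
    span = 5 * generations
    cfg = SimConfig(
        n_founders=true_ne, births_per_year=true_ne,
        start_year=1950, end_year=1950 + span,
        generation_interval=5.0, discrete_generations=True,
        n_chromosomes=1, n_snps_per_chromosome=10, n_qtl=0, n_traits=1,
        heritabilities=(0.4,), ebv_accuracy_r2=(0.7,),
        index_eras=[(1950, np.array([0.0]))],  # random mating
        sire_usage_skew=0.0,  # uniform sire usage, else Ne < census size
        seed=seed)
    pop = simulate_selected_population(cfg)
    F = pedigree_inbreeding(pop.pedigree)
    gens = generation_number(pop.pedigree.birth_dates().to_numpy())
    est = ne_from_inbreeding_regression(F.F.to_numpy(), gens,
                                        subset="random mating")
    return {"ne_estimate": est.Ne, "true_ne": true_ne,
            "delta_F": est.delta_F, "n_animals": est.n}


def null_reml_ratio(n: int = 500, m: int = 200, seed: int = 0) -> dict:
    """REML variance ratio for pure-noise birth dates on neutral genotypes.

    Under no selection the genomic variance share of birth date should be
    near zero.  The null sampling SD of the REML ratio grows roughly as
    sqrt(2 m)/n for an unstructured marker-derived kernel, so the default
    panel of m=200 markers at n=500 keeps that SD near 0.03 and the
    estimate well below 0.1.
    """
    g = neutral_genotypes(n, m, seed)
    rng = np.random.default_rng(seed + 1)
    y = rng.normal(0, 1, n)
    G = grm_vanraden(g, g.dosages().mean(axis=0) / 2.0)
    vc = reml_single_kernel(y, None, G)
    return {"variance_ratio": vc.ratio, "n": n, "m": m}


def drift_calibration(ne: float = 100.0, m: int = 10_000,
                      threshold_log10_p: float = 1.30,
                      seed: int = 0) -> dict:
    """Type-I error of the drift test on one-generation Wright-Fisher data.

    At -log10 p = 1.30 (a 95% interval) the flag rate of truly neutral loci
    should sit near 0.05; cohort frequencies are the exact post-drift
    frequencies, matching the test's omission of finite-sample noise.
    """
    drift = simulate_neutral_drift(ne, np.full(m, 0.5), 1, seed=seed)
    res = drift_test(drift.trajectories[0], drift.trajectories[1], ne,
                     threshold_log10_p=threshold_log10_p)
    return {"flag_rate": res.fraction_flagged, "m": m,
            "threshold": threshold_log10_p}
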