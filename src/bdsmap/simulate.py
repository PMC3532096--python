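"""Forward-in-time simulation of a pedigreed population under selection.

The generator emulates the data structure behind birth-date selection
mapping: an overlapping-generation pedigree spanning decades, multi-trait
truncation selection on an index of EBV-like criteria (with era-dependent
weights whose signs may flip mid-span, as happened historically for birth
weight), pleiotropic QTLs on a recombining genome, biased temporal sampling
of families for genotyping, and pure neutral drift controls.

Design choices: one Morgan per chromosome with Haldane (no-interference)
recombination; additive QTL effects only, matching the zero-dominance
assumption of the ASE framework downstream; EBV proxies are true breeding
values plus normal noise calibrated to a target accuracy, standing in for a
full genetic evaluation; all randomness flows through a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeDataset, Pedigree

__all__ = [
    "SimConfig",
    "SimPopulation",
    "simulate_selected_population",
    "simulate_neutral_drift",
    "NeutralDrift",
    "simulate_confounded_families",
    "make_fixture_bundle",
    "FIXTURES",
]


@dataclass
class SimConfig:
    """Study conditions for the forward simulator.

    The defaults describe a beef-cattle-like register: births every year
    from 1950 to 2000, a 5-year generation interval, parents used between 2
    and 10 years of age, a handful of heavily used sires (AI skew), three
    moderately heritable traits under index selection, and 20 pleiotropic
    QTLs among 500 SNPs on 5 one-Morgan chromosomes.
    """

    n_founders: int = 100
    births_per_year: int = 100
    start_year: int = 1950
    end_year: int = 2000
    generation_interval: float = 5.0
    min_parent_age: float = 2.0
    max_parent_age: float = 10.0
    n_chromosomes: int = 5
    n_snps_per_chromosome: int = 100
    n_qtl: int = 20
    n_traits: int = 3
    qtl_effect_corr: np.ndarray | None = None  # traits x traits; default I
    heritabilities: tuple = (0.4, 0.4, 0.4)
    ebv_accuracy_r2: tuple = (0.7, 0.7, 0.7)
    # eras: list of (first_year, index weights per trait); weights may change
    # sign between eras (e.g. a birth-weight style reversal)
    index_eras: list = field(default_factory=list)
    proportion_sires: float = 0.10
    proportion_dams: float = 0.50
    sire_usage_skew: float = 0.3  # geometric usage decay across ranked sires
    discrete_generations: bool = False
    founder_freq_range: tuple = (0.1, 0.9)
    n_genotyped_per_year: int | None = None  # None = genotype everyone
    sampling_family_bias: dict | None = None  # decade index -> {family: weight}
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_founders", "births_per_year", "n_chromosomes",
                     "n_snps_per_chromosome", "n_traits"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_qtl < 0 or self.n_qtl > self.n_snps:
            raise ValueError("n_qtl must lie in [0, total SNPs]")
        for h in self.heritabilities[: self.n_traits]:
            if not 0 < h < 1:
                raise ValueError("heritabilities must lie in (0, 1)")
        if not self.index_eras:
            self.index_eras = [(self.start_year, np.ones(self.n_traits))]

    @property
    def n_snps(self) -> int:
        return self.n_chromosomes * self.n_snps_per_chromosome

    def era_weights(self, year: float) -> np.ndarray:
        w = None
        for first, weights in self.index_eras:
            if year >= first:
                w = np.asarray(weights, dtype=float)
        if w is None:
            w = np.asarray(self.index_eras[0][1], dtype=float)
        return w

    def to_text(self, path):
        """Log the configuration verbatim as key = value lines."""
        with open(path, "w") as fh:
            for k, v in self.__dict__.items():
                fh.write(f"{k} = {v!r}\n")


@dataclass
class SimPopulation:
    """Simulator output: pedigree, genotypes, truth labels and trajectories."""

    pedigree: Pedigree
    genotypes: GenotypeDataset
    tbv: pd.DataFrame           # true breeding values, all animals x traits
    ebv: pd.DataFrame           # EBV proxies, all animals x traits
    ebv_accuracy_r2: tuple
    qtl_ids: list[str]
    qtl_effects: pd.DataFrame   # QTL x traits allele effects
    trajectories: pd.DataFrame  # year x SNP counted-allele frequency
    family: pd.Series           # paternal founder line per animal
    config: SimConfig

    @property
    def causal_ids(self) -> list[str]:
        return self.qtl_ids


def _genetic_map(cfg: SimConfig):
    """SNP map: chromosome labels, bp positions, genetic positions (Morgan)."""
    per = cfg.n_snps_per_chromosome
    chroms = np.repeat([str(c + 1) for c in range(cfg.n_chromosomes)], per)
    gpos = np.tile((np.arange(per) + 0.5) / per, cfg.n_chromosomes)
    bp = np.tile(((np.arange(per) + 0.5) / per * 1e8).astype(np.int64),
                 cfg.n_chromosomes)
    return chroms, bp, gpos


def _make_gametes(H, parents, chrom_slices, rng) -> np.ndarray:
    """Gametes for a batch of parents under Haldane recombination.

    Each chromosome spans one Morgan with evenly spaced loci, so the parental
    haplotype along it is a two-state Markov chain: a random starting strand
    and independent switches between adjacent loci with probability
    (1 - exp(-2d))/2 for map distance d — exactly the no-interference
    crossover model.  Returns a (len(parents), m) array.
    """
    parents = np.asarray(parents)
    G = parents.size
    gam = np.empty((G, H.shape[2]), dtype=H.dtype)
    for sl in chrom_slices:
        L = sl.stop - sl.start
        r = 0.5 * (1.0 - np.exp(-2.0 / L))  # adjacent-locus map distance 1/L
        start = rng.integers(0, 2, size=(G, 1))
        if L > 1:
            switches = (rng.random((G, L - 1)) < r).astype(np.int64)
            hap = (start + np.concatenate(
                [np.zeros((G, 1), dtype=np.int64),
                 np.cumsum(switches, axis=1)], axis=1)) % 2
        else:
            hap = start
        block = H[parents][:, :, sl]
        gam[:, sl] = np.where(hap == 0, block[:, 0, :], block[:, 1, :])
    return gam


def simulate_selected_population(cfg: SimConfig) -> SimPopulation:
    """Run the forward simulator; see :class:`SimConfig` for the knobs.

    Yearly steps: each year, age-eligible sires and dams are truncation
    selected on the current era's index of EBV proxies, sires drawing usage
    from a geometric (AI-skewed) distribution, and offspring genomes are
    formed by recombination and Mendelian segregation.  With
    ``discrete_generations`` births happen only every generation interval
    and parents come from the immediately preceding cohort.
    """
    rng = np.random.default_rng(cfg.seed)
    chroms, bp, gpos = _genetic_map(cfg)
    m = cfg.n_snps
    per = cfg.n_snps_per_chromosome
    chrom_slices = [slice(c * per, (c + 1) * per)
                    for c in range(cfg.n_chromosomes)]

    years = list(range(cfg.start_year, cfg.end_year + 1))
    if cfg.discrete_generations:
        step = int(cfg.generation_interval)
        birth_years = years[::step][1:]
    else:
        birth_years = years[1:]
    n_total = cfg.n_founders + cfg.births_per_year * len(birth_years)

    H = np.zeros((n_total, 2, m), dtype=np.uint8)
    sex = np.zeros(n_total, dtype=np.int8)          # 0 = male, 1 = female
    byear = np.zeros(n_total, dtype=float)
    sire = np.full(n_total, -1, dtype=np.int64)
    dam = np.full(n_total, -1, dtype=np.int64)
    family = np.zeros(n_total, dtype=np.int64)

    p0 = rng.uniform(*cfg.founder_freq_range, size=m)
    n_f = cfg.n_founders
    H[:n_f] = (rng.random((n_f, 2, m)) < p0).astype(np.uint8)
    sex[:n_f] = rng.permutation(np.arange(n_f) % 2).astype(np.int8)
    if cfg.discrete_generations:
        # founders are cohort 0, born in the first year of the span
        byear[:n_f] = cfg.start_year + rng.uniform(0.0, 1.0, size=n_f)
    else:
        byear[:n_f] = cfg.start_year - rng.uniform(
            0.5, cfg.generation_interval, size=n_f)
    family[:n_f] = np.arange(n_f)

    # QTL architecture: effects correlated across traits per the pleiotropy
    # matrix; same loci affect every trait
    qtl_idx = np.sort(rng.choice(m, size=cfg.n_qtl, replace=False))
    corr = (np.eye(cfg.n_traits) if cfg.qtl_effect_corr is None
            else np.asarray(cfg.qtl_effect_corr, dtype=float))
    L = np.linalg.cholesky(corr)
    effects = rng.standard_normal((cfg.n_qtl, cfg.n_traits)) @ L.T

    def tbv_of(rows: np.ndarray) -> np.ndarray:
        dos = H[rows][:, :, qtl_idx].sum(axis=1).astype(float)
        return dos @ effects

    tbv = np.zeros((n_total, cfg.n_traits))
    ebv = np.zeros((n_total, cfg.n_traits))
    tbv[:n_f] = tbv_of(np.arange(n_f))
    sd_g0 = tbv[:n_f].std(axis=0)
    sd_g0[sd_g0 == 0] = 1.0
    r2 = np.asarray(cfg.ebv_accuracy_r2[: cfg.n_traits], dtype=float)
    noise_sd = sd_g0 * np.sqrt(np.clip(1.0 / r2 - 1.0, 0.0, None))
    ebv[:n_f] = tbv[:n_f] + rng.standard_normal((n_f, cfg.n_traits)) * noise_sd

    traj_rows = {int(np.floor(cfg.start_year)):
                 H[:n_f].sum(axis=(1,)).mean(axis=0) / 2.0}
    next_row = n_f

    for year in birth_years:
        age = year - byear[:next_row]
        if cfg.discrete_generations:
            step = cfg.generation_interval
            eligible = (age >= step * 0.5) & (age <= step * 1.5)
        else:
            eligible = (age >= cfg.min_parent_age) & (age <= cfg.max_parent_age)
        males = np.flatnonzero(eligible & (sex[:next_row] == 0))
        females = np.flatnonzero(eligible & (sex[:next_row] == 1))
        if males.size == 0 or females.size == 0:
            raise RuntimeError(f"population extinct in {year}: no eligible "
                               "parents of one sex")
        w = cfg.era_weights(year)
        idx_m = ebv[males] @ w
        idx_f = ebv[females] @ w
        if np.allclose(w, 0):
            sel_m, sel_f = males, females  # random mating
        else:
            n_s = max(1, int(np.ceil(cfg.proportion_sires * males.size)))
            n_d = max(1, int(np.ceil(cfg.proportion_dams * females.size)))
            sel_m = males[np.argsort(-idx_m, kind="stable")[:n_s]]
            sel_f = females[np.argsort(-idx_f, kind="stable")[:n_d]]
        # AI skew: geometric usage over ranked sires
        usage = np.exp(-cfg.sire_usage_skew * np.arange(sel_m.size))
        usage /= usage.sum()
        n_b = cfg.births_per_year
        chosen_s = rng.choice(sel_m, size=n_b, p=usage)
        chosen_d = rng.choice(sel_f, size=n_b)
        rows = np.arange(next_row, next_row + n_b)
        H[rows, 0] = _make_gametes(H, chosen_s, chrom_slices, rng)
        H[rows, 1] = _make_gametes(H, chosen_d, chrom_slices, rng)
        sire[rows] = chosen_s
        dam[rows] = chosen_d
        family[rows] = family[chosen_s]
        sex[rows] = (rng.random(n_b) < 0.5).astype(np.int8)
        byear[rows] = year + rng.uniform(0.0, 1.0, size=n_b)
        tbv[rows] = tbv_of(rows)
        ebv[rows] = (tbv[rows]
                     + rng.standard_normal((n_b, cfg.n_traits)) * noise_sd)
        traj_rows[year] = H[rows].sum(axis=1).mean(axis=0) / 2.0
        next_row += n_b

    ids = [f"A{i:06d}" for i in range(n_total)]
    ped = Pedigree(pd.DataFrame({
        "animal": ids,
        "sire": [ids[s] if s >= 0 else "0" for s in sire],
        "dam": [ids[d] if d >= 0 else "0" for d in dam],
        "birth_date": byear,
    }))

    snp_ids = [f"snp{j:05d}" for j in range(m)]
    loci = pd.DataFrame({"snp": snp_ids, "chrom": chroms, "pos": bp})

    geno_rows = _choose_genotyped(cfg, byear, family, n_total, rng)
    calls = H[geno_rows].sum(axis=1).astype(np.int8)
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING
    genotypes = GenotypeDataset([ids[i] for i in geno_rows],
                                byear[geno_rows], loci, calls)

    qtl_ids = [snp_ids[j] for j in qtl_idx]
    traits = [f"trait{t + 1}" for t in range(cfg.n_traits)]
    traj = pd.DataFrame.from_dict(traj_rows, orient="index", columns=snp_ids)
    return SimPopulation(
        pedigree=ped,
        genotypes=genotypes,
        tbv=pd.DataFrame(tbv, index=ids, columns=traits),
        ebv=pd.DataFrame(ebv, index=ids, columns=traits),
        ebv_accuracy_r2=tuple(r2),
        qtl_ids=qtl_ids,
        qtl_effects=pd.DataFrame(effects, index=qtl_ids, columns=traits),
        trajectories=traj,
        family=pd.Series(family, index=ids, name="family"),
        config=cfg,
    )


def _choose_genotyped(cfg: SimConfig, byear, family, n_total, rng):
    """Which animals enter the genotyped sample, honoring the per-family
    depth schedule when one is configured."""
    if cfg.n_genotyped_per_year is None and cfg.sampling_family_bias is None:
        return np.arange(n_total)
    rows = []
    years = np.floor(byear).astype(int)
    per_year = cfg.n_genotyped_per_year or cfg.births_per_year
    for year in np.unique(years):
        cand = np.flatnonzero(years == year)
        k = min(per_year, cand.size)
        if cfg.sampling_family_bias:
            decade = (year - cfg.start_year) // 10
            fam_w = cfg.sampling_family_bias.get(int(decade), {})
            w = np.array([fam_w.get(int(family[i]), 1.0) for i in cand],
                         dtype=float)
            w /= w.sum()
            rows.extend(rng.choice(cand, size=k, replace=False, p=w))
        else:
            rows.extend(rng.choice(cand, size=k, replace=False))
    return np.sort(np.asarray(rows, dtype=np.int64))


# ---------------------------------------------------------------------------
# Neutral drift
# ---------------------------------------------------------------------------

@dataclass
class NeutralDrift:
    """Wright-Fisher trajectories and optional sampled cohort genotypes."""

    trajectories: np.ndarray            # (generations + 1, m)
    cohorts: dict                       # generation -> (n, m) genotype matrix

    def frequencies(self, generation: int) -> np.ndarray:
        return self.trajectories[generation]


def simulate_neutral_drift(Ne: float, p0, generations: int,
                           sample_sizes: dict | None = None,
                           seed: int = 0) -> NeutralDrift:
    """Binomial Wright-Fisher drift of independent loci at size Ne.

    Each generation resamples 2 Ne gametes per locus; fixation is absorbing.
    ``sample_sizes`` maps generation -> cohort size n; for those generations
    an (n, m) genotype sample (binomial(2, p)) is drawn.
    """
    if Ne <= 0:
        raise ValueError("Ne must be positive")
    p0 = np.asarray(p0, dtype=float)
    if np.any((p0 <= 0) | (p0 >= 1)):
        raise ValueError("starting frequencies must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    two_ne = int(round(2 * Ne))
    traj = np.empty((generations + 1, p0.size))
    traj[0] = p0
    cohorts = {}
    sample_sizes = sample_sizes or {}
    if 0 in sample_sizes:
        cohorts[0] = rng.binomial(2, p0, size=(sample_sizes[0], p0.size))
    for g in range(1, generations + 1):
        traj[g] = rng.binomial(two_ne, traj[g - 1]) / two_ne
        if g in sample_sizes:
            cohorts[g] = rng.binomial(2, traj[g],
                                      size=(sample_sizes[g], p0.size))
    return NeutralDrift(trajectories=traj, cohorts=cohorts)


# ---------------------------------------------------------------------------
# Confounded family sampling (the Poisson-baseline failure mode)
# ---------------------------------------------------------------------------

def simulate_confounded_families(n_animals: int = 300, m_snps: int = 1000,
                                 n_families: int = 6, fst: float = 0.1,
                                 span_years: tuple = (1950, 2000),
                                 family_time_concentration: float = 0.75,
                                 seed: int = 0) -> GenotypeDataset:
    """Neutral loci with family structure confounded with birth date.

    Families are drift-diverged lineages (family frequencies drawn from the
    Balding-Nichols beta at the given Fst); each family's members are
    concentrated in its own era of the time span, emulating the uneven
    temporal sampling depth of real family material.  No locus is under
    selection, so any scan association with birth date is spurious.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.15, 0.85, size=m_snps)
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    fam_freq = rng.beta(a, b, size=(n_families, m_snps))
    y0, y1 = span_years
    era_len = (y1 - y0) / n_families
    fam = np.empty(n_animals, dtype=int)
    birth = np.empty(n_animals)
    for i in range(n_animals):
        birth[i] = rng.uniform(y0, y1)
        era = min(int((birth[i] - y0) / era_len), n_families - 1)
        if rng.random() < family_time_concentration:
            fam[i] = era
        else:
            fam[i] = rng.integers(n_families)
    calls = rng.binomial(2, fam_freq[fam]).astype(np.int8)
    # guard against monomorphic columns in the sample
    mono = (calls.std(axis=0) == 0)
    if mono.any():
        flip = np.flatnonzero(mono)
        calls[rng.integers(n_animals, size=flip.size), flip] = 1
    loci = pd.DataFrame({
        "snp": [f"snp{j:05d}" for j in range(m_snps)],
        "chrom": "1",
        "pos": np.arange(1, m_snps + 1) * 1000,
    })
    return GenotypeDataset([f"A{i:05d}" for i in range(n_animals)],
                           birth, loci, calls)


# ---------------------------------------------------------------------------
# Fixture bundles
# ---------------------------------------------------------------------------

def _fixture_tiny_qc(outdir, seed):
    """10-SNP toy with exactly one violation of each QC filter."""
    from .io import write_genotypes

    rng = np.random.default_rng(seed)
    n = 400  # large enough that a het-free SNP exceeds the HWE cap of 300
    calls = rng.binomial(2, 0.5, size=(n, 10)).astype(np.int8)
    calls[: int(n * 0.2), 0] = MISSING           # SNP0: 80% call rate < 90%
    calls[:, 1] = 0                              # SNP1: monomorphic (MAF 0)
    half = n // 2
    calls[:half, 2] = 2                          # SNP2: no hets, chi2 = n
    calls[half:, 2] = 0
    calls[0, 1:] = MISSING                       # animal 0: 10% call rate
    loci = pd.DataFrame({"snp": [f"qc{j}" for j in range(10)], "chrom": "1",
                         "pos": np.arange(1, 11) * 100})
    g = GenotypeDataset([f"A{i:02d}" for i in range(n)],
                        1950 + rng.uniform(0, 50, n), loci, calls)
    write_genotypes(g, outdir / "tiny_qc.csv", format="counts_csv")
    return {"genotypes": outdir / "tiny_qc.csv"}


def _fixture_gblup_oracle(outdir, seed):
    """Small complete dataset (n=50, m=200) for dense-solver equivalences."""
    from .io import write_genotypes

    rng = np.random.default_rng(seed)
    n, m = 50, 200
    p = rng.uniform(0.1, 0.9, m)
    calls = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    mono = calls.std(axis=0) == 0
    calls[0, mono] = 1
    beta = np.where(rng.random(m) < 0.05, rng.normal(0, 0.5, m), 0.0)
    y = calls @ beta + rng.normal(0, 1.0, n)
    loci = pd.DataFrame({"snp": [f"s{j:03d}" for j in range(m)], "chrom": "1",
                         "pos": np.arange(1, m + 1) * 500})
    g = GenotypeDataset([f"A{i:03d}" for i in range(n)], 1950 + y - y.min(),
                        loci, calls)
    write_genotypes(g, outdir / "gblup_oracle.csv", format="counts_csv")
    return {"genotypes": outdir / "gblup_oracle.csv"}


def _fixture_confounded_sampling(outdir, seed):
    from .io import write_genotypes

    g = simulate_confounded_families(seed=seed)
    write_genotypes(g, outdir / "confounded_sampling.csv", format="counts_csv")
    return {"genotypes": outdir / "confounded_sampling.csv"}


def sweep_config(seed: int = 0) -> SimConfig:
    """Study conditions for the single-QTL selective-sweep scenario:
    discrete-generation truncation selection (top 20% of sires, 80% of dams)
    on one trait controlled by a single large QTL, over 10 generations.

    All loci start at frequency 0.5 so the sweep has room to run and the
    neutral drift variance is homogeneous across loci; parent numbers are
    kept high (Ne of a few hundred) so the drift envelope stays narrow
    relative to the selective response.  60 animals per cohort are
    genotyped, giving an analysis sample spread evenly over the span.
    """
    return SimConfig(
        n_founders=1000, births_per_year=1000,
        start_year=1950, end_year=2000, generation_interval=5.0,
        discrete_generations=True,
        n_chromosomes=5, n_snps_per_chromosome=100, n_qtl=1, n_traits=1,
        heritabilities=(0.4,), ebv_accuracy_r2=(0.7,),
        index_eras=[(1950, np.array([1.0]))],
        proportion_sires=0.20, proportion_dams=0.80, sire_usage_skew=0.0,
        founder_freq_range=(0.5, 0.5),
        n_genotyped_per_year=60,
        seed=seed)


def _fixture_selected_sweep(outdir, seed):
    from .io import write_genotypes

    pop = simulate_selected_population(sweep_config(seed))
    write_genotypes(pop.genotypes, outdir / "selected_sweep.ped",
                    format="ped_map")
    pop.pedigree.to_csv(outdir / "selected_sweep.pedigree.csv")
    pd.DataFrame({"qtl": pop.qtl_ids}).to_csv(
        outdir / "selected_sweep.truth.tsv", sep="\t", index=False)
    return {"genotypes": outdir / "selected_sweep.ped",
            "pedigree": outdir / "selected_sweep.pedigree.csv",
            "truth": outdir / "selected_sweep.truth.tsv"}


def _fixture_neutral_null(outdir, seed):
    from .io import write_genotypes

    rng = np.random.default_rng(seed)
    n, m = 300, 1000
    p = rng.uniform(0.1, 0.9, m)
    calls = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    mono = calls.std(axis=0) == 0
    calls[0, mono] = 1
    loci = pd.DataFrame({"snp": [f"s{j:04d}" for j in range(m)], "chrom": "1",
                         "pos": np.arange(1, m + 1) * 500})
    g = GenotypeDataset([f"A{i:03d}" for i in range(n)],
                        1950 + rng.uniform(0, 50, n), loci, calls)
    write_genotypes(g, outdir / "neutral_null.csv", format="counts_csv")
    return {"genotypes": outdir / "neutral_null.csv"}


FIXTURES = {
    "tiny_qc": _fixture_tiny_qc,
    "gblup_oracle": _fixture_gblup_oracle,
    "confounded_sampling": _fixture_confounded_sampling,
    "selected_sweep": _fixture_selected_sweep,
    "neutral_null": _fixture_neutral_null,
}


def make_fixture_bundle(name: str, outdir, seed: int = 0) -> dict:
    """Write one of the registered fixture bundles to ``outdir``.

    Returns a mapping of artefact role -> path.  Fixture names:
    ``tiny_qc``, ``gblup_oracle``, ``confounded_sampling``,
    ``selected_sweep``, ``neutral_null``.
    """
    from pathlib import Path

    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from "
                         f"{sorted(FIXTURES)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return FIXTURES[name](outdir, seed)
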