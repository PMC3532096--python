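"""Genotype, pedigree and trait-table containers with readers, writers and QC.

The central container is :class:`GenotypeDataset`: an animals x SNPs matrix of
counted-allele dosages (0/1/2, -1 for missing) together with a SNP map and each
animal's birth date expressed in decimal years (month and day converted to a
fraction of a year).  Genotypes arrive either as PLINK PED/MAP text files or as
a simple allele-count CSV.

QC mirrors standard SNP-array filtering: SNP call rate, animal call rate,
minor allele frequency, and a 1-df Hardy-Weinberg chi-square cap used to weed
out assay artefacts (e.g. polymorphisms inside copy-number variants) rather
than selected loci.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "SNPLocus",
    "GenotypeDataset",
    "Pedigree",
    "TraitTable",
    "QCReport",
    "GenotypeParseError",
    "GenotypeDataError",
    "read_genotypes",
    "write_genotypes",
    "read_pedigree",
    "qc_filter",
    "hwe_chi_square",
    "impute_missing",
]


class GenotypeParseError(ValueError):
    """A genotype file could not be parsed."""


class GenotypeDataError(ValueError):
    """Parsed genotype data are internally inconsistent."""


@dataclass(frozen=True)
class SNPLocus:
    """A mapped SNP: id, chromosome label, 1-based position, allele pair.

    ``alleles[0]`` is the counted allele: the 0/1/2 code is the number of
    copies of this allele.  Chromosome labels are strings ("1".."29", "X").
    """

    id: str
    chromosome: str
    position_bp: int
    alleles: tuple[str, str]

    @property
    def counted_allele(self) -> str:
        return self.alleles[0]


class GenotypeDataset:
    """Animals x SNPs allele-count matrix with map positions and birth dates.

    Parameters
    ----------
    animals : sequence of str
        Animal identifiers (unique).
    birth_date : array-like of float
        Birth date per animal, decimal years (e.g. 1987.45).
    loci : pandas.DataFrame
        Columns ``snp, chrom, pos, allele_counted, allele_other`` (alleles
        optional; default "A"/"B").
    calls : ndarray (n_animals, n_snps) of int8
        Counted-allele dosage codes in {0, 1, 2}; missing = -1.
    """

    def __init__(self, animals, birth_date, loci, calls):
        self.animals = list(map(str, animals))
        self.birth_date = np.asarray(birth_date, dtype=float)
        loci = loci.copy().reset_index(drop=True)
        if "allele_counted" not in loci:
            loci["allele_counted"] = "A"
        if "allele_other" not in loci:
            loci["allele_other"] = "B"
        loci["chrom"] = loci["chrom"].astype(str)
        loci["pos"] = loci["pos"].astype(np.int64)
        self.loci = loci
        self.calls = np.ascontiguousarray(calls, dtype=np.int8)
        self._validate()

    def _validate(self):
        n, m = self.calls.shape
        if len(self.animals) != n:
            raise GenotypeDataError(
                f"{len(self.animals)} animals but {n} genotype rows")
        if len(self.loci) != m:
            raise GenotypeDataError(
                f"{len(self.loci)} mapped loci but {m} genotype columns")
        if len(set(self.animals)) != n:
            raise GenotypeDataError("duplicate animal ids")
        if self.birth_date.shape != (n,):
            raise GenotypeDataError("birth_date length mismatch")
        if not np.all(np.isfinite(self.birth_date)):
            raise GenotypeDataError("non-finite birth dates")
        bad = ~np.isin(self.calls, [MISSING, 0, 1, 2])
        if bad.any():
            raise GenotypeDataError("genotype codes must be in {-1,0,1,2}")
        dup = self.loci.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise GenotypeDataError(
                "duplicate map position(s): "
                + ", ".join(self.loci.loc[dup, "snp"].head(5)))

    # -- basic properties -------------------------------------------------
    @property
    def n_animals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.loci["snp"])

    def has_missing(self) -> bool:
        return bool((self.calls == MISSING).any())

    def dosages(self) -> np.ndarray:
        """Dosage matrix as float64; raises if any call is missing."""
        if self.has_missing():
            raise GenotypeDataError(
                "dataset contains missing calls; run impute_missing first")
        return self.calls.astype(np.float64)

    def allele_freqs(self) -> np.ndarray:
        """Counted-allele frequency per SNP over non-missing calls."""
        c = self.calls.astype(float)
        c[self.calls == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(c, axis=0) / 2.0

    def snp_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def animal_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def subset(self, animal_idx=None, snp_idx=None) -> "GenotypeDataset":
        ai = np.arange(self.n_animals) if animal_idx is None else np.asarray(animal_idx)
        si = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeDataset(
            [self.animals[i] for i in ai],
            self.birth_date[ai],
            self.loci.iloc[si],
            self.calls[np.ix_(ai, si)],
        )

    def locus(self, j: int) -> SNPLocus:
        row = self.loci.iloc[j]
        return SNPLocus(str(row["snp"]), str(row["chrom"]), int(row["pos"]),
                        (str(row["allele_counted"]), str(row["allele_other"])))

    def __repr__(self):
        return (f"GenotypeDataset({self.n_animals} animals x {self.n_snps} SNPs, "
                f"{(self.calls == MISSING).mean():.2%} missing)")


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

class PedigreeError(ValueError):
    pass


class Pedigree:
    """Animal/sire/dam records with birth dates; unknown parent = "0".

    Records are stored topologically sorted (ancestors first), which the
    inbreeding recursion and the simulator both rely on.
    """

    UNKNOWN = "0"

    def __init__(self, records: pd.DataFrame):
        df = records.copy()
        for col in ("animal", "sire", "dam"):
            df[col] = df[col].astype(str)
        if df["animal"].duplicated().any():
            raise PedigreeError("duplicate animal records")
        known = set(df["animal"])
        # implicit founders: parents that have no record of their own
        extra = sorted(
            {p for p in pd.concat([df["sire"], df["dam"]])
             if p != self.UNKNOWN and p not in known})
        if extra:
            pad = pd.DataFrame({
                "animal": extra, "sire": self.UNKNOWN, "dam": self.UNKNOWN,
                "birth_date": np.nan})
            df = pd.concat([pad, df], ignore_index=True)
        g = nx.DiGraph()
        g.add_nodes_from(df["animal"])
        for _, r in df.iterrows():
            for p in (r["sire"], r["dam"]):
                if p != self.UNKNOWN:
                    g.add_edge(p, r["animal"])
        try:
            order = list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible:
            cyc = nx.find_cycle(g)
            raise PedigreeError(f"pedigree contains a cycle: {cyc}")
        df = df.set_index("animal").loc[order].reset_index()
        self.records = df
        self._index = {a: i for i, a in enumerate(df["animal"])}
        self._check_dates()

    def _check_dates(self):
        bd = dict(zip(self.records["animal"], self.records["birth_date"]))
        for _, r in self.records.iterrows():
            for p in (r["sire"], r["dam"]):
                if p == self.UNKNOWN:
                    continue
                bp, bc = bd.get(p, np.nan), r["birth_date"]
                if np.isfinite(bp) and np.isfinite(bc) and bp >= bc:
                    raise PedigreeError(
                        f"parent {p} (born {bp}) not older than {r['animal']} "
                        f"(born {bc})")

    def __len__(self):
        return len(self.records)

    @property
    def animals(self) -> list[str]:
        return list(self.records["animal"])

    def birth_dates(self) -> pd.Series:
        return self.records.set_index("animal")["birth_date"]

    def parent_indices(self) -> np.ndarray:
        """(n, 2) array of sire/dam row indices; -1 for unknown."""
        out = np.full((len(self), 2), -1, dtype=np.int64)
        for i, (_, r) in enumerate(self.records.iterrows()):
            for k, p in enumerate((r["sire"], r["dam"])):
                if p != self.UNKNOWN:
                    out[i, k] = self._index[p]
        return out

    def to_csv(self, path):
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        df = pd.read_csv(path, dtype={"animal": str, "sire": str, "dam": str})
        need = {"animal", "sire", "dam", "birth_date"}
        if not need.issubset(df.columns):
            raise PedigreeError(f"pedigree CSV must have columns {sorted(need)}")
        return cls(df)


def read_pedigree(path) -> Pedigree:
    return Pedigree.from_csv(path)


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------

@dataclass
class TraitTable:
    """EBVs with accuracies per animal x trait, plus per-trait h2 and c.

    ``ebv``/``accuracy_r2`` are DataFrames indexed by animal id with one
    column per trait.  ``h2[t]`` is the trait heritability; ``c[t]`` the
    fraction of genetic variance not captured by the markers (enters the
    deregression weights).
    """

    ebv: pd.DataFrame
    accuracy_r2: pd.DataFrame
    h2: dict[str, float]
    c: dict[str, float]

    def __post_init__(self):
        if not self.ebv.columns.equals(self.accuracy_r2.columns):
            raise ValueError("ebv and accuracy_r2 trait columns differ")
        r2 = self.accuracy_r2.to_numpy(dtype=float)
        if np.nanmin(r2) < 0 or np.nanmax(r2) > 1:
            raise ValueError("accuracies r2 must lie in [0, 1]")
        for t in self.ebv.columns:
            if not 0 < self.h2[t] <= 1:
                raise ValueError(f"h2 for {t} must be in (0, 1]")
            if not 0 <= self.c[t] <= 1:
                raise ValueError(f"c for {t} must be in [0, 1]")

    @property
    def traits(self) -> list[str]:
        return list(self.ebv.columns)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_map(map_path) -> pd.DataFrame:
    rows = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise GenotypeParseError(f"{map_path}:{ln}: expected 4 MAP fields")
        rows.append((parts[1], parts[0], int(parts[3])))
    if not rows:
        raise GenotypeParseError(f"{map_path}: empty MAP file")
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos"])


def _read_ped_map(path) -> GenotypeDataset:
    path = Path(path)
    map_path = path.with_suffix(".map")
    loci = _read_map(map_path)
    m = len(loci)
    animals, birth, rows = [], [], []
    alleles_seen: list[set] = [set() for _ in range(m)]
    raw = []
    lines = path.read_text().splitlines()
    if not any(l.strip() for l in lines):
        raise GenotypeParseError(f"{path}: empty PED file")
    for ln, line in enumerate(lines, 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise GenotypeParseError(
                f"{path}:{ln}: expected {6 + 2 * m} fields, got {len(parts)}")
        animals.append(parts[1])
        try:
            birth.append(float(parts[5]))
        except ValueError:
            raise GenotypeParseError(
                f"{path}:{ln}: phenotype field (birth date) not numeric")
        pair = parts[6:]
        raw.append(pair)
        for j in range(m):
            for a in (pair[2 * j], pair[2 * j + 1]):
                if a != "0":
                    alleles_seen[j].add(a)
    # counted allele = alphabetically first observed allele at the locus
    counted, other = [], []
    for j, s in enumerate(alleles_seen):
        if len(s) > 2:
            raise GenotypeDataError(
                f"locus {loci['snp'][j]}: more than two alleles {sorted(s)}")
        srt = sorted(s) if s else ["A", "B"]
        counted.append(srt[0])
        other.append(srt[1] if len(srt) > 1 else ("B" if srt[0] != "B" else "A"))
    loci["allele_counted"] = counted
    loci["allele_other"] = other
    calls = np.full((len(animals), m), MISSING, dtype=np.int8)
    for i, pair in enumerate(raw):
        for j in range(m):
            a1, a2 = pair[2 * j], pair[2 * j + 1]
            if a1 == "0" or a2 == "0":
                continue
            calls[i, j] = (a1 == counted[j]) + (a2 == counted[j])
    return GenotypeDataset(animals, birth, loci, calls)


def _read_counts_csv(path, map_path=None) -> GenotypeDataset:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise GenotypeParseError(f"{path}: empty file")
    if "animal" not in df.columns or "birth_date" not in df.columns:
        raise GenotypeParseError(
            f"{path}: counts CSV needs 'animal' and 'birth_date' columns")
    snp_cols = [c for c in df.columns if c not in ("animal", "birth_date")]
    if not snp_cols:
        raise GenotypeParseError(f"{path}: no SNP columns")
    calls = df[snp_cols].to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    if map_path is not None:
        loci = _read_map(map_path)
        if list(loci["snp"]) != snp_cols:
            raise GenotypeDataError("MAP SNP ids do not match CSV header")
    else:
        loci = pd.DataFrame({"snp": snp_cols, "chrom": "1",
                             "pos": np.arange(1, len(snp_cols) + 1)})
    return GenotypeDataset(df["animal"], df["birth_date"], loci, calls)


def read_genotypes(path, format: str = "counts_csv", map_path=None) -> GenotypeDataset:
    """Read genotypes from PLINK PED/MAP (``ped_map``) or an allele-count CSV.

    For ``ped_map`` the path is the .ped file (its .map sibling is implied)
    and the PED phenotype column carries the birth date in decimal years.
    Codes count the alphabetically first allele observed at each locus.
    """
    if format == "ped_map":
        return _read_ped_map(path)
    if format == "counts_csv":
        return _read_counts_csv(path, map_path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(g: GenotypeDataset, path, format: str = "counts_csv"):
    """Write a dataset in a format ``read_genotypes`` round-trips exactly."""
    path = Path(path)
    if format == "counts_csv":
        df = pd.DataFrame(
            g.calls.astype(float), columns=g.loci["snp"], index=None)
        df[df == MISSING] = np.nan
        df.insert(0, "birth_date", g.birth_date)
        df.insert(0, "animal", g.animals)
        df.to_csv(path, index=False)
        g.loci[["chrom", "snp", "pos"]].assign(cm=0)[
            ["chrom", "snp", "cm", "pos"]].to_csv(
            path.with_suffix(".map"), sep="\t", header=False, index=False)
        return
    if format == "ped_map":
        with open(path, "w") as fh:
            for i, animal in enumerate(g.animals):
                fields = ["FAM", animal, "0", "0", "0",
                          repr(float(g.birth_date[i]))]
                for j in range(g.n_snps):
                    c = g.calls[i, j]
                    a, b = g.loci["allele_counted"][j], g.loci["allele_other"][j]
                    fields += {0: [b, b], 1: [a, b], 2: [a, a],
                               MISSING: ["0", "0"]}[int(c)]
                fh.write(" ".join(fields) + "\n")
        with open(path.with_suffix(".map"), "w") as fh:
            for _, r in g.loci.iterrows():
                fh.write(f"{r['chrom']}\t{r['snp']}\t0\t{r['pos']}\n")
        return
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Counts of SNPs/animals removed by each filter, in application order."""

    snps_input: int
    animals_input: int
    snps_removed_call_rate: int = 0
    animals_removed_call_rate: int = 0
    snps_removed_maf: int = 0
    snps_removed_hwe: int = 0

    @property
    def snps_removed(self) -> int:
        return (self.snps_removed_call_rate + self.snps_removed_maf
                + self.snps_removed_hwe)

    def to_tsv(self, path):
        pd.Series(self.__dict__).to_csv(path, sep="\t", header=False)

    def __str__(self):
        return (f"QC: {self.snps_input} SNPs in; removed "
                f"{self.snps_removed_call_rate} (call rate), "
                f"{self.snps_removed_maf} (MAF), "
                f"{self.snps_removed_hwe} (HWE); "
                f"{self.animals_removed_call_rate} animals removed")


def hwe_chi_square(n_AA: float, n_AB: float, n_BB: float) -> float:
    """1-df Hardy-Weinberg chi-square from observed genotype counts.

    Expected counts use the sample allele frequency.  Monomorphic samples
    return 0 (observed equals expected exactly).
    """
    n = n_AA + n_AB + n_BB
    if min(n_AA, n_AB, n_BB) < 0:
        raise ValueError("negative genotype count")
    if n == 0:
        raise ValueError("no genotypes")
    p = (2 * n_AA + n_AB) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 0.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_AA, n_AB, n_BB], dtype=float)
    return float(np.sum((obs - exp) ** 2 / exp))


def _hwe_stats(calls: np.ndarray) -> np.ndarray:
    """Vectorized per-SNP HWE chi-square over non-missing calls."""
    nAA = (calls == 2).sum(axis=0).astype(float)
    nAB = (calls == 1).sum(axis=0).astype(float)
    nBB = (calls == 0).sum(axis=0).astype(float)
    n = nAA + nAB + nBB
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * nAA + nAB) / (2 * n)
        q = 1 - p
        eAA, eAB, eBB = n * p * p, 2 * n * p * q, n * q * q
        chi2 = ((nAA - eAA) ** 2 / eAA + (nAB - eAB) ** 2 / eAB
                + (nBB - eBB) ** 2 / eBB)
    chi2[~np.isfinite(chi2)] = 0.0  # monomorphic or empty
    return chi2


def qc_filter(g: GenotypeDataset, snp_call_min: float = 0.90,
              animal_call_min: float = 0.95, maf_min: float = 0.01,
              hwe_chi2_max: float = 300.0,
              hwe_autosomes_only: bool = True,
              x_label: str = "X") -> tuple[GenotypeDataset, QCReport]:
    """Apply the standard array QC filters, in a fixed order.

    Order: SNP call rate >= ``snp_call_min`` -> animal call rate >=
    ``animal_call_min`` -> MAF >= ``maf_min`` -> HWE chi-square <=
    ``hwe_chi2_max``.  MAF and HWE are computed on non-missing calls after the
    call-rate filters.  The HWE cap (default 300, far in the tail of a 1-df
    chi-square) targets assay artefacts, and by default is applied to
    autosomal SNPs only, X-linked loci being out of Hardy-Weinberg scope.
    """
    for thr, lo, hi, nm in ((snp_call_min, 0, 1, "snp_call_min"),
                            (animal_call_min, 0, 1, "animal_call_min"),
                            (maf_min, 0, 0.5, "maf_min")):
        if not lo <= thr <= hi:
            raise ValueError(f"{nm}={thr} outside [{lo},{hi}]")
    rep = QCReport(snps_input=g.n_snps, animals_input=g.n_animals)

    keep_snp = g.snp_call_rate() >= snp_call_min
    rep.snps_removed_call_rate = int((~keep_snp).sum())
    g = g.subset(snp_idx=np.flatnonzero(keep_snp))

    keep_an = g.animal_call_rate() >= animal_call_min
    rep.animals_removed_call_rate = int((~keep_an).sum())
    g = g.subset(animal_idx=np.flatnonzero(keep_an))

    p = g.allele_freqs()
    maf = np.minimum(p, 1 - p)
    keep_snp = maf >= maf_min
    # all-missing columns have NaN frequency: drop them here as uninformative
    keep_snp &= np.isfinite(maf)
    rep.snps_removed_maf = int((~keep_snp).sum())
    g = g.subset(snp_idx=np.flatnonzero(keep_snp))

    chi2 = _hwe_stats(g.calls)
    fail = chi2 > hwe_chi2_max
    if hwe_autosomes_only:
        fail &= (g.loci["chrom"] != x_label).to_numpy()
    rep.snps_removed_hwe = int(fail.sum())
    g = g.subset(snp_idx=np.flatnonzero(~fail))

    if g.n_snps == 0:
        raise GenotypeDataError("QC removed every SNP: empty dataset")
    return g, rep


def impute_missing(g: GenotypeDataset, method: str = "mean_dosage",
                   seed: int | None = None) -> GenotypeDataset:
    """Fill missing calls; ``mean_dosage`` rounds the locus mean dosage to the
    nearest integer code, ``sample_hwe`` draws binomial(2, p) genotypes at the
    locus frequency.  Non-missing calls are never touched."""
    if method not in ("mean_dosage", "sample_hwe"):
        raise ValueError(f"unknown imputation method {method!r}")
    if not g.has_missing():
        return g
    calls = g.calls.copy()
    miss = calls == MISSING
    all_missing = miss.all(axis=0)
    if all_missing.any():
        bad = list(g.loci.loc[all_missing, "snp"].head(10))
        raise GenotypeDataError(f"loci with every call missing: {bad}")
    p = g.allele_freqs()
    rng = np.random.default_rng(seed)
    for j in np.flatnonzero(miss.any(axis=0)):
        rows = np.flatnonzero(miss[:, j])
        if method == "mean_dosage":
            fill = np.int8(np.clip(round(2 * p[j]), 0, 2))
            calls[rows, j] = fill
        else:
            calls[rows, j] = rng.binomial(2, p[j], size=rows.size).astype(np.int8)
    return GenotypeDataset(g.animals, g.birth_date, g.loci, calls)
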