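"""Genomic and pedigree relationship structures.

Two genomic matrices are used downstream: the VanRaden genomic relationship
matrix G = ZZ'/(2 sum p(1-p)) with Z the dosage matrix centered by twice the
base-generation allele frequencies (used by GBLUP, and whose diagonal minus
one yields genomic inbreeding coefficients), and a Balding-Nichols kinship
(per-SNP centered and scaled identity-in-state average) used by the EMMAX
scan.  Pedigree inbreeding uses the Meuwissen-Luo recursion that underlies
the rapid numerator-relationship-matrix inverse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .io import GenotypeDataset, Pedigree

__all__ = [
    "RelationshipMatrix",
    "InbreedingVector",
    "base_allele_freqs",
    "grm_vanraden",
    "balding_nichols_kinship",
    "pedigree_inbreeding",
    "genomic_inbreeding",
    "grm_principal_components",
]


@dataclass
class RelationshipMatrix:
    """n x n symmetric relationship/kinship matrix with provenance.

    ``base_freqs`` records the per-SNP frequencies used for centering and
    scaling so SNP-effect backsolving can reuse exactly the same reference.
    """

    matrix: np.ndarray
    kind: str  # "grm_vanraden" | "balding_nichols"
    base_freqs: np.ndarray | None = None
    ids: list[str] | None = None
    ridge: float = 0.0

    def __post_init__(self):
        a = np.asarray(self.matrix, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("relationship matrix must be square")
        if not np.allclose(a, a.T, atol=1e-8):
            raise ValueError("relationship matrix must be symmetric")
        self.matrix = (a + a.T) / 2.0

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def stabilized(self, ridge: float = 1e-8) -> np.ndarray:
        """Matrix with a small diagonal ridge, for safe inversion."""
        return self.matrix + ridge * np.eye(self.n)

    def to_tsv(self, path):
        ids = self.ids or [str(i) for i in range(self.n)]
        pd.DataFrame(self.matrix, index=ids, columns=ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, kind="grm_vanraden"):
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), kind=kind, ids=list(df.index.astype(str)))

    def to_hdf5(self, path):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("matrix", data=self.matrix)
            f.attrs["kind"] = self.kind
            if self.base_freqs is not None:
                f.create_dataset("base_freqs", data=self.base_freqs)
            if self.ids is not None:
                f.create_dataset("ids", data=np.array(self.ids, dtype="S"))

    @classmethod
    def from_hdf5(cls, path):
        import h5py

        with h5py.File(path, "r") as f:
            ids = ([s.decode() for s in f["ids"][:]] if "ids" in f else None)
            bf = f["base_freqs"][:] if "base_freqs" in f else None
            return cls(f["matrix"][:], kind=str(f.attrs["kind"]),
                       base_freqs=bf, ids=ids)


@dataclass
class InbreedingVector:
    """Per-animal inbreeding coefficients F with their provenance.

    Pedigree F lies in [0, 1); genomic F (GRM diagonal minus 1) is referenced
    to the base allele frequencies and may be negative.
    """

    F: pd.Series
    source: str  # "pedigree" | "genomic"

    def to_tsv(self, path):
        self.F.rename(f"F_{self.source}").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------

def base_allele_freqs(g: GenotypeDataset, base_animals) -> np.ndarray:
    """Counted-allele frequencies over a declared base cohort.

    Frequencies are clamped to [eps, 1-eps] with eps = 1/(4*n_base) so that
    loci monomorphic within the (often small) base cohort do not produce
    degenerate centering or zero scaling downstream.
    """
    base = set(map(str, base_animals))
    if not base:
        raise ValueError("empty base animal set")
    idx = [i for i, a in enumerate(g.animals) if a in base]
    if not idx:
        raise ValueError("no base animals present in the dataset")
    missing = base - {g.animals[i] for i in idx}
    if missing:
        raise ValueError(f"base animals absent from dataset: {sorted(missing)[:5]}")
    sub = g.subset(animal_idx=idx)
    p = sub.dosages().mean(axis=0) / 2.0
    eps = 1.0 / (4.0 * len(idx))
    n_clamped = int(((p < eps) | (p > 1 - eps)).sum())
    if n_clamped:
        warnings.warn(
            f"{n_clamped} loci monomorphic or near-fixed in the base cohort; "
            f"frequencies clamped to [{eps:.4g}, {1 - eps:.4g}]")
    return np.clip(p, eps, 1 - eps)


def earliest_cohort(g: GenotypeDataset, m: int) -> list[str]:
    """The m earliest-born animals (stable tie-break on id order) — a
    convenience rule for choosing a base cohort."""
    order = np.argsort(g.birth_date, kind="stable")[:m]
    return [g.animals[i] for i in order]


def grm_vanraden(g: GenotypeDataset, p: np.ndarray) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    G = ZZ' / (2 sum_i p_i (1 - p_i)),  Z = M - 2p,
    with M the dosage matrix and p the base-generation allele frequencies.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (g.n_snps,):
        raise ValueError("frequency vector length does not match loci")
    M = g.dosages()
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("zero scaling denominator: all base frequencies fixed")
    Z = M - 2.0 * p
    G = (Z @ Z.T) / denom
    return RelationshipMatrix(G, kind="grm_vanraden", base_freqs=p,
                              ids=list(g.animals))


def balding_nichols_kinship(g: GenotypeDataset) -> RelationshipMatrix:
    """Balding-Nichols kinship matrix as used by the EMMAX scan.

    Each SNP column is centered by 2p and scaled by sqrt(2p(1-p)) at the
    sample frequency p, and the kinship is the average over SNPs of the
    products of the standardized scores.  Monomorphic SNPs are rejected
    (they carry no information and their scaling is undefined).
    """
    M = g.dosages()
    p = M.mean(axis=0) / 2.0
    mono = (p <= 0) | (p >= 1)
    if mono.any():
        bad = list(g.loci.loc[mono, "snp"].head(5))
        raise ValueError(f"monomorphic SNPs present (remove in QC): {bad}")
    Zs = (M - 2 * p) / np.sqrt(2 * p * (1 - p))
    K = (Zs @ Zs.T) / g.n_snps
    return RelationshipMatrix(K, kind="balding_nichols", base_freqs=p,
                              ids=list(g.animals))


@njit(cache=True)
def _meuwissen_luo(sire, dam):  # pragma: no cover - exercised via wrapper
    n = sire.shape[0]
    F = np.zeros(n)
    D = np.empty(n)
    t = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            D[i] = 1.0
        elif s < 0:
            D[i] = 0.75 - 0.25 * F[d]
        elif d < 0:
            D[i] = 0.75 - 0.25 * F[s]
        else:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        for j in range(i + 1):
            t[j] = 0.0
        t[i] = 1.0
        aii = 0.0
        for j in range(i, -1, -1):
            c = t[j]
            if c == 0.0:
                continue
            if sire[j] >= 0:
                t[sire[j]] += 0.5 * c
            if dam[j] >= 0:
                t[dam[j]] += 0.5 * c
            aii += c * c * D[j]
        F[i] = aii - 1.0
    return F


def pedigree_inbreeding(ped: Pedigree) -> InbreedingVector:
    """Pedigree inbreeding coefficients by the Meuwissen-Luo recursion.

    Founders (unknown parents) are assumed non-inbred and unrelated; the
    pedigree container guarantees acyclicity and ancestors-first ordering.
    """
    pars = ped.parent_indices()
    F = _meuwissen_luo(pars[:, 0].copy(), pars[:, 1].copy())
    return InbreedingVector(pd.Series(F, index=ped.animals), source="pedigree")


def genomic_inbreeding(G: RelationshipMatrix) -> InbreedingVector:
    """Genomic F = GRM diagonal minus one (base-frequency referenced)."""
    if G.kind != "grm_vanraden":
        raise TypeError("genomic inbreeding requires a VanRaden GRM")
    ids = G.ids or [str(i) for i in range(G.n)]
    return InbreedingVector(pd.Series(np.diag(G.matrix) - 1.0, index=ids),
                            source="genomic")


def grm_principal_components(G: RelationshipMatrix, k: int):
    """Top-k principal component scores of a relationship matrix.

    Returns ``(scores, eigenvalues)`` where scores are eigenvectors scaled by
    the square root of their (non-increasing) eigenvalues — the coordinates
    used to visualize population substructure.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= G.n:
        raise ValueError("k must be smaller than the matrix dimension")
    w, v = np.linalg.eigh(G.matrix)
    order = np.argsort(w)[::-1]
    w, v = w[order][:k], v[:, order][:, :k]
    scores = v * np.sqrt(np.clip(w, 0.0, None))
    return scores, w
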