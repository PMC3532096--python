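"""Single-kernel REML and GBLUP with SNP-effect backsolving.

Birth Date Selection Mapping fits the animal model

    y = X beta + g + e,   g ~ N(0, G sigma2_g),  e ~ N(0, D sigma2_e)

with y the vector of birth dates (or deregressed EBVs for trait analyses),
G a VanRaden genomic relationship matrix and D = diag(1/w) for optional
deregression weights w.  Variance components come from restricted maximum
likelihood, profiled over the heritability ratio after an eigendecomposition
of the (weight-transformed) kernel, so the optimization is one-dimensional,
deterministic and exact to the stated tolerance.

Allele substitution effects (ASEs) are recovered from the fitted animal
effects by backsolving

    alpha = Z' G^{-1} ghat / (2 sum_i p_i (1 - p_i)),   Z = M - 2p,

which is algebraically identical to ridge SNP-BLUP with shrinkage
lambda = sigma2_e * 2 sum p q / sigma2_g.  ASEs are converted to per-SNP
additive genetic variances 2 p (1-p) alpha^2 for ranking; GBLUP itself
produces no per-SNP significance tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .io import GenotypeDataset
from .relationship import RelationshipMatrix

__all__ = [
    "VarianceComponents",
    "ScanResult",
    "reml_single_kernel",
    "GBLUP",
    "GBLUPResults",
    "snp_blup_ase",
]


@dataclass
class VarianceComponents:
    """Genetic and residual variances (units of the dependent variable squared)."""

    sigma2_g: float
    sigma2_e: float

    def __post_init__(self):
        if self.sigma2_g < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def ratio(self) -> float:
        """Proportion of variance explained by the kernel (h2 analogue)."""
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0

    def __repr__(self):
        return (f"VarianceComponents(sigma2_g={self.sigma2_g:.6g}, "
                f"sigma2_e={self.sigma2_e:.6g}, ratio={self.ratio:.4f})")


class ScanResult:
    """Per-SNP scan table: ASE, 2p(1-p)alpha^2, optional p/q-values, ranks.

    A thin wrapper over a DataFrame with columns
    ``snp, chrom, pos, freq, ase, var_2pqa2[, se, p, q], rank``.
    Ranks are 1-based: by ascending q/p where present (association scans),
    else by descending per-SNP variance (GBLUP/BayesC-pi scans); ties break
    by map order (chromosome, position).
    """

    def __init__(self, table: pd.DataFrame, kind: str):
        self.table = table.reset_index(drop=True)
        self.kind = kind
        self._add_rank()

    def _add_rank(self):
        t = self.table
        chrom_key = t["chrom"].astype(str)
        if "p" in t.columns:
            order = np.lexsort((t["pos"], chrom_key, t["p"].fillna(np.inf)))
        else:
            order = np.lexsort((t["pos"], chrom_key, -t["var_2pqa2"]))
        rank = np.empty(len(t), dtype=int)
        rank[order] = np.arange(1, len(t) + 1)
        t["rank"] = rank

    def top(self, k: int) -> pd.DataFrame:
        return self.table[self.table["rank"] <= k].sort_values("rank")

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)

    def __len__(self):
        return len(self.table)

    def __repr__(self):
        return f"ScanResult({self.kind}, {len(self)} SNPs)"


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def _null_space_rotation(X: np.ndarray):
    """Orthonormal basis of the orthogonal complement of col(X)."""
    n, p = X.shape
    q, r = np.linalg.qr(X, mode="complete")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix X is rank deficient")
    return q[:, p:]


def reml_single_kernel(y, X, K, tol: float = 1e-8) -> VarianceComponents:
    """REML variance components of y = X beta + g + e, g ~ N(0, K sigma2_g).

    The restricted likelihood is profiled over the ratio
    h = sigma2_g / (sigma2_g + sigma2_e) after projecting onto the null
    space of X and eigendecomposing the projected kernel, leaving a 1-D
    bounded Brent optimization.  Deterministic given inputs.
    """
    y = np.asarray(y, dtype=float).ravel()
    K = K.matrix if isinstance(K, RelationshipMatrix) else np.asarray(K, float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kernel must be symmetric")
    Q2 = _null_space_rotation(X)
    Kq = Q2.T @ K @ Q2
    lam, U = np.linalg.eigh((Kq + Kq.T) / 2)
    if lam.min() < -1e-6 * max(1.0, abs(lam.max())):
        raise ValueError(f"kernel is not PSD (min projected eigenvalue {lam.min():.3g})")
    lam = np.clip(lam, 0.0, None)
    if lam.max() - lam.min() < 1e-8 * max(1.0, lam.max()):
        warnings.warn("kernel is nearly isotropic (K ~ I): variance ratio "
                      "is weakly identified")
    yt = U.T @ (Q2.T @ y)
    nf = yt.size  # n - p residual degrees of freedom

    def neg_restricted_ll(h):
        xi = h * lam + (1.0 - h)
        s2 = np.sum(yt * yt / xi) / nf
        return nf * np.log(s2) + np.sum(np.log(xi))

    res = minimize_scalar(neg_restricted_ll, bounds=(0.0, 1.0 - 1e-9),
                          method="bounded", options={"xatol": tol})
    h = float(res.x)
    # guard against boundary-adjacent local flatness: compare with endpoints
    for h0 in (0.0, 1.0 - 1e-9):
        if neg_restricted_ll(h0) < neg_restricted_ll(h):
            h = h0
    xi = h * lam + (1.0 - h)
    s2 = float(np.sum(yt * yt / xi) / nf)
    return VarianceComponents(sigma2_g=h * s2, sigma2_e=(1.0 - h) * s2)


# ---------------------------------------------------------------------------
# GBLUP model / results
# ---------------------------------------------------------------------------

class GBLUP:
    """Animal-model GBLUP of a dependent variable on a relationship matrix.

    Parameters
    ----------
    endog : array-like (n,)
        Dependent variable: birth dates in decimal years for selection
        mapping, or deregressed EBVs for trait analyses.
    relationship : RelationshipMatrix or ndarray
        Genomic relationship matrix G.
    exog : ndarray (n, p), optional
        Fixed-effect design; default intercept only.
    weights : array-like (n,), optional
        Positive record weights w; residual variance is sigma2_e / w_i
        (deregression weights).  Default uniform.
    """

    def __init__(self, endog, relationship, exog=None, weights=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        n = self.endog.size
        if isinstance(relationship, RelationshipMatrix):
            self.relationship = relationship
        else:
            self.relationship = RelationshipMatrix(
                np.asarray(relationship, float), kind="grm_vanraden")
        if self.relationship.n != n:
            raise ValueError("relationship matrix size does not match endog")
        self.exog = (np.ones((n, 1)) if exog is None
                     else np.asarray(exog, dtype=float))
        if weights is None:
            self.weights = np.ones(n)
        else:
            self.weights = np.asarray(weights, dtype=float).ravel()
            if np.any(self.weights <= 0):
                raise ValueError("weights must be positive")

    def estimate_variance_components(self) -> VarianceComponents:
        """Null-model REML for this endog/kernel/weights combination."""
        sw = np.sqrt(self.weights)
        yt = self.endog * sw
        Xt = self.exog * sw[:, None]
        Kt = self.relationship.matrix * np.outer(sw, sw)
        return reml_single_kernel(yt, Xt, Kt)

    def fit(self, vc: VarianceComponents | None = None) -> "GBLUPResults":
        if vc is None:
            vc = self.estimate_variance_components()
        n = self.endog.size
        G = self.relationship.matrix
        Dinv = 1.0 / self.weights  # residual covariance = sigma2_e * diag(1/w)
        V = vc.sigma2_g * G + vc.sigma2_e * np.diag(Dinv)
        if vc.sigma2_g == 0 and vc.sigma2_e == 0:
            raise ValueError("both variance components are zero")
        try:
            c, low = _chol(V)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "singular phenotypic covariance; consider a diagonal ridge "
                "on the relationship matrix")
        Vinv_y = _chol_solve(c, low, self.endog)
        Vinv_X = _chol_solve(c, low, self.exog)
        XtVinvX = self.exog.T @ Vinv_X
        beta = np.linalg.solve(XtVinvX, self.exog.T @ Vinv_y)
        beta_cov = np.linalg.inv(XtVinvX)
        resid = self.endog - self.exog @ beta
        ghat = vc.sigma2_g * (G @ _chol_solve(c, low, resid))
        return GBLUPResults(self, beta, beta_cov, ghat, vc)


def _chol(V):
    from scipy.linalg import cho_factor

    return cho_factor(V, lower=True)


def _chol_solve(c, low, b):
    from scipy.linalg import cho_solve

    return cho_solve((c, low), b)


def snp_blup_ase(y, g: GenotypeDataset, p: np.ndarray,
                 vc: VarianceComponents, weights=None) -> ScanResult:
    """Allele substitution effects by ridge SNP-BLUP (marker-space GBLUP).

    Solves (Zc' D Zc + lambda I) alpha = Zc' D yc with Z = M - 2p, lambda =
    sigma2_e * 2 sum p q / sigma2_g, D = diag(w), and the intercept absorbed
    by weighted centering.  Algebraically identical to fitting the animal
    model on the VanRaden GRM built from (g, p) and backsolving, but the
    linear algebra is m x m instead of n x n, so it is the preferred route
    when animals outnumber markers.
    """
    y = np.asarray(y, dtype=float).ravel()
    p = np.asarray(p, dtype=float)
    if p.shape != (g.n_snps,):
        raise ValueError("frequency vector length does not match loci")
    w = np.ones(y.size) if weights is None else np.asarray(weights, float)
    if vc.sigma2_g <= 0:
        raise ValueError("sigma2_g must be positive for SNP-BLUP")
    denom = 2.0 * np.sum(p * (1.0 - p))
    lam = vc.sigma2_e * denom / vc.sigma2_g
    Z = g.dosages() - 2.0 * p
    wsum = w.sum()
    yc = y - (w @ y) / wsum
    Zc = Z - (w @ Z) / wsum
    A = (Zc * w[:, None]).T @ Zc + lam * np.eye(g.n_snps)
    alpha = np.linalg.solve(A, (Zc * w[:, None]).T @ yc)
    table = pd.DataFrame({
        "snp": g.loci["snp"],
        "chrom": g.loci["chrom"],
        "pos": g.loci["pos"],
        "freq": p,
        "ase": alpha,
        "var_2pqa2": 2.0 * p * (1.0 - p) * alpha ** 2,
    })
    return ScanResult(table, kind="snp_blup")


class GBLUPResults:
    """Fitted GBLUP: fixed effects, animal effects, variance components."""

    def __init__(self, model: GBLUP, fixed_effects, fixed_cov, animal_effects, vc):
        self.model = model
        self.fixed_effects = np.asarray(fixed_effects)
        self.fixed_cov = np.asarray(fixed_cov)
        ids = model.relationship.ids or [str(i) for i in range(model.endog.size)]
        self.animal_effects = pd.Series(animal_effects, index=ids, name="ghat")
        self.variance_components = vc

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.exog @ self.fixed_effects + self.animal_effects.to_numpy()

    def snp_effects(self, g: GenotypeDataset,
                    p: np.ndarray | None = None,
                    ridge: float = 1e-8) -> ScanResult:
        """Backsolve per-SNP allele substitution effects from animal effects.

        ``g`` and ``p`` must be the loci and base frequencies the GRM was
        built from (checked against the matrix provenance when available).
        """
        G = self.model.relationship
        if G.kind != "grm_vanraden":
            raise TypeError("SNP backsolving requires a VanRaden GRM")
        if p is None:
            p = G.base_freqs
        if p is None:
            raise ValueError("base frequencies required for backsolving")
        p = np.asarray(p, dtype=float)
        if p.shape != (g.n_snps,):
            raise ValueError("locus mismatch between fit and genotype dataset")
        if G.base_freqs is not None and not np.allclose(G.base_freqs, p):
            raise ValueError("frequencies differ from those used to build G")
        if G.n != g.n_animals:
            raise ValueError("animal mismatch between fit and genotype dataset")
        Z = g.dosages() - 2.0 * p
        denom = 2.0 * np.sum(p * (1.0 - p))
        Ginv_g = np.linalg.solve(G.stabilized(ridge), self.animal_effects.to_numpy())
        alpha = (Z.T @ Ginv_g) / denom
        table = pd.DataFrame({
            "snp": g.loci["snp"],
            "chrom": g.loci["chrom"],
            "pos": g.loci["pos"],
            "freq": p,
            "ase": alpha,
            "var_2pqa2": 2.0 * p * (1.0 - p) * alpha ** 2,
        })
        return ScanResult(table, kind="gblup")

    def snp_blup_ase(self, g: GenotypeDataset,
                     p: np.ndarray | None = None) -> ScanResult:
        """ASEs via the marker-space route (identical to :meth:`snp_effects`)."""
        G = self.model.relationship
        return snp_blup_ase(self.model.endog, g,
                            G.base_freqs if p is None else p,
                            self.variance_components,
                            weights=self.model.weights)

    def summary(self) -> str:
        vc = self.variance_components
        se = np.sqrt(np.diag(self.fixed_cov))
        lines = [
            "GBLUP animal model",
            "==================",
            f"n animals:        {self.model.endog.size}",
            f"sigma2_g:         {vc.sigma2_g:.6g}",
            f"sigma2_e:         {vc.sigma2_e:.6g}",
            f"variance ratio:   {vc.ratio:.4f}",
            "fixed effects (estimate +/- se):",
        ]
        for i, (b, s) in enumerate(zip(self.fixed_effects, se)):
            lines.append(f"  beta[{i}] = {b:.6g} +/- {s:.3g}")
        g = self.animal_effects
        lines.append(f"animal effects:   mean {g.mean():.3g}, sd {g.std():.4g}")
        return "\n".join(lines)
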