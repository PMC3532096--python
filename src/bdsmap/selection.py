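"""Ranking selected SNPs, LD pruning, selection-intensity GLS, trends, genes.

The selection-intensity regression inverts the classical single-generation
response of allele frequency to selection on a correlated trait,

    delta q = -i p q a / sigma_p,

where i is the (signed) selection intensity and a the genotypic value, for
which the allele substitution effect (ASE) is the proxy under zero dominance.
Per-SNP birth-date ASEs (the realized frequency response) are regressed on
x_j = p_j q_j ASE_j^trait / sigma_ASE for each trait by generalized least
squares with error covariance proportional to V, the signed LD correlation
matrix of the SNPs, giving a relative selection intensity per trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gblup import ScanResult
from .io import GenotypeDataset

__all__ = [
    "ase_variance",
    "rank_top_snps",
    "ld_signed_correlation",
    "prune_perfect_ld",
    "SelectionIntensityGLS",
    "IntensityResults",
    "IntensityEstimate",
    "TrendFit",
    "genetic_trend",
    "GeneWindowHit",
    "genes_near_snps",
    "read_gene_annotation",
]

BONFERRONI_ALPHA = 0.05 / 16  # 16 production traits


def ase_variance(p, alpha):
    """Additive genetic variance attributed to a SNP: 2 p (1-p) alpha^2."""
    p = np.asarray(p, dtype=float)
    a = np.asarray(alpha, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    return 2.0 * p * (1.0 - p) * a ** 2


def rank_top_snps(scan: ScanResult, fraction: float | None = None,
                  k: int | None = None) -> list[str]:
    """Ids of the top SNPs of a scan (by its native ranking).

    Exactly one of ``fraction`` (of all SNPs, rounded to nearest) or an
    explicit ``k`` must be given.  Ties break by map order (the rank column
    is already deterministic).
    """
    if (fraction is None) == (k is None):
        raise ValueError("give exactly one of fraction or k")
    m = len(scan)
    if fraction is not None:
        if not 0 < fraction <= 1:
            raise ValueError("fraction must lie in (0, 1]")
        k = int(np.rint(fraction * m))
        k = max(k, 1)
    if not 0 < k <= m:
        raise ValueError(f"k={k} outside 1..{m}")
    top = scan.table.sort_values("rank").head(k)
    return list(top["snp"])


def ld_signed_correlation(g: GenotypeDataset, snps) -> pd.DataFrame:
    """Signed Pearson correlation r between dosages at pairs of SNPs."""
    snps = list(snps)
    if not snps:
        raise ValueError("empty SNP list")
    pos = {s: j for j, s in enumerate(g.loci["snp"])}
    missing = [s for s in snps if s not in pos]
    if missing:
        raise ValueError(f"SNPs absent from dataset: {missing[:5]}")
    M = g.dosages()[:, [pos[s] for s in snps]]
    sd = M.std(axis=0)
    if np.any(sd == 0):
        bad = [snps[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance SNP(s): {bad[:5]}")
    Z = (M - M.mean(axis=0)) / sd
    V = (Z.T @ Z) / M.shape[0]
    np.fill_diagonal(V, 1.0)
    return pd.DataFrame(V, index=snps, columns=snps)


def prune_perfect_ld(g: GenotypeDataset, snps, tol: float = 1e-12) -> list[str]:
    """Collapse runs of consecutive SNPs in perfect LD (|r| = 1) to the first.

    ``snps`` must be ordered by chromosome and position.  Within each maximal
    run of map-consecutive SNPs whose dosage columns are pairwise perfectly
    correlated, only the first is kept.
    """
    snps = list(snps)
    if len(snps) < 2:
        return snps
    pos = {s: j for j, s in enumerate(g.loci["snp"])}
    M = g.dosages()
    kept = [snps[0]]
    anchor = snps[0]
    for s in snps[1:]:
        same_chrom = (g.loci["chrom"][pos[s]] == g.loci["chrom"][pos[anchor]])
        a, b = M[:, pos[anchor]], M[:, pos[s]]
        if same_chrom and a.std() > 0 and b.std() > 0:
            r = float(np.corrcoef(a, b)[0, 1])
            if abs(abs(r) - 1.0) <= tol:
                continue  # still inside the perfect-LD run
        kept.append(s)
        anchor = s
    return kept


@dataclass
class IntensityEstimate:
    """Relative selection intensity for one trait (sign included)."""

    trait: str
    i_hat: float
    se: float
    p_value: float
    adjusted_R2: float
    model: str = "single-trait"

    @property
    def significant(self) -> bool:
        return self.p_value < BONFERRONI_ALPHA


class SelectionIntensityGLS:
    """GLS regression of birth-date ASEs on scaled trait ASEs.

    Parameters
    ----------
    birth_ases : array-like (s,)
        Birth-date ASEs over the (pruned) selected SNP set.
    trait_ases : DataFrame (s, traits)
        Per-trait ASEs over the same SNPs.
    freqs : array-like (s,)
        Counted-allele frequencies p of the SNPs.
    V : DataFrame or ndarray (s, s), optional
        Signed LD correlation matrix; identity (OLS) if omitted.

    Each trait's regressor is x_j = p_j (1-p_j) ASE_j / sd(ASE) with the
    standard deviation taken over the SNP set entering the regression.
    """

    def __init__(self, birth_ases, trait_ases: pd.DataFrame, freqs, V=None):
        self.y = np.asarray(birth_ases, dtype=float).ravel()
        self.trait_ases = trait_ases
        self.p = np.asarray(freqs, dtype=float).ravel()
        s = self.y.size
        if len(trait_ases) != s or self.p.size != s:
            raise ValueError("birth ASEs, trait ASEs and freqs must align")
        if V is None:
            V = np.eye(s)
        self.V = V.to_numpy() if isinstance(V, pd.DataFrame) else np.asarray(V, float)
        if self.V.shape != (s, s):
            raise ValueError("V dimension does not match the SNP set")
        w = np.linalg.eigvalsh(self.V)
        if w.min() <= 1e-10 * max(w.max(), 1.0):
            raise np.linalg.LinAlgError(
                "V is singular: prune perfect-LD SNPs before the regression")

    def _design(self, traits) -> np.ndarray:
        cols = []
        for t in traits:
            a = self.trait_ases[t].to_numpy(dtype=float)
            sd = a.std()
            if sd == 0:
                raise ValueError(f"trait {t!r} has constant ASEs")
            cols.append(self.p * (1 - self.p) * a / sd)
        return np.column_stack(cols)

    def fit(self) -> "IntensityResults":
        import statsmodels.api as sm

        traits = list(self.trait_ases.columns)
        singles = []
        for t in traits:
            X = sm.add_constant(self._design([t]))
            res = sm.GLS(self.y, X, sigma=self.V).fit()
            singles.append(IntensityEstimate(
                trait=t, i_hat=float(res.params[1]), se=float(res.bse[1]),
                p_value=float(res.pvalues[1]),
                adjusted_R2=float(res.rsquared_adj)))
        Xj = self._design(traits)
        cond = float(np.linalg.cond(Xj))
        if cond > 1e3:
            warnings.warn(f"joint design condition number {cond:.3g}: "
                          "joint coefficients are unreliable (multicollinearity)")
        res_joint = sm.GLS(self.y, sm.add_constant(Xj), sigma=self.V).fit()
        return IntensityResults(singles,
                                joint_adjusted_R2=float(res_joint.rsquared_adj),
                                joint_params=dict(zip(traits,
                                                      res_joint.params[1:])),
                                condition_number=cond)


class IntensityResults:
    """Per-trait relative selection intensities and the joint-model R2.

    Joint-model coefficients are retained but flagged unreliable when the
    design is multicollinear; only its adjusted R2 is reported in the
    summary.
    """

    def __init__(self, estimates: list[IntensityEstimate],
                 joint_adjusted_R2: float, joint_params: dict,
                 condition_number: float):
        self.estimates = estimates
        self.joint_adjusted_R2 = joint_adjusted_R2
        self.joint_params = joint_params
        self.condition_number = condition_number

    def __getitem__(self, trait: str) -> IntensityEstimate:
        for e in self.estimates:
            if e.trait == trait:
                return e
        raise KeyError(trait)

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "trait": e.trait, "i_hat": e.i_hat, "se": e.se, "p": e.p_value,
            "adj_R2": e.adjusted_R2,
            "significant": e.significant,
        } for e in self.estimates])

    def summary(self) -> str:
        lines = ["Relative selection intensities (single-trait GLS)",
                 "=================================================",
                 f"Bonferroni alpha = {BONFERRONI_ALPHA:.6f}"]
        for e in sorted(self.estimates, key=lambda e: -abs(e.i_hat)):
            star = " *" if e.significant else ""
            lines.append(f"  {e.trait:<12} i = {e.i_hat:+.4f} +/- {e.se:.4f} "
                         f"(p = {e.p_value:.3g}, adj R2 = {e.adjusted_R2:.3f})"
                         f"{star}")
        lines.append(f"joint model adjusted R2 = {self.joint_adjusted_R2:.3f} "
                     f"(condition number {self.condition_number:.3g}; "
                     "coefficients not reported)")
        return "\n".join(lines)


@dataclass
class TrendFit:
    """Linear and quadratic genetic-trend regressions for one trait."""

    linear_slope: float
    linear_aic: float
    linear_adj_r2: float
    linear_p: float
    quadratic_coef: float
    quadratic_aic: float
    quadratic_adj_r2: float
    quadratic_p: float

    @property
    def prefers_quadratic(self) -> bool:
        return self.quadratic_aic < self.linear_aic

    def summary(self) -> str:
        return "\n".join([
            "Genetic trend",
            "=============",
            f"linear:    slope {self.linear_slope:+.4g}/yr, "
            f"AIC {self.linear_aic:.2f}, adj R2 {self.linear_adj_r2:.3f}, "
            f"p {self.linear_p:.3g}",
            f"quadratic: x2 coef {self.quadratic_coef:+.4g}, "
            f"AIC {self.quadratic_aic:.2f}, adj R2 {self.quadratic_adj_r2:.3f}, "
            f"p {self.quadratic_p:.3g}",
            f"preferred: {'quadratic' if self.prefers_quadratic else 'linear'}",
        ])


def genetic_trend(debv, birth_date) -> TrendFit:
    """Fit linear and quadratic regressions of (deregressed) EBV on birth date."""
    import statsmodels.api as sm

    y = np.asarray(debv, dtype=float)
    t = np.asarray(birth_date, dtype=float)
    if y.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(t) == 0:
        raise ValueError("constant birth dates")
    tc = t - t.mean()  # center for a stable quadratic design
    lin = sm.OLS(y, sm.add_constant(tc)).fit()
    quad = sm.OLS(y, sm.add_constant(np.column_stack([tc, tc ** 2]))).fit()
    return TrendFit(
        linear_slope=float(lin.params[1]), linear_aic=float(lin.aic),
        linear_adj_r2=float(lin.rsquared_adj), linear_p=float(lin.f_pvalue),
        quadratic_coef=float(quad.params[2]), quadratic_aic=float(quad.aic),
        quadratic_adj_r2=float(quad.rsquared_adj),
        quadratic_p=float(quad.f_pvalue))


# ---------------------------------------------------------------------------
# Gene windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneWindowHit:
    snp: str
    gene: str
    distance_bp: int
    chromosome: str


def read_gene_annotation(path, format: str = "bed") -> pd.DataFrame:
    """Read gene intervals into a 1-based inclusive table
    ``gene, chrom, start, end``.

    BED input is 0-based half-open and converted; GFF3 is 1-based inclusive
    and used as-is (only ``gene`` features are kept).
    """
    if format == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 4:
            raise ValueError("BED needs >= 4 columns (chrom,start,end,name)")
        out = pd.DataFrame({
            "gene": df[3].astype(str), "chrom": df[0].astype(str),
            "start": df[1].astype(int) + 1, "end": df[2].astype(int)})
    elif format == "gff3":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "source", "type", "start", "end",
                                "score", "strand", "phase", "attributes"])
        df = df[df["type"] == "gene"]
        ids = df["attributes"].str.extract(r"ID=([^;]+)")[0]
        names = df["attributes"].str.extract(r"Name=([^;]+)")[0]
        out = pd.DataFrame({
            "gene": names.fillna(ids).astype(str),
            "chrom": df["chrom"].astype(str),
            "start": df["start"].astype(int), "end": df["end"].astype(int)})
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if (out["start"] > out["end"]).any():
        raise ValueError("annotation has intervals with start > end")
    return out.reset_index(drop=True)


def genes_near_snps(snps: pd.DataFrame, genes: pd.DataFrame,
                    window: int = 100_000) -> list[GeneWindowHit]:
    """All genes within ``window`` bp of each SNP (distance 0 if inside).

    ``snps`` needs columns ``snp, chrom, pos``; ``genes`` the output of
    :func:`read_gene_annotation`.  Distances run from the SNP position to
    the nearest edge of the gene interval (1-based inclusive, strand
    ignored).  SNP chromosomes with no counterpart in the annotation raise.
    """
    snp_chroms = set(snps["chrom"].astype(str))
    gene_chroms = set(genes["chrom"].astype(str))
    unmatched = snp_chroms - gene_chroms
    if unmatched:
        raise ValueError(
            f"chromosomes absent from annotation: {sorted(unmatched)}")
    hits: list[GeneWindowHit] = []
    for chrom, snp_sub in snps.groupby(snps["chrom"].astype(str)):
        gsub = genes[genes["chrom"].astype(str) == chrom]
        starts = gsub["start"].to_numpy()
        ends = gsub["end"].to_numpy()
        names = gsub["gene"].to_numpy()
        for _, row in snp_sub.iterrows():
            pos = int(row["pos"])
            dist = np.maximum.reduce([starts - pos, pos - ends,
                                      np.zeros_like(starts)])
            for gi in np.flatnonzero(dist <= window):
                hits.append(GeneWindowHit(snp=str(row["snp"]), gene=str(names[gi]),
                                          distance_bp=int(dist[gi]),
                                          chromosome=chrom))
    return hits
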