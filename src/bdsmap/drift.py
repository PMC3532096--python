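"""Effective population size from inbreeding and the drift-vs-selection test.

Under an idealized population of inbreeding effective size Ne, inbreeding
accumulates at dF = 1/(2 Ne) per generation; regressing individual inbreeding
coefficients F on generation number therefore estimates dF as the slope, and
Ne = 1 / (2 dF) with SE(Ne) ~= 2 Ne SE(dF) by the delta method.

Generation numbers for animals with shallow pedigrees are derived from birth
year as (birth_year - 1950) / 5, i.e. a 5-year generation interval anchored
at 1950; fractional and negative values are permitted.

The drift test asks, per SNP, whether the allele-frequency change between an
earlier and a later cohort exceeds what neutral drift can plausibly produce:
under drift, delta p ~ N(0, p1 (1 - p1) t / (2 Ne)) for autosomes (1.5 Ne for
the X chromosome, reflecting its 3/4 copy number), with p1 the earlier-cohort
frequency and t the number of generations separating the cohorts.  Loci whose
two-sided -log10 p exceeds the threshold (default 8) are flagged as selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeDataset
from .relationship import InbreedingVector

__all__ = [
    "generation_number",
    "NeEstimate",
    "ne_from_inbreeding_regression",
    "cohort_allele_freqs",
    "DriftTestResult",
    "drift_test",
]

REFERENCE_YEAR = 1950.0
GENERATION_INTERVAL = 5.0


def generation_number(birth_year) -> np.ndarray | float:
    """Generation number = (birth_year - 1950) / 5 (fractional allowed)."""
    by = np.asarray(birth_year, dtype=float)
    if not np.all(np.isfinite(by)):
        raise ValueError("birth years must be finite")
    out = (by - REFERENCE_YEAR) / GENERATION_INTERVAL
    return float(out) if out.ndim == 0 else out


@dataclass
class NeEstimate:
    """Inbreeding effective population size from an F-on-generation regression."""

    delta_F: float
    se_delta_F: float
    Ne: float
    se_Ne: float
    intercept: float
    n: int
    subset: str = "all"

    def summary(self) -> str:
        return "\n".join([
            "Effective population size (inbreeding regression)",
            "=================================================",
            f"subset:          {self.subset}",
            f"n animals:       {self.n}",
            f"intercept:       {self.intercept:.4f}",
            f"dF/generation:   {self.delta_F:.6g} +/- {self.se_delta_F:.4g}",
            f"Ne:              {self.Ne:.4f} +/- {self.se_Ne:.4f}",
        ])


def se_ne(Ne: float, se_delta_F: float) -> float:
    """Delta-method standard error: SE(Ne) ~= 2 Ne SE(dF)."""
    return 2.0 * Ne * se_delta_F


def ne_from_inbreeding_regression(F, generations, subset: str = "all") -> NeEstimate:
    """OLS of individual inbreeding F on generation number; Ne = 1/(2 slope).

    Raises if the fitted slope is non-positive (no inbreeding accumulation —
    Ne is then undefined).
    """
    f = F.F.to_numpy() if isinstance(F, InbreedingVector) else np.asarray(F, float)
    g = np.asarray(generations, dtype=float)
    if f.size != g.size:
        raise ValueError("F and generations length mismatch")
    if f.size < 3:
        raise ValueError("need at least 3 animals")
    if np.ptp(g) <= 0:
        raise ValueError("animals must span more than one generation value")
    res = stats.linregress(g, f)
    if res.slope <= 0:
        raise ValueError(
            f"no inbreeding accumulation (slope {res.slope:.3g} <= 0); "
            "Ne undefined")
    Ne = 1.0 / (2.0 * res.slope)
    return NeEstimate(delta_F=float(res.slope),
                      se_delta_F=float(res.stderr),
                      Ne=Ne, se_Ne=se_ne(Ne, float(res.stderr)),
                      intercept=float(res.intercept), n=f.size, subset=subset)


def cohort_allele_freqs(g: GenotypeDataset, cohort_a, cohort_b):
    """Counted-allele frequencies (p1, p2) per SNP in two disjoint cohorts."""
    a, b = set(map(str, cohort_a)), set(map(str, cohort_b))
    if not a or not b:
        raise ValueError("cohorts must be nonempty")
    overlap = a & b
    if overlap:
        raise ValueError(f"animals in both cohorts: {sorted(overlap)[:5]}")
    idx = {an: i for i, an in enumerate(g.animals)}
    missing = (a | b) - idx.keys()
    if missing:
        raise ValueError(f"cohort animals absent from dataset: "
                         f"{sorted(missing)[:5]}")
    M = g.dosages()
    p1 = M[[idx[x] for x in sorted(a)], :].mean(axis=0) / 2.0
    p2 = M[[idx[x] for x in sorted(b)], :].mean(axis=0) / 2.0
    return p1, p2


class DriftTestResult:
    """Per-SNP drift test table plus the flagged fraction.

    Columns: ``snp, chrom, p1, p2, delta_p, z, minus_log10_p, flagged``.
    SNPs fixed in the earlier cohort (zero drift variance) are excluded and
    counted in ``n_skipped``.
    """

    def __init__(self, table: pd.DataFrame, threshold: float, ne: float,
                 n_skipped: int):
        self.table = table
        self.threshold = threshold
        self.ne = ne
        self.n_skipped = n_skipped

    @property
    def fraction_flagged(self) -> float:
        return float(self.table["flagged"].mean()) if len(self.table) else 0.0

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        return (f"drift test: {len(self.table)} SNPs, Ne = {self.ne:.2f}, "
                f"threshold -log10 p = {self.threshold:g}; "
                f"{self.fraction_flagged:.2%} flagged as selected "
                f"({self.n_skipped} fixed loci skipped)")


def drift_test(p1, p2, Ne: float, chrom_type=None,
               threshold_log10_p: float = 8.0,
               n_generations: float = 1.0,
               snp_ids=None) -> DriftTestResult:
    """Test observed allele-frequency changes against neutral drift.

    Parameters
    ----------
    p1, p2 : array-like
        Counted-allele frequencies in the earlier and later cohorts; the
        earlier cohort supplies the drift variance.
    Ne : float
        Inbreeding effective population size.
    chrom_type : array-like of {"A", "X"}, optional
        Per-SNP chromosome class; drift variance is p1(1-p1)/(2 Ne) for
        autosomes and p1(1-p1)/(1.5 Ne) for the X.  Default all autosomal.
    threshold_log10_p : float
        Flag a SNP when -log10(two-sided p) exceeds this (8 corresponds to a
        99.999999% confidence interval).
    n_generations : float
        Generations separating the cohorts; the per-generation drift
        variance is multiplied by this (1 = adjacent generations).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("p1 and p2 must have equal length")
    if Ne <= 0:
        raise ValueError("Ne must be positive")
    m = p1.size
    if chrom_type is None:
        chrom_type = np.full(m, "A")
    chrom_type = np.asarray(chrom_type)
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(m)]
    ok = (p1 > 0) & (p1 < 1)
    n_skipped = int((~ok).sum())
    if n_skipped:
        warnings.warn(f"{n_skipped} SNP(s) fixed in the earlier cohort "
                      "skipped (zero drift variance)")
    denom = np.where(chrom_type == "X", 1.5 * Ne, 2.0 * Ne)
    var = p1 * (1 - p1) * n_generations / denom
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (p2 - p1) / np.sqrt(var)
    # -log10 two-sided normal p, computed in log space to survive z >> 8
    log10_sf = stats.norm.logsf(np.abs(z)) / np.log(10.0)
    minus_log10_p = -(log10_sf + np.log10(2.0))
    table = pd.DataFrame({
        "snp": np.asarray(snp_ids),
        "chrom": chrom_type,
        "p1": p1,
        "p2": p2,
        "delta_p": p2 - p1,
        "z": z,
        "minus_log10_p": minus_log10_p,
    })[ok]
    table["flagged"] = table["minus_log10_p"] > threshold_log10_p
    return DriftTestResult(table.reset_index(drop=True), threshold_log10_p,
                           Ne, n_skipped)
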