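"""Deregression of estimated breeding values into weighted pseudo-phenotypes.

An EBV is a shrunken predictor; using EBVs directly as dependent variables in
genomic analyses double-counts pedigree information and understates records on
well-proven animals.  Deregression removes the shrinkage (and, optionally,
the parent-average contribution), returning a pseudo-phenotype dEBV with an
information weight

    w = (1 - h2) / ((c + (1 - r2) / r2) * h2)

where r2 is the (deregressed) reliability, h2 the trait heritability and c
the fraction of genetic variance not captured by the markers.

Two modes are provided:

``simple``
    dEBV = EBV / r2 with the weight above — appropriate when parent-average
    double counting is negligible or parent EBVs are unavailable.
``parent_adjusted``
    Removes the parent-average contribution by solving the 2x2
    mixed-model-equation system for (parent average, individual) implied by
    the reliabilities, following the cited deregression procedure for
    genomic regression analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["DeregressedRecord", "deregress_ebv"]

WEIGHT_CAP = 1e4


@dataclass
class DeregressedRecord:
    """A deregressed pseudo-phenotype with its information weight."""

    debv: float
    weight: float
    accuracy_r2: float  # reliability of the deregressed information
    c: float
    mode: str

    def __post_init__(self):
        if not np.isfinite(self.debv):
            raise ValueError("non-finite deregressed EBV")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


def _weight(r2: float, h2: float, c: float) -> float:
    denom = (c + (1.0 - r2) / r2) * h2
    if denom <= 0:
        warnings.warn(
            f"deregression weight unbounded (r2={r2}, c={c}); capped at "
            f"{WEIGHT_CAP:g}")
        return WEIGHT_CAP
    w = (1.0 - h2) / denom
    if w > WEIGHT_CAP:
        warnings.warn(f"deregression weight {w:.3g} capped at {WEIGHT_CAP:g}")
        return WEIGHT_CAP
    return w


def deregress_ebv(ebv: float, r2: float, h2: float, c: float,
                  mode: str = "simple",
                  sire_ebv: float = 0.0, sire_r2: float = 0.0,
                  dam_ebv: float = 0.0, dam_r2: float = 0.0) -> DeregressedRecord:
    """Deregress one EBV given its reliability r2, trait h2 and constant c.

    See the module docstring for the two modes.  ``parent_adjusted`` needs
    sire/dam EBVs and reliabilities; unknown parents may be left at the
    defaults (EBV 0, reliability 0), which reduces the parent average to the
    population mean.
    """
    if not 0 < r2 <= 1:
        if r2 == 0:
            raise ValueError("r2 = 0: no information to deregress")
        raise ValueError("r2 must lie in (0, 1]")
    if not 0 < h2 <= 1:
        raise ValueError("h2 must lie in (0, 1]")
    if not 0 <= c < 1:
        raise ValueError("c must lie in [0, 1)")

    if mode == "simple":
        return DeregressedRecord(debv=ebv / r2, weight=_weight(r2, h2, c),
                                 accuracy_r2=r2, c=c, mode=mode)

    if mode != "parent_adjusted":
        raise ValueError(f"unknown deregression mode {mode!r}")

    lam = (1.0 - h2) / h2 if h2 < 1 else 1e-8
    r2_pa = (sire_r2 + dam_r2) / 4.0
    if r2_pa >= 0.5:
        r2_pa = 0.5 - 1e-9
    # information content (in lambda units) of the parent-average and of the
    # individual, recovered from the reliabilities via the 2x2 MME with
    # relationship precision [[4, -2], [-2, 2]] between PA and animal
    zpa = 4.0 * r2_pa / (1.0 - 2.0 * r2_pa)          # Z'Z_PA / lambda
    a = zpa + 4.0
    if r2 >= 1:
        r2 = 1 - 1e-9
    b = 4.0 / a + 1.0 / (1.0 - r2)                   # Z'Z_i / lambda + 2
    zi = b - 2.0
    if zi <= 0:
        raise ValueError(
            "EBV reliability does not exceed the parent-average information; "
            "nothing to deregress")
    pa = (sire_ebv + dam_ebv) / 2.0
    # right-hand sides y* = C [pa, ebv] with C in lambda units
    y_star_i = -2.0 * lam * pa + (zi + 2.0) * lam * ebv
    debv = y_star_i / (zi * lam)
    r2_star = zi / (zi + 1.0)
    return DeregressedRecord(debv=debv, weight=_weight(r2_star, h2, c),
                             accuracy_r2=r2_star, c=c, mode=mode)
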