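"""Correlation analyses over the strain survey table.

Ordinary least squares is used throughout (the copy-number literature
reports R² from linear fits, not rank correlations).  Censored inhibitory
copper values — recorded only as an upper bound, e.g. '<0.1 mM' for the
single-copy strain DTY3 — are included at their bound when a regression
requests all strains; whether to substitute the bound is an explicit,
logged assumption, not a silent default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .locus_model import StrainRecord

__all__ = ["RegressionResult", "linfit", "regress_copy_estimates", "regress_copper"]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r_squared: float
    p_two_sided: float
    n_points: int


def linfit(x: list[float], y: list[float]) -> RegressionResult:
    """Ordinary least squares of y on x with the two-sided zero-slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length with at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        r_squared=float(fit.rvalue**2),
        p_two_sided=float(fit.pvalue),
        n_points=int(x.size),
    )


def regress_copy_estimates(records: list[StrainRecord]) -> RegressionResult:
    """Deep-sequencing vs Southern copy number over strains with both estimates."""
    pairs = [
        (r.southern_copies, r.deepseq_copies) for r in records if r.deepseq_copies is not None
    ]
    if not pairs:
        raise ValueError("no strains with both copy-number estimates")
    x, y = zip(*pairs)
    return linfit(list(x), list(y))


def regress_copper(
    records: list[StrainRecord],
    subset: str = "diploid",
    censored_at_bound: bool = True,
) -> RegressionResult:
    """Inhibitory copper concentration vs Southern copy number.

    ``subset`` selects 'diploid', 'haploid' or 'all' strains.  Censored
    copper values are substituted at their bound when ``censored_at_bound``
    is set; otherwise censored strains are dropped.
    """
    if subset not in ("diploid", "haploid", "all"):
        raise ValueError(f"unknown subset {subset!r}")
    chosen = [r for r in records if subset == "all" or r.ploidy == subset]
    if not censored_at_bound:
        chosen = [r for r in chosen if not r.cu_censored]
    if not chosen:
        raise ValueError("empty strain subset")
    x = [r.southern_copies for r in chosen]
    y = [r.cu_inhib_mM for r in chosen]
    return linfit(x, y)
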