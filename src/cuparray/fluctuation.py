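"""Luria-Delbrück fluctuation analysis: culture simulation and rate estimation.

Mutation rates are estimated from the distribution of mutant counts across
parallel cultures.  The Lea-Coulson method of the median solves

    r_median / m - ln(m) = 1.24

for m, the expected number of mutations per culture, and converts it to a
per-division rate as mu = m / N_final.  The culture simulator grows each
culture by discrete doublings from a small inoculum, draws new mutations
binomially from the divisions of each generation, and doubles existing
mutant lineages, producing the characteristic heavy-tailed ("jackpot")
count distribution.

A composite rate scales a base rate by an event fraction observed in a
secondary screen — here the fraction of marker-loss derivatives whose array
collapsed all the way to a single CUP1 copy — with a Clopper-Pearson
binomial interval propagated onto the rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "FluctuationResult",
    "CompositeRate",
    "lc_median_estimate",
    "simulate_ld_cultures",
    "composite_rate",
]

LEA_COULSON_CONSTANT = 1.24


@dataclass(frozen=True)
class FluctuationResult:
    median_mutants: float
    m_hat: float | None  # inferred mutations per culture
    mu_hat: float | None  # per-division rate
    n_cultures: int
    n_final: float
    below_detection: bool = False


def _solve_lea_coulson(r_median: float, lo: float = 1e-6, hi: float = 1e9, rtol: float = 1e-9) -> float:
    """Bisection solve of r/m - ln(m) = 1.24 for m (left side decreasing in m)."""

    def f(m: float) -> float:
        return r_median / m - math.log(m) - LEA_COULSON_CONSTANT

    if f(lo) < 0 or f(hi) > 0:
        raise ValueError(f"median {r_median} outside solvable range")
    while (hi - lo) > rtol * max(abs(lo), abs(hi)):
        mid = math.sqrt(lo * hi)  # bisect in log space; m spans 15 decades
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def lc_median_estimate(mutant_counts: list[int], n_final: float) -> FluctuationResult:
    """Method-of-the-median rate estimate from per-culture mutant counts.

    A zero median means the rate is below what the culture size can detect;
    the result is flagged rather than given a numeric estimate.
    """
    if n_final <= 0:
        raise ValueError("final cell count must be positive")
    counts = list(mutant_counts)
    if not counts:
        raise ValueError("no cultures given")
    if len(counts) < 10:
        warnings.warn(
            f"only {len(counts)} cultures; the median estimator is unreliable below 10",
            stacklevel=2,
        )
    r_med = float(np.median(counts))
    if r_med <= 0:
        return FluctuationResult(r_med, None, None, len(counts), n_final, below_detection=True)
    m = _solve_lea_coulson(r_med)
    return FluctuationResult(r_med, m, m / n_final, len(counts), n_final)


def simulate_ld_cultures(
    mu: float,
    n0: int = 1000,
    n_final: float = 2e7,
    n_cultures: int = 60,
    seed: int | np.random.Generator = 0,
    return_mutation_events: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Per-culture mutant counts under discrete-generation exponential growth.

    Each generation the population doubles (the final generation may be
    partial so the target ``n_final`` is hit exactly); every division can
    yield a mutant with probability ``mu`` and existing mutant lineages grow
    at the same rate as the rest of the culture.
    """
    if not 0 <= mu < 0.1:
        raise ValueError("mu must be a small probability")
    if n0 >= n_final:
        raise ValueError("inoculum must be smaller than the final population")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_final = int(n_final)

    mutants = np.zeros(n_cultures, dtype=np.int64)
    events = np.zeros(n_cultures, dtype=np.int64)
    pop = n0
    while pop < n_final:
        new_pop = min(2 * pop, n_final)
        divisions = new_pop - pop
        growth = new_pop / pop - 1.0  # 1.0 for a full doubling
        if growth >= 1.0:
            mutants *= 2
        else:
            mutants += rng.binomial(mutants, growth)
        if mu > 0:
            new = rng.binomial(divisions, mu, size=n_cultures)
            mutants += new
            events += new
        pop = new_pop
    if return_mutation_events:
        return mutants, events
    return mutants


@dataclass(frozen=True)
class CompositeRate:
    rate: float
    ci_low: float
    ci_high: float
    k_events: int
    n_screened: int
    base_rate: float


def composite_rate(
    k_events: int, n_screened: int, base_rate: float, confidence: float = 0.95
) -> CompositeRate:
    """Rate of a sub-class of events: (k/n) x base_rate with a binomial interval.

    The Clopper-Pearson interval on the proportion k/n is propagated
    linearly onto the rate.
    """
    if n_screened <= 0:
        raise ValueError("n_screened must be positive")
    if not 0 <= k_events <= n_screened:
        raise ValueError("k_events must lie in 0..n_screened")
    alpha = 1.0 - confidence
    lo = 0.0 if k_events == 0 else stats.beta.ppf(alpha / 2, k_events, n_screened - k_events + 1)
    hi = (
        1.0
        if k_events == n_screened
        else stats.beta.ppf(1 - alpha / 2, k_events + 1, n_screened - k_events)
    )
    frac = k_events / n_screened
    return CompositeRate(
        rate=frac * base_rate,
        ci_low=lo * base_rate,
        ci_high=hi * base_rate,
        k_events=k_events,
        n_screened=n_screened,
        base_rate=base_rate,
    )
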