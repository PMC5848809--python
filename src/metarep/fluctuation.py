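"""Expected read-count fluctuation between equal-depth replicates.

Given a gene's mapped-read count c1 in replicate 1, the count in an
equal-depth technical replicate is modeled as Poisson with mean c1 (the
large-catalog limit of binomial thinning; a binomial(depth, c1/depth)
alternative is available).  The concordance band is the equal-tail
two-sided interval at the chosen level, with the discrete CDF computed by
direct pmf summation and ties resolved toward the wider interval:

    lo = max{k : P(X <  k) <= (1-level)/2}
    hi = min{k : P(X <= k) >= 1-(1-level)/2}

A replicate pair "agrees" on a gene when the replicate-2 count falls in
the band built from the replicate-1 count.  Note the band conditions on
c1 as if it were the true mean; it does not propagate replicate 1's own
sampling noise, so on twin draws from a common abundance vector the
realized concordance of mid-count genes sits below the nominal level
(asymptotically ~93% for a 99% band).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "FluctuationInterval",
    "CoverageSummary",
    "fluctuation_interval",
    "interval_bounds",
    "coverage_fraction",
    "detectability_threshold",
]


@dataclass(frozen=True)
class FluctuationInterval:
    count1: int
    level: float
    lo: int
    hi: int


@dataclass(frozen=True)
class CoverageSummary:
    n_genes_evaluated: int
    n_within: int

    @property
    def fraction_within(self) -> float:
        return self.n_within / self.n_genes_evaluated if self.n_genes_evaluated else float("nan")


def _check_level(level: float) -> None:
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0,1), got {level}")


@lru_cache(maxsize=None)
def _poisson_bounds(count1: int, level: float) -> tuple[int, int]:
    # CDF by direct pmf summation (log pmf exponentiated, cumulative sum);
    # the 12-sigma grid comfortably brackets both tails
    lam = float(count1)
    alpha = (1.0 - level) / 2.0
    kmax = int(lam + 12.0 * np.sqrt(lam) + 20.0)
    k = np.arange(kmax + 1)
    log_pmf = -lam + k * np.log(lam) - gammaln(k + 1)
    cdf = np.cumsum(np.exp(log_pmf))
    cdf_before = np.concatenate(([0.0], cdf[:-1]))  # P(X < k)
    lo = int(np.flatnonzero(cdf_before <= alpha)[-1])
    hi = int(np.searchsorted(cdf, 1.0 - alpha, side="left"))
    return lo, min(hi, kmax)


@lru_cache(maxsize=None)
def _binomial_bounds(count1: int, level: float, depth: int) -> tuple[int, int]:
    alpha = (1.0 - level) / 2.0
    dist = stats.binom(depth, count1 / depth)
    k = np.arange(depth + 1)
    cdf = dist.cdf(k)
    # lo = max{k : P(X < k) <= alpha}
    below = np.flatnonzero(np.concatenate(([0.0], cdf[:-1])) <= alpha)
    lo = int(below[-1])
    hi = int(np.argmax(cdf >= 1.0 - alpha))
    return lo, hi


def interval_bounds(count1: int, level: float = 0.99, model: str = "poisson", depth: int | None = None) -> tuple[int, int]:
    """Equal-tail concordance bounds (lo, hi) for a replicate-2 count."""
    _check_level(level)
    if count1 < 0:
        raise ValueError("count1 must be >= 0")
    if count1 == 0:
        return 0, 0
    if model == "poisson":
        return _poisson_bounds(int(count1), float(level))
    if model == "binomial":
        if depth is None:
            raise ValueError("binomial model requires depth")
        return _binomial_bounds(int(count1), float(level), int(depth))
    raise ValueError(f"unknown fluctuation model {model!r}")


def fluctuation_interval(count1: int, level: float = 0.99, model: str = "poisson", depth: int | None = None) -> FluctuationInterval:
    lo, hi = interval_bounds(count1, level, model, depth)
    return FluctuationInterval(int(count1), float(level), lo, hi)


def coverage_fraction(rep1, rep2, level: float = 0.99, model: str = "poisson", depth: int | None = None) -> CoverageSummary:
    """Fraction of genes (rep1 count >= 1) with rep2 inside the band.

    ``rep1`` and ``rep2`` are count vectors over one shared gene universe,
    in the same order.
    """
    _check_level(level)
    rep1 = np.asarray(rep1, dtype=np.int64)
    rep2 = np.asarray(rep2, dtype=np.int64)
    if rep1.shape != rep2.shape:
        raise ValueError("replicates must share one gene universe")
    mask = rep1 >= 1
    c1 = rep1[mask]
    c2 = rep2[mask]
    uniq, inv = np.unique(c1, return_inverse=True)
    bounds = np.array([interval_bounds(int(c), level, model, depth) for c in uniq])
    lo, hi = bounds[inv, 0], bounds[inv, 1]
    within = (c2 >= lo) & (c2 <= hi)
    return CoverageSummary(int(mask.sum()), int(within.sum()))


def detectability_threshold(level: float = 0.99, model: str = "poisson", depth: int | None = None, max_count: int = 1000) -> int:
    """Smallest replicate-1 count whose band excludes zero.

    Genes at or above this count are predicted detectable (>= 1 read) in
    the replicate at the given concordance level.
    """
    _check_level(level)
    for c in range(1, max_count + 1):
        if interval_bounds(c, level, model, depth)[0] >= 1:
            return c
    raise RuntimeError(f"no detectable count found up to {max_count}")
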