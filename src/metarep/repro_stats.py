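"""Replicate reproducibility statistics over highly-reproducible genes.

Highly reproducible (HR) genes carry at least ``min_count`` mapped reads in
*both* members of a replicate pair; for multi-pair analyses a gene must
qualify in at least ``min_pairs`` pairs.  On that gene set the module
computes:

* Spearman rank correlation of abundance profiles,
* ALC — the area left of the cumulative curve of per-gene |log2|
  abundance differences, which equals their mean; ``2**ALC`` expresses it
  as an average fold change (1.0 = perfect agreement),
* per-gene paired t tests (on log2 abundance) and exact paired sign tests
  across pairs, each family adjusted by Benjamini-Hochberg step-up, a gene
  being called significantly different when either family's FDR q-value
  falls below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "hr_genes",
    "hr_gene_mask",
    "spearman",
    "alc",
    "ALCResult",
    "CorrelationResult",
    "paired_gene_tests",
    "bh_adjust",
]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    level: str = "gene"


@dataclass(frozen=True)
class ALCResult:
    alc: float
    n_genes: int

    @property
    def fold_change(self) -> float:
        return float(2.0 ** self.alc)


def hr_gene_mask(pairs, min_count: int = 10, min_pairs: int = 6) -> np.ndarray:
    """Boolean mask of genes with >= min_count reads in both members of
    at least ``min_pairs`` of the given (rep1, rep2) count-vector pairs."""
    if len(pairs) == 0:
        raise ValueError("need at least one replicate pair")
    if min_pairs > len(pairs):
        raise ValueError(f"min_pairs={min_pairs} exceeds the {len(pairs)} pairs given")
    qual = None
    for a, b in pairs:
        a = np.asarray(a)
        b = np.asarray(b)
        q = (a >= min_count) & (b >= min_count)
        qual = q.astype(np.int64) if qual is None else qual + q
    return qual >= min_pairs


def hr_genes(pairs_df: dict[str, pd.DataFrame] | list, min_count: int = 10, min_pairs: int = 6):
    """Index-aware variant: pairs as list of (SeriesA, SeriesB); returns the
    qualifying gene index."""
    first = pairs_df[0][0]
    mask = hr_gene_mask(
        [(a.to_numpy(), b.reindex(a.index).to_numpy()) for a, b in pairs_df],
        min_count,
        min_pairs,
    )
    return first.index[mask]


def spearman(a, b, level: str = "gene") -> CorrelationResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be 1-D and share their ids")
    if a.size < 3:
        raise ValueError("need n >= 3 for a rank correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("rank correlation undefined for a constant profile")
    rho = stats.spearmanr(a, b).statistic
    return CorrelationResult(float(rho), int(a.size), level)


def alc(a, b) -> ALCResult:
    """Mean |log2(a_g / b_g)| over the (HR-filtered) genes of two profiles."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must share their gene set")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("ALC needs positive abundances; filter to HR genes first")
    d = np.abs(np.log2(a / b))
    return ALCResult(float(d.mean()), int(d.size))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _sign_test_pvals(diffs: np.ndarray) -> np.ndarray:
    """Exact two-sided sign test per row; zero differences dropped from n."""
    pos = (diffs > 0).sum(axis=1)
    neg = (diffs < 0).sum(axis=1)
    n = pos + neg
    k = np.minimum(pos, neg)
    p = np.ones(len(diffs))
    nz = n > 0
    # two-sided exact binomial(1/2): 2 * P(X <= min(pos, neg)), capped at 1
    p[nz] = np.minimum(1.0, 2.0 * stats.binom.cdf(k[nz], n[nz], 0.5))
    return p


def paired_gene_tests(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    genes,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene paired tests of abundance across matched sample pairs.

    ``group_a`` and ``group_b`` are genes x samples abundance tables whose
    columns are paired positionally.  Returns one row per gene in
    ``genes``: p and BH q for the paired t test on log2 abundance and for
    the exact sign test, plus a ``significant`` flag (either q < alpha).
    Genes with zero abundance in some sample are testable by the sign test
    only; the t test requires >= 3 pairs of finite log abundances.
    """
    if group_a.shape[1] != group_b.shape[1]:
        raise ValueError("groups must contain the same number of paired samples")
    n_pairs = group_a.shape[1]
    a = group_a.loc[genes].to_numpy(dtype=float)
    b = group_b.loc[genes].to_numpy(dtype=float)

    with np.errstate(divide="ignore"):
        log_d = np.log2(a) - np.log2(b)
    diffs = a - b

    p_sign = _sign_test_pvals(diffs)

    finite = np.isfinite(log_d)
    p_t = np.ones(len(log_d))
    t_ok = finite.all(axis=1) & (n_pairs >= 3)
    if t_ok.any():
        d = log_d[t_ok]
        sd = d.std(axis=1, ddof=1)
        const = sd == 0
        tt = np.full(d.shape[0], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            tt = d.mean(axis=1) / (sd / np.sqrt(n_pairs))
        pt = 2.0 * stats.t.sf(np.abs(tt), df=n_pairs - 1)
        pt[const & (np.abs(d.mean(axis=1)) == 0)] = 1.0  # all differences zero
        p_t[t_ok] = pt

    q_t = np.ones_like(p_t)
    q_t[t_ok] = bh_adjust(p_t[t_ok])
    q_sign = bh_adjust(p_sign)

    return pd.DataFrame(
        {
            "n_pairs": n_pairs,
            "p_t": p_t,
            "q_t": q_t,
            "p_sign": p_sign,
            "q_sign": q_sign,
            "significant": (q_t < alpha) | (q_sign < alpha),
        },
        index=pd.Index(genes, name="gene_id"),
    )
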