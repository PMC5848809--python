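"""GC-bias quantification across sequencing platforms.

Two complementary analyses:

* **Per-species robust regression.**  Within one species, gene abundance
  should not depend on gene GC content, so for each species log10 gene
  abundance is regressed on GC fraction with a Huber M-estimator
  (c = 1.345, MAD scale); the median slope across species summarizes the
  platform's GC tilt.  A platform free of GC bias has median slope near 0.

* **Log-linear test on a 2x2x2 species cube.**  Species observations are
  dichotomized at the pooled medians into high/low abundance and high/low
  GC on each platform; the no-three-way-interaction hierarchical
  log-linear model is fitted by iterative proportional fitting (IPF) and
  compared to the saturated model with a likelihood-ratio (G²) test on
  1 degree of freedom.  A small P value means the abundance-GC association
  differs between platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RobustFit",
    "SpeciesSlopeSummary",
    "LRTResult",
    "gc_content",
    "huber_fit",
    "species_slopes",
    "build_cube",
    "ipf_fit",
    "loglinear_lrt",
]

_GC = frozenset("GCgc")
_AT = frozenset("ATat")


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T), case-insensitive; ambiguous bases ignored."""
    gc = sum(1 for ch in seq if ch in _GC)
    at = sum(1 for ch in seq if ch in _AT)
    if gc + at == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return gc / (gc + at)


@dataclass(frozen=True)
class RobustFit:
    slope: float
    intercept: float
    scale: float
    n_iter: int
    converged: bool


def huber_fit(x, y, c: float = 1.345, tol: float = 1e-8, max_iter: int = 50) -> RobustFit:
    """Huber M-estimate of y = intercept + slope*x via IRLS.

    Scale is the (renormalized) median absolute deviation of residuals.
    With no outliers beyond c scale units the estimate coincides with
    ordinary least squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("design degenerate: x is constant")
    X = sm.add_constant(x)
    model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=c))
    res = model.fit(scale_est="mad", conv="coefs", tol=tol, maxiter=max_iter)
    n_iter = len(res.fit_history["params"])
    return RobustFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        scale=float(res.scale),
        n_iter=n_iter,
        converged=bool(n_iter < max_iter),
    )


@dataclass
class SpeciesSlopeSummary:
    slopes: pd.Series  # per-species Huber slope
    skipped: list = field(default_factory=list)

    @property
    def median_slope(self) -> float:
        return float(self.slopes.median())

    @property
    def n_species(self) -> int:
        return int(self.slopes.size)


def species_slopes(
    abundance: pd.Series,
    catalog: pd.DataFrame,
    species_list=None,
    min_genes: int = 3,
) -> SpeciesSlopeSummary:
    """Per-species Huber slope of log10 gene abundance on gene GC.

    ``abundance`` is indexed by gene id; ``catalog`` provides ``gc_fraction``
    and ``species`` per gene (genes without a species label are ignored).
    Species with fewer than ``min_genes`` positively-abundant genes are
    skipped and reported in ``skipped``.
    """
    cat = catalog.dropna(subset=["species"]) if "species" in catalog else catalog
    if "species" not in cat:
        raise ValueError("catalog lacks a species column")
    ab = abundance.reindex(cat.index)
    pos = ab > 0
    slopes = {}
    skipped = []
    groups = cat.index.groupby(cat["species"])
    names = species_list if species_list is not None else sorted(groups)
    for sp in names:
        genes = pd.Index(groups.get(sp, []))
        genes = genes[pos.reindex(genes, fill_value=False)]
        gc = cat.loc[genes, "gc_fraction"].to_numpy(dtype=float)
        if len(genes) < min_genes or np.ptp(gc) == 0:
            skipped.append(sp)
            continue
        fit = huber_fit(gc, np.log10(ab.loc[genes].to_numpy(dtype=float)))
        slopes[sp] = fit.slope
    return SpeciesSlopeSummary(pd.Series(slopes, dtype=float), skipped)


def build_cube(
    species_a: pd.DataFrame | pd.Series,
    species_b: pd.DataFrame | pd.Series,
    gc_by_species: pd.Series,
) -> np.ndarray:
    """Tally a 2x2x2 cube (abundance hi/lo, GC hi/lo, platform).

    Inputs are species abundance profiles per platform (a Series, or a
    DataFrame of samples averaged per species).  Hi/lo cutpoints are the
    medians of the pooled abundance observations and of the species GC
    values.  Species without a GC value are dropped.  Axis order:
    [abundance (0=hi,1=lo), GC (0=hi,1=lo), platform (0=A,1=B)].
    """
    prof = []
    for p in (species_a, species_b):
        s = p.mean(axis=1) if isinstance(p, pd.DataFrame) else p
        prof.append(s.astype(float))
    common = prof[0].index.union(prof[1].index)
    gc = gc_by_species.reindex(common).dropna()
    prof = [s.reindex(gc.index).dropna() for s in prof]
    pooled = np.concatenate([s.to_numpy() for s in prof])
    ab_med = float(np.median(pooled))
    gc_med = float(gc.median())
    cube = np.zeros((2, 2, 2), dtype=np.int64)
    for k, s in enumerate(prof):
        ab_lo = (s.to_numpy() <= ab_med).astype(int)
        gc_lo = (gc.reindex(s.index).to_numpy() <= gc_med).astype(int)
        np.add.at(cube, (ab_lo, gc_lo, k), 1)
    return cube


@dataclass(frozen=True)
class LRTResult:
    g2: float
    df: int
    p: float
    converged: bool
    fitted: np.ndarray


def ipf_fit(cube: np.ndarray, tol: float = 1e-10, max_iter: int = 1000) -> tuple[np.ndarray, bool]:
    """Fit the no-three-way-interaction log-linear model by IPF.

    Cycles over the three two-way margins (01, 02, 12) rescaling the fitted
    table until every margin matches the observed one within ``tol``.
    """
    obs = np.asarray(cube, dtype=float)
    if obs.shape != (2, 2, 2) or obs.min() < 0 or obs.sum() <= 0:
        raise ValueError("cube must be a non-negative 2x2x2 table with positive total")
    fit = np.ones_like(obs) * obs.sum() / 8.0
    margins = [(2,), (1,), (0,)]  # sum out one axis -> preserve the other two
    for _ in range(max_iter):
        for ax in margins:
            target = obs.sum(axis=ax, keepdims=True)
            current = fit.sum(axis=ax, keepdims=True)
            ratio = np.where(current > 0, target / np.where(current > 0, current, 1.0), 0.0)
            fit = fit * ratio
        # all margins must agree simultaneously, not just the last one matched
        delta = max(
            float(np.abs(fit.sum(axis=ax) - obs.sum(axis=ax)).max()) for ax in (0, 1, 2)
        )
        if delta < tol:
            return fit, True
    return fit, False


def loglinear_lrt(cube: np.ndarray) -> LRTResult:
    """G² likelihood-ratio test of the three-way interaction term.

    Compares the IPF fit (all two-way margins preserved, three-way term
    omitted) against the saturated model; G² = 2 Σ obs·ln(obs/fit) over
    cells with obs > 0, on 1 df.
    """
    obs = np.asarray(cube, dtype=float)
    fitted, converged = ipf_fit(obs)
    nz = obs > 0
    g2 = float(2.0 * np.sum(obs[nz] * np.log(obs[nz] / fitted[nz])))
    g2 = max(g2, 0.0)
    p = float(stats.chi2.sf(g2, df=1))
    return LRTResult(g2=g2, df=1, p=p, converged=converged, fitted=fitted)
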