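"""End-to-end synthetic experiments composing the pipeline stages.

These are the experiments the package's validation rests on: twin
technical replicates drawn from one shared community (the reproducibility
null) and a two-platform comparison with an injected GC tilt (the bias
alternative).  Both are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fluctuation, gc_bias, quantify, repro_stats, synthetic

__all__ = [
    "twin_coverage_pct",
    "twin_reproducibility",
    "platform_comparison",
    "TwinReproResult",
    "PlatformComparisonResult",
]


def _twin_world(n_genes: int, sigma: float, seed: int):
    spec = synthetic.SimCatalogSpec(n_genes=n_genes, n_species=max(20, n_genes // 2000))
    catalog = synthetic.simulate_catalog(spec, seed)
    profile = synthetic.simulate_abundances(catalog, synthetic.SimCommunitySpec(sigma=sigma), seed)
    return catalog, profile


def twin_coverage_pct(
    n_genes: int = 100_000,
    sigma: float = 2.0,
    depth: int = 1_000_000,
    level: float = 0.99,
    seed: int = 1,
) -> float:
    """Concordance of one twin-replicate pair with the fluctuation bands.

    Draws two independent multinomial replicates of ``depth`` reads from one
    log-normal community and returns the percentage of genes (replicate-1
    count >= 1) whose replicate-2 count lies inside the equal-tail
    ``level`` band.
    """
    _, profile = _twin_world(n_genes, sigma, seed)
    ss = np.random.SeedSequence(seed).spawn(2)
    c1 = synthetic.simulate_replicate_counts(profile, depth, ss[0])
    c2 = synthetic.simulate_replicate_counts(profile, depth, ss[1])
    summ = fluctuation.coverage_fraction(c1.to_numpy(), c2.to_numpy(), level)
    return 100.0 * summ.fraction_within


@dataclass
class TwinReproResult:
    n_hr_genes: int
    mean_rho: float
    mean_alc: float
    n_significant: int

    @property
    def mean_fold_change(self) -> float:
        return float(2.0 ** self.mean_alc)


def twin_reproducibility(
    n_genes: int = 100_000,
    sigma: float = 2.0,
    depth: int = 1_000_000,
    n_pairs: int = 8,
    min_count: int = 10,
    min_pairs: int = 6,
    alpha: float = 0.05,
    seed: int = 1,
) -> TwinReproResult:
    """Reproducibility statistics on twin replicate pairs of one community.

    Each pair is two independent multinomial draws from the same abundance
    vector; HR genes need >= ``min_count`` reads in both members of
    >= ``min_pairs`` pairs.  Returns the pair-averaged Spearman rho and ALC
    over HR genes plus the number of genes flagged by the paired tests at
    BH-FDR < alpha (expected ~0 under this null).
    """
    catalog, profile = _twin_world(n_genes, sigma, seed)
    lengths = catalog["length_bp"].to_numpy()
    ss = np.random.SeedSequence(seed).spawn(2 * n_pairs)
    pairs = []
    for j in range(n_pairs):
        c1 = synthetic.simulate_replicate_counts(profile, depth, ss[2 * j]).to_numpy()
        c2 = synthetic.simulate_replicate_counts(profile, depth, ss[2 * j + 1]).to_numpy()
        pairs.append((c1, c2))
    mask = repro_stats.hr_gene_mask(pairs, min_count, min_pairs)
    genes = catalog.index[mask]

    ra_a = pd.DataFrame(
        {f"p{j}": quantify.relative_abundance(pairs[j][0], lengths) for j in range(n_pairs)},
        index=catalog.index,
    )
    ra_b = pd.DataFrame(
        {f"p{j}": quantify.relative_abundance(pairs[j][1], lengths) for j in range(n_pairs)},
        index=catalog.index,
    )
    rhos, alcs = [], []
    for j in range(n_pairs):
        a = ra_a.iloc[:, j].loc[genes].to_numpy()
        b = ra_b.iloc[:, j].loc[genes].to_numpy()
        ok = (a > 0) & (b > 0)
        rhos.append(repro_stats.spearman(a[ok], b[ok]).rho)
        alcs.append(repro_stats.alc(a[ok], b[ok]).alc)
    tests = repro_stats.paired_gene_tests(ra_a, ra_b, genes, alpha)
    return TwinReproResult(
        n_hr_genes=int(mask.sum()),
        mean_rho=float(np.mean(rhos)),
        mean_alc=float(np.mean(alcs)),
        n_significant=int(tests["significant"].sum()),
    )


@dataclass
class PlatformComparisonResult:
    n_hr_genes: int
    n_significant: int
    gc_var_flagged: float
    gc_var_background: float
    median_slope_a: float
    median_slope_b: float

    @property
    def slope_difference(self) -> float:
        return self.median_slope_b - self.median_slope_a


def platform_comparison(
    beta: float,
    n_genes: int = 2000,
    n_species: int = 20,
    sigma: float = 2.0,
    depth: int = 1_000_000,
    n_pairs: int = 8,
    min_count: int = 10,
    alpha: float = 0.05,
    seed: int = 1,
) -> PlatformComparisonResult:
    """Two platforms sequencing one community, platform B GC-tilted by beta.

    Platform A draws replicates from the community profile, platform B from
    the exponentially tilted profile.  Computes the paired-test flagged
    gene set and its GC variance against the HR background, and each
    platform's median per-species Huber slope of log10 gene abundance on
    GC (slope_difference recovers the injected tilt, ~beta/ln 10).
    """
    spec = synthetic.SimCatalogSpec(n_genes=n_genes, n_species=n_species)
    catalog = synthetic.simulate_catalog(spec, seed)
    profile = synthetic.simulate_abundances(
        catalog, synthetic.SimCommunitySpec(sigma=sigma), seed
    )
    tilted = synthetic.apply_platform_bias(profile, catalog, synthetic.BiasSpec(beta=beta))
    lengths = catalog["length_bp"].to_numpy()
    ss = np.random.SeedSequence(seed).spawn(2 * n_pairs)
    pairs = []
    for j in range(n_pairs):
        ca = synthetic.simulate_replicate_counts(profile, depth, ss[2 * j]).to_numpy()
        cb = synthetic.simulate_replicate_counts(tilted, depth, ss[2 * j + 1]).to_numpy()
        pairs.append((ca, cb))
    mask = repro_stats.hr_gene_mask(pairs, min_count, min_pairs=min(6, n_pairs))
    genes = catalog.index[mask]
    ra_a = pd.DataFrame(
        {f"p{j}": quantify.relative_abundance(pairs[j][0], lengths) for j in range(n_pairs)},
        index=catalog.index,
    )
    ra_b = pd.DataFrame(
        {f"p{j}": quantify.relative_abundance(pairs[j][1], lengths) for j in range(n_pairs)},
        index=catalog.index,
    )
    tests = repro_stats.paired_gene_tests(ra_a, ra_b, genes, alpha)
    flagged = tests.index[tests["significant"]]
    gc = catalog["gc_fraction"]
    gc_var_flagged = float(gc.loc[flagged].var()) if len(flagged) > 1 else 0.0

    slopes_a = gc_bias.species_slopes(ra_a.mean(axis=1), catalog)
    slopes_b = gc_bias.species_slopes(ra_b.mean(axis=1), catalog)
    return PlatformComparisonResult(
        n_hr_genes=int(mask.sum()),
        n_significant=int(len(flagged)),
        gc_var_flagged=gc_var_flagged,
        gc_var_background=float(gc.loc[genes].var()),
        median_slope_a=slopes_a.median_slope,
        median_slope_b=slopes_b.median_slope,
    )
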