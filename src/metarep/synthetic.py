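"""Synthetic inputs with the statistical structure the pipeline assumes.

Emulates, at desk scale, the moving parts of a platform-comparison
experiment on a gut-metagenome gene catalog:

* a catalog whose gene GC fractions follow a bimodal (two-component
  truncated normal) mixture and whose genes belong to species with
  log-series-like size skew;
* a community whose gene abundances are i.i.d. log-normal masses,
  GC-independent by construction (the null for every GC-bias analysis);
* a platform GC tilt ``a_g ∝ a_g · exp(beta·(gc_g − pivot))`` — the
  simplest monotone enrichment of high-GC genes, beta = 0 being identity;
* paired technical replicates as independent multinomial draws of a fixed
  read depth from one shared abundance vector;
* FASTQ reads with linear 5'→3' quality decay plus, at some per-read rate,
  one randomly placed low-quality segment (the failure mode OA-based QC
  exists to catch).

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .formats_io import ReadRecord

__all__ = [
    "SimCatalogSpec",
    "SimCommunitySpec",
    "BiasSpec",
    "FastqSimSpec",
    "simulate_catalog",
    "simulate_abundances",
    "apply_platform_bias",
    "simulate_replicate_counts",
    "simulate_fastq",
]


@dataclass(frozen=True)
class SimCatalogSpec:
    n_genes: int = 100_000
    n_species: int = 50
    gc_means: tuple = (0.38, 0.55)
    gc_sds: tuple = (0.05, 0.05)
    gc_weight: float = 0.55  # weight of the low-GC component
    length_median_bp: int = 750
    length_sigma: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.gc_weight < 1:
            raise ValueError("gc mixture weight must be strictly between 0 and 1")
        if self.n_species > self.n_genes:
            raise ValueError("n_species cannot exceed n_genes")


@dataclass(frozen=True)
class SimCommunitySpec:
    sigma: float = 2.0  # log-normal sd (natural log) of gene masses
    depth: int = 1_000_000  # reads per replicate
    n_pairs: int = 8


@dataclass(frozen=True)
class BiasSpec:
    beta: float = 0.0
    pivot_gc: float = 0.5


@dataclass(frozen=True)
class FastqSimSpec:
    n_reads: int = 1000
    read_length: int = 100
    q_start: float = 38.0
    q_end: float = 30.0
    q_noise_sd: float = 2.0
    drop_rate: float = 0.05
    drop_length: int = 10
    drop_q: int = 2


def _truncnorm01(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    out = rng.normal(mean, sd, n)
    bad = (out < 0) | (out > 1)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < 0) | (out > 1)
    return out


def simulate_catalog(spec: SimCatalogSpec, seed: int) -> pd.DataFrame:
    """Gene catalog: gene_id, length_bp, gc_fraction, species.

    Species sizes follow a log-series-like skew (a few large species, many
    small); GC is a two-component truncated-normal mixture, bimodal under
    the defaults.  Lengths are log-normal with a 100 bp floor.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_genes
    comp = rng.random(n) < spec.gc_weight
    gc = np.where(
        comp,
        _truncnorm01(rng, spec.gc_means[0], spec.gc_sds[0], n),
        _truncnorm01(rng, spec.gc_means[1], spec.gc_sds[1], n),
    )
    lengths = np.maximum(
        100, np.rint(spec.length_median_bp * np.exp(rng.normal(0, spec.length_sigma, n)))
    ).astype(np.int64)
    # log-series species sizes: weights ~ p^k / k
    k = np.arange(1, spec.n_species + 1)
    w = 0.95 ** k / k
    sizes = rng.multinomial(n - spec.n_species, w / w.sum()) + 1  # every species non-empty
    species = np.repeat([f"sp{i:03d}" for i in k], sizes)
    rng.shuffle(species)
    ids = [f"gene{i:06d}" for i in range(n)]
    return pd.DataFrame(
        {"length_bp": lengths, "gc_fraction": gc, "species": species},
        index=pd.Index(ids, name="gene_id"),
    )


def simulate_abundances(catalog: pd.DataFrame, spec: SimCommunitySpec, seed: int) -> pd.Series:
    """I.i.d. log-normal gene masses, normalized; independent of GC."""
    rng = np.random.default_rng(seed)
    mass = rng.lognormal(0.0, spec.sigma, len(catalog)) if spec.sigma > 0 else np.ones(len(catalog))
    return pd.Series(mass / mass.sum(), index=catalog.index, name="abundance")


def apply_platform_bias(profile: pd.Series, catalog: pd.DataFrame, bias: BiasSpec) -> pd.Series:
    """Exponential GC tilt: a_g <- a_g * exp(beta*(gc_g - pivot)), renormalized."""
    gc = catalog["gc_fraction"].reindex(profile.index).to_numpy(dtype=float)
    tilted = profile.to_numpy(dtype=float) * np.exp(bias.beta * (gc - bias.pivot_gc))
    return pd.Series(tilted / tilted.sum(), index=profile.index, name=profile.name)


def simulate_replicate_counts(profile: pd.Series, depth: int, seed: int) -> pd.Series:
    """One multinomial draw of ``depth`` reads over genes."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, profile.to_numpy(dtype=float))
    return pd.Series(counts, index=profile.index, name="count")


def simulate_fastq(spec: FastqSimSpec, seed: int) -> Iterator[ReadRecord]:
    """Reads with linear quality decay and random low-quality segments.

    Per-base Q follows a linear ramp from ``q_start`` to ``q_end`` plus
    Gaussian noise, clipped to [0, 45]; with probability ``drop_rate`` one
    contiguous segment at a uniform random offset is overwritten with
    ``drop_q``.  Bases are uniform over ACGT.
    """
    rng = np.random.default_rng(seed)
    ramp = np.linspace(spec.q_start, spec.q_end, spec.read_length)
    bases_alphabet = np.array(list("ACGT"))
    for i in range(spec.n_reads):
        q = np.clip(np.rint(ramp + rng.normal(0, spec.q_noise_sd, spec.read_length)), 0, 45)
        if rng.random() < spec.drop_rate:
            start = rng.integers(0, max(1, spec.read_length - spec.drop_length + 1))
            q[start : start + spec.drop_length] = spec.drop_q
        seq = "".join(bases_alphabet[rng.integers(0, 4, spec.read_length)])
        yield ReadRecord(f"sim_read_{i}", seq, q.astype(np.int64))
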