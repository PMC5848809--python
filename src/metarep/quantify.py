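"""Depth equalization and gene relative abundance.

Samples are equalized by rarefying uniquely-mapped read counts to a fixed
depth (20 million in a full-scale run) by sampling reads without
replacement — a multivariate hypergeometric draw over genes.  Gene relative
abundance divides each count by gene length before normalizing, so a long
gene does not look more abundant than a short one sequenced at the same
molar concentration:

    a_g = (c_g / L_g) / sum_j (c_j / L_j)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["InsufficientDepthError", "downsample", "downsample_table", "relative_abundance"]

DEFAULT_DEPTH = 20_000_000


class InsufficientDepthError(ValueError):
    """Sample has fewer reads than the requested rarefaction depth."""


def downsample(counts, depth: int, seed: int | np.random.Generator) -> np.ndarray:
    """Rarefy one sample's gene counts to ``depth`` reads without replacement.

    The output always sums to exactly ``depth`` and is bounded above by the
    input counts elementwise.  Deterministic for a given integer seed.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    total = int(counts.sum())
    if total < depth:
        raise InsufficientDepthError(f"sample total {total} < requested depth {depth}")
    if total == depth:
        return counts.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth, method="marginals").astype(np.int64)


def downsample_table(table: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Rarefy every column of a genes x samples count table independently.

    Per-column child seeds are spawned from ``seed`` so adding or removing a
    sample does not disturb the draws of the others.
    """
    ss = np.random.SeedSequence(seed)
    out = {}
    for child, col in zip(ss.spawn(table.shape[1]), table.columns):
        out[col] = downsample(table[col].to_numpy(), depth, np.random.default_rng(child))
    return pd.DataFrame(out, index=table.index)


def relative_abundance(counts, lengths) -> np.ndarray:
    """Length-normalized relative abundance; sums to 1."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths differ in shape")
    dens = counts / lengths
    total = dens.sum()
    if total <= 0:
        raise ValueError("all-zero counts: relative abundance undefined")
    return dens / total
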