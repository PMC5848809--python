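"""Readers and writers for the formats the pipeline touches.

FASTQ (Phred+33 / Phred+64, strict 4-line dialect, plain or gzip) and the
TSV tables that stand in for upstream aligner / profiler output: gene
catalogs, gene-by-sample count tables, species relative-abundance profiles
and species GC tables.  Also the run configuration object shared by the
command-line interface.

The FASTQ layer is deliberately strict: quality characters decoding to a
Phred score above ``MAX_PHRED`` are rejected, because scores past 60 almost
always mean the wrong ASCII offset was chosen (a +64 file read as +33).
"""

from __future__ import annotations

import gzip

from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ReadRecord",
    "QualityEncoding",
    "RunConfig",
    "FastqParseError",
    "QualityEncodingError",
    "SchemaError",
    "read_fastq",
    "write_fastq",
    "read_table",
    "write_table",
    "TABLE_SCHEMAS",
]

MAX_PHRED = 60
_VALID_BASES = frozenset("ACGTNacgtn")


class FastqParseError(ValueError):
    """Malformed FASTQ record; the message names the offending line."""


class QualityEncodingError(ValueError):
    """Quality character incompatible with the declared ASCII offset."""


class SchemaError(ValueError):
    """A TSV table violates the declared column schema."""


@dataclass(frozen=True)
class QualityEncoding:
    """ASCII offset for FASTQ quality characters: 33 (Sanger) or 64."""

    offset: int = 33

    def __post_init__(self) -> None:
        if self.offset not in (33, 64):
            raise ValueError(f"quality offset must be 33 or 64, got {self.offset}")

    def decode(self, qual: str, line_no: int | None = None) -> np.ndarray:
        scores = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64)
        scores -= self.offset
        where = f" (line {line_no})" if line_no is not None else ""
        if scores.min(initial=0) < 0:
            raise QualityEncodingError(
                f"quality character below offset {self.offset}{where}: "
                "wrong encoding selected?"
            )
        if scores.max(initial=0) > MAX_PHRED:
            raise QualityEncodingError(
                f"Phred score above {MAX_PHRED}{where}: probable "
                f"Phred+{97 - self.offset} file read with offset {self.offset}"
            )
        return scores

    def encode(self, phred: np.ndarray) -> str:
        scores = np.asarray(phred, dtype=np.int64)
        if scores.size and (scores.min() < 0 or scores.max() + self.offset > 126):
            raise QualityEncodingError(
                f"Phred scores {scores.min()}..{scores.max()} not printable "
                f"at offset {self.offset}"
            )
        return (scores + self.offset).astype(np.uint8).tobytes().decode("ascii")


@dataclass
class ReadRecord:
    """One sequencing read: identifier, bases and per-base Phred scores."""

    read_id: str
    bases: str
    phred: np.ndarray

    def __post_init__(self) -> None:
        self.phred = np.asarray(self.phred, dtype=np.int64)
        if len(self.phred) != len(self.bases):
            raise ValueError(
                f"{self.read_id}: {len(self.bases)} bases but "
                f"{len(self.phred)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def prefix(self, n: int) -> "ReadRecord":
        return ReadRecord(self.read_id, self.bases[:n], self.phred[:n])


def _open_text(path, mode: str = "rt") -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path, enc: QualityEncoding = QualityEncoding(33)) -> Iterator[ReadRecord]:
    """Stream 4-line FASTQ records from ``path`` (plain or .gz).

    Memory use is constant in file size.  Raises :class:`FastqParseError`
    naming the line number on structural problems and
    :class:`QualityEncodingError` when a quality character is incompatible
    with the declared offset.
    """
    with _open_text(path) as fh:
        yield from parse_fastq(fh, enc)


def parse_fastq(fh: Iterable[str], enc: QualityEncoding = QualityEncoding(33)) -> Iterator[ReadRecord]:
    it = iter(fh)
    line_no = 0
    while True:
        try:
            header = next(it)
        except StopIteration:
            return
        line_no += 1
        header = header.rstrip("\n")
        if not header.startswith("@"):
            raise FastqParseError(f"line {line_no}: expected '@' header, got {header[:20]!r}")
        rest = []
        for expect in ("sequence", "separator", "quality"):
            try:
                rest.append(next(it).rstrip("\n"))
            except StopIteration:
                raise FastqParseError(
                    f"line {line_no}: truncated record (missing {expect} line)"
                ) from None
        seq, sep, qual = rest
        line_no += 3
        if not sep.startswith("+"):
            raise FastqParseError(f"line {line_no - 1}: expected '+' separator, got {sep[:20]!r}")
        if len(seq) != len(qual):
            raise FastqParseError(
                f"line {line_no}: sequence length {len(seq)} != quality length {len(qual)}"
            )
        if not set(seq) <= _VALID_BASES:
            bad = sorted(set(seq) - _VALID_BASES)
            raise FastqParseError(f"line {line_no - 2}: invalid bases {bad}")
        yield ReadRecord(header[1:], seq, enc.decode(qual, line_no))


def write_fastq(records: Iterable[ReadRecord], path, enc: QualityEncoding = QualityEncoding(33)) -> int:
    """Write records as 4-line FASTQ; returns the number written."""
    n = 0
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f"@{rec.read_id}\n{rec.bases}\n+\n{enc.encode(rec.phred)}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# TSV tables


def _check_gene_catalog(df: pd.DataFrame) -> pd.DataFrame:
    bad = df.index[(df["gc_fraction"] < 0) | (df["gc_fraction"] > 1)]
    if len(bad):
        raise SchemaError(f"gene_catalog: gc_fraction outside [0,1] at row {bad[0] + 2}")
    bad = df.index[df["length_bp"] < 1]
    if len(bad):
        raise SchemaError(f"gene_catalog: length_bp < 1 at row {bad[0] + 2}")
    if df["gene_id"].duplicated().any():
        raise SchemaError("gene_catalog: duplicate gene_id")
    return df.set_index("gene_id")


def _check_counts(df: pd.DataFrame) -> pd.DataFrame:
    df = df.set_index(df.columns[0])
    df.index.name = "gene_id"
    if df.index.duplicated().any():
        raise SchemaError("counts: duplicate gene_id")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            row = df.index.get_loc(bad[0]) + 2
            raise SchemaError(f"counts: non-numeric count in column {col!r} at row {row}")
        if (vals < 0).any() or (vals % 1 != 0).any():
            raise SchemaError(f"counts: negative or non-integer count in column {col!r}")
        df[col] = vals.astype(np.int64)
    return df


def _check_species_profile(df: pd.DataFrame) -> pd.DataFrame:
    df = df.set_index(df.columns[0])
    df.index.name = "species"
    if (df < 0).any().any():
        raise SchemaError("species_profile: negative abundance")
    return df.astype(float)


def _check_species_gc(df: pd.DataFrame) -> pd.DataFrame:
    bad = df.index[(df["gc_fraction"] < 0) | (df["gc_fraction"] > 1)]
    if len(bad):
        raise SchemaError(f"species_gc: gc_fraction outside [0,1] at row {bad[0] + 2}")
    return df.set_index("species")


TABLE_SCHEMAS = {
    "gene_catalog": (["gene_id", "length_bp", "gc_fraction"], _check_gene_catalog),
    "counts": (None, _check_counts),
    "species_profile": (None, _check_species_profile),
    "species_gc": (["species", "gc_fraction"], _check_species_gc),
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a tab-separated table with header and validate it against a schema.

    Schemas: ``gene_catalog`` (gene_id, length_bp, gc_fraction, optional
    species), ``counts`` (first column gene id, remaining columns integer
    counts per sample), ``species_profile`` (first column species, remaining
    columns relative abundances), ``species_gc`` (species, gc_fraction).
    """
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(TABLE_SCHEMAS)}")
    required, check = TABLE_SCHEMAS[schema]
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str} if required is None else None)
    if required is not None:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{schema}: missing column(s) {missing}")
    return check(df)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Bag of pipeline parameters; every stochastic step reads its seed here."""

    encoding_offset: int = 33
    oa_fragment_threshold: float = 0.8
    window: int = 10
    min_retained_length: int = 30
    downsample_depth: int = 20_000_000
    ci_level: float = 0.99
    hr_min_count: int = 10
    hr_min_pairs: int = 6
    fdr_alpha: float = 0.05
    fluctuation_model: str = "poisson"  # or "binomial"
    seed: int = 0
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw.pop(k) for k in list(raw) if k in cls.__dataclass_fields__}
        return cls(**known, extras=raw)
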