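"""Overall-accuracy (OA) read quality control.

A read's bases each carry a Phred score Q, i.e. a per-base accuracy
``1 - 10**(-Q/10)``.  The OA of a fragment is the product of its per-base
accuracies — the probability that the whole fragment is error-free.  A
sliding window of length ``window`` (step 1) moves 5'→3'; the read is cut
immediately before the start of the first window whose OA falls below
``oa_fragment_threshold``.  Unlike plain tail trimming this catches short
random quality drops in the middle of a read.  Retained reads are always
prefixes of the input; reads whose retained prefix is shorter than
``min_retained_length`` are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Tuple

import numpy as np

from .formats_io import ReadRecord

__all__ = [
    "QCParams",
    "TrimResult",
    "QCReport",
    "base_accuracy",
    "fragment_oa",
    "trim_read",
    "run_qc",
]


@dataclass(frozen=True)
class QCParams:
    oa_fragment_threshold: float = 0.8
    window: int = 10
    min_retained_length: int = 30

    def __post_init__(self) -> None:
        if not 0 < self.oa_fragment_threshold < 1:
            raise ValueError("oa_fragment_threshold must be in (0,1)")
        if self.window < 1 or self.min_retained_length < 1:
            raise ValueError("window and min_retained_length must be >= 1")


@dataclass
class TrimResult:
    retained: ReadRecord | None
    reason: str  # kept_full | trimmed | discarded_short
    whole_read_oa: float


@dataclass
class QCReport:
    n_raw: int = 0
    n_retained: int = 0
    n_bases_retained: int = 0
    n_q30_retained: int = 0
    _sum_len: int = 0
    _sum_oa: float = 0.0

    @property
    def pct_retained(self) -> float:
        return 100.0 * self.n_retained / self.n_raw if self.n_raw else 0.0

    @property
    def pct_q30(self) -> float:
        return 100.0 * self.n_q30_retained / self.n_bases_retained if self.n_bases_retained else 0.0

    @property
    def mean_retained_length(self) -> float:
        return self._sum_len / self.n_retained if self.n_retained else 0.0

    @property
    def mean_oa(self) -> float:
        return self._sum_oa / self.n_retained if self.n_retained else 0.0

    def as_dict(self) -> dict:
        return {
            "n_raw": self.n_raw,
            "n_retained": self.n_retained,
            "pct_retained": self.pct_retained,
            "pct_q30": self.pct_q30,
            "mean_retained_length": self.mean_retained_length,
            "mean_oa": self.mean_oa,
        }


def base_accuracy(q) -> np.ndarray | float:
    """Per-base accuracy 1 - 10**(-q/10); 0 at q=0, strictly increasing."""
    q = np.asarray(q)
    if np.any(q < 0):
        raise ValueError("Phred scores must be >= 0")
    out = -np.expm1(-q / 10.0 * np.log(10.0))
    return float(out) if out.ndim == 0 else out


def fragment_oa(accuracies) -> float:
    """Probability an entire fragment is error-free: product of accuracies."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.size == 0:
        raise ValueError("fragment_oa of an empty fragment is undefined")
    return float(np.exp(np.log(acc, where=acc > 0, out=np.full(acc.shape, -np.inf)).sum()))


def _first_failing_window(log_acc: np.ndarray, window: int, log_thresh: float) -> int | None:
    """Index of the first length-``window`` window whose OA < threshold.

    Reads shorter than the window are judged as one fragment of their own
    length.  Returns None when every window passes.
    """
    n = len(log_acc)
    if n <= window:
        return 0 if log_acc.sum() < log_thresh else None
    cum = np.concatenate(([0.0], np.cumsum(log_acc)))
    win = cum[window:] - cum[:-window]  # win[i] = sum of log-acc over [i, i+window)
    fails = np.flatnonzero(win < log_thresh)
    return int(fails[0]) if fails.size else None


def trim_read(read: ReadRecord, params: QCParams) -> TrimResult:
    """Apply the sliding-window OA rule; keep the passing 5' prefix."""
    # floor accuracy so q=0 bases give a huge-but-finite log penalty; a
    # -inf would turn window sums into NaN and silently pass the filter
    log_acc = np.log(np.maximum(base_accuracy(read.phred), 1e-300))
    fail = _first_failing_window(log_acc, params.window, np.log(params.oa_fragment_threshold))
    if fail is None:
        keep = len(read)
        reason = "kept_full"
    else:
        keep = fail
        reason = "trimmed"
    if keep < params.min_retained_length:
        return TrimResult(None, "discarded_short", 0.0)
    retained = read if reason == "kept_full" else read.prefix(keep)
    oa = float(np.exp(log_acc[:keep].sum()))
    return TrimResult(retained, reason, oa)


def run_qc(
    records: Iterable[ReadRecord], params: QCParams
) -> Tuple[Iterator[ReadRecord], QCReport]:
    """Stream QC over reads; returns (retained-read iterator, live report).

    The report is filled in as the iterator is consumed, so aggregate
    fields are only final once iteration ends.
    """
    report = QCReport()

    def gen() -> Iterator[ReadRecord]:
        for read in records:
            report.n_raw += 1
            res = trim_read(read, params)
            if res.retained is None:
                continue
            report.n_retained += 1
            report.n_bases_retained += len(res.retained)
            report.n_q30_retained += int((res.retained.phred >= 30).sum())
            report._sum_len += len(res.retained)
            report._sum_oa += res.whole_read_oa
            yield res.retained

    return gen(), report
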