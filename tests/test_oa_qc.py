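"""Overall-accuracy QC: per-base accuracy, window trimming, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metarep.formats_io import ReadRecord
from metarep.oa_qc import QCParams, base_accuracy, fragment_oa, run_qc, trim_read
from metarep.synthetic import FastqSimSpec, simulate_fastq


def brute_force_trim(phred, threshold, window):
    """Independent oracle: scan every window position with direct products."""
    acc = [1 - 10 ** (-q / 10) for q in phred]
    n = len(acc)
    if n <= window:
        return n if np.prod(acc) >= threshold else 0
    for i in range(n - window + 1):
        if np.prod(acc[i : i + window]) < threshold:
            return i
    return n


@pytest.mark.parametrize("q,acc", [(0, 0.0), (10, 0.9), (20, 0.99), (30, 0.999)])
def test_base_accuracy_values(q, acc):
    assert base_accuracy(q) == pytest.approx(acc, abs=1e-12)


def test_base_accuracy_monotone_and_domain():
    qs = np.arange(0, 61)
    assert np.all(np.diff(base_accuracy(qs)) > 0)
    with pytest.raises(ValueError):
        base_accuracy(-1)


def test_fragment_oa_is_product():
    assert fragment_oa([0.9, 0.9]) == pytest.approx(0.81)
    assert fragment_oa([1.0] * 5) == 1.0
    assert fragment_oa([base_accuracy(30)] * 10) == pytest.approx(0.999**10)
    assert fragment_oa([0.5, 0.9]) <= 0.5  # never exceeds the min
    with pytest.raises(ValueError):
        fragment_oa([])


def test_trim_examples(uniform_read):
    params = QCParams(oa_fragment_threshold=0.8, window=10, min_retained_length=30)
    # 100 bases at q30: every window OA ~ 0.990 >= 0.8
    res = trim_read(uniform_read(30), params)
    assert res.reason == "kept_full" and len(res.retained) == 100
    assert res.whole_read_oa == pytest.approx(0.999**100, rel=1e-9)
    # 90 good bases then a q3 tail: trimmed no later than base 90
    phred = np.concatenate([np.full(90, 30), np.full(10, 3)])
    read = ReadRecord("r", "A" * 100, phred)
    res = trim_read(read, params)
    assert res.reason == "trimmed"
    assert len(res.retained) == brute_force_trim(phred, 0.8, 10) <= 90
    # all-bad short read: first window fails at position 0
    res = trim_read(uniform_read(2, length=20), params)
    assert res.reason == "discarded_short" and res.retained is None


def test_trim_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    params = QCParams(0.8, 10, 1)  # min length 1: compare raw cut points
    for _ in range(50):
        phred = rng.integers(0, 41, size=rng.integers(5, 120))
        read = ReadRecord("r", "A" * len(phred), phred)
        expected = brute_force_trim(phred, 0.8, 10)
        res = trim_read(read, params)
        got = len(res.retained) if res.retained is not None else 0
        assert got == expected


def test_retained_is_prefix(uniform_read):
    phred = np.concatenate([np.full(50, 35), np.full(10, 4), np.full(40, 35)])
    read = ReadRecord("r", "ACGT" * 25, phred)
    res = trim_read(read, QCParams())
    assert res.retained.bases == read.bases[: len(res.retained)]
    np.testing.assert_array_equal(res.retained.phred, read.phred[: len(res.retained)])


@given(st.integers(min_value=0, max_value=45), st.integers(min_value=1, max_value=120))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_uniform_quality_closed_form(q, length):
    """On uniform-quality reads, kept_full <=> accuracy(q)**min(W, len) >= threshold."""
    params = QCParams(0.8, 10, 1)
    read = ReadRecord("r", "A" * length, np.full(length, q))
    res = trim_read(read, params)
    w = min(params.window, length)
    if base_accuracy(q) ** w >= params.oa_fragment_threshold:
        assert res.reason == "kept_full"
    else:
        assert res.retained is None  # first window already fails


def test_threshold_monotonicity():
    """Raising the OA threshold never lengthens any read's retained prefix."""
    rng = np.random.default_rng(3)
    reads = [
        ReadRecord(f"r{i}", "A" * 100, rng.integers(2, 41, 100)) for i in range(40)
    ]
    prev_lengths = None
    prev_retained = None
    for thr in (0.5, 0.7, 0.8, 0.9, 0.97):
        params = QCParams(thr, 10, 30)
        results = [trim_read(r, params) for r in reads]
        lengths = [len(t.retained) if t.retained else 0 for t in results]
        n_ret = sum(1 for t in results if t.retained)
        if prev_lengths is not None:
            assert all(a >= b for a, b in zip(prev_lengths, lengths))
            assert prev_retained >= n_ret
        prev_lengths, prev_retained = lengths, n_ret


def test_run_qc_report(uniform_read):
    params = QCParams()
    perfect = [uniform_read(40, read_id=f"p{i}") for i in range(5)]
    kept, report = run_qc(perfect, params)
    assert len(list(kept)) == 5
    assert report.pct_retained == 100.0
    assert report.mean_retained_length == 100.0
    assert report.pct_q30 == 100.0

    awful = [uniform_read(2, read_id=f"a{i}") for i in range(5)]
    kept, report = run_qc(awful, params)
    assert list(kept) == []
    assert report.pct_retained == 0.0


def test_run_qc_on_simulated_drop_reads():
    """Reads with an injected low-quality segment get trimmed at or before it."""
    spec = FastqSimSpec(n_reads=300, drop_rate=1.0, drop_q=2, q_noise_sd=0.5)
    kept, report = run_qc(simulate_fastq(spec, seed=9), QCParams())
    lengths = [len(r) for r in kept]
    assert report.n_raw == 300
    # every read has a q2 segment somewhere, so none can be kept full-length
    assert report.mean_retained_length < spec.read_length
    assert all(l >= 30 for l in lengths)

    clean = FastqSimSpec(n_reads=200, drop_rate=0.0, q_noise_sd=0.5)
    kept, report = run_qc(simulate_fastq(clean, seed=10), QCParams())
    assert len(list(kept)) == 200
    assert report.pct_retained == 100.0
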