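"""FASTQ read processing: adapter trimming, quality filtering,
negative-reference exclusion, perfect-match alignment, count filtering.

The alignment model is deliberately strict: a read maps to a mature miRNA
iff its first 20 bases occur verbatim on the reference's forward strand.
Multi-mapping reads resolve to the reference earliest in file order.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, ProcessingStats
from .io import iter_fastq

logger = logging.getLogger(__name__)

DEFAULT_SEED_LEN = 20
DEFAULT_QUAL_THRESHOLD = 30
DEFAULT_MIN_LENGTH = 16
DEFAULT_MIN_OVERLAP = 3
DEFAULT_MAX_ERROR_RATE = 0.1
DEFAULT_MIN_TOTAL = 4


@dataclass
class ReadRecord:
    """One sequencing read: id, bases, per-base Phred scores."""

    id: str
    seq: str
    qual: list[int]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


def trim_adapter(read: ReadRecord, adapter: str,
                 min_overlap: int = DEFAULT_MIN_OVERLAP,
                 max_error_rate: float = DEFAULT_MAX_ERROR_RATE) -> ReadRecord:
    """Remove a 3' adapter from a read.

    Scans candidate start positions left to right; at position ``p`` the
    adapter prefix of length ``min(len(adapter), len(read) - p)`` is compared
    with the read, and the read is cut at the leftmost ``p`` whose overlap is
    at least ``min_overlap`` with a mismatch fraction at most
    ``max_error_rate``. Qualities are trimmed in lockstep. Reads with no
    qualifying position are returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be a non-empty string")
    if min_overlap < 3:
        raise ValueError("min_overlap must be >= 3")
    if not 0 <= max_error_rate < 0.5:
        raise ValueError("max_error_rate must be in [0, 0.5)")
    pos = _find_adapter(read.seq, adapter, min_overlap, max_error_rate)
    if pos is None:
        return read
    return ReadRecord(read.id, read.seq[:pos], read.qual[:pos])


def _find_adapter(seq: str, adapter: str, min_overlap: int,
                  max_error_rate: float) -> int | None:
    n = len(seq)
    # Fast path: a full, exact adapter occurrence bounds the search; only
    # positions to its left can host an earlier (mismatched) hit.
    exact = seq.find(adapter) if len(adapter) >= min_overlap else -1
    limit = exact if exact >= 0 else n - min_overlap
    seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    ad_arr = np.frombuffer(adapter.encode(), dtype=np.uint8)
    for p in range(0, limit + 1):
        overlap = min(len(adapter), n - p)
        if overlap < min_overlap:
            break
        mism = int(np.count_nonzero(seq_arr[p : p + overlap] != ad_arr[:overlap]))
        if mism <= max_error_rate * overlap:
            return p
    if exact >= 0:
        return exact
    return None


def quality_filter(read: ReadRecord, threshold: float = DEFAULT_QUAL_THRESHOLD,
                   min_length: int = DEFAULT_MIN_LENGTH) -> bool:
    """True (keep) iff mean Phred >= threshold and length >= min_length."""
    if len(read.seq) < min_length or not read.qual:
        return False
    return sum(read.qual) / len(read.qual) >= threshold


class ReferenceIndex:
    """Exact-substring index over reference sequences.

    Maps every ``seed_len``-mer window of every reference to the id of the
    first reference (in file order) containing it, giving a deterministic
    tie-break for multi-mapping reads.
    """

    def __init__(self, references: list[tuple[str, str]], seed_len: int = DEFAULT_SEED_LEN):
        if not references:
            raise ValueError("cannot build an index from an empty reference")
        self.seed_len = seed_len
        self._index: dict[str, str] = {}
        for ref_id, seq in references:
            seq = seq.upper()
            for i in range(len(seq) - seed_len + 1):
                self._index.setdefault(seq[i : i + seed_len], ref_id)

    def __len__(self) -> int:
        return len(self._index)

    def lookup(self, prefix: str) -> str | None:
        return self._index.get(prefix)


def matches_reference(read: ReadRecord, reference_index: ReferenceIndex,
                      seed_len: int | None = None) -> str | None:
    """Return the id of the reference whose sequence contains the read's
    first ``seed_len`` bases verbatim, or None.

    Reads shorter than the seed return None; any N in the seed prevents a
    match (perfect-match semantics).
    """
    seed_len = reference_index.seed_len if seed_len is None else seed_len
    if len(read.seq) < seed_len:
        return None
    prefix = read.seq[:seed_len]
    if "N" in prefix:
        return None
    return reference_index.lookup(prefix)


def filter_negative(read: ReadRecord, negative_index: ReferenceIndex) -> bool:
    """True (pass) iff the read does NOT match the negative reference."""
    return matches_reference(read, negative_index) is None


def count_samples(fastq_paths: dict[str, str], groups: dict[str, str],
                  adapter: str, positive_reference: list[tuple[str, str]],
                  negative_reference: list[tuple[str, str]], *,
                  min_overlap: int = DEFAULT_MIN_OVERLAP,
                  max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
                  qual_threshold: float = DEFAULT_QUAL_THRESHOLD,
                  min_length: int = DEFAULT_MIN_LENGTH,
                  seed_len: int = DEFAULT_SEED_LEN):
    """Run the per-read pipeline (trim -> quality -> negative filter ->
    align -> tally) over one FASTQ per sample.

    Returns ``(CountMatrix, {sample: ProcessingStats})``. The count matrix
    has one row per positive-reference miRNA (file order) and one column per
    sample (input order).
    """
    pos_index = ReferenceIndex(positive_reference, seed_len)
    neg_index = ReferenceIndex(negative_reference, seed_len)
    mirna_ids = [ref_id for ref_id, _ in positive_reference]
    counts = pd.DataFrame(0, index=mirna_ids, columns=list(fastq_paths), dtype=int)
    stats: dict[str, ProcessingStats] = {}

    for sample, path in fastq_paths.items():
        st = ProcessingStats(sample_id=sample)
        tally: dict[str, int] = {}
        for read_id, seq, qual in iter_fastq(path):
            st.n_input += 1
            read = trim_adapter(ReadRecord(read_id, seq, qual), adapter,
                                min_overlap, max_error_rate)
            st.n_post_trim += 1
            if not quality_filter(read, qual_threshold, min_length):
                continue
            st.n_post_quality += 1
            if not filter_negative(read, neg_index):
                continue
            st.n_post_negative += 1
            hit = matches_reference(read, pos_index)
            if hit is None:
                st.n_unaligned += 1
            else:
                st.n_aligned += 1
                tally[hit] = tally.get(hit, 0) + 1
        counts[sample] = [tally.get(mid, 0) for mid in mirna_ids]
        if st.n_input == 0:
            logger.warning("sample %s: empty FASTQ, zero count column", sample)
        st.validate()
        stats[sample] = st

    return CountMatrix(counts=counts, groups=dict(groups)), stats


def apply_min_count(counts: CountMatrix, min_total: int = DEFAULT_MIN_TOTAL) -> CountMatrix:
    """Keep miRNAs whose total count across samples is strictly greater
    than ``min_total`` (default: more than four reads), preserving order."""
    totals = counts.counts.sum(axis=1)
    kept = counts.counts.loc[totals > min_total]
    if kept.empty:
        raise ValueError(
            f"no miRNA exceeds the minimum total count of {min_total}; nothing to analyze"
        )
    return CountMatrix(counts=kept.copy(), groups=dict(counts.groups))


def stats_frame(stats: dict[str, ProcessingStats]) -> pd.DataFrame:
    """Tabulate per-sample stage counts."""
    rows = {
        s: {
            "n_input": st.n_input,
            "n_post_trim": st.n_post_trim,
            "n_post_quality": st.n_post_quality,
            "n_post_negative": st.n_post_negative,
            "n_aligned": st.n_aligned,
            "n_unaligned": st.n_unaligned,
        }
        for s, st in stats.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")
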