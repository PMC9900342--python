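"""Adapter/quality/length trimming and known-ncRNA decontamination.

Trimming follows the classic 3' pipeline for small RNA libraries: quality
bases are removed from the 3' end first (suffix maximizing the running sum
of ``min_quality - q``), then the longest 3' adapter occurrence is clipped
(10% mismatch rate, minimum overlap 3, a partial adapter prefix is allowed
at the read end), then short inserts are discarded and survivors collapsed
to unique sequences with multiplicities.

Decontamination is a deterministic ungapped search: a read is removed iff
some reference window (either orientation) aligns with query coverage,
identity and mismatch count within the configured criteria.  Gaps are
deliberately not modeled: at <=1 mismatch over >=90% of a 25-35 nt read
they cannot change any decision, and the ungapped model is exactly
reproducible by the brute-force oracle used in the tests.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .io import SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchCriteria:
    """Thresholds for ungapped read-vs-reference matching."""

    min_identity: float = 80.0
    max_mismatches: int = 1
    min_query_coverage: float = 90.0
    max_hits_reported: int = 1
    orientations: tuple[str, ...] = ("sense", "antisense")

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 100):
            raise ValueError("min_identity must be in (0, 100]")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if not (0 < self.min_query_coverage <= 100):
            raise ValueError("min_query_coverage must be in (0, 100]")
        bad = set(self.orientations) - {"sense", "antisense"}
        if bad:
            raise ValueError(f"unknown orientations: {sorted(bad)}")


@dataclass(frozen=True)
class CollapsedRead:
    """A unique read sequence with its abundance in one sample."""

    sequence: str
    multiplicity: int
    sample: str = "sample"

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")


@dataclass
class AlignmentHit:
    """Best ungapped hit of a read against a labeled reference."""

    reference_id: str
    reference_class: str
    orientation: str
    identity: float
    coverage: float
    mismatches: int


# ---------------------------------------------------------------------------
# Trimming


def quality_trim_index(quality: Sequence[int], min_quality: int) -> int:
    """Index at which to cut the 3' end, by the standard partial-sum rule.

    Scans 3'->5' accumulating ``min_quality - q`` and cuts at the position
    where the running sum is maximal (no cut if it never goes positive).
    """
    best = 0
    best_i = len(quality)
    running = 0
    for i in range(len(quality) - 1, -1, -1):
        running += min_quality - quality[i]
        if running > best:
            best = running
            best_i = i
    return best_i


def adapter_start_index(
    seq: str, adapter: str, error_rate: float = 0.1, min_overlap: int = 3
) -> int:
    """Start of the leftmost (= longest) 3' adapter occurrence, or len(seq).

    An occurrence is either the full adapter inside the read (everything
    from its start onward is removed) or a prefix of the adapter flush with
    the read's 3' end.  Mismatches are allowed up to
    ``floor(error_rate * overlap)``; N counts as a mismatch.
    """
    n, m = len(seq), len(adapter)
    # fast path: exact full-adapter occurrence
    exact = seq.find(adapter)
    limit = exact if exact != -1 else n
    for i in range(0, limit):
        overlap = min(m, n - i)
        if overlap < min_overlap:
            break
        if overlap < m and i + overlap < n:
            continue  # partial adapter is only allowed flush with the 3' end
        allowed = int(error_rate * overlap)
        if allowed == 0:
            continue  # exact case already covered by the fast path
        window = seq[i : i + overlap]
        mismatches = sum(1 for a, b in zip(window, adapter) if a != b)
        if mismatches <= allowed:
            return i
    if exact != -1:
        return exact
    # pure-suffix partial matches shorter than handled above
    for i in range(max(0, n - m + 1), n - min_overlap + 1):
        overlap = n - i
        window = seq[i:]
        mismatches = sum(1 for a, b in zip(window, adapter) if a != b)
        if mismatches <= int(error_rate * overlap):
            return i
    return n


@dataclass
class TrimStats:
    total_in: int = 0
    quality_trimmed: int = 0
    adapter_trimmed: int = 0
    too_short: int = 0
    survivors: int = 0
    unique_sequences: int = 0


def trim_reads(
    records: Iterable[SequenceRecord],
    adapter: str,
    min_quality: int = 20,
    min_length: int = 25,
    sample: str = "sample",
    adapter_error_rate: float = 0.1,
    adapter_min_overlap: int = 3,
) -> tuple[list[CollapsedRead], TrimStats]:
    """Quality-trim, adapter-trim, length-filter and collapse reads.

    Reads whose trimmed insert is shorter than ``min_length`` (default 25,
    i.e. everything <=24 nt) are discarded.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    stats = TrimStats()
    counts: Counter[str] = Counter()
    insert_cache: dict[str, Optional[str]] = {}
    for rec in records:
        stats.total_in += 1
        seq = rec.sequence
        if rec.quality is not None:
            cut = quality_trim_index(rec.quality, min_quality)
            if cut < len(seq):
                stats.quality_trimmed += 1
                seq = seq[:cut]
        insert = insert_cache.get(seq, "__miss__")
        if insert == "__miss__":
            a = adapter_start_index(seq, adapter, adapter_error_rate, adapter_min_overlap)
            insert = seq[:a] if a < len(seq) else seq
            insert_cache[seq] = insert if a < len(seq) else None
            if a < len(seq):
                stats.adapter_trimmed += 1
        elif insert is None:
            insert = seq
        else:
            stats.adapter_trimmed += 1
        if len(insert) < min_length:
            stats.too_short += 1
            continue
        stats.survivors += 1
        counts[insert] += 1
    reads = [CollapsedRead(s, m, sample) for s, m in sorted(counts.items())]
    stats.unique_sequences = len(reads)
    logger.info(
        "trim[%s]: %d in, %d survived (%d unique), %d too short",
        sample, stats.total_in, stats.survivors, stats.unique_sequences, stats.too_short,
    )
    return reads, stats


# ---------------------------------------------------------------------------
# Ungapped alignment for decontamination


def _longest_window(mism: Sequence[int], a: int, b: int, max_mm: int) -> tuple[int, int]:
    """Longest sub-window of [a, b) containing at most ``max_mm`` of the
    sorted mismatch positions ``mism``; returns (length, mismatches_inside)."""
    best_len, best_mm = 0, 0
    start = a
    count = 0  # mismatches in [start, end)
    j = 0  # mismatches consumed so far (mism[j-count:j] are inside the window)
    for end in range(a + 1, b + 1):
        if j < len(mism) and mism[j] == end - 1:
            count += 1
            j += 1
        while count > max_mm:
            start = mism[j - count] + 1
            count -= 1
        if end - start > best_len:
            best_len, best_mm = end - start, count
    return best_len, best_mm


def best_ungapped_hit(
    query: str, reference: str, criteria: MatchCriteria
) -> Optional[tuple[float, float, int]]:
    """Best qualifying ungapped alignment of ``query`` against ``reference``.

    Considers every shift of the query along the reference (end-overhangs
    free) and every contiguous sub-window of the overlap of length at least
    ``ceil(min_query_coverage * len(query) / 100)``.  For each shift and
    each mismatch budget k <= max_mismatches, the longest window with <= k
    mismatches dominates every other window with <= k mismatches in both
    coverage and identity, so scanning those candidates is exhaustive.
    Returns ``(identity, coverage, mismatches)`` of the hit maximizing
    matched bases (ties: fewer mismatches), or None if nothing qualifies.
    """
    m, n = len(query), len(reference)
    qmin = math.ceil(criteria.min_query_coverage / 100.0 * m)
    if qmin > n:
        return None
    best_key: Optional[tuple[int, int]] = None  # (matches, -mismatches)
    best_stats: Optional[tuple[float, float, int]] = None
    for p in range(-(m - qmin), n - qmin + 1):
        a = max(0, -p)
        b = min(m, n - p)
        if b - a < qmin:
            continue
        mism = [i for i in range(a, b) if query[i] != reference[i + p]]
        for budget in range(criteria.max_mismatches + 1):
            length, mm = _longest_window(mism, a, b, budget)
            if length < qmin:
                continue
            identity = 100.0 * (length - mm) / length
            if identity < criteria.min_identity:
                continue
            key = (length - mm, -mm)
            if best_key is None or key > best_key:
                best_key = key
                best_stats = (identity, 100.0 * length / m, mm)
    return best_stats


def find_best_hit(
    sequence: str,
    references: Sequence[tuple[str, str, str]],
    criteria: MatchCriteria,
    candidate_indices: Optional[Sequence[int]] = None,
) -> Optional[AlignmentHit]:
    """Best hit of a read over labeled references ``(id, class, sequence)``.

    Ties are broken by reference order; orientation order is sense first.
    ``candidate_indices`` restricts the search (in reference order) when a
    prescreen has already excluded the rest.
    """
    queries = []
    if "sense" in criteria.orientations:
        queries.append(("sense", sequence))
    if "antisense" in criteria.orientations:
        queries.append(("antisense", reverse_complement(sequence)))
    indices = range(len(references)) if candidate_indices is None else candidate_indices
    best: Optional[AlignmentHit] = None
    best_key: Optional[tuple[float, float]] = None
    for idx in indices:
        ref_id, ref_class, ref_seq = references[idx]
        perfect = None
        for orientation, q in queries:
            if q in ref_seq:  # exact containment: unbeatable for this pair
                perfect = AlignmentHit(ref_id, ref_class, orientation, 100.0, 100.0, 0)
                break
        if perfect is not None:
            if best is None or (100.0, 100.0) > best_key:
                best, best_key = perfect, (100.0, 100.0)
            break  # a perfect hit cannot be beaten; reference order keeps ties
        for orientation, q in queries:
            hit = best_ungapped_hit(q, ref_seq, criteria)
            if hit is None:
                continue
            identity, coverage, mm = hit
            key = (coverage, identity)
            if best is None or key > best_key:
                best = AlignmentHit(ref_id, ref_class, orientation, identity, coverage, mm)
                best_key = key
        if best is not None and best.mismatches == 0 and best.coverage >= 100.0 - 1e-9:
            break  # cannot be beaten; keeps reference-order tie-breaking
    return best


def _kmer_candidate_index(
    references: Sequence[tuple[str, str, str]], k: int
) -> dict[str, set[int]]:
    kmers: dict[str, set[int]] = {}
    for idx, (_, _, seq) in enumerate(references):
        for i in range(len(seq) - k + 1):
            kmers.setdefault(seq[i : i + k], set()).add(idx)
    return kmers


def filter_ncrna(
    reads: Sequence[CollapsedRead],
    references: Sequence[tuple[str, str, str]],
    criteria: MatchCriteria = MatchCriteria(),
) -> tuple[list[CollapsedRead], list[tuple[CollapsedRead, AlignmentHit]]]:
    """Split reads into (retained, removed-with-best-hit) by ncRNA matching.

    A qualifying alignment with <=``max_mismatches`` mismatches over at
    least ``min_query_coverage`` of the read must contain an exact run of
    ~qmin/(mm+1) bases (pigeonhole), so a shared-k-mer prescreen restricts
    full alignment to references that could possibly qualify.
    """
    if not references:
        logger.warning("filter_ncrna: empty reference set, all reads retained")
        return list(reads), []
    retained: list[CollapsedRead] = []
    removed: list[tuple[CollapsedRead, AlignmentHit]] = []
    min_len = min((len(r.sequence) for r in reads), default=25)
    qmin = math.ceil(criteria.min_query_coverage / 100.0 * min_len)
    k = max(4, qmin // (criteria.max_mismatches + 1) - 1)
    kmers = _kmer_candidate_index(references, k)
    for read in reads:
        seq = read.sequence
        queries = [seq]
        if "antisense" in criteria.orientations:
            queries.append(reverse_complement(seq))
        candidates: set[int] = set()
        for q in queries:
            for i in range(len(q) - k + 1):
                hit_refs = kmers.get(q[i : i + k])
                if hit_refs:
                    candidates |= hit_refs
        hit = (
            find_best_hit(seq, references, criteria, sorted(candidates))
            if candidates
            else None
        )
        if hit is None:
            retained.append(read)
        else:
            removed.append((read, hit))
    logger.info(
        "filter_ncrna: %d reads in, %d retained, %d removed",
        len(reads), len(retained), len(removed),
    )
    return retained, removed


def removal_report(removed: Sequence[tuple[CollapsedRead, AlignmentHit]]):
    """Removal report rows as a pandas DataFrame (read, class, identity, coverage)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "sequence": read.sequence,
                "multiplicity": read.multiplicity,
                "sample": read.sample,
                "reference_id": hit.reference_id,
                "class": hit.reference_class,
                "orientation": hit.orientation,
                "identity": hit.identity,
                "coverage": hit.coverage,
                "mismatches": hit.mismatches,
            }
            for read, hit in removed
        ]
    )
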