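"""piRNA identification, genome alignment, cluster calling and counting.

The internal aligner is exact-match only (seed-and-verify over a k-mer
index), which is sufficient for the zero-mismatch annotated-reference
contract and for synthetic genomes; alignments produced externally can be
substituted at the same interfaces for full-scale runs.  Cluster calling
merges overlapping and book-ended annotation intervals strand-agnostically;
read counting requires full containment of the alignment in the cluster
(the ``-f 1`` intersection contract) and is alignment-based: every
placement of a multi-mapping read contributes its full multiplicity.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass, field
from statistics import mean, median
from typing import Optional, Sequence

from .io import GenomeInterval, reverse_complement
from .preprocess import CollapsedRead

logger = logging.getLogger(__name__)


@dataclass
class Alignment:
    """Ungapped placements of one collapsed read on the genome."""

    read: CollapsedRead
    intervals: list[GenomeInterval]
    mismatches: list[int]

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.mismatches):
            raise ValueError("intervals and mismatches must be parallel")
        for iv in self.intervals:
            if len(iv) != len(self.read.sequence):
                raise ValueError("ungapped alignment interval must equal read length")


@dataclass
class PirnaCluster:
    id: str
    interval: GenomeInterval
    member_pirna_ids: list[str] = field(default_factory=list)
    per_sample_counts: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Annotated-reference matching (zero mismatch)


def match_pirbase(
    reads: Sequence[CollapsedRead],
    reference: Sequence[tuple[str, str]],
) -> list[CollapsedRead]:
    """Reads that perfectly align (no mismatch) with an annotated piRNA.

    A read matches iff it is contained in a reference sequence or a
    reference sequence is contained in the read (sense orientation only).
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    joined = "#".join(seq for _, seq in reference)
    ref_seqs = {seq for _, seq in reference}
    ref_lengths = sorted({len(seq) for _, seq in reference})
    matched: list[CollapsedRead] = []
    for read in reads:
        seq = read.sequence
        if seq in joined:
            matched.append(read)
            continue
        hit = False
        for L in ref_lengths:
            if L >= len(seq):
                break
            for i in range(len(seq) - L + 1):
                if seq[i : i + L] in ref_seqs:
                    hit = True
                    break
            if hit:
                break
        if hit:
            matched.append(read)
    logger.info("match_pirbase: %d/%d reads matched", len(matched), len(reads))
    return matched


# ---------------------------------------------------------------------------
# Exact genome alignment


class GenomeIndex:
    """Seed-and-verify exact-occurrence index over a genome."""

    def __init__(self, genome: dict[str, str], k: int = 16):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom in sorted(self.genome):
            seq = self.genome[chrom]
            for i in range(len(seq) - k + 1):
                self._index[seq[i : i + k]].append((chrom, i))

    def occurrences(self, pattern: str) -> list[tuple[str, int]]:
        """All exact occurrences of ``pattern`` on the forward strand."""
        if len(pattern) < self.k:
            hits = []
            for chrom in sorted(self.genome):
                seq = self.genome[chrom]
                start = seq.find(pattern)
                while start != -1:
                    hits.append((chrom, start))
                    start = seq.find(pattern, start + 1)
            return hits
        seed = pattern[: self.k]
        out = []
        for chrom, pos in self._index.get(seed, ()):
            if self.genome[chrom][pos : pos + len(pattern)] == pattern:
                out.append((chrom, pos))
        return sorted(out)


def align_genome(
    reads: Sequence[CollapsedRead],
    genome: dict[str, str] | GenomeIndex,
    cap: int = 100,
) -> list[Alignment]:
    """All exact occurrences of each read on both strands, up to ``cap``.

    Placements are reported in deterministic (chrom, start, strand) order;
    reads with zero occurrences are dropped (count logged); reads with more
    than ``cap`` placements keep the first ``cap``.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    alignments: list[Alignment] = []
    unaligned = 0
    for read in reads:
        seq = read.sequence
        placements: list[tuple[str, int, str]] = [
            (c, p, "+") for c, p in index.occurrences(seq)
        ]
        rc = reverse_complement(seq)
        placements += [(c, p, "-") for c, p in index.occurrences(rc)]
        placements.sort()
        if not placements:
            unaligned += 1
            continue
        placements = placements[:cap]
        intervals = [
            GenomeInterval(c, p, p + len(seq), strand) for c, p, strand in placements
        ]
        alignments.append(Alignment(read, intervals, [0] * len(intervals)))
    logger.info(
        "align_genome: %d/%d reads aligned (%d dropped with no occurrence)",
        len(alignments), len(reads), unaligned,
    )
    return alignments


# ---------------------------------------------------------------------------
# Cluster calling and counting


def call_clusters(
    annotations: Sequence[tuple[str, GenomeInterval]],
) -> list[PirnaCluster]:
    """Merge overlapping and book-ended annotation intervals into clusters.

    Merging ignores strand (preset mergeBed-style behavior, gap 0 merges);
    output is sorted by (chrom, start) and clusters are pairwise disjoint.
    """
    by_key = sorted(annotations, key=lambda t: (t[1].chrom, t[1].start, t[1].end))
    clusters: list[PirnaCluster] = []
    cur_chrom: Optional[str] = None
    cur_start = cur_end = 0
    cur_members: list[str] = []

    def flush() -> None:
        if cur_chrom is None:
            return
        cid = f"cluster_{len(clusters) + 1}"
        clusters.append(
            PirnaCluster(cid, GenomeInterval(cur_chrom, cur_start, cur_end), list(cur_members))
        )

    for name, iv in by_key:
        if cur_chrom == iv.chrom and iv.start <= cur_end:  # overlap or book-ended
            cur_end = max(cur_end, iv.end)
            cur_members.append(name)
        else:
            flush()
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
            cur_members = [name]
    flush()
    logger.info("call_clusters: %d annotations -> %d clusters", len(by_key), len(clusters))
    return clusters


def count_cluster_reads(
    alignments: Sequence[Alignment],
    clusters: Sequence[PirnaCluster],
    weighted_multimappers: bool = False,
) -> dict[str, dict[str, float]]:
    """Per-cluster, per-sample multiplicity-weighted alignment counts.

    An alignment is counted for a cluster iff 100% of its interval lies
    within the cluster interval.  Each placement of a multi-mapping read
    contributes ``multiplicity`` (or ``multiplicity / n_placements`` in the
    non-default weighted mode).  Cluster counts are also stored on the
    cluster objects.  Raises if clusters overlap (violated precondition).
    """
    by_chrom: dict[str, list[tuple[int, int, PirnaCluster]]] = defaultdict(list)
    for cl in clusters:
        by_chrom[cl.interval.chrom].append((cl.interval.start, cl.interval.end, cl))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping clusters on {chrom} at {s2} < {e1}")
    starts = {c: [s for s, _, _ in ivs] for c, ivs in by_chrom.items()}

    counts: dict[str, dict[str, float]] = defaultdict(lambda: defaultdict(float))
    for aln in alignments:
        weight = aln.read.multiplicity
        if weighted_multimappers and aln.intervals:
            weight = weight / len(aln.intervals)
        for iv in aln.intervals:
            ivs = by_chrom.get(iv.chrom)
            if not ivs:
                continue
            j = bisect_right(starts[iv.chrom], iv.start) - 1
            if j < 0:
                continue
            s, e, cl = ivs[j]
            if iv.start >= s and iv.end <= e:
                counts[cl.id][aln.read.sample] += weight
    for cl in clusters:
        cl.per_sample_counts = dict(counts.get(cl.id, {}))
    return {cid: dict(per) for cid, per in counts.items()}


def cluster_summary(clusters: Sequence[PirnaCluster]) -> dict:
    """Headline cluster statistics (count, lengths, reads, chromosome tally)."""
    if not clusters:
        raise ValueError("cluster_summary requires at least one cluster")
    lengths = [len(cl.interval) for cl in clusters]
    reads = [sum(cl.per_sample_counts.values()) for cl in clusters]
    per_chrom: dict[str, int] = defaultdict(int)
    for cl in clusters:
        per_chrom[cl.interval.chrom] += 1
    return {
        "n_clusters": len(clusters),
        "mean_length": mean(lengths),
        "median_length": median(lengths),
        "max_length": max(lengths),
        "mean_reads_per_cluster": mean(reads) if reads else 0.0,
        "max_reads_per_cluster": max(reads) if reads else 0.0,
        "clusters_per_chromosome": dict(sorted(per_chrom.items())),
    }
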