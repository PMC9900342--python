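"""Annotation categorization and in-silico piRNA target assignment.

A transcript harbors a target site when it contains, within the configured
mismatch/coverage criteria, either the piRNA sequence itself (sense
homology) or its reverse complement (antisense complementarity).  The
match criteria are deliberately shared with the decontamination filter
(<=1 mismatch over >=90% of the piRNA) and exposed in configuration,
since no tighter definition is available; genes are the unit of
reporting and unique piRNA sequences count once per gene no matter how
many sites they hit.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats, special

from .io import GenomeInterval, reverse_complement
from .preprocess import MatchCriteria, best_ungapped_hit

logger = logging.getLogger(__name__)

CATEGORY_PRECEDENCE = (
    "RE_within_GENCODE",
    "RE_only",
    "GENCODE_element",
    "cluster_member",
    "unannotated",
)


@dataclass
class PirnaCategory:
    pirna_id: str
    category: str
    re_family: Optional[str] = None


@dataclass
class TargetReport:
    gene_id: str
    n_unique_targeting_pirnas: int = 0
    summed_targeting_tpm: float = 0.0
    sense_sites: int = 0
    antisense_sites: int = 0
    is_target: bool = False
    log2_fold_change: float = float("nan")
    modulated: bool = False


# ---------------------------------------------------------------------------
# Annotation categories


def categorize_pirnas(
    loci: Sequence[tuple[str, GenomeInterval]],
    repeats: Sequence[tuple[GenomeInterval, str]],
    genes: Sequence[tuple[GenomeInterval, str]],
    clusters: Sequence[GenomeInterval] = (),
) -> tuple[list[PirnaCategory], dict[str, float], dict[str, float]]:
    """Assign each piRNA locus to exactly one annotation category.

    Precedence: overlaps a repeat AND a gene element -> RE_within_GENCODE;
    repeat only -> RE_only; gene only -> GENCODE_element; otherwise
    cluster_member when a called cluster overlaps, else unannotated.
    Returns (categories, category proportions, RE-family proportions among
    repeat-overlapping piRNAs).
    """
    known_chroms = {iv.chrom for iv, _ in repeats} | {iv.chrom for iv, _ in genes} | {
        iv.chrom for iv in clusters
    }
    categories: list[PirnaCategory] = []
    family_counts: dict[str, int] = {}
    for pid, locus in loci:
        if known_chroms and locus.chrom not in known_chroms:
            raise ValueError(
                f"piRNA {pid}: chromosome {locus.chrom!r} absent from annotations"
            )
        re_hits = [fam for iv, fam in repeats if iv.overlaps(locus)]
        gene_hit = any(iv.overlaps(locus) for iv, _ in genes)
        cluster_hit = any(iv.overlaps(locus) for iv in clusters)
        family = re_hits[0] if re_hits else None
        if re_hits and gene_hit:
            cat = "RE_within_GENCODE"
        elif re_hits:
            cat = "RE_only"
        elif gene_hit:
            cat = "GENCODE_element"
        elif cluster_hit:
            cat = "cluster_member"
        else:
            cat = "unannotated"
        if family is not None:
            family_counts[family] = family_counts.get(family, 0) + 1
        categories.append(PirnaCategory(pid, cat, family))
    n = len(categories) or 1
    proportions = {
        cat: sum(1 for c in categories if c.category == cat) / n
        for cat in CATEGORY_PRECEDENCE
    }
    fam_total = sum(family_counts.values()) or 1
    family_proportions = {f: c / fam_total for f, c in sorted(family_counts.items())}
    return categories, proportions, family_proportions


# ---------------------------------------------------------------------------
# Target prediction


def _site_exists(query: str, transcript: str, criteria: MatchCriteria) -> bool:
    if criteria.max_mismatches == 0 and criteria.min_query_coverage >= 100:
        return query in transcript
    return best_ungapped_hit(query, transcript, criteria) is not None


def predict_targets(
    pirnas: Sequence[tuple[str, str, float]],
    transcripts: Sequence[tuple[str, str, str]],
    criteria: MatchCriteria = MatchCriteria(),
    fold_changes: Optional[dict[str, float]] = None,
    modulated: Optional[set[str]] = None,
) -> tuple[pd.DataFrame, dict[str, TargetReport]]:
    """Assign piRNAs ``(id, sequence, tpm)`` to transcript targets.

    ``transcripts`` rows are ``(transcript_id, gene_id, sequence)``.  A
    sense site means the transcript contains the piRNA sequence (homology)
    and an antisense site that it contains its reverse complement
    (complementarity), both within ``criteria``.  Returns the site table
    and per-gene reports; a gene is a target iff at least one unique piRNA
    targets any of its transcripts, with summed TPM over distinct
    targeting piRNA sequences.
    """
    if not transcripts:
        raise ValueError("empty transcriptome")
    sites = []
    gene_pirnas: dict[str, dict[str, float]] = {}
    gene_orient: dict[str, dict[str, int]] = {}
    # prescreen: any qualifying site shares an exact k-mer with the probe
    # (pigeonhole over the allowed mismatches), so only transcripts sharing
    # a k-mer need full alignment
    min_len = min((len(seq) for _, seq, _ in pirnas), default=25)
    qmin = math.ceil(criteria.min_query_coverage / 100.0 * min_len)
    k = max(4, qmin // (criteria.max_mismatches + 1) - 1)
    tx_kmers: dict[str, set[int]] = {}
    for t_idx, (_, _, seq) in enumerate(transcripts):
        for i in range(len(seq) - k + 1):
            tx_kmers.setdefault(seq[i : i + k], set()).add(t_idx)
    for pid, pseq, tpm in pirnas:
        probes = []
        if "sense" in criteria.orientations:
            probes.append(("sense", pseq))
        if "antisense" in criteria.orientations:
            probes.append(("antisense", reverse_complement(pseq)))
        for orient, q in probes:
            candidates: set[int] = set()
            for i in range(len(q) - k + 1):
                candidates |= tx_kmers.get(q[i : i + k], set())
            for t_idx in sorted(candidates):
                tx_id, gene_id, tx_seq = transcripts[t_idx]
                if not _site_exists(q, tx_seq, criteria):
                    continue
                sites.append(
                    {"pirna_id": pid, "gene_id": gene_id, "transcript_id": tx_id,
                     "orientation": orient, "tpm": tpm}
                )
                gene_pirnas.setdefault(gene_id, {})[pid] = tpm
                orient_counts = gene_orient.setdefault(gene_id, {"sense": 0, "antisense": 0})
                orient_counts[orient] += 1
    site_table = pd.DataFrame(
        sites, columns=["pirna_id", "gene_id", "transcript_id", "orientation", "tpm"]
    )
    reports: dict[str, TargetReport] = {}
    gene_ids = sorted({gene_id for _, gene_id, _ in transcripts})
    for gene_id in gene_ids:
        per = gene_pirnas.get(gene_id, {})
        orient = gene_orient.get(gene_id, {"sense": 0, "antisense": 0})
        report = TargetReport(
            gene_id=gene_id,
            n_unique_targeting_pirnas=len(per),
            summed_targeting_tpm=float(sum(per.values())),
            sense_sites=orient["sense"],
            antisense_sites=orient["antisense"],
            is_target=len(per) >= 1,
        )
        if fold_changes is not None and gene_id in fold_changes:
            report.log2_fold_change = float(fold_changes[gene_id])
        if modulated is not None:
            report.modulated = gene_id in modulated
        reports[gene_id] = report
    n_targets = sum(r.is_target for r in reports.values())
    logger.info("predict_targets: %d/%d genes targeted", n_targets, len(reports))
    return site_table, reports


def predict_targets_by_locus(
    pirna_loci: Sequence[tuple[str, GenomeInterval]],
    gene_intervals: Sequence[tuple[GenomeInterval, str]],
) -> dict[str, set[str]]:
    """Alternative locus-overlap target mode: gene -> overlapping piRNA ids.

    A gene is a target when any piRNA genomic locus overlaps its interval;
    this trades the sequence-level site definition for a purely positional
    one and is provided for comparison with the sequence-matching default.
    """
    out: dict[str, set[str]] = {gene_id: set() for _, gene_id in gene_intervals}
    for pid, locus in pirna_loci:
        for iv, gene_id in gene_intervals:
            if iv.overlaps(locus):
                out[gene_id].add(pid)
    return out


def target_load_summary(reports: Sequence[TargetReport]) -> dict:
    """Distribution summaries of per-gene target load and modulation split."""
    if not reports:
        raise ValueError("no gene reports")
    uniques = [r.n_unique_targeting_pirnas for r in reports]
    tpms = [r.summed_targeting_tpm for r in reports]
    return {
        "n_genes": len(reports),
        "n_target_genes": sum(r.is_target for r in reports),
        "max_unique_pirnas": max(uniques),
        "median_unique_pirnas": float(np.median(uniques)),
        "max_summed_tpm": max(tpms),
        "median_summed_tpm": float(np.median(tpms)),
        "modulated_targets": sum(r.modulated and r.is_target for r in reports),
        "modulated_nontargets": sum(r.modulated and not r.is_target for r in reports),
    }


# ---------------------------------------------------------------------------
# Statistics


def ks_compare(
    sample1: Sequence[float], sample2: Sequence[float], exact_limit: int = 20
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov D and p.

    D is the supremum ECDF difference.  For n1 + n2 <= ``exact_limit`` the
    p-value is computed by exhaustive enumeration over all C(n1+n2, n1)
    labelings of the pooled values; otherwise the asymptotic Kolmogorov
    distribution is used with effective n = n1*n2/(n1+n2).
    """
    a = np.sort(np.asarray(sample1, dtype=float))
    b = np.sort(np.asarray(sample2, dtype=float))
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    d_obs = _ks_statistic(a, b)
    if n1 + n2 <= exact_limit:
        pooled = np.concatenate([a, b])
        total = 0
        extreme = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(combo)] = True
            d = _ks_statistic(np.sort(pooled[mask]), np.sort(pooled[~mask]))
            total += 1
            if d >= d_obs - 1e-12:
                extreme += 1
        return float(d_obs), extreme / total
    en = n1 * n2 / (n1 + n2)
    p = float(special.kolmogorov(math.sqrt(en) * d_obs))
    return float(d_obs), min(1.0, max(0.0, p))


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Sup |ECDF_a - ECDF_b| for sorted samples."""
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


def spearman_targets(
    pirna_levels: Sequence[float], fold_changes: Sequence[float]
) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with t-approximation p-value."""
    x = np.asarray(pirna_levels, dtype=float)
    y = np.asarray(fold_changes, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rho undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
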