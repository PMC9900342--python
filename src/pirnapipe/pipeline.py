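"""End-to-end orchestration: simulate -> trim -> decontaminate -> match ->
align -> clusters -> counts -> signatures -> DE -> targets -> statistics.

Each stage logs record counts in and out; the machine-readable summary
collects every headline statistic plus a reconciliation ledger of read
counts so that no stage can silently gain reads.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import characterize, discovery, expression, simdata, targeting
from .config import RunConfig
from .io import (
    GenomeInterval,
    write_bed,
    write_collapsed_fasta,
    write_fasta,
    write_json,
    write_matrix,
)
from .preprocess import MatchCriteria, filter_ncrna, removal_report, trim_reads

logger = logging.getLogger(__name__)


def assign_cluster_reads(
    alignments: list[discovery.Alignment],
    clusters: list[discovery.PirnaCluster],
) -> dict[str, list[characterize.ClusterRead]]:
    """Map cluster id -> reads fully contained in it, with genomic 5' ends."""
    out: dict[str, list[characterize.ClusterRead]] = {cl.id: [] for cl in clusters}
    sorted_clusters = sorted(clusters, key=lambda c: (c.interval.chrom, c.interval.start))
    for aln in alignments:
        for iv in aln.intervals:
            for cl in sorted_clusters:
                if cl.interval.contains(iv):
                    five_prime = iv.start if iv.strand == "+" else iv.end - 1
                    out[cl.id].append(
                        characterize.ClusterRead(
                            aln.read.sequence, five_prime, iv.strand, aln.read.multiplicity
                        )
                    )
                    break
    return out


def _reference_tpm(pirna_reference, matched_reads) -> list[tuple[str, str, float]]:
    """Per-million abundance of each reference piRNA among matched reads.

    A matched read contributes its multiplicity to every reference it is
    contained in (or that it contains); abundances are scaled to TPM.
    """
    counts = {rec.id: 0.0 for rec in pirna_reference}
    for read in matched_reads:
        seq = read.sequence
        for rec in pirna_reference:
            if seq in rec.sequence or rec.sequence in seq:
                counts[rec.id] += read.multiplicity
    total = sum(counts.values()) or 1.0
    return [
        (rec.id, rec.sequence, counts[rec.id] / total * 1e6) for rec in pirna_reference
    ]


def run_pipeline(
    run_config: RunConfig,
    sim_config: Optional[simdata.SimulationConfig] = None,
    output_dir: Optional[str] = None,
) -> dict:
    """Simulate data per ``sim_config`` and run every analysis stage.

    Writes stage artifacts under the output directory and returns (and
    writes) a summary JSON with all headline statistics.  Determinism:
    identical configs produce identical summaries.
    """
    if sim_config is None:
        sim_config = simdata.SimulationConfig(seed=run_config.seed)
    outdir = Path(output_dir or run_config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_config.echo(outdir)
    write_json(simdata.config_to_dict(sim_config), outdir / "sim_config.json")

    criteria = MatchCriteria(
        min_identity=run_config.min_identity,
        max_mismatches=run_config.max_mismatches,
        min_query_coverage=run_config.min_query_coverage,
    )

    # --- simulate
    sim = simdata.make_genome(sim_config)
    reads_by_sample, read_truth = simdata.make_reads(sim_config, sim)
    write_fasta(sim.pirna_reference, outdir / "pirna_reference.fa")
    write_bed(
        [(iv, f"cluster_{i + 1}", 0.0) for i, iv in enumerate(sim.truth_clusters)],
        outdir / "truth_clusters.bed",
    )

    ledger: dict[str, dict] = {}
    summary: dict = {"seed": run_config.seed}

    # --- trim + decontaminate + reference match, per sample
    all_matched: dict[str, list] = {}
    retained_by_sample: dict[str, list] = {}
    for sample_id, records in reads_by_sample.items():
        trimmed, tstats = trim_reads(
            records,
            adapter=run_config.adapter,
            min_quality=run_config.min_quality,
            min_length=run_config.min_length,
            sample=sample_id,
        )
        retained, removed = filter_ncrna(trimmed, sim.ncrna_references, criteria)
        matched = discovery.match_pirbase(
            retained, [(r.id, r.sequence) for r in sim.pirna_reference]
        )
        retained_by_sample[sample_id] = retained
        all_matched[sample_id] = matched
        write_collapsed_fasta(matched, outdir / f"{sample_id}.matched.fa")
        rep = removal_report(removed)
        rep.to_csv(outdir / f"{sample_id}.ncrna_removed.tsv", sep="\t", index=False)
        ledger[sample_id] = {
            "reads_in": tstats.total_in,
            "too_short": tstats.too_short,
            "survived_trim": tstats.survivors,
            "removed_ncrna": int(sum(r.multiplicity for r, _ in removed)),
            "putative_pirnas": int(sum(r.multiplicity for r in retained)),
            "matched_reference": int(sum(r.multiplicity for r in matched)),
        }
        lost = tstats.total_in - tstats.too_short - tstats.survivors
        if lost != 0 or ledger[sample_id]["removed_ncrna"] + ledger[sample_id][
            "putative_pirnas"
        ] != tstats.survivors:
            raise AssertionError(f"count ledger does not reconcile for {sample_id}")

    summary["n_putative_pirnas"] = int(sum(l["putative_pirnas"] for l in ledger.values()))
    summary["n_matched_reference"] = int(sum(l["matched_reference"] for l in ledger.values()))

    # --- align matched reads, project annotations, call clusters, count
    index = discovery.GenomeIndex(sim.genome)
    annotation_loci = []
    for rec in sim.pirna_reference:
        for chrom, pos in index.occurrences(rec.sequence):
            annotation_loci.append((rec.id, GenomeInterval(chrom, pos, pos + len(rec.sequence))))
    clusters = discovery.call_clusters(annotation_loci)

    alignments = []
    for sample_id, matched in all_matched.items():
        alignments.extend(discovery.align_genome(matched, index, cap=run_config.alignment_cap))
    discovery.count_cluster_reads(alignments, clusters)
    csum = discovery.cluster_summary(clusters) if clusters else {}
    summary["n_clusters"] = len(clusters)
    summary["mean_cluster_length"] = csum.get("mean_length")
    summary["max_reads_per_cluster"] = csum.get("max_reads_per_cluster")
    cluster_table = pd.DataFrame(
        [
            {
                "cluster_id": cl.id,
                "chrom": cl.interval.chrom,
                "start": cl.interval.start,
                "end": cl.interval.end,
                "length": len(cl.interval),
                "n_members": len(cl.member_pirna_ids),
                **{f"count_{s}": c for s, c in sorted(cl.per_sample_counts.items())},
            }
            for cl in clusters
        ]
    )
    cluster_table.to_csv(outdir / "clusters.tsv", sep="\t", index=False)

    # --- truth comparison (recall / spurious rate)
    recovered = 0
    for truth_iv in sim.truth_clusters:
        if any(cl.interval.overlaps(truth_iv) for cl in clusters):
            recovered += 1
    spurious = sum(
        1 for cl in clusters if not any(cl.interval.overlaps(t) for t in sim.truth_clusters)
    )
    summary["cluster_recall"] = recovered / len(sim.truth_clusters)
    summary["spurious_cluster_rate"] = spurious / max(len(clusters), 1)

    # --- signatures on matched reads (pooled across samples)
    pooled = [r for reads in all_matched.values() for r in reads]
    freqs, mode = characterize.length_distribution(pooled)
    matrix, u1 = characterize.five_prime_bias(pooled)
    summary["mode_read_length"] = mode
    summary["u1_fraction"] = u1
    pd.DataFrame(
        {"length": list(freqs), "frequency": list(freqs.values())}
    ).to_csv(outdir / "length_distribution.tsv", sep="\t", index=False)

    cluster_reads = assign_cluster_reads(alignments, clusters)
    profile = characterize.distance_probability(
        cluster_reads, window=run_config.distance_window, lowess_span=run_config.lowess_span
    )
    summary["distance_argmax"] = profile.argmax_distance()
    summary["distance_argmax_smoothed"] = profile.argmax_distance(smoothed=True)
    pd.DataFrame(
        {
            "distance": profile.distances,
            "probability": profile.probability,
            "smoothed": profile.smoothed,
        }
    ).to_csv(outdir / "distance_profile.tsv", sep="\t", index=False)

    # --- expression: knockdown table, DE, targets
    expr, expr_truth = simdata.make_expression(sim_config)
    write_matrix(expr, outdir / "expression_counts.tsv")
    de_results = expression.differential_features(
        expr, alpha=run_config.de_padj, lfc_threshold=run_config.de_lfc
    )
    de_table = pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "baseMean": r.base_mean,
                "log2FC": r.log2_fold_change,
                "p": r.p_value,
                "padj": r.padj,
                "call": r.call,
            }
            for r in de_results
        ]
    )
    de_table.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
    summary["n_up"] = int((de_table["call"] == "up").sum())
    summary["n_down"] = int((de_table["call"] == "down").sum())

    # --- in-silico target assignment against a planted transcriptome
    targeted_ids = list(expr_truth.index[expr_truth["is_target"]])
    transcripts = simdata.make_transcriptome(sim_config, sim.pirna_reference, targeted_ids)
    pirna_tpms = _reference_tpm(sim.pirna_reference, pooled)
    lfc = de_table.set_index("feature_id")["log2FC"]
    modulated = set(de_table.loc[de_table["call"] != "unchanged", "feature_id"])
    site_table, reports = targeting.predict_targets(
        pirna_tpms,
        transcripts,
        criteria,
        fold_changes=lfc.to_dict(),
        modulated=modulated,
    )
    site_table.to_csv(outdir / "target_sites.tsv", sep="\t", index=False)
    load = targeting.target_load_summary(list(reports.values()))
    summary["max_target_load"] = load["max_unique_pirnas"]
    summary["max_target_tpm"] = load["max_summed_tpm"]

    target_lfc = [r.log2_fold_change for r in reports.values() if r.is_target]
    nontarget_lfc = [r.log2_fold_change for r in reports.values() if not r.is_target]
    if target_lfc and nontarget_lfc:
        d_stat, ks_p = targeting.ks_compare(target_lfc, nontarget_lfc)
        summary["ks_D"] = d_stat
        summary["ks_p"] = ks_p
    summary["read_ledger"] = ledger

    write_json(summary, outdir / "summary.json")
    logger.info("run_pipeline: summary written to %s", outdir / "summary.json")
    return summary
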