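"""Synthetic genomes, annotations, reads and expression tables with ground truth.

The generator plants exactly the statistical structure the downstream
analysis assumes: piRNA clusters at known, well-separated genomic loci,
tiled with overlapping annotated piRNA sequences (so merging recovers one
cluster per locus); read lengths drawn from a 24-35 nt distribution with a
configurable mode; a 5'U bias for primary reads; secondary reads whose 5'
termini sit near primary 5' ends per a configurable offset kernel; ncRNA
contaminants sampled as exact reference substrings (the worst case for the
decontamination filter); a 3' adapter plus random padding to instrument
length; and a knockdown-vs-control expression table in which targeted
genes are preferentially shifted by a configurable log2 effect.

Everything is deterministic under a fixed seed: each stage derives its own
``numpy.random.default_rng([seed, tag])`` stream, so regenerating any
output with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GenomeInterval, SequenceRecord, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"

# rng stream tags, one per generation stage
_TAG_GENOME, _TAG_READS, _TAG_EXPR, _TAG_TX = 1, 2, 3, 4


def _default_length_distribution() -> dict[int, float]:
    # 24-35 nt, unimodal with mode 30; mass at 24 exercises the length filter
    weights = {24: 0.01, 25: 0.03, 26: 0.05, 27: 0.08, 28: 0.12, 29: 0.16,
               30: 0.22, 31: 0.14, 32: 0.09, 33: 0.05, 34: 0.03, 35: 0.02}
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


def _default_kernel() -> dict[int, float]:
    return {-2: 0.1, -1: 0.2, 0: 0.4, 1: 0.2, 2: 0.1}


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_size: int = 200_000
    n_clusters: int = 10
    cluster_length_range: tuple[int, int] = (150, 300)
    reads_per_sample: int = 50_000
    length_distribution: dict[int, float] = field(default_factory=_default_length_distribution)
    u_bias: float = 0.8
    secondary_fraction: float = 0.3
    distance_kernel: dict[int, float] = field(default_factory=_default_kernel)
    contaminant_fraction: float = 0.05
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    instrument_length: int = 50
    samples: tuple[tuple[str, str], ...] = (("DIF0", "DIF0"), ("DIF4", "DIF4"))
    quality_decay: bool = False
    # cap on primary annotations tiled per cluster; None tiles the full span.
    # Small caps (e.g. 1) give clusters whose only 5'-5' pair structure is
    # the planted kernel, making the distance profile directly identifiable.
    pirnas_per_cluster: Optional[int] = None
    # expression table
    n_genes: int = 2_000
    targeted_fraction: float = 0.3
    n_replicates: int = 3
    expr_mean: float = 200.0
    expr_log_sigma: float = 1.0
    nb_dispersion: float = 0.1
    kd_effect_mean: float = 1.0
    kd_effect_sd: float = 0.0
    transcript_length: int = 300

    def __post_init__(self) -> None:
        probs = np.array(list(self.length_distribution.values()))
        if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError("length_distribution must be a probability distribution")
        if any(not (24 <= k <= 35) for k in self.length_distribution):
            raise ValueError("read lengths must lie in 24-35")
        kernel = np.array(list(self.distance_kernel.values()))
        if abs(kernel.sum() - 1.0) > 1e-9 or (kernel < 0).any():
            raise ValueError("distance_kernel must be a probability distribution")
        for name in ("u_bias", "secondary_fraction", "contaminant_fraction", "targeted_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("non-positive dispersion")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")


@dataclass
class SimAnnotation:
    pirna_id: str
    cluster_index: int
    start: int  # genomic, chrom "chr1"
    length: int
    role: str  # primary / secondary

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class SimulatedGenome:
    config: SimulationConfig
    genome: dict[str, str]
    annotations: list[SimAnnotation]
    pirna_reference: list[SequenceRecord]
    truth_clusters: list[GenomeInterval]  # union span per planted cluster
    ncrna_references: list[tuple[str, str, str]]  # (id, class, sequence)
    cluster_weights: dict[str, np.ndarray]  # sample -> per-cluster probability

    @property
    def chrom(self) -> str:
        return next(iter(self.genome))


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


NCRNA_TEMPLATE = (
    ("snoRNA", 150, 2),
    ("tRNA", 76, 2),
    ("miRNA_hairpin", 85, 2),
    ("miRNA_mature", 22, 2),
    ("rDNA", 400, 1),
)


def make_genome(config: SimulationConfig) -> SimulatedGenome:
    """Generate genome, tiled piRNA annotations, reference sets and truth.

    Clusters are placed without overlap with >=100 bp gaps; annotations
    within a cluster are tiled with steps shorter than the minimum
    annotation length, so adjacent annotations always overlap and merging
    yields exactly one cluster per planted locus.
    """
    rng = np.random.default_rng([config.seed, _TAG_GENOME])
    lo, hi = config.cluster_length_range
    if not (35 <= lo <= hi):
        raise ValueError("cluster lengths must be >= 35 and ordered")
    lengths = rng.integers(lo, hi + 1, config.n_clusters)
    gap_min = 100
    needed = int(lengths.sum()) + (config.n_clusters + 1) * gap_min
    if needed > config.genome_size:
        raise ValueError(
            f"infeasible packing: need {needed} bases for {config.n_clusters} "
            f"clusters, genome_size is {config.genome_size}"
        )
    slack = config.genome_size - needed
    extra = rng.multinomial(slack, np.full(config.n_clusters + 1, 1 / (config.n_clusters + 1)))
    starts = []
    pos = 0
    for i in range(config.n_clusters):
        pos += gap_min + int(extra[i])
        starts.append(pos)
        pos += int(lengths[i])

    bases = _random_bases(rng, config.genome_size)
    constraints: dict[int, str] = {}
    annotations: list[SimAnnotation] = []
    kernel_offsets = np.array(sorted(config.distance_kernel))
    kernel_probs = np.array([config.distance_kernel[o] for o in kernel_offsets])
    sec_frac = config.secondary_fraction
    p_partner = min(1.0, sec_frac / (1.0 - sec_frac)) if sec_frac < 1 else 1.0

    def constrain(pos_: int, base: str) -> bool:
        existing = constraints.get(pos_)
        if existing is not None and existing != base:
            return False
        constraints[pos_] = base
        return True

    counter = 0
    for ci, (cstart, clen) in enumerate(zip(starts, lengths)):
        cend = cstart + int(clen)
        tile = cstart
        cluster_anns: list[SimAnnotation] = []
        while tile + 25 <= cend and (
            config.pirnas_per_cluster is None
            or len(cluster_anns) < config.pirnas_per_cluster
        ):
            alen = int(rng.integers(25, 33))
            if tile + alen > cend:
                alen = cend - tile
            counter += 1
            ann = SimAnnotation(f"piRNA_{counter}", ci, tile, alen, "primary")
            cluster_anns.append(ann)
            # plant the 5' base (U bias)
            first = "T" if rng.random() < config.u_bias else "ACG"[rng.integers(0, 3)]
            constrain(tile, first)
            tile += int(rng.integers(8, 16))
        # secondary partners with 5' offsets drawn from the kernel; a
        # secondary read carries the 10A / non-1U signature, so sites whose
        # planted bases would clash with an existing constraint are dropped
        for ann in list(cluster_anns):
            if ann.role != "primary" or rng.random() >= p_partner:
                continue
            offset = int(rng.choice(kernel_offsets, p=kernel_probs))
            site = ann.start + offset
            alen = int(rng.integers(25, 33))
            if site < cstart or site + alen > cend:
                continue
            c0, c9 = constraints.get(site), constraints.get(site + 9)
            if c0 == "T" or c9 not in (None, "A"):
                continue
            first = c0 if c0 is not None else "ACG"[rng.integers(0, 3)]
            constraints[site] = first
            constraints[site + 9] = "A"
            counter += 1
            cluster_anns.append(SimAnnotation(f"piRNA_{counter}", ci, site, alen, "secondary"))
        annotations.extend(sorted(cluster_anns, key=lambda a: (a.start, a.end)))

    for pos_, base in constraints.items():
        bases[pos_] = ord(base)
    genome_str = _to_str(bases)

    pirna_reference = [
        SequenceRecord(a.pirna_id, genome_str[a.start : a.end]) for a in annotations
    ]
    truth_clusters = []
    for ci in range(config.n_clusters):
        anns = [a for a in annotations if a.cluster_index == ci]
        truth_clusters.append(
            GenomeInterval("chr1", min(a.start for a in anns), max(a.end for a in anns))
        )

    ncrna_references = []
    for cls, length, count in NCRNA_TEMPLATE:
        for j in range(count):
            ncrna_references.append(
                (f"{cls}_{j + 1}", cls, _to_str(_random_bases(rng, length)))
            )

    cluster_weights = {}
    for sample_id, _cond in config.samples:
        w = rng.dirichlet(np.full(config.n_clusters, 5.0))
        cluster_weights[sample_id] = w

    return SimulatedGenome(
        config=config,
        genome={"chr1": genome_str},
        annotations=annotations,
        pirna_reference=pirna_reference,
        truth_clusters=truth_clusters,
        ncrna_references=ncrna_references,
        cluster_weights=cluster_weights,
    )


def make_reads(
    config: SimulationConfig, sim: SimulatedGenome
) -> tuple[dict[str, list[SequenceRecord]], pd.DataFrame]:
    """Simulate per-sample reads plus the per-read origin truth table.

    Cluster reads start at an annotation 5' end and run for a length drawn
    from the configured distribution (clipped at the cluster's 3' boundary,
    so genuine cluster reads are always fully contained in their cluster);
    contaminants are exact substrings of the ncRNA references.  Each read
    is the insert followed by the 3' adapter, padded with random bases and
    truncated to instrument length.
    """
    rng = np.random.default_rng([config.seed, _TAG_READS])
    genome = sim.genome["chr1"]
    anns = sim.annotations
    if any(
        not [a for a in anns if a.cluster_index == ci] for ci in range(config.n_clusters)
    ):
        raise ValueError("cluster with zero annotated piRNAs")
    ann_cluster = np.array([a.cluster_index for a in anns])
    cluster_union = {ci: (iv.start, iv.end) for ci, iv in enumerate(sim.truth_clusters)}
    lengths_support = np.array(sorted(config.length_distribution))
    length_probs = np.array([config.length_distribution[k] for k in lengths_support])
    eligible_ncrna = [
        (rid, cls, seq) for rid, cls, seq in sim.ncrna_references if len(seq) >= 35
    ]
    instr = config.instrument_length
    base_quality = [40] * instr
    if config.quality_decay:
        base_quality = [40] * (instr - 5) + [2] * 5

    per_sample: dict[str, list[SequenceRecord]] = {}
    truth_rows: list[tuple] = []
    for sample_id, _cond in config.samples:
        weights = sim.cluster_weights[sample_id]
        ann_probs = np.zeros(len(anns))
        for ci in range(config.n_clusters):
            members = np.flatnonzero(ann_cluster == ci)
            ann_probs[members] = weights[ci] / len(members)
        ann_probs /= ann_probs.sum()
        n = config.reads_per_sample
        is_contam = rng.random(n) < config.contaminant_fraction
        ann_idx = rng.choice(len(anns), size=n, p=ann_probs)
        read_lengths = rng.choice(lengths_support, size=n, p=length_probs)
        pad_pool = _to_str(_random_bases(rng, n * instr))
        contam_ref = rng.integers(0, len(eligible_ncrna), size=n)
        contam_u = rng.random(n)

        records: list[SequenceRecord] = []
        pad_ptr = 0
        for i in range(n):
            L = int(read_lengths[i])
            if is_contam[i]:
                rid, cls, ref_seq = eligible_ncrna[contam_ref[i]]
                start = int(contam_u[i] * (len(ref_seq) - L + 1))
                insert = ref_seq[start : start + L]
                origin, label, five_prime = "ncrna", cls, -1
            else:
                a = anns[ann_idx[i]]
                ustart, uend = cluster_union[a.cluster_index]
                L = min(L, uend - a.start)
                insert = genome[a.start : a.start + L]
                origin, label, five_prime = "cluster", f"cluster_{a.cluster_index + 1}", a.start
            full = insert + config.adapter
            if len(full) < instr:
                need = instr - len(full)
                full += pad_pool[pad_ptr : pad_ptr + need]
                pad_ptr += need
            else:
                full = full[:instr]
            read_id = f"{sample_id}_r{i + 1}"
            records.append(SequenceRecord(read_id, full, quality=list(base_quality)))
            truth_rows.append((read_id, sample_id, origin, label, len(insert), five_prime))
        per_sample[sample_id] = records
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "sample", "origin", "label", "insert_length", "five_prime"],
    )
    return per_sample, truth


def make_expression(
    config: SimulationConfig, targeted_ids: Optional[Sequence[str]] = None
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Knockdown-vs-control NB count table with planted target upregulation.

    Control counts are negative binomial around per-gene lognormal means;
    targeted genes' knockdown means are multiplied by ``2**effect`` with
    ``effect ~ Normal(kd_effect_mean, kd_effect_sd)``; non-targeted genes
    differ by sampling noise only.
    """
    rng = np.random.default_rng([config.seed, _TAG_EXPR])
    genes = [f"gene_{i + 1:05d}" for i in range(config.n_genes)]
    if targeted_ids is None:
        n_t = int(round(config.targeted_fraction * config.n_genes))
        targeted_ids = list(rng.choice(genes, size=n_t, replace=False))
    targeted = set(targeted_ids)
    is_target = np.array([g in targeted for g in genes])

    mu = rng.lognormal(mean=np.log(config.expr_mean), sigma=config.expr_log_sigma, size=config.n_genes)
    effects = np.zeros(config.n_genes)
    effects[is_target] = rng.normal(config.kd_effect_mean, config.kd_effect_sd, is_target.sum())

    disp = config.nb_dispersion
    r = 1.0 / disp

    def nb_draws(means: np.ndarray, n_cols: int) -> np.ndarray:
        p = r / (r + means)
        return rng.negative_binomial(r, p[:, None], size=(len(means), n_cols))

    ctrl = nb_draws(mu, config.n_replicates)
    kd = nb_draws(mu * np.exp2(effects), config.n_replicates)
    columns = [f"ctrl_{j + 1}" for j in range(config.n_replicates)] + [
        f"kd_{j + 1}" for j in range(config.n_replicates)
    ]
    df = pd.DataFrame(np.hstack([ctrl, kd]), index=genes, columns=columns, dtype=float)
    conditions = {c: ("control" if c.startswith("ctrl") else "KD") for c in columns}
    truth = pd.DataFrame(
        {"gene_id": genes, "is_target": is_target, "true_log2fc": effects}
    ).set_index("gene_id")
    return ExpressionMatrix(df, conditions=conditions, unit="count"), truth


def make_transcriptome(
    config: SimulationConfig,
    pirna_reference: Sequence[SequenceRecord],
    targeted_ids: Sequence[str],
    sites_per_gene: int = 2,
) -> list[tuple[str, str, str]]:
    """Random transcripts; targeted genes carry planted piRNA sites.

    Each targeted gene's transcript embeds ``sites_per_gene`` sites, the
    reverse complement of a randomly chosen reference piRNA (antisense
    complementarity) or the sequence itself (sense homology), overwriting
    the local bases.  Returns ``(transcript_id, gene_id, sequence)`` rows.
    """
    rng = np.random.default_rng([config.seed, _TAG_TX])
    targeted = set(targeted_ids)
    out = []
    gene_ids = [f"gene_{i + 1:05d}" for i in range(config.n_genes)]
    for gene_id in gene_ids:
        seq = list(_to_str(_random_bases(rng, config.transcript_length)))
        if gene_id in targeted and pirna_reference:
            for _ in range(sites_per_gene):
                ref = pirna_reference[int(rng.integers(0, len(pirna_reference)))]
                site = ref.sequence if rng.random() < 0.5 else reverse_complement(ref.sequence)
                if len(site) >= config.transcript_length:
                    continue
                pos = int(rng.integers(0, config.transcript_length - len(site) + 1))
                seq[pos : pos + len(site)] = site
        out.append((f"{gene_id}.t1", gene_id, "".join(seq)))
    return out


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["length_distribution"] = {str(k): v for k, v in config.length_distribution.items()}
    d["distance_kernel"] = {str(k): v for k, v in config.distance_kernel.items()}
    d["samples"] = [list(s) for s in config.samples]
    d["cluster_length_range"] = list(config.cluster_length_range)
    return d
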