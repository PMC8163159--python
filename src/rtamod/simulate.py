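"""Synthetic 3'-CCA-anchored tRNA-seq data with planted RT signatures.

The generator emulates the read structure of CCA-selective tRNA sequencing:
every read begins at the 3' CCA end of a mature tRNA and extends 5'-ward
until the reverse transcriptase either reaches the 5' end or arrests at a
planted modification (the read's 5' end then lies one position 3' of the
modified base).  Modified positions that are read through receive a
misincorporated base according to a per-site mismatch spectrum; every
emitted base is additionally subject to a uniform background error rate.

Output is written both as FASTQ (for an external-mapping workflow) and as a
truth-aligned SAM — correct by construction — so the profiling and calling
stages can be exercised without running an aligner.  All randomness flows
from a single integer seed; identical configurations produce byte-identical
files.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam

from .reference import (
    MITOCHONDRIAL,
    NUCLEAR,
    TRNACluster,
    TRNAGene,
    cluster_identical,
    mature_sequence,
)
from .sprinzl import _BACKBONE, _CONSERVED

BASES = ("A", "C", "G", "T")

# anticodons used round-robin when generating gene sets
_ANTICODONS = [
    ("Ala", "AGC"), ("Gly", "GCC"), ("Pro", "TGG"), ("Thr", "AGT"),
    ("Val", "AAC"), ("Ser", "AGA"), ("Arg", "ACG"), ("Leu", "AAG"),
    ("Phe", "GAA"), ("Asn", "GTT"), ("Lys", "CTT"), ("Asp", "GTC"),
    ("Glu", "TTC"), ("His", "GTG"), ("Gln", "TTG"), ("Ile", "AAT"),
    ("Met", "CAT"), ("Tyr", "GTA"), ("Cys", "GCA"), ("Trp", "CCA"),
]


@dataclass(frozen=True)
class SimSite:
    """One planted modification."""

    cluster_id: str
    position: int  # 1-based mature coordinate
    modification_code: str
    stop_prob: float
    mismatch_probs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.stop_prob <= 1.0:
            raise ValueError("stop_prob outside [0,1]")
        if sum(self.mismatch_probs.values()) > 1.0 + 1e-9:
            raise ValueError("mismatch probabilities sum above 1")


@dataclass
class SimConfig:
    """Study-condition knobs; the seed fully determines all output."""

    n_clusters: int = 70
    n_mitochondrial: int = 15
    multiplicities: Optional[Sequence[int]] = None  # per-cluster gene copies
    total_genes: int = 421
    intron_prob: float = 0.15
    intron_length: tuple[int, int] = (11, 30)
    depth_mean: float = 300.0
    depth_shape: float = 2.0  # gamma shape for per-cluster depth
    background_error: float = 0.001
    background_stop: float = 0.0  # per-position spurious arrest rate
    quality_score: int = 40
    seed: int = 0


# ---------------------------------------------------------------------------
# gene / cluster generation


def _random_mature(rng: np.random.Generator, anticodon: str) -> str:
    """Mutate the consensus scaffold at non-conserved, non-anticodon columns.

    Conserved columns and the anchored anticodon stay fixed so template
    fitting always succeeds; ~12 other positions are substituted per cluster.
    """
    seq = list(_BACKBONE)
    seq[33:36] = list(anticodon)
    free = [
        i for i in range(73)
        if (i + 1) not in _CONSERVED and not 33 <= i <= 35
    ]
    for i in rng.choice(free, size=12, replace=False):
        seq[i] = BASES[rng.integers(4)]
    return "".join(seq)


def simulate_genes(config: SimConfig) -> tuple[list[TRNAGene], list[TRNACluster]]:
    """Generate a gene set whose clustering yields exactly the configured counts.

    Returns the genes and the clusters they collapse into.  With defaults this
    reproduces the study cardinality: 421 genes in 70 clusters, of which 15
    are mitochondrial.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_clusters
    mult = list(config.multiplicities) if config.multiplicities else _default_multiplicities(
        rng, n, config.total_genes
    )
    if len(mult) != n:
        raise ValueError("multiplicities length must equal n_clusters")

    matures: set[str] = set()
    genes: list[TRNAGene] = []
    gid = 0
    for ci in range(n):
        iso, ac = _ANTICODONS[ci % len(_ANTICODONS)]
        mat = _random_mature(rng, ac)
        while mat in matures:
            mat = _random_mature(rng, ac)
        matures.add(mat)
        origin = MITOCHONDRIAL if ci >= n - config.n_mitochondrial else NUCLEAR
        for copy in range(mult[ci]):
            gid += 1
            # drop the terminal CCA so the tail is appended during maturation
            gene_seq = mat[:-3]
            introns: tuple[tuple[int, int], ...] = ()
            if origin == NUCLEAR and rng.random() < config.intron_prob:
                ilen = int(rng.integers(*config.intron_length))
                intron = "".join(BASES[b] for b in rng.integers(0, 4, ilen))
                # canonical intron location: one base 3' of the anticodon
                gene_seq = gene_seq[:37] + intron + gene_seq[37:]
                introns = ((38, 37 + ilen),)
            contig = f"chrM_{gid}" if origin == MITOCHONDRIAL else f"contig_{gid}"
            start = 51  # 50 nt of 5' flank in the toy genome
            genes.append(
                TRNAGene(
                    gene_id=f"trna{gid:04d}",
                    contig=contig,
                    start=start,
                    end=start + len(gene_seq) - 1,
                    strand="+" if rng.random() < 0.5 else "-",
                    sequence=gene_seq,
                    anticodon=ac,
                    isotype=iso,
                    intron_intervals=introns,
                    origin=origin,
                )
            )
    clusters = cluster_identical(genes)
    return genes, clusters


def _default_multiplicities(rng: np.random.Generator, n: int, total: int) -> list[int]:
    """n positive integers summing to ``total``, skewed like real gene families."""
    if total < n:
        raise ValueError("total_genes must be >= n_clusters")
    weights = rng.dirichlet(np.full(n, 0.8))
    mult = np.maximum(1, np.floor(weights * total).astype(int))
    # adjust to the exact total deterministically
    diff = total - int(mult.sum())
    order = np.argsort(-weights)
    i = 0
    while diff != 0:
        j = order[i % n]
        if diff > 0:
            mult[j] += 1
            diff -= 1
        elif mult[j] > 1:
            mult[j] -= 1
            diff += 1
        i += 1
    return mult.tolist()


def write_genome(genes: list[TRNAGene], fasta_path, genes_tsv_path,
                 seed: int = 0) -> None:
    """Write a toy genome FASTA (one contig per gene, 50 nt flanks) + gene TSV."""
    rng = np.random.default_rng(seed ^ 0x5EED)
    from Bio.Seq import Seq

    with open(fasta_path, "w") as fa, open(genes_tsv_path, "w") as tsv:
        tsv.write(
            "gene_id\tcontig\tstart\tend\tstrand\tisotype\tanticodon\tintrons\torigin\n"
        )
        for g in genes:
            flank5 = "".join(BASES[b] for b in rng.integers(0, 4, g.start - 1))
            flank3 = "".join(BASES[b] for b in rng.integers(0, 4, 50))
            insert = g.sequence if g.strand == "+" else str(
                Seq(g.sequence).reverse_complement()
            )
            fa.write(f">{g.contig}\n{flank5}{insert}{flank3}\n")
            introns = ",".join(f"{a}-{b}" for a, b in g.intron_intervals)
            tsv.write(
                f"{g.gene_id}\t{g.contig}\t{g.start}\t{g.end}\t{g.strand}\t"
                f"{g.isotype}\t{g.anticodon}\t{introns}\t{g.origin}\n"
            )


# ---------------------------------------------------------------------------
# planted sites


def plant_sites(
    clusters: list[TRNACluster],
    rng: np.random.Generator,
    sites_per_cluster: tuple[int, int] = (1, 4),
    stop_range: tuple[float, float] = (0.3, 0.9),
    mismatch_range: tuple[float, float] = (0.2, 0.8),
    min_spacing: int = 5,
) -> list[SimSite]:
    """Draw random planted modifications, spaced apart within each cluster.

    Each site carries an arrest probability, a misincorporation fraction, or
    both (equal thirds); positions avoid the first 5 and last 4 nt so stops
    remain observable and the CCA stays clean.
    """
    sites = []
    for c in clusters:
        L = len(c.mature_sequence)
        nsites = int(rng.integers(sites_per_cluster[0], sites_per_cluster[1] + 1))
        chosen: list[int] = []
        candidates = list(range(6, L - 4))
        rng.shuffle(candidates)
        for pos in candidates:
            if len(chosen) >= nsites:
                break
            if all(abs(pos - p) >= min_spacing for p in chosen):
                chosen.append(pos)
        for pos in sorted(chosen):
            kind = rng.integers(3)  # 0 stop, 1 mismatch, 2 both
            stop = float(rng.uniform(*stop_range)) if kind in (0, 2) else 0.0
            mm: dict[str, float] = {}
            if kind in (1, 2):
                ref = c.mature_sequence[pos - 1]
                targets = [b for b in BASES if b != ref]
                tgt = targets[rng.integers(3)]
                mm = {tgt: float(rng.uniform(*mismatch_range))}
            sites.append(
                SimSite(
                    cluster_id=c.cluster_id,
                    position=pos,
                    modification_code="sim",
                    stop_prob=stop,
                    mismatch_probs=mm,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    clusters: list[TRNACluster],
    sites: list[SimSite],
    config: SimConfig,
    out_dir: str | Path,
    sample_id: str = "sample",
    depths: Optional[dict[str, int]] = None,
) -> dict[str, Path]:
    """Emit FASTQ + truth-aligned SAM + truth TSV for one sample.

    ``depths`` overrides the per-cluster read counts (otherwise gamma-drawn
    around ``depth_mean``).  Returns paths keyed by artifact kind.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # stable per-sample stream: crc32 is process-invariant, unlike hash()
    rng = np.random.default_rng(
        (config.seed * 1000003 + zlib.crc32(sample_id.encode())) % (2**31)
    )
    by_cluster: dict[str, list[SimSite]] = {}
    for s in sites:
        by_cluster.setdefault(s.cluster_id, []).append(s)
    for cid in by_cluster:
        by_cluster[cid].sort(key=lambda s: -s.position)  # 3' -> 5'

    fastq_path = out_dir / f"{sample_id}.fastq"
    sam_path = out_dir / f"{sample_id}.sam"
    truth_path = out_dir / f"{sample_id}.truth.tsv"

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": c.cluster_id, "LN": len(c.mature_sequence)}
            for c in clusters
        ],
    }
    qchar = chr(config.quality_score + 33)
    n_total = 0
    with open(fastq_path, "w") as fq, pysam.AlignmentFile(
        str(sam_path), "wh", header=header
    ) as sam:
        for tid, c in enumerate(clusters):
            L = len(c.mature_sequence)
            depth = (
                depths[c.cluster_id]
                if depths is not None
                else max(10, int(rng.gamma(config.depth_shape,
                                           config.depth_mean / config.depth_shape)))
            )
            cl_sites = by_cluster.get(c.cluster_id, [])
            for ri in range(depth):
                five_prime = 1
                stopped = False
                for s in cl_sites:  # ordered 3' -> 5'
                    if s.stop_prob and rng.random() < s.stop_prob:
                        five_prime = s.position + 1
                        stopped = True
                        break
                if not stopped and config.background_stop:
                    for pos in range(L - 1, 1, -1):
                        if rng.random() < config.background_stop:
                            five_prime = pos
                            break
                seq = list(c.mature_sequence[five_prime - 1 :])
                for s in cl_sites:
                    if s.position >= five_prime and s.mismatch_probs:
                        u = rng.random()
                        acc = 0.0
                        for tgt, pr in sorted(s.mismatch_probs.items()):
                            acc += pr
                            if u < acc:
                                seq[s.position - five_prime] = tgt
                                break
                if config.background_error:
                    hits = np.nonzero(
                        rng.random(len(seq)) < config.background_error
                    )[0]
                    for i in hits:
                        alt = [b for b in BASES if b != seq[i]]
                        seq[i] = alt[rng.integers(3)]
                read_seq = "".join(seq)
                name = f"{sample_id}:{c.cluster_id}:{ri}"
                fq.write(f"@{name}\n{read_seq}\n+\n{qchar * len(read_seq)}\n")
                a = pysam.AlignedSegment()
                a.query_name = name
                a.query_sequence = read_seq
                a.flag = 0
                a.reference_id = tid
                a.reference_start = five_prime - 1
                a.mapping_quality = 60
                a.cigarstring = f"{len(read_seq)}M"
                a.query_qualities = pysam.qualitystring_to_array(
                    qchar * len(read_seq)
                )
                a.set_tag("NH", 1)
                sam.write(a)
                n_total += 1

    with open(truth_path, "w") as fh:
        fh.write("cluster_id\tposition\tmodification_code\tstop_prob\tmismatch_probs\n")
        for s in sorted(sites, key=lambda s: (s.cluster_id, s.position)):
            mm = ";".join(f"{b}:{p!r}" for b, p in sorted(s.mismatch_probs.items()))
            fh.write(
                f"{s.cluster_id}\t{s.position}\t{s.modification_code}\t"
                f"{s.stop_prob!r}\t{mm}\n"
            )
    return {"fastq": fastq_path, "sam": sam_path, "truth": truth_path,
            "n_reads": n_total}


def read_truth(path) -> list[SimSite]:
    import csv

    sites = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            mm = {}
            if row["mismatch_probs"]:
                for part in row["mismatch_probs"].split(";"):
                    b, p = part.split(":")
                    mm[b] = float(p)
            sites.append(
                SimSite(
                    cluster_id=row["cluster_id"],
                    position=int(row["position"]),
                    modification_code=row["modification_code"],
                    stop_prob=float(row["stop_prob"]),
                    mismatch_probs=mm,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# time course


TIME_LABELS = ("0h", "6h", "16h", "20h", "24h")


def simulate_timecourse(
    clusters: list[TRNACluster],
    config: SimConfig,
    out_dir: str | Path,
    time_labels: Sequence[str] = TIME_LABELS,
    site_overrides: Optional[dict[str, list[SimSite]]] = None,
    expression: Optional[dict[str, float]] = None,
) -> Path:
    """One sample per time label; returns the manifest TSV path.

    Per-sample read depths are drawn independently around cluster expression
    weights (lognormal unless ``expression`` is given); arrest probabilities
    may vary per sample via ``site_overrides``.  Expression and planted
    arrest strength are drawn independently of each other, so under the
    default configuration there is no built-in correlation between the two.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng((config.seed * 2654435761 + 17) % (2**31))
    if expression is None:
        expression = {
            c.cluster_id: float(rng.lognormal(0.0, 0.8)) for c in clusters
        }
    base_sites = plant_sites(clusters, rng) if site_overrides is None else None
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("sample_id\ttime_label\tsam\ttruth\treference\n")
        for t in time_labels:
            sites = (
                site_overrides[t] if site_overrides is not None else [
                    dataclasses.replace(
                        s,
                        stop_prob=min(
                            1.0, s.stop_prob * float(rng.uniform(0.6, 1.4))
                        ) if s.stop_prob else 0.0,
                    )
                    for s in base_sites
                ]
            )
            depths = {
                c.cluster_id: max(
                    10,
                    int(rng.poisson(config.depth_mean * expression[c.cluster_id])),
                )
                for c in clusters
            }
            arts = simulate_reads(
                clusters, sites, config, out_dir, sample_id=t, depths=depths
            )
            fh.write(f"{t}\t{t}\t{arts['sam']}\t{arts['truth']}\t-\n")
    return manifest
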