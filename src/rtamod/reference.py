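"""Non-redundant mature tRNA reference construction.

tRNA genes are frequently present in many identical copies; reads from such
copies cannot be told apart after mapping.  This module turns a set of
annotated tRNA genes into the set of distinct *mature* sequences (introns
spliced out, 3'-CCA appended) and records which genes belong to which
cluster.  All downstream profiling is per cluster, not per gene.

Coordinates are 1-based inclusive throughout; mature reference positions run
1..L with the terminal A of the CCA tail at position L.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

_DNA = set("ACGT")

NUCLEAR = "nuclear"
MITOCHONDRIAL = "mitochondrial"


class ReferenceError(ValueError):
    """Raised for invalid gene annotations or malformed reference inputs."""


@dataclass(frozen=True)
class TRNAGene:
    """One annotated tRNA gene.

    ``sequence`` is in gene-strand orientation (5'->3'); ``intron_intervals``
    are 1-based inclusive and relative to that sequence.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    sequence: str
    anticodon: str
    isotype: str
    intron_intervals: tuple[tuple[int, int], ...] = ()
    origin: str = NUCLEAR

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ReferenceError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.origin not in {NUCLEAR, MITOCHONDRIAL}:
            raise ReferenceError(f"{self.gene_id}: unknown origin {self.origin!r}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ReferenceError(
                f"{self.gene_id}: sequence length {len(self.sequence)} does not "
                f"match coordinates {self.start}-{self.end}"
            )
        if set(self.sequence) - _DNA:
            raise ReferenceError(f"{self.gene_id}: non-ACGT characters in sequence")
        if len(self.anticodon) != 3:
            raise ReferenceError(f"{self.gene_id}: anticodon must be a 3-mer")
        _validate_introns(self.gene_id, self.intron_intervals, len(self.sequence))


def _validate_introns(
    gene_id: str, intervals: Sequence[tuple[int, int]], gene_len: int
) -> None:
    prev_end = 0
    total = 0
    for lo, hi in intervals:
        if lo > hi:
            raise ReferenceError(f"{gene_id}: inverted intron interval ({lo},{hi})")
        if lo <= prev_end:
            raise ReferenceError(f"{gene_id}: overlapping/unsorted intron intervals")
        if lo < 1 or hi > gene_len:
            raise ReferenceError(f"{gene_id}: intron ({lo},{hi}) outside gene")
        prev_end = hi
        total += hi - lo + 1
    if intervals and total >= gene_len:
        raise ReferenceError(f"{gene_id}: introns cover the entire gene")


@dataclass(frozen=True)
class TRNACluster:
    """A group of tRNA genes with identical mature sequences."""

    cluster_id: str
    mature_sequence: str
    member_gene_ids: tuple[str, ...]
    anticodon: str
    isotype: str
    origin: str = NUCLEAR

    def __post_init__(self) -> None:
        if not self.mature_sequence.endswith("CCA"):
            raise ReferenceError(f"{self.cluster_id}: mature sequence must end in CCA")


def splice_introns(gene: TRNAGene) -> str:
    """Excise the gene's intron intervals, preserving exon order."""
    seq = gene.sequence
    pieces = []
    pos = 0  # 0-based cursor
    for lo, hi in gene.intron_intervals:
        pieces.append(seq[pos : lo - 1])
        pos = hi
    pieces.append(seq[pos:])
    return "".join(pieces)


def append_cca(spliced: str) -> str:
    """Append a 3'-CCA tail unless the sequence already ends in one.

    Conditional appending avoids CCACCA artifacts for genomically encoded
    tails.
    """
    if not spliced:
        raise ReferenceError("empty sequence cannot receive a CCA tail")
    if set(spliced) - _DNA:
        raise ReferenceError("non-ACGT characters in spliced sequence")
    if spliced.endswith("CCA"):
        return spliced
    return spliced + "CCA"


def mature_sequence(gene: TRNAGene) -> str:
    """Spliced, CCA-appended sequence of a gene."""
    return append_cca(splice_introns(gene))


def cluster_identical(genes: Iterable[TRNAGene]) -> list[TRNACluster]:
    """Group genes whose mature sequences are identical.

    Nuclear and mitochondrial genes never share a cluster even when their
    sequences coincide.  Cluster ids are deterministic: isotype + anticodon +
    ordinal, ordinals assigned in lexicographic mature-sequence order within
    each (isotype, anticodon, origin) group; mitochondrial ids carry an
    ``mt-`` prefix.
    """
    genes = list(genes)
    seen_ids: set[str] = set()
    for g in genes:
        if g.gene_id in seen_ids:
            raise ReferenceError(f"duplicate gene_id {g.gene_id}")
        seen_ids.add(g.gene_id)

    groups: dict[tuple[str, str], list[TRNAGene]] = {}
    for g in genes:
        groups.setdefault((mature_sequence(g), g.origin), []).append(g)

    # ordinal assignment within (isotype, anticodon, origin)
    keyed = sorted(
        groups.items(),
        key=lambda kv: (
            kv[1][0].isotype,
            kv[1][0].anticodon,
            kv[0][1],
            kv[0][0],
        ),
    )
    counters: dict[tuple[str, str, str], int] = {}
    clusters = []
    for (seq, origin), members in keyed:
        iso, ac = members[0].isotype, members[0].anticodon
        n = counters.get((iso, ac, origin), 0) + 1
        counters[(iso, ac, origin)] = n
        prefix = "mt-" if origin == MITOCHONDRIAL else ""
        clusters.append(
            TRNACluster(
                cluster_id=f"{prefix}{iso}-{ac}-{n}",
                mature_sequence=seq,
                member_gene_ids=tuple(sorted(g.gene_id for g in members)),
                anticodon=ac,
                isotype=iso,
                origin=origin,
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# I/O


def load_genes(genes_tsv: str | Path, genome_fasta: str | Path) -> list[TRNAGene]:
    """Read a gene annotation TSV plus genome FASTA into TRNAGene records.

    Expected TSV columns: gene_id, contig, start, end, strand, isotype,
    anticodon, introns (comma-separated lo-hi pairs, empty for none), origin.
    """
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    genes = []
    with open(genes_tsv) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            contig = row["contig"]
            if contig not in contigs:
                raise ReferenceError(f"{row['gene_id']}: contig {contig!r} not in FASTA")
            start, end = int(row["start"]), int(row["end"])
            raw = contigs[contig][start - 1 : end]
            if row["strand"] == "-":
                raw = str(Seq(raw).reverse_complement())
            introns = _parse_introns(row.get("introns", ""))
            genes.append(
                TRNAGene(
                    gene_id=row["gene_id"],
                    contig=contig,
                    start=start,
                    end=end,
                    strand=row["strand"],
                    sequence=raw,
                    anticodon=row["anticodon"].upper(),
                    isotype=row["isotype"],
                    intron_intervals=introns,
                    origin=row.get("origin", NUCLEAR) or NUCLEAR,
                )
            )
    return genes


def _parse_introns(text: str) -> tuple[tuple[int, int], ...]:
    text = text.strip()
    if not text:
        return ()
    out = []
    for part in text.split(","):
        lo, hi = part.split("-")
        out.append((int(lo), int(hi)))
    return tuple(out)


def write_reference(
    clusters: Sequence[TRNACluster], out_prefix: str | Path
) -> tuple[Path, Path]:
    """Write mature reference FASTA and gene->cluster membership TSV."""
    out_prefix = Path(out_prefix)
    fasta = out_prefix.with_suffix(".fa")
    tsv = out_prefix.with_suffix(".members.tsv")
    with open(fasta, "w") as fh:
        for c in clusters:
            fh.write(f">{c.cluster_id} isotype={c.isotype} anticodon={c.anticodon} origin={c.origin}\n")
            fh.write(c.mature_sequence + "\n")
    with open(tsv, "w") as fh:
        fh.write("gene_id\tcluster_id\n")
        for c in clusters:
            for gid in c.member_gene_ids:
                fh.write(f"{gid}\t{c.cluster_id}\n")
    return fasta, tsv


def read_reference(fasta: str | Path, members_tsv: str | Path) -> list[TRNACluster]:
    """Inverse of :func:`write_reference`."""
    members: dict[str, list[str]] = {}
    with open(members_tsv) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            members.setdefault(row["cluster_id"], []).append(row["gene_id"])
    clusters = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        meta = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        clusters.append(
            TRNACluster(
                cluster_id=rec.id,
                mature_sequence=str(rec.seq).upper(),
                member_gene_ids=tuple(sorted(members.get(rec.id, ()))),
                anticodon=meta.get("anticodon", "NNN"),
                isotype=meta.get("isotype", "Xxx"),
                origin=meta.get("origin", NUCLEAR),
            )
        )
    return clusters
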