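"""Read retention rules applied around the external mapping steps.

Three small, pure predicates/helpers:

* :func:`retain_read` — raw-read retention: 3'-quality trimming at a Phred
  cutoff followed by a length window (default 8-95 nt).
* :func:`max_mismatches` — the mismatch budget implied by a minimum mapping
  accuracy (default 80%, i.e. up to 20 mismatches on a 100 nt read); the
  mapping itself is performed externally.
* :func:`exclude_pre_trna` — removal of reads that reach outside the mature
  interval of a precursor contig (5' leaders / 3' trailers mark unprocessed
  pre-tRNAs, which must not contribute to mature-pool profiles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]  # Phred scores, one per base

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.read_id}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )


def quality_trim_length(qualities: Sequence[int], cutoff: int) -> int:
    """Length kept after 3'-end quality trimming at ``cutoff``.

    BWA-style partial-sum algorithm (as used by common trimmers): subtract the
    cutoff from each quality, accumulate from the 3' end, and cut where the
    running sum is minimal.  A read of uniformly high quality is untouched; a
    low-quality 3' tail is removed entirely.
    """
    best_sum = 0
    best_len = len(qualities)
    running = 0
    for i in range(len(qualities) - 1, -1, -1):
        running += cutoff - qualities[i]
        if running > best_sum:
            best_sum = running
            best_len = i
    return best_len


def retain_read(
    read: ReadRecord,
    min_len: int = 8,
    max_len: int = 95,
    qual_cutoff: int = 25,
) -> bool:
    """True iff the read survives quality trimming and the length window."""
    trimmed = quality_trim_length(read.qualities, qual_cutoff)
    return min_len <= trimmed <= max_len


def max_mismatches(read_len: int, accuracy_pct: float = 80.0) -> int:
    """Mismatch budget for a read at a minimum mapping accuracy.

    floor((1 - accuracy/100) * read_len): 20 mismatches for a 100 nt read at
    80% accuracy.
    """
    if not 0 <= accuracy_pct <= 100:
        raise ValueError("accuracy_pct must be within [0, 100]")
    if read_len < 0:
        raise ValueError("read_len must be non-negative")
    # exact rational floor: (1 - 0.8) * 100 must be 20, not 19.999...
    from fractions import Fraction

    frac = (100 - Fraction(str(accuracy_pct))) * read_len / 100
    return int(frac)  # truncation == floor for non-negative values


def exclude_pre_trna(
    aln_start: int,
    aln_end: int,
    mature_start: int,
    mature_end: int,
    k: int = 1,
) -> bool:
    """True (exclude) iff the alignment reaches >= ``k`` nt outside the mature interval.

    Coordinates are 1-based inclusive on the precursor contig.  A read whose
    alignment begins in the 5' leader or ends in the 3' trailer is a pre-tRNA
    hallmark and is removed from mature-pool analysis.
    """
    if aln_start > aln_end:
        raise ValueError("alignment interval inverted")
    return (mature_start - aln_start >= k) or (aln_end - mature_end >= k)


# ---------------------------------------------------------------------------
# FASTQ plumbing


def filter_fastq(
    reads: Iterable[ReadRecord],
    min_len: int = 8,
    max_len: int = 95,
    qual_cutoff: int = 25,
) -> Iterator[ReadRecord]:
    """Yield trimmed reads passing :func:`retain_read`."""
    for read in reads:
        n = quality_trim_length(read.qualities, qual_cutoff)
        if min_len <= n <= max_len:
            yield ReadRecord(read.read_id, read.sequence[:n], read.qualities[:n])


def read_fastq(path) -> Iterator[ReadRecord]:
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fastq"):
        yield ReadRecord(
            rec.id,
            str(rec.seq).upper(),
            tuple(rec.letter_annotations["phred_quality"]),
        )


def write_fastq(reads: Iterable[ReadRecord], path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")
            n += 1
    return n
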