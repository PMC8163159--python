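"""Per-position alignment profiles over mature tRNA cluster references.

For every reference position we record coverage, the number of reads whose
5'-most aligned base lies there ("stops"), and the base composition of the
aligned reads.  In 3'-anchored tRNA-seq libraries a reverse-transcriptase
arrest at a modified base n truncates cDNA so that the read's 5' end is n+1;
stop counts are therefore the raw signal for arrest-based modification
detection, and base counts carry the misincorporation signal.

The RTa intensity at position n is the fraction of reads covering n+1 that
terminate there:  stops(n+1) / coverage(n+1).  Under strict 3' anchoring this
equals 1 - coverage(n)/coverage(n+1); the latter read-through form is kept as
a debug quantity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

BASES = ("A", "C", "G", "T")


class ProfileError(ValueError):
    pass


@dataclass
class ClusterProfile:
    """Per-position counts over one cluster reference (positions 1..L)."""

    cluster_id: str
    ref_seq: str
    coverage: np.ndarray  # int, length L
    stop_count: np.ndarray  # int, length L
    base_counts: np.ndarray  # int, shape (L, 5): A C G T deletion
    total_reads: int = 0
    sprinzl_labels: Optional[dict[int, str]] = None

    @property
    def length(self) -> int:
        return len(self.ref_seq)

    def mismatch_count(self, pos: int) -> int:
        """Non-reference, non-deletion base calls at 1-based ``pos``."""
        row = self.base_counts[pos - 1]
        ref = self.ref_seq[pos - 1]
        total_bases = int(row[:4].sum())
        ref_idx = BASES.index(ref) if ref in BASES else None
        return total_bases - (int(row[ref_idx]) if ref_idx is not None else 0)

    def mismatch_spectrum(self, pos: int) -> dict[str, float]:
        """Fraction of coverage carrying each non-reference base at ``pos``."""
        cov = int(self.coverage[pos - 1])
        if cov == 0:
            return {}
        row = self.base_counts[pos - 1]
        ref = self.ref_seq[pos - 1]
        return {
            b: int(row[i]) / cov
            for i, b in enumerate(BASES)
            if b != ref and row[i] > 0
        }


def rta_intensity(profile: ClusterProfile, n: int) -> Optional[float]:
    """Fraction of reads covering n+1 whose 5' end is n+1 (arrest at n).

    Returns None (missing) when position n+1 has no coverage; 1 <= n < L.
    """
    if not 1 <= n < profile.length:
        raise ProfileError(f"position {n} out of range 1..{profile.length - 1}")
    cov = int(profile.coverage[n])  # 0-based index n == position n+1
    if cov == 0:
        return None
    return int(profile.stop_count[n]) / cov


def readthrough_fraction(profile: ClusterProfile, n: int) -> Optional[float]:
    """coverage(n)/coverage(n+1) — the literal complement of the stop fraction."""
    if not 1 <= n < profile.length:
        raise ProfileError(f"position {n} out of range")
    cov = int(profile.coverage[n])
    if cov == 0:
        return None
    return int(profile.coverage[n - 1]) / cov


def build_profiles(
    alignments: str | Path,
    reference: str | Path,
    sprinzl_maps: Optional[dict] = None,
    exclude_read_ids: Optional[set[str]] = None,
) -> dict[str, ClusterProfile]:
    """Build per-cluster profiles from a SAM/BAM over the mature reference.

    Secondary/supplementary records and reads flagged multi-mapped (NH > 1)
    are dropped; soft-clipped bases are ignored; deletions count toward
    coverage but not base composition; insertions are skipped.  ``exclude_read_ids``
    allows upstream pre-tRNA exclusion to be honoured here.
    """
    refs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(reference), "fasta")}
    profiles = {
        cid: ClusterProfile(
            cluster_id=cid,
            ref_seq=seq,
            coverage=np.zeros(len(seq), dtype=np.int64),
            stop_count=np.zeros(len(seq), dtype=np.int64),
            base_counts=np.zeros((len(seq), 5), dtype=np.int64),
            sprinzl_labels=(
                sprinzl_maps[cid].to_dict()
                if sprinzl_maps and cid in sprinzl_maps
                else None
            ),
        )
        for cid, seq in refs.items()
    }

    mode = "rb" if str(alignments).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(alignments), mode, check_sq=False) as sam:
        missing = [
            name for name in (sam.references or ()) if name not in refs
        ]
        if missing:
            raise ProfileError(
                "alignment references absent from FASTA: " + ", ".join(missing)
            )
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.has_tag("NH") and aln.get_tag("NH") > 1:
                continue
            if exclude_read_ids and aln.query_name in exclude_read_ids:
                continue
            prof = profiles[aln.reference_name]
            _add_read(prof, aln)
            prof.total_reads += 1
    return profiles


def _add_read(prof: ClusterProfile, aln: "pysam.AlignedSegment") -> None:
    qseq = aln.query_sequence or ""
    five_prime: Optional[int] = None
    for qpos, rpos in aln.get_aligned_pairs():
        if rpos is None:  # insertion or soft clip: no reference anchor
            continue
        if rpos >= prof.length:
            raise ProfileError(
                f"{prof.cluster_id}: alignment past reference end ({rpos + 1})"
            )
        if five_prime is None:
            five_prime = rpos
        prof.coverage[rpos] += 1
        if qpos is None:  # deletion in the read
            prof.base_counts[rpos, 4] += 1
        else:
            base = qseq[qpos].upper()
            if base in BASES:
                prof.base_counts[rpos, BASES.index(base)] += 1
            else:
                prof.coverage[rpos] -= 1  # N calls carry no information
    if five_prime is not None:
        prof.stop_count[five_prime] += 1


# ---------------------------------------------------------------------------
# tabular output


def profiles_to_frame(profiles: dict[str, ClusterProfile]) -> pd.DataFrame:
    """Long-format table: one row per (cluster, position); positions 1-based."""
    rows = []
    for cid in sorted(profiles):
        p = profiles[cid]
        for i in range(p.length):
            n = i + 1
            lab = p.sprinzl_labels.get(n, "") if p.sprinzl_labels else ""
            intensity = rta_intensity(p, n - 1) if n >= 2 else None
            rows.append(
                {
                    "cluster_id": cid,
                    "pos": n,
                    "sprinzl": lab,
                    "ref": p.ref_seq[i],
                    "cov": int(p.coverage[i]),
                    "stops": int(p.stop_count[i]),
                    "A": int(p.base_counts[i, 0]),
                    "C": int(p.base_counts[i, 1]),
                    "G": int(p.base_counts[i, 2]),
                    "T": int(p.base_counts[i, 3]),
                    "del": int(p.base_counts[i, 4]),
                    # arrest evidence for position n-1 lives at row n
                    "rta_at_prev": "" if intensity is None else f"{intensity:.6g}",
                }
            )
    return pd.DataFrame(rows)


def write_profiles(profiles: dict[str, ClusterProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False)


def frame_to_profiles(df: pd.DataFrame) -> dict[str, ClusterProfile]:
    """Rebuild ClusterProfile objects from the long-format table."""
    out = {}
    for cid, sub in df.groupby("cluster_id", sort=True):
        sub = sub.sort_values("pos")
        L = len(sub)
        labels = {
            int(r.pos): str(r.sprinzl)
            for r in sub.itertuples()
            if isinstance(r.sprinzl, str) and r.sprinzl
        }
        prof = ClusterProfile(
            cluster_id=str(cid),
            ref_seq="".join(sub["ref"]),
            coverage=sub["cov"].to_numpy(np.int64),
            stop_count=sub["stops"].to_numpy(np.int64),
            base_counts=sub[["A", "C", "G", "T", "del"]].to_numpy(np.int64),
            total_reads=int(sub["stops"].sum()),
            sprinzl_labels=labels or None,
        )
        out[str(cid)] = prof
    return out


def read_profiles(path: str | Path) -> dict[str, ClusterProfile]:
    return frame_to_profiles(pd.read_csv(path, sep="\t", keep_default_na=False))
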