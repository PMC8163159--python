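"""Candidate modification-site calling from pileup profiles.

Two independent evidence channels are combined:

* **Misincorporation**: at each position the number of non-reference base
  calls is tested against a null in which mismatches arise independently at a
  fixed per-base error rate.  The one-sided exact binomial tail
  P(X >= k | coverage, error_rate) is Phred-scaled (-10 log10 p, capped at
  1000); positions reaching the confidence threshold (default 20, i.e.
  p <= 0.01) with at least ``min_reads`` coverage are called.

* **Reverse-transcriptase arrest (RTa)**: position n is called when the
  fraction of reads covering n+1 that terminate there is at least
  ``min_intensity`` (default 20%) with at least ``min_reads`` reads at n+1.

A third step removes a known reverse-transcriptase artifact: the TGIRT
enzyme can produce weak secondary arrest/mismatch echoes up to a few
positions 3' of a genuine modification.  Candidate arrest calls that sit
within ``window`` nt 3' of a stronger call, are weaker than it, and co-occur
with sub-threshold mismatches are flagged suppressed (never deleted).

Calling is fully deterministic: no randomness, no multiple-testing
correction (thresholds are the published operating point).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import pandas as pd
from scipy.stats import binom

from .profile import ClusterProfile, rta_intensity

PHRED_CAP = 1000.0


@dataclass
class ModificationCall:
    cluster_id: str
    position: int  # 1-based mature coordinate of the putative modified base
    sprinzl_label: Optional[str]
    ref_base: str
    evidence_rta: bool
    evidence_mismatch: bool
    rta_intensity: Optional[float]
    mismatch_fraction: float
    mismatch_spectrum: dict[str, float] = field(default_factory=dict)
    confidence_phred: float = 0.0
    coverage: int = 0
    suppressed_by_artifact_filter: bool = False
    candidate_identities: list[str] = field(default_factory=list)
    novelty: Optional[str] = None

    @property
    def key(self) -> tuple[str, int]:
        return (self.cluster_id, self.position)

    @property
    def dominant_mismatch(self) -> Optional[str]:
        if not self.mismatch_spectrum:
            return None
        return max(sorted(self.mismatch_spectrum), key=self.mismatch_spectrum.get)


def mismatch_confidence_phred(k: int, coverage: int, error_rate: float) -> float:
    """Phred-scaled one-sided binomial tail P(X >= k | coverage, error_rate)."""
    if not 0 < error_rate < 0.5:
        raise ValueError("error_rate must be in (0, 0.5)")
    if k <= 0:
        return 0.0
    p = float(binom.sf(k - 1, coverage, error_rate))
    if p <= 0.0:
        return PHRED_CAP
    return min(-10.0 * math.log10(p), PHRED_CAP)


def call_mismatch_sites(
    profiles: dict[str, ClusterProfile],
    min_conf_phred: float = 20.0,
    min_reads: int = 10,
    error_rate: float = 0.01,
) -> list[ModificationCall]:
    """Sites with misincorporation excess over the sequencing-error null."""
    calls = []
    for cid in sorted(profiles):
        p = profiles[cid]
        for pos in range(1, p.length + 1):
            cov = int(p.coverage[pos - 1])
            if cov < min_reads:
                continue
            k = p.mismatch_count(pos)
            conf = mismatch_confidence_phred(k, cov, error_rate)
            if conf < min_conf_phred:
                continue
            calls.append(
                ModificationCall(
                    cluster_id=cid,
                    position=pos,
                    sprinzl_label=(p.sprinzl_labels or {}).get(pos),
                    ref_base=p.ref_seq[pos - 1],
                    evidence_rta=False,
                    evidence_mismatch=True,
                    rta_intensity=rta_intensity(p, pos) if pos < p.length else None,
                    mismatch_fraction=k / cov,
                    mismatch_spectrum=p.mismatch_spectrum(pos),
                    confidence_phred=conf,
                    coverage=cov,
                )
            )
    return calls


def call_rta_sites(
    profiles: dict[str, ClusterProfile],
    min_intensity: float = 0.20,
    min_reads: int = 10,
) -> list[ModificationCall]:
    """Positions n where the arrest fraction at n+1 reaches the threshold."""
    calls = []
    for cid in sorted(profiles):
        p = profiles[cid]
        for n in range(1, p.length):
            cov_next = int(p.coverage[n])  # coverage at n+1
            if cov_next < min_reads:
                continue
            intensity = rta_intensity(p, n)
            if intensity is None or intensity < min_intensity:
                continue
            cov = int(p.coverage[n - 1])
            k = p.mismatch_count(n)
            calls.append(
                ModificationCall(
                    cluster_id=cid,
                    position=n,
                    sprinzl_label=(p.sprinzl_labels or {}).get(n),
                    ref_base=p.ref_seq[n - 1],
                    evidence_rta=True,
                    evidence_mismatch=False,
                    rta_intensity=intensity,
                    mismatch_fraction=(k / cov) if cov else 0.0,
                    mismatch_spectrum=p.mismatch_spectrum(n),
                    confidence_phred=0.0,
                    coverage=cov_next,
                )
            )
    return calls


def tgirt_artifact_filter(
    calls: list[ModificationCall],
    profiles: dict[str, ClusterProfile],
    window: int = 3,
    min_conf_phred: float = 20.0,
    error_rate: float = 0.01,
) -> list[ModificationCall]:
    """Flag secondary arrest echoes 3' of a stronger call as suppressed.

    A call at p is suppressed when a stronger RTa call q exists with
    q < p <= q + window, intensity(p) < intensity(q), and p shows mismatches
    that stay below the misincorporation confidence threshold (the echo
    pattern: some mismatch, but not enough for an independent call).
    Suppression flags only; nothing is removed from the list.
    """
    by_cluster: dict[str, list[ModificationCall]] = {}
    for c in calls:
        if c.evidence_rta:
            by_cluster.setdefault(c.cluster_id, []).append(c)
    out = []
    for c in calls:
        if not c.evidence_rta or c.rta_intensity is None:
            out.append(c)
            continue
        prof = profiles[c.cluster_id]
        k = prof.mismatch_count(c.position)
        cov = int(prof.coverage[c.position - 1])
        sub_threshold_mm = (
            k > 0
            and mismatch_confidence_phred(k, cov, error_rate) < min_conf_phred
        )
        suppressed = False
        if sub_threshold_mm:
            for q in by_cluster.get(c.cluster_id, ()):
                if (
                    q.position < c.position <= q.position + window
                    and q.rta_intensity is not None
                    and c.rta_intensity < q.rta_intensity
                ):
                    suppressed = True
                    break
        out.append(replace(c, suppressed_by_artifact_filter=suppressed))
    return out


def merge_evidence(
    mismatch_calls: list[ModificationCall],
    rta_calls: list[ModificationCall],
) -> list[ModificationCall]:
    """Union of the two channels by (cluster, position), evidence flags OR-ed."""
    merged: dict[tuple[str, int], ModificationCall] = {}
    for c in mismatch_calls:
        merged[c.key] = replace(c)
    for c in rta_calls:
        if c.key in merged:
            m = merged[c.key]
            merged[c.key] = replace(
                m,
                evidence_rta=True,
                rta_intensity=c.rta_intensity,
                suppressed_by_artifact_filter=(
                    m.suppressed_by_artifact_filter or c.suppressed_by_artifact_filter
                ),
            )
        else:
            merged[c.key] = replace(c)
    return [merged[k] for k in sorted(merged)]


def call_sites(
    profiles: dict[str, ClusterProfile],
    min_intensity: float = 0.20,
    min_reads: int = 10,
    min_conf_phred: float = 20.0,
    error_rate: float = 0.01,
    tgirt_window: int = 3,
) -> list[ModificationCall]:
    """Full calling pipeline: both channels, artifact filter, merge."""
    mm = call_mismatch_sites(profiles, min_conf_phred, min_reads, error_rate)
    rta = call_rta_sites(profiles, min_intensity, min_reads)
    rta = tgirt_artifact_filter(rta, profiles, tgirt_window, min_conf_phred, error_rate)
    return merge_evidence(mm, rta)


# ---------------------------------------------------------------------------
# tabular output


def calls_to_frame(calls: list[ModificationCall]) -> pd.DataFrame:
    rows = []
    for c in sorted(calls, key=lambda x: x.key):
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "pos": c.position,
                "sprinzl": c.sprinzl_label or "",
                "ref": c.ref_base,
                "evidence": _evidence_class(c),
                "rta_intensity": "" if c.rta_intensity is None else f"{c.rta_intensity:.6g}",
                "mismatch_fraction": f"{c.mismatch_fraction:.6g}",
                "mismatch_spectrum": ";".join(
                    f"{b}:{f:.4g}" for b, f in sorted(c.mismatch_spectrum.items())
                ),
                "confidence_phred": f"{c.confidence_phred:.4g}",
                "coverage": c.coverage,
                "suppressed": int(c.suppressed_by_artifact_filter),
                "candidate_identities": "|".join(c.candidate_identities),
                "novelty": c.novelty or "",
            }
        )
    return pd.DataFrame(rows)


def _evidence_class(c: ModificationCall) -> str:
    if c.evidence_rta and c.evidence_mismatch:
        return "rta+mismatch"
    return "rta" if c.evidence_rta else "mismatch"


def write_calls(calls: list[ModificationCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def write_bed(calls: list[ModificationCall], path) -> None:
    """BED6 on cluster references: 0-based half-open, score = round(100*intensity)."""
    with open(path, "w") as fh:
        for c in sorted(calls, key=lambda x: x.key):
            if c.suppressed_by_artifact_filter:
                continue
            score = round(100 * (c.rta_intensity or 0.0))
            name = "|".join(c.candidate_identities) or _evidence_class(c)
            fh.write(
                f"{c.cluster_id}\t{c.position - 1}\t{c.position}\t{name}\t{score}\t+\n"
            )
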