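"""Aggregation of modification signals across developmental time points.

Given per-sample profiles and classified calls, this module produces:

* a per-standard-position RTa distribution — arrest stops summed over all
  qualifying tRNA clusters and normalised by their summed coverage, per
  sample (a coverage-weighted mean, so deeply sequenced clusters contribute
  proportionally to their reads);
* a presence/absence matrix — how many clusters carry an emitted call at
  each (standard position, reference base) per sample;
* per-cluster grids of intensity and evidence class, ordered by isoacceptor
  family and anticodon;
* a per-position Spearman check that arrest intensity is not simply an
  expression artifact (cluster read totals vs cluster arrest intensity).

A cluster "qualifies" for the aggregated distribution at a standard position
when its arrest intensity reaches the call threshold there in *at least one*
sample; the same cluster set is then summed at every time point so values
are comparable across the course.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .calling import ModificationCall
from .profile import ClusterProfile
from .sprinzl import label_sort_key

MIN_CLUSTERS_FOR_CORRELATION = 4


@dataclass
class SampleResult:
    sample_id: str
    time_label: str
    profiles: dict[str, ClusterProfile]
    calls: list[ModificationCall]

    @property
    def read_totals(self) -> dict[str, int]:
        return {cid: p.total_reads for cid, p in self.profiles.items()}


def _label_positions(profiles: dict[str, ClusterProfile]) -> dict[str, dict[str, int]]:
    """cluster_id -> {sprinzl_label -> mature position} (labeled clusters only)."""
    out: dict[str, dict[str, int]] = {}
    for cid, p in profiles.items():
        if p.sprinzl_labels:
            out[cid] = {lab: pos for pos, lab in p.sprinzl_labels.items()}
    return out


def _intensity_at(p: ClusterProfile, pos: int) -> Optional[float]:
    if not 1 <= pos < p.length:
        return None
    cov = int(p.coverage[pos])
    return (int(p.stop_count[pos]) / cov) if cov else None


def qualifying_clusters(
    samples: Sequence[SampleResult],
    min_intensity: float = 0.20,
    min_reads: int = 10,
) -> dict[str, set[str]]:
    """label -> clusters reaching the arrest threshold there in any sample."""
    out: dict[str, set[str]] = {}
    for s in samples:
        for cid, lab2pos in _label_positions(s.profiles).items():
            p = s.profiles[cid]
            for lab, pos in lab2pos.items():
                if not 1 <= pos < p.length:
                    continue
                cov = int(p.coverage[pos])
                if cov < min_reads:
                    continue
                if int(p.stop_count[pos]) / cov >= min_intensity:
                    out.setdefault(lab, set()).add(cid)
    return out


def aggregate_rta_distribution(
    samples: Sequence[SampleResult],
    min_intensity: float = 0.20,
    min_reads: int = 10,
) -> pd.DataFrame:
    """Coverage-weighted arrest intensity per standard position per sample.

    Rows: Sprinzl labels in canonical order; columns: one per sample plus
    ``n_qualifying``.  Labels where no cluster ever reaches the threshold are
    reported as zero.
    """
    qual = qualifying_clusters(samples, min_intensity, min_reads)
    all_labels: set[str] = set()
    for s in samples:
        for lab2pos in _label_positions(s.profiles).values():
            all_labels.update(lab2pos)
    # position 76 has no downstream stop position; drop terminal label
    rows = []
    for lab in sorted(all_labels, key=label_sort_key):
        row: dict[str, object] = {"sprinzl_label": lab,
                                  "n_qualifying": len(qual.get(lab, ()))}
        for s in samples:
            stops = 0
            cov = 0
            for cid in qual.get(lab, ()):
                p = s.profiles.get(cid)
                if p is None or not p.sprinzl_labels:
                    continue
                lab2pos = {l: q for q, l in p.sprinzl_labels.items()}
                pos = lab2pos.get(lab)
                if pos is None or not 1 <= pos < p.length:
                    continue
                stops += int(p.stop_count[pos])
                cov += int(p.coverage[pos])
            row[s.sample_id] = (stops / cov) if cov else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def presence_matrix(samples: Sequence[SampleResult]) -> pd.DataFrame:
    """Counts of clusters with an emitted (unsuppressed) call per label/base/sample."""
    rows: dict[tuple[str, str], dict[str, int]] = {}
    for s in samples:
        for c in s.calls:
            if c.suppressed_by_artifact_filter or c.sprinzl_label is None:
                continue
            key = (c.sprinzl_label, c.ref_base)
            rows.setdefault(key, {})
            rows[key][s.sample_id] = rows[key].get(s.sample_id, 0) + 1
    out = []
    for (lab, base) in sorted(rows, key=lambda k: (label_sort_key(k[0]), k[1])):
        row = {"sprinzl_label": lab, "ref_base": base}
        for s in samples:
            row[s.sample_id] = rows[(lab, base)].get(s.sample_id, 0)
        out.append(row)
    return pd.DataFrame(out)


def expression_rta_correlation(
    samples: Sequence[SampleResult],
    min_intensity: float = 0.20,
    min_reads: int = 10,
    min_clusters: int = MIN_CLUSTERS_FOR_CORRELATION,
) -> pd.DataFrame:
    """Spearman rank correlation of cluster expression vs arrest intensity.

    Per (label, sample): clusters qualifying at that label contribute their
    total read count (expression proxy) and their arrest intensity.  Fewer
    than ``min_clusters`` points -> rho and p reported as NaN (missing).
    """
    qual = qualifying_clusters(samples, min_intensity, min_reads)
    rows = []
    for lab in sorted(qual, key=label_sort_key):
        for s in samples:
            xs, ys = [], []
            for cid in qual[lab]:
                p = s.profiles.get(cid)
                if p is None or not p.sprinzl_labels:
                    continue
                lab2pos = {l: q for q, l in p.sprinzl_labels.items()}
                pos = lab2pos.get(lab)
                if pos is None:
                    continue
                intensity = _intensity_at(p, pos)
                if intensity is None:
                    continue
                xs.append(p.total_reads)
                ys.append(intensity)
            if len(xs) < min_clusters:
                rho, pval = float("nan"), float("nan")
            else:
                rho, pval = spearmanr(xs, ys)
            rows.append(
                {
                    "sprinzl_label": lab,
                    "sample_id": s.sample_id,
                    "n_clusters": len(xs),
                    "spearman_rho": rho,
                    "p_value": pval,
                }
            )
    return pd.DataFrame(rows)


def grid_report(
    sample: SampleResult,
    cluster_meta: Optional[dict[str, tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Per-cluster modification grid for one sample.

    Rows: clusters sorted by isotype then anticodon (``cluster_meta`` maps
    cluster_id -> (isotype, anticodon); parsed from the id when absent).
    Columns: Sprinzl labels.  Cells: "intensity:class" with class one of
    rta+mismatch / mismatch / rta, empty when no call.
    """
    def meta(cid: str) -> tuple[str, str]:
        if cluster_meta and cid in cluster_meta:
            return cluster_meta[cid]
        parts = cid.replace("mt-", "").split("-")
        return (parts[0], parts[1]) if len(parts) >= 2 else (cid, "")

    calls_by_cluster: dict[str, list[ModificationCall]] = {}
    for c in sample.calls:
        if not c.suppressed_by_artifact_filter:
            calls_by_cluster.setdefault(c.cluster_id, []).append(c)

    labels: set[str] = set()
    for c in sample.calls:
        if c.sprinzl_label:
            labels.add(c.sprinzl_label)
    ordered_labels = sorted(labels, key=label_sort_key)

    rows = []
    for cid in sorted(sample.profiles, key=lambda c: (meta(c)[0], meta(c)[1], c)):
        iso, ac = meta(cid)
        row: dict[str, object] = {"cluster_id": cid, "isotype": iso, "anticodon": ac}
        cells = {lab: "" for lab in ordered_labels}
        for c in calls_by_cluster.get(cid, ()):
            if not c.sprinzl_label:
                continue
            if c.evidence_rta and c.evidence_mismatch:
                cls = "rta+mismatch"
            elif c.evidence_mismatch:
                cls = "mismatch"
            else:
                cls = "rta"
            val = c.rta_intensity if c.rta_intensity is not None else 0.0
            cells[c.sprinzl_label] = f"{val:.3f}:{cls}"
        row.update(cells)
        rows.append(row)
    return pd.DataFrame(rows)


def write_timecourse_outputs(
    samples: Sequence[SampleResult],
    out_dir: str | Path,
    min_intensity: float = 0.20,
    min_reads: int = 10,
) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    df = aggregate_rta_distribution(samples, min_intensity, min_reads)
    paths["rta_distribution"] = out_dir / "rta_distribution.tsv"
    df.to_csv(paths["rta_distribution"], sep="\t", index=False)
    pm = presence_matrix(samples)
    paths["presence_matrix"] = out_dir / "presence_matrix.tsv"
    pm.to_csv(paths["presence_matrix"], sep="\t", index=False)
    corr = expression_rta_correlation(samples, min_intensity, min_reads)
    paths["expression_correlation"] = out_dir / "expression_correlation.tsv"
    corr.to_csv(paths["expression_correlation"], sep="\t", index=False)
    for s in samples:
        g = grid_report(s)
        p = out_dir / f"grid_{s.sample_id}.tsv"
        g.to_csv(p, sep="\t", index=False)
        paths[f"grid_{s.sample_id}"] = p
    return paths
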