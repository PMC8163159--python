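"""End-to-end orchestration: cluster -> number -> profile -> call -> classify -> aggregate."""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .calling import call_sites, write_bed, write_calls
from .classify import classify_calls, load_catalogue, load_signature_table
from .config import RunConfig
from .profile import build_profiles, write_profiles
from .reference import cluster_identical, load_genes, write_reference
from .sprinzl import fit_clusters, write_sprinzl_tsv
from .timecourse import SampleResult, write_timecourse_outputs


class PipelineError(RuntimeError):
    pass


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(
    config: RunConfig,
    genes_tsv: str | Path,
    genome_fasta: str | Path,
    sample_alignments: dict[str, str | Path],
    out_dir: str | Path,
    time_labels: Optional[dict[str, str]] = None,
) -> Path:
    """Run every stage over a gene annotation and per-sample alignments.

    ``sample_alignments`` maps sample_id -> SAM/BAM over the mature cluster
    reference (generated here); ``time_labels`` optionally maps sample_id to
    a time-course label (defaults to the sample_id).  Writes all artifacts
    plus a JSON run manifest into ``out_dir`` and returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for p in [genes_tsv, genome_fasta, *sample_alignments.values()]:
        if not Path(p).exists():
            raise PipelineError(f"input file not found: {p}")

    genes = load_genes(genes_tsv, genome_fasta)
    clusters = cluster_identical(genes)
    ref_fa, members_tsv = write_reference(clusters, out_dir / "reference")

    maps = fit_clusters(clusters)
    write_sprinzl_tsv(maps, out_dir / "sprinzl.tsv")
    fitted = {cid: m for cid, m in maps.items() if m.fit_ok}

    rules = load_signature_table()
    catalogue = load_catalogue()

    samples = []
    for sample_id in sorted(sample_alignments):
        aln = sample_alignments[sample_id]
        profiles = build_profiles(aln, ref_fa, sprinzl_maps=fitted)
        write_profiles(profiles, out_dir / f"profiles_{sample_id}.tsv")
        calls = call_sites(
            profiles,
            min_intensity=config.min_intensity,
            min_reads=config.min_reads,
            min_conf_phred=config.min_conf_phred,
            error_rate=config.error_rate,
            tgirt_window=config.tgirt_window,
        )
        calls = classify_calls(
            calls, rules, catalogue, weak_strong=config.weak_strong_boundary
        )
        write_calls(calls, out_dir / f"calls_{sample_id}.tsv")
        write_bed(calls, out_dir / f"calls_{sample_id}.bed")
        label = (time_labels or {}).get(sample_id, sample_id)
        samples.append(
            SampleResult(sample_id=sample_id, time_label=label,
                         profiles=profiles, calls=calls)
        )

    write_timecourse_outputs(
        samples, out_dir, min_intensity=config.min_intensity,
        min_reads=config.min_reads,
    )

    manifest = {
        "tool": "rtamod",
        "version": __version__,
        "python": platform.python_version(),
        "config": config.digest(),
        "inputs": {
            str(p): _checksum(Path(p))
            for p in [genes_tsv, genome_fasta, *sample_alignments.values()]
        },
        "outputs": {
            p.name: _checksum(p)
            for p in sorted(out_dir.iterdir())
            if p.is_file() and p.suffix in {".tsv", ".fa", ".bed"}
        },
        "n_genes": len(genes),
        "n_clusters": len(clusters),
        "n_unfittable": sum(1 for m in maps.values() if not m.fit_ok),
    }
    manifest_path = out_dir / "run_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest_path
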