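"""Pileup profiles: counting oracle on hand-built SAM, arrest-fraction identities."""

import numpy as np
import pysam
import pytest

from rtamod.profile import (
    ProfileError,
    build_profiles,
    frame_to_profiles,
    profiles_to_frame,
    read_profiles,
    readthrough_fraction,
    rta_intensity,
    write_profiles,
)
from rtamod.reference import write_reference
from rtamod.simulate import SimConfig, plant_sites, simulate_reads

REF = "GGGGCCCCAAAATTTTGGGGCCCCAAAATTTTGGGGCCCCAAAATTTTGGGGCCCCAAAACCA"  # 63 nt


def write_sam(path, records, ref_name="clu1", ref_len=len(REF)):
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": ref_name, "LN": ref_len}]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for i, (start, seq, cigar, extra) in enumerate(records):
            a = pysam.AlignedSegment()
            a.query_name = f"r{i}"
            a.query_sequence = seq
            a.flag = extra.get("flag", 0)
            a.reference_id = 0
            a.reference_start = start  # 0-based
            a.mapping_quality = 60
            a.cigarstring = cigar
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            for tag, val in extra.get("tags", []):
                a.set_tag(tag, val)
            fh.write(a)


@pytest.fixture()
def ref_fasta(tmp_path):
    p = tmp_path / "ref.fa"
    p.write_text(f">clu1\n{REF}\n")
    return p


def test_full_length_reads_counting(tmp_path, ref_fasta):
    sam = tmp_path / "a.sam"
    write_sam(sam, [(0, REF, f"{len(REF)}M", {}) for _ in range(10)])
    prof = build_profiles(sam, ref_fasta)["clu1"]
    assert (prof.coverage == 10).all()
    assert prof.stop_count[0] == 10
    assert (prof.stop_count[1:] == 0).all()
    assert prof.total_reads == 10
    # no mismatches anywhere
    assert all(prof.mismatch_count(i) == 0 for i in range(1, len(REF) + 1))


def test_truncated_reads_stop_and_coverage(tmp_path, ref_fasta):
    """6 full-length + 4 reads with 5' end at position 59 (0-based start 58)."""
    recs = [(0, REF, f"{len(REF)}M", {}) for _ in range(6)]
    recs += [(58, REF[58:], f"{len(REF) - 58}M", {}) for _ in range(4)]
    sam = tmp_path / "b.sam"
    write_sam(sam, recs)
    prof = build_profiles(sam, ref_fasta)["clu1"]
    assert prof.stop_count[58] == 4  # position 59
    assert prof.coverage[57] == 6  # position 58
    assert prof.coverage[58] == 10  # position 59
    # arrest evidence for position 58: stops(59)/cov(59)
    assert rta_intensity(prof, 58) == pytest.approx(0.4)


def test_empty_sam(tmp_path, ref_fasta):
    sam = tmp_path / "c.sam"
    write_sam(sam, [])
    prof = build_profiles(sam, ref_fasta)["clu1"]
    assert prof.total_reads == 0
    assert prof.coverage.sum() == 0


def test_multimappers_secondary_softclips(tmp_path, ref_fasta):
    recs = [
        (0, REF, f"{len(REF)}M", {}),
        (0, REF, f"{len(REF)}M", {"tags": [("NH", 2)]}),  # multi-mapped: dropped
        (0, REF, f"{len(REF)}M", {"flag": 256}),  # secondary: dropped
        (14, "TTTT" + REF[14:], f"4S{len(REF) - 14}M", {}),  # clip ignored
    ]
    sam = tmp_path / "d.sam"
    write_sam(sam, recs)
    prof = build_profiles(sam, ref_fasta)["clu1"]
    assert prof.total_reads == 2
    assert prof.coverage[0] == 1  # only the full-length read covers pos 1
    assert prof.stop_count[14] == 1  # soft-clipped read stops at first aligned base
    assert prof.coverage[13] == 1 and prof.coverage[14] == 2


def test_deletions_count_coverage_not_bases(tmp_path, ref_fasta):
    seq = REF[:10] + REF[12:]
    sam = tmp_path / "e.sam"
    write_sam(sam, [(0, seq, "10M2D51M", {})])
    prof = build_profiles(sam, ref_fasta)["clu1"]
    assert prof.coverage[10] == 1 and prof.coverage[11] == 1
    assert prof.base_counts[10, 4] == 1  # deletion category
    assert prof.mismatch_count(11) == 0
    # conservation: base calls + deletions == coverage at every position
    assert (prof.base_counts.sum(axis=1) == prof.coverage).all()


def test_reference_name_mismatch_raises(tmp_path, ref_fasta):
    sam = tmp_path / "f.sam"
    write_sam(sam, [], ref_name="unknown_cluster")
    with pytest.raises(ProfileError, match="unknown_cluster"):
        build_profiles(sam, ref_fasta)


def test_rta_identities_on_anchored_simulation(tmp_path, small_sim, rng):
    """On 3'-anchored reads: coverage non-decreasing toward 3', stop sums conserve
    reads, and stop fraction == 1 - cov(n)/cov(n+1)."""
    cfg, _, clusters = small_sim
    fa, _ = write_reference(clusters, tmp_path / "ref")
    sites = plant_sites(clusters, rng)
    arts = simulate_reads(clusters, sites, cfg, tmp_path, "s1")
    profiles = build_profiles(arts["sam"], fa)
    total = sum(p.total_reads for p in profiles.values())
    assert total == arts["n_reads"]
    for p in profiles.values():
        assert int(p.stop_count.sum()) == p.total_reads
        assert (np.diff(p.coverage) >= 0).all()  # non-increasing toward 5'
        for n in range(1, p.length):
            intensity = rta_intensity(p, n)
            if intensity is None:
                continue
            assert 0.0 <= intensity <= 1.0
            rt = readthrough_fraction(p, n)
            assert intensity == pytest.approx(1.0 - rt, abs=1e-12)


def test_intensity_matches_planted_stop_probability(tmp_path, small_sim):
    """Binomial sampling oracle: planted stop 0.5, 1000 reads, within 3 SE."""
    cfg, _, clusters = small_sim
    c = clusters[0]
    fa, _ = write_reference([c], tmp_path / "ref")
    from rtamod.simulate import SimSite

    site = SimSite(c.cluster_id, 40, "sim", stop_prob=0.5)
    cfg2 = SimConfig(seed=77, background_error=0.0)
    arts = simulate_reads([c], [site], cfg2, tmp_path, "s2",
                          depths={c.cluster_id: 1000})
    prof = build_profiles(arts["sam"], fa)[c.cluster_id]
    intensity = rta_intensity(prof, 40)
    se = (0.25 / 1000) ** 0.5
    assert abs(intensity - 0.5) <= 3 * se


def test_profile_table_round_trip(tmp_path, small_sim, rng):
    cfg, _, clusters = small_sim
    fa, _ = write_reference(clusters, tmp_path / "ref")
    sites = plant_sites(clusters, rng)
    arts = simulate_reads(clusters, sites, cfg, tmp_path, "s3")
    profiles = build_profiles(arts["sam"], fa)
    out = tmp_path / "profiles.tsv"
    write_profiles(profiles, out)
    back = read_profiles(out)
    for cid, p in profiles.items():
        q = back[cid]
        assert q.ref_seq == p.ref_seq
        assert (q.coverage == p.coverage).all()
        assert (q.stop_count == p.stop_count).all()
        assert (q.base_counts == p.base_counts).all()


def test_rta_intensity_bounds_and_missing(tmp_path, ref_fasta):
    sam = tmp_path / "g.sam"
    write_sam(sam, [(30, REF[30:], f"{len(REF) - 30}M", {})])
    prof = build_profiles(sam, ref_fasta)["clu1"]
    assert rta_intensity(prof, 10) is None  # no coverage at 11
    with pytest.raises(ProfileError):
        rta_intensity(prof, 0)
    with pytest.raises(ProfileError):
        rta_intensity(prof, len(REF))
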