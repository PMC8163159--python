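"""Site calling: binomial oracle equivalence, threshold sharpness, artifact filter."""

import math
from math import comb

import numpy as np
import pytest

from rtamod.calling import (
    call_mismatch_sites,
    call_rta_sites,
    call_sites,
    merge_evidence,
    mismatch_confidence_phred,
    tgirt_artifact_filter,
)
from rtamod.profile import ClusterProfile

BASES = "ACGT"


def exact_binom_tail(k, n, p):
    """Independent oracle: P(X >= k) by direct enumeration with exact binomials."""
    if k <= 0:
        return 1.0
    return sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


def make_profile(ref, coverage, stops=None, mismatches=None, cluster_id="c1",
                 labels=None):
    """Profile from explicit per-position counts.

    ``mismatches`` maps 1-based position -> {alt_base: count}; those counts are
    taken out of the reference-base tally.
    """
    L = len(ref)
    cov = np.asarray(coverage, dtype=np.int64)
    stop = np.zeros(L, dtype=np.int64) if stops is None else np.asarray(stops, np.int64)
    bases = np.zeros((L, 5), dtype=np.int64)
    for i in range(L):
        bases[i, BASES.index(ref[i])] = cov[i]
    for pos, alts in (mismatches or {}).items():
        for b, n in alts.items():
            bases[pos - 1, BASES.index(b)] += n
            bases[pos - 1, BASES.index(ref[pos - 1])] -= n
    return ClusterProfile(
        cluster_id=cluster_id, ref_seq=ref, coverage=cov, stop_count=stop,
        base_counts=bases, total_reads=int(stop.sum()), sprinzl_labels=labels,
    )


def test_confidence_matches_exact_oracle_all_small_coverages():
    """Call/no-call decisions agree with brute-force binomial tails for cov <= 30."""
    eps = 0.01
    for cov in range(1, 31):
        for k in range(0, cov + 1):
            conf = mismatch_confidence_phred(k, cov, eps)
            p_exact = exact_binom_tail(k, cov, eps)
            conf_exact = min(-10 * math.log10(p_exact), 1000) if p_exact > 0 else 1000
            assert conf == pytest.approx(conf_exact, abs=1e-6)
            ref = "A" * max(cov, 12)
            prof = make_profile("A" * 40, [cov] * 40,
                                mismatches={5: {"G": k}} if k else None)
            calls = call_mismatch_sites({"c1": prof}, min_reads=1, error_rate=eps)
            called = any(c.position == 5 for c in calls)
            assert called == (conf_exact >= 20.0)


@pytest.mark.parametrize(
    "cov,k,expect_called",
    [
        (100, 40, True),  # overwhelming excess
        (9, 9, False),  # below the coverage floor
        (100, 1, False),  # p ~ 0.63 -> confidence ~ 2
    ],
)
def test_mismatch_calling_examples(cov, k, expect_called):
    prof = make_profile("A" * 40, [cov] * 40, mismatches={7: {"T": k}})
    calls = call_mismatch_sites({"c1": prof})
    assert any(c.position == 7 for c in calls) is expect_called


def test_mismatch_call_records_spectrum():
    prof = make_profile("A" * 40, [100] * 40, mismatches={7: {"G": 30, "T": 10}})
    calls = call_mismatch_sites({"c1": prof})
    c = next(c for c in calls if c.position == 7)
    assert c.mismatch_fraction == pytest.approx(0.4)
    assert c.mismatch_spectrum == {"G": 0.3, "T": 0.1}
    assert c.dominant_mismatch == "G"
    assert c.confidence_phred >= 20


def test_rta_threshold_sharp_at_20_percent():
    stops = [0] * 60
    stops[30] = 199  # position 31; cov 1000 -> intensity 0.199
    prof = make_profile("A" * 60, [1000] * 60, stops=stops)
    assert call_rta_sites({"c1": prof}) == []
    stops[30] = 200
    prof = make_profile("A" * 60, [1000] * 60, stops=stops)
    calls = call_rta_sites({"c1": prof})
    assert [c.position for c in calls] == [30]
    assert calls[0].rta_intensity == pytest.approx(0.20)


def test_rta_threshold_sharp_at_coverage_10():
    for cov, expected in [(9, []), (10, [30])]:
        covs = [cov] * 60
        stops = [0] * 60
        stops[30] = max(2, math.ceil(0.2 * cov))
        prof = make_profile("A" * 60, covs, stops=stops)
        assert [c.position for c in call_rta_sites({"c1": prof})] == expected


def test_threshold_boundary_bisection():
    """Bisection over synthetic intensities/coverages localises the operating point."""
    cov = 1000

    def called(k):
        stops = [0] * 60
        stops[30] = k
        prof = make_profile("A" * 60, [cov] * 60, stops=stops)
        return bool(call_rta_sites({"c1": prof}))

    lo, hi = 0, cov  # called(hi) True, called(lo) False
    while hi - lo > 1:
        mid = (lo + hi) // 2
        lo, hi = (mid, hi) if not called(mid) else (lo, mid)
    assert hi / cov == pytest.approx(0.20)

    def called_cov(cov):
        stops = [0] * 60
        stops[30] = cov  # intensity 1.0
        prof = make_profile("A" * 60, [cov] * 60, stops=stops)
        return bool(call_rta_sites({"c1": prof}))

    lo, hi = 0, 100
    while hi - lo > 1:
        mid = (lo + hi) // 2
        lo, hi = (mid, hi) if not called_cov(mid) else (lo, mid)
    assert hi == 10


def test_full_length_reads_produce_no_calls():
    stops = [0] * 60
    stops[0] = 500
    prof = make_profile("A" * 60, [500] * 60, stops=stops)
    assert call_rta_sites({"c1": prof}) == []
    assert call_mismatch_sites({"c1": prof}) == []


def test_tgirt_echo_suppressed():
    """Weaker echo 2 nt 3' of a strong arrest, with sub-threshold mismatches."""
    stops = [0] * 60
    stops[32] = 600  # arrest call at 32 (stops pile at 33), intensity 0.6
    stops[34] = 250  # echo call at 34, intensity 0.25
    prof = make_profile("A" * 60, [1000] * 60, stops=stops,
                        mismatches={34: {"T": 2}})  # 2/1000: far below confidence
    calls = tgirt_artifact_filter(call_rta_sites({"c1": prof}), {"c1": prof})
    by_pos = {c.position: c for c in calls}
    assert not by_pos[32].suppressed_by_artifact_filter
    assert by_pos[34].suppressed_by_artifact_filter


def test_independent_calls_outside_window_not_suppressed():
    stops = [0] * 60
    stops[21] = 600
    stops[31] = 250
    prof = make_profile("A" * 60, [1000] * 60, stops=stops,
                        mismatches={31: {"T": 2}})
    calls = tgirt_artifact_filter(call_rta_sites({"c1": prof}), {"c1": prof})
    assert not any(c.suppressed_by_artifact_filter for c in calls)


def test_stronger_secondary_not_suppressed():
    stops = [0] * 60
    stops[32] = 250
    stops[34] = 600  # 3'-side call is the stronger one
    prof = make_profile("A" * 60, [1000] * 60, stops=stops,
                        mismatches={34: {"T": 2}, 32: {"T": 2}})
    calls = tgirt_artifact_filter(call_rta_sites({"c1": prof}), {"c1": prof})
    assert not any(c.suppressed_by_artifact_filter for c in calls)


def test_merge_evidence_union():
    stops = [0] * 60
    stops[30] = 300  # arrest evidence for position 30
    prof = make_profile("A" * 60, [1000] * 60, stops=stops,
                        mismatches={30: {"G": 400}, 10: {"T": 100}})
    merged = call_sites({"c1": prof})
    by_pos = {c.position: c for c in merged}
    assert by_pos[30].evidence_rta and by_pos[30].evidence_mismatch
    assert by_pos[10].evidence_mismatch and not by_pos[10].evidence_rta
    assert len(merged) == 2


def test_calling_is_deterministic():
    rng = np.random.default_rng(5)
    cov = rng.integers(0, 300, 60)
    stops = (cov * rng.random(60) * 0.4).astype(int)
    prof = make_profile("A" * 60, cov, stops=stops)
    a = call_sites({"c1": prof})
    b = call_sites({"c1": prof})
    assert a == b


def test_planted_site_recovery(tmp_path):
    """Sensitivity >= 0.95 and FDR <= 0.05 over >= 200 planted sites
    (coverage >= 100, stop prob >= 0.3, mismatch fraction >= 0.2, eps = 0.005)."""
    from rtamod.profile import build_profiles
    from rtamod.reference import write_reference
    from rtamod.simulate import SimConfig, plant_sites, simulate_genes, simulate_reads

    cfg = SimConfig(seed=42, n_clusters=60, n_mitochondrial=0, total_genes=60,
                    background_error=0.005)
    _, clusters = simulate_genes(cfg)
    fa, _ = write_reference(clusters, tmp_path / "ref")
    rng = np.random.default_rng(4242)
    sites = plant_sites(clusters, rng, sites_per_cluster=(3, 4),
                        stop_range=(0.3, 0.7), mismatch_range=(0.2, 0.8),
                        min_spacing=8)
    assert len(sites) >= 200
    depths = {c.cluster_id: 600 for c in clusters}
    arts = simulate_reads(clusters, sites, cfg, tmp_path, "rec", depths=depths)
    profiles = build_profiles(arts["sam"], fa)
    # caller stays at its published operating point (assumed error 1%)
    calls = [c for c in call_sites(profiles)
             if not c.suppressed_by_artifact_filter]
    truth = {(s.cluster_id, s.position) for s in sites}
    called = {(c.cluster_id, c.position) for c in calls}
    tp = len(truth & called)
    sensitivity = tp / len(truth)
    fdr = (len(called) - tp) / max(1, len(called))
    assert sensitivity >= 0.95
    assert fdr <= 0.05
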