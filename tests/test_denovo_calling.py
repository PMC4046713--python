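"""De novo variant calling in pools: filter cascade and replicate concordance."""

import dataclasses

import numpy as np
import pytest

from snvpool import (
    CohortConfig,
    DeNovoConfig,
    DepthModel,
    PoolSpec,
    allele_fraction,
    denovo_scan,
    generate_cohort,
    replicate_intersect,
    simulate_experiment,
)
from snvpool.synthetic_cohort import SampleTruth, TruthRecord

from conftest import make_counts, make_site

CFG = DeNovoConfig()


def _counts_at(pos: int, af: float, depth: int = 1000):
    alt = round(af * depth)
    return make_counts(depth - alt, alt, pos=pos)


# ---------------------------------------------------------------------------
# Hand-applied cascade (N=5: expected AF 0.1, window [0.05, 0.2])
# ---------------------------------------------------------------------------

def test_call_inside_window_absent_elsewhere():
    calls = denovo_scan([_counts_at(1, 0.12, depth=200)], 5, CFG, {}, pool_id="p")
    assert len(calls) == 1
    assert calls[0].observed_af == pytest.approx(0.12)
    assert set(calls[0].filters_passed) == {
        "depth", "af_window", "majority_alt", "blacklist", "cross_experiment",
    }


def test_af_above_window_rejected_as_multisample():
    assert denovo_scan([_counts_at(1, 0.30)], 5, CFG, {}, pool_id="p") == []


def test_af_below_window_rejected():
    assert denovo_scan([_counts_at(1, 0.04)], 5, CFG, {}, pool_id="p") == []


def test_window_boundaries_inclusive():
    for af in (0.05, 0.2):
        assert len(denovo_scan([_counts_at(1, af)], 5, CFG, {}, pool_id="p")) == 1


def test_depth_requirement_scales_with_pool_size():
    # 30 per sample in a 5-pool = 150 total reads
    assert denovo_scan([_counts_at(1, 0.12, depth=149)], 5, CFG, {}, pool_id="p") == []
    assert len(denovo_scan([_counts_at(1, 0.12, depth=150)], 5, CFG, {}, pool_id="p")) == 1


def test_cross_experiment_filter():
    pool = [_counts_at(1, 0.12)]
    others = {"unrelated": {make_site(1): _counts_at(1, 0.02)}}
    assert denovo_scan(pool, 5, CFG, others, pool_id="p") == []
    # boundary: AF exactly 1% elsewhere does not filter (rule is > 1%)
    others_at_boundary = {"unrelated": {make_site(1): _counts_at(1, 0.01)}}
    assert len(denovo_scan(pool, 5, CFG, others_at_boundary, pool_id="p")) == 1


def test_cross_experiment_ignores_replicate_and_shallow_data():
    pool = [_counts_at(1, 0.12)]
    # same AF seen in the replicate: exempt
    others = {"p_rep": {make_site(1): _counts_at(1, 0.12)}}
    assert len(denovo_scan(pool, 5, CFG, others, pool_id="p", replicate_id="p_rep")) == 1
    # seen elsewhere, but below the informative-depth cutoff: not evidence
    shallow = {"unrelated": {make_site(1): _counts_at(1, 0.2, depth=20)}}
    assert len(denovo_scan(pool, 5, CFG, shallow, pool_id="p")) == 1


def test_blacklist_filter():
    cfg = dataclasses.replace(CFG, blacklist=frozenset({("1", 1)}))
    assert denovo_scan([_counts_at(1, 0.12)], 5, cfg, {}, pool_id="p") == []


def test_majority_alt_filter():
    # alt is not the dominant non-reference base
    counts = make_counts(820, 80, other=100, pos=1)
    assert denovo_scan([counts], 5, CFG, {}, pool_id="p") == []


def test_pool_of_one_is_a_configuration_error():
    with pytest.raises(ValueError, match="pool"):
        denovo_scan([_counts_at(1, 0.12)], 1, CFG, {}, pool_id="p")


def test_emitted_calls_satisfy_every_filter_post_hoc():
    rng = np.random.default_rng(4)
    pool = [
        make_counts(int(rng.integers(0, 2000)), int(rng.integers(0, 60)), int(rng.integers(0, 10)), pos=i + 1)
        for i in range(500)
    ]
    cfg = dataclasses.replace(CFG, blacklist=frozenset({("1", i) for i in range(0, 500, 7)}))
    stats: dict[str, int] = {}
    calls = denovo_scan(pool, 5, cfg, {}, pool_id="p", stats=stats)
    low, high = cfg.window(5)
    for call in calls:
        counts = next(c for c in pool if c.site == call.site)
        assert counts.depth >= 150
        assert low <= allele_fraction(counts) <= high
        assert counts.alt_count > counts.other_count
        assert call.site.key not in cfg.blacklist
    assert stats["n_called"] == len(calls)
    assert stats["n_sites"] == 500


# ---------------------------------------------------------------------------
# Replicate concordance
# ---------------------------------------------------------------------------

def test_replicate_intersect_marks_shared_sites_high_confidence():
    a = denovo_scan([_counts_at(1, 0.12), _counts_at(2, 0.1)], 5, CFG, {}, pool_id="a")
    b = denovo_scan([_counts_at(1, 0.11)], 5, CFG, {}, pool_id="b")
    merged = replicate_intersect(a, b)
    by_site = {}
    for call in merged:
        by_site.setdefault(call.site.pos, []).append(call)
    assert all(c.high_confidence for c in by_site[1])
    assert all(not c.high_confidence for c in by_site[2])
    # discordant call keeps its provenance
    assert by_site[2][0].pool_id == "a"


def test_replicate_intersect_identical_and_empty_sets():
    a = denovo_scan([_counts_at(1, 0.12)], 5, CFG, {}, pool_id="a")
    merged = replicate_intersect(a, a)
    assert merged and all(c.high_confidence for c in merged)
    assert replicate_intersect([], []) == []


# ---------------------------------------------------------------------------
# End-to-end recovery and germline suppression on simulated pools
# ---------------------------------------------------------------------------

def _planted_cohort(seq_error=0.001, seed=42):
    """5 samples; u1 carries 6 private variants at AF 0.45; shared germline sites."""
    samples = ["u1", "u2", "u3", "u4", "u5"]
    truths = {s: SampleTruth(sample_id=s) for s in samples}
    for i in range(6):  # planted single-sample variants
        truths["u1"].records[make_site(100 + i)] = TruthRecord("somatic", 0.45, 0.0)
    blacklisted = []
    for i in range(4):  # common SNPs: het in two pool members, on the blacklist
        site = make_site(200 + i)
        blacklisted.append(site)
        for s in ("u2", "u3"):
            truths[s].records[site] = TruthRecord("germline", 0.5, 0.5)
    two_member = []
    for i in range(4):  # novel germline: het in two pool members and in an outside sample
        site = make_site(300 + i)
        two_member.append(site)
        for s in ("u4", "u5"):
            truths[s].records[site] = TruthRecord("germline", 0.5, 0.5)
    three_member = []
    for i in range(4):  # germline in three members: pooled AF 0.3, above the window
        site = make_site(400 + i)
        three_member.append(site)
        for s in ("u2", "u3", "u4"):
            truths[s].records[site] = TruthRecord("germline", 0.5, 0.5)
    outside = SampleTruth(sample_id="ref")
    for site in two_member:
        outside.records[site] = TruthRecord("germline", 0.5, 0.5)
    cfg = CohortConfig(n_samples=1, n_somatic=0, n_null=0, n_germline=0, seq_error=seq_error, seed=seed)
    return truths, outside, blacklisted, two_member, three_member, cfg


def test_planted_variants_recovered_and_germline_suppressed():
    truths, outside, blacklisted, two_member, three_member, cfg = _planted_cohort()
    pool = PoolSpec(tuple(truths))
    model = DepthModel(mean_depth=1500, dispersion=0.1)
    all_truths = dict(truths, ref=outside)
    sites = sorted({s for t in all_truths.values() for s in t.records})

    _, ref_counts = simulate_experiment(
        all_truths, PoolSpec.single("ref"), model, cfg, experiment_id="ref", kind="tumor", sites=sites, seed=1
    )
    others = {"ref": {c.site: c for c in ref_counts}}
    dn_cfg = dataclasses.replace(DeNovoConfig(), blacklist=frozenset(s.key for s in blacklisted))

    calls = {}
    for rep, seed in (("a", 2), ("b", 3)):
        _, pool_counts = simulate_experiment(
            all_truths, pool, model, cfg, experiment_id=rep, kind="pool", sites=sites, seed=seed
        )
        calls[rep] = denovo_scan(pool_counts, pool.n, dn_cfg, others, pool_id=rep, replicate_id="ab"[rep == "a"])
    merged = replicate_intersect(calls["a"], calls["b"])
    high_conf = {c.site for c in merged if c.high_confidence}

    planted = {make_site(100 + i) for i in range(6)}
    assert len(high_conf & planted) >= 5  # >= k-1 of k planted variants
    called_sites = {c.site for c in merged}
    assert not called_sites & set(blacklisted)
    assert not called_sites & set(two_member)  # cross-experiment filter removes shared germline
    assert not called_sites & set(three_member)  # pooled AF 0.3 sits above the window
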