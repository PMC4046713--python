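"""Synthetic cohort generator: truth structure, noise model, pool mixing."""

import dataclasses

import numpy as np
import pytest

from snvpool import (
    CohortConfig,
    DepthModel,
    GDNA_DEPTH_MODEL,
    PoolSpec,
    WGA_DEPTH_MODEL,
    generate_cohort,
    gini_index,
    simulate_depths,
    simulate_experiment,
    simulate_site_counts,
    true_pool_af,
)
from snvpool.synthetic_cohort import load_truth_table, write_truth_table

from conftest import make_site

SMALL = CohortConfig(n_samples=3, n_somatic=(227, 50, 10), n_null=(20, 20, 0), seed=7)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def test_somatic_count_by_construction():
    truths = generate_cohort(SMALL)
    assert len(truths[0].sites("somatic")) == 227
    assert len(truths[1].sites("somatic")) == 50
    assert len(truths[2].sites("null")) == 0


def test_same_seed_reproduces_truth_exactly():
    a = generate_cohort(SMALL)
    b = generate_cohort(SMALL)
    assert [t.records for t in a] == [t.records for t in b]


def test_truth_label_invariants():
    for truth in generate_cohort(SMALL):
        for rec in truth.records.values():
            if rec.label == "somatic":
                assert rec.true_af_normal == 0.0
            elif rec.label == "germline":
                assert rec.true_af_normal == 0.5
            else:
                assert rec.true_af_tumor == rec.true_af_normal == 0.0


def test_somatic_sites_private_by_default():
    truths = generate_cohort(SMALL)
    somatic_sets = [set(t.sites("somatic")) for t in truths]
    for i in range(len(somatic_sets)):
        for j in range(i + 1, len(somatic_sets)):
            assert not somatic_sets[i] & somatic_sets[j]


def test_recurrent_option_shares_somatic_sites():
    cfg = dataclasses.replace(SMALL, recurrent_fraction=0.2)
    truths = generate_cohort(cfg)
    shared = set(truths[0].sites("somatic")) & set(truths[1].sites("somatic"))
    assert len(shared) > 0


def test_subclonal_mixture_mean_recovered():
    # Closed-form mixture: mean 0.5*0.2 + 0.5*0.45 = 0.325,
    # var = 0.5*(sd^2+0.2^2) + 0.5*(sd^2+0.45^2) - 0.325^2 = 0.016525
    cfg = dataclasses.replace(SMALL, n_samples=1, n_somatic=227, n_null=0)
    truths = generate_cohort(cfg)
    afs = [truths[0].records[s].true_af_tumor for s in truths[0].sites("somatic")]
    se = np.sqrt(0.016525 / len(afs))
    assert abs(np.mean(afs) - 0.325) < 3 * se


def test_infeasible_loh_fraction_rejected():
    with pytest.raises(ValueError):
        CohortConfig(loh_fraction=1.5)


def test_anchor_sites_are_somatic_with_midrange_af():
    cfg = dataclasses.replace(SMALL, n_anchors=15)
    truth = generate_cohort(cfg)[0]
    anchors = [s for s, r in truth.records.items() if r.anchor]
    assert len(anchors) == 15
    for site in anchors:
        rec = truth.records[site]
        assert rec.label == "somatic"
        assert 0.2 <= rec.true_af_tumor <= 0.8


def test_truth_table_round_trip(tmp_path):
    truths = generate_cohort(SMALL)
    path = tmp_path / "truth.tsv"
    write_truth_table(truths, path)
    loaded = {t.sample_id: t.records for t in load_truth_table(path)}
    for truth in truths:
        for site, rec in truth.records.items():
            got = loaded[truth.sample_id][site]
            assert got.label == rec.label
            assert got.true_af_tumor == pytest.approx(rec.true_af_tumor, abs=1e-6)


# ---------------------------------------------------------------------------
# Pooled allele fractions
# ---------------------------------------------------------------------------

def test_true_pool_af_examples():
    assert true_pool_af(PoolSpec(("a", "b")), [0.4, 0.0]) == pytest.approx(0.2)
    # lowest detectable single-sample variant: AF 0.1 carried by one of ten
    ten = PoolSpec(tuple(f"s{i}" for i in range(10)))
    assert true_pool_af(ten, [0.1] + [0.0] * 9) == pytest.approx(0.01)
    assert true_pool_af(ten, [0.0] * 10) == 0.0
    with pytest.raises(ValueError):
        true_pool_af(ten, [0.1] * 9)


def test_pool_spec_weight_validation():
    with pytest.raises(ValueError):
        PoolSpec(("a", "b"), (0.7, 0.7))
    with pytest.raises(ValueError):
        PoolSpec(("a", "a"))


# ---------------------------------------------------------------------------
# Depth simulation
# ---------------------------------------------------------------------------

def test_zero_dispersion_gives_constant_depth():
    model = DepthModel(mean_depth=1400.4, dispersion=0.0)
    depths = simulate_depths(model, 50, seed=1)
    assert (depths == 1400).all()


def test_depths_deterministic_given_seed():
    a = simulate_depths(GDNA_DEPTH_MODEL, 1000, seed=3)
    b = simulate_depths(GDNA_DEPTH_MODEL, 1000, seed=3)
    assert (a == b).all()


def test_wga_preset_is_more_uneven_than_gdna():
    wga = dataclasses.replace(WGA_DEPTH_MODEL, mean_depth=1400.0)
    g = simulate_depths(GDNA_DEPTH_MODEL, 10_000, seed=11)
    w = simulate_depths(wga, 10_000, seed=11)
    assert gini_index(w) > gini_index(g)


# ---------------------------------------------------------------------------
# Read-count simulation
# ---------------------------------------------------------------------------

def test_noise_free_extremes():
    site = make_site()
    all_alt = simulate_site_counts(site, 1.0, 500, 0.0, seed=1)
    assert all_alt.alt_count == 500 and all_alt.ref_count == 0
    no_alt = simulate_site_counts(site, 0.0, 500, 0.0, seed=1)
    assert no_alt.alt_count == 0 and no_alt.ref_count == 500


def test_counts_conserve_depth(rng):
    site = make_site()
    for _ in range(200):
        depth = int(rng.integers(0, 3000))
        counts = simulate_site_counts(site, float(rng.uniform()), depth, 0.01, rng)
        assert counts.depth == depth


def test_observed_fraction_tracks_truth_at_high_depth(rng):
    # Binomial tail: |obs - 0.5| < 3*sqrt(0.25/10000) with probability ~0.997
    counts = simulate_site_counts(make_site(), 0.5, 10_000, 0.0, rng)
    assert abs(counts.alt_count / 10_000 - 0.5) < 3 * np.sqrt(0.25 / 10_000)


def test_mean_recovery_over_many_sites(rng):
    depth, n = 100, 10_000
    fractions = [
        simulate_site_counts(make_site(), 0.3, depth, 0.0, rng).alt_count / depth for _ in range(n)
    ]
    se = np.sqrt(0.3 * 0.7 / depth / n)
    assert abs(np.mean(fractions) - 0.3) < 3 * se


# ---------------------------------------------------------------------------
# Experiment simulation
# ---------------------------------------------------------------------------

def test_single_sample_experiment_recovers_true_af():
    cfg = dataclasses.replace(SMALL, seq_error=0.0)
    truths = generate_cohort(cfg)
    model = DepthModel(mean_depth=100_000, dispersion=0.0)
    _, counts = simulate_experiment(
        truths, PoolSpec.single(truths[0].sample_id), model, cfg, experiment_id="t", kind="tumor", seed=5
    )
    by_site = {c.site: c for c in counts}
    for site, rec in truths[0].records.items():
        obs = by_site[site].alt_count / by_site[site].depth
        assert abs(obs - rec.true_af_tumor) <= 0.005


def test_pool_linearity_at_extreme_depth():
    cfg = dataclasses.replace(SMALL, seq_error=0.0)
    truths = generate_cohort(cfg)
    pool = PoolSpec(tuple(t.sample_id for t in truths), (0.5, 0.3, 0.2))
    model = DepthModel(mean_depth=100_000, dispersion=0.0)
    _, counts = simulate_experiment(truths, pool, model, cfg, experiment_id="p", seed=9)
    truth_map = {t.sample_id: t for t in truths}
    for c in counts:
        member_afs = [
            truth_map[m].records[c.site].true_af_tumor if c.site in truth_map[m].records else 0.0
            for m in pool.member_ids
        ]
        expected = true_pool_af(pool, member_afs)
        assert abs(c.alt_count / c.depth - expected) <= 0.005


def test_normal_kind_uses_normal_allele_fractions():
    cfg = dataclasses.replace(SMALL, seq_error=0.0)
    truths = generate_cohort(cfg)
    model = DepthModel(mean_depth=10_000, dispersion=0.0)
    _, counts = simulate_experiment(
        truths, PoolSpec.single(truths[0].sample_id), model, cfg, experiment_id="n", kind="normal", seed=2
    )
    by_site = {c.site: c for c in counts}
    for site in truths[0].sites("somatic"):
        assert by_site[site].alt_count == 0  # somatic variants absent from normal tissue


def test_replicates_differ_but_share_truth():
    truths = generate_cohort(SMALL)
    pool = PoolSpec(tuple(t.sample_id for t in truths))
    _, a = simulate_experiment(truths, pool, GDNA_DEPTH_MODEL, SMALL, experiment_id="p", seed=1)
    _, b = simulate_experiment(truths, pool, GDNA_DEPTH_MODEL, SMALL, experiment_id="p_rep", seed=2)
    assert [c.site for c in a] == [c.site for c in b]
    assert any(x != y for x, y in zip(a, b))


def test_unknown_pool_member_rejected():
    truths = generate_cohort(SMALL)
    with pytest.raises(KeyError):
        simulate_experiment(truths, PoolSpec.single("nobody"), GDNA_DEPTH_MODEL, SMALL, experiment_id="x")
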