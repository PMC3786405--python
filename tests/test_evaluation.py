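"""Recall scoring, S/N arithmetic, and weight-change summaries."""

import json
import math

import numpy as np
import pytest

import downsel as ds
from downsel.core import Phase, Rule


def test_sn_arithmetic():
    r = ds.RecallResult(10, 9, 1)
    assert r.s_n == pytest.approx(9.0)
    assert r.recall_pct == pytest.approx(90.0)
    r = ds.RecallResult(100, 75, 25, mode="percentages")
    assert r.s_n == pytest.approx(3.0)


def test_sn_infinite_serialises_as_string():
    r = ds.RecallResult(10, 5, 0)
    assert math.isinf(r.s_n)
    payload = r.as_dict()
    assert payload["s_n"] == "inf"
    json.dumps(payload)  # round-trippable


def test_recall_result_validates_counts():
    with pytest.raises(ValueError):
        ds.RecallResult(10, 8, 5)


def test_untrained_sequence_recall_is_zero(procedural_net):
    r = ds.recall_sequence(procedural_net.copy(), 0, [0, 1, 2, 3], [4, 5],
                           seed=1, n_trials=15, noise_p=0.1)
    assert r.recall_pct == 0.0
    assert r.s_n == 0.0


def test_saturated_route_recalls_deterministically(procedural_net):
    """With the trained route at the ceiling and everything else silent, the
    sequence propagates one group per step and is always recalled."""
    net = procedural_net.copy()
    net.ff_w[net.ff_plastic] = 0.0
    net.fb_w[net.fb_plastic] = 0.0
    pre_g = net.group_id[net.ff_pre]
    post_g = net.group_id[net.ff_post]
    for a, b in [(0, 1), (1, 2), (2, 3)]:        # A->B->C->D
        net.ff_w[(pre_g == a) & (post_g == b)] = 0.9
    r = ds.recall_sequence(net, 0, [0, 1, 2, 3], [4, 5], seed=2,
                           n_trials=10, noise_p=0.0)
    assert r.recall_pct == 100.0
    assert r.n_incorrect == 0


def test_spurious_activation_marks_trial_incorrect(procedural_net):
    net = procedural_net.copy()
    net.ff_w[net.ff_plastic] = 0.0
    net.fb_w[net.fb_plastic] = 0.0
    pre_g = net.group_id[net.ff_pre]
    post_g = net.group_id[net.ff_post]
    for a, b in [(0, 1), (1, 2), (2, 3), (0, 4)]:  # plus a strong A->E route
        net.ff_w[(pre_g == a) & (post_g == b)] = 0.9
    r = ds.recall_sequence(net, 0, [0, 1, 2, 3], [4, 5], seed=2,
                           n_trials=10, noise_p=0.0)
    assert r.n_incorrect == 10


def test_recall_never_mutates_weights(procedural_net):
    net = procedural_net.copy()
    ff0, fb0 = net.ff_w.copy(), net.fb_w.copy()
    ds.recall_sequence(net, 0, [0, 1, 2, 3], [4, 5], seed=3, n_trials=5,
                       noise_p=0.3)
    assert np.array_equal(net.ff_w, ff0)
    assert np.array_equal(net.fb_w, fb0)


def test_pair_recall_untrained_and_embedded():
    wiring = ds.WiringParams(k_ff=2, k_fb=1, intra_fanin=0)
    net = ds.build_declarative(seed=0, wiring=wiring)
    r = ds.recall_pairs(net, [(0, 1), (2, 3)], seed=1, n_trials_per_pair=5,
                        noise_p=0.03)
    assert r.recall_pct == 0.0
    # embed one pair bidirectionally: deterministic partner response
    pre_g = net.group_id[net.ff_pre]
    post_g = net.group_id[net.ff_post]
    sel = ((pre_g == 0) & (post_g == 1)) | ((pre_g == 1) & (post_g == 0))
    net.ff_w[sel] = 0.9
    fsel = ((net.group_id[net.fb_pre] == 0) & (net.group_id[net.fb_post] == 1)) | (
        (net.group_id[net.fb_pre] == 1) & (net.group_id[net.fb_post] == 0)
    )
    net.fb_w[fsel & net.fb_plastic] = 0.9
    r = ds.recall_pairs(net, [(0, 1)], seed=1, n_trials_per_pair=6, noise_p=0.0)
    assert r.recall_pct == 100.0


def test_recall_pct_matches_counts(procedural_net):
    r = ds.recall_sequence(procedural_net.copy(), 0, [0, 1, 2, 3], [4, 5],
                           seed=4, n_trials=12, noise_p=0.2)
    assert r.recall_pct == pytest.approx(100.0 * r.n_correct / r.n_trials)
    assert r.n_correct + r.n_incorrect <= r.n_trials


def test_weight_change_stats_identities():
    a = ds.build_procedural(seed=0)
    b = a.copy()
    assert ds.weight_change_stats(a, b) == pytest.approx(0.0)
    b.ff_w[b.ff_plastic] *= 0.5
    ff_only = np.ones(a.ff_pre.size, dtype=bool)
    assert ds.weight_change_stats(a, b, ff_mask=ff_only) == pytest.approx(-50.0)


def test_weight_change_stats_rejects_empty_selection():
    a = ds.build_procedural(seed=0)
    with pytest.raises(ValueError):
        ds.weight_change_stats(a, a.copy(), ff_mask=np.zeros(a.ff_pre.size, bool))


def test_percolation_zero_weights_zero_chains():
    wiring = ds.WiringParams(intra_fanin=0)
    net = ds.build_hierarchy([6, 4, 2], seed=0, wiring=wiring)
    net.ff_w[:] = 0.0
    net.fb_w[:] = 0.0
    sched = ds.SleepSchedule(total_ms=1000, up_noise_p=0.0, down_noise_p=0.0,
                             onset_ms=0)
    td, bu = ds.count_percolations(net, seed=1, n_probes=5, schedule=sched)
    assert (td, bu) == (0, 0)


def test_percolation_requires_three_levels():
    net = ds.build_hierarchy([6, 3], seed=0)
    with pytest.raises(ValueError):
        ds.count_percolations(net, seed=1)


def test_compare_drive_rates_contract():
    net = ds.build_hierarchy([6, 4, 2], seed=0)
    rate = ds.compare_drive_rates(net, "top", seed=1, duration_ms=500)
    assert 0.0 <= rate <= 1.0
    with pytest.raises(ValueError):
        ds.compare_drive_rates(net, "sideways", seed=1)
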