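"""Neuron equations, engine contracts, and engine-vs-scalar equivalence."""

import numpy as np
import pytest

import downsel as ds
from downsel.core import EPS, Phase, Rule, SimState


# ---------------------------------------------------------------------------
# membrane integration and the spike rule
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "ff,fb1,fb2,noise,intra,expected",
    [
        (0.0, 0.0, 0.0, 0.0, 0.0, 0.0),                 # silent network
        (0.1, 1.0, 0.0, 0.0, 0.0, 0.1),                 # below z_th: FB gated out
        (0.3, 1.0, 0.5, 0.0, 0.0, 1.8),                 # gate open: FB added
        (0.0, 1.0, 1.0, 2.0, 0.0, 4.0),                 # noise opens the gate
        (0.0, 0.5, 0.0, 0.1, 0.3, 0.4),                 # intra does not open the gate
    ],
)
def test_integrate_membrane(ff, fb1, fb2, noise, intra, expected):
    v = ds.integrate_membrane(ff, fb1, fb2, noise, intra_drive=intra)
    assert v == pytest.approx(expected)


def test_integrate_membrane_rejects_negative_drive():
    with pytest.raises(ValueError):
        ds.integrate_membrane(-0.1, 0, 0, 0)


def test_fire_threshold_is_strict():
    c = ds.ModelConstants()
    assert ds.fire(0.0) == 0
    assert ds.fire(2 * c.w_max) == 0          # exactly two maximal inputs: not enough
    assert ds.fire(2 * c.w_max + 0.015) == 1  # any extra depolarisation fires
    assert ds.fire(2 * c.w_max - 0.1) == 0


def test_two_noise_inputs_fire_with_local_context():
    """Two coincident noise synapses recruit a neuron embedded in active
    tissue: the noise drive reaches the threshold exactly and one active
    intra-group neighbour supplies the rest."""
    c = ds.ModelConstants()
    v = ds.integrate_membrane(0.0, 0.0, 0.0, 2 * c.w_max, intra_drive=0.015)
    assert ds.fire(v) == 1


# ---------------------------------------------------------------------------
# engine contracts
# ---------------------------------------------------------------------------

def test_silent_network_stays_silent(procedural_net):
    res, _ = ds.run(procedural_net.copy(), [Phase(200, Rule.OFF, 0.0)], rng=1)
    assert res.group_counts.sum() == 0


def test_clamped_neurons_fire_every_step(procedural_net):
    net = procedural_net.copy()
    a = np.flatnonzero(net.group_id == 0)
    res, _ = ds.run(
        net, [Phase(50, Rule.OFF, 0.0, clamp=a, record_raster=True)],
        rng=1, record_raster=True,
    )
    assert (res.raster[:, a] == 1).all()


def test_inhibited_neurons_stay_silent(procedural_net):
    net = procedural_net.copy()
    b = np.flatnonzero(net.group_id == 1)
    res, _ = ds.run(
        net, [Phase(100, Rule.OFF, 0.5, inhibit=b, record_raster=True)],
        rng=1, record_raster=True,
    )
    assert res.raster[:, b].sum() == 0


def test_seed_determinism(procedural_net):
    out = []
    for _ in range(2):
        net = procedural_net.copy()
        res, _ = ds.run(
            net, [Phase(300, Rule.SLEEP_DOWNSELECTION, 0.2, record_raster=True)],
            rng=77, record_raster=True,
        )
        out.append((res.raster.copy(), net.ff_w.copy(), net.fb_w.copy()))
    assert np.array_equal(out[0][0], out[1][0])
    assert np.array_equal(out[0][1], out[1][1])
    assert np.array_equal(out[0][2], out[1][2])


def test_plasticity_off_leaves_weights(procedural_net):
    net = procedural_net.copy()
    ff0, fb0 = net.ff_w.copy(), net.fb_w.copy()
    ds.run(net, [Phase(1000, Rule.OFF, 0.3)], rng=3)
    assert np.array_equal(net.ff_w, ff0)
    assert np.array_equal(net.fb_w, fb0)


def test_weight_bounds_after_mixed_schedule(procedural_net):
    net = procedural_net.copy()
    phases = [
        Phase(400, Rule.WAKE_POTENTIATION, 0.3),
        Phase(400, Rule.SLEEP_DOWNSELECTION, 0.2),
        Phase(400, Rule.WAKE_STDP_DEPRESSION, 0.3),
        Phase(400, Rule.POTENTIATION_IN_SLEEP, 0.2),
    ]
    ds.run(net, phases, rng=5)
    c = net.constants
    for w in (net.ff_w, net.fb_w):
        assert w.min() >= 0.0
        assert w.max() <= c.w_max + 1e-12
    # non-plastic synapses never move
    assert np.array_equal(
        net.fb_w[~net.fb_plastic], procedural_net.fb_w[~procedural_net.fb_plastic]
    )


def test_empty_schedule_is_empty():
    net = ds.build_procedural(seed=0)
    res, _ = ds.run(net, [], rng=1)
    assert res.total_ms == 0


def test_unknown_rule_rejected(procedural_net):
    with pytest.raises(ValueError):
        ds.run(procedural_net.copy(), [Phase(10, rule=7)], rng=0)


def test_clamp_inhibit_conflict_rejected():
    with pytest.raises(ValueError):
        Phase(10, clamp=np.array([1, 2]), inhibit=np.array([2, 3]))


def test_phantom_neurons_echo_their_counterparts(procedural_net):
    net = procedural_net.copy()
    d = net.group_of("D")
    d_neurons = np.flatnonzero((net.group_id == d) & ~net.is_phantom)
    res, _ = ds.run(
        net,
        [Phase(10, Rule.OFF, 0.0, clamp=d_neurons, record_raster=True),
         Phase(5, Rule.OFF, 0.0, record_raster=True)],
        rng=1, record_raster=True,
    )
    ph = np.flatnonzero(net.is_phantom)
    src = net.phantom_src[ph]
    # the phantom copy of a spike train is the train shifted one step
    assert np.array_equal(res.raster[1:, ph], res.raster[:-1, src])


# ---------------------------------------------------------------------------
# engine vs straight-line scalar reimplementation
# ---------------------------------------------------------------------------

def _scalar_membrane(ff, fb1, fb2, noise, z_th, threshold):
    """Independent straight-line statement of the membrane and spike rules."""
    v_pre = ff + noise
    v = v_pre
    if v_pre > z_th + EPS:
        v = v + fb1 + fb2
    a = 1 if v > threshold + EPS else 0
    return v, a


def test_single_neuron_oracle_bitwise():
    c = ds.ModelConstants()
    rng = np.random.default_rng(99)
    for _ in range(1000):
        ff, fb1, fb2 = rng.random(3) * 3
        noise = float(rng.integers(0, 4)) * c.w_max
        v_ref, a_ref = _scalar_membrane(ff, fb1, fb2, noise, c.z_th, c.fire_threshold)
        v = ds.integrate_membrane(ff, fb1, fb2, noise, c)
        assert v == v_ref               # bit-wise, not approx
        assert ds.fire(v, c) == a_ref


def test_engine_matches_reference_network_step():
    """The compiled engine and the naive per-neuron reference produce
    identical spikes and weights under an active plastic regime."""
    net_a = ds.build_procedural(seed=3)
    net_b = ds.build_procedural(seed=3)
    rng = np.random.default_rng(7)
    T = 150
    noise = rng.binomial(3, 0.25, size=(T, net_a.n)).astype(np.uint8)
    clamp = np.flatnonzero(net_a.group_id == 0)[:9]

    state_b = SimState.zeros(net_b.n)
    ras_b = np.zeros((T, net_b.n), np.uint8)
    for t in range(T):
        ras_b[t] = ds.step_network(
            net_b, state_b, noise[t], clamp=clamp, rule=Rule.WAKE_POTENTIATION
        )

    from downsel._kernel import run_segment
    state_a = SimState.zeros(net_a.n)
    counts = np.zeros((T, net_a.n_groups), np.int16)
    ras_a = np.zeros((T, net_a.n), np.uint8)
    c = net_a.constants
    r = ds.PlasticityRates()
    clamp_mask = np.zeros(net_a.n, np.uint8)
    clamp_mask[clamp] = 1
    run_segment(
        T, net_a.n, state_a.spikes_prev, state_a.spikes_prev2, noise,
        clamp_mask, np.zeros(net_a.n, np.uint8),
        net_a.group_id, np.int64(net_a.n_groups), net_a.intra_w,
        net_a.intra_post, net_a.intra_by_pre_ptr, net_a.intra_by_pre_idx,
        net_a.phantom_src, net_a.dom_owner, net_a.neuron_dom_ptr,
        net_a.dom_ff_ptr, net_a.dom_fb_ptr,
        net_a.ff_pre, net_a.ff_w, net_a.ff_plastic,
        net_a.fb_pre, net_a.fb_w, net_a.fb_plastic,
        net_a.ff_by_pre_ptr, net_a.ff_by_pre_idx,
        net_a.fb_by_pre_ptr, net_a.fb_by_pre_idx,
        net_a.ff_post, net_a.fb_post,
        c.w_max, c.z_th, c.fire_threshold, np.int64(c.fb_window),
        np.int64(int(Rule.WAKE_POTENTIATION)),
        r.alpha_ff, r.alpha_fb, r.beta_ff, r.beta_fb,
        r.w_ceil, r.fb_ceil, r.conf_ff, r.conf_fb,
        np.int64(r.fb_coincidence_window), np.int64(r.sustain_steps),
        state_a.run_len, counts, ras_a, True,
    )
    assert np.array_equal(ras_a, ras_b)
    assert np.array_equal(net_a.ff_w, net_b.ff_w)
    assert np.array_equal(net_a.fb_w, net_b.fb_w)


def test_network_json_roundtrip(procedural_net):
    clone = ds.Network.from_json(procedural_net.to_json())
    assert clone.n == procedural_net.n
    assert np.array_equal(clone.ff_pre, procedural_net.ff_pre)
    assert np.array_equal(clone.ff_w, procedural_net.ff_w)
    assert np.array_equal(clone.intra_pre, procedural_net.intra_pre)
    # same dynamics after the round trip
    r1, _ = ds.run(procedural_net.copy(), [Phase(100, Rule.OFF, 0.2)], rng=4)
    r2, _ = ds.run(clone.copy(), [Phase(100, Rule.OFF, 0.2)], rng=4)
    assert np.array_equal(r1.group_counts, r2.group_counts)


def test_spike_record_export(procedural_net):
    net = procedural_net.copy()
    a = np.flatnonzero(net.group_id == 0)[:4]
    res, _ = ds.run(
        net, [Phase(5, Rule.OFF, 0.0, clamp=a, record_raster=True)],
        rng=1, record_raster=True,
    )
    frame = res.spike_frame(net)
    assert set(frame.columns) == {"time_ms", "neuron_id", "group_id"}
    assert len(frame) == 5 * 4  # exactly the clamped spikes
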