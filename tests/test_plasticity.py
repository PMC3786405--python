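"""Potentiation, down-selection, and the control rules."""

import numpy as np
import pytest

import downsel as ds
from downsel.core import Phase, Rule, SimState
from downsel.plasticity import (
    PlasticityConfig,
    apply_rule,
    domain_activity,
    downselect_sleep,
    potentiate_wake,
)


def tiny_net(ff_w=0.1, fb_w=0.1, n_ff=3, n_fb=2):
    """One three-group chain (pre -> post <- fb sources) with one domain."""
    wiring = ds.WiringParams(k_ff=n_ff, k_fb=n_fb, intra_fanin=0,
                             fb_alignment="downstream")
    net = ds.build_procedural(seed=1, wiring=wiring)
    net.ff_w[net.ff_plastic] = ff_w
    net.fb_w[net.fb_plastic] = fb_w
    return net


def spikes_for(net, neurons):
    s = np.zeros(net.n, dtype=np.uint8)
    s[list(neurons)] = 1
    return s


def first_domain_of(net, label_post, label_pre):
    """A domain on a neuron of ``label_post`` whose FF afferent is ``label_pre``."""
    gp = net.group_of(label_post)
    ga = net.group_of(label_pre)
    for d in range(net.dom_owner.size):
        owner = net.dom_owner[d]
        if net.group_id[owner] != gp:
            continue
        lo, hi = net.dom_ff_ptr[d], net.dom_ff_ptr[d + 1]
        if hi > lo and net.group_id[net.ff_pre[lo]] == ga:
            return d
    raise AssertionError("no matching domain")


# ---------------------------------------------------------------------------
# domain activity (count form)
# ---------------------------------------------------------------------------

def test_domain_activity_products():
    net = tiny_net()
    d = first_domain_of(net, "B", "A")
    ff_pres = net.ff_pre[net.dom_ff_ptr[d]: net.dom_ff_ptr[d + 1]]
    fb_pres = net.fb_pre[net.dom_fb_ptr[d]: net.dom_fb_ptr[d + 1]]
    # FF active without FB: product is zero
    assert domain_activity(net, d, spikes_for(net, ff_pres[:2])) == 0
    # one of each
    assert domain_activity(net, d, spikes_for(net, [ff_pres[0], fb_pres[0]])) == 1
    # three FF and two FB active: product six
    s = spikes_for(net, list(ff_pres[:3]) + list(fb_pres[:2]))
    assert domain_activity(net, d, s) == 6


# ---------------------------------------------------------------------------
# wake potentiation
# ---------------------------------------------------------------------------

def _sustained(net, owners):
    rl = np.zeros(net.n, dtype=np.int64)
    rl[list(owners)] = 10
    return rl


def test_potentiation_requires_coincidence_and_burst():
    net = tiny_net()
    cfg = PlasticityConfig(rates=ds.PlasticityRates(sustain_steps=1))
    d = first_domain_of(net, "B", "A")
    owner = net.dom_owner[d]
    ff = slice(net.dom_ff_ptr[d], net.dom_ff_ptr[d + 1])
    fb = slice(net.dom_fb_ptr[d], net.dom_fb_ptr[d + 1])
    pres = list(net.ff_pre[ff]) + list(net.fb_pre[fb])

    # postsynaptic neuron silent: nothing changes anywhere
    w0 = net.ff_w.copy()
    potentiate_wake(net, spikes_for(net, []), spikes_for(net, pres), cfg)
    assert np.array_equal(net.ff_w, w0)

    # FF only (no FB): the gray-box case, no change
    potentiate_wake(net, spikes_for(net, [owner]), spikes_for(net, net.ff_pre[ff]), cfg)
    assert np.array_equal(net.ff_w, w0)

    # matched FF + FB: active synapses gain alpha (0.1 FF, 0.05 FB)
    potentiate_wake(net, spikes_for(net, [owner]), spikes_for(net, pres), cfg)
    assert np.allclose(net.ff_w[ff], 0.2)
    assert np.allclose(net.fb_w[fb], 0.15)


def test_potentiation_gated_by_neuromodulator():
    net = tiny_net()
    cfg = PlasticityConfig(
        rates=ds.PlasticityRates(sustain_steps=1), neuromodulator_high=False
    )
    d = first_domain_of(net, "B", "A")
    owner = net.dom_owner[d]
    pres = list(net.ff_pre[net.dom_ff_ptr[d]: net.dom_ff_ptr[d + 1]])
    pres += list(net.fb_pre[net.dom_fb_ptr[d]: net.dom_fb_ptr[d + 1]])
    w0 = net.ff_w.copy()
    potentiate_wake(net, spikes_for(net, [owner]), spikes_for(net, pres), cfg)
    assert np.array_equal(net.ff_w, w0)


def test_potentiation_requires_sustained_burst():
    net = tiny_net()
    cfg = PlasticityConfig(rates=ds.PlasticityRates(sustain_steps=3))
    d = first_domain_of(net, "B", "A")
    owner = net.dom_owner[d]
    pres = list(net.ff_pre[net.dom_ff_ptr[d]: net.dom_ff_ptr[d + 1]])
    pres += list(net.fb_pre[net.dom_fb_ptr[d]: net.dom_fb_ptr[d + 1]])
    w0 = net.ff_w.copy()
    # an isolated burst (no firing history) does not potentiate
    potentiate_wake(net, spikes_for(net, [owner]), spikes_for(net, pres), cfg,
                    run_len=np.zeros(net.n, dtype=np.int64))
    assert np.array_equal(net.ff_w, w0)
    # a sustained burst does
    potentiate_wake(net, spikes_for(net, [owner]), spikes_for(net, pres), cfg,
                    run_len=_sustained(net, [owner]))
    assert not np.array_equal(net.ff_w, w0)


def test_weights_clip_at_ceiling():
    net = tiny_net(ff_w=0.85)
    cfg = PlasticityConfig(rates=ds.PlasticityRates(sustain_steps=1))
    d = first_domain_of(net, "B", "A")
    owner = net.dom_owner[d]
    ff = slice(net.dom_ff_ptr[d], net.dom_ff_ptr[d + 1])
    pres = list(net.ff_pre[ff]) + list(net.fb_pre[net.dom_fb_ptr[d]: net.dom_fb_ptr[d + 1]])
    for _ in range(5):
        potentiate_wake(net, spikes_for(net, [owner]), spikes_for(net, pres), cfg)
    assert np.allclose(net.ff_w[ff], cfg.rates.w_ceil)


# ---------------------------------------------------------------------------
# sleep down-selection
# ---------------------------------------------------------------------------

def test_downselection_depresses_mismatched_and_protects_matched():
    net = tiny_net(ff_w=0.5, fb_w=0.5)
    cfg = PlasticityConfig(rates=ds.PlasticityRates())
    d = first_domain_of(net, "B", "A")
    owner = net.dom_owner[d]
    ff = slice(net.dom_ff_ptr[d], net.dom_ff_ptr[d + 1])
    fb = slice(net.dom_fb_ptr[d], net.dom_fb_ptr[d + 1])

    # FF active without FB: active synapses lose beta_ff
    downselect_sleep(net, spikes_for(net, [owner]), spikes_for(net, net.ff_pre[ff]), cfg)
    assert np.allclose(net.ff_w[ff], 0.49)

    # matched FF + FB: protected, nothing changes
    w_ff, w_fb = net.ff_w.copy(), net.fb_w.copy()
    both = list(net.ff_pre[ff]) + list(net.fb_pre[fb])
    downselect_sleep(net, spikes_for(net, [owner]), spikes_for(net, both), cfg)
    assert np.array_equal(net.ff_w, w_ff)
    assert np.array_equal(net.fb_w, w_fb)


def test_downselection_floors_at_zero():
    net = tiny_net(ff_w=0.005)
    cfg = PlasticityConfig(rates=ds.PlasticityRates())
    d = first_domain_of(net, "B", "A")
    owner = net.dom_owner[d]
    ff = slice(net.dom_ff_ptr[d], net.dom_ff_ptr[d + 1])
    downselect_sleep(net, spikes_for(net, [owner]), spikes_for(net, net.ff_pre[ff]), cfg)
    assert np.allclose(net.ff_w[ff], 0.0)


def test_stdp_like_wake_rule_depresses_inactive():
    net = tiny_net(ff_w=1.0)
    cfg = PlasticityConfig(rates=ds.PlasticityRates(sustain_steps=1))
    d = first_domain_of(net, "B", "A")
    owner = net.dom_owner[d]
    ff = slice(net.dom_ff_ptr[d], net.dom_ff_ptr[d + 1])
    # all pres inactive while the neuron fires: every synapse loses alpha
    apply_rule(net, Rule.WAKE_STDP_DEPRESSION, spikes_for(net, [owner]),
               spikes_for(net, []), cfg.rates)
    assert np.allclose(net.ff_w[ff], 0.9)
    # silent neuron: no change
    w0 = net.ff_w.copy()
    apply_rule(net, Rule.WAKE_STDP_DEPRESSION, spikes_for(net, []),
               spikes_for(net, []), cfg.rates)
    assert np.array_equal(net.ff_w, w0)


# ---------------------------------------------------------------------------
# monotonicity and locality properties (through the engine)
# ---------------------------------------------------------------------------

def test_wake_weight_sum_monotone_nondecreasing(small_net):
    totals = []
    for _ in range(5):
        ds.run(small_net, [Phase(200, Rule.WAKE_POTENTIATION, 0.25)], rng=8)
        totals.append(small_net.weights().sum())
    assert all(b >= a - 1e-12 for a, b in zip(totals, totals[1:]))


def test_sleep_weight_sum_monotone_nonincreasing(small_net):
    small_net.ff_w[small_net.ff_plastic] = 0.6
    totals = [small_net.weights().sum()]
    for _ in range(5):
        ds.run(small_net, [Phase(200, Rule.SLEEP_DOWNSELECTION, 0.25)], rng=9)
        totals.append(small_net.weights().sum())
    assert all(b <= a + 1e-12 for a, b in zip(totals, totals[1:]))


def test_rule_locality_under_unrelated_spikes():
    """A weight update depends only on the domain's own pre/post spikes:
    permuting activity elsewhere leaves the update unchanged."""
    cfg = PlasticityConfig(rates=ds.PlasticityRates(sustain_steps=1))
    outcomes = []
    for extra_group in ("E", "F"):
        net = tiny_net()
        d = first_domain_of(net, "B", "A")
        owner = net.dom_owner[d]
        ff = slice(net.dom_ff_ptr[d], net.dom_ff_ptr[d + 1])
        pres = list(net.ff_pre[ff])
        pres += list(net.fb_pre[net.dom_fb_ptr[d]: net.dom_fb_ptr[d + 1]])
        unrelated = np.flatnonzero(net.group_id == net.group_of(extra_group))[:5]
        prev = spikes_for(net, pres + list(unrelated))
        potentiate_wake(net, spikes_for(net, [owner]), prev, cfg)
        outcomes.append(net.ff_w[ff].copy())
    assert np.array_equal(outcomes[0], outcomes[1])
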