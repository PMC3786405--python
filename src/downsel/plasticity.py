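"""Synaptic plasticity rules.

Wake is dominated by potentiation: when a neuron fires a strong (sustained)
burst and one of its dendritic domains received coincident feedforward and
feedback input on the previous step, every synapse in that domain that was
active gains a fixed increment (``alpha_ff`` for feedforward, ``alpha_fb``
for feedback), up to the ceiling.  The feedforward side of the coincidence
is weighted (a single stray spike does not look like afferent drive); the
feedback side is a spike count over surviving synapses.

Sleep inverts the logic into *down-selection*: when a neuron bursts but a
domain's input was mismatched (feedforward without feedback confirmation
within the feedback persistence window, or feedback without feedforward),
the active synapses of that domain are depressed by ``beta``; matched
domains are protected and left untouched.  Feedback rates are smaller than
feedforward rates so top-down weights change more slowly than bottom-up
ones, and synapses driven to zero count as eliminated.

Two control variants are provided: running the potentiation rule during sleep
(neuromodulator forced high), and a wake rule that adds depression of synapses
that were inactive when the postsynaptic neuron fired, akin to the depressing
branch of STDP, using the potentiation rates for the depression as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernel import EPS
from .core import ModelConstants, Network, PlasticityRates, Rule

__all__ = [
    "PlasticityConfig",
    "PlasticityRates",
    "Rule",
    "domain_activity",
    "potentiate_wake",
    "downselect_sleep",
    "depress_wake_stdp_like",
    "apply_rule",
]


@dataclass(frozen=True)
class PlasticityConfig:
    """Rates plus the rule selection and the neuromodulator gate."""

    rates: PlasticityRates = PlasticityRates()
    rule: Rule = Rule.WAKE_POTENTIATION
    neuromodulator_high: bool = True

    @property
    def alpha_ff(self) -> float:
        return self.rates.alpha_ff

    @property
    def alpha_fb(self) -> float:
        return self.rates.alpha_fb

    @property
    def beta_ff(self) -> float:
        return self.rates.beta_ff

    @property
    def beta_fb(self) -> float:
        return self.rates.beta_fb


def _domain_drives(
    network: Network,
    spikes_prev: np.ndarray,
    spikes_prev2: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted active drive per domain: feedforward at t-1, feedback over
    its (possibly 2-step) coincidence window."""
    sp = np.asarray(spikes_prev).astype(np.float64)
    nd = network.dom_owner.size
    if nd == 0:
        return np.zeros(0), np.zeros(0)
    fb_on = np.asarray(spikes_prev).astype(bool)
    if spikes_prev2 is not None:
        fb_on = fb_on | np.asarray(spikes_prev2).astype(bool)
    ff_hit = sp[network.ff_pre] * network.ff_w
    fb_hit = fb_on[network.fb_pre] * network.fb_w
    ff_drv = np.add.reduceat(ff_hit, network.dom_ff_ptr[:-1])
    fb_drv = np.add.reduceat(fb_hit, network.dom_fb_ptr[:-1])
    return ff_drv, fb_drv


def _coincident(
    network: Network,
    spikes_prev: np.ndarray,
    rates: PlasticityRates,
    spikes_prev2: np.ndarray | None = None,
    window: bool = False,
) -> np.ndarray:
    """Per-domain flag for the two coincidence tests.

    With ``window=False``: the exact coincidence gating potentiation -- the
    feedforward side must deliver its weighted drive at t-1 and at least one
    feedback synapse must have fired at t-1 (a spike count, so an eroded
    feedback weight can recover through renewed learning).  With
    ``window=True``: the tolerant match protecting a domain from
    down-selection -- feedback is weighted and assessed over its persistence
    window, so synapses eroded below the initial strength lose their vote."""
    if window:
        sp2 = spikes_prev2 if rates.fb_coincidence_window >= 2 else None
        ff_drv, fb_drv = _domain_drives(network, spikes_prev, sp2)
        return (ff_drv >= rates.conf_ff - EPS) & (fb_drv >= rates.conf_fb - EPS)
    ff_drv, _ = _domain_drives(network, spikes_prev)
    sp = np.asarray(spikes_prev).astype(np.int64)
    alive = sp[network.fb_pre] * (network.fb_w > EPS)
    fb_act = np.add.reduceat(alive, network.dom_fb_ptr[:-1])
    return (ff_drv >= rates.conf_ff - EPS) & (fb_act > 0)


def domain_activity(network: Network, domain: int, spikes_prev: np.ndarray) -> int:
    """Coincidence measure of one domain at t-1.

    The product of the number of feedforward synapses whose presynaptic
    neuron spiked and the number of feedback synapses whose presynaptic
    neuron spiked; any value > 0 marks a matched (coincident) domain.
    """
    sp = np.asarray(spikes_prev).astype(np.int64)
    ff = int(sp[network.ff_pre[network.dom_ff_ptr[domain] : network.dom_ff_ptr[domain + 1]]].sum())
    fb = int(sp[network.fb_pre[network.dom_fb_ptr[domain] : network.dom_fb_ptr[domain + 1]]].sum())
    return ff * fb


def _post_fired(network: Network, spikes_now: np.ndarray) -> np.ndarray:
    """Per-domain flag: owner (a real neuron) spiked at t."""
    fired = np.asarray(spikes_now).astype(bool) & ~network.is_phantom
    return fired[network.dom_owner]


def potentiate_wake(
    network: Network,
    spikes_now: np.ndarray,
    spikes_prev: np.ndarray,
    config: PlasticityConfig,
    spikes_prev2: np.ndarray | None = None,
    run_len: np.ndarray | None = None,
) -> None:
    """Apply the wake potentiation rule in place.

    No-op when the global neuromodulator level is low: potentiation is
    enabled only while neuromodulators are high (wake, or the
    potentiation-in-sleep control which forces them high).
    """
    if not config.neuromodulator_high:
        return
    # a strong burst: sustain_steps consecutive spikes including now
    if config.rates.sustain_steps <= 1:
        sustained = np.ones(network.n, dtype=bool)
    elif run_len is None:
        # without history, fall back to the previous step's spikes
        sustained = np.asarray(spikes_prev).astype(bool)
    else:
        sustained = np.asarray(run_len) >= config.rates.sustain_steps - 1
    hot = (
        _post_fired(network, spikes_now)
        & np.asarray(sustained, dtype=bool)[network.dom_owner]
        & _coincident(network, spikes_prev, config.rates, spikes_prev2)
    )
    sp = np.asarray(spikes_prev).astype(bool)
    ff_sel = hot[network.ff_dom] & sp[network.ff_pre] & network.ff_plastic
    fb_sel = hot[network.fb_dom] & sp[network.fb_pre] & network.fb_plastic
    network.ff_w[ff_sel] = np.minimum(
        network.ff_w[ff_sel] + config.alpha_ff, config.rates.w_ceil
    )
    network.fb_w[fb_sel] = np.minimum(
        network.fb_w[fb_sel] + config.alpha_fb, config.rates.fb_ceil
    )


def downselect_sleep(
    network: Network,
    spikes_now: np.ndarray,
    spikes_prev: np.ndarray,
    config: PlasticityConfig,
    spikes_prev2: np.ndarray | None = None,
    run_len: np.ndarray | None = None,
) -> None:
    """Apply the sleep down-selection rule in place.

    Synapses active at t-1 in a *mismatched* domain of a bursting neuron are
    depressed; matched domains are protected entirely.
    """
    mismatched = _post_fired(network, spikes_now) & ~_coincident(
        network, spikes_prev, config.rates, spikes_prev2, window=True
    )
    sp = np.asarray(spikes_prev).astype(bool)
    ff_sel = mismatched[network.ff_dom] & sp[network.ff_pre] & network.ff_plastic
    fb_sel = mismatched[network.fb_dom] & sp[network.fb_pre] & network.fb_plastic
    network.ff_w[ff_sel] = np.maximum(network.ff_w[ff_sel] - config.beta_ff, 0.0)
    network.fb_w[fb_sel] = np.maximum(network.fb_w[fb_sel] - config.beta_fb, 0.0)


def depress_wake_stdp_like(
    network: Network,
    spikes_now: np.ndarray,
    spikes_prev: np.ndarray,
    config: PlasticityConfig,
    spikes_prev2: np.ndarray | None = None,
    run_len: np.ndarray | None = None,
) -> None:
    """Wake renormalisation control: potentiate as in wake, and additionally
    depress every synapse that was inactive when its postsynaptic neuron
    fired, at the potentiation rates."""
    potentiate_wake(network, spikes_now, spikes_prev, config, spikes_prev2, run_len)
    fired = _post_fired(network, spikes_now)
    sp = np.asarray(spikes_prev).astype(bool)
    ff_sel = fired[network.ff_dom] & ~sp[network.ff_pre] & network.ff_plastic
    fb_sel = fired[network.fb_dom] & ~sp[network.fb_pre] & network.fb_plastic
    network.ff_w[ff_sel] = np.maximum(network.ff_w[ff_sel] - config.alpha_ff, 0.0)
    network.fb_w[fb_sel] = np.maximum(network.fb_w[fb_sel] - config.alpha_fb, 0.0)


def _downselect_alt(
    network: Network,
    spikes_now: np.ndarray,
    spikes_prev: np.ndarray,
    config: PlasticityConfig,
    spikes_prev2: np.ndarray | None = None,
    run_len: np.ndarray | None = None,
) -> None:
    """Pilot alternative sleep rule: when a neuron does NOT burst, active
    synapses in its matched (active) domains are depressed."""
    silent = ~np.asarray(spikes_now).astype(bool)[network.dom_owner]
    silent &= ~network.is_phantom[network.dom_owner]
    hot = silent & _coincident(
        network, spikes_prev, config.rates, spikes_prev2, window=True
    )
    sp = np.asarray(spikes_prev).astype(bool)
    ff_sel = hot[network.ff_dom] & sp[network.ff_pre] & network.ff_plastic
    fb_sel = hot[network.fb_dom] & sp[network.fb_pre] & network.fb_plastic
    network.ff_w[ff_sel] = np.maximum(network.ff_w[ff_sel] - config.beta_ff, 0.0)
    network.fb_w[fb_sel] = np.maximum(network.fb_w[fb_sel] - config.beta_fb, 0.0)


def apply_rule(
    network: Network,
    rule: Rule,
    spikes_now: np.ndarray,
    spikes_prev: np.ndarray,
    rates: PlasticityRates = PlasticityRates(),
    spikes_prev2: np.ndarray | None = None,
    run_len: np.ndarray | None = None,
) -> None:
    """Dispatch one plasticity update (the engine's per-step hook)."""
    cfg = PlasticityConfig(rates=rates, rule=rule, neuromodulator_high=True)
    if rule == Rule.OFF:
        return
    if rule in (Rule.WAKE_POTENTIATION, Rule.POTENTIATION_IN_SLEEP):
        potentiate_wake(network, spikes_now, spikes_prev, cfg, spikes_prev2, run_len)
    elif rule == Rule.SLEEP_DOWNSELECTION:
        downselect_sleep(network, spikes_now, spikes_prev, cfg, spikes_prev2, run_len)
    elif rule == Rule.WAKE_STDP_DEPRESSION:
        depress_wake_stdp_like(network, spikes_now, spikes_prev, cfg, spikes_prev2, run_len)
    elif rule == Rule.SLEEP_DOWNSELECTION_ALT:
        _downselect_alt(network, spikes_now, spikes_prev, cfg, spikes_prev2, run_len)
    else:  # pragma: no cover
        raise ValueError(f"unknown rule {rule!r}")
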