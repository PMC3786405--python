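"""Integrate-and-fire neurons, dendritic domains, and the network stepping engine.

The neuron model runs on a 1 ms grid.  Each neuron sums three voltage-independent
drives from the previous step -- plastic feedforward synapses, fixed intra-group
synapses, and external noise synapses -- and, only when that sum reaches the
depolarisation threshold ``z_th``, adds the voltage-dependent feedback drive
integrated over the past two steps.  A spike is emitted when the total membrane
potential reaches twice the weight ceiling, after which the membrane is reset,
so no temporal integration is carried between steps.

Plastic synapses are grouped into *dendritic domains*: per-neuron compartments
holding at least one feedforward and one feedback synapse.  Domains are the unit
over which presynaptic coincidence is detected by the plasticity rules (see
:mod:`downsel.plasticity`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._kernel import EPS, run_segment

__all__ = [
    "ModelConstants",
    "Rule",
    "Network",
    "Phase",
    "SimState",
    "SimResult",
    "integrate_membrane",
    "fire",
    "step_network",
    "run",
]


# ---------------------------------------------------------------------------
# constants and rule codes
# ---------------------------------------------------------------------------

class Rule(IntEnum):
    """Plasticity rule in force during a simulation phase."""

    OFF = 0
    WAKE_POTENTIATION = 1
    SLEEP_DOWNSELECTION = 2
    POTENTIATION_IN_SLEEP = 3      # potentiation rule with neuromodulator forced high
    WAKE_STDP_DEPRESSION = 4       # potentiation plus depression of inactive synapses
    SLEEP_DOWNSELECTION_ALT = 5    # pilot variant: depress active domains of silent neurons


@dataclass(frozen=True)
class ModelConstants:
    """Neuron-model constants.

    All voltages are expressed in units of the weight ceiling ``w_max``:
    the firing threshold is two maximal synapses, and the feedback
    gate ``z_th`` opens at one fifth of a maximal synapse.
    """

    w_max: float = 1.0
    dt_ms: float = 1.0
    fb_window: int = 2            # steps of spike history feeding the FB drive
    noise_per_neuron: int = 3
    group_size: int = 18

    def __post_init__(self) -> None:
        if self.w_max <= 0:
            raise ValueError("w_max must be strictly positive")
        if self.fb_window < 1:
            raise ValueError("fb_window must be >= 1")
        if self.noise_per_neuron < 0 or self.group_size < 1:
            raise ValueError("invalid network size constants")

    @property
    def fire_threshold(self) -> float:
        return 2.0 * self.w_max

    @property
    def z_th(self) -> float:
        return self.w_max / 5.0


# ---------------------------------------------------------------------------
# scalar neuron equations (also the reference path for the engine)
# ---------------------------------------------------------------------------

def integrate_membrane(
    ff_drive: float,
    fb_drive_1: float,
    fb_drive_2: float,
    noise_drive: float,
    constants: ModelConstants = ModelConstants(),
    intra_drive: float = 0.0,
) -> float:
    """Membrane potential of one neuron for one step.

    ``ff_drive`` and ``noise_drive`` are the weighted spike sums of the
    voltage-independent inputs (feedforward at t-1, noise at t); the two
    feedback drives are the weighted spike sums at t-1 and t-2.  Feedback
    is counted only when the *extrinsic* voltage-independent depolarisation
    (feedforward plus noise) reaches ``z_th``.  ``intra_drive`` is the
    fixed local intra-group recurrence: it contributes to the membrane
    potential but, attaching outside the dendritic domains, does not open
    the voltage-dependence gate.
    """
    if ff_drive < 0 or fb_drive_1 < 0 or fb_drive_2 < 0 or noise_drive < 0 or intra_drive < 0:
        raise ValueError("drives must be non-negative (weights and spikes are)")
    v_pre = ff_drive + noise_drive
    v = v_pre + intra_drive
    if v_pre <= constants.z_th + EPS:
        return v
    return v + fb_drive_1 + fb_drive_2


def fire(v: float, constants: ModelConstants = ModelConstants()) -> int:
    """Spike output for a membrane potential.

    The comparison is strict (``V > threshold``): two simultaneously active
    maximal-weight inputs reach the threshold exactly and fire only with any
    further depolarisation -- e.g. two noise synapses plus a single active
    intra-group neighbour.  The strict form keeps isolated noise
    coincidences from igniting quiescent tissue, so spontaneous activity is
    contextual: it concentrates where afferent or local drive is present.
    """
    if not np.isfinite(v):
        raise ValueError("membrane potential must be finite")
    return 1 if v > constants.fire_threshold + EPS else 0


# ---------------------------------------------------------------------------
# network container
# ---------------------------------------------------------------------------

class Network:
    """Neuronal groups plus the inter-group synapse and domain tables.

    Synapses are stored as flat arrays sorted by (owner neuron, domain), so a
    domain is a contiguous slice of the feedforward and feedback arrays.
    Phantom neurons (the echo level that supplies feedback to groups with no
    downstream target) mirror their counterpart's spike one step delayed and
    have no dynamics of their own.
    """

    def __init__(
        self,
        constants: ModelConstants,
        group_id: np.ndarray,
        n_real_groups: int,
        is_phantom: np.ndarray,
        phantom_src: np.ndarray,
        dom_owner: np.ndarray,
        neuron_dom_ptr: np.ndarray,
        dom_ff_ptr: np.ndarray,
        dom_fb_ptr: np.ndarray,
        ff_pre: np.ndarray,
        ff_w: np.ndarray,
        ff_plastic: np.ndarray,
        fb_pre: np.ndarray,
        fb_w: np.ndarray,
        fb_plastic: np.ndarray,
        intra_w: float,
        intra_pre: np.ndarray | None = None,
        intra_post: np.ndarray | None = None,
        group_labels: Sequence[str] | None = None,
        group_level: np.ndarray | None = None,
        ff_group_edges: Sequence[tuple[int, int]] = (),
    ) -> None:
        self.constants = constants
        self.group_id = np.asarray(group_id, dtype=np.int64)
        self.n = int(self.group_id.size)
        self.n_groups = int(self.group_id.max()) + 1 if self.n else 0
        self.n_real_groups = int(n_real_groups)
        self.is_phantom = np.asarray(is_phantom, dtype=bool)
        self.phantom_src = np.asarray(phantom_src, dtype=np.int64)
        self.dom_owner = np.asarray(dom_owner, dtype=np.int64)
        self.neuron_dom_ptr = np.asarray(neuron_dom_ptr, dtype=np.int64)
        self.dom_ff_ptr = np.asarray(dom_ff_ptr, dtype=np.int64)
        self.dom_fb_ptr = np.asarray(dom_fb_ptr, dtype=np.int64)
        self.ff_pre = np.asarray(ff_pre, dtype=np.int64)
        self.ff_w = np.asarray(ff_w, dtype=np.float64)
        self.ff_plastic = np.asarray(ff_plastic, dtype=bool)
        self.fb_pre = np.asarray(fb_pre, dtype=np.int64)
        self.fb_w = np.asarray(fb_w, dtype=np.float64)
        self.fb_plastic = np.asarray(fb_plastic, dtype=bool)
        self.intra_w = float(intra_w)
        self.intra_pre = (
            np.asarray(intra_pre, dtype=np.int64) if intra_pre is not None else np.zeros(0, np.int64)
        )
        self.intra_post = (
            np.asarray(intra_post, dtype=np.int64) if intra_post is not None else np.zeros(0, np.int64)
        )
        self.group_labels = (
            list(group_labels)
            if group_labels is not None
            else [str(g) for g in range(self.n_groups)]
        )
        self.group_level = (
            np.asarray(group_level, dtype=np.int64) if group_level is not None else None
        )
        self.ff_group_edges = [tuple(e) for e in ff_group_edges]
        self._validate()
        self._build_pre_index()

    # -- construction helpers ------------------------------------------------

    def _validate(self) -> None:
        c = self.constants
        nd = self.dom_owner.size
        if self.neuron_dom_ptr.size != self.n + 1:
            raise ValueError("neuron_dom_ptr must have n+1 entries")
        if self.dom_ff_ptr.size != nd + 1 or self.dom_fb_ptr.size != nd + 1:
            raise ValueError("domain pointer arrays inconsistent with domain count")
        if nd and np.diff(self.dom_fb_ptr).min() < 1:
            raise ValueError("every dendritic domain needs at least one FB synapse")
        for w in (self.ff_w, self.fb_w):
            if w.size and (w.min() < 0 or w.max() > c.w_max + 1e-12):
                raise ValueError("synaptic weights must lie in [0, w_max]")

    def _build_pre_index(self) -> None:
        """Index synapses by presynaptic neuron for event-driven drive sums."""
        def by_pre(pre: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            order = np.argsort(pre, kind="stable")
            ptr = np.zeros(self.n + 1, dtype=np.int64)
            np.add.at(ptr, pre + 1, 1)
            np.cumsum(ptr, out=ptr)
            return ptr, order.astype(np.int64)

        self.ff_by_pre_ptr, self.ff_by_pre_idx = by_pre(self.ff_pre)
        self.fb_by_pre_ptr, self.fb_by_pre_idx = by_pre(self.fb_pre)
        self.intra_by_pre_ptr, self.intra_by_pre_idx = by_pre(self.intra_pre)
        # post neuron of each synapse (owner of its domain)
        nd = self.dom_owner.size
        self.ff_dom = np.repeat(np.arange(nd), np.diff(self.dom_ff_ptr)).astype(np.int64)
        self.fb_dom = np.repeat(np.arange(nd), np.diff(self.dom_fb_ptr)).astype(np.int64)
        self.ff_post = self.dom_owner[self.ff_dom] if nd else np.zeros(0, np.int64)
        self.fb_post = self.dom_owner[self.fb_dom] if nd else np.zeros(0, np.int64)

    # -- convenience views ---------------------------------------------------

    @property
    def n_real(self) -> int:
        return int((~self.is_phantom).sum())

    def neurons_of_group(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.group_id == g)

    def group_of(self, label: str) -> int:
        return self.group_labels.index(label)

    def weights(self) -> np.ndarray:
        """Concatenated plastic weights (FF then FB)."""
        return np.concatenate([self.ff_w[self.ff_plastic], self.fb_w[self.fb_plastic]])

    def synapse_table(self) -> pd.DataFrame:
        """Long-format synapse table (kind, pre, post, groups, domain, weight)."""
        frames = []
        for kind, pre, post, dom, w, plastic in (
            ("FF", self.ff_pre, self.ff_post, self.ff_dom, self.ff_w, self.ff_plastic),
            ("FB", self.fb_pre, self.fb_post, self.fb_dom, self.fb_w, self.fb_plastic),
        ):
            frames.append(
                pd.DataFrame(
                    {
                        "kind": kind,
                        "pre": pre,
                        "post": post,
                        "pre_group": self.group_id[pre],
                        "post_group": self.group_id[post],
                        "domain": dom,
                        "weight": w,
                        "plastic": plastic,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def copy(self) -> "Network":
        new = Network.__new__(Network)
        new.__dict__.update(self.__dict__)
        new.ff_w = self.ff_w.copy()
        new.fb_w = self.fb_w.copy()
        return new

    # -- serialization -------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "constants": {
                "w_max": self.constants.w_max,
                "dt_ms": self.constants.dt_ms,
                "fb_window": self.constants.fb_window,
                "noise_per_neuron": self.constants.noise_per_neuron,
                "group_size": self.constants.group_size,
            },
            "n_real_groups": self.n_real_groups,
            "intra_w": self.intra_w,
            "group_labels": self.group_labels,
            "group_level": None if self.group_level is None else self.group_level.tolist(),
            "ff_group_edges": self.ff_group_edges,
        }
        for name in (
            "group_id", "is_phantom", "phantom_src", "dom_owner", "neuron_dom_ptr",
            "dom_ff_ptr", "dom_fb_ptr", "ff_pre", "ff_w", "ff_plastic",
            "fb_pre", "fb_w", "fb_plastic", "intra_pre", "intra_post",
        ):
            arr = getattr(self, name)
            payload[name] = arr.tolist()
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "Network":
        d = json.loads(text)
        return cls(
            constants=ModelConstants(**d["constants"]),
            group_id=np.array(d["group_id"]),
            n_real_groups=d["n_real_groups"],
            is_phantom=np.array(d["is_phantom"], dtype=bool),
            phantom_src=np.array(d["phantom_src"]),
            dom_owner=np.array(d["dom_owner"]),
            neuron_dom_ptr=np.array(d["neuron_dom_ptr"]),
            dom_ff_ptr=np.array(d["dom_ff_ptr"]),
            dom_fb_ptr=np.array(d["dom_fb_ptr"]),
            ff_pre=np.array(d["ff_pre"]),
            ff_w=np.array(d["ff_w"], dtype=float),
            ff_plastic=np.array(d["ff_plastic"], dtype=bool),
            fb_pre=np.array(d["fb_pre"]),
            fb_w=np.array(d["fb_w"], dtype=float),
            fb_plastic=np.array(d["fb_plastic"], dtype=bool),
            intra_w=d["intra_w"],
            intra_pre=np.array(d["intra_pre"], dtype=np.int64),
            intra_post=np.array(d["intra_post"], dtype=np.int64),
            group_labels=d["group_labels"],
            group_level=None if d["group_level"] is None else np.array(d["group_level"]),
            ff_group_edges=[tuple(e) for e in d["ff_group_edges"]],
        )


# ---------------------------------------------------------------------------
# simulation state, phases, and results
# ---------------------------------------------------------------------------

@dataclass
class SimState:
    """Spike history carried between steps/phases.

    ``run_len`` counts each neuron's consecutive spikes up to t-1; it backs
    the strong-burst (sustained firing) requirement of the potentiation rule.
    """

    spikes_prev: np.ndarray
    spikes_prev2: np.ndarray
    run_len: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.run_len is None:
            self.run_len = np.zeros(self.spikes_prev.size, dtype=np.int64)

    @classmethod
    def zeros(cls, n: int) -> "SimState":
        return cls(np.zeros(n, dtype=np.uint8), np.zeros(n, dtype=np.uint8))


@dataclass
class Phase:
    """One homogeneous stretch of simulation.

    ``noise_p`` may be a scalar (all real neurons) or a per-neuron vector;
    clamped neurons emit a spike every step regardless of membrane state,
    inhibited neurons are forced silent after the spike rule.
    """

    duration_ms: int
    rule: Rule = Rule.OFF
    noise_p: float | np.ndarray = 0.0
    clamp: np.ndarray | None = None      # neuron ids
    inhibit: np.ndarray | None = None    # neuron ids
    name: str = ""
    record_raster: bool = False

    def __post_init__(self) -> None:
        if self.duration_ms < 0:
            raise ValueError("phase duration must be non-negative")
        if self.clamp is not None and self.inhibit is not None:
            overlap = np.intersect1d(np.asarray(self.clamp), np.asarray(self.inhibit))
            if overlap.size:
                raise ValueError(
                    f"neurons {overlap.tolist()} both clamped and inhibited"
                )


@dataclass
class SimResult:
    """Raster summaries and per-phase weight snapshots from :func:`run`."""

    group_counts: np.ndarray                 # (T, n_groups) spike counts per step
    phase_slices: list[tuple[str, slice]] = field(default_factory=list)
    raster: np.ndarray | None = None         # (T, n) when requested
    raster_slices: list[tuple[str, slice]] = field(default_factory=list)
    weight_snapshots: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @property
    def total_ms(self) -> int:
        return int(self.group_counts.shape[0])

    def group_fraction(self, group_size: int) -> np.ndarray:
        return self.group_counts / float(group_size)

    def spike_frame(self, network: Network) -> pd.DataFrame:
        """Raster as a (time_ms, neuron_id, group_id) frame; needs record_raster."""
        if self.raster is None:
            raise ValueError("raster was not recorded; set record_raster on phases")
        t, i = np.nonzero(self.raster)
        return pd.DataFrame(
            {"time_ms": t, "neuron_id": i, "group_id": network.group_id[i]}
        )


# ---------------------------------------------------------------------------
# plasticity rate container (kernel-facing; the module-level rules live in
# downsel.plasticity and share these numbers)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlasticityRates:
    """Plasticity rates and the domain-coincidence parameters.

    ``w_ceil`` is the ceiling feedforward potentiation saturates at
    (0.9 w_max, so a single saturated synapse plus one noise input stays
    strictly subthreshold); ``fb_ceil`` caps feedback weights at the
    voltage-gate scale ``z_th``, keeping feedback modulatory -- a fully
    trained loop still needs noise or local drive to fire, so stored
    patterns reactivate stochastically instead of latching on.  ``conf_ff``/``conf_fb`` are the weighted drives a
    domain side must reach to count as receiving a burst: the feedforward
    side needs two fresh synapses' worth at t-1 (stray single spikes do
    not look like afferent drive), the feedback side one initial weight,
    so a single fresh feedback synapse can still bootstrap learning while
    synapses eroded below initial strength lose their vote.  Feedback
    activity is assessed over ``fb_coincidence_window`` steps, mirroring
    the slower membrane timescale of the feedback synapses.
    """

    alpha_ff: float = 0.1
    alpha_fb: float = 0.05
    beta_ff: float = 0.01
    beta_fb: float = 0.005
    w_ceil: float = 0.9
    fb_ceil: float = 0.9
    conf_ff: float = 0.2
    conf_fb: float = 0.1
    fb_coincidence_window: int = 1
    sustain_steps: int = 4

    def __post_init__(self) -> None:
        if min(self.alpha_ff, self.alpha_fb, self.beta_ff, self.beta_fb) <= 0:
            raise ValueError("plasticity rates must be strictly positive")
        if not (self.alpha_fb < self.alpha_ff and self.beta_fb < self.beta_ff):
            raise ValueError("feedback rates must be smaller than feedforward rates")
        if self.w_ceil <= 0 or self.conf_ff < 0 or self.conf_fb < 0:
            raise ValueError("w_ceil must be positive and thresholds non-negative")
        if self.sustain_steps < 1:
            raise ValueError("sustain_steps must be at least 1")


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

def _ids_to_mask(n: int, ids: np.ndarray | None) -> np.ndarray:
    mask = np.zeros(n, dtype=np.uint8)
    if ids is not None and len(ids):
        mask[np.asarray(ids, dtype=np.int64)] = 1
    return mask


def _noise_vector(net: Network, noise_p: float | np.ndarray) -> np.ndarray:
    p = np.broadcast_to(np.asarray(noise_p, dtype=np.float64), (net.n,)).copy()
    p[net.is_phantom] = 0.0
    if p.min() < 0 or p.max() > 1:
        raise ValueError("noise probabilities must lie in [0, 1]")
    return p


def run(
    network: Network,
    phases: Iterable[Phase],
    rng: np.random.Generator | int,
    rates: PlasticityRates = PlasticityRates(),
    state: SimState | None = None,
    record_raster: bool = False,
    snapshot_phases: bool = False,
) -> tuple[SimResult, SimState]:
    """Simulate an ordered schedule of phases, applying plasticity in place.

    Identical (network, phases, seed) triples give bit-identical results.
    The network's weight arrays are modified in place by plastic phases.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    phases = list(phases)
    if state is None:
        state = SimState.zeros(network.n)
    c = network.constants
    total = sum(p.duration_ms for p in phases)
    n_groups = network.n_groups
    counts = np.zeros((total, n_groups), dtype=np.int16)
    want_raster = record_raster or any(p.record_raster for p in phases)
    raster = np.zeros((total, network.n), dtype=np.uint8) if want_raster else None
    result = SimResult(group_counts=counts, raster=raster)

    t0 = 0
    for ph in phases:
        T = int(ph.duration_ms)
        if T == 0:
            result.phase_slices.append((ph.name, slice(t0, t0)))
            continue
        if not isinstance(ph.rule, Rule):
            raise ValueError(f"unknown rule {ph.rule!r}")
        clamp = _ids_to_mask(network.n, ph.clamp)
        inhibit = _ids_to_mask(network.n, ph.inhibit)
        p_vec = _noise_vector(network, ph.noise_p)
        # independent Bernoulli draw per noise synapse per step
        noise_counts = rng.binomial(
            c.noise_per_neuron, p_vec[None, :], size=(T, network.n)
        ).astype(np.uint8)
        rec = raster[t0 : t0 + T] if want_raster else np.zeros((0, 0), dtype=np.uint8)
        run_segment(
            T,
            network.n,
            state.spikes_prev,
            state.spikes_prev2,
            noise_counts,
            clamp,
            inhibit,
            network.group_id,
            np.int64(n_groups),
            network.intra_w,
            network.intra_post,
            network.intra_by_pre_ptr,
            network.intra_by_pre_idx,
            network.phantom_src,
            network.dom_owner,
            network.neuron_dom_ptr,
            network.dom_ff_ptr,
            network.dom_fb_ptr,
            network.ff_pre,
            network.ff_w,
            network.ff_plastic,
            network.fb_pre,
            network.fb_w,
            network.fb_plastic,
            network.ff_by_pre_ptr,
            network.ff_by_pre_idx,
            network.fb_by_pre_ptr,
            network.fb_by_pre_idx,
            network.ff_post,
            network.fb_post,
            c.w_max,
            c.z_th,
            c.fire_threshold,
            np.int64(c.fb_window),
            np.int64(int(ph.rule)),
            rates.alpha_ff,
            rates.alpha_fb,
            rates.beta_ff,
            rates.beta_fb,
            rates.w_ceil,
            rates.fb_ceil,
            rates.conf_ff,
            rates.conf_fb,
            np.int64(rates.fb_coincidence_window),
            np.int64(rates.sustain_steps),
            state.run_len,
            counts[t0 : t0 + T],
            rec,
            want_raster,
        )
        result.phase_slices.append((ph.name, slice(t0, t0 + T)))
        if snapshot_phases:
            result.weight_snapshots[ph.name or f"phase{len(result.phase_slices)}"] = (
                network.ff_w.copy(),
                network.fb_w.copy(),
            )
        t0 += T
    return result, state


# ---------------------------------------------------------------------------
# straight-line reference engine (slow; used as the independent oracle)
# ---------------------------------------------------------------------------

def step_network(
    network: Network,
    state: SimState,
    noise_counts: np.ndarray,
    clamp: np.ndarray | None = None,
    inhibit: np.ndarray | None = None,
    rule: Rule = Rule.OFF,
    rates: PlasticityRates = PlasticityRates(),
) -> np.ndarray:
    """Advance the network one step with plain scalar arithmetic.

    This is a deliberately naive re-statement of the membrane equations and
    plasticity rules used to cross-check the compiled engine; it mutates
    ``state`` (and weights, under a plastic rule) exactly as the engine does.
    """
    from . import plasticity as _pl

    c = network.constants
    n = network.n
    clamp_mask = _ids_to_mask(n, clamp).astype(bool)
    inhibit_mask = _ids_to_mask(n, inhibit).astype(bool)
    s1, s2 = state.spikes_prev, state.spikes_prev2
    intra_in = np.zeros(n)
    for k in range(network.intra_pre.size):
        if s1[network.intra_pre[k]]:
            intra_in[network.intra_post[k]] += network.intra_w
    new = np.zeros(n, dtype=np.uint8)
    for i in range(n):
        if network.is_phantom[i]:
            new[i] = s1[network.phantom_src[i]]
            continue
        ff = 0.0
        fb1 = 0.0
        fb2 = 0.0
        for d in range(network.neuron_dom_ptr[i], network.neuron_dom_ptr[i + 1]):
            for s in range(network.dom_ff_ptr[d], network.dom_ff_ptr[d + 1]):
                ff += network.ff_w[s] * s1[network.ff_pre[s]]
            for s in range(network.dom_fb_ptr[d], network.dom_fb_ptr[d + 1]):
                # each feedback synapse counts once within its window
                if s1[network.fb_pre[s]]:
                    fb1 += network.fb_w[s]
                elif c.fb_window >= 2 and s2[network.fb_pre[s]]:
                    fb2 += network.fb_w[s]
        noise = c.w_max * float(noise_counts[i])
        v = integrate_membrane(ff, fb1, fb2, noise, c, intra_drive=intra_in[i])
        a = fire(v, c)
        if clamp_mask[i]:
            a = 1
        if inhibit_mask[i]:
            a = 0
        new[i] = a
    if rule != Rule.OFF:
        _pl.apply_rule(
            network, rule, new, s1, rates, spikes_prev2=s2, run_len=state.run_len
        )
    state.run_len = np.where(new > 0, state.run_len + 1, 0)
    state.spikes_prev2 = s1
    state.spikes_prev = new
    return new
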