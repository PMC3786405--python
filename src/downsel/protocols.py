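"""Training, sleep, and cuing schedules for the memory experiments.

Wake training presents stimuli by clamping whole neuronal groups in the
active state while the wake potentiation rule runs; simulated sleep drives
the network with alternating high-noise up-states and low-noise down-states
(the slow-oscillation surrogate) under the down-selection rule.  All
schedules are expressed as lists of :class:`downsel.core.Phase` and executed
by the shared engine, so a fixed seed reproduces any protocol exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Network, Phase, PlasticityRates, Rule, SimResult, SimState, run

__all__ = [
    "StimulusEvent",
    "SleepSchedule",
    "WAKE_NOISE_P",
    "train_sequence",
    "train_pairs",
    "wake_with_spurious_pairs",
    "sleep",
    "cue_in_sleep",
    "train_gist",
    "train_integration",
]

#: spontaneous noise-synapse activation probability per ms in wake.  The
#: source model states only that neurons "become spontaneously active" in
#: wake; this default makes isolated noise bursts (two coincident noise
#: inputs) rare enough that training is stimulus-driven.
WAKE_NOISE_P = 0.05


@dataclass(frozen=True)
class StimulusEvent:
    """A stimulus window: target groups driven from ``onset`` for ``duration``."""

    targets: tuple[int, ...]
    onset_ms: int
    duration_ms: int
    drive: str = "CLAMP"           # CLAMP | NOISE_BOOST

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.drive not in ("CLAMP", "NOISE_BOOST"):
            raise ValueError(f"unknown drive {self.drive!r}")


@dataclass(frozen=True)
class SleepSchedule:
    """Slow-oscillation schedule: alternating up/down noise regimes.

    Each up-state opens with a brief high-noise onset modelling the
    near-synchronous down-to-up transition of cortical slow waves; the
    resulting volley ignites whole neuronal groups at once, so stored
    memories replay as synchronous waves along their strong connections.
    """

    total_ms: int = 10_000
    up_ms: int = 500
    up_noise_p: float = 0.20
    down_ms: int = 500
    down_noise_p: float = 0.05
    onset_ms: int = 3
    onset_noise_p: float = 0.80

    def phases(self) -> list[Phase]:
        out: list[Phase] = []
        t = 0
        while t < self.total_ms:
            segs = (
                (self.onset_ms, self.onset_noise_p, "onset"),
                (self.up_ms - self.onset_ms, self.up_noise_p, "up"),
                (self.down_ms, self.down_noise_p, "down"),
            )
            for dur, p, tag in segs:
                d = min(dur, self.total_ms - t)
                if d > 0:
                    out.append(Phase(d, noise_p=p, name=f"sleep-{tag}@{t}"))
                    t += d
        return out


def _group_neurons(network: Network, groups) -> np.ndarray:
    groups = np.atleast_1d(np.asarray(groups, dtype=np.int64))
    return np.flatnonzero(np.isin(network.group_id, groups) & ~network.is_phantom)


# ---------------------------------------------------------------------------
# wake training
# ---------------------------------------------------------------------------

def train_sequence(
    network: Network,
    sequence: list[int],
    spurious: list[list[int]],
    rng: np.random.Generator | int,
    p_correct: float = 0.9,
    total_ms: int = 10_000,
    window_ms: int = 5,
    overlap_ms: int = 2,
    gap_ms: int = 10,
    noise_p: float = WAKE_NOISE_P,
    rates: PlasticityRates = PlasticityRates(),
) -> tuple[SimResult, SimState]:
    """Pairwise sequence training with occasional spurious-route trials.

    The sequence is taught pair by pair (first A=>B, then B=>C, ...), each
    stage taking an equal share of ``total_ms``.  In a trial the leading
    group is clamped for ``window_ms`` and the trailing group joins for the
    final ``overlap_ms`` of that window (so the trailing clamp overlaps the
    arrival of spikes driven by the leading group, which is what the
    coincidence rule needs), after which the network idles for ``gap_ms``.
    With probability ``1 - p_correct`` a trial presents the corresponding
    pair of a randomly chosen spurious sequence instead.
    """
    if not 0.0 <= p_correct <= 1.0:
        raise ValueError("p_correct must lie in [0, 1]")
    if overlap_ms >= window_ms:
        raise ValueError("overlap must be shorter than the window")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_stages = len(sequence) - 1
    stage_ms = total_ms // n_stages
    trial_ms = window_ms + gap_ms
    phases: list[Phase] = []
    used = 0
    for s in range(n_stages):
        n_trials = stage_ms // trial_ms
        for _ in range(n_trials):
            if spurious and rng.random() >= p_correct:
                route = spurious[rng.integers(len(spurious))]
                first, second = route[s], route[s + 1]
            else:
                first, second = sequence[s], sequence[s + 1]
            a = _group_neurons(network, first)
            b = _group_neurons(network, second)
            lead = window_ms - overlap_ms
            phases.append(Phase(lead, Rule.WAKE_POTENTIATION, noise_p, clamp=a))
            both = np.concatenate([a, b])
            phases.append(Phase(overlap_ms, Rule.WAKE_POTENTIATION, noise_p, clamp=both))
            phases.append(Phase(gap_ms, Rule.WAKE_POTENTIATION, noise_p))
            used += trial_ms
    if used < total_ms:  # idle remainder keeps the schedule accounting exact
        phases.append(Phase(total_ms - used, Rule.WAKE_POTENTIATION, noise_p))
    return run(network, phases, rng, rates=rates)


def train_pairs(
    network: Network,
    pairs: list[tuple[int, int]],
    rng: np.random.Generator | int,
    per_pair_ms: int = 2000,
    noise_p: float = WAKE_NOISE_P,
    rates: PlasticityRates = PlasticityRates(),
) -> tuple[SimResult, SimState]:
    """Paired-associate training: each pair co-clamped for ``per_pair_ms``."""
    flat = [g for p in pairs for g in p]
    if len(set(flat)) != len(flat):
        raise ValueError("trained pairs must be disjoint")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    phases: list[Phase] = []
    for k in rng.permutation(len(pairs)):
        members = _group_neurons(network, list(pairs[k]))
        phases.append(
            Phase(
                per_pair_ms,
                Rule.WAKE_POTENTIATION,
                noise_p,
                clamp=members,
                name=f"pair{k}",
            )
        )
        # stimulus offset: brief silencing of the presented groups so the
        # freshly strengthened assembly does not persist into the next block
        phases.append(Phase(2, Rule.WAKE_POTENTIATION, noise_p, inhibit=members))
    return run(network, phases, rng, rates=rates)


def wake_with_spurious_pairs(
    network: Network,
    exclude_pairs: list[tuple[int, int]],
    rng: np.random.Generator | int,
    n_spurious: int = 6,
    assoc_ms: int = 300,
    total_ms: int = 20_000,
    noise_p: float = WAKE_NOISE_P,
    rates: PlasticityRates = PlasticityRates(),
) -> tuple[SimResult, SimState]:
    """Post-training wake: brief random novel associations amid idle wake.

    Mimics interference accrued while awake -- ``n_spurious`` random pairs,
    different from the trained ones, are each co-clamped for ``assoc_ms``,
    evenly spread through ``total_ms`` of wake with potentiation on.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    taken = {frozenset(p) for p in exclude_pairs}
    groups = np.arange(network.n_real_groups)
    novel: list[tuple[int, int]] = []
    while len(novel) < n_spurious:
        a, b = rng.choice(groups, size=2, replace=False)
        if frozenset((int(a), int(b))) not in taken:
            novel.append((int(a), int(b)))
            taken.add(frozenset((int(a), int(b))))
    slot = total_ms // n_spurious
    phases: list[Phase] = []
    for k, pair in enumerate(novel):
        idle = slot - assoc_ms
        phases.append(Phase(idle // 2, Rule.WAKE_POTENTIATION, noise_p))
        members = _group_neurons(network, list(pair))
        phases.append(
            Phase(
                assoc_ms,
                Rule.WAKE_POTENTIATION,
                noise_p,
                clamp=members,
                name=f"spurious{k}",
            )
        )
        phases.append(Phase(2, Rule.WAKE_POTENTIATION, noise_p, inhibit=members))
        phases.append(Phase(idle - idle // 2 - 2, Rule.WAKE_POTENTIATION, noise_p))
    rest = total_ms - slot * n_spurious
    if rest:
        phases.append(Phase(rest, Rule.WAKE_POTENTIATION, noise_p))
    return run(network, phases, rng, rates=rates)


# ---------------------------------------------------------------------------
# sleep
# ---------------------------------------------------------------------------

def sleep(
    network: Network,
    schedule: SleepSchedule,
    rng: np.random.Generator | int,
    rule: Rule = Rule.SLEEP_DOWNSELECTION,
    rates: PlasticityRates = PlasticityRates(),
    record_raster: bool = False,
) -> tuple[SimResult, SimState]:
    """Simulated slow-wave sleep under down-selection (or a control rule)."""
    if rule not in (
        Rule.SLEEP_DOWNSELECTION,
        Rule.POTENTIATION_IN_SLEEP,
        Rule.SLEEP_DOWNSELECTION_ALT,
        Rule.OFF,
    ):
        raise ValueError(f"rule {rule!r} is not a sleep rule")
    phases = [
        Phase(p.duration_ms, rule, p.noise_p, name=p.name) for p in schedule.phases()
    ]
    return run(network, phases, rng, rates=rates, record_raster=record_raster)


def cue_in_sleep(
    network: Network,
    cued_pairs: list[tuple[int, int]],
    schedule: SleepSchedule,
    rng: np.random.Generator | int,
    reps: int = 3,
    cue_ms: int = 500,
    cue_noise_p: float = 0.60,
    rule: Rule = Rule.SLEEP_DOWNSELECTION,
    rates: PlasticityRates = PlasticityRates(),
) -> tuple[SimResult, SimState]:
    """Sleep during which selected pairs are externally cued.

    Each cued pair is presented ``reps`` times (one pair at a time) for
    ``cue_ms`` by raising the noise activation probability of its two groups
    to ``cue_noise_p``; plasticity stays governed by down-selection.  Cue
    windows are spread evenly through the night in a seed-shuffled order.
    """
    n_cues = reps * len(cued_pairs)
    if n_cues * cue_ms > schedule.total_ms:
        raise ValueError("cue windows exceed the total sleep time")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    order = rng.permutation(np.repeat(np.arange(len(cued_pairs)), reps))
    slot = schedule.total_ms // n_cues if n_cues else schedule.total_ms
    # per-ms base noise level from the up/down alternation
    base = np.empty(schedule.total_ms)
    for ph in schedule.phases():
        t0 = int(ph.name.split("@")[1])
        base[t0 : t0 + ph.duration_ms] = ph.noise_p
    boost = np.zeros(schedule.total_ms, dtype=np.int64) - 1
    for k, pair_idx in enumerate(order):
        start = k * slot + (slot - cue_ms) // 2
        boost[start : start + cue_ms] = pair_idx
    # compress into phases with constant (noise level, cued pair)
    phases: list[Phase] = []
    t = 0
    while t < schedule.total_ms:
        t1 = t + 1
        while (
            t1 < schedule.total_ms
            and base[t1] == base[t]
            and boost[t1] == boost[t]
        ):
            t1 += 1
        p_vec: float | np.ndarray = float(base[t])
        if boost[t] >= 0:
            p_vec = np.full(network.n, float(base[t]))
            cued = _group_neurons(network, list(cued_pairs[int(boost[t])]))
            p_vec[cued] = cue_noise_p
        phases.append(Phase(t1 - t, rule, p_vec))
        t = t1
    return run(network, phases, rng, rates=rates)


# ---------------------------------------------------------------------------
# hierarchy protocols
# ---------------------------------------------------------------------------

def train_gist(
    network: Network,
    stimuli: list[list[int]],
    rng: np.random.Generator | int,
    per_stim_ms: int = 500,
    reps: int = 4,
    noise_p: float = WAKE_NOISE_P,
    rates: PlasticityRates = PlasticityRates(),
) -> tuple[SimResult, SimState]:
    """Present overlapping stimuli (sets of level-1 groups) in random order."""
    if network.group_level is None:
        raise ValueError("gist training requires a levelled hierarchy")
    for stim in stimuli:
        if any(network.group_level[g] != 0 for g in stim):
            raise ValueError("stimuli must address level-1 groups only")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    order = rng.permutation(np.repeat(np.arange(len(stimuli)), reps))
    phases: list[Phase] = []
    for s in order:
        members = _group_neurons(network, stimuli[int(s)])
        phases.append(
            Phase(
                per_stim_ms,
                Rule.WAKE_POTENTIATION,
                noise_p,
                clamp=members,
                name=f"stim{int(s)}",
            )
        )
        phases.append(Phase(2, Rule.WAKE_POTENTIATION, noise_p, inhibit=members))
    return run(network, phases, rng, rates=rates)


def train_integration(
    network: Network,
    new_stimulus: list[int],
    inhibited_groups: list[int],
    rng: np.random.Generator | int,
    total_ms: int = 10_000,
    rule: Rule = Rule.WAKE_POTENTIATION,
    noise_p: float = WAKE_NOISE_P,
    rates: PlasticityRates = PlasticityRates(),
) -> tuple[SimResult, SimState]:
    """Acquire a new memory while most higher-level groups are silenced.

    The new stimulus is clamped onto its level-1 groups; ``inhibited_groups``
    are forced inactive every step (the stand-in for intra-cortical
    inhibition/competition).  ``rule`` may be the wake potentiation rule or
    the STDP-like wake-renormalisation control.
    """
    if set(new_stimulus) & set(inhibited_groups):
        raise ValueError("stimulus groups cannot also be inhibited")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    phases = [
        Phase(
            total_ms,
            rule,
            noise_p,
            clamp=_group_neurons(network, new_stimulus),
            inhibit=_group_neurons(network, inhibited_groups),
            name="integration-wake",
        )
    ]
    return run(network, phases, rng, rates=rates)
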