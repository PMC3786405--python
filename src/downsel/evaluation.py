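"""Recall testing, signal-to-noise statistics, and weight-change summaries.

Recall is probed with plasticity hard-off.  A neuronal group counts as
*activated* when at least half of its neurons fire in the same 1 ms step.
For sequences, a trial clamps the start group briefly and is correct when
the downstream groups each reach criterion, in order, within the window; it
is incorrect when a spurious group reaches criterion at any time in the
window (even if the sequence also completes).  For paired associates, one
group of a pair is stimulated and the partner must reach criterion within a
short window, with any third group reaching criterion marking the trial
incorrect.  S/N is the ratio of correct to incorrect recalls (counts for
sequences, percentages for pairs); with no incorrect recalls it is infinite
and serialised as the string ``"inf"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Network, Phase, Rule, SimState, run
from .protocols import WAKE_NOISE_P, SleepSchedule, _group_neurons

__all__ = [
    "RecallResult",
    "recall_sequence",
    "recall_pairs",
    "count_percolations",
    "compare_drive_rates",
    "weight_change_stats",
]


@dataclass(frozen=True)
class RecallResult:
    """Counts of correct/incorrect recalls and the derived S/N statistic."""

    n_trials: int
    n_correct: int
    n_incorrect: int
    mode: str = "counts"           # counts (sequences) | percentages (pairs)

    def __post_init__(self) -> None:
        if self.n_correct + self.n_incorrect > self.n_trials:
            raise ValueError("correct + incorrect cannot exceed the trial count")

    @property
    def recall_pct(self) -> float:
        return 100.0 * self.n_correct / self.n_trials if self.n_trials else 0.0

    @property
    def incorrect_pct(self) -> float:
        return 100.0 * self.n_incorrect / self.n_trials if self.n_trials else 0.0

    @property
    def s_n(self) -> float:
        if self.n_correct == 0:
            return 0.0
        if self.n_incorrect == 0:
            return math.inf
        # counts and percentages share a denominator, so the ratio coincides;
        # the distinction is kept for reporting fidelity
        return self.n_correct / self.n_incorrect

    def as_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "n_correct": self.n_correct,
            "n_incorrect": self.n_incorrect,
            "recall_pct": self.recall_pct,
            "s_n": "inf" if math.isinf(self.s_n) else self.s_n,
        }


def _first_criterion_step(frac: np.ndarray, criterion: float) -> int:
    """First step at which a per-step activation fraction reaches criterion."""
    hits = np.flatnonzero(frac >= criterion)
    return int(hits[0]) if hits.size else -1


def recall_sequence(
    network: Network,
    start_group: int,
    target_sequence: list[int],
    spurious_groups: list[int],
    seed: int | np.random.Generator,
    n_trials: int = 100,
    clamp_ms: int = 25,
    window_ms: int = 500,
    criterion: float = 0.5,
    noise_p: float = WAKE_NOISE_P,
) -> RecallResult:
    """Probe sequence recall by clamping the start group.

    A trial is correct when every group of ``target_sequence`` (excluding the
    start group) first reaches the criterion in strictly increasing temporal
    order within the window, and no spurious group ever reaches criterion.
    """
    if window_ms < clamp_ms:
        raise ValueError("the recall window cannot be shorter than the clamp")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    gs = network.constants.group_size
    targets = [g for g in target_sequence if g != start_group]
    clamp = _group_neurons(network, start_group)
    n_correct = n_incorrect = 0
    for _ in range(n_trials):
        phases = [
            Phase(clamp_ms, Rule.OFF, noise_p, clamp=clamp),
            Phase(window_ms - clamp_ms, Rule.OFF, noise_p),
        ]
        res, _ = run(network, phases, rng, state=SimState.zeros(network.n))
        frac = res.group_counts / gs
        bad = any(
            _first_criterion_step(frac[:, g], criterion) >= 0 for g in spurious_groups
        )
        times = [_first_criterion_step(frac[:, g], criterion) for g in targets]
        good = all(t >= 0 for t in times) and all(
            a < b for a, b in zip(times, times[1:])
        )
        if bad:
            n_incorrect += 1
        elif good:
            n_correct += 1
    return RecallResult(n_trials, n_correct, n_incorrect, mode="counts")


def recall_pairs(
    network: Network,
    pairs: list[tuple[int, int]],
    seed: int | np.random.Generator,
    n_trials_per_pair: int = 12,
    window_ms: int = 50,
    criterion: float = 0.5,
    noise_p: float = WAKE_NOISE_P,
) -> RecallResult:
    """Probe paired-associate recall, alternating the stimulated member."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    gs = network.constants.group_size
    n_correct = n_incorrect = n_trials = 0
    for a, b in pairs:
        for k in range(n_trials_per_pair):
            probe, partner = (a, b) if k % 2 == 0 else (b, a)
            clamp = _group_neurons(network, probe)
            res, _ = run(
                network,
                [Phase(window_ms, Rule.OFF, noise_p, clamp=clamp)],
                rng,
                state=SimState.zeros(network.n),
            )
            frac = res.group_counts / gs
            others = [
                g
                for g in range(network.n_real_groups)
                if g not in (probe, partner)
            ]
            bad = any(
                _first_criterion_step(frac[:, g], criterion) >= 0 for g in others
            )
            good = _first_criterion_step(frac[:, partner], criterion) >= 0
            n_trials += 1
            if bad:
                n_incorrect += 1
            elif good:
                n_correct += 1
    return RecallResult(n_trials, n_correct, n_incorrect, mode="percentages")


# ---------------------------------------------------------------------------
# hierarchy diagnostics
# ---------------------------------------------------------------------------

def _downward_targets(network: Network, neuron: int) -> np.ndarray:
    """Neurons one level below that receive feedback from ``neuron``."""
    lo, hi = network.fb_by_pre_ptr[neuron], network.fb_by_pre_ptr[neuron + 1]
    return np.unique(network.fb_post[network.fb_by_pre_idx[lo:hi]])

def _upward_targets(network: Network, neuron: int) -> np.ndarray:
    """Neurons one level above that receive feedforward from ``neuron``."""
    lo, hi = network.ff_by_pre_ptr[neuron], network.ff_by_pre_ptr[neuron + 1]
    return np.unique(network.ff_post[network.ff_by_pre_idx[lo:hi]])


def count_percolations(
    network: Network,
    seed: int | np.random.Generator,
    n_probes: int = 20,
    duration_ms: int = 10_000,
    schedule: SleepSchedule | None = None,
) -> tuple[int, int]:
    """Count spontaneous three-step spike chains through the hierarchy.

    While the network undergoes the sleep noise schedule with plasticity
    off, a top-down percolation is counted when a probed level-3 neuron
    spikes, a level-2 neuron within its (feedback) projection spikes on the
    next step, and a level-1 neuron within *that* neuron's projection spikes
    on the step after; bottom-up chains are counted symmetrically along
    feedforward projections from probed level-1 neurons.
    """
    if network.group_level is None:
        raise ValueError("percolation counting needs a levelled hierarchy")
    real_levels = network.group_level[network.group_id[~network.is_phantom]]
    if real_levels.max() < 2:
        raise ValueError("percolation counting needs a >= 3-level hierarchy")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sched = schedule or SleepSchedule(total_ms=duration_ms)
    phases = [
        Phase(p.duration_ms, Rule.OFF, p.noise_p, name=p.name, record_raster=True)
        for p in sched.phases()
    ]
    res, _ = run(network, phases, rng, record_raster=True)
    raster = res.raster
    levels = network.group_level[network.group_id]
    real = ~network.is_phantom
    top = np.flatnonzero((levels == 2) & real)
    bottom = np.flatnonzero((levels == 0) & real)
    top_probes = rng.choice(top, size=min(n_probes, top.size), replace=False)
    bottom_probes = rng.choice(bottom, size=min(n_probes, bottom.size), replace=False)

    def chain_count(probes: np.ndarray, targets_of) -> int:
        total = 0
        T = raster.shape[0]
        for p in probes:
            mid = targets_of(network, int(p))
            if mid.size == 0:
                continue
            far = {int(m): targets_of(network, int(m)) for m in mid}
            spike_ts = np.flatnonzero(raster[:, p])
            for t in spike_ts:
                if t + 2 >= T:
                    break
                mids_hit = mid[raster[t + 1, mid] > 0]
                if any(
                    far[int(m)].size and raster[t + 2, far[int(m)]].any()
                    for m in mids_hit
                ):
                    total += 1
        return total

    n_topdown = chain_count(top_probes, _downward_targets)
    n_bottomup = chain_count(bottom_probes, _upward_targets)
    return n_topdown, n_bottomup


def compare_drive_rates(
    network: Network,
    target_level: str,
    seed: int | np.random.Generator,
    fraction: float = 1.0 / 3.0,
    duration_ms: int = 10_000,
    schedule: SleepSchedule | None = None,
) -> float:
    """Mean firing rate (spikes/ms/neuron) of the non-clamped network while a
    random fraction of one level is held steadily active during sleep noise."""
    if target_level not in ("top", "bottom"):
        raise ValueError("target_level must be 'top' or 'bottom'")
    if network.group_level is None:
        raise ValueError("steady-drive comparison needs a levelled hierarchy")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    levels = network.group_level[network.group_id]
    real = ~network.is_phantom
    # the visible top level is the highest non-phantom level
    lvl = int(levels[real].max()) if target_level == "top" else 0
    pool = np.flatnonzero((levels == lvl) & real)
    clamp = rng.choice(pool, size=int(round(fraction * pool.size)), replace=False)
    sched = schedule or SleepSchedule(total_ms=duration_ms)
    phases = [
        Phase(p.duration_ms, Rule.OFF, p.noise_p, clamp=clamp, name=p.name)
        for p in sched.phases()
    ]
    res, _ = run(network, phases, rng, record_raster=True)
    observed = np.flatnonzero(real)
    observed = np.setdiff1d(observed, clamp)
    return float(res.raster[:, observed].mean())


def weight_change_stats(
    network_before: Network,
    network_after: Network,
    ff_mask: np.ndarray | None = None,
    fb_mask: np.ndarray | None = None,
) -> float:
    """Mean signed percent weight change over a synapse selection.

    Masks address the FF/FB synapse arrays.  With no masks, all plastic
    synapses are pooled; if only one mask is given, the other kind is
    excluded.  The two networks must share a synapse table.
    """
    if (
        network_before.ff_pre.size != network_after.ff_pre.size
        or network_before.fb_pre.size != network_after.fb_pre.size
    ):
        raise ValueError("networks have different synapse tables")
    neither = ff_mask is None and fb_mask is None
    pieces = []
    for before, after, mask, plastic in (
        (network_before.ff_w, network_after.ff_w, ff_mask, network_before.ff_plastic),
        (network_before.fb_w, network_after.fb_w, fb_mask, network_before.fb_plastic),
    ):
        if mask is None:
            m = plastic.copy() if neither else np.zeros_like(plastic)
        else:
            m = np.asarray(mask, bool) & plastic
        m &= before > 0
        if m.any():
            pieces.append(100.0 * (after[m] - before[m]) / before[m])
    if not pieces:
        raise ValueError("selection matches no synapses")
    return float(np.concatenate(pieces).mean())
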