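"""Experiment presets and table replication.

Each preset bundles the network topology, wiring, plasticity rates, and
protocol constants for one of the four memory experiments (procedural
sequence learning, declarative paired associates, gist extraction, memory
integration), together with the evaluation conditions reported for it.
Presets are plain dictionaries so a YAML/JSON config can override any key.

The per-experiment wiring and noise levels are the package's calibration of
quantities the source model leaves open; see the methods note for the
reasoning behind each choice.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

from .builders import (
    WiringParams,
    build_declarative,
    build_hierarchy,
    build_procedural,
    embed_memory,
)
from .core import ModelConstants, Network, PlasticityRates, Rule
from .evaluation import (
    RecallResult,
    compare_drive_rates,
    count_percolations,
    recall_pairs,
    recall_sequence,
    weight_change_stats,
)
from .protocols import (
    SleepSchedule,
    cue_in_sleep,
    sleep,
    train_gist,
    train_integration,
    train_pairs,
    train_sequence,
    wake_with_spurious_pairs,
)

__all__ = [
    "PRESETS",
    "ExperimentReport",
    "run_experiment",
    "replicate_table",
    "run_procedural",
    "run_declarative",
    "run_gist",
    "run_integration",
    "run_wake_renormalization",
]


# ---------------------------------------------------------------------------
# presets (the calibrated study conditions)
# ---------------------------------------------------------------------------

PRESETS: dict[str, dict[str, Any]] = {
    "procedural": {
        "wiring": dict(k_ff=3, k_fb=1, intra_fanin=4),
        "rates": dict(fb_coincidence_window=2, sustain_steps=2),
        "train_noise_p": 0.10,
        "recall_noise_p": 0.20,
        "window_ms": 6,
        "overlap_ms": 3,
        "gap_ms": 10,
        "train_ms": 10_000,
        "sleep": dict(total_ms=10_000, onset_ms=0),
        "sequence": "ABCD",
        "spurious": ["AECD", "ABFD"],
        "p_correct": 0.9,
        "n_trials": 100,
    },
    "declarative": {
        "wiring": dict(k_ff=2, k_fb=1, intra_fanin=0),
        "rates": dict(fb_coincidence_window=2, sustain_steps=4),
        "train_noise_p": 0.01,
        "recall_noise_p": 0.035,
        "per_pair_ms": 2000,
        "sleep": dict(total_ms=20_000, onset_ms=0),
        "n_pairs": 8,
        "n_trials_per_pair": 12,
        "cue_reps": 3,
        "cue_ms": 500,
        "cue_noise_p": 0.60,
    },
    "gist": {
        "wiring": dict(k_ff=3, k_fb=1, intra_fanin=4),
        "rates": dict(fb_coincidence_window=2, sustain_steps=2),
        "train_noise_p": 0.20,
        "level_sizes": [26, 14, 3],
        "per_stim_ms": 500,
        "reps": 4,
        "sleep": dict(total_ms=10_000, onset_ms=0),
    },
    "percolation": {
        "wiring": dict(k_ff=3, k_fb=1, intra_fanin=4, w_init=0.2, rf_overlap=0),
        "level_sizes": [26, 14, 3],
        "duration_ms": 10_000,
        "n_probes": 20,
    },
    "integration": {
        "wiring": dict(k_ff=3, k_fb=1, intra_fanin=4),
        "rates": dict(fb_coincidence_window=2, sustain_steps=2),
        "train_noise_p": 0.10,
        "level_sizes": [30, 30, 30],
        "train_ms": 10_000,
        "sleep": dict(total_ms=10_000, onset_ms=0),
        "old_l1": list(range(8, 14)),   # contiguous blocks per level
        "old_l2": list(range(9, 13)),
        "old_l3": list(range(10, 12)),
    },
}


def _wiring(preset: dict) -> WiringParams:
    return WiringParams(**preset["wiring"])


def _rates(preset: dict) -> PlasticityRates:
    return PlasticityRates(**preset.get("rates", {}))


def _sched(preset: dict) -> SleepSchedule:
    return SleepSchedule(**preset.get("sleep", {}))


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------

def run_procedural(
    seed: int,
    conditions: list[str] | None = None,
    n_trials: int | None = None,
    cycles: int = 10,
    preset: dict | None = None,
) -> dict[str, RecallResult]:
    """The sequence-learning experiment: one network per seed, all conditions.

    Conditions: ``baseline`` (untrained), ``wake`` (one training phase),
    ``cycle1`` (training plus one sleep), ``cycles10`` (ten wake/sleep
    cycles), ``extra_wake`` (training extended instead of sleep), and
    ``potentiation_sleep`` (the sleep phase run under the potentiation rule).
    """
    p = {**PRESETS["procedural"], **(preset or {})}
    conditions = conditions or [
        "baseline", "wake", "cycle1", "cycles10", "extra_wake", "potentiation_sleep",
    ]
    n_trials = n_trials or p["n_trials"]
    rng = np.random.default_rng(seed)
    rates = _rates(p)
    net0 = build_procedural(wiring=_wiring(p), seed=rng)
    G = {l: i for i, l in enumerate(net0.group_labels)}
    seq = [G[x] for x in p["sequence"]]
    spur = [[G[x] for x in s] for s in p["spurious"]]
    spurious_groups = sorted({g for s in spur for g in s} - set(seq))

    def train(net: Network, ms: int) -> None:
        train_sequence(
            net, seq, spur, rng,
            p_correct=p["p_correct"], total_ms=ms,
            window_ms=p["window_ms"], overlap_ms=p["overlap_ms"],
            gap_ms=p["gap_ms"], noise_p=p["train_noise_p"], rates=rates,
        )

    def rec(net: Network) -> RecallResult:
        return recall_sequence(
            net, seq[0], seq, spurious_groups, rng,
            n_trials=n_trials, noise_p=p["recall_noise_p"],
        )

    out: dict[str, RecallResult] = {}
    if "baseline" in conditions:
        out["baseline"] = rec(net0.copy())
    trained = net0.copy()
    train(trained, p["train_ms"])
    if "wake" in conditions:
        out["wake"] = rec(trained)
    slept = trained.copy()
    sleep(slept, _sched(p), rng, rates=rates)
    if "cycle1" in conditions:
        out["cycle1"] = rec(slept)
    if "cycles10" in conditions:
        multi = slept.copy()
        for _ in range(cycles - 1):
            train(multi, p["train_ms"])
            sleep(multi, _sched(p), rng, rates=rates)
        out["cycles10"] = rec(multi)
    if "extra_wake" in conditions:
        extra = trained.copy()
        train(extra, 2 * p["train_ms"])
        out["extra_wake"] = rec(extra)
    if "potentiation_sleep" in conditions:
        pot = trained.copy()
        sleep(pot, _sched(p), rng, rule=Rule.POTENTIATION_IN_SLEEP, rates=rates)
        out["potentiation_sleep"] = rec(pot)
    return out


def run_declarative(
    seed: int,
    conditions: list[str] | None = None,
    n_trials_per_pair: int | None = None,
    cycles: int = 10,
    preset: dict | None = None,
) -> dict[str, RecallResult]:
    """The paired-associate experiment with its control and cuing conditions."""
    p = {**PRESETS["declarative"], **(preset or {})}
    conditions = conditions or [
        "baseline", "wake", "cycle1", "cycles10",
        "extra_wake", "potentiation_sleep", "cue", "cue_cued", "cue_uncued",
    ]
    trials = n_trials_per_pair or p["n_trials_per_pair"]
    rng = np.random.default_rng(seed)
    rates = _rates(p)
    net0 = build_declarative(wiring=_wiring(p), seed=rng)
    groups = rng.permutation(net0.n_real_groups)
    pairs = [
        (int(groups[2 * i]), int(groups[2 * i + 1])) for i in range(p["n_pairs"])
    ]

    def rec(net: Network, ps=None) -> RecallResult:
        return recall_pairs(
            net, ps or pairs, rng,
            n_trials_per_pair=trials, noise_p=p["recall_noise_p"],
        )

    out: dict[str, RecallResult] = {}
    if "baseline" in conditions:
        out["baseline"] = rec(net0.copy())
    trained = net0.copy()
    train_pairs(trained, pairs, rng, per_pair_ms=p["per_pair_ms"],
                noise_p=p["train_noise_p"], rates=rates)
    if "wake" in conditions:
        out["wake"] = rec(trained)
    slept = trained.copy()
    sleep(slept, _sched(p), rng, rates=rates)
    if "cycle1" in conditions:
        out["cycle1"] = rec(slept)
    if "cycles10" in conditions:
        multi = slept.copy()
        for _ in range(cycles - 1):
            train_pairs(multi, pairs, rng, per_pair_ms=p["per_pair_ms"],
                        noise_p=p["train_noise_p"], rates=rates)
            sleep(multi, _sched(p), rng, rates=rates)
        out["cycles10"] = rec(multi)
    if "extra_wake" in conditions:
        extra = trained.copy()
        wake_with_spurious_pairs(extra, pairs, rng, total_ms=p["sleep"]["total_ms"],
                                 noise_p=p["train_noise_p"], rates=rates)
        out["extra_wake"] = rec(extra)
    if "potentiation_sleep" in conditions:
        pot = trained.copy()
        sleep(pot, _sched(p), rng, rule=Rule.POTENTIATION_IN_SLEEP, rates=rates)
        out["potentiation_sleep"] = rec(pot)
    if {"cue", "cue_cued", "cue_uncued"} & set(conditions):
        cued_net = trained.copy()
        cue_in_sleep(cued_net, pairs[:4], _sched(p), rng, reps=p["cue_reps"],
                     cue_ms=p["cue_ms"], cue_noise_p=p["cue_noise_p"], rates=rates)
        if "cue" in conditions:
            out["cue"] = rec(cued_net)
        if "cue_cued" in conditions:
            out["cue_cued"] = rec(cued_net, pairs[:4])
        if "cue_uncued" in conditions:
            out["cue_uncued"] = rec(cued_net, pairs[4:])
    return out


def _gist_stimuli(rng: np.random.Generator, n_l1: int = 26) -> list[list[int]]:
    """Four stimuli over level-1 groups; three share about half their groups
    with the fourth (the gist)."""
    shared = list(range(0, 8))
    privates = [list(range(8 + 4 * i, 12 + 4 * i)) for i in range(3)]
    gist = shared
    stims = [shared[2 * i : 2 * i + 4] + privates[i] for i in range(3)]
    return stims + [gist]


def run_gist(seed: int, preset: dict | None = None) -> dict[str, float]:
    """Gist extraction: train overlapping stimuli, sleep, and compare how well
    upper-level connections are retained relative to lower-level ones."""
    p = {**PRESETS["gist"], **(preset or {})}
    rng = np.random.default_rng(seed)
    rates = _rates(p)
    net = build_hierarchy(p["level_sizes"], wiring=_wiring(p), seed=rng)
    stimuli = _gist_stimuli(rng, p["level_sizes"][0])
    train_gist(net, stimuli, rng, per_stim_ms=p["per_stim_ms"],
               reps=p["reps"], noise_p=p["train_noise_p"], rates=rates)
    before = net.copy()
    sleep(net, _sched(p), rng, rates=rates)

    lvl = net.group_level[net.group_id]
    pre_l = lvl[net.ff_pre]
    post_l = lvl[net.ff_post]
    trained = before.ff_w > before.constants.w_max / 10 + 1e-9
    out = {}
    for name, lo in (("l1_l2", 0), ("l2_l3", 1)):
        mask = (pre_l == lo) & (post_l == lo + 1) & trained
        if mask.sum() == 0:
            out[f"retention_{name}"] = float("nan")
            continue
        out[f"retention_{name}"] = float(
            net.ff_w[mask].sum() / before.ff_w[mask].sum()
        )
    out["n_trained_l1_l2"] = int(((pre_l == 0) & (post_l == 1) & trained).sum())
    out["n_trained_l2_l3"] = int(((pre_l == 1) & (post_l == 2) & trained).sum())
    return out


def run_percolation(seed: int, preset: dict | None = None) -> dict[str, float]:
    """Direction bias of spontaneous sleep activity in the fixed-weight
    hierarchy: top-down vs bottom-up three-step chains, and the steady-drive
    firing-rate comparison."""
    p = {**PRESETS["percolation"], **(preset or {})}
    rng = np.random.default_rng(seed)
    wiring = _wiring(p)
    net = build_hierarchy(p["level_sizes"], wiring=wiring, seed=rng)
    net.ff_w[net.ff_plastic] = wiring.w_init
    net.fb_w[net.fb_plastic] = wiring.w_init
    td, bu = count_percolations(net, rng, n_probes=p["n_probes"],
                                duration_ms=p["duration_ms"])
    top_rate = compare_drive_rates(net, "top", rng, duration_ms=p["duration_ms"])
    bottom_rate = compare_drive_rates(net, "bottom", rng, duration_ms=p["duration_ms"])
    return {
        "n_topdown": td,
        "n_bottomup": bu,
        "ratio": td / bu if bu else float("inf"),
        "rate_top_drive": top_rate,
        "rate_bottom_drive": bottom_rate,
    }


def _integration_setup(
    rng: np.random.Generator, p: dict, overlap: str
) -> tuple[Network, list[int], list[int], list[list[int]]]:
    wiring = _wiring(p)
    net = build_hierarchy(p["level_sizes"], wiring=wiring, seed=rng)
    n1 = p["level_sizes"][0]
    off2 = n1
    off3 = n1 + p["level_sizes"][1]
    old_chain = [
        [g for g in p["old_l1"]],
        [off2 + g for g in p["old_l2"]],
        [off3 + g for g in p["old_l3"]],
    ]
    embed_memory(net, old_chain)
    if overlap == "substantial":
        # new stimulus shares most groups with the old memory's level-1 base
        new_l1 = p["old_l1"][1:] + [p["old_l1"][0] - 1, p["old_l1"][-1] + 1]
        new_l2 = [off2 + g for g in p["old_l2"]]
        new_l3 = [off3 + g for g in p["old_l3"]]
    else:
        # single shared group per level: a neighbouring block touching the
        # old memory at one end
        w1 = len(p["old_l1"])
        start1 = p["old_l1"][-1]
        new_l1 = [start1 + i for i in range(w1)]
        w2 = len(p["old_l2"])
        new_l2 = [off2 + p["old_l2"][-1] + i for i in range(w2)]
        w3 = len(p["old_l3"])
        new_l3 = [off3 + p["old_l3"][-1] + i for i in range(w3)]
    allowed = set(new_l1) | set(new_l2) | set(new_l3) | {
        g for level in old_chain for g in level
    }
    upper = [g for g in range(n1, net.n_real_groups) if g not in allowed]
    return net, new_l1, upper, [new_l1, new_l2, new_l3]


def _new_memory_masks(
    net: Network,
    chain: list[list[int]],
    w_after_train,
    w_before_train=None,
):
    """FF masks for the new memory's level-1->2 and level-2->3 links: the
    synapses between its group sets that were *strengthened during the new
    learning* (pre-embedded old-memory synapses are not part of the new
    trace)."""
    pre_g = net.group_id[net.ff_pre]
    post_g = net.group_id[net.ff_post]
    strengthened = w_after_train > net.constants.w_max / 10 + 1e-9
    masks = {}
    for name, lo in (("l1_l2", 0), ("l2_l3", 1)):
        sel = (
            np.isin(pre_g, chain[lo]) & np.isin(post_g, chain[lo + 1]) & strengthened
        )
        masks[name] = sel
    return masks


def run_integration(
    seed: int, overlap: str = "substantial", preset: dict | None = None
) -> dict[str, float]:
    """Memory integration: embed an old memory, learn a new one with most
    higher-level groups silenced, sleep, and report the percent change of the
    new memory's feedforward weights."""
    p = {**PRESETS["integration"], **(preset or {})}
    rng = np.random.default_rng(seed)
    rates = _rates(p)
    net, stim, inhibited, chain = _integration_setup(rng, p, overlap)
    before_train = net.copy()
    train_integration(net, stim, inhibited, rng, total_ms=p["train_ms"],
                      noise_p=p["train_noise_p"], rates=rates)
    after_train = net.copy()
    sleep(net, _sched(p), rng, rates=rates)
    masks = _new_memory_masks(net, chain, after_train.ff_w, before_train.ff_w)
    out = {}
    for name, mask in masks.items():
        if mask.sum():
            out[f"change_{name}"] = weight_change_stats(after_train, net, ff_mask=mask)
        else:
            out[f"change_{name}"] = float("nan")
        out[f"n_{name}"] = int(mask.sum())
    both = masks["l1_l2"] | masks["l2_l3"]
    out["change_all"] = (
        weight_change_stats(after_train, net, ff_mask=both) if both.any() else float("nan")
    )
    return out


def run_wake_renormalization(seed: int, preset: dict | None = None) -> dict[str, float]:
    """The wake-renormalisation hazard: learn the overlapping new memory under
    the STDP-like wake rule and report what happens to old-memory synapses
    onto the shared neurons."""
    p = {**PRESETS["integration"], **(preset or {})}
    rng = np.random.default_rng(seed)
    rates = _rates(p)
    net, stim, inhibited, chain = _integration_setup(rng, p, "substantial")
    before = net.copy()
    train_integration(net, stim, inhibited, rng, total_ms=p["train_ms"],
                      rule=Rule.WAKE_STDP_DEPRESSION,
                      noise_p=p["train_noise_p"], rates=rates)
    pre_g = net.group_id[net.ff_pre]
    post_g = net.group_id[net.ff_post]
    # old-memory synapses: embedded at w_max before training
    old_sel = before.ff_w >= before.constants.w_max - 1e-9
    # ... onto neurons shared with the new memory, from old-memory groups
    # that stay inactive during the new learning (the level-1 base groups
    # outside the new stimulus; higher-level groups respond and are excluded)
    shared_groups = [g for level in chain for g in level]
    active_groups = set(stim) | set(shared_groups)
    onto_shared = np.isin(post_g, shared_groups)
    from_inactive = ~np.isin(pre_g, list(active_groups))
    sel = old_sel & onto_shared & from_inactive
    out = {"n_old_onto_shared": int(sel.sum())}
    out["old_memory_change"] = (
        weight_change_stats(before, net, ff_mask=sel) if sel.any() else float("nan")
    )
    # the new memory's own synapses should finish near the ceiling
    masks = _new_memory_masks(net, chain, net.ff_w)
    both = masks["l1_l2"] | masks["l2_l3"]
    out["new_memory_mean_w"] = float(net.ff_w[both].mean()) if both.any() else float("nan")
    return out


# ---------------------------------------------------------------------------
# reports and table replication
# ---------------------------------------------------------------------------

@dataclass
class ExperimentReport:
    """Aggregated multi-seed results for one experiment preset."""

    experiment: str
    seeds: list[int]
    config: dict[str, Any]
    per_seed: list[dict[str, Any]] = field(default_factory=list)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def aggregate(self) -> dict[str, dict[str, float]]:
        keys = self.per_seed[0].keys()
        agg: dict[str, dict[str, float]] = {}
        for k in keys:
            vals = [s[k] for s in self.per_seed]
            if isinstance(vals[0], RecallResult):
                recall = np.array([v.recall_pct for v in vals], dtype=float)
                inc = np.array([v.incorrect_pct for v in vals], dtype=float)
                tot_inc = inc.mean()
                agg[k] = {
                    "recall_mean": float(recall.mean()),
                    "recall_sd": float(recall.std()),
                    "incorrect_mean": float(tot_inc),
                    "s_n": float(recall.mean() / tot_inc) if tot_inc else float("inf"),
                }
            else:
                arr = np.array(vals, dtype=float)
                arr = arr[np.isfinite(arr)]
                agg[k] = {
                    "mean": float(arr.mean()) if arr.size else float("nan"),
                    "sd": float(arr.std()) if arr.size else float("nan"),
                }
        return agg

    def to_json(self) -> str:
        payload = {
            "experiment": self.experiment,
            "seeds": self.seeds,
            "config_hash": self.config_hash,
            "aggregate": {
                k: {m: ("inf" if isinstance(v, float) and np.isinf(v) else v)
                    for m, v in d.items()}
                for k, d in self.aggregate().items()
            },
        }
        return json.dumps(payload, indent=2)


_RUNNERS: dict[str, Callable[..., dict]] = {
    "procedural": run_procedural,
    "declarative": run_declarative,
    "gist": run_gist,
    "percolation": run_percolation,
    "integration": run_integration,
    "integration-disjoint": lambda seed, **kw: run_integration(seed, "single", **kw),
    "wake-renorm": run_wake_renormalization,
}


def run_experiment(
    name: str,
    seeds: list[int],
    out_dir: str | Path | None = None,
    preset_override: dict | None = None,
    **kwargs,
) -> ExperimentReport:
    """Run one experiment preset across seeds and aggregate the results."""
    if name not in _RUNNERS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_RUNNERS)}")
    if not seeds:
        raise ValueError("at least one seed is required")
    base = name.split("-")[0] if name != "wake-renorm" else "integration"
    config = {**PRESETS.get(base, {}), **(preset_override or {})}
    report = ExperimentReport(experiment=name, seeds=list(seeds), config=config)
    for s in seeds:
        if preset_override:
            kwargs["preset"] = preset_override
        report.per_seed.append(_RUNNERS[name](s, **kwargs))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / f"{name}-report.json").write_text(report.to_json())
    return report


#: condition order of the two printed tables
TABLE1_COLUMNS = [
    "baseline", "wake", "cycle1", "cycles10", "extra_wake", "potentiation_sleep",
]
TABLE2_COLUMNS = TABLE1_COLUMNS + ["cue"]


def replicate_table(
    table: int,
    n_seeds: int = 20,
    out_dir: str | Path | None = None,
    n_trials: int | None = None,
) -> pd.DataFrame:
    """Rebuild the recall/S-N summary table for the procedural (1) or
    declarative (2) experiment, averaged over seeds."""
    if table not in (1, 2):
        raise ValueError("table must be 1 or 2")
    seeds = list(range(n_seeds))
    if table == 1:
        rep = run_experiment("procedural", seeds, n_trials=n_trials or 25)
        cols = TABLE1_COLUMNS
    else:
        rep = run_experiment(
            "declarative", seeds,
            conditions=TABLE2_COLUMNS, n_trials_per_pair=n_trials or 6,
        )
        cols = TABLE2_COLUMNS
    agg = rep.aggregate()
    frame = pd.DataFrame(
        {
            c: {
                "recall_pct": agg[c]["recall_mean"],
                "recall_sd": agg[c]["recall_sd"],
                "s_n": agg[c]["s_n"],
            }
            for c in cols
        }
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out_dir / f"table{table}.csv")
    return frame
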