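"""Network builders for the four experiment topologies.

Each network is an assembly of densely interconnected 18-neuron groups wired
by inter-group feedforward edges; feedback edges mirror them in the opposite
direction.  On every neuron, one dendritic domain is created per afferent
group, holding ``k_ff`` feedforward synapses from random neurons of that
group and ``k_fb`` feedback synapses.  Feedback sources are chosen
*reciprocally* (from the same group the domain listens to) whenever the
reverse feedforward edge exists -- in an associative (all-to-all) matrix this
makes a domain a detector of "my input group is also confirming my output" --
and otherwise from the groups downstream of the owner, so that in channels
and hierarchies feedback descends from above.

Groups with no downstream target (a channel's last group, the top level of a
hierarchy) are echoed by a *phantom* group: a non-plastic mirror, one step
delayed, standing in for the next processing stage so that these groups still
receive the feedback activations required to trigger plasticity.

All plastic weights start at ``w_max/10`` (``w_max/5`` for the percolation
configuration), every neuron carries three non-plastic noise synapses at
``w_max``, and intra-group connectivity is uniform, fixed, and strong enough
to correlate a group's neurons without letting a fully active group sustain
itself in the absence of input.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, replace

import numpy as np

from .core import ModelConstants, Network

__all__ = [
    "WiringParams",
    "build_procedural",
    "build_declarative",
    "build_hierarchy",
    "embed_memory",
    "PROCEDURAL_EDGES",
]

#: feedforward channel of the sequence-learning task: the trained route
#: A=>B=>C=>D plus the spurious routes A=>E=>C=>D and A=>B=>F=>D.
PROCEDURAL_EDGES = [
    ("A", "B"),
    ("A", "E"),
    ("B", "C"),
    ("B", "F"),
    ("E", "C"),
    ("C", "D"),
    ("F", "D"),
]


@dataclass(frozen=True)
class WiringParams:
    """Inter- and intra-group wiring knobs the source model leaves open."""

    k_ff: int = 3                  # FF synapses per dendritic domain
    k_fb: int = 1                  # FB synapses per dendritic domain
    w_init: float = 0.1            # initial plastic weight (w_max / 10)
    intra_w: float = 0.015         # fixed intra-group synapse weight
    intra_fanin: int = 6           # intra-group synapses received per neuron
    fb_alignment: str = "auto"     # reciprocal | downstream | auto
    phantom_fb_w: float = 0.1      # weight of non-plastic phantom feedback
    phantom_k_fb: int = 3          # FB synapses per domain fed by a phantom echo
    rf_overlap: int = 1            # extra receptive-field neighbours per side

    def __post_init__(self) -> None:
        if self.k_ff < 1 or self.k_fb < 1:
            raise ValueError("domains need at least one FF and one FB synapse")
        if self.fb_alignment not in ("reciprocal", "downstream", "auto", "mixed"):
            raise ValueError(f"unknown fb_alignment {self.fb_alignment!r}")


def _assemble(
    constants: ModelConstants,
    labels: list[str],
    ff_edges: list[tuple[int, int]],
    phantom_for: list[int],
    wiring: WiringParams,
    rng: np.random.Generator,
    group_level: list[int] | None = None,
) -> Network:
    gs = constants.group_size
    n_real_groups = len(labels)
    n_groups = n_real_groups + len(phantom_for)
    all_labels = list(labels)
    group_level_full = list(group_level) if group_level is not None else None

    group_id = np.repeat(np.arange(n_groups), gs)
    n = n_groups * gs
    is_phantom = np.zeros(n, dtype=bool)
    phantom_src = np.full(n, -1, dtype=np.int64)
    phantom_group_of: dict[int, int] = {}
    for k, g in enumerate(phantom_for):
        pg = n_real_groups + k
        phantom_group_of[g] = pg
        all_labels.append(labels[g] + "'")
        if group_level_full is not None:
            group_level_full.append(max(group_level_full) + 1)
        sl = slice(pg * gs, (pg + 1) * gs)
        is_phantom[sl] = True
        phantom_src[sl] = np.arange(g * gs, (g + 1) * gs)

    edge_set = set(ff_edges)
    afferents: list[list[int]] = [[] for _ in range(n_real_groups)]
    downstream: list[list[int]] = [[] for _ in range(n_real_groups)]
    for src, dst in ff_edges:
        afferents[dst].append(src)
        downstream[src].append(dst)

    # sparse fixed intra-group recurrence: each real neuron listens to a few
    # random neurons of its own group; total intra drive is kept small enough
    # that one strong synapse plus one noise input stays subthreshold
    intra_pre: list[int] = []
    intra_post: list[int] = []
    fanin = min(wiring.intra_fanin, gs - 1)
    for g in range(n_real_groups):
        for i in range(g * gs, (g + 1) * gs):
            others = np.array([j for j in range(g * gs, (g + 1) * gs) if j != i])
            for pre in rng.choice(others, size=fanin, replace=False):
                intra_pre.append(int(pre))
                intra_post.append(i)

    dom_owner: list[int] = []
    neuron_dom_ptr = [0]
    dom_ff_ptr = [0]
    dom_fb_ptr = [0]
    ff_pre: list[int] = []
    ff_w: list[float] = []
    ff_plastic: list[bool] = []
    fb_pre: list[int] = []
    fb_w: list[float] = []
    fb_plastic: list[bool] = []

    def pick(group: int, k: int, phantom: bool = False) -> np.ndarray:
        g = phantom_group_of[group] if phantom else group
        base = g * gs
        k_eff = min(k, gs)
        return base + rng.choice(gs, size=k_eff, replace=False)

    for g in range(n_real_groups):
        for i in range(g * gs, (g + 1) * gs):
            # a group with downstream targets but no afferents (a bottom
            # level driven by external stimuli) still receives the divergent
            # feedback projection; its feedback synapses sit in a domain of
            # their own with no feedforward side, so they deliver drive and
            # are exposed to down-selection but can never meet the
            # potentiation coincidence
            if not afferents[g] and downstream[g]:
                dom_owner.append(i)
                dom_ff_ptr.append(len(ff_pre))
                for j in range(wiring.k_fb):
                    z = downstream[g][int(rng.integers(len(downstream[g])))]
                    fb_pre.append(int(pick(z, 1)[0]))
                    fb_w.append(wiring.w_init)
                    fb_plastic.append(True)
                dom_fb_ptr.append(len(fb_pre))
            for x in afferents[g]:
                dom_owner.append(i)
                # feedforward side: k_ff random neurons of the afferent group
                for pre in pick(x, wiring.k_ff):
                    ff_pre.append(int(pre))
                    ff_w.append(wiring.w_init)
                    ff_plastic.append(True)
                dom_ff_ptr.append(len(ff_pre))
                # feedback side
                reciprocal_ok = (g, x) in edge_set
                use_reciprocal = wiring.fb_alignment == "reciprocal" or (
                    wiring.fb_alignment == "auto" and reciprocal_ok
                )
                if wiring.fb_alignment == "mixed" and reciprocal_ok:
                    # one feedback synapse from the domain's own afferent
                    # group, the rest from random downstream groups
                    pool = [(z, False) for z in downstream[g] if z != x]
                    if not pool:
                        pool = [(x, False)]
                    sources = [(x, False)] + [
                        pool[int(rng.integers(len(pool)))]
                        for _ in range(wiring.k_fb - 1)
                    ]
                elif use_reciprocal and reciprocal_ok:
                    sources = [(x, False)] * wiring.k_fb
                else:
                    pool: list[tuple[int, bool]] = [(z, False) for z in downstream[g]]
                    if g in phantom_group_of:
                        pool.append((g, True))
                    if not pool:
                        # a group with no downstream target and no phantom echo
                        # hears feedback from its afferent groups instead,
                        # preferring the domain's own afferent
                        pool = [(z, False) for z in afferents[g] if z == x]
                        pool += [(z, False) for z in afferents[g] if z != x]
                    if not pool:
                        raise ValueError(
                            f"group {labels[g]} has no feedback source; "
                            "add a downstream edge or a phantom echo"
                        )
                    k_here = (
                        max(wiring.k_fb, wiring.phantom_k_fb)
                        if g in phantom_group_of
                        else wiring.k_fb
                    )
                    if len(pool) <= k_here:
                        sources = [pool[j % len(pool)] for j in range(k_here)]
                    else:
                        picks = rng.choice(len(pool), size=k_here, replace=False)
                        sources = [pool[int(j)] for j in picks]
                for z, phantom in sources:
                    pre = int(pick(z, 1, phantom=phantom)[0])
                    fb_pre.append(pre)
                    fb_w.append(wiring.phantom_fb_w if phantom else wiring.w_init)
                    fb_plastic.append(not phantom)
                dom_fb_ptr.append(len(fb_pre))
            neuron_dom_ptr.append(len(dom_owner))
    # phantom neurons own no domains
    for _ in range(n - n_real_groups * gs):
        neuron_dom_ptr.append(len(dom_owner))

    return Network(
        constants=constants,
        group_id=group_id,
        n_real_groups=n_real_groups,
        is_phantom=is_phantom,
        phantom_src=phantom_src,
        dom_owner=np.array(dom_owner, dtype=np.int64),
        neuron_dom_ptr=np.array(neuron_dom_ptr, dtype=np.int64),
        dom_ff_ptr=np.array(dom_ff_ptr, dtype=np.int64),
        dom_fb_ptr=np.array(dom_fb_ptr, dtype=np.int64),
        ff_pre=np.array(ff_pre, dtype=np.int64),
        ff_w=np.array(ff_w, dtype=np.float64),
        ff_plastic=np.array(ff_plastic, dtype=bool),
        fb_pre=np.array(fb_pre, dtype=np.int64),
        fb_w=np.array(fb_w, dtype=np.float64),
        fb_plastic=np.array(fb_plastic, dtype=bool),
        intra_w=wiring.intra_w,
        intra_pre=np.array(intra_pre, dtype=np.int64),
        intra_post=np.array(intra_post, dtype=np.int64),
        group_labels=all_labels,
        group_level=np.array(group_level_full) if group_level_full is not None else None,
        ff_group_edges=ff_edges,
    )


def build_procedural(
    constants: ModelConstants = ModelConstants(),
    wiring: WiringParams = WiringParams(),
    seed: int | np.random.Generator = 0,
) -> Network:
    """Six-group segregated channel for the sequence (procedural) task."""
    rng = np.random.default_rng(seed)
    labels = list("ABCDEF")
    idx = {l: i for i, l in enumerate(labels)}
    edges = [(idx[a], idx[b]) for a, b in PROCEDURAL_EDGES]
    terminal = [g for g in range(len(labels)) if all(src != g for src, _ in edges)]
    return _assemble(constants, labels, edges, terminal, wiring, rng)


def build_declarative(
    constants: ModelConstants = ModelConstants(),
    wiring: WiringParams = WiringParams(),
    seed: int | np.random.Generator = 0,
    n_groups: int = 16,
) -> Network:
    """Associative matrix: inter-group connections between all group pairs."""
    rng = np.random.default_rng(seed)
    labels = list(string.ascii_uppercase[:n_groups])
    edges = [(i, j) for i in range(n_groups) for j in range(n_groups) if i != j]
    return _assemble(constants, labels, edges, [], wiring, rng)


def build_hierarchy(
    level_sizes: list[int],
    constants: ModelConstants = ModelConstants(),
    wiring: WiringParams = WiringParams(),
    seed: int | np.random.Generator = 0,
) -> Network:
    """Convergent-divergent hierarchy with a phantom echo above the top level.

    Each group of a higher level receives feedforward input from a contiguous
    block of the level below (blocks partition the lower level, with any
    residue assigned under the seed, extended by ``rf_overlap`` neighbours on
    each side); feedback mirrors the feedforward edges downward.
    """
    if len(level_sizes) < 2:
        raise ValueError("a hierarchy needs at least two levels")
    if any(b > a for a, b in zip(level_sizes, level_sizes[1:])):
        import warnings

        warnings.warn("level sizes increase upward; hierarchy expected convergent")
    rng = np.random.default_rng(seed)
    offsets = np.concatenate([[0], np.cumsum(level_sizes)])
    labels = [f"L{l + 1}G{j}" for l, size in enumerate(level_sizes) for j in range(size)]
    group_level = [l for l, size in enumerate(level_sizes) for _ in range(size)]
    edges: list[tuple[int, int]] = []
    for l in range(len(level_sizes) - 1):
        lo, hi = level_sizes[l], level_sizes[l + 1]
        base = lo // hi
        extras = rng.permutation(hi) < (lo % hi)
        sizes = base + extras.astype(int)
        starts = np.concatenate([[0], np.cumsum(sizes)])[:-1]
        for j in range(hi):
            a = max(0, starts[j] - wiring.rf_overlap)
            b = min(lo, starts[j] + sizes[j] + wiring.rf_overlap)
            for src in range(a, b):
                edges.append((int(offsets[l] + src), int(offsets[l + 1] + j)))
    top = [int(g) for g in range(offsets[-2], offsets[-1])]
    return _assemble(constants, labels, edges, top, wiring, rng, group_level)


def embed_memory(
    network: Network, group_chain: list[list[int]] | list[int], w: float | None = None
) -> Network:
    """Set all inter-level FF and FB synapses along a memory chain to w_max.

    ``group_chain`` lists the member groups per level, bottom first (a flat
    list is read as one group per level).  Each consecutive pair of levels
    must be connected by at least one feedforward edge, otherwise the chain
    is rejected.  Embedding is idempotent and leaves all other synapses
    untouched.
    """
    if group_chain and not isinstance(group_chain[0], (list, tuple, np.ndarray)):
        chain = [[int(g)] for g in group_chain]  # type: ignore[arg-type]
    else:
        chain = [list(map(int, level)) for level in group_chain]  # type: ignore[union-attr]
    w_val = network.constants.w_max if w is None else float(w)
    edge_set = set(network.ff_group_edges)
    pre_g_ff = network.group_id[network.ff_pre]
    post_g_ff = network.group_id[network.ff_post]
    pre_g_fb = network.group_id[network.fb_pre]
    post_g_fb = network.group_id[network.fb_post]
    for lower, upper in zip(chain, chain[1:]):
        pairs = [(a, b) for a in lower for b in upper if (a, b) in edge_set]
        if not pairs:
            raise ValueError(
                f"memory chain levels {lower} -> {upper} are not adjacent"
            )
        for a, b in pairs:
            ff_sel = (pre_g_ff == a) & (post_g_ff == b) & network.ff_plastic
            network.ff_w[ff_sel] = w_val
            fb_sel = (pre_g_fb == b) & (post_g_fb == a) & network.fb_plastic
            network.fb_w[fb_sel] = w_val
    return network
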