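"""Hudson-style ancestral recombination graph simulation under the 2-population
isolation-with-migration model.

The simulator runs backwards in time from the present.  While ``t < tau`` two
populations exist: each specific pair of lineages in population ``p`` coalesces
at rate ``2/theta_p``, each lineage currently in population 1 migrates to
population 2 at rate ``m1`` (and 2 -> 1 at rate ``m2``), and each lineage
recombines at rate ``rho * (b - a)`` where ``[a, b]`` is the interval from its
leftmost to its rightmost ancestral marker (trapped non-ancestral material
included, as in Hudson's algorithm).  At ``t = tau`` all surviving lineages
enter the ancestral population (pair rate ``2/theta3``, no migration).  The
locus is the continuous unit interval ``[0, 1)``; simulation stops once every
position has reached its most recent common ancestor.

The output of one run is an :class:`ARGLocus`: the sorted recombination
breakpoints plus the marginal :class:`~imcoal.trees.GeneTree` of every
non-recombined block.  Breakpoints whose flanking marginal trees happen to be
identical (invisible recombination) are retained — they are real events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import IMParams
from .trees import GeneTree, tip_label

__all__ = ["SimulationConfig", "ARGLocus", "simulate_locus", "simulate_loci", "marginal_tree"]


@dataclass(frozen=True)
class SimulationConfig:
    """One locus-simulation setting.

    ``rho`` is the scaled recombination rate: expected cross-overs per
    mutation-unit of time across the whole locus when the full unit interval
    is ancestral.
    """

    params: IMParams
    rho: float = 0.0
    samples_per_pop: int = 2
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.rho) or self.rho < 0:
            raise ValueError(f"rho must be finite and >= 0, got {self.rho!r}")
        if self.samples_per_pop < 1:
            raise ValueError("samples_per_pop must be >= 1")


@dataclass(frozen=True)
class ARGLocus:
    """One locus' ARG reduced to per-block marginal trees.

    ``blocks`` tile ``[0, 1)`` with half-open ``[start, end)`` intervals, one
    per non-recombined block; ``len(blocks) == len(breakpoints) + 1``.
    Adjacent blocks may carry identical trees (invisible recombination).
    """

    breakpoints: tuple[float, ...]
    blocks: tuple[tuple[float, float, GeneTree], ...]

    def __post_init__(self) -> None:
        if len(self.blocks) != len(self.breakpoints) + 1:
            raise ValueError("need exactly len(breakpoints) + 1 blocks")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def trees(self) -> tuple[GeneTree, ...]:
        return tuple(t for _, _, t in self.blocks)


def marginal_tree(locus: ARGLocus, position: float) -> GeneTree:
    """Gene tree of the unique block whose half-open interval contains ``position``."""
    if not (0.0 <= position < 1.0):
        raise ValueError(f"position must lie in [0, 1), got {position!r}")
    for start, end, tree in locus.blocks:
        if start <= position < end:
            return tree
    raise AssertionError("blocks do not tile [0, 1)")  # pragma: no cover


# ---------------------------------------------------------------------------
# internal machinery
# ---------------------------------------------------------------------------
#
# A lineage is [pop, segments]; a segment is (left, right, node, n_samples_below)
# and the segment list is left-sorted and disjoint.  Coalescences record edges
# (left, right, parent, child); regions whose sample count reaches the full
# sample size have found their local MRCA and are dropped from the lineage.


def _merge(a_segs, b_segs, parent, n_samples, edges):
    bounds = sorted({x for l, r, _, _ in a_segs for x in (l, r)}
                    | {x for l, r, _, _ in b_segs for x in (l, r)})
    out = []
    ia = ib = 0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        while ia < len(a_segs) and a_segs[ia][1] <= lo:
            ia += 1
        while ib < len(b_segs) and b_segs[ib][1] <= lo:
            ib += 1
        pa = a_segs[ia] if ia < len(a_segs) and a_segs[ia][0] <= lo else None
        pb = b_segs[ib] if ib < len(b_segs) and b_segs[ib][0] <= lo else None
        if pa is None and pb is None:
            continue
        if pb is None:
            piece = (lo, hi, pa[2], pa[3])
        elif pa is None:
            piece = (lo, hi, pb[2], pb[3])
        else:
            edges.append((lo, hi, parent, pa[2]))
            edges.append((lo, hi, parent, pb[2]))
            cnt = pa[3] + pb[3]
            if cnt == n_samples:
                continue  # local MRCA reached; stop tracking this region
            piece = (lo, hi, parent, cnt)
        if out and out[-1][1] == piece[0] and out[-1][2:] == piece[2:]:
            out[-1] = (out[-1][0], piece[1], piece[2], piece[3])
        else:
            out.append(piece)
    return out


def _split(segments, x):
    """Cut a segment list at x into (left-of-x, right-of-x) lists."""
    left, right = [], []
    for seg in segments:
        l, r, node, cnt = seg
        if r <= x:
            left.append(seg)
        elif l >= x:
            right.append(seg)
        else:
            left.append((l, x, node, cnt))
            right.append((x, r, node, cnt))
    return left, right


def simulate_locus(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> ARGLocus:
    """Simulate one locus' ARG and return its per-block marginal gene trees."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = config.params
    k = config.samples_per_pop
    n_samples = 2 * k
    tip_labels = [tip_label(1, i + 1) for i in range(k)] + [
        tip_label(2, i + 1) for i in range(k)
    ]
    tip_pops = [1] * k + [2] * k

    node_times: list[float] = [0.0] * n_samples
    edges: list[tuple[float, float, int, int]] = []
    breakpoints: list[float] = []
    # lineage = [pop, segments]
    lineages: list[list] = [
        [tip_pops[i], [(0.0, 1.0, i, 1)]] for i in range(n_samples)
    ]

    t = 0.0
    ancestral = p.tau == 0.0
    if ancestral:
        for lin in lineages:
            lin[0] = 3
    rho = config.rho

    while lineages:
        if ancestral:
            n = len(lineages)
            coal_rates = ((3, n * (n - 1) / p.theta3),)
            mig_rates = ()
        else:
            k1 = sum(1 for lin in lineages if lin[0] == 1)
            k2 = len(lineages) - k1
            coal_rates = (
                (1, k1 * (k1 - 1) / p.theta1),
                (2, k2 * (k2 - 1) / p.theta2),
            )
            mig_rates = ((1, k1 * p.m1), (2, k2 * p.m2))
        if rho:
            spans = [lin[1][-1][1] - lin[1][0][0] for lin in lineages]
            rec_rate = rho * sum(spans)
        else:
            rec_rate = 0.0
        total = sum(r for _, r in coal_rates) + sum(r for _, r in mig_rates) + rec_rate
        if total == 0.0:
            t = p.tau  # isolated lineages waiting for the split
        else:
            t += rng.exponential(1.0 / total)
        if not ancestral and t >= p.tau:
            t = p.tau
            ancestral = True
            for lin in lineages:
                lin[0] = 3
            continue

        u = rng.random() * total
        event = None
        for pop, rate in coal_rates:
            if u < rate:
                event = ("coal", pop)
                break
            u -= rate
        if event is None:
            for pop, rate in mig_rates:
                if u < rate:
                    event = ("mig", pop)
                    break
                u -= rate
        if event is None:
            event = ("rec", None)

        if event[0] == "coal":
            pop = event[1]
            group = (
                range(len(lineages))
                if pop == 3
                else [i for i, lin in enumerate(lineages) if lin[0] == pop]
            )
            ia, ib = rng.choice(len(group), size=2, replace=False)
            i, j = group[int(ia)], group[int(ib)]
            parent = len(node_times)
            node_times.append(t)
            merged = _merge(lineages[i][1], lineages[j][1], parent, n_samples, edges)
            for idx in sorted((i, j), reverse=True):
                lineages.pop(idx)
            if merged:
                lineages.append([pop, merged])
        elif event[0] == "mig":
            pop = event[1]
            group = [i for i, lin in enumerate(lineages) if lin[0] == pop]
            lineages[group[rng.integers(len(group))]][0] = 2 if pop == 1 else 1
        else:
            target = u / rho
            acc = 0.0
            idx = len(lineages) - 1
            for i, s in enumerate(spans):
                acc += s
                if target < acc:
                    idx = i
                    break
            segs = lineages[idx][1]
            a0, b0 = segs[0][0], segs[-1][1]
            x = a0 + (b0 - a0) * rng.random()
            left, right = _split(segs, x)
            if left and right:
                breakpoints.append(x)
                pop = lineages[idx][0]
                lineages[idx] = [pop, left]
                lineages.append([pop, right])

    bps = sorted(set(breakpoints))
    bounds = [0.0] + bps + [1.0]
    el = np.array([e[0] for e in edges])
    er = np.array([e[1] for e in edges])
    blocks = []
    cache: dict[bytes, GeneTree] = {}
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        x = 0.5 * (lo + hi)
        active = np.flatnonzero((el <= x) & (x < er))
        key = active.tobytes()
        tree = cache.get(key)
        if tree is None:
            children_at: dict[int, list[int]] = {}
            for i in active:
                _, _, parent, child = edges[i]
                children_at.setdefault(parent, []).append(child)
            internal = sorted(children_at, key=lambda v: node_times[v])
            new_id = {v: n_samples + rank for rank, v in enumerate(internal)}
            events = []
            for v in internal:
                ca, cb = children_at[v]
                events.append(
                    (
                        node_times[v],
                        ca if ca < n_samples else new_id[ca],
                        cb if cb < n_samples else new_id[cb],
                    )
                )
            tree = GeneTree.from_events(tip_labels, tip_pops, events)
            cache[key] = tree
        blocks.append((lo, hi, tree))
    return ARGLocus(breakpoints=tuple(bps), blocks=tuple(blocks))


def simulate_loci(
    config: SimulationConfig, n_loci: int, seed: Optional[int] = None
) -> list[ARGLocus]:
    """Simulate independent loci (free recombination between loci).

    Each locus gets its own generator seeded ``base + locus_index`` so that
    runs are reproducible and trivially parallelizable; ``base`` defaults to
    ``config.seed``.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    base = config.seed if seed is None else seed
    if base is None:
        ss = np.random.SeedSequence()
        base = int(ss.generate_state(1)[0] % (2**31))
    return [
        simulate_locus(config, rng=np.random.default_rng(base + i))
        for i in range(n_loci)
    ]
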