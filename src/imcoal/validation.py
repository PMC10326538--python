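"""Independent consistency checks between the simulator and the likelihood.

The simulator and the likelihood module are two independent encodings of the
same stochastic model, so probabilities integrated from the gene-tree density
must match Monte-Carlo frequencies from simulation.  This module integrates
the density over the coalescence times of every ranked labeled history by
nested Gauss-Legendre quadrature, giving

* the probability of each ranked history (they must sum to 1 — a strong
  normalization check of the density itself),
* probabilities of coarse topology classes (whether each population's sample
  forms its own clade), and
* the distribution function of the sample's TMRCA,

all of which are directly comparable with empirical frequencies.

Because the density has a kink at the split time ``tau`` (the event rates
change there), the ordered time region ``0 < t_1 < ... < t_{k-1}`` is split by
how many events precede ``tau``, and each sub-region is integrated separately:
times before the split on a plain scaled Gauss-Legendre grid, times after the
split through an exponential map matched to the ancestral coalescent rate so
the unbounded tail is resolved.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

from .likelihood import _batch_log_density, _pair_list
from .params import IMParams
from .trees import GeneTree

__all__ = [
    "enumerate_ranked_histories",
    "history_probability",
    "topology_class_of",
    "topology_class_probabilities",
    "tmrca_cdf",
]


@lru_cache(maxsize=None)
def enumerate_ranked_histories(k: int) -> tuple[tuple[int, ...], ...]:
    """All ranked labeled histories of a k-tip sample as pair-code sequences.

    A history is the time-ordered sequence of merging slot pairs, encoded with
    the same pair codes the likelihood engine uses; there are
    ``prod_{j=2..k} j(j-1)/2`` of them (18 for k = 4).
    """

    def rec(kk: int):
        if kk == 1:
            yield ()
            return
        for c in range(len(_pair_list(kk))):
            for rest in rec(kk - 1):
                yield (c,) + rest

    return tuple(rec(k))


@lru_cache(maxsize=None)
def _gl_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w  # mapped to (0, 1)


def _history_clades(codes: Sequence[int], k: int) -> set[frozenset[int]]:
    """Tip-sets created by each merge of a ranked history."""
    slots: list[frozenset[int]] = [frozenset((i,)) for i in range(k)]
    clades = set()
    for kk, c in zip(range(k, 1, -1), codes):
        ia, ib = _pair_list(kk)[c]
        merged = slots[ia] | slots[ib]
        clades.add(merged)
        slots[ia] = merged
        slots.pop(ib)
    return clades


def history_probability(
    codes: Sequence[int],
    pops: Sequence[int],
    params: IMParams,
    *,
    t_upper: Optional[float] = None,
    n_nodes: int = 24,
) -> float:
    """Probability of one ranked labeled history, times integrated out.

    Integrates the gene-tree density over ``0 < t_1 < ... < t_{k-1}``
    (optionally with ``t_{k-1} < t_upper``) by nested Gauss-Legendre
    quadrature with the region split at ``tau``.
    """
    k = len(pops)
    codes = tuple(codes)
    if len(codes) != k - 1:
        raise ValueError("need k-1 merge codes for k tips")
    tau = params.tau
    upper = math.inf if t_upper is None else float(t_upper)
    if upper <= 0:
        return 0.0
    y, w = _gl_nodes(n_nodes)

    total = 0.0
    for r in range(k):  # r = number of events before the split
        pre_cap = min(tau, upper)
        if r > 0 and pre_cap <= 0.0:
            continue
        if r < k - 1 and upper <= tau:
            continue  # post-split events would exceed the bound
        # --- pre-split block: r ordered times in (0, pre_cap), built top-down
        times_cols: list[np.ndarray] = [np.zeros(1)] * (k - 1)
        jac = np.ones(1)
        bound = np.full(1, pre_cap)
        for level in range(r - 1, -1, -1):
            n_old = jac.size
            jac = np.repeat(jac, n_nodes) * np.repeat(bound, n_nodes) * np.tile(w, n_old)
            t = np.repeat(bound, n_nodes) * np.tile(y, n_old)
            for j in range(r - 1, level, -1):
                times_cols[j] = np.repeat(times_cols[j], n_nodes)
            times_cols[level] = t
            bound = t
        # reverse: level r-1 was built first (largest pre-split time)
        # (times_cols built so that index j holds t_{j+1}; ordering is ascending)
        # --- post-split block: k-1-r ordered times in (tau, upper), bottom-up
        low = np.full(jac.size, tau)
        for j in range(r, k - 1):
            kk = k - j  # lineages during the interval ending at event j+1
            c_rate = kk * (kk - 1) / params.theta3
            n_old = jac.size
            low = np.repeat(low, n_nodes)
            jac = np.repeat(jac, n_nodes)
            for jj in range(r, j):
                times_cols[jj] = np.repeat(times_cols[jj], n_nodes)
            for jj in range(r):
                times_cols[jj] = np.repeat(times_cols[jj], n_nodes)
            yy = np.tile(y, n_old)
            ww = np.tile(w, n_old)
            if math.isinf(upper):
                t = low - np.log1p(-yy) / c_rate
                jac = jac * ww / (c_rate * (1.0 - yy))
            else:
                z = -np.expm1(-c_rate * (upper - low))
                t = low - np.log1p(-yy * z) / c_rate
                jac = jac * ww * z / (c_rate * (1.0 - yy * z))
            times_cols[j] = t
            low = t
        times = np.column_stack(times_cols[: k - 1])
        dens = np.exp(
            _batch_log_density(
                times,
                np.broadcast_to(np.array(codes), (times.shape[0], k - 1)),
                tuple(pops),
                params,
            )
        )
        total += float((dens * jac).sum())
    return total


def topology_class_of(tree: GeneTree) -> tuple[bool, bool]:
    """(population-1 sample is a clade, population-2 sample is a clade)."""
    pop1 = frozenset(i for i, p in enumerate(tree.tip_pops) if p == 1)
    pop2 = frozenset(i for i, p in enumerate(tree.tip_pops) if p == 2)
    clades = {tree.clade(tree.n_tips + j) for j in range(tree.n_tips - 1)}
    return (pop1 in clades, pop2 in clades)


def topology_class_probabilities(
    params: IMParams,
    pops: Sequence[int] = (1, 1, 2, 2),
    n_nodes: int = 24,
) -> dict[tuple[bool, bool], float]:
    """Class probabilities integrated from the density over all ranked histories."""
    k = len(pops)
    pop1 = frozenset(i for i, p in enumerate(pops) if p == 1)
    pop2 = frozenset(i for i, p in enumerate(pops) if p == 2)
    out: dict[tuple[bool, bool], float] = {}
    for codes in enumerate_ranked_histories(k):
        clades = _history_clades(codes, k)
        cls = (pop1 in clades, pop2 in clades)
        p = history_probability(codes, pops, params, n_nodes=n_nodes)
        out[cls] = out.get(cls, 0.0) + p
    return out


def tmrca_cdf(
    params: IMParams,
    t: float,
    pops: Sequence[int] = (1, 1, 2, 2),
    n_nodes: int = 24,
) -> float:
    """P(TMRCA <= t) for the sample, integrated from the gene-tree density."""
    k = len(pops)
    return float(
        sum(
            history_probability(codes, pops, params, t_upper=t, n_nodes=n_nodes)
            for codes in enumerate_ranked_histories(k)
        )
    )
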