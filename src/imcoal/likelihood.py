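"""Exact gene-tree density under the 2-population isolation-with-migration model.

The density of a labeled ultrametric gene tree given the six demographic
parameters is computed with every possible migration history integrated out.
Before the population split (``t < tau``) the locations of the ``k`` extant
lineages follow a continuous-time Markov chain over the ``2^k`` assignments of
lineages to populations.  The chain is *defective*: each state's exit rate
includes the total coalescent hazard ``sum_p k_p (k_p - 1) / theta_p``, so the
mass propagated over an interval is the joint probability of the migration
path and of observing no coalescence.  At each observed coalescence the state
vector is mapped to the reduced lineage set with weight ``2 / theta_p`` for
every configuration in which the coalescing pair is co-located in population
``p`` (configurations with the pair separated contribute nothing).  At ``tau``
the vector is summed over configurations and the remaining intervals follow
the single-population coalescent with size ``theta3``.

The density is taken with respect to Lebesgue measure on the coalescence times
and counting measure on labeled topologies.  Trees that are impossible under
the parameters (for example a cross-population coalescence before ``tau`` with
both migration rates zero) get log-density ``-inf``, never an exception.

Two computational routes are provided and tested against each other:

* :func:`gene_tree_log_density` — a per-tree reference using
  ``scipy.linalg.expm`` (scaling-and-squaring), generic in the number of tips;
* :class:`LociLikelihood` — a vectorized engine that groups trees by their
  ranked coalescence history and propagates all intervals of a group at once
  through an eigendecomposition of the same generators.  Used by
  :func:`loci_log_likelihood` and the MAP optimizer, and falling back to the
  reference route whenever the eigendecomposition is ill-conditioned.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .params import IMParams
from .trees import GeneTree

__all__ = [
    "EventSchedule",
    "build_schedule",
    "migration_generator",
    "gene_tree_log_density",
    "loci_log_likelihood",
    "LociLikelihood",
]

_NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# lineage bookkeeping
# ---------------------------------------------------------------------------
#
# Extant lineages occupy "slots".  Tips are assigned to slots sorted by
# (population, label); when the pair in slots (ia, ib), ia < ib, coalesces the
# merged lineage takes slot ia and slots above ib shift down.  A configuration
# of k lineages is a bitmask: bit s is 0 if the lineage in slot s is in
# population 1 and 1 if in population 2.


@lru_cache(maxsize=None)
def _pair_list(k: int) -> tuple[tuple[int, int], ...]:
    return tuple((i, j) for i in range(k) for j in range(i + 1, k))


@lru_cache(maxsize=None)
def _pair_index(k: int) -> dict[tuple[int, int], int]:
    return {p: c for c, p in enumerate(_pair_list(k))}


@lru_cache(maxsize=None)
def _pop2_counts(k: int) -> np.ndarray:
    """Number of pop-2 lineages for every k-bit configuration mask."""
    masks = np.arange(2**k)
    counts = np.zeros(2**k, dtype=np.int64)
    for i in range(k):
        counts += (masks >> i) & 1
    return counts


@lru_cache(maxsize=None)
def _merge_maps(k: int, code: int) -> tuple[np.ndarray, np.ndarray]:
    """0/1 matrices (A, B) mapping k-lineage masks to (k-1)-lineage masks.

    ``A[m, m']`` is 1 when in mask ``m`` the merging pair is co-located in
    population 1 and ``m'`` is the reduced mask; ``B`` likewise for
    population 2.  The coalescence operator is ``(2/theta1) A + (2/theta2) B``.
    """
    ia, ib = _pair_list(k)[code]
    A = np.zeros((2**k, 2 ** (k - 1)))
    B = np.zeros((2**k, 2 ** (k - 1)))
    for m in range(2**k):
        bi = (m >> ia) & 1
        bj = (m >> ib) & 1
        if bi != bj:
            continue
        reduced = (m & ((1 << ib) - 1)) | ((m >> (ib + 1)) << ib)
        (A if bi == 0 else B)[m, reduced] = 1.0
    return A, B


def _slot_events(
    tree: GeneTree, canonical: bool = False
) -> tuple[np.ndarray, tuple[int, ...], tuple[int, ...]]:
    """Encode a tree as (event times, per-event pair codes, initial slot pops).

    With ``canonical=True`` the assignment of same-population tips to slots is
    chosen so the code sequence is lexicographically minimal — the density is
    invariant under within-population relabeling, so canonical trees with the
    same codes can share computation.
    """
    k = tree.n_tips
    base = sorted(range(k), key=lambda i: (tree.tip_pops[i], tree.tip_labels[i]))
    pops = tuple(tree.tip_pops[i] for i in base)
    events = tree.coalescence_events()

    def codes_for(order: Sequence[int]) -> tuple[int, ...]:
        cur = list(order)
        out = []
        for _, a, b, parent in events:
            ia = cur.index(a)
            ib = cur.index(b)
            if ia > ib:
                ia, ib = ib, ia
            out.append(_pair_index(len(cur))[(ia, ib)])
            cur[ia] = parent
            cur.pop(ib)
        return tuple(out)

    orders = [base]
    if canonical:
        groups: dict[int, list[int]] = {}
        for i in base:
            groups.setdefault(tree.tip_pops[i], []).append(i)
        n_perms = math.prod(math.factorial(len(g)) for g in groups.values())
        if 1 < n_perms <= 24:
            pops_sorted = sorted(groups)
            orders = [
                list(itertools.chain.from_iterable(perm))
                for perm in itertools.product(
                    *(itertools.permutations(groups[p]) for p in pops_sorted)
                )
            ]
    codes = min(codes_for(o) for o in orders)
    times = np.array([e[0] for e in events], dtype=float)
    return times, codes, pops


def _initial_mask(pops: Sequence[int]) -> int:
    return sum((1 << s) for s, p in enumerate(pops) if p == 2)


# ---------------------------------------------------------------------------
# schedule (public plumbing)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventSchedule:
    """Time-ordered coalescences of a tree with the split time as a boundary.

    ``merges[e]`` is the slot pair merging at ``times[e]``; the first
    ``n_pre_split`` events fall strictly before ``tau`` (events at exactly
    ``tau`` count as ancestral-side).
    """

    times: tuple[float, ...]
    merges: tuple[tuple[int, int], ...]
    slot_pops: tuple[int, ...]
    tau: float

    @property
    def n_pre_split(self) -> int:
        return sum(1 for t in self.times if t < self.tau)


def build_schedule(tree: GeneTree, tau: float) -> EventSchedule:
    """Event schedule of ``tree`` relative to split time ``tau``.

    ``GeneTree`` stores node times directly, so ultrametricity holds by
    construction; external Newick input is validated by
    :func:`imcoal.io.parse_newick` before it becomes a ``GeneTree``.
    """
    if tau < 0 or not math.isfinite(tau):
        raise ValueError("tau must be finite and >= 0")
    times, codes, pops = _slot_events(tree)
    merges = tuple(_pair_list(k)[c] for k, c in zip(range(tree.n_tips, 1, -1), codes))
    return EventSchedule(
        times=tuple(times), merges=merges, slot_pops=pops, tau=float(tau)
    )


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _flip_indices(k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(from, to) mask pairs for single-lineage moves 1->2 and 2->1."""
    up_from, up_to, down_from, down_to = [], [], [], []
    for m in range(2**k):
        for i in range(k):
            if (m >> i) & 1:
                down_from.append(m)
                down_to.append(m & ~(1 << i))
            else:
                up_from.append(m)
                up_to.append(m | (1 << i))
    return tuple(np.array(a, dtype=np.intp) for a in (up_from, up_to, down_from, down_to))


def migration_generator(n_lineages: int, params: IMParams) -> np.ndarray:
    """Defective CTMC generator over the ``2^k`` lineage-location configurations.

    Entry ``Q[m, m']`` for masks differing in exactly one lineage's population
    is ``m1`` (that lineage in population 1) or ``m2`` (population 2); other
    off-diagonals are zero.  Diagonals subtract both the total migration
    hazard and the total coalescent hazard ``sum_p k_p (k_p - 1) / theta_p``,
    so propagated mass is P(location path and no coalescence).
    """
    if n_lineages < 1:
        raise ValueError("need at least one lineage")
    k = n_lineages
    S = 2**k
    Q = np.zeros((S, S))
    up_from, up_to, down_from, down_to = _flip_indices(k)
    if params.m1:
        np.add.at(Q, (up_from, up_to), params.m1)
    if params.m2:
        np.add.at(Q, (down_from, down_to), params.m2)
    n2 = _pop2_counts(k)
    n1 = k - n2
    coal = n1 * (n1 - 1) / params.theta1 + n2 * (n2 - 1) / params.theta2
    mig = n1 * params.m1 + n2 * params.m2
    Q[np.arange(S), np.arange(S)] = -(coal + mig)
    return Q


# ---------------------------------------------------------------------------
# per-tree reference density
# ---------------------------------------------------------------------------


def gene_tree_log_density(tree: GeneTree, params: IMParams) -> float:
    """Log-density of one labeled gene tree under the IM model (reference route)."""
    times, codes, pops = _slot_events(tree)
    return float(
        _reference_log_density(times, codes, pops, params)
    )


def _reference_log_density(times, codes, pops, params: IMParams) -> float:
    k = len(pops)
    tau = params.tau
    n_pre = int((times < tau).sum())
    v = np.zeros(2**k)
    v[_initial_mask(pops)] = 1.0
    log_acc = 0.0
    prev = 0.0
    kk = k
    for e in range(n_pre):
        Q = migration_generator(kk, params)
        v = v @ expm(Q * (times[e] - prev))
        A, B = _merge_maps(kk, codes[e])
        v = v @ (2.0 / params.theta1 * A + 2.0 / params.theta2 * B)
        peak = v.max()
        if peak <= 0.0:
            return _NEG_INF
        v /= peak
        log_acc += math.log(peak)
        prev = times[e]
        kk -= 1
    if n_pre < k - 1 and tau > prev:
        # survival (and location mixing) of the remaining lineages up to tau
        Q = migration_generator(kk, params)
        v = v @ expm(Q * (tau - prev))
    s = float(v.sum())
    if s <= 0.0:
        return _NEG_INF
    log_acc += math.log(s)
    prev = tau
    for e in range(n_pre, k - 1):
        log_acc += -kk * (kk - 1) * (times[e] - prev) / params.theta3 + math.log(
            2.0 / params.theta3
        )
        prev = times[e]
        kk -= 1
    return log_acc


# ---------------------------------------------------------------------------
# vectorized batch engine
# ---------------------------------------------------------------------------


class _EigUnreliable(Exception):
    """Raised when the spectral factorization is too ill-conditioned to trust."""


def _stage_propagators(k: int, params: IMParams):
    """Spectral factorizations of the generators for k, k-1, ..., 2 lineages.

    Returns, per stage, either ("diag", diagonal) when both migration rates
    are zero (the generator is diagonal) or ("eig", lam, V, Vinv).  The
    factorization is rejected when it fails to reproduce the generator to
    1e-8 relative accuracy (near-defective cases), in which case the caller
    switches to the scaling-and-squaring reference route.
    """
    out = {}
    for kk in range(k, 1, -1):
        Q = migration_generator(kk, params)
        if params.m1 == 0.0 and params.m2 == 0.0:
            out[kk] = ("diag", np.diag(Q).copy())
            continue
        lam, V = np.linalg.eig(Q)
        try:
            Vinv = np.linalg.inv(V)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - near-defective
            raise _EigUnreliable() from exc
        scale = np.abs(Q).max() or 1.0
        err = np.abs((V * lam) @ Vinv - Q).max() / scale
        if err > 1e-8:
            raise _EigUnreliable()
        out[kk] = ("eig", lam, V, Vinv)
    return out


def _propagate(prop, v: np.ndarray, dt: np.ndarray) -> np.ndarray:
    """Row-wise v[i] @ expm(Q * dt[i]) through a cached factorization."""
    if prop[0] == "diag":
        return v * np.exp(np.outer(dt, prop[1]))
    _, lam, V, Vinv = prop
    return ((v @ V) * np.exp(np.outer(dt, lam))) @ Vinv


def _batch_log_density(
    times: np.ndarray,
    codes: np.ndarray,
    pops: tuple[int, ...],
    params: IMParams,
) -> np.ndarray:
    """Log-densities for n trees sharing one tip configuration.

    times : (n, k-1) sorted event times per tree
    codes : (n, k-1) slot-pair code of each event
    """
    n, _ = times.shape
    k = len(pops)
    tau = params.tau
    props = _stage_propagators(k, params)

    n_pre = (times < tau).sum(axis=1)
    out = np.zeros(n)
    # ancestral-side factors, in closed form
    log_rate3 = math.log(2.0 / params.theta3)
    for e in range(k - 1):
        kk = k - e
        anc = n_pre <= e
        if not anc.any():
            continue
        prev = np.where(e == 0, 0.0, times[:, max(e - 1, 0)])
        prev = np.where(n_pre == e, tau, prev)
        out[anc] += (
            -kk * (kk - 1) * (times[anc, e] - prev[anc]) / params.theta3 + log_rate3
        )

    # pre-split CTMC propagation, stage-wise over the whole batch
    idx = np.arange(n)
    v = np.zeros((n, 2**k), dtype=complex if (params.m1 or params.m2) else float)
    v[:, _initial_mask(pops)] = 1.0
    logscale = np.zeros(n)
    prev_t = np.zeros(n)
    for e in range(k - 1):
        kk = k - e
        exiting = n_pre[idx] == e
        if exiting.any():
            sub = v[exiting]
            dt = tau - prev_t[idx[exiting]]
            if e < k - 1:  # survival of the kk remaining lineages up to tau
                sub = _propagate(props[kk], sub, dt)
            s = sub.sum(axis=1).real
            tgt = idx[exiting]
            with np.errstate(divide="ignore", invalid="ignore"):
                out[tgt] += np.where(
                    s > 0.0, logscale[tgt] + np.log(np.maximum(s, 1e-300)), _NEG_INF
                )
        stay = ~exiting
        if not stay.any():
            idx = idx[:0]
            break
        idx = idx[stay]
        v = v[stay]
        dt = times[idx, e] - prev_t[idx]
        v = _propagate(props[kk], v, dt)
        # observed coalescence: apply the merge operator per pair code
        w = np.zeros((v.shape[0], 2 ** (kk - 1)), dtype=v.dtype)
        stage_codes = codes[idx, e]
        for c in np.unique(stage_codes):
            A, B = _merge_maps(kk, int(c))
            T = (2.0 / params.theta1) * A + (2.0 / params.theta2) * B
            sel = stage_codes == c
            w[sel] = v[sel] @ T
        v = w
        peak = np.abs(v).max(axis=1)
        dead = peak <= 0.0
        if dead.any():
            out[idx[dead]] = _NEG_INF
            idx = idx[~dead]
            v = v[~dead]
            peak = peak[~dead]
        logscale[idx] += np.log(peak)
        v /= peak[:, None]
        prev_t[idx] = times[idx, e]
    if idx.size:
        # trees whose final coalescence precedes tau: remaining propagation is
        # migration-only and conserves mass, so the sum is taken directly
        s = v.sum(axis=1).real
        with np.errstate(divide="ignore"):
            out[idx] += np.where(
                s > 0.0, logscale[idx] + np.log(np.maximum(s, 1e-300)), _NEG_INF
            )
    return out


class LociLikelihood:
    """Joint log-likelihood of independent loci given their true gene trees.

    Loci are unlinked (free recombination between loci), so the joint
    log-likelihood is the sum of per-tree log-densities.  All trees must share
    one tip configuration (same number of tips per population); heterogeneous
    collections go through :func:`loci_log_likelihood` instead.
    """

    def __init__(self, trees: Sequence[GeneTree], canonicalize: bool = True):
        if not trees:
            raise ValueError("need at least one tree")
        self.trees = list(trees)
        k = trees[0].n_tips
        pops0 = tuple(sorted(trees[0].tip_pops))
        encoded = []
        for t in trees:
            if t.n_tips != k or tuple(sorted(t.tip_pops)) != pops0:
                raise ValueError("all trees must share one tip configuration")
            encoded.append(_slot_events(t, canonical=canonicalize))
        self._pops = encoded[0][2]
        self._times = np.array([e[0] for e in encoded])
        self._codes = np.array([e[1] for e in encoded], dtype=np.int64)

    @property
    def n_loci(self) -> int:
        return len(self.trees)

    def per_tree_log_density(self, params: IMParams) -> np.ndarray:
        try:
            return _batch_log_density(self._times, self._codes, self._pops, params)
        except _EigUnreliable:
            return np.array(
                [
                    _reference_log_density(self._times[i], tuple(self._codes[i]), self._pops, params)
                    for i in range(len(self.trees))
                ]
            )

    def log_likelihood(self, params: IMParams) -> float:
        return float(self.per_tree_log_density(params).sum())


def loci_log_likelihood(trees: Sequence[GeneTree], params: IMParams) -> float:
    """Sum of gene-tree log-densities over independent loci (-inf if any is impossible)."""
    if not trees:
        raise ValueError("need at least one tree")
    try:
        return LociLikelihood(trees).log_likelihood(params)
    except ValueError:
        return float(sum(gene_tree_log_density(t, params) for t in trees))
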