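"""Labeled ultrametric gene trees.

A :class:`GeneTree` is a rooted binary genealogy over labeled tips, each tip
carrying a population label (1 or 2), with internal-node times measured in
mutational units (tips sit at time 0, the root at the TMRCA).  Branch lengths
are derived quantities (parent time minus child time), so the container is
ultrametric by construction; parsing external Newick strings goes through
:func:`imcoal.io.parse_newick`, which validates ultrametricity.

Node numbering convention: for ``k`` tips, nodes ``0 .. k-1`` are the tips and
nodes ``k .. 2k-2`` the internal nodes in order of strictly increasing time
(node ``2k-2`` is the root).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["GeneTree", "tip_label", "parse_tip_label"]


def tip_label(pop: int, index: int) -> str:
    """Canonical tip label carrying the population: ``P<pop>_<index>``."""
    return f"P{pop}_{index}"


def parse_tip_label(label: str) -> int:
    """Population encoded in a ``P<pop>_<index>`` tip label."""
    if not label.startswith("P") or "_" not in label:
        raise ValueError(f"tip label {label!r} does not follow 'P<pop>_<index>'")
    try:
        pop = int(label[1:].split("_", 1)[0])
    except ValueError as exc:
        raise ValueError(f"tip label {label!r} does not follow 'P<pop>_<index>'") from exc
    if pop not in (1, 2):
        raise ValueError(f"tip label {label!r}: population must be 1 or 2")
    return pop


@dataclass(frozen=True)
class GeneTree:
    """Rooted binary ultrametric genealogy with tip population labels.

    Parameters
    ----------
    tip_labels
        Label of each tip, indexed ``0 .. k-1``.
    tip_pops
        Population (1 or 2) of each tip, same order.
    children
        ``children[j]`` is the pair of child node ids of internal node
        ``k + j``; child ids are always smaller than the parent id.
    times
        Time of each internal node (mutational units), strictly increasing.
    """

    tip_labels: tuple[str, ...]
    tip_pops: tuple[int, ...]
    children: tuple[tuple[int, int], ...]
    times: tuple[float, ...]

    def __post_init__(self) -> None:
        k = len(self.tip_labels)
        if k < 2:
            raise ValueError("a gene tree needs at least 2 tips")
        if len(self.tip_pops) != k:
            raise ValueError("tip_pops must match tip_labels")
        if any(p not in (1, 2) for p in self.tip_pops):
            raise ValueError("populations must be 1 or 2")
        if len(self.children) != k - 1 or len(self.times) != k - 1:
            raise ValueError("a binary tree over k tips has k-1 internal nodes")
        seen = set()
        for j, (a, b) in enumerate(self.children):
            parent = k + j
            if a == b or a >= parent or b >= parent or a < 0 or b < 0:
                raise ValueError("children ids must be distinct and precede the parent")
            if a in seen or b in seen:
                raise ValueError("a node may have only one parent")
            seen.update((a, b))
            for c in (a, b):
                if self.node_time(c) >= self.times[j]:
                    raise ValueError("node times must strictly increase towards the root")
        if list(self.times) != sorted(self.times):
            raise ValueError("internal nodes must be ordered by time")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def root(self) -> int:
        return 2 * self.n_tips - 2

    @property
    def tmrca(self) -> float:
        return self.times[-1]

    def node_time(self, node: int) -> float:
        return 0.0 if node < self.n_tips else self.times[node - self.n_tips]

    def coalescence_events(self) -> list[tuple[float, int, int, int]]:
        """Events as ``(time, child_a, child_b, parent)``, oldest last."""
        k = self.n_tips
        return [(t, a, b, k + j) for j, ((a, b), t) in enumerate(zip(self.children, self.times))]

    def clade(self, node: int) -> frozenset[int]:
        """Tip ids below ``node`` (inclusive for tips)."""
        if node < self.n_tips:
            return frozenset((node,))
        a, b = self.children[node - self.n_tips]
        return self.clade(a) | self.clade(b)

    def mrca_time(self, tip_a: int, tip_b: int) -> float:
        """Coalescence time of two tips: the time of their most recent common ancestor."""
        want = {tip_a, tip_b}
        for j in range(self.n_tips - 1):
            if want <= self.clade(self.n_tips + j):
                return self.times[j]
        raise ValueError("tips not in tree")  # pragma: no cover

    # -- construction ------------------------------------------------------

    @classmethod
    def from_events(
        cls,
        tip_labels: Sequence[str],
        tip_pops: Sequence[int],
        events: Sequence[tuple[float, int, int]],
    ) -> "GeneTree":
        """Build a tree from time-ordered merge events.

        ``events[j] = (time, a, b)`` merges nodes ``a`` and ``b`` (ids as in
        the node-numbering convention) into new node ``k + j``.
        """
        ev = sorted(events, key=lambda e: e[0])
        return cls(
            tip_labels=tuple(tip_labels),
            tip_pops=tuple(int(p) for p in tip_pops),
            children=tuple((a, b) for _, a, b in ev),
            times=tuple(float(t) for t, _, _ in ev),
        )

    def relabel(self, mapping: dict[str, str]) -> "GeneTree":
        """Return a copy with tip labels replaced through ``mapping``."""
        return GeneTree(
            tip_labels=tuple(mapping.get(l, l) for l in self.tip_labels),
            tip_pops=self.tip_pops,
            children=self.children,
            times=self.times,
        )

    # -- output ------------------------------------------------------------

    def to_newick(self, precision: int = 12) -> str:
        """Newick string with branch lengths in mutational units."""

        def fmt(x: float) -> str:
            return f"{x:.{precision}g}"

        def render(node: int) -> str:
            if node < self.n_tips:
                return self.tip_labels[node]
            a, b = self.children[node - self.n_tips]
            t = self.node_time(node)
            return (
                f"({render(a)}:{fmt(t - self.node_time(a))},"
                f"{render(b)}:{fmt(t - self.node_time(b))})"
            )

        return render(self.root) + ";"
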