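"""Random-interval sampling of non-recombined blocks.

One locus with recombination carries several non-recombined blocks, each with
its own marginal gene tree.  The study design analyzes a single block per
locus, chosen at random.  The default draws uniformly over blocks (each of the
``B`` blocks with probability ``1/B``, regardless of length); an optional
length-weighted mode draws blocks proportionally to their share of the unit
interval, which is what picking a uniform position on the locus would do.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .simulate import ARGLocus
from .trees import GeneTree

__all__ = ["sample_block", "sample_blocks"]


def sample_block(
    locus: ARGLocus,
    rng: np.random.Generator,
    length_weighted: bool = False,
) -> GeneTree:
    """Gene tree of one randomly selected non-recombined block.

    Deterministic given the generator's state; the returned object is the
    block's tree itself, not a copy.
    """
    if locus.n_blocks == 0:
        raise ValueError("locus has no blocks")
    if locus.n_blocks == 1:
        return locus.blocks[0][2]
    if length_weighted:
        widths = np.array([end - start for start, end, _ in locus.blocks])
        choice = rng.choice(locus.n_blocks, p=widths / widths.sum())
    else:
        choice = rng.integers(locus.n_blocks)
    return locus.blocks[int(choice)][2]


def sample_blocks(
    loci: Sequence[ARGLocus],
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    length_weighted: bool = False,
) -> list[GeneTree]:
    """One block tree per locus, drawn with a single seeded generator."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return [sample_block(locus, rng, length_weighted=length_weighted) for locus in loci]
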