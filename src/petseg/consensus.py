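"""Voxel-wise majority-vote consensus of the four standard delineations.

If enough of the standard operators agree that a voxel belongs to a lesion,
the consensus includes it: MV2 keeps voxels selected by at least two of the
four methods, MV3 by at least three.  Voting is computed over whole-body
masks; lesions of a consensus mask are re-derived afterwards by connected
components, so a consensus component need not coincide with any single
method's component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .image_model import BinaryMask, Grid

__all__ = ["VoteMap", "vote", "consensus_mask", "majority_vote"]


@dataclass(frozen=True)
class VoteMap:
    """Per-voxel count of agreeing source masks."""

    counts: np.ndarray          # integer field in {0..n_sources}
    grid: Grid
    sources: tuple[str, ...]    # ordered labels of the contributing methods

    @property
    def n_sources(self) -> int:
        return len(self.sources)


def vote(masks: Sequence[BinaryMask], sources: Sequence[str] | None = None) -> VoteMap:
    """Sum the indicator fields of masks sharing one grid.

    The count at a voxel is exactly the number of masks containing it, so
    it is invariant under permutation of the inputs.
    """
    if len(masks) == 0:
        raise ValueError("need at least one mask to vote")
    grid = masks[0].grid
    for m in masks[1:]:
        grid.require_match(m.grid)
    counts = np.zeros(grid.shape, dtype=np.int16)
    for m in masks:
        counts += m.values
    if sources is None:
        sources = tuple(f"mask{i + 1}" for i in range(len(masks)))
    return VoteMap(counts, grid, tuple(sources))


def consensus_mask(votes: VoteMap, min_votes: int) -> BinaryMask:
    """Voxels with at least ``min_votes`` agreeing sources.

    ``min_votes=1`` is the union of the sources, ``min_votes=n_sources`` the
    intersection; MV2 and MV3 are ``min_votes`` 2 and 3 over the four
    standard methods.  Monotone: raising ``min_votes`` never adds a voxel.
    """
    if not 1 <= min_votes <= votes.n_sources:
        raise ValueError(
            f"min_votes must be in 1..{votes.n_sources}, got {min_votes}"
        )
    return BinaryMask(votes.counts >= min_votes, votes.grid)


def majority_vote(masks: Sequence[BinaryMask], min_votes: int) -> BinaryMask:
    """Convenience: ``consensus_mask(vote(masks), min_votes)``."""
    return consensus_mask(vote(masks), min_votes)
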