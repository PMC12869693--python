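"""Immutable run-length tag array with run-start markers.

``starts`` is the sorted vector of run start positions [0, L1, L1+L2, ...]
(the sparse-bitvector contract: space proportional to the number of runs,
logarithmic rank via binary search) and ``tags`` holds one (v, o, b) triple
per run.  ``tag_at_row`` and ``distinct_tags`` are the two-rank queries; they
touch O(overlapping runs + log r) structure elements, never the interval
width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import IntegrityError
from .graph import GAP_TAG, SENTINEL_TAG, GraphPosition
from .index import LexInterval
from .rlbtree import RLBTree


@dataclass
class TagArray:
    starts: np.ndarray  # (r,) int64, strictly increasing, starts[0] == 0
    tags: np.ndarray    # (r, 3) int64 triples (v, o, b)
    N: int
    #: structure elements touched by the last distinct_tags call (runs
    #: collected + binary-search steps); used to assert output-sensitivity.
    last_query_cost: int = field(default=0, compare=False)

    @property
    def run_count(self) -> int:
        return len(self.starts)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TagArray)
            and self.N == other.N
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.tags, other.tags)
        )

    # ------------------------------------------------------------------
    def _run_of(self, i: int) -> int:
        """rank1(starts, i+1) - 1: index of the run containing row i."""
        return int(np.searchsorted(self.starts, i, side="right")) - 1

    def tag_at_row(self, i: int) -> GraphPosition:
        if not 0 <= i < self.N:
            raise ValueError(f"row {i} out of range [0, {self.N})")
        return GraphPosition(*self.tags[self._run_of(i)])

    def distinct_tags(self, iv: LexInterval) -> list[GraphPosition]:
        """Sorted, deduplicated real tags over the rows of ``iv``.

        Two rank queries delimit the overlapping runs; reserved tags
        (end-marker rows) are filtered out.
        """
        if iv.empty:
            self.last_query_cost = 0
            return []
        if not (0 <= iv.a and iv.b < self.N):
            raise ValueError(f"interval {iv} out of bounds [0, {self.N})")
        j0 = self._run_of(iv.a)
        j1 = self._run_of(iv.b)
        sub = self.tags[j0 : j1 + 1]
        self.last_query_cost = (j1 - j0 + 1) + 2 * (
            int(math.log2(self.run_count)) + 1
        )
        uniq = np.unique(sub, axis=0)
        return [GraphPosition(*row) for row in uniq if row[0] != 0]

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "starts": self.starts.tolist(),
            "tags": self.tags.reshape(-1).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TagArray":
        tags = np.asarray(d["tags"], dtype=np.int64).reshape(-1, 3)
        return cls(
            starts=np.asarray(d["starts"], dtype=np.int64),
            tags=tags,
            N=int(d["N"]),
        )

    @classmethod
    def from_runs(cls, runs: list[tuple[int, GraphPosition]], N: int) -> "TagArray":
        """Build from (start, tag) pairs, coalescing adjacent equal tags."""
        starts: list[int] = []
        tags: list[GraphPosition] = []
        for start, tag in runs:
            if tags and tags[-1] == tag:
                continue
            starts.append(start)
            tags.append(tag)
        return cls(
            starts=np.asarray(starts, dtype=np.int64),
            tags=np.asarray(tags, dtype=np.int64).reshape(-1, 3),
            N=N,
        )

    def expand(self) -> np.ndarray:
        """Per-row (N, 3) tag matrix; test/debug helper, O(N) space."""
        ends = np.concatenate((self.starts[1:], [self.N]))
        return np.repeat(self.tags, ends - self.starts, axis=0)


def freeze(tree: RLBTree) -> TagArray:
    """Freeze a fully covered RLB+ tree into the immutable query structure."""
    runs = []
    for start, tag in tree.iterate_runs():
        if tag == SENTINEL_TAG and start == tree.N:
            continue
        if tag == GAP_TAG:
            raise IntegrityError(f"GAP run at row {start}: tree is not fully covered")
        runs.append((start, tag))
    return TagArray.from_runs(runs, tree.N)
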