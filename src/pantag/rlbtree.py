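"""Run-Length B+ tree: the mutable tag array used during construction.

The tree is an ordered map from BWT start positions to tags; run lengths are
implicit (difference of successive starts).  Unassigned rows are materialized
as runs carrying the reserved GAP tag, so the run sequence always partitions
``[0, N)``; a sentinel entry at position ``N`` terminates the sequence.

Insertion applies the four merge cases (no merge / forward / backward /
bidirectional) and, because bidirectional merges can shrink a leaf below its
minimum occupancy, a borrow-then-merge rebalancing that can propagate to the
root.  Deletion of runs is never exposed publicly; it is used internally when
an inserted range subsumes existing entries.
"""

from __future__ import annotations

from bisect import bisect_right, insort
from typing import Iterator, NamedTuple

from .errors import ConflictError
from .graph import GAP_TAG, SENTINEL_TAG, GraphPosition


class TagRun(NamedTuple):
    start: int
    tag: GraphPosition


class _Leaf:
    __slots__ = ("entries", "prev", "next", "parent")

    def __init__(self):
        self.entries: list[tuple[int, GraphPosition]] = []
        self.prev: _Leaf | None = None
        self.next: _Leaf | None = None
        self.parent: _Internal | None = None

    @property
    def is_leaf(self):
        return True


class _Internal:
    __slots__ = ("keys", "children", "parent")

    def __init__(self):
        self.keys: list[int] = []       # keys[i] separates children[i] / children[i+1]
        self.children: list = []
        self.parent: _Internal | None = None

    @property
    def is_leaf(self):
        return False


class RLBTree:
    """Mutable run-length tag map over the BWT domain [0, N)."""

    def __init__(self, N: int, degree: int = 64):
        if N < 1:
            raise ValueError(f"domain size must be >= 1, got {N}")
        if degree < 4:
            raise ValueError(f"degree must be >= 4, got {degree}")
        self.N = N
        self.degree = degree
        self.min_fill = (degree + 1) // 2
        root = _Leaf()
        root.entries = [(0, GAP_TAG), (N, SENTINEL_TAG)]
        self.root: _Leaf | _Internal = root
        self.first_leaf = root
        self.covered_count = 0
        self.node_visits = 0  # incremented per node touched on descent

    # ------------------------------------------------------------------
    @property
    def run_count(self) -> int:
        """Number of runs, including GAP runs and the sentinel."""
        n = 0
        leaf = self.first_leaf
        while leaf is not None:
            n += len(leaf.entries)
            leaf = leaf.next
        return n

    def _find_leaf(self, pos: int) -> _Leaf:
        node = self.root
        self.node_visits += 1
        while not node.is_leaf:
            idx = bisect_right(node.keys, pos)
            node = node.children[idx]
            self.node_visits += 1
        return node

    def tag_at(self, i: int) -> GraphPosition:
        if not 0 <= i < self.N:
            raise ValueError(f"row {i} out of domain [0, {self.N})")
        leaf = self._find_leaf(i)
        idx = bisect_right(leaf.entries, (i, GraphPosition(1 << 62, 0, 0))) - 1
        if idx < 0:
            # i precedes the first entry of this leaf: the covering run lives
            # in the previous leaf (can happen transiently during rewrites).
            leaf = leaf.prev
            idx = len(leaf.entries) - 1
        return leaf.entries[idx][1]

    def iterate_runs(self) -> Iterator[TagRun]:
        leaf = self.first_leaf
        while leaf is not None:
            for start, tag in leaf.entries:
                yield TagRun(start, tag)
            leaf = leaf.next

    def runs(self) -> list[TagRun]:
        return list(self.iterate_runs())

    # ------------------------------------------------------------------
    # Internal structural primitives

    def _insert_entry(self, key: int, tag: GraphPosition) -> None:
        leaf = self._find_leaf(key)
        insort(leaf.entries, (key, tag))
        if len(leaf.entries) > self.degree:
            self._split_leaf(leaf)

    def _split_leaf(self, leaf: _Leaf) -> None:
        mid = len(leaf.entries) // 2
        right = _Leaf()
        right.entries = leaf.entries[mid:]
        leaf.entries = leaf.entries[:mid]
        right.next = leaf.next
        right.prev = leaf
        if leaf.next is not None:
            leaf.next.prev = right
        leaf.next = right
        self._insert_into_parent(leaf, right.entries[0][0], right)

    def _insert_into_parent(self, left, key: int, right) -> None:
        parent = left.parent
        if parent is None:
            new_root = _Internal()
            new_root.keys = [key]
            new_root.children = [left, right]
            left.parent = new_root
            right.parent = new_root
            self.root = new_root
            return
        idx = parent.children.index(left)
        parent.keys.insert(idx, key)
        parent.children.insert(idx + 1, right)
        right.parent = parent
        if len(parent.children) > self.degree:
            self._split_internal(parent)

    def _split_internal(self, node: _Internal) -> None:
        mid = len(node.children) // 2
        right = _Internal()
        push_key = node.keys[mid - 1]
        right.keys = node.keys[mid:]
        right.children = node.children[mid:]
        node.keys = node.keys[: mid - 1]
        node.children = node.children[:mid]
        for ch in right.children:
            ch.parent = right
        self._insert_into_parent(node, push_key, right)

    def _delete_entry_at(self, leaf: _Leaf, idx: int) -> None:
        del leaf.entries[idx]
        self._rebalance_leaf(leaf)

    def _rebalance_leaf(self, leaf: _Leaf) -> None:
        if leaf.parent is None or len(leaf.entries) >= self.min_fill:
            return
        parent = leaf.parent
        idx = parent.children.index(leaf)
        # Borrow from a sibling under the same parent if possible.
        if idx > 0 and len(parent.children[idx - 1].entries) > self.min_fill:
            left = parent.children[idx - 1]
            leaf.entries.insert(0, left.entries.pop())
            parent.keys[idx - 1] = leaf.entries[0][0]
            return
        if idx + 1 < len(parent.children) and len(parent.children[idx + 1].entries) > self.min_fill:
            right = parent.children[idx + 1]
            leaf.entries.append(right.entries.pop(0))
            parent.keys[idx] = right.entries[0][0]
            return
        # Merge with a sibling.
        if idx > 0:
            left, right, kidx = parent.children[idx - 1], leaf, idx - 1
        else:
            left, right, kidx = leaf, parent.children[idx + 1], idx
        left.entries.extend(right.entries)
        left.next = right.next
        if right.next is not None:
            right.next.prev = left
        del parent.keys[kidx]
        del parent.children[kidx + 1]
        self._rebalance_internal(parent)

    def _rebalance_internal(self, node: _Internal) -> None:
        if node.parent is None:
            if len(node.children) == 1:
                self.root = node.children[0]
                self.root.parent = None
            return
        if len(node.children) >= self.min_fill:
            return
        parent = node.parent
        idx = parent.children.index(node)
        if idx > 0 and len(parent.children[idx - 1].children) > self.min_fill:
            left = parent.children[idx - 1]
            node.keys.insert(0, parent.keys[idx - 1])
            parent.keys[idx - 1] = left.keys.pop()
            moved = left.children.pop()
            moved.parent = node
            node.children.insert(0, moved)
            return
        if idx + 1 < len(parent.children) and len(parent.children[idx + 1].children) > self.min_fill:
            right = parent.children[idx + 1]
            node.keys.append(parent.keys[idx])
            parent.keys[idx] = right.keys.pop(0)
            moved = right.children.pop(0)
            moved.parent = node
            node.children.append(moved)
            return
        if idx > 0:
            left, right, kidx = parent.children[idx - 1], node, idx - 1
        else:
            left, right, kidx = node, parent.children[idx + 1], idx
        left.keys.append(parent.keys[kidx])
        left.keys.extend(right.keys)
        for ch in right.children:
            ch.parent = left
        left.children.extend(right.children)
        del parent.keys[kidx]
        del parent.children[kidx + 1]
        self._rebalance_internal(parent)

    # ------------------------------------------------------------------
    def _entry_leq(self, pos: int) -> tuple[_Leaf | None, int]:
        """(leaf, idx) of the last entry with start <= pos, or (None, -1)."""
        leaf = self._find_leaf(pos)
        idx = bisect_right(leaf.entries, (pos, GraphPosition(1 << 62, 0, 0))) - 1
        while idx < 0:
            leaf = leaf.prev
            if leaf is None:
                return None, -1
            idx = len(leaf.entries) - 1
        return leaf, idx

    def insert_run(
        self,
        start: int,
        length: int,
        tag: GraphPosition,
        overwrite: bool = False,
    ) -> None:
        """Assign ``tag`` to rows [start, start+length).

        Rows that were GAP become tagged; rows already carrying ``tag`` are
        absorbed (idempotent); rows carrying a different tag raise
        ConflictError unless ``overwrite``.  Merges with equal-tagged
        neighbors follow the four-way rule.
        """
        if length < 1:
            raise ValueError(f"run length must be >= 1, got {length}")
        if tag == GAP_TAG:
            raise ValueError("cannot insert the reserved GAP tag")
        end = start + length
        if not (0 <= start and end <= self.N):
            raise ValueError(f"run [{start}, {end}) out of domain [0, {self.N})")

        # Scan the overlapped runs: count GAP rows converted and detect
        # conflicts before mutating anything.
        leaf, idx = self._entry_leq(start)
        pos = start
        gap_rows = 0
        while pos < end:
            run_start, run_tag = leaf.entries[idx]
            nxt = self._next_start(leaf, idx)
            seg_end = min(nxt, end)
            if run_tag == GAP_TAG:
                gap_rows += seg_end - pos
            elif run_tag != tag and not overwrite:
                raise ConflictError(
                    f"rows [{pos}, {seg_end}) already tagged {run_tag}, "
                    f"refusing to overwrite with {tag}"
                )
            pos = seg_end
            leaf, idx = self._advance(leaf, idx)

        t_before = self.tag_at(start - 1) if start > 0 else None
        t_after = self.tag_at(end) if end < self.N else SENTINEL_TAG
        has_entry_at_end = end < self.N and self._has_entry_at(end)

        # Remove every entry whose start lies inside [start, end).
        while True:
            leaf, idx = self._entry_leq(end - 1)
            if leaf is None or leaf.entries[idx][0] < start:
                break
            self._delete_entry_at(leaf, idx)

        if end < self.N:
            if has_entry_at_end:
                if t_after == tag:  # backward merge
                    leaf, idx = self._entry_leq(end)
                    self._delete_entry_at(leaf, idx)
            elif t_after != tag:
                self._insert_entry(end, t_after)
        if t_before != tag:  # no forward merge
            self._insert_entry(start, tag)
        self.covered_count += gap_rows

    def _has_entry_at(self, pos: int) -> bool:
        leaf, idx = self._entry_leq(pos)
        return leaf is not None and leaf.entries[idx][0] == pos

    @staticmethod
    def _next_start(leaf: _Leaf, idx: int) -> int:
        if idx + 1 < len(leaf.entries):
            return leaf.entries[idx + 1][0]
        nxt = leaf.next
        while nxt is not None and not nxt.entries:
            nxt = nxt.next
        return nxt.entries[0][0]

    @staticmethod
    def _advance(leaf: _Leaf, idx: int) -> tuple[_Leaf, int]:
        if idx + 1 < len(leaf.entries):
            return leaf, idx + 1
        nxt = leaf.next
        while nxt is not None and not nxt.entries:
            nxt = nxt.next
        return nxt, 0

    # ------------------------------------------------------------------
    def audit(self) -> None:
        """Walk the whole tree checking structural invariants; raises
        AssertionError with a description on violation."""
        # Uniform leaf depth and occupancy.
        depths = set()

        def walk(node, depth, lo, hi):
            if node.is_leaf:
                depths.add(depth)
                if node is not self.root:
                    assert self.min_fill <= len(node.entries) <= self.degree, (
                        f"leaf occupancy {len(node.entries)} outside "
                        f"[{self.min_fill}, {self.degree}]"
                    )
                for k, _ in node.entries:
                    assert lo <= k < hi, f"leaf key {k} outside [{lo}, {hi})"
                keys = [k for k, _ in node.entries]
                assert keys == sorted(set(keys)), "leaf keys not strictly increasing"
            else:
                if node is not self.root:
                    assert self.min_fill <= len(node.children) <= self.degree, (
                        f"internal fanout {len(node.children)} outside bounds"
                    )
                else:
                    assert len(node.children) >= 2, "internal root with < 2 children"
                assert len(node.keys) == len(node.children) - 1
                assert node.keys == sorted(node.keys)
                bounds = [lo] + node.keys + [hi]
                for i, ch in enumerate(node.children):
                    assert ch.parent is node, "broken parent pointer"
                    walk(ch, depth + 1, bounds[i], bounds[i + 1])

        walk(self.root, 0, 0, self.N + 1)
        assert len(depths) == 1, f"leaves at different depths: {depths}"

        flat = self.runs()
        starts = [r.start for r in flat]
        assert starts[0] == 0, "first run must start at 0"
        assert starts == sorted(set(starts)), "run starts not strictly increasing"
        assert flat[-1] == TagRun(self.N, SENTINEL_TAG), "missing sentinel run"
        covered = 0
        for (s1, t1), (s2, t2) in zip(flat, flat[1:]):
            assert t1 != t2, f"adjacent runs at {s1}/{s2} share tag {t1}"
            if t1 != GAP_TAG:
                covered += s2 - s1
        assert covered == self.covered_count, (
            f"covered_count {self.covered_count} != recount {covered}"
        )
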