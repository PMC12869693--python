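"""Sampled tag array at node starts and one-to-all coordinate translation.

Only tag runs whose graph offset is o = 0 (node-start positions, either
orientation) are kept, each with its BWT interval; everything else is a gap
region.  A value index maps each kept tag to the sampled runs carrying it, so
translation can enumerate every haplotype passing through a node start.

The translation query maps an interval [p, q) on one indexed sequence to all
(sequence, offset) pairs that traverse the same node-start graph positions:
phase 1 walks the interval backwards with LF collecting sampled tags, phase 2
locates every BWT interval carrying each tag.  Resolution is node starts:
an interval crossing no node start translates to nothing (sub-node offsets
are the caller's arithmetic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import GraphPosition
from .index import LexInterval, MSBWTIndex
from .tagarray import TagArray


@dataclass
class SampledTagArray:
    starts: np.ndarray  # (s,) BWT start of each sampled run, increasing
    ends: np.ndarray    # (s,) exclusive BWT end of each sampled run
    tags: np.ndarray    # (s, 3)
    N: int
    value_index: dict[GraphPosition, list[int]] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.starts)

    def run_containing(self, row: int) -> int | None:
        """Index of the sampled run covering a BWT row, or None (gap)."""
        j = int(np.searchsorted(self.starts, row, side="right")) - 1
        if j >= 0 and row < self.ends[j]:
            return j
        return None

    def runs_with_tag(self, tag: GraphPosition) -> list[int]:
        return self.value_index.get(tag, [])


def build_sampled(arr: TagArray) -> SampledTagArray:
    """Keep exactly the runs whose tag has o = 0 (real nodes only)."""
    run_ends = np.concatenate((arr.starts[1:], [arr.N]))
    mask = (arr.tags[:, 1] == 0) & (arr.tags[:, 0] != 0)
    starts = arr.starts[mask]
    ends = run_ends[mask]
    tags = arr.tags[mask]
    value_index: dict[GraphPosition, list[int]] = {}
    for j, row in enumerate(tags):
        value_index.setdefault(GraphPosition(*row), []).append(j)
    return SampledTagArray(starts, ends, tags, arr.N, value_index)


def find_tags(
    index: MSBWTIndex, sampled: SampledTagArray, sid: int, p: int, q: int
) -> list[tuple[int, GraphPosition]]:
    """Phase 1: node-start tags traversed by [p, q) on sequence ``sid``,
    as (offset within the interval, tag) in ascending offset order."""
    L = int(index.text.lengths[sid])
    if not (0 <= p < q <= L):
        raise ValueError(f"bad interval [{p}, {q}) for sequence {sid} of length {L}")
    out: list[tuple[int, GraphPosition]] = []
    row = index.row_of_seq_pos(sid, q - 1)
    j = q - 1
    while True:
        k = sampled.run_containing(row)
        if k is not None:
            out.append((j - p, GraphPosition(*sampled.tags[k])))
        if j == p:
            break
        row = index.lf(row)
        j -= 1
    out.reverse()
    return out


def find_sequences(
    index: MSBWTIndex, sampled: SampledTagArray, tag: GraphPosition
) -> list[tuple[int, int]]:
    """Phase 2: every (sequence, offset) whose suffix starts at ``tag``.

    Each sampled run with this tag value is a BWT interval whose rows all
    carry the tag; locating them enumerates the haplotype positions."""
    if tag.o != 0:
        raise ValueError(f"tag {tag} is not a node-start position (o != 0)")
    pairs: list[tuple[int, int]] = []
    for k in sampled.runs_with_tag(tag):
        iv = LexInterval(int(sampled.starts[k]), int(sampled.ends[k]) - 1)
        pairs.extend(index.locate_all(iv))
    pairs.sort()
    return pairs


@dataclass
class TranslationEntry:
    query_offset: int            # offset of the node start within [p, q)
    tag: GraphPosition
    matches: list[tuple[int, int, bool]]  # (sid', offset', is_other)


@dataclass
class TranslationReport:
    sid: int
    p: int
    q: int
    entries: list[TranslationEntry]

    def pairs(self, include_self: bool = True) -> dict[int, list[tuple[int, int]]]:
        out: dict[int, list[tuple[int, int]]] = {}
        for e in self.entries:
            out[e.query_offset] = [
                (s, o) for s, o, other in e.matches if include_self or other
            ]
        return out


def translate(
    index: MSBWTIndex, sampled: SampledTagArray, sid: int, p: int, q: int
) -> TranslationReport:
    """Two-phase one-to-all translation; the query sequence's own hits are
    kept (is_other = False) for verification."""
    entries = []
    for offset, tag in find_tags(index, sampled, sid, p, q):
        matches = [
            (s, o, s != sid) for s, o in find_sequences(index, sampled, tag)
        ]
        entries.append(TranslationEntry(offset, tag, matches))
    return TranslationReport(sid, p, q, entries)
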