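"""Maximal-exact-match enumeration over the bidirectional index.

For every query start the longest match is grown by forward bi-directional
extension; a candidate [i, e) is a MEM iff it is long enough and the match
starting one position earlier ends strictly before e (left-maximality).
Matching against forward sequences suffices because the reverse complements
are indexed.  'N' in the query never matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph import GraphPosition
from .index import LexInterval, MSBWTIndex
from .tagarray import TagArray


@dataclass
class MEM:
    q_start: int
    q_end: int
    iv: LexInterval
    tags: list[GraphPosition] | None = field(default=None)

    @property
    def length(self) -> int:
        return self.q_end - self.q_start


def find_mems(index: MSBWTIndex, query: str, lmin: int = 1) -> list[MEM]:
    """All maximal exact matches of length >= lmin, sorted by query start."""
    if lmin < 1:
        raise ValueError(f"lmin must be >= 1, got {lmin}")
    L = len(query)
    ends = [0] * L          # ends[i]: end of the longest match starting at i
    ivs: list[LexInterval] = [LexInterval(0, -1)] * L
    for i in range(L):
        bi = index.bi_all()
        e = i
        # Matches shrink by at most the dropped character: restarting the
        # forward extension from scratch is quadratic but contract-exact.
        while e < L and query[e] != "N":
            nxt = index.bi_extend_forward(bi, query[e])
            if nxt.empty:
                break
            bi = nxt
            e += 1
        ends[i] = e
        ivs[i] = bi.fwd if e > i else LexInterval(0, -1)
    out = []
    for i in range(L):
        e = ends[i]
        if e - i < lmin:
            continue
        if i > 0 and ends[i - 1] >= e:
            continue  # not left-maximal
        out.append(MEM(i, e, ivs[i]))
    return out


def mems_with_tags(
    index: MSBWTIndex, arr: TagArray, query: str, lmin: int = 1
) -> list[MEM]:
    """MEMs annotated with the distinct graph positions of their intervals."""
    mems = find_mems(index, query, lmin)
    for m in mems:
        m.tags = arr.distinct_tags(m.iv)
    return mems
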