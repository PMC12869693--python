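"""Naive reference implementations used as independent oracles.

Everything here is deliberately brute-force and shares no code with the
index machinery under test: suffix sorting is a plain Python sort over byte
slices, tag arrays are built by listing walk positions in text order and
permuting with the naive suffix array, MEMs are enumerated by checking all
substrings, and translation maps come straight from the walks.
"""

from __future__ import annotations

from pantag.graph import END_TAG, GraphPosition

# Sentinel byte codes: sequence i gets byte i+1 (all below 'A' = 65).
_BASE = 1


def concat_with_sentinels(seqs: list[str]) -> bytes:
    assert len(seqs) < 60, "too many sequences for byte sentinels"
    out = bytearray()
    for i, s in enumerate(seqs):
        out += s.encode()
        out.append(_BASE + i)
    return bytes(out)


def naive_sa(seqs: list[str]) -> list[int]:
    t = concat_with_sentinels(seqs)
    return sorted(range(len(t)), key=lambda i: t[i:])


def naive_bwt(seqs: list[str]) -> str:
    """BWT string with all end-markers collapsed to '$'."""
    t = concat_with_sentinels(seqs)
    sa = naive_sa(seqs)
    out = []
    for i in sa:
        c = t[i - 1]
        out.append("$" if c < 65 else chr(c))
    return "".join(out)


def naive_rank(bwt: str, c: str, i: int) -> int:
    return bwt[:i].count(c)


def naive_count_array(seqs: list[str]) -> dict[str, int]:
    text = "".join(seqs) + "$" * len(seqs)
    return {c: sum(1 for x in text if x < c or (x == "$" and c != "$"))
            for c in "$ACGNT"}


def naive_find(seqs: list[str], pattern: str) -> tuple[int, int]:
    """Inclusive [a, b] row interval of suffixes starting with pattern."""
    t = concat_with_sentinels(seqs)
    sa = naive_sa(seqs)
    p = pattern.encode()
    rows = [r for r, i in enumerate(sa) if t[i : i + len(p)] == p]
    if not rows:
        return (0, -1)
    return (rows[0], rows[-1])


def naive_seq_of_pos(seqs: list[str], t: int) -> tuple[int, int]:
    for sid, s in enumerate(seqs):
        if t <= len(s):
            return (sid, t)
        t -= len(s) + 1
    raise AssertionError("position out of text")


def naive_locate(seqs: list[str], a: int, b: int) -> list[tuple[int, int]]:
    sa = naive_sa(seqs)
    return [naive_seq_of_pos(seqs, sa[r]) for r in range(a, b + 1)]


# ----------------------------------------------------------------------
# Walk positions, independent of the package's graph helpers.

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def walk_positions(graph, walk_steps) -> list[GraphPosition]:
    out = []
    for v, b in walk_steps:
        out.extend(GraphPosition(v, o, b) for o in range(len(graph.nodes[v])))
    return out


def walk_string(graph, walk_steps) -> str:
    parts = []
    for v, b in walk_steps:
        s = graph.nodes[v]
        parts.append(s if b == 0 else "".join(_COMP[c] for c in reversed(s)))
    return "".join(parts)


def text_sequences(graph):
    """(string, positions) per indexed sequence: forward walk then its
    reverse complement, per haplotype."""
    out = []
    for walk in graph.haplotypes:
        fwd = walk.steps
        rev = [(v, 1 - b) for v, b in reversed(fwd)]
        for steps in (fwd, rev):
            out.append((walk_string(graph, steps), walk_positions(graph, steps)))
    return out


def gold_tag_array(graph) -> list[GraphPosition]:
    """Tags in text order permuted by the naive SA (end rows get END_TAG)."""
    entries = text_sequences(graph)
    seqs = [s for s, _ in entries]
    tags_in_text_order: list[GraphPosition] = []
    for s, pos in entries:
        tags_in_text_order.extend(pos)
        tags_in_text_order.append(END_TAG)
    sa = naive_sa(seqs)
    return [tags_in_text_order[i] for i in sa]


# ----------------------------------------------------------------------
class FlatTags:
    """Flat-array reference with insert_run semantics identical to RLBTree."""

    def __init__(self, N: int, gap, conflict_error):
        self.N = N
        self.gap = gap
        self.conflict_error = conflict_error
        self.arr = [gap] * N

    def insert_run(self, start, length, tag, overwrite=False):
        assert length >= 1 and 0 <= start and start + length <= self.N
        for i in range(start, start + length):
            if self.arr[i] not in (self.gap, tag) and not overwrite:
                raise self.conflict_error(f"row {i}")
        for i in range(start, start + length):
            self.arr[i] = tag

    def runs(self):
        out = []
        for i, t in enumerate(self.arr):
            if not out or out[-1][1] != t:
                out.append((i, t))
        return out

    @property
    def covered(self):
        return sum(1 for t in self.arr if t != self.gap)


# ----------------------------------------------------------------------
def brute_mems(seqs: list[str], query: str, lmin: int):
    """All MEMs as (q_start, q_end) by quadratic substring checking.
    'N' in the query never matches."""

    def occurs(sub: str) -> bool:
        return "N" not in sub and any(sub in s for s in seqs)

    L = len(query)
    out = []
    for i in range(L):
        for j in range(i + lmin, L + 1):
            sub = query[i:j]
            if not occurs(sub):
                break
            left_max = i == 0 or not occurs(query[i - 1 : j])
            right_max = j == L or not occurs(query[i : j + 1])
            if left_max and right_max:
                out.append((i, j))
    return out


def brute_translation(graph, sid: int, p: int, q: int):
    """offset-in-interval -> sorted (sid', offset') pairs sharing the same
    node-start graph position, computed purely from the walks."""
    entries = text_sequences(graph)
    by_tag: dict[GraphPosition, list[tuple[int, int]]] = {}
    for s2, (_, pos) in enumerate(entries):
        for off, t in enumerate(pos):
            if t.o == 0:
                by_tag.setdefault(t, []).append((s2, off))
    _, pos = entries[sid]
    out = {}
    for j in range(p, q):
        t = pos[j]
        if t.o == 0:
            out[j - p] = sorted(by_tag[t])
    return out
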