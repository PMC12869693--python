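"""Multi-string BWT / FM-index over haplotypes plus reverse complements.

The text is ``T = H0 $0 H1 $1 ... H_{M-1} $_{M-1}`` where every input
haplotype is immediately followed by its reverse complement (FMD pairing:
the reverse-complement partner of sequence ``sid`` is ``sid ^ 1``).  The
per-sequence end-markers are distinct and ordered ``$0 < $1 < ... < A`` for
suffix sorting, but collapse to the single symbol ``$`` in the BWT.

The index is run-length encoded and carries r-index style machinery:

* suffix-array samples at the first and last row of every BWT run,
* explicit samples for every row whose BWT character is ``$`` (these rows
  break the LF order-preservation that the run-boundary machinery relies on
  in a multi-string text, so they get their own toeholds),
* a predecessor table for the phi function SA[i] -> SA[i-1], which makes
  ``locate_all`` walk an interval from its toehold without per-row LF chases.

The alphabet order is fixed to ``$ < A < C < G < N < T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .errors import IntegrityError
from .graph import PangenomeGraph, graph_positions_of, rc_walk, revcomp, spell

# Character codes in the collapsed BWT alphabet.
ALPHABET = "$ACGNT"
CODE = {c: i for i, c in enumerate(ALPHABET)}
COMPLEMENT_CODE = {1: 5, 2: 3, 3: 2, 4: 4, 5: 1}  # A<->T, C<->G, N<->N


class LexInterval(NamedTuple):
    """Inclusive interval [a, b] of BWT rows; empty iff b < a."""

    a: int
    b: int

    @property
    def empty(self) -> bool:
        return self.b < self.a

    @property
    def width(self) -> int:
        return max(0, self.b + 1 - self.a)


EMPTY_INTERVAL = LexInterval(0, -1)


class BiInterval(NamedTuple):
    """Synchronized intervals for a pattern (fwd) and its reverse complement
    (rev) on the same index; equal width by construction."""

    fwd: LexInterval
    rev: LexInterval

    @property
    def empty(self) -> bool:
        return self.fwd.empty

    @property
    def width(self) -> int:
        return self.fwd.width


@dataclass
class TextCollection:
    """The indexed sequences, in sid order."""

    sequences: list[str]
    names: list[str]
    rc_paired: bool = True  # sid ^ 1 is the reverse complement of sid

    def __post_init__(self) -> None:
        self.lengths = np.array([len(s) for s in self.sequences], dtype=np.int64)
        # Sequence sid occupies text positions [starts[sid], starts[sid]+len],
        # the last of which is its end-marker.
        self.starts = np.zeros(len(self.sequences), dtype=np.int64)
        if len(self.sequences) > 1:
            self.starts[1:] = np.cumsum(self.lengths[:-1] + 1)
        self.N = int(self.lengths.sum()) + len(self.sequences)

    @property
    def m(self) -> int:
        return len(self.sequences)

    def rc_partner(self, sid: int) -> int:
        if not self.rc_paired:
            raise IntegrityError("text collection has no reverse-complement pairing")
        return sid ^ 1

    def seq_of_text_pos(self, t: int) -> tuple[int, int]:
        """Map a text position to (sid, offset); offset == |H_sid| is the
        end-marker."""
        sid = int(np.searchsorted(self.starts, t, side="right")) - 1
        return sid, int(t - self.starts[sid])

    @classmethod
    def from_strings(cls, seqs: list[str], names=None, rc_paired=False):
        if names is None:
            names = [f"seq{i}" for i in range(len(seqs))]
        return cls(list(seqs), list(names), rc_paired)


def build_text(graph: PangenomeGraph) -> TextCollection:
    """Forward spelling then reverse complement for each haplotype, in walk
    order (FMD convention)."""
    if not graph.haplotypes:
        raise ValueError("graph has no haplotype walks")
    seqs, names = [], []
    for walk in graph.haplotypes:
        s = spell(walk, graph)
        seqs.append(s)
        names.append(walk.name)
        seqs.append(revcomp(s))
        names.append(walk.name + "_rc")
    return TextCollection(seqs, names, rc_paired=True)


# ----------------------------------------------------------------------
# Suffix sorting (prefix doubling on integer ranks)

def _suffix_array(ints: np.ndarray) -> np.ndarray:
    """Manber–Myers prefix doubling; ``ints`` must already give the correct
    first-character order (distinct sentinels included)."""
    n = len(ints)
    rank = np.asarray(ints, dtype=np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        changed = np.ones(n, dtype=bool)
        changed[1:] = (rank[order[1:]] != rank[order[:-1]]) | (
            key2[order[1:]] != key2[order[:-1]]
        )
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order.astype(np.int64)
        k *= 2


@dataclass
class MSBWTIndex:
    """Run-length FM-index with run-boundary SA samples and phi support."""

    text: TextCollection
    run_chars: np.ndarray       # uint8 codes, one per run
    run_starts: np.ndarray      # first row of each run (len r)
    C: np.ndarray               # count array over codes, len 7 (cumulative)
    occ: np.ndarray             # (r, 6): count of code c in rows < run_starts[j]
    sample_first: np.ndarray    # SA at the first row of each run
    sample_last: np.ndarray     # SA at the last row of each run
    dollar_rows: dict[int, int]  # row -> SA for rows whose BWT char is '$'
    phi_keys: np.ndarray        # sorted breakpoint SA values
    phi_vals: np.ndarray        # SA of the preceding row at each breakpoint
    nodes_visited: int = field(default=0, repr=False)

    # -- basic accessors ------------------------------------------------
    @property
    def N(self) -> int:
        return self.text.N

    @property
    def r(self) -> int:
        return len(self.run_chars)

    def run_of_row(self, i: int) -> int:
        return int(np.searchsorted(self.run_starts, i, side="right")) - 1

    def char_at(self, i: int) -> str:
        return ALPHABET[self.run_chars[self.run_of_row(i)]]

    def rank(self, code: int, i: int) -> int:
        """Occurrences of ``code`` in BWT[0..i-1]."""
        if i <= 0:
            return 0
        j = int(np.searchsorted(self.run_starts, i - 1, side="right")) - 1
        n = int(self.occ[j, code])
        if self.run_chars[j] == code:
            n += i - int(self.run_starts[j])
        return n

    # -- FM operations --------------------------------------------------
    def lf_char(self, c: str, i: int) -> int:
        """C[c] + rank_BWT(c, i)."""
        if c not in CODE:
            raise ValueError(f"character {c!r} not in alphabet {ALPHABET!r}")
        if not 0 <= i <= self.N:
            raise ValueError(f"row {i} out of range [0, {self.N}]")
        code = CODE[c]
        return int(self.C[code]) + self.rank(code, i)

    def lf(self, i: int) -> int:
        """LF(i) = LF(BWT[i], i)."""
        j = self.run_of_row(i)
        code = int(self.run_chars[j])
        return int(self.C[code]) + int(self.occ[j, code]) + (i - int(self.run_starts[j]))

    def backward_search(self, pattern: str) -> LexInterval:
        """Rows whose suffixes start with ``pattern`` (empty pattern -> all)."""
        a, b = 0, self.N - 1
        for c in reversed(pattern):
            a = self.lf_char(c, a)
            b = self.lf_char(c, b + 1) - 1
            if b < a:
                return EMPTY_INTERVAL
        return LexInterval(a, b)

    # -- locate machinery ----------------------------------------------
    def sa_at(self, i: int) -> int:
        """SA[i] from run-boundary samples: LF-walk to the nearest toehold."""
        if not 0 <= i < self.N:
            raise ValueError(f"row {i} out of range [0, {self.N})")
        t = 0
        while True:
            if i in self.dollar_rows:
                return self.dollar_rows[i] + t
            j = self.run_of_row(i)
            if i == self.run_starts[j]:
                return int(self.sample_first[j]) + t
            last = (
                int(self.run_starts[j + 1]) - 1 if j + 1 < self.r else self.N - 1
            )
            if i == last:
                return int(self.sample_last[j]) + t
            # BWT[i] is a regular character here ('$' rows were caught above),
            # so stepping LF moves to the suffix starting one position earlier.
            code = int(self.run_chars[j])
            i = int(self.C[code]) + int(self.occ[j, code]) + (i - int(self.run_starts[j]))
            t += 1

    def phi(self, t: int) -> int:
        """SA value of the row just above the row holding SA value ``t``."""
        idx = int(np.searchsorted(self.phi_keys, t, side="right")) - 1
        if idx < 0:
            raise IntegrityError(f"phi has no predecessor for SA value {t}")
        return int(self.phi_vals[idx]) + (t - int(self.phi_keys[idx]))

    def sequence_of_row(self, i: int) -> tuple[int, int]:
        """(sid, offset) of suffix SA[i]; offset == |H_sid| is the end-marker."""
        return self.text.seq_of_text_pos(self.sa_at(i))

    def locate_all(self, iv: LexInterval) -> list[tuple[int, int]]:
        """One (sid, offset) per row of ``iv`` in row order, derived from the
        toehold at the interval end via phi."""
        if iv.empty:
            return []
        if not (0 <= iv.a and iv.b < self.N):
            raise ValueError(f"interval {iv} out of bounds")
        vals = [self.sa_at(iv.b)]
        for _ in range(iv.b - iv.a):
            vals.append(self.phi(vals[-1]))
        return [self.text.seq_of_text_pos(t) for t in reversed(vals)]

    def row_of_seq_pos(self, sid: int, offset: int) -> int:
        """Inverse of sequence_of_row: LF-step back from the end-marker row
        of ``sid`` (which is row sid itself)."""
        L = int(self.text.lengths[sid])
        if not 0 <= offset <= L:
            raise ValueError(f"offset {offset} out of range for sequence {sid} (len {L})")
        row = sid
        for _ in range(L - offset):
            row = self.lf(row)
        return row

    # -- bidirectional (FMD) extension ----------------------------------
    def bi_all(self) -> BiInterval:
        full = LexInterval(0, self.N - 1)
        return BiInterval(full, full)

    def _interval_counts(self, iv: LexInterval) -> np.ndarray:
        w = np.zeros(6, dtype=np.int64)
        for code in range(6):
            w[code] = self.rank(code, iv.b + 1) - self.rank(code, iv.a)
        return w

    def bi_extend_backward(self, bi: BiInterval, c: str) -> BiInterval:
        """Extend the pattern P to cP, keeping the reverse-complement
        interval synchronized (small-alphabet cumulative-width rule)."""
        if bi.empty:
            return BiInterval(EMPTY_INTERVAL, EMPTY_INTERVAL)
        code = CODE[c]
        if code == 0:
            raise ValueError("cannot extend with the end-marker")
        w = self._interval_counts(bi.fwd)
        if w[code] == 0:
            return BiInterval(EMPTY_INTERVAL, EMPTY_INTERVAL)
        new_a = int(self.C[code]) + self.rank(code, bi.fwd.a)
        fwd = LexInterval(new_a, new_a + int(w[code]) - 1)
        # Rows of the rev interval subdivide by the character following the
        # reverse-complement pattern, in alphabet order; the sub-block for x
        # has width w[comp(x)] (and the '$' block, width w[0], comes first).
        rev_a = bi.rev.a + int(w[0])
        comp_c = COMPLEMENT_CODE[code]
        for x in (1, 2, 3, 4, 5):
            if x == comp_c:
                break
            rev_a += int(w[COMPLEMENT_CODE[x]])
        rev = LexInterval(rev_a, rev_a + int(w[code]) - 1)
        return BiInterval(fwd, rev)

    def bi_extend_forward(self, bi: BiInterval, c: str) -> BiInterval:
        """Extend P to Pc: backward extension of the complement on the
        reverse-complement side, with the components swapped."""
        comp_c = ALPHABET[COMPLEMENT_CODE[CODE[c]]]
        ext = self.bi_extend_backward(BiInterval(bi.rev, bi.fwd), comp_c)
        return BiInterval(ext.rev, ext.fwd)


def build_msbwt(text: TextCollection) -> MSBWTIndex:
    """Index construction by suffix sorting the concatenated text.

    Sentinels are given distinct integer codes below 'A' (ordered by sid) for
    sorting, then collapsed to '$' in the stored BWT.
    """
    m = text.m
    if m == 0:
        raise ValueError("empty text collection")
    N = text.N
    ints = np.empty(N, dtype=np.int64)
    for sid, s in enumerate(text.sequences):
        start = int(text.starts[sid])
        seq_codes = np.frombuffer(s.encode(), dtype=np.uint8)
        lut = np.zeros(256, dtype=np.int64)
        for ch, code in CODE.items():
            lut[ord(ch)] = m + code
        ints[start : start + len(s)] = lut[seq_codes]
        ints[start + len(s)] = sid  # distinct ordered sentinel
    sa = _suffix_array(ints)

    prev = ints[(sa - 1) % N]
    bwt = np.where(prev < m, 0, prev - m).astype(np.uint8)

    boundaries = np.flatnonzero(np.diff(bwt)) + 1
    run_starts = np.concatenate(([0], boundaries)).astype(np.int64)
    run_chars = bwt[run_starts]
    run_ends = np.concatenate((run_starts[1:], [N])) - 1

    counts = np.bincount(bwt, minlength=6).astype(np.int64)
    C = np.zeros(7, dtype=np.int64)
    C[1:] = np.cumsum(counts)

    r = len(run_starts)
    occ = np.zeros((r, 6), dtype=np.int64)
    lengths = run_ends - run_starts + 1
    for code in range(6):
        contrib = np.where(run_chars == code, lengths, 0)
        occ[1:, code] = np.cumsum(contrib)[:-1]

    sample_first = sa[run_starts].astype(np.int64)
    sample_last = sa[run_ends].astype(np.int64)

    dollar_row_idx = np.flatnonzero(bwt == 0)
    dollar_rows = {int(i): int(sa[i]) for i in dollar_row_idx}

    # phi breakpoints: run starts, plus every row adjacent to a '$' BWT char
    # (where LF order preservation across equal characters does not give
    # SA[LF(i)] = SA[i] - 1 in a multi-string text).
    bp = set(int(x) for x in run_starts)
    for i in dollar_row_idx:
        if i >= 1:
            bp.add(int(i))
        if i + 1 < N:
            bp.add(int(i) + 1)
    keys, vals = [], []
    for s in bp:
        keys.append(int(sa[s]))
        vals.append(int(sa[s - 1]) if s > 0 else int(sa[N - 1]))
    order = np.argsort(keys)
    phi_keys = np.asarray(keys, dtype=np.int64)[order]
    phi_vals = np.asarray(vals, dtype=np.int64)[order]

    return MSBWTIndex(
        text=text,
        run_chars=run_chars,
        run_starts=run_starts,
        C=C,
        occ=occ,
        sample_first=sample_first,
        sample_last=sample_last,
        dollar_rows=dollar_rows,
        phi_keys=phi_keys,
        phi_vals=phi_vals,
    )


def bwt_string(index: MSBWTIndex) -> str:
    """The BWT as a string (collapsed end-markers); mainly for tests/reports."""
    out = []
    starts = index.run_starts
    ends = np.concatenate((starts[1:], [index.N]))
    for c, s, e in zip(index.run_chars, starts, ends):
        out.append(ALPHABET[c] * int(e - s))
    return "".join(out)


def text_positions_in_order(graph: PangenomeGraph):
    """Graph positions of every text base in text order, one list per
    sequence (forward walk, then reverse-complement walk, per haplotype)."""
    out = []
    for walk in graph.haplotypes:
        out.append(graph_positions_of(walk, graph))
        out.append(graph_positions_of(rc_walk(walk), graph))
    return out
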