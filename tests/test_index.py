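"""FM-index operations against the naive full-suffix-sort oracle."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pantag import (
    LexInterval,
    TextCollection,
    build_msbwt,
    build_text,
    bwt_string,
    revcomp,
)

import oracles as O

dna = st.text(alphabet="ACGT", min_size=1, max_size=25)


def make_index(seqs, rc_paired=False):
    return build_msbwt(TextCollection.from_strings(seqs, rc_paired=rc_paired))


def test_known_small_examples():
    idx = make_index(["ACG"])
    assert bwt_string(idx) == "G$AC"
    assert idx.lf_char("C", 3) == 2
    assert idx.backward_search("CG") == LexInterval(2, 2)
    assert idx.backward_search("T").empty
    assert idx.backward_search("") == LexInterval(0, 3)
    assert idx.locate_all(idx.backward_search("CG")) == [(0, 1)]

    idx2 = make_index(["A", "C"])
    assert bwt_string(idx2) == "AC$$"
    # the '$' characters at rows 2 and 3 are the end-markers of sequences 1
    # and 0 respectively (they precede the suffixes "A$0..." and "C$1")
    assert idx2.sequence_of_row(2) == (0, 0)
    assert idx2.sequence_of_row(3) == (1, 0)
    # end-marker rows sort by sequence id
    assert idx2.sequence_of_row(0) == (0, 1)
    assert idx2.sequence_of_row(1) == (1, 1)


def test_lf_char_edges():
    idx = make_index(["ACGT", "GGA"])
    for c in "$ACGNT":
        assert idx.lf_char(c, 0) == idx.C[ "$ACGNT".index(c)]
    assert idx.lf_char("$", idx.N) == 2
    with pytest.raises(ValueError):
        idx.lf_char("X", 0)


@given(st.lists(dna, min_size=1, max_size=5), st.data())
@settings(max_examples=60, deadline=None)
def test_index_matches_oracle(seqs, data):
    idx = make_index(seqs)
    assert bwt_string(idx) == O.naive_bwt(seqs)
    sa = O.naive_sa(seqs)
    row = data.draw(st.integers(0, idx.N - 1))
    assert idx.sa_at(row) == sa[row]
    assert idx.sequence_of_row(row) == O.naive_seq_of_pos(seqs, sa[row])
    pat = data.draw(dna)
    iv = idx.backward_search(pat)
    na, nb = O.naive_find(seqs, pat)
    assert (iv.a, iv.b) == (na, nb) or (iv.empty and nb < na)
    if not iv.empty:
        assert idx.locate_all(iv) == O.naive_locate(seqs, na, nb)


def test_full_interval_locates_every_position():
    seqs = ["ACGTACG", "TTGA"]
    idx = make_index(seqs)
    got = sorted(idx.locate_all(LexInterval(0, idx.N - 1)))
    want = sorted(
        (sid, off) for sid, s in enumerate(seqs) for off in range(len(s) + 1)
    )
    assert got == want


def test_row_of_seq_pos_is_inverse():
    rng = random.Random(5)
    seqs = ["".join(rng.choice("ACGT") for _ in range(rng.randint(2, 30))) for _ in range(4)]
    idx = make_index(seqs)
    for row in range(idx.N):
        sid, off = idx.sequence_of_row(row)
        assert idx.row_of_seq_pos(sid, off) == row
    assert idx.row_of_seq_pos(2, len(seqs[2])) == 2  # end-marker row
    with pytest.raises(ValueError):
        idx.row_of_seq_pos(0, len(seqs[0]) + 1)


def test_lf_injective_and_cycles_visit_own_sequence():
    seqs = ["GATTACA", "CATCAT"]
    idx = make_index(seqs)
    sa = O.naive_sa(seqs)
    non_dollar = [i for i in range(idx.N) if idx.char_at(i) != "$"]
    images = [idx.lf(i) for i in non_dollar]
    assert len(set(images)) == len(images)
    for sid, s in enumerate(seqs):
        row, seen = sid, set()
        for _ in range(len(s)):
            row = idx.lf(row)
            seen.add(idx.sa_at(row))
        start = sum(len(x) + 1 for x in seqs[:sid])
        assert seen == set(range(start, start + len(s)))


def test_run_count_matches_oracle_segments():
    rng = random.Random(6)
    for _ in range(20):
        seqs = ["".join(rng.choice("ACGT") for _ in range(rng.randint(1, 50)))
                for _ in range(rng.randint(1, 5))]
        idx = make_index(seqs)
        bwt = O.naive_bwt(seqs)
        segs = 1 + sum(1 for a, b in zip(bwt, bwt[1:]) if a != b)
        assert idx.r == segs


# ---------------------------------------------------------------------
# bidirectional (FMD) extension

def rc_text(rng, n_seqs=2):
    seqs = []
    for _ in range(n_seqs):
        s = "".join(rng.choice("ACGT") for _ in range(rng.randint(3, 25)))
        seqs += [s, revcomp(s)]
    return seqs


def test_bi_extension_equals_backward_search():
    rng = random.Random(7)
    for _ in range(15):
        seqs = rc_text(rng)
        idx = make_index(seqs, rc_paired=True)
        for _ in range(25):
            pat = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 6)))
            bi = idx.bi_all()
            for c in reversed(pat):
                bi = idx.bi_extend_backward(bi, c)
                if not bi.empty:
                    assert bi.fwd.width == bi.rev.width
            iv = idx.backward_search(pat)
            assert (bi.empty and iv.empty) or bi.fwd == iv
            if not bi.empty:
                assert bi.rev == idx.backward_search(revcomp(pat))
            fbi = idx.bi_all()
            for c in pat:
                fbi = idx.bi_extend_forward(fbi, c)
            assert (fbi.empty and iv.empty) or fbi.fwd == iv


def test_extending_empty_stays_empty():
    idx = make_index(["ACGT", revcomp("ACGT")], rc_paired=True)
    bi = idx.bi_extend_backward(idx.bi_all(), "T")
    while not bi.empty:
        bi = idx.bi_extend_backward(bi, "T")
    assert idx.bi_extend_backward(bi, "A").empty
    assert idx.bi_extend_forward(bi, "A").empty


# ---------------------------------------------------------------------
def test_build_text_fmd_pairing(toy):
    text = build_text(toy)
    assert text.m == 2 * len(toy.haplotypes)
    for sid in range(text.m):
        partner = text.rc_partner(sid)
        assert partner == sid ^ 1
        assert text.sequences[partner] == revcomp(text.sequences[sid])
    assert text.N == sum(len(s) for s in text.sequences) + text.m
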