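"""Coordinate translation: sampled tag arrays and the two-phase query."""

import pytest

from pantag import (
    GraphPosition,
    TagArray,
    build_sampled,
    build_tag_array,
    find_sequences,
    find_tags,
    random_pangenome,
    translate,
)

import oracles as O


@pytest.fixture(scope="module")
def dup_build():
    """Duplicate-haplotype pangenome: mut_rate 0 makes all walks identical."""
    g = random_pangenome(n_nodes=6, n_haps=2, mut_rate=0.0, seed=21)
    index, tags, _ = build_tag_array(g, k=5, degree=8)
    return g, index, tags, build_sampled(tags)


@pytest.fixture(scope="module")
def var_build(small_pangenome):
    index, tags, _ = build_tag_array(small_pangenome, k=5, degree=8)
    return small_pangenome, index, tags, build_sampled(tags)


def test_build_sampled_keeps_only_node_starts(var_build):
    _, _, tags, sampled = var_build
    assert sampled.size <= tags.run_count
    assert all(t[1] == 0 and t[0] != 0 for t in sampled.tags)
    kept = {(int(s), GraphPosition(*t)) for s, t in zip(sampled.starts, sampled.tags)}
    want = {
        (int(s), GraphPosition(*t))
        for s, t in zip(tags.starts, tags.tags)
        if t[1] == 0 and t[0] != 0
    }
    assert kept == want


def test_all_interior_tags_gives_empty_sampled():
    arr = TagArray.from_runs([(0, GraphPosition(1, 2, 0)), (5, GraphPosition(2, 1, 0))], N=9)
    assert build_sampled(arr).size == 0


def test_unit_nodes_sample_everything():
    g = random_pangenome(n_nodes=6, n_haps=2, mut_rate=0.0, seed=3, node_len=(1, 1))
    _, tags, _ = build_tag_array(g, k=3, degree=8)
    sampled = build_sampled(tags)
    reserved = sum(1 for t in tags.tags if t[0] == 0)
    assert sampled.size == tags.run_count - reserved


def test_find_tags_matches_walk_brute_force(var_build):
    g, index, _, sampled = var_build
    entries = O.text_sequences(g)
    for sid in (0, 1, 3):
        _, pos = entries[sid]
        L = len(pos)
        for p, q in [(0, L), (1, L // 2), (L // 3, L // 3 + 8)]:
            if not 0 <= p < q <= L:
                continue
            got = find_tags(index, sampled, sid, p, q)
            want = [(j - p, pos[j]) for j in range(p, q) if pos[j].o == 0]
            assert got == want, (sid, p, q)


def test_interval_inside_one_node_translates_to_nothing(var_build):
    g, index, _, sampled = var_build
    # find a node of length >= 3 on haplotype 0 and query strictly inside it
    pos = O.text_sequences(g)[0][1]
    for j in range(len(pos) - 1):
        if pos[j].o == 1 and pos[j + 1].o == 2:  # interior stretch
            assert find_tags(index, sampled, 0, j, j + 1) == []
            return
    pytest.skip("no node of length >= 3 on haplotype 0")


def test_whole_haplotype_yields_one_tag_per_step(var_build):
    g, index, _, sampled = var_build
    walk = g.haplotypes[0]
    L = int(index.text.lengths[0])
    got = find_tags(index, sampled, 0, 0, L)
    assert len(got) == len(walk.steps)
    assert [t.v for _, t in got] == [v for v, _ in walk.steps]


def test_find_sequences_is_the_master_property(var_build):
    g, index, _, sampled = var_build
    entries = O.text_sequences(g)
    by_tag = {}
    for sid, (_, pos) in enumerate(entries):
        for off, t in enumerate(pos):
            if t.o == 0:
                by_tag.setdefault(t, []).append((sid, off))
    for tag, want in by_tag.items():
        assert find_sequences(index, sampled, tag) == sorted(want)


def test_duplicate_haplotypes_mirror_each_other(dup_build):
    g, index, _, sampled = dup_build
    L = int(index.text.lengths[0])
    rep = translate(index, sampled, 0, 0, L)
    assert rep.entries, "expected node starts in a whole-haplotype query"
    for e in rep.entries:
        sids = {s for s, _, _ in e.matches}
        assert {0, 2} <= sids  # both identical forward haplotypes
        offs = {s: o for s, o, _ in e.matches}
        assert offs[0] == offs[2]  # identical walks share offsets
        assert any(not other for _, _, other in e.matches)  # self-hit present


def test_forward_rc_coherence(var_build):
    """A node-start hit on a forward sequence implies the mirrored node-start
    hit on its reverse-complement partner."""
    g, index, _, sampled = var_build
    node_len = {v: len(s) for v, s in g.nodes.items()}
    entries = O.text_sequences(g)
    checked = 0
    for tag, offs in list(sampled.value_index.items())[:10]:
        for sid, off in find_sequences(index, sampled, tag):
            L = len(entries[sid][0])
            mirror_tag = GraphPosition(tag.v, 0, 1 - tag.b)
            mirror_off = L - off - node_len[tag.v]
            assert (sid ^ 1, mirror_off) in find_sequences(index, sampled, mirror_tag)
            checked += 1
    assert checked > 0


def test_translate_equals_brute_force_map(var_build):
    g, index, _, sampled = var_build
    entries = O.text_sequences(g)
    for sid in (0, 2, 5):
        L = len(entries[sid][0])
        for p in range(0, L - 1, 5):
            q = min(L, p + 12)
            rep = translate(index, sampled, sid, p, q)
            got = {
                e.query_offset: sorted((s, o) for s, o, _ in e.matches)
                for e in rep.entries
            }
            assert got == O.brute_translation(g, sid, p, q)


def test_bad_interval_rejected(var_build):
    _, index, _, sampled = var_build
    with pytest.raises(ValueError):
        find_tags(index, sampled, 0, 5, 5)
    with pytest.raises(ValueError):
        find_sequences(index, sampled, GraphPosition(1, 2, 0))
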