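"""Construction pipeline: stages, gold oracle, grouped extension, merging."""

import json
from pathlib import Path

import pytest

from pantag import (
    GraphPosition,
    RLBTree,
    anchor_unique_kmers,
    build_component,
    build_msbwt,
    build_tag_array,
    build_text,
    extend_anchors,
    fill_gaps,
    grouped_predecessor_graph,
    merge_components,
    random_pangenome,
    unique_kmers,
)
from pantag.graph import END_TAG, GAP_TAG

import oracles as O


def expand(tags):
    return [GraphPosition(*row) for row in tags.expand()]


def staged_build(graph, k, degree=8):
    """Run the pipeline stage by stage, returning per-row snapshots."""
    text = build_text(graph)
    index = build_msbwt(text)
    tree = RLBTree(index.N, degree=degree)
    tree.insert_run(0, text.m, END_TAG)
    kmers = unique_kmers(graph, k)
    r1 = anchor_unique_kmers(index, tree, kmers)
    snap1 = {i: t for i, t in _rows(tree, index.N)}
    r2 = extend_anchors(graph, index, tree, kmers)
    snap2 = {i: t for i, t in _rows(tree, index.N)}
    r3 = fill_gaps(graph, index, tree)
    return index, tree, (r1, r2, r3), snap1, snap2


def _rows(tree, N):
    runs = tree.runs()
    for (s, t), (s2, _) in zip(runs, runs[1:]):
        for i in range(s, s2):
            yield i, t


def test_pipeline_equals_gold_oracle_on_toy(toy_build):
    toy, index, tags, report = toy_build
    assert expand(tags) == O.gold_tag_array(toy)


def test_toy_matches_checked_in_fixture(toy_build):
    _, _, tags, _ = toy_build
    with open(Path(__file__).parent / "data" / "toy_tags.json") as fh:
        frozen = [GraphPosition(*t) for t in json.load(fh)["tags"]]
    assert expand(tags) == frozen


def test_stage_coverage_monotone_and_complete(small_pangenome):
    index, tree, reports, snap1, snap2 = staged_build(small_pangenome, k=5)
    r1, r2, r3 = reports
    assert 0 <= r1.coverage <= r2.coverage <= r3.coverage == 1.0
    assert tree.covered_count == index.N


def test_anchor_rows_carry_the_anchor_tag(small_pangenome):
    """Every row inside a unique k-mer's interval has the k-mer's position
    as its true (oracle) tag."""
    g = small_pangenome
    text = build_text(g)
    index = build_msbwt(text)
    gold = O.gold_tag_array(g)
    for km, pos in unique_kmers(g, 5).items():
        iv = index.backward_search(km)
        assert not iv.empty
        for row in range(iv.a, iv.b + 1):
            assert gold[row] == pos, (km, row)


def test_extension_only_fills_gap_rows(small_pangenome):
    _, _, _, snap1, snap2 = staged_build(small_pangenome, k=5)
    for i, t in snap1.items():
        if t != GAP_TAG:
            assert snap2[i] == t, f"stage 2 changed row {i}"


def test_fill_gaps_alone_builds_the_array(small_pangenome):
    g = small_pangenome
    _, tags_full, _ = build_tag_array(g, k=5, degree=8)
    _, tags_fill_only, report = build_tag_array(g, k=5, degree=8, run_stage12=False)
    assert tags_full == tags_fill_only
    assert [s.stage for s in report.stages] == ["fill"]


def test_grouped_predecessor_rule_extends_two_of_five():
    """Five predecessors ending A, A, A, T, C: extension passes through the
    T and C branches only."""
    g = grouped_predecessor_graph()
    index, tree, _, snap1, snap2 = staged_build(g, k=4)
    z = g.id_of("z")
    p4, p5 = g.id_of("p4"), g.id_of("p5")
    # The anchor AAGC sits at the start of node z; its T/C-branch extensions
    # tag the last base of p4 and p5.
    t_iv = index.backward_search("TAAGC")
    c_iv = index.backward_search("CAAGC")
    assert not t_iv.empty and not c_iv.empty
    for row in range(t_iv.a, t_iv.b + 1):
        assert snap2[row] == GraphPosition(p4, 2, 0)
    for row in range(c_iv.a, c_iv.b + 1):
        assert snap2[row] == GraphPosition(p5, 2, 0)
    # The shared A branch is ambiguous: rows of A·AAGC remain gaps.
    a_iv = index.backward_search("AAAGC")
    assert not a_iv.empty
    for row in range(a_iv.a, a_iv.b + 1):
        assert snap2[row] == GAP_TAG
    # Exactly the two unambiguous branches were extended from the z anchor.
    branch_tags = {t for t in snap2.values() if t.v in (p4, p5) and t.o == 2}
    assert branch_tags == {GraphPosition(p4, 2, 0), GraphPosition(p5, 2, 0)}


@pytest.mark.parametrize("seed", range(10))
def test_gold_oracle_on_random_pangenomes(seed):
    g = random_pangenome(
        n_nodes=6 + seed, n_haps=2 + seed % 3, mut_rate=0.1 * (seed % 4), seed=seed
    )
    _, tags, report = build_tag_array(g, k=5, degree=8)
    assert expand(tags) == O.gold_tag_array(g)
    covs = [s.coverage for s in report.stages]
    assert covs == sorted(covs)


def test_single_component_build_equals_whole_build(small_pangenome):
    g = small_pangenome
    assert g.n_components == 1
    cb = build_component(g, 0, k=5, degree=8)
    _, tags, _ = build_tag_array(g, k=5, degree=8)
    assert cb.tags == tags


def test_merge_two_components_equals_whole_build():
    g = random_pangenome(n_nodes=8, n_haps=3, mut_rate=0.2, seed=9, n_components=2)
    comps = sorted(set(g.components.values()))
    assert len(comps) == 2
    parts = []
    total_runs = 0
    for c in comps:
        cb = build_component(g, c, k=5, degree=8)
        parts.append((c, cb.tags))
        total_runs += cb.tags.run_count
    whole_index = build_msbwt(build_text(g))
    merged = merge_components(whole_index, parts, g)
    _, whole_tags, _ = build_tag_array(g, k=5, degree=8)
    assert merged == whole_tags
    assert merged.run_count >= max(p.run_count for _, p in parts)


def test_merge_single_component_is_identity(small_pangenome):
    g = small_pangenome
    index, tags, _ = build_tag_array(g, k=5, degree=8)
    assert merge_components(index, [(0, tags)], g) == tags


def test_component_without_walks_rejected():
    g = random_pangenome(n_nodes=8, n_haps=2, mut_rate=0.1, seed=3, n_components=2)
    # strip the walks of component 1 to fabricate an uncovered component
    comp1_nodes = {v for v, c in g.components.items() if c == 1}
    g.haplotypes = [w for w in g.haplotypes if w.steps[0][0] not in comp1_nodes]
    for i, w in enumerate(g.haplotypes):
        w.sid = i
    with pytest.raises(ValueError):
        build_component(g, 1, k=5)
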