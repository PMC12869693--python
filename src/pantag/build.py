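"""Three-stage tag-array construction, per-component builds, and merging.

Stage 1 anchors the BWT with unique k-mers: a k-mer with a single starting
graph position tags its whole lexicographic interval [A, B] with that
position (run length B + 1 - A).  Stage 2 extends anchors backwards through
the graph: a unique predecessor base c turns a graph-unique U into a
graph-unique cU, and when several predecessor nodes exist the extension
passes through every base contributed by exactly one of them (e.g.
predecessors ending A, A, A, T, C extend through T and C only).  Stage 3
walks every haplotype (and reverse-complement) backwards with LF from its
end-marker row and fills the remaining gaps from the walk's known positions,
guaranteeing total coverage.

Per-component construction runs the pipeline on each weakly connected
component (chromosome proxy) and interleaves the component arrays into the
whole-text array using the sequence number of every global BWT row.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .errors import IntegrityError
from .graph import (
    END_TAG,
    GAP_TAG,
    GraphPosition,
    PangenomeGraph,
    graph_positions_of,
    predecessors,
    rc_walk,
    unique_kmers,
)
from .index import LexInterval, MSBWTIndex, build_msbwt, build_text
from .rlbtree import RLBTree
from .tagarray import TagArray, freeze


@dataclass
class StageReport:
    stage: str
    rows_covered: int      # cumulative coverage after this stage (non-END rows)
    coverage: float        # rows_covered / coverable rows
    runs_inserted: int = 0
    rounds: int = 0


@dataclass
class BuildReport:
    N: int
    n_sequences: int
    k: int
    stages: list[StageReport] = field(default_factory=list)

    def coverage_by_stage(self) -> dict[str, float]:
        return {s.stage: s.coverage for s in self.stages}


@dataclass
class ComponentBuild:
    component: int | None
    graph: PangenomeGraph
    index: MSBWTIndex
    tags: TagArray
    report: BuildReport


def anchor_unique_kmers(
    index: MSBWTIndex, tree: RLBTree, kmers: dict[str, GraphPosition]
) -> StageReport:
    """Stage 1: one run per unique k-mer over its whole BWT interval."""
    inserted = 0
    for km, pos in kmers.items():
        iv = index.backward_search(km)
        if iv.empty:
            continue
        tree.insert_run(iv.a, iv.width, pos)
        inserted += 1
    return StageReport(
        stage="anchor",
        rows_covered=tree.covered_count,
        coverage=_coverage(tree, index),
        runs_inserted=inserted,
    )


def extend_anchors(
    graph: PangenomeGraph,
    index: MSBWTIndex,
    tree: RLBTree,
    kmers: dict[str, GraphPosition],
    max_rounds: int = 256,
) -> StageReport:
    """Stage 2: breadth-first backward extension of the anchor intervals.

    Each worklist item is (interval, graph position of the pattern start).
    Branches re-enter the worklist (extensions are themselves extended) and
    stop at ambiguity, empty intervals, sequence starts, or the round cap.
    Extension only ever fills GAP rows: an overlapping anchor necessarily
    carries the same tag, so equal-tag absorption keeps this idempotent.
    """
    work: deque[tuple[LexInterval, GraphPosition]] = deque()
    seen: set[int] = set()
    for km, pos in kmers.items():
        iv = index.backward_search(km)
        if not iv.empty:
            work.append((iv, pos))
            seen.add(iv.a)
    inserted = 0
    rounds = 0
    while work and rounds < max_rounds:
        rounds += 1
        for _ in range(len(work)):
            iv, pos = work.popleft()
            by_char: dict[str, list[GraphPosition]] = {}
            for c, ppos in predecessors(pos, graph):
                by_char.setdefault(c, []).append(ppos)
            for c, plist in by_char.items():
                if len(plist) != 1:
                    continue  # base contributed by several predecessors: ambiguous
                ppos = plist[0]
                a = index.lf_char(c, iv.a)
                b = index.lf_char(c, iv.b + 1) - 1
                if b < a or a in seen:
                    continue
                seen.add(a)
                tree.insert_run(a, b + 1 - a, ppos)
                inserted += 1
                work.append((LexInterval(a, b), ppos))
    return StageReport(
        stage="extend",
        rows_covered=tree.covered_count,
        coverage=_coverage(tree, index),
        runs_inserted=inserted,
        rounds=rounds,
    )


def fill_gaps(graph: PangenomeGraph, index: MSBWTIndex, tree: RLBTree) -> StageReport:
    """Stage 3: backward haplotype traversal filling every remaining gap.

    Correct on its own (stages 1-2 only reduce its work); a disagreement
    between an existing tag and the traversal tag is an integrity error.
    """
    inserted = 0
    for sid in range(index.text.m):
        walk = graph.haplotypes[sid // 2]
        if sid % 2 == 1:
            walk = rc_walk(walk)
        positions = graph_positions_of(walk, graph)
        row = sid  # end-marker row of this sequence
        for j in range(len(positions) - 1, -1, -1):
            row = index.lf(row)
            tag = tree.tag_at(row)
            if tag == GAP_TAG:
                tree.insert_run(row, 1, positions[j])
                inserted += 1
            elif tag != positions[j]:
                raise IntegrityError(
                    f"stage mismatch at BWT row {row}: tree has {tag}, "
                    f"traversal of sequence {sid} offset {j} gives {positions[j]}"
                )
    return StageReport(
        stage="fill",
        rows_covered=tree.covered_count,
        coverage=_coverage(tree, index),
        runs_inserted=inserted,
    )


def _coverage(tree: RLBTree, index: MSBWTIndex) -> float:
    """Covered fraction of coverable rows (end-marker rows excluded)."""
    coverable = index.N - index.text.m
    end_rows = min(tree.covered_count, index.text.m)
    return (tree.covered_count - end_rows) / coverable if coverable else 1.0


def build_tag_array(
    graph: PangenomeGraph,
    k: int = 31,
    degree: int = 64,
    max_rounds: int = 256,
    run_stage12: bool = True,
) -> tuple[MSBWTIndex, TagArray, BuildReport]:
    """Full pipeline on a (sub)graph: text, index, three stages, freeze."""
    if not graph.haplotypes:
        raise ValueError("graph (or component) has haplotype-free text: nothing to build")
    text = build_text(graph)
    index = build_msbwt(text)
    tree = RLBTree(index.N, degree=degree)
    # End-marker rows (the first m rows) have no graph base; they get the
    # reserved END tag so the array stays total.
    tree.insert_run(0, text.m, END_TAG)
    report = BuildReport(N=index.N, n_sequences=text.m, k=k)
    if run_stage12:
        kmers = unique_kmers(graph, k)
        report.stages.append(anchor_unique_kmers(index, tree, kmers))
        report.stages.append(extend_anchors(graph, index, tree, kmers, max_rounds))
    report.stages.append(fill_gaps(graph, index, tree))
    return index, freeze(tree), report


def build_component(
    graph: PangenomeGraph,
    component: int,
    k: int = 31,
    degree: int = 64,
    max_rounds: int = 256,
) -> ComponentBuild:
    """Run the pipeline on one weakly connected component."""
    sub = graph.subgraph(component)
    if sub.nodes and not sub.haplotypes:
        raise ValueError(
            f"component {component} has nodes but no haplotype walks; "
            "its text would remain untagged"
        )
    index, tags, report = build_tag_array(sub, k=k, degree=degree, max_rounds=max_rounds)
    return ComponentBuild(component, sub, index, tags, report)


def document_array(index: MSBWTIndex) -> np.ndarray:
    """Sequence number of every BWT row, via one LF walk per sequence."""
    doc = np.full(index.N, -1, dtype=np.int64)
    for sid in range(index.text.m):
        doc[sid] = sid
        row = sid
        for _ in range(int(index.text.lengths[sid])):
            row = index.lf(row)
            doc[row] = sid
    if (doc < 0).any():
        raise IntegrityError("document array has unreached rows")
    return doc


def merge_components(
    whole_index: MSBWTIndex,
    parts: list[tuple[int, TagArray]],
    graph: PangenomeGraph,
) -> TagArray:
    """Interleave per-component tag arrays into the whole-text array.

    For every global BWT row, the owning sequence determines the component;
    that component's array is consumed one row at a time through a cursor.
    The relative lexicographic order of one component's suffixes is the same
    in the global and per-component BWTs, so the cursors read each part
    strictly in order.
    """
    doc = document_array(whole_index)
    hap_comp = [graph.component_of_walk(w) for w in graph.haplotypes]
    arrays = dict(parts)
    cursors = {c: [0, 0] for c in arrays}  # component -> [run idx, offset in run]

    out_runs: list[tuple[int, GraphPosition]] = []
    for i in range(whole_index.N):
        comp = hap_comp[int(doc[i]) // 2]
        if comp not in arrays:
            raise IntegrityError(f"row {i} maps to component {comp} with no tag array")
        arr = arrays[comp]
        cur = cursors[comp]
        if cur[0] >= arr.run_count:
            raise IntegrityError(f"component {comp} tag array exhausted at global row {i}")
        tag = GraphPosition(*arr.tags[cur[0]])
        if not out_runs or out_runs[-1][1] != tag:
            out_runs.append((i, tag))
        cur[1] += 1
        run_end = int(arr.starts[cur[0] + 1]) if cur[0] + 1 < arr.run_count else arr.N
        if int(arr.starts[cur[0]]) + cur[1] >= run_end:
            cur[0] += 1
            cur[1] = 0
    for comp, arr in arrays.items():
        if cursors[comp][0] != arr.run_count or cursors[comp][1] != 0:
            raise IntegrityError(f"component {comp} tag array has leftover rows")
    return TagArray.from_runs(out_runs, whole_index.N)
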