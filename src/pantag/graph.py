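"""Pangenome graph model: oriented nodes, edges, haplotype walks, GFA1 I/O.

A pangenome graph stores DNA sequences on nodes; haplotypes are embedded as
walks, i.e. ordered lists of oriented node visits.  Every base spelled by a
walk has a *graph position* ``(v, o, b)``: node id ``v``, 0-based offset ``o``
counted along the traversal direction, and orientation ``b`` (0 = the node's
forward strand, 1 = its reverse strand).  Node id 0 is reserved and never
names a real node; reserved tags (gap / end-marker / sentinel) use it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .errors import GFAFormatError

DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Alphabet allowed in node sequences.
VALID_BASES = frozenset("ACGTN")


def revcomp(s: str) -> str:
    """Reverse complement of a DNA string (N is self-complementary)."""
    return s.translate(DNA_COMPLEMENT)[::-1]


class GraphPosition(NamedTuple):
    """A position in the graph: ``(v, o, b)``.

    Ordered lexicographically, which fixes the deterministic output order of
    distinct-tag queries.
    """

    v: int
    o: int
    b: int


#: Reserved tags (v = 0 never names a real node).
GAP_TAG = GraphPosition(0, 0, 0)      # unassigned rows during construction
END_TAG = GraphPosition(0, 1, 0)      # end-marker (sentinel suffix) rows
SENTINEL_TAG = GraphPosition(0, 2, 0)  # RLB+ tree terminator at position N


def is_reserved(tag: GraphPosition) -> bool:
    return tag[0] == 0


@dataclass
class HaplotypeWalk:
    """One haplotype embedded in the graph as an oriented node walk."""

    sid: int
    name: str
    steps: list[tuple[int, int]]  # (node id, orientation)


@dataclass
class PangenomeGraph:
    nodes: dict[int, str]
    node_names: dict[int, str]
    edges: set[tuple[tuple[int, int], tuple[int, int]]]
    haplotypes: list[HaplotypeWalk]
    components: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.components:
            self.components = _weak_components(self.nodes, self.edges)
        self._name_to_id = {n: v for v, n in self.node_names.items()}

    def id_of(self, name: str) -> int:
        return self._name_to_id[name]

    def node_len(self, v: int) -> int:
        return len(self.nodes[v])

    @property
    def n_components(self) -> int:
        return len(set(self.components.values())) if self.components else 0

    def component_of_walk(self, walk: HaplotypeWalk) -> int:
        return self.components[walk.steps[0][0]]

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check the structural invariants; raise GFAFormatError on failure."""
        for v, seq in self.nodes.items():
            if v <= 0:
                raise GFAFormatError(f"node id {v} is not a positive integer")
            if not seq or not set(seq) <= VALID_BASES:
                raise GFAFormatError(
                    f"node {self.node_names.get(v, v)} has an empty or non-ACGTN sequence"
                )
        for (v1, b1), (v2, b2) in self.edges:
            if v1 not in self.nodes or v2 not in self.nodes:
                raise GFAFormatError(f"edge ({v1},{b1})->({v2},{b2}) names a missing node")
            if ((v2, 1 - b2), (v1, 1 - b1)) not in self.edges:
                raise GFAFormatError(
                    f"edge set not closed under reversal at ({v1},{b1})->({v2},{b2})"
                )
        for walk in self.haplotypes:
            if not walk.steps:
                raise GFAFormatError(f"walk {walk.name} is empty")
            comp = self.components[walk.steps[0][0]]
            for (u, bu), (v, bv) in zip(walk.steps, walk.steps[1:]):
                if ((u, bu), (v, bv)) not in self.edges:
                    raise GFAFormatError(
                        f"walk {walk.name} uses unsupported edge ({u},{bu})->({v},{bv})"
                    )
            for v, _ in walk.steps:
                if self.components[v] != comp:
                    raise GFAFormatError(f"walk {walk.name} crosses components")
        for i, walk in enumerate(self.haplotypes):
            if walk.sid != i:
                raise GFAFormatError(f"walk {walk.name} has sid {walk.sid}, expected {i}")

    # ------------------------------------------------------------------
    def subgraph(self, component: int) -> "PangenomeGraph":
        """Restriction to one weakly connected component.

        Node ids (and their names) are preserved so that graph positions in a
        per-component build agree with a whole-graph build.  Haplotypes keep
        their relative order and are renumbered densely.
        """
        keep = {v for v, c in self.components.items() if c == component}
        haps = []
        for walk in self.haplotypes:
            if walk.steps[0][0] in keep:
                haps.append(HaplotypeWalk(len(haps), walk.name, list(walk.steps)))
        return PangenomeGraph(
            nodes={v: self.nodes[v] for v in keep},
            node_names={v: self.node_names[v] for v in keep},
            edges={e for e in self.edges if e[0][0] in keep and e[1][0] in keep},
            haplotypes=haps,
            components={v: component for v in keep},
        )


def _weak_components(nodes: dict[int, str], edges: Iterable) -> dict[int, int]:
    """Weakly connected components (orientation ignored), numbered 0.. in
    ascending order of their smallest node id."""
    parent = {v: v for v in nodes}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (v1, _), (v2, _) in edges:
        r1, r2 = find(v1), find(v2)
        if r1 != r2:
            parent[r2] = r1
    roots: dict[int, int] = {}
    comp = {}
    for v in sorted(nodes):
        r = find(v)
        if r not in roots:
            roots[r] = len(roots)
        comp[v] = roots[r]
    return comp


# ----------------------------------------------------------------------
# GFA1 I/O (S, L, P, W lines)

def _symmetrize(edges: set) -> set:
    out = set(edges)
    for (v1, b1), (v2, b2) in edges:
        out.add(((v2, 1 - b2), (v1, 1 - b1)))
    return out


def read_gfa(path) -> PangenomeGraph:
    """Parse a GFA1 file with S and L lines plus P and/or W walk lines.

    Internal node ids are assigned in S-line order starting at 1.  P-line
    overlaps must be ``*`` or all-``0M``; edges are symmetrized.
    """
    with open(path) as fh:
        return parse_gfa(fh.read())


def parse_gfa(text: str) -> PangenomeGraph:
    nodes: dict[int, str] = {}
    names: dict[int, str] = {}
    name_to_id: dict[str, int] = {}
    edges: set = set()
    walks: list[HaplotypeWalk] = []

    def resolve(name: str, line: str) -> int:
        if name not in name_to_id:
            raise GFAFormatError(f"unknown segment {name!r} referenced on line: {line}")
        return name_to_id[name]

    deferred: list[tuple[str, str]] = []  # L/P/W lines, processed after all S lines
    for raw in text.splitlines():
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        kind = line.split("\t", 1)[0]
        if kind == "S":
            f = line.split("\t")
            if len(f) < 3:
                raise GFAFormatError(f"bad S line: {line}")
            name, seq = f[1], f[2].upper()
            if name in name_to_id:
                raise GFAFormatError(f"duplicate segment name {name!r}")
            if not seq or not set(seq) <= VALID_BASES:
                raise GFAFormatError(f"segment {name!r} has empty or non-ACGTN sequence")
            vid = len(nodes) + 1
            nodes[vid] = seq
            names[vid] = name
            name_to_id[name] = vid
        elif kind in ("L", "P", "W"):
            deferred.append((kind, line))
        # H and other record types are ignored

    for kind, line in deferred:
        f = line.split("\t")
        if kind == "L":
            if len(f) < 6:
                raise GFAFormatError(f"bad L line: {line}")
            v1 = resolve(f[1], line)
            v2 = resolve(f[3], line)
            b1 = 0 if f[2] == "+" else 1
            b2 = 0 if f[4] == "+" else 1
            edges.add(((v1, b1), (v2, b2)))
        elif kind == "P":
            if len(f) < 3:
                raise GFAFormatError(f"bad P line: {line}")
            pname = f[1]
            if len(f) > 3 and f[3] not in ("*", ""):
                for ov in f[3].split(","):
                    if ov not in ("0M", "*"):
                        raise GFAFormatError(
                            f"P line {pname!r} has unsupported overlap {ov!r}"
                        )
            steps = []
            if not f[2]:
                raise GFAFormatError(f"empty walk on P line {pname!r}")
            for tok in f[2].split(","):
                if not tok or tok[-1] not in "+-":
                    raise GFAFormatError(f"bad step {tok!r} on P line {pname!r}")
                steps.append((resolve(tok[:-1], line), 0 if tok[-1] == "+" else 1))
            walks.append(HaplotypeWalk(len(walks), pname, steps))
        elif kind == "W":
            if len(f) < 7:
                raise GFAFormatError(f"bad W line: {line}")
            wname = f"{f[1]}#{f[2]}#{f[3]}"
            steps = []
            spec = f[6]
            if not spec:
                raise GFAFormatError(f"empty walk on W line {wname!r}")
            i = 0
            while i < len(spec):
                orient = spec[i]
                if orient not in "><":
                    raise GFAFormatError(f"bad W walk {spec!r} at char {i}")
                j = i + 1
                while j < len(spec) and spec[j] not in "><":
                    j += 1
                steps.append((resolve(spec[i + 1 : j], line), 0 if orient == ">" else 1))
                i = j
            walks.append(HaplotypeWalk(len(walks), wname, steps))

    if not walks:
        raise GFAFormatError("GFA has no P or W lines (no haplotype walks)")
    # Walk steps imply edges even when L lines are sparse in hand-written files;
    # the GFA spec requires the links, so missing ones are an error.
    edges = _symmetrize(edges)
    g = PangenomeGraph(nodes, names, edges, walks)
    g.validate()
    return g


def write_gfa(graph: PangenomeGraph, path=None) -> str:
    """Serialize back to GFA1 (S/L/P lines).  Deterministic byte output."""
    out = ["H\tVN:Z:1.0"]
    for v in sorted(graph.nodes):
        out.append(f"S\t{graph.node_names[v]}\t{graph.nodes[v]}")
    seen = set()
    for (v1, b1), (v2, b2) in sorted(graph.edges):
        rev = ((v2, 1 - b2), (v1, 1 - b1))
        if rev in seen:
            continue
        seen.add(((v1, b1), (v2, b2)))
        out.append(
            "L\t{}\t{}\t{}\t{}\t0M".format(
                graph.node_names[v1], "+-"[b1], graph.node_names[v2], "+-"[b2]
            )
        )
    for walk in graph.haplotypes:
        steps = ",".join(graph.node_names[v] + "+-"[b] for v, b in walk.steps)
        out.append(f"P\t{walk.name}\t{steps}\t*")
    text = "\n".join(out) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ----------------------------------------------------------------------
# Walk geometry

def spell(walk: HaplotypeWalk, graph: PangenomeGraph) -> str:
    """The DNA string a walk spells (reverse complement for b = 1 steps)."""
    parts = []
    for v, b in walk.steps:
        seq = graph.nodes[v]
        parts.append(seq if b == 0 else revcomp(seq))
    return "".join(parts)


def rc_walk(walk: HaplotypeWalk, name_suffix: str = "_rc") -> HaplotypeWalk:
    """The reverse-complement walk: steps reversed, orientations flipped."""
    return HaplotypeWalk(
        walk.sid, walk.name + name_suffix, [(v, 1 - b) for v, b in reversed(walk.steps)]
    )


def graph_positions_of(walk: HaplotypeWalk, graph: PangenomeGraph) -> list[GraphPosition]:
    """One GraphPosition per spelled base, offsets counted along traversal."""
    out = []
    for v, b in walk.steps:
        out.extend(GraphPosition(v, o, b) for o in range(len(graph.nodes[v])))
    return out


def base_at(graph: PangenomeGraph, pos: GraphPosition) -> str:
    """The base emitted at a graph position (complemented on strand 1)."""
    seq = graph.nodes[pos.v]
    if pos.b == 0:
        return seq[pos.o]
    return seq[len(seq) - 1 - pos.o].translate(DNA_COMPLEMENT)


def predecessors(
    pos: GraphPosition, graph: PangenomeGraph
) -> list[tuple[str, GraphPosition]]:
    """All (base, position) pairs that can immediately precede ``pos`` along
    an edge-consistent path.

    Within a node there is exactly one predecessor; at a node start (o = 0)
    there is one per incoming oriented edge, contributing the final base of
    the predecessor node in its traversal orientation.
    """
    if pos.o > 0:
        p = GraphPosition(pos.v, pos.o - 1, pos.b)
        return [(base_at(graph, p), p)]
    out = []
    for (u, bu), (v, bv) in graph.edges:
        if (v, bv) == (pos.v, pos.b):
            p = GraphPosition(u, len(graph.nodes[u]) - 1, bu)
            out.append((base_at(graph, p), p))
    out.sort(key=lambda cp: cp[1])
    return out


def unique_kmers(graph: PangenomeGraph, k: int) -> dict[str, GraphPosition]:
    """K-mers with exactly one distinct starting graph position.

    Occurrences are enumerated over every haplotype walk *and* its reverse
    complement (the doubled text that the index stores), so uniqueness is
    decided over both strands.  K-mers containing N never become anchors.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    occ: dict[str, set[GraphPosition]] = {}
    for walk in graph.haplotypes:
        for w in (walk, rc_walk(walk)):
            s = spell(w, graph)
            pos = graph_positions_of(w, graph)
            for i in range(len(s) - k + 1):
                km = s[i : i + k]
                if "N" in km:
                    continue
                occ.setdefault(km, set()).add(pos[i])
    return {km: next(iter(ps)) for km, ps in occ.items() if len(ps) == 1}
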