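"""Synthetic pangenome generation and hand-built test graphs.

``random_pangenome`` emulates a small bubble-rich pangenome: a random
backbone chopped into nodes, SNP bubbles (alternate node alleles), short
deletions (node skips) and insertions (extra nodes), applied per node at a
configurable rate, with every variant branch guaranteed to be used by at
least one haplotype so the graph carries no walk-free nodes.  Multiple
weakly connected components model separate chromosomes.  It does not model
realistic human variation (no long repeats, no structural rearrangements,
uniform base composition); it exists to exercise the index machinery.
"""

from __future__ import annotations

import numpy as np

from .graph import HaplotypeWalk, PangenomeGraph, parse_gfa

#: Hand-built worked example: head node, a SNP bubble, a middle node, a
#: second bubble, and a shared two-node tail; 3 haplotypes.
TOY_GFA = """\
H	VN:Z:1.0
S	s1	GATT
S	s2	ACA
S	s3	AGA
S	s4	TTGC
S	s5	C
S	s6	G
S	s7	TAGGA
S	s8	CAT
L	s1	+	s2	+	0M
L	s1	+	s3	+	0M
L	s2	+	s4	+	0M
L	s3	+	s4	+	0M
L	s4	+	s5	+	0M
L	s4	+	s6	+	0M
L	s5	+	s7	+	0M
L	s6	+	s7	+	0M
L	s7	+	s8	+	0M
P	hap1	s1+,s2+,s4+,s5+,s7+,s8+	*
P	hap2	s1+,s3+,s4+,s6+,s7+,s8+	*
P	hap3	s1+,s2+,s4+,s6+,s7+,s8+	*
"""

#: A node-start with five predecessor nodes whose final bases are
#: A, A, A, T, C: the grouped-predecessor extension rule passes through the
#: T and C branches only (each base contributed by exactly one node).  The
#: three A-branches are distinct nodes with identical sequence, so their
#: k-mers are shared and never unique.
GROUPED_PRED_GFA = """\
H	VN:Z:1.0
S	p1	TTA
S	p2	TTA
S	p3	TTA
S	p4	CGT
S	p5	GAC
S	z	AAGCGTCC
L	p1	+	z	+	0M
L	p2	+	z	+	0M
L	p3	+	z	+	0M
L	p4	+	z	+	0M
L	p5	+	z	+	0M
P	hap1	p1+,z+	*
P	hap2	p2+,z+	*
P	hap3	p3+,z+	*
P	hap4	p4+,z+	*
P	hap5	p5+,z+	*
"""


def toy_graph() -> PangenomeGraph:
    return parse_gfa(TOY_GFA)


def grouped_predecessor_graph() -> PangenomeGraph:
    return parse_gfa(GROUPED_PRED_GFA)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def random_pangenome(
    n_nodes: int = 30,
    n_haps: int = 4,
    mut_rate: float = 0.08,
    seed: int = 0,
    n_components: int = 1,
    node_len: tuple[int, int] = (3, 8),
) -> PangenomeGraph:
    """Deterministic random pangenome; ``n_nodes``/``n_haps`` are per
    component.  ``mut_rate`` is the per-backbone-node probability of a
    variant site (SNP bubble, deletion, or insertion)."""
    if n_nodes < 3 or n_haps < 1 or not 0 <= mut_rate <= 1 or n_components < 1:
        raise ValueError("degenerate generator parameters")
    lo, hi = node_len
    if not 1 <= lo <= hi:
        raise ValueError(f"bad node length range {node_len}")
    rng = np.random.default_rng(seed)

    nodes: dict[int, str] = {}
    walks: list[list[tuple[int, int]]] = []
    names: list[str] = []
    next_id = 1

    for comp in range(n_components):
        backbone = []
        for _ in range(n_nodes):
            nodes[next_id] = _random_seq(rng, int(rng.integers(lo, hi + 1)))
            backbone.append(next_id)
            next_id += 1
        # Variant sites on interior backbone nodes.
        sites: dict[int, tuple[str, int]] = {}  # backbone idx -> (kind, aux node id)
        for bi in range(1, n_nodes - 1):
            if rng.random() >= mut_rate:
                continue
            kind = rng.choice(["snp", "del", "ins"])
            if kind == "snp":
                ref = nodes[backbone[bi]]
                p = int(rng.integers(len(ref)))
                alt_base = rng.choice([b for b in "ACGT" if b != ref[p]])
                nodes[next_id] = ref[:p] + alt_base + ref[p + 1 :]
                sites[bi] = ("snp", next_id)
                next_id += 1
            elif kind == "del":
                sites[bi] = ("del", 0)
            else:
                nodes[next_id] = _random_seq(rng, int(rng.integers(lo, hi + 1)))
                sites[bi] = ("ins", next_id)
                next_id += 1

        for h in range(n_haps):
            steps: list[tuple[int, int]] = []
            for bi, v in enumerate(backbone):
                site = sites.get(bi)
                # Haplotype 0 takes the reference allele everywhere so the
                # backbone is always realized; others flip a fair coin.
                take_alt = h > 0 and site is not None and rng.random() < 0.5
                if site is None or not take_alt:
                    steps.append((v, 0))
                    continue
                kind, aux = site
                if kind == "snp":
                    steps.append((aux, 0))
                elif kind == "del":
                    continue
                else:  # insertion after the reference node
                    steps.append((v, 0))
                    steps.append((aux, 0))
            walks.append(steps)
            names.append(f"hap_c{comp}_{h}")

    # Drop alt nodes no haplotype used, renumber densely, derive edges from
    # the walks (then symmetrize via the graph validator's convention).
    used = sorted({v for steps in walks for v, _ in steps})
    remap = {v: i + 1 for i, v in enumerate(used)}
    final_nodes = {remap[v]: nodes[v] for v in used}
    node_names = {remap[v]: f"s{remap[v]}" for v in used}
    edges = set()
    haplotypes = []
    for i, steps in enumerate(walks):
        mapped = [(remap[v], b) for v, b in steps]
        for a, b in zip(mapped, mapped[1:]):
            edges.add((a, b))
            edges.add(((b[0], 1 - b[1]), (a[0], 1 - a[1])))
        haplotypes.append(HaplotypeWalk(i, names[i], mapped))
    g = PangenomeGraph(final_nodes, node_names, edges, haplotypes)
    g.validate()
    return g
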