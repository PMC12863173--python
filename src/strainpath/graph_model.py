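"""Variation-graph data model and GFA I/O.

A variation graph represents one species' pangenome: nodes are genomic
segments, edges are adjacencies observed in at least one strain genome, and
each strain genome is embedded as a path. Per-species graphs are merged into
a single super-graph with disjoint node-id ranges so that one read-to-graph
alignment pass covers every species at once.

Orientation conventions follow GFA: a step ``(v, '+')`` traverses node *v*
forward, ``(v, '-')`` traverses its reverse complement. An edge
``(a, oa) -> (b, ob)`` is equivalent to its reverse-complement twin
``(b, flip(ob)) -> (a, flip(oa))``; edges are stored canonically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = [
    "SegmentNode",
    "GraphPath",
    "VariationGraph",
    "SuperGraph",
    "Triplet",
    "GfaParseError",
    "read_gfa",
    "write_gfa",
    "fragment_linear_genome",
    "merge_graphs",
    "enumerate_strain_specific_triplets",
    "canonical_triple",
]

Step = tuple[int, str]  # (node_id, orientation '+'/'-')

_FLIP = {"+": "-", "-": "+"}


class GfaParseError(ValueError):
    """Malformed GFA input; message names the offending line."""


@dataclass(frozen=True)
class SegmentNode:
    """A segment node: a stretch of genomic sequence."""

    node_id: int
    sequence: str

    def __post_init__(self) -> None:
        if self.node_id <= 0:
            raise ValueError(f"node_id must be positive, got {self.node_id}")
        if len(self.sequence) < 1:
            raise ValueError(f"node {self.node_id}: empty sequence")

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass
class GraphPath:
    """One strain genome embedded as an oriented walk through the graph."""

    strain_id: str
    steps: list[Step]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError(f"path {self.strain_id}: empty step list")

    def genome_length_bp(self, graph: "VariationGraph") -> int:
        """Total path length in bases, counting repeated nodes per visit."""
        return sum(graph.nodes[v].length_bp for v, _ in self.steps)

    def node_multiplicity(self) -> dict[int, int]:
        """Visit count per node id (paths may revisit segments)."""
        mult: dict[int, int] = {}
        for v, _ in self.steps:
            mult[v] = mult.get(v, 0) + 1
        return mult


def _canonical_edge(a: Step, b: Step) -> tuple[Step, Step]:
    fwd = (a, b)
    rev = ((b[0], _FLIP[b[1]]), (a[0], _FLIP[a[1]]))
    return min(fwd, rev)


@dataclass
class VariationGraph:
    """A species-specific pangenome graph (one path per strain)."""

    species_taxid: int = 0
    nodes: dict[int, SegmentNode] = field(default_factory=dict)
    edges: set[tuple[Step, Step]] = field(default_factory=set)
    paths: dict[str, GraphPath] = field(default_factory=dict)
    #: original GFA segment names when the file used non-integer names
    name_map: dict[int, str] = field(default_factory=dict)

    def add_node(self, node_id: int, sequence: str) -> SegmentNode:
        if node_id in self.nodes:
            raise ValueError(f"duplicate node_id {node_id}")
        node = SegmentNode(node_id, sequence.upper())
        self.nodes[node_id] = node
        return node

    def add_edge(self, a: Step, b: Step) -> None:
        for v, o in (a, b):
            if v not in self.nodes:
                raise ValueError(f"edge endpoint {v} not in graph")
            if o not in "+-":
                raise ValueError(f"bad orientation {o!r}")
        self.edges.add(_canonical_edge(a, b))

    def has_edge(self, a: Step, b: Step) -> bool:
        return _canonical_edge(a, b) in self.edges

    def add_path(self, strain_id: str, steps: Sequence[Step],
                 add_missing_edges: bool = False) -> GraphPath:
        if strain_id in self.paths:
            raise ValueError(f"duplicate path {strain_id}")
        path = GraphPath(strain_id, list(steps))
        for v, _ in path.steps:
            if v not in self.nodes:
                raise ValueError(
                    f"path {strain_id}: step references unknown segment {v}")
        for a, b in zip(path.steps, path.steps[1:]):
            if add_missing_edges:
                self.edges.add(_canonical_edge(a, b))
            elif not self.has_edge(a, b):
                raise ValueError(
                    f"path {strain_id}: consecutive steps {a}->{b} "
                    f"not connected by an edge")
        self.paths[strain_id] = path
        return path

    # -- derived quantities -------------------------------------------------

    def path_length_bp(self, strain_id: str) -> int:
        return self.paths[strain_id].genome_length_bp(self)

    def mean_genome_length_bp(self) -> float:
        """Arithmetic mean of the strain path lengths (used for c_i)."""
        if not self.paths:
            raise ValueError("graph has no paths")
        return sum(p.genome_length_bp(self) for p in self.paths.values()) / len(self.paths)

    def validate(self, strict: bool = True) -> None:
        """Check graph invariants.

        With ``strict=False`` (external GFA), an edge traversed by no path
        only raises a warning — external builders may emit extra edges.
        """
        if not self.paths:
            raise ValueError("graph must contain at least one path")
        traversed: set[tuple[Step, Step]] = set()
        for path in self.paths.values():
            for a, b in zip(path.steps, path.steps[1:]):
                traversed.add(_canonical_edge(a, b))
        orphan = self.edges - traversed
        if orphan:
            msg = f"{len(orphan)} edge(s) traversed by no path"
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)


@dataclass(frozen=True)
class Triplet:
    """Three consecutive oriented steps of one strain's path."""

    steps: tuple[Step, Step, Step]
    owner_strain: str
    is_strain_specific: bool


def canonical_triple(t: tuple[Step, Step, Step]) -> tuple[Step, ...]:
    """Orientation-invariant key: a triple equals its reverse traversal."""
    rev = tuple((v, _FLIP[o]) for v, o in reversed(t))
    return min(t, rev)


# ---------------------------------------------------------------------------
# GFA I/O
# ---------------------------------------------------------------------------

def _parse_p_steps(text: str, line_no: int) -> list[tuple[str, str]]:
    steps = []
    for token in text.split(","):
        if len(token) < 2 or token[-1] not in "+-":
            raise GfaParseError(f"line {line_no}: bad path step {token!r}")
        steps.append((token[:-1], token[-1]))
    return steps


def _parse_walk(text: str, line_no: int) -> list[tuple[str, str]]:
    steps = []
    i = 0
    while i < len(text):
        mark = text[i]
        if mark not in "><":
            raise GfaParseError(f"line {line_no}: bad walk syntax at {text[i:]!r}")
        j = i + 1
        while j < len(text) and text[j] not in "><":
            j += 1
        name = text[i + 1:j]
        if not name:
            raise GfaParseError(f"line {line_no}: empty segment name in walk")
        steps.append((name, "+" if mark == ">" else "-"))
        i = j
    if not steps:
        raise GfaParseError(f"line {line_no}: empty walk")
    return steps


def read_gfa(source, species_taxid: int = 0) -> VariationGraph:
    """Parse a GFA 1.0/1.1 file into a :class:`VariationGraph`.

    Accepts paths as P lines or W (walk) lines; both dialects yield the same
    structure. Segment names that are not all positive integers are
    renumbered 1..N in order of appearance, with originals kept in
    ``graph.name_map``.

    Parameters
    ----------
    source
        A file path or an open text handle.
    species_taxid
        Taxid to stamp on the graph (GFA itself carries none).
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()

    seg_seqs: dict[str, str] = {}
    links: list[tuple[tuple[str, str], tuple[str, str]]] = []
    raw_paths: list[tuple[str, list[tuple[str, str]]]] = []

    for line_no, line in enumerate(lines, 1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag == "S":
            if len(fields) < 3:
                raise GfaParseError(f"line {line_no}: S line needs name and sequence")
            name, seq = fields[1], fields[2]
            if seq == "*" or not seq:
                raise GfaParseError(f"line {line_no}: segment {name} has no sequence")
            if name in seg_seqs:
                raise GfaParseError(f"line {line_no}: duplicate segment {name}")
            seg_seqs[name] = seq.upper()
        elif tag == "L":
            if len(fields) < 5:
                raise GfaParseError(f"line {line_no}: truncated L line")
            links.append(((fields[1], fields[2]), (fields[3], fields[4])))
        elif tag == "P":
            if len(fields) < 3:
                raise GfaParseError(f"line {line_no}: truncated P line")
            raw_paths.append((fields[1], _parse_p_steps(fields[2], line_no)))
        elif tag == "W":
            if len(fields) < 7:
                raise GfaParseError(f"line {line_no}: truncated W line")
            sample, hap = fields[1], fields[2]
            name = sample if all(p[0] != sample for p in raw_paths) else f"{sample}#{hap}"
            raw_paths.append((name, _parse_walk(fields[6], line_no)))
        # H and unknown record types are ignored

    if not seg_seqs:
        raise GfaParseError("no S lines found")

    integer_named = all(n.isdigit() and int(n) > 0 for n in seg_seqs)
    if integer_named:
        ids = {name: int(name) for name in seg_seqs}
    else:
        ids = {name: i for i, name in enumerate(seg_seqs, 1)}

    graph = VariationGraph(species_taxid=species_taxid)
    for name, seq in seg_seqs.items():
        graph.add_node(ids[name], seq)
    if not integer_named:
        graph.name_map = {ids[n]: n for n in seg_seqs}

    def resolve(step: tuple[str, str], kind: str) -> Step:
        name, orient = step
        if name not in ids:
            raise GfaParseError(f"{kind} references unknown segment {name!r}")
        return ids[name], orient

    for a, b in links:
        graph.add_edge(resolve(a, "L line"), resolve(b, "L line"))
    for strain_id, steps in raw_paths:
        resolved = [resolve(s, f"path {strain_id}") for s in steps]
        # external graphs may omit L lines that paths imply
        graph.add_path(strain_id, resolved, add_missing_edges=not links)
    graph.validate(strict=False)
    return graph


def write_gfa(graph: VariationGraph, dest=None) -> str:
    """Serialize a graph to GFA 1.0 text (S, L, P lines).

    Output is deterministic: segments in ascending node id, links in sorted
    canonical order, paths in lexicographic strain order.
    """
    out = ["H\tVN:Z:1.0"]
    for node_id in sorted(graph.nodes):
        out.append(f"S\t{node_id}\t{graph.nodes[node_id].sequence}")
    for (a, oa), (b, ob) in sorted(graph.edges):
        out.append(f"L\t{a}\t{oa}\t{b}\t{ob}\t0M")
    for strain_id in sorted(graph.paths):
        steps = ",".join(f"{v}{o}" for v, o in graph.paths[strain_id].steps)
        out.append(f"P\t{strain_id}\t{steps}\t*")
    text = "\n".join(out) + "\n"
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            with open(dest, "w") as fh:
                fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Graph construction helpers
# ---------------------------------------------------------------------------

def fragment_linear_genome(genome: str, fragment_bp: int = 1024,
                           species_taxid: int = 0,
                           strain_id: str = "genome") -> VariationGraph:
    """Turn a single linear genome into a chain graph of fixed-size fragments.

    Species represented by a single genome get no variation bubbles; the
    genome is cut into ``fragment_bp``-sized segments (default 1024 bp, the
    last one possibly shorter) chained by a single forward path.
    """
    if not genome:
        raise ValueError("empty genome")
    if fragment_bp < 1:
        raise ValueError("fragment_bp must be >= 1")
    graph = VariationGraph(species_taxid=species_taxid)
    steps: list[Step] = []
    for i, start in enumerate(range(0, len(genome), fragment_bp), 1):
        graph.add_node(i, genome[start:start + fragment_bp])
        steps.append((i, "+"))
    for a, b in zip(steps, steps[1:]):
        graph.add_edge(a, b)
    graph.add_path(strain_id, steps)
    return graph


@dataclass
class SuperGraph:
    """Disjoint union of per-species graphs with renumbered node ids.

    Node-id ranges of distinct species never overlap and no edge crosses a
    species boundary, so a single alignment against the super-graph can be
    binned back to species by node id alone.
    """

    species_graphs: list[VariationGraph]
    id_offsets: dict[int, int]
    #: per species: (lowest node id, highest node id) after remapping
    id_ranges: dict[int, tuple[int, int]]

    @property
    def node_to_species(self) -> dict[int, int]:
        mapping: dict[int, int] = {}
        for g in self.species_graphs:
            for v in g.nodes:
                mapping[v] = g.species_taxid
        return mapping

    def species_of_node(self, node_id: int) -> int:
        for taxid, (lo, hi) in self.id_ranges.items():
            if lo <= node_id <= hi:
                return taxid
        raise KeyError(f"node id {node_id} outside every species range")

    def graph_for(self, species_taxid: int) -> VariationGraph:
        for g in self.species_graphs:
            if g.species_taxid == species_taxid:
                return g
        raise KeyError(f"no graph for species {species_taxid}")


def merge_graphs(graphs: Iterable[VariationGraph]) -> SuperGraph:
    """Merge species graphs into a super-graph with disjoint id ranges.

    Node ids of graph *k* are shifted by the cumulative maximum id of the
    preceding graphs; inputs are left untouched. Each original graph is
    recoverable by restricting to its id range.
    """
    graphs = list(graphs)
    taxids = [g.species_taxid for g in graphs]
    if len(set(taxids)) != len(taxids):
        raise ValueError("duplicate species_taxid among input graphs")

    merged: list[VariationGraph] = []
    offsets: dict[int, int] = {}
    ranges: dict[int, tuple[int, int]] = {}
    offset = 0
    for g in graphs:
        if not g.nodes:
            raise ValueError(f"species {g.species_taxid}: empty graph")
        shifted = VariationGraph(species_taxid=g.species_taxid)
        for v in sorted(g.nodes):
            shifted.add_node(v + offset, g.nodes[v].sequence)
        shifted.edges = {(((a + offset), oa), ((b + offset), ob))
                         for (a, oa), (b, ob) in g.edges}
        for strain_id, path in g.paths.items():
            shifted.paths[strain_id] = GraphPath(
                strain_id, [(v + offset, o) for v, o in path.steps])
        if g.name_map:
            shifted.name_map = {v + offset: n for v, n in g.name_map.items()}
        offsets[g.species_taxid] = offset
        ranges[g.species_taxid] = (offset + min(g.nodes), offset + max(g.nodes))
        merged.append(shifted)
        offset += max(g.nodes)
    return SuperGraph(species_graphs=merged, id_offsets=offsets, id_ranges=ranges)


# ---------------------------------------------------------------------------
# Strain-specific triplets
# ---------------------------------------------------------------------------

def _path_triples(path: GraphPath) -> Iterator[tuple[Step, Step, Step]]:
    s = path.steps
    for i in range(len(s) - 2):
        yield (s[i], s[i + 1], s[i + 2])


def enumerate_strain_specific_triplets(graph: VariationGraph,
                                       strain_id: str) -> set[Triplet]:
    """Consecutive oriented triples unique to one strain within its species.

    A triple of the target strain is *strain-specific* when no other path of
    the same graph contains it consecutively, in either traversal direction
    (a reverse walk visits the same genomic context, so triples are compared
    under reverse-complement canonicalization).
    """
    if strain_id not in graph.paths:
        raise KeyError(f"unknown strain {strain_id!r}")
    others: set[tuple[Step, ...]] = set()
    for sid, path in graph.paths.items():
        if sid == strain_id:
            continue
        for t in _path_triples(path):
            others.add(canonical_triple(t))
    result: set[Triplet] = set()
    for t in _path_triples(graph.paths[strain_id]):
        if canonical_triple(t) not in others:
            result.add(Triplet(steps=t, owner_strain=strain_id,
                               is_strain_specific=True))
    return result
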